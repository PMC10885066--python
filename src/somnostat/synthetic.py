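"""Synthetic spectral-EEG-like indicator series and hypnograms.

The empirical indicators the model was built for are per-epoch spectral
EEG summaries: the score on the first principal component of the EEG power
spectrum (PC1, positive in deep NREM, negative elsewhere) and ln-power
slow-wave activity (SWA).  Real recordings of either are not distributed
here; this module emulates them as the noiseless model trajectory plus
i.i.d. Gaussian epoch noise, with an affine map from the PC1-like scale to
a strictly positive SWA-like scale.  The generator is fully seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import ConfigurationError, ModelParams
from .schedule import NREM, REM, Schedule, WAKE
from .simulate import simulate_protocol

__all__ = ["NoiseModel", "generate_indicator", "generate_hypnogram"]


@dataclass(frozen=True)
class NoiseModel:
    """Homoscedastic Gaussian epoch noise and the PC1->SWA affine map.

    ``swa_affine = (a, b)`` maps a PC1-like value x to a*x + b; the default
    (1.0, 3.0) shifts the indicator onto a positive ln-power-like scale.
    """

    sigma: float = 0.02
    seed: int = 0
    swa_affine: Tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")


def generate_indicator(
    params: Optional[ModelParams] = None,
    schedule: Optional[Schedule] = None,
    noise: Optional[NoiseModel] = None,
    dt: float = 1.0 / 60.0,
    include_wake: bool = False,
    kind: str = "pc1",
) -> pd.DataFrame:
    """Simulate a protocol and emit a noisy observed indicator series.

    Returns the trajectory frame (``time_h, S, s_u, s, state``) with an
    extra ``observed`` column: s(t) plus N(0, sigma^2) noise on sleep
    epochs and, when ``include_wake``, S(t) plus noise on wake epochs
    (NaN otherwise).  ``kind='swa'`` applies the affine map of the noise
    model to the noiseless signal before adding noise.
    """
    params = params or ModelParams()
    noise = noise or NoiseModel()
    if schedule is None:
        from .schedule import build_allnight_schedule

        schedule = build_allnight_schedule()
    if kind not in ("pc1", "swa"):
        raise ConfigurationError(f"kind must be 'pc1' or 'swa', got {kind!r}")
    traj = simulate_protocol(schedule, params, dt=dt)
    df = traj.to_frame()
    rng = np.random.default_rng(noise.seed)
    signal = np.where(df["state"].eq(WAKE), df["S"], df["s"]).astype(float)
    if kind == "swa":
        a, b = noise.swa_affine
        signal = a * signal + b
    observed = signal + rng.normal(0.0, noise.sigma, size=len(df))
    mask = df["state"].isin([NREM, REM]).to_numpy()
    if include_wake:
        mask = mask | df["state"].eq(WAKE).to_numpy()
    df["observed"] = np.where(mask, observed, np.nan)
    return df


def generate_hypnogram(schedule: Schedule, dt: float = 1.0 / 60.0) -> pd.DataFrame:
    """Per-epoch stage labels {W, NREM, REM} for a scheduled-mode protocol.

    Epochs are ``[t, t+dt)``; each is labelled by the scheduled state at
    its midpoint.  Relay-mode schedules have no explicit NREM/REM
    boundaries — simulate first and take the trajectory's state labels.
    """
    if schedule.mode != "scheduled":
        raise ConfigurationError(
            "hypnograms need explicit phase boundaries; simulate the relay-mode "
            "protocol and use the trajectory's state labels instead"
        )
    n = int(round((schedule.end - schedule.start) / dt))
    starts = schedule.start + np.arange(n) * dt
    mids = starts + dt / 2.0
    bounds = np.array([iv.start for iv in schedule.intervals])
    idx = np.clip(np.searchsorted(bounds, mids, side="right") - 1, 0,
                  len(schedule.intervals) - 1)
    label = {WAKE: "W", NREM: "NREM", REM: "REM"}
    stages = np.array(
        [label[schedule.intervals[i].state] for i in idx], dtype=object
    )
    return pd.DataFrame({"time_h": starts, "stage": stages})
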