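"""Reference relay-thermostat oscillator.

An on/off controller heats toward a hot asymptote and cools toward a cold
asymptote, switching at fixed hysteresis bounds around the setpoint.  Each
limb is a pure exponential, so switch times are solved in closed form by
inverting the exponential rather than detected on a sampling grid.  This is
the technical counterpart of a somnostat: once the first bound is reached,
the cycle shape (period, peak, trough) is identical from cycle to cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .core import ConfigurationError

__all__ = ["RelayConfig", "RelayTrace", "simulate_relay", "relay_period"]


@dataclass(frozen=True)
class RelayConfig:
    """Hysteresis band, device asymptotes and time constants of the relay.

    Defaults are demonstration values for a domestic-style thermostat with
    a 1-degree hysteresis band around a 37-degree setpoint.
    """

    setpoint: float = 37.0
    upper_bound: float = 37.5
    lower_bound: float = 36.5
    heat_asymptote: float = 39.0
    cool_asymptote: float = 35.0
    T_heat: float = 0.5
    T_cool: float = 1.0
    initial_temp: float = 36.5
    initial_mode: str = "heating"
    dt: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        if not (self.cool_asymptote < self.lower_bound < self.setpoint
                < self.upper_bound < self.heat_asymptote):
            raise ConfigurationError(
                "relay requires cool_asymptote < lower_bound < setpoint "
                "< upper_bound < heat_asymptote"
            )
        if min(self.T_heat, self.T_cool, self.dt) <= 0:
            raise ConfigurationError("T_heat, T_cool and dt must be > 0")
        if not self.lower_bound <= self.initial_temp <= self.upper_bound:
            raise ConfigurationError("initial_temp must lie within the hysteresis band")
        if self.initial_mode not in ("heating", "cooling"):
            raise ConfigurationError(f"unknown initial_mode {self.initial_mode!r}")


@dataclass
class RelayTrace:
    """Sampled relay trajectory plus the exact switch times."""

    time_h: np.ndarray
    temperature: np.ndarray
    mode: np.ndarray  # 'heating' / 'cooling' per sample
    switch_times: List[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "temperature": self.temperature, "mode": self.mode}
        )


def relay_period(cfg: RelayConfig) -> float:
    """Closed-form steady-state cycle period of the relay oscillator.

    period = T_heat*ln((A_h - L)/(A_h - U)) + T_cool*ln((U - A_c)/(L - A_c))

    with hysteresis bounds L, U and device asymptotes A_h, A_c; this is the
    time to heat across the band plus the time to cool back.
    """
    up = cfg.T_heat * math.log(
        (cfg.heat_asymptote - cfg.lower_bound) / (cfg.heat_asymptote - cfg.upper_bound)
    )
    down = cfg.T_cool * math.log(
        (cfg.upper_bound - cfg.cool_asymptote) / (cfg.lower_bound - cfg.cool_asymptote)
    )
    return up + down


def _time_to_reach(start: float, target: float, asymptote: float, T: float) -> float:
    """Exact time for an exponential limb to reach ``target`` from ``start``."""
    # start and target on the same side of the asymptote; ratio in (0, 1]
    return T * math.log((asymptote - start) / (asymptote - target))


def simulate_relay(cfg: RelayConfig, duration: float) -> RelayTrace:
    """Simulate the relay for ``duration`` hours with analytic switching.

    The trajectory is piecewise exponential; the mode flips heating->cooling
    exactly when temperature reaches the upper bound and cooling->heating
    exactly at the lower bound.  Samples are reported on the ``cfg.dt`` grid.
    """
    if not duration > 0:
        raise ConfigurationError("duration must be > 0")

    # segments: (t_start, temp_start, mode); switch times solved exactly
    segments: List[Tuple[float, float, str]] = [(0.0, cfg.initial_temp, cfg.initial_mode)]
    switches: List[float] = []
    t, temp, mode = segments[0]
    while True:
        if mode == "heating":
            dt_switch = _time_to_reach(temp, cfg.upper_bound, cfg.heat_asymptote, cfg.T_heat)
            nxt = (cfg.upper_bound, "cooling")
        else:
            dt_switch = _time_to_reach(temp, cfg.lower_bound, cfg.cool_asymptote, cfg.T_cool)
            nxt = (cfg.lower_bound, "heating")
        if t + dt_switch >= duration:
            break
        t += dt_switch
        temp, mode = nxt
        switches.append(t)
        segments.append((t, temp, mode))

    n = int(round(duration / cfg.dt))
    time = np.arange(n + 1) * cfg.dt
    starts = np.array([s[0] for s in segments])
    idx = np.minimum(np.searchsorted(starts, time, side="right") - 1, len(segments) - 1)
    temperature = np.empty_like(time)
    mode_arr = np.empty(time.shape, dtype=object)
    for i, (t0, v0, m) in enumerate(segments):
        sel = idx == i
        if not np.any(sel):
            continue
        asym = cfg.heat_asymptote if m == "heating" else cfg.cool_asymptote
        T = cfg.T_heat if m == "heating" else cfg.T_cool
        temperature[sel] = asym - (asym - v0) * np.exp(-(time[sel] - t0) / T)
        mode_arr[sel] = m
    return RelayTrace(time_h=time, temperature=temperature, mode=mode_arr, switch_times=switches)
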