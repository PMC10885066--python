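"""Per-cycle summaries of simulated NREM-REM sleep cycles.

One sleep cycle is one NREM interval together with the REM interval that
follows it.  The quantities summarized here are the model's ordinal
predictions: the mean level and amplitude of the ultradian process s
shrink over the night, the fraction of time s spends below zero grows
from cycle to cycle, and the initial buildup slope at sleep onset
increases with the duration of the preceding wake phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import SomnostatParams
from .schedule import NREM, REM
from .simulate import Trajectory

__all__ = [
    "CycleSummary",
    "summarize_cycles",
    "buildup_steepness",
    "shape_sections",
    "nap_slopes",
]

_TOL = 1e-9


@dataclass(frozen=True)
class CycleSummary:
    cycle: int
    start: float
    end: float
    mean_s: float
    amplitude: float  # within-cycle max(s) - min(s)
    nrem_duration: float
    rem_duration: float
    negative_time: float  # hours with s < 0 (rectangle rule on the grid)
    negative_fraction: float


def _cycle_bounds(traj: Trajectory):
    """(nrem_interval, rem_interval_or_None) pairs; a trailing NREM without
    REM is an incomplete cycle and is dropped."""
    pairs = []
    ivs = traj.intervals
    i = 0
    while i < len(ivs):
        if ivs[i].state == NREM:
            if i + 1 < len(ivs) and ivs[i + 1].state == REM:
                pairs.append((ivs[i], ivs[i + 1]))
                i += 2
                continue
        i += 1
    return pairs


def summarize_cycles(traj: Trajectory) -> List[CycleSummary]:
    """One summary per complete NREM+REM cycle in the trajectory.

    Integrals (mean level, time below zero) use the rectangle rule on the
    trajectory's grid; durations come from the exact realized boundaries.
    Returns an empty list when the trajectory contains no complete cycle.
    """
    out: List[CycleSummary] = []
    t = traj.time_h
    for idx, (nrem, rem) in enumerate(_cycle_bounds(traj), start=1):
        sel = (t >= nrem.start - _TOL) & (t < rem.end - _TOL)
        s = traj.s[sel]
        if s.size == 0:
            continue
        neg = float(np.count_nonzero(s < 0)) * traj.dt
        total = rem.end - nrem.start
        out.append(
            CycleSummary(
                cycle=idx,
                start=nrem.start,
                end=rem.end,
                mean_s=float(np.mean(s)),
                amplitude=float(np.max(s) - np.min(s)),
                nrem_duration=nrem.end - nrem.start,
                rem_duration=rem.end - rem.start,
                negative_time=neg,
                negative_fraction=neg / total,
            )
        )
    return out


def summaries_frame(summaries: List[CycleSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in summaries])


@dataclass(frozen=True)
class Steepness:
    empirical_slope: float  # finite-difference slope over the window
    analytic_slope: float  # (s_u(onset) - s_b) / t_b
    onset: float
    window_h: float


def buildup_steepness(
    traj: Trajectory,
    onset: float,
    s_params: SomnostatParams,
    window_minutes: float = 2.0,
) -> Steepness:
    """Initial steepness of the Process-s buildup at a sleep-episode onset.

    Reports both the finite-difference slope of s over the first
    ``window_minutes`` of sleep and the analytic initial slope
    ``(s_u(onset) - s_b) / t_b`` of the buildup toward the setpoint.
    """
    onsets = [ep[0] for ep in traj.episodes]
    matches = [i for i, o in enumerate(onsets) if abs(o - onset) < 1e-6]
    if not matches:
        raise ValueError(f"{onset} is not a sleep-episode onset of this trajectory")
    w = window_minutes / 60.0
    first_iv = next(iv for iv in traj.intervals
                    if iv.state == NREM and abs(iv.start - onset) < 1e-6)
    ep_end = first_iv.end
    for iv in traj.intervals:
        if iv.start >= ep_end - _TOL and iv.state in (NREM, REM) and abs(
            iv.start - ep_end
        ) < _TOL:
            ep_end = iv.end
    if onset + w > ep_end + _TOL:
        raise ValueError("episode shorter than the steepness window")
    sleep = ~pd.isna(traj.s)
    t_sleep = traj.time_h[sleep]
    s_sleep = traj.s[sleep]
    s0 = float(np.interp(onset, t_sleep, s_sleep))
    s1 = float(np.interp(onset + w, t_sleep, s_sleep))
    su0 = first_iv.su_entry
    analytic = (su0 - s_params.B) / s_params.T_build
    return Steepness(
        empirical_slope=(s1 - s0) / w,
        analytic_slope=analytic,
        onset=onset,
        window_h=w,
    )


def nap_slopes(
    traj: Trajectory, s_params: SomnostatParams, window_minutes: float = 2.0
) -> pd.DataFrame:
    """Buildup steepness at every sleep-episode onset (one row per episode)."""
    rows = []
    for i, (onset, S0) in enumerate(traj.episodes, start=1):
        st = buildup_steepness(traj, onset, s_params, window_minutes)
        rows.append(
            {
                "episode": i,
                "onset": onset,
                "S_at_onset": S0,
                "analytic_slope": st.analytic_slope,
                "empirical_slope": st.empirical_slope,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ShapeSections:
    """Rising / saturation / decaying split of one cycle.

    The decaying section is the REM interval.  Within NREM, the rising
    section ends at the first grid time where the local slope of s falls
    below ``slope_fraction`` of the initial slope; the remainder of NREM is
    the saturation section.  Sections may be empty (a zero-length REM gives
    no decaying section; a very short NREM may have no saturation).
    """

    rising: tuple
    saturation: Optional[tuple]
    decaying: Optional[tuple]


def shape_sections(
    traj: Trajectory, cycle: int, slope_fraction: float = 0.10
) -> ShapeSections:
    """Split cycle number ``cycle`` (1-based) into its three sections."""
    pairs = _cycle_bounds(traj)
    if not 1 <= cycle <= len(pairs):
        raise ValueError(f"trajectory has {len(pairs)} complete cycles, not {cycle}")
    nrem, rem = pairs[cycle - 1]
    t = traj.time_h
    sel = (t >= nrem.start - _TOL) & (t <= nrem.end + _TOL)
    ts, ss = t[sel], traj.s[sel]
    slopes = np.diff(ss) / np.diff(ts)
    split = nrem.end
    if slopes.size and slopes[0] > 0:
        below = np.nonzero(slopes < slope_fraction * slopes[0])[0]
        if below.size:
            split = ts[below[0]]
    rising = (nrem.start, split)
    saturation = (split, nrem.end) if split < nrem.end - _TOL else None
    decaying = (rem.start, rem.end) if rem.end > rem.start + _TOL else None
    return ShapeSections(rising=rising, saturation=saturation, decaying=decaying)
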