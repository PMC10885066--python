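"""Nested-doll simulation of processes S and s over a protocol.

During every wake interval Process S builds up toward its (optionally
circadian-modulated) upper asymptote, continuously across interleaved
naps.  During sleep, Process S *is* the moving setpoint s_u(t) of the
ultradian Process s: it relaxes from its sleep-onset value toward the
baseline setpoint with time constant ``T_set`` while the setpoint clock
advances (cumulative NREM time by default), is frozen during REM, and is
held constant after the NREM phase of the freeze cycle (the fourth by
default) ends.  Process s itself restarts from its lower threshold s_b at
every sleep onset and alternates inverse-exponential NREM buildups toward
the current s_u(t) with exponential REM decays toward s_l.

In ``scheduled`` mode the NREM/REM boundaries come from the schedule; in
``relay`` mode they emerge from the hysteresis thresholds s_d (switch to
REM) and s_b (switch back to NREM), with switch times solved on the
closed-form pieces rather than detected on the sampling grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    ConfigurationError,
    ModelParams,
    SetpointCoupling,
    SomnostatParams,
    UnreachableThresholdError,
    process_S,
)
from .schedule import NREM, REM, SLEEP_WINDOW, WAKE, Interval, Schedule

__all__ = [
    "Trajectory",
    "IntervalRecord",
    "setpoint_trace",
    "simulate_sleep_episode",
    "simulate_protocol",
    "compile_protocol",
    "CompiledProtocol",
]

_TOL = 1e-9


# ---------------------------------------------------------------------------
# piecewise segments

@dataclass
class _Seg:
    """One closed-form piece of the trajectory."""

    start: float
    end: float
    state: str  # WAKE / NREM / REM
    # wake piece
    S_entry: float = math.nan
    # sleep piece
    s_entry: float = math.nan
    su_kind: str = "const"  # 'const' | 'decay'
    su_const: float = math.nan
    su_c0: float = 0.0  # setpoint clock at segment start (decay kind)
    episode_S0: float = math.nan

    def su_at(self, ts: np.ndarray, coupling: SetpointCoupling) -> np.ndarray:
        if self.su_kind == "const":
            return np.full_like(ts, self.su_const, dtype=float)
        b = coupling.s_u_baseline
        c = self.su_c0 + (ts - self.start)
        return b + (self.episode_S0 - b) * np.exp(-c / coupling.T_set)


@dataclass
class IntervalRecord:
    """Realized interval with analytic entry/exit values (continuity audit)."""

    start: float
    end: float
    state: str
    S_entry: float
    S_exit: float
    su_entry: float
    su_exit: float
    s_entry: float
    s_exit: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Trajectory:
    """Aligned time grid with S(t), setpoint s_u(t), s(t) and state labels.

    ``s`` and ``s_u`` are NaN outside sleep: the ultradian process exists
    only within sleep episodes.  ``intervals`` carries the realized phase
    boundaries (emergent ones included, in relay mode) with exact entry and
    exit values; ``episodes`` lists (onset time, S at onset) per sleep
    episode.
    """

    time_h: np.ndarray
    S: np.ndarray
    s_u: np.ndarray
    s: np.ndarray
    state: np.ndarray
    dt: float
    intervals: List[IntervalRecord] = field(default_factory=list)
    episodes: List[Tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "S": self.S,
                "s_u": self.s_u,
                "s": self.s,
                "state": self.state,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        """Rebuild a trajectory (and grid-resolution intervals) from CSV data."""
        t = df["time_h"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ConfigurationError("trajectory needs at least two samples")
        dt = float(np.median(np.diff(t)))
        state = df["state"].to_numpy(dtype=object)
        S = df["S"].to_numpy(dtype=float)
        su = df["s_u"].to_numpy(dtype=float)
        s = df["s"].to_numpy(dtype=float)
        intervals: List[IntervalRecord] = []
        run_start = 0
        bounds = list(np.nonzero(state[1:] != state[:-1])[0] + 1) + [len(t)]
        for b in bounds:
            i, j = run_start, min(b, len(t) - 1)
            intervals.append(
                IntervalRecord(
                    start=t[i], end=t[b] if b < len(t) else t[-1] + dt,
                    state=state[i],
                    S_entry=S[i], S_exit=S[j],
                    su_entry=su[i], su_exit=su[j],
                    s_entry=s[i], s_exit=s[j],
                )
            )
            run_start = b
        episodes = []
        prev_sleep = False
        for iv in intervals:
            is_sleep = iv.state in (NREM, REM)
            if is_sleep and not prev_sleep:
                episodes.append((iv.start, iv.S_entry))
            prev_sleep = is_sleep
        return cls(time_h=t, S=S, s_u=su, s=s, state=state, dt=dt,
                   intervals=intervals, episodes=episodes)


# ---------------------------------------------------------------------------
# episode compilation (Process s within one sleep episode)

def _clock_advances(state: str, coupling: SetpointCoupling) -> bool:
    if coupling.clock_mode == "elapsed_sleep":
        return True
    return state == NREM


def _compile_episode(
    S0: float,
    intervals: Sequence[Interval],
    sp: SomnostatParams,
    coupling: SetpointCoupling,
    mode: str,
) -> List[_Seg]:
    """Compile one sleep episode into closed-form segments.

    ``intervals`` are NREM/REM phases (scheduled) or SLEEP_WINDOW pieces
    (relay).  Setpoint relaxation toward the baseline is applied from
    either side: after a long wake phase S0 lies above the baseline and the
    setpoint decays; after restricted sleep it may lie below and relaxes
    upward (same exponential law).
    """
    b = coupling.s_u_baseline
    segs: List[_Seg] = []
    clock = 0.0
    cycle = 0
    frozen = False
    su_frozen = math.nan
    s_entry = sp.B  # Process s restarts at its lower threshold at sleep onset

    def su_value(c: float) -> float:
        if frozen:
            return su_frozen
        return b + (S0 - b) * math.exp(-c / coupling.T_set)

    def push(state: str, start: float, end: float) -> None:
        nonlocal clock, cycle, frozen, su_frozen, s_entry
        if state == NREM:
            cycle += 1
        advancing = _clock_advances(state, coupling) and not frozen
        seg = _Seg(start=start, end=end, state=state, s_entry=s_entry,
                   episode_S0=S0)
        if frozen or not advancing:
            seg.su_kind = "const"
            seg.su_const = su_value(clock)
        else:
            seg.su_kind = "decay"
            seg.su_c0 = clock
        segs.append(seg)
        d = end - start
        if advancing:
            clock += d
        s_entry = float(_eval_seg_s(seg, np.asarray([end]), sp, coupling)[0])
        if state == NREM and cycle >= coupling.freeze_after_cycle and not frozen:
            su_frozen = su_value(clock)
            frozen = True

    if mode == "scheduled":
        for iv in intervals:
            if iv.state not in (NREM, REM):
                raise ConfigurationError(
                    f"scheduled episode intervals must be NREM/REM, got {iv.state}"
                )
            push(iv.state, iv.start, iv.end)
        return segs

    # relay mode: thresholds generate the NREM/REM alternation
    w_start, w_end = intervals[0].start, intervals[-1].end
    t = w_start
    state = NREM
    while t < w_end - _TOL:
        if state == NREM:
            su_now = su_value(clock)
            if sp.D >= su_now:
                raise UnreachableThresholdError(
                    f"NREM->REM threshold s_d={sp.D} is not below the current "
                    f"setpoint s_u={su_now:.4f}"
                )
            dur = _nrem_switch_time(s_entry, su_now, S0, b, clock, sp, coupling,
                                    frozen, w_end - t)
        else:
            if sp.B <= sp.L:
                dur = math.inf
            else:
                dur = sp.T_decay * math.log((s_entry - sp.L) / (sp.B - sp.L))
        end = min(t + dur, w_end)
        push(state, t, end)
        t = end
        state = REM if state == NREM else NREM
    return segs


def _nrem_switch_time(
    s_entry: float,
    su_now: float,
    S0: float,
    baseline: float,
    clock: float,
    sp: SomnostatParams,
    coupling: SetpointCoupling,
    frozen: bool,
    remaining: float,
) -> float:
    """Time for the NREM buildup to reach the upper threshold s_d.

    With a constant setpoint the crossing is the inverted exponential; with
    a decaying setpoint the crossing of the compound curve is bracketed on
    a fine scan and polished with Brent's method to ~1e-12 h.
    """
    if frozen or not _clock_advances(NREM, coupling):
        return sp.T_build * math.log((su_now - s_entry) / (su_now - sp.D))

    def f(delta: float) -> float:
        su = baseline + (S0 - baseline) * math.exp(-(clock + delta) / coupling.T_set)
        s = su - (su - s_entry) * math.exp(-delta / sp.T_build)
        return s - sp.D

    # first guess from the frozen-setpoint closed form
    guess = sp.T_build * math.log(max((su_now - s_entry) / (su_now - sp.D), 1.0))
    hi = min(remaining, max(4.0 * guess, 0.5))
    n = max(64, int(hi / 1e-3))
    deltas = np.linspace(0.0, hi, n + 1)
    vals = np.array([f(d) for d in deltas])
    pos = np.nonzero(vals > 0)[0]
    while pos.size == 0:
        if hi >= remaining - _TOL:
            return math.inf  # threshold not reached inside the window
        hi = min(2.0 * hi, remaining)
        deltas = np.linspace(0.0, hi, n + 1)
        vals = np.array([f(d) for d in deltas])
        pos = np.nonzero(vals > 0)[0]
    i = pos[0]
    if i == 0:
        return 0.0
    return float(brentq(f, deltas[i - 1], deltas[i], xtol=1e-13, rtol=1e-15))


def _eval_seg_s(
    seg: _Seg, ts: np.ndarray, sp: SomnostatParams, coupling: SetpointCoupling
) -> np.ndarray:
    su = seg.su_at(ts, coupling)
    delta = ts - seg.start
    if seg.state == NREM:
        return su - (su - seg.s_entry) * np.exp(-delta / sp.T_build)
    return sp.L + (seg.s_entry - sp.L) * np.exp(-delta / sp.T_decay)


# ---------------------------------------------------------------------------
# full-protocol compilation

@dataclass
class CompiledProtocol:
    """Piecewise closed-form trajectory, evaluable at arbitrary times."""

    segments: List[_Seg]
    params: ModelParams
    episodes: List[Tuple[float, float]]

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def _seg_values(self, seg: _Seg, ts: np.ndarray):
        p = self.params
        # grid rounding can land a boundary sample 1 ulp before the piece
        ts = np.maximum(ts, seg.start)
        if seg.state == WAKE:
            S = np.asarray(
                process_S(ts, "wake", seg.start, seg.S_entry, p.S, p.circadian),
                dtype=float,
            )
            nan = np.full_like(S, np.nan)
            return S, nan, nan
        su = seg.su_at(ts, p.coupling)
        s = _eval_seg_s(seg, ts, p.s, p.coupling)
        return su.copy(), su, s

    def values_at(self, times: np.ndarray):
        """Evaluate (S, s_u, s, state) at arbitrary times within the protocol."""
        ts = np.asarray(times, dtype=float)
        starts = np.array([g.start for g in self.segments])
        idx = np.clip(np.searchsorted(starts, ts, side="right") - 1, 0,
                      len(self.segments) - 1)
        S = np.empty_like(ts)
        su = np.empty_like(ts)
        s = np.empty_like(ts)
        state = np.empty(ts.shape, dtype=object)
        for i, seg in enumerate(self.segments):
            sel = idx == i
            if not np.any(sel):
                continue
            S[sel], su[sel], s[sel] = self._seg_values(seg, ts[sel])
            state[sel] = seg.state
        return S, su, s, state

    def sample(self, dt: float) -> Trajectory:
        """Sample on a uniform grid; boundary samples go to the later piece."""
        t0, t1 = self.start, self.end
        n = int(round((t1 - t0) / dt))
        time = t0 + np.arange(n + 1) * dt
        S = np.empty(n + 1)
        su = np.empty(n + 1)
        s = np.empty(n + 1)
        state = np.empty(n + 1, dtype=object)
        # index-based assignment keeps on-grid boundaries exact
        for seg in self.segments:
            k0 = int(round((seg.start - t0) / dt))
            k1 = int(round((seg.end - t0) / dt))
            k1 = min(max(k1, k0 + 1), n + 1)
            if seg is self.segments[-1]:
                k1 = n + 1
            ts = time[k0:k1]
            S[k0:k1], su[k0:k1], s[k0:k1] = self._seg_values(seg, ts)
            state[k0:k1] = seg.state
        records = self._interval_records()
        return Trajectory(time_h=time, S=S, s_u=su, s=s, state=state, dt=dt,
                          intervals=records, episodes=list(self.episodes))

    def _interval_records(self) -> List[IntervalRecord]:
        recs = []
        for seg in self.segments:
            ends = np.array([seg.start, seg.end])
            S, su, s = self._seg_values(seg, ends)
            recs.append(
                IntervalRecord(
                    start=seg.start, end=seg.end, state=seg.state,
                    S_entry=S[0], S_exit=S[1],
                    su_entry=su[0], su_exit=su[1],
                    s_entry=s[0], s_exit=s[1],
                )
            )
        return recs


def compile_protocol(
    schedule: Schedule,
    params: Optional[ModelParams] = None,
    initial_S: Optional[float] = None,
) -> CompiledProtocol:
    """Compile a protocol into closed-form segments.

    Process S starts at ``initial_S`` (default: the lowest-allowed-decay
    value S_b) at the first interval's start and is carried continuously
    through every wake phase and sleep episode; ``schedule.s_resets`` may
    pin it to a prescribed value at specific wake onsets.
    """
    params = params or ModelParams()
    S_cur = params.S.B if initial_S is None else float(initial_S)
    segs: List[_Seg] = []
    episodes: List[Tuple[float, float]] = []
    ivs = list(schedule.intervals)
    i = 0
    while i < len(ivs):
        iv = ivs[i]
        if iv.state == WAKE:
            for t_reset, v_reset in schedule.s_resets.items():
                if abs(iv.start - t_reset) < _TOL:
                    S_cur = float(v_reset)
            segs.append(_Seg(start=iv.start, end=iv.end, state=WAKE, S_entry=S_cur))
            S_cur = float(
                process_S(iv.end, "wake", iv.start, S_cur, params.S, params.circadian)
            )
            i += 1
            continue
        run = []
        while i < len(ivs) and ivs[i].state != WAKE:
            run.append(ivs[i])
            i += 1
        ep_segs = _compile_episode(S_cur, run, params.s, params.coupling, schedule.mode)
        episodes.append((run[0].start, S_cur))
        segs.extend(ep_segs)
        # S leaves the episode at the level the setpoint reached
        last = ep_segs[-1]
        S_cur = float(last.su_at(np.asarray([last.end]), params.coupling)[0])
    if not segs:
        raise ConfigurationError("schedule compiled to an empty protocol")
    return CompiledProtocol(segments=segs, params=params, episodes=episodes)


def simulate_protocol(
    schedule: Schedule,
    params: Optional[ModelParams] = None,
    dt: float = 1.0 / 60.0,
    initial_S: Optional[float] = None,
) -> Trajectory:
    """Simulate processes S and s over a full protocol on a ``dt`` grid."""
    if not dt > 0:
        raise ConfigurationError("dt must be > 0")
    return compile_protocol(schedule, params, initial_S).sample(dt)


def simulate_sleep_episode(
    S_at_onset: float,
    s_params: Optional[SomnostatParams] = None,
    coupling: Optional[SetpointCoupling] = None,
    schedule: Union[Schedule, Sequence[Interval], Tuple[float, float], None] = None,
    dt: float = 1.0 / 60.0,
    mode: str = "scheduled",
) -> Trajectory:
    """Simulate one sleep episode in isolation.

    ``schedule`` is either a sequence of NREM/REM intervals (scheduled
    mode) or a ``(start, end)`` sleep window (relay mode: phase boundaries
    emerge from the thresholds).  Process s starts at the lower threshold
    s_b at onset.
    """
    params = ModelParams(
        s=s_params or ModelParams().s,
        coupling=coupling or SetpointCoupling(),
    )
    if isinstance(schedule, Schedule):
        ivs = list(schedule.intervals)
        mode = schedule.mode
    elif isinstance(schedule, tuple) and len(schedule) == 2 and not isinstance(
        schedule[0], Interval
    ):
        ivs = [Interval(float(schedule[0]), float(schedule[1]), SLEEP_WINDOW)]
        mode = "relay"
    else:
        ivs = list(schedule or [])
    if not ivs:
        raise ConfigurationError("sleep episode needs a schedule or window")
    segs = _compile_episode(float(S_at_onset), ivs, params.s, params.coupling, mode)
    compiled = CompiledProtocol(segments=segs, params=params,
                                episodes=[(ivs[0].start, float(S_at_onset))])
    return compiled.sample(dt)


def setpoint_trace(
    S_at_onset: float,
    coupling: Optional[SetpointCoupling] = None,
    schedule: Union[Schedule, Sequence[Interval], None] = None,
    dt: float = 1.0 / 60.0,
) -> pd.DataFrame:
    """Time course of the setpoint s_u(t) over a within-sleep schedule.

    The setpoint relaxes from ``S_at_onset`` toward the baseline while the
    setpoint clock runs, is constant during REM intervals, and is frozen
    after the NREM phase of the freeze cycle ends.  Requires
    ``S_at_onset`` above the baseline (otherwise there is no decaying
    setpoint to trace).
    """
    coupling = coupling or SetpointCoupling()
    if not S_at_onset > coupling.s_u_baseline:
        raise ConfigurationError(
            "setpoint trace requires S_at_onset above the baseline "
            f"({S_at_onset} <= {coupling.s_u_baseline})"
        )
    traj = simulate_sleep_episode(
        S_at_onset, coupling=coupling, schedule=schedule, dt=dt
    )
    return pd.DataFrame({"time_h": traj.time_h, "s_u": traj.s_u})
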