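"""Vigilance-state schedules and the standard experimental protocols.

A :class:`Schedule` is an ordered, contiguous sequence of half-open
intervals ``[start, end)`` labelled WAKE, NREM, REM or SLEEP_WINDOW, on a
continuous decimal-hour axis.  In ``scheduled`` mode the NREM/REM phase
boundaries are given; in ``relay`` mode sleep is given as a SLEEP_WINDOW
and the boundaries emerge from the hysteresis thresholds of Process s.

Two protocol builders are provided: the habitual all-night episode
(wake 7.00 -> 23.00 followed by sleep cycles) and the two-day 12-nap
protocols following either total sleep deprivation (SD: 20-min naps at
every even hour from 6:00 of day 1) or sleep restriction to 7 h
(SR: night sleep 23:00-6:00, then naps at every odd hour from 7:00).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List

from .core import ConfigurationError

__all__ = [
    "WAKE", "NREM", "REM", "SLEEP_WINDOW",
    "Interval", "Schedule",
    "build_allnight_schedule", "build_nap_schedule",
]

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
SLEEP_WINDOW = "SLEEP_WINDOW"

_SLEEP_STATES = {NREM, REM, SLEEP_WINDOW}
_TOL = 1e-9


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    state: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ConfigurationError(
                f"interval must have end > start, got [{self.start}, {self.end})"
            )
        if self.state not in {WAKE, NREM, REM, SLEEP_WINDOW}:
            raise ConfigurationError(f"unknown state {self.state!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Schedule:
    """Contiguous, strictly increasing sequence of vigilance-state intervals.

    ``s_resets`` maps a wake-onset clock time to a prescribed value of
    Process S at that instant.  This expresses the convention of the fitted
    nap protocols, where the morning wake phase restarts from the fitted
    lowest-allowed-decay value rather than from the level the setpoint
    relaxation reached overnight.
    """

    intervals: tuple
    mode: str = "scheduled"
    s_resets: Dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("scheduled", "relay"):
            raise ConfigurationError(f"unknown schedule mode {self.mode!r}")
        ivs = tuple(self.intervals)
        if not ivs:
            raise ConfigurationError("schedule must contain at least one interval")
        object.__setattr__(self, "intervals", ivs)
        for a, b in zip(ivs, ivs[1:]):
            if abs(b.start - a.end) > _TOL:
                raise ConfigurationError(
                    f"intervals must be contiguous: gap between {a.end} and {b.start}"
                )
        for iv in ivs:
            if self.mode == "scheduled" and iv.state == SLEEP_WINDOW:
                raise ConfigurationError("SLEEP_WINDOW requires relay mode")
            if self.mode == "relay" and iv.state in (NREM, REM):
                raise ConfigurationError(
                    "relay mode takes SLEEP_WINDOW intervals; NREM/REM boundaries are emergent"
                )

    @property
    def start(self) -> float:
        return self.intervals[0].start

    @property
    def end(self) -> float:
        return self.intervals[-1].end

    def sleep_episodes(self) -> List[List[Interval]]:
        """Maximal runs of consecutive sleep intervals (episodes)."""
        episodes: List[List[Interval]] = []
        run: List[Interval] = []
        for iv in self.intervals:
            if iv.state in _SLEEP_STATES:
                run.append(iv)
            elif run:
                episodes.append(run)
                run = []
        if run:
            episodes.append(run)
        return episodes

    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "intervals": [
                {"start": iv.start, "end": iv.end, "state": iv.state}
                for iv in self.intervals
            ],
        }
        if self.s_resets:
            payload["s_resets"] = {repr(k): v for k, v in self.s_resets.items()}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        payload = json.loads(text)
        ivs = [Interval(d["start"], d["end"], d["state"]) for d in payload["intervals"]]
        resets = {float(k): float(v) for k, v in payload.get("s_resets", {}).items()}
        return cls(tuple(ivs), mode=payload.get("mode", "scheduled"), s_resets=resets)


_DEFAULT_REM_MINUTES = (10.0, 15.0, 20.0, 25.0, 30.0)


def _per_cycle(value, n: int, name: str) -> List[float]:
    if isinstance(value, (int, float)):
        return [float(value)] * n
    seq = [float(v) for v in value]
    if len(seq) != n:
        raise ConfigurationError(f"{name} must have one entry per cycle ({n})")
    return seq


def build_allnight_schedule(
    t1: float = 7.00,
    t2: float = 23.00,
    n_cycles: int = 5,
    nrem_minutes=None,
    rem_minutes=None,
    mode: str = "scheduled",
) -> Schedule:
    """Habitual monophasic day: one wake phase then one all-night episode.

    ``nrem_minutes`` and ``rem_minutes`` may be scalars or one value per
    cycle.  The default night holds five 90-min cycles whose REM episodes
    lengthen across the night (10, 15, 20, 25, 30 min), the textbook
    architecture of adult sleep and the pattern the nested model itself
    predicts for the negative-value interval.  In relay mode the night is
    a single SLEEP_WINDOW of the same total length and the NREM/REM
    boundaries emerge from the thresholds.
    """
    if not t2 > t1:
        raise ConfigurationError("sleep onset t2 must follow wake onset t1")
    if rem_minutes is None:
        rem_minutes = (_DEFAULT_REM_MINUTES[:n_cycles]
                       if n_cycles <= len(_DEFAULT_REM_MINUTES) else 25.0)
    rem = _per_cycle(rem_minutes, n_cycles, "rem_minutes") if n_cycles else []
    if nrem_minutes is None:
        nrem = [90.0 - r for r in rem]  # keep 90-min cycles by default
    else:
        nrem = _per_cycle(nrem_minutes, n_cycles, "nrem_minutes") if n_cycles else []
    total_sleep = sum(nrem) / 60.0 + sum(rem) / 60.0
    if total_sleep > 24.0:
        raise ConfigurationError(
            f"{n_cycles} cycles totalling {total_sleep:.2f} h overflow the sleep window"
        )
    ivs = [Interval(t1, t2, WAKE)]
    if mode == "relay" or n_cycles == 0:
        window = total_sleep if n_cycles > 0 else 24.0 - (t2 - t1)
        ivs.append(Interval(t2, t2 + window, SLEEP_WINDOW))
        return Schedule(tuple(ivs), mode="relay")
    t = t2
    for n_min, r_min in zip(nrem, rem):
        ivs.append(Interval(t, t + n_min / 60.0, NREM))
        t += n_min / 60.0
        if r_min > 0:
            ivs.append(Interval(t, t + r_min / 60.0, REM))
            t += r_min / 60.0
    return Schedule(tuple(ivs), mode="scheduled")


def build_nap_schedule(
    group: str,
    nap_minutes: float = 20.0,
    nrem_fraction_of_nap: float = 1.0,
) -> Schedule:
    """Two-day 12-nap protocol after sleep deprivation (SD) or restriction (SR).

    SD: continuous wake from 7.00 of day 0, then 12 naps at every even
    clock hour starting 6:00 of day 1 (30.00, 32.00, ... 52.00).
    SR: wake 7.00 -> 23.00, night sleep restricted to 23.00-30.00 (7 h),
    then 12 naps at every odd clock hour starting 7:00 of day 1
    (31.00, 33.00, ... 53.00).  The SR morning wake phase restarts
    Process S at the fitted nap-study value 0.23 at 6.00 (= 30.00).

    Naps are sleep episodes of ``nap_minutes`` whose first
    ``nrem_fraction_of_nap`` is NREM and remainder REM (default: all NREM).
    """
    if group not in ("SD", "SR"):
        raise ConfigurationError(f"group must be 'SD' or 'SR', got {group!r}")
    if not 0 < nrem_fraction_of_nap <= 1:
        raise ConfigurationError("nrem_fraction_of_nap must be in (0, 1]")
    nap_h = nap_minutes / 60.0
    ivs: List[Interval] = []
    resets: Dict[float, float] = {}
    if group == "SD":
        first_nap = 30.00  # 6:00 of day 1 after 23 h of wake
        ivs.append(Interval(7.00, first_nap, WAKE))
    else:
        ivs.append(Interval(7.00, 23.00, WAKE))
        # restriction night: the default all-night architecture truncated
        # at the 30.00 (6:00) lights-on
        t = 23.00
        for r_min in _DEFAULT_REM_MINUTES:
            if t >= 30.00 - _TOL:
                break
            n_end = min(t + (90.0 - r_min) / 60.0, 30.00)
            ivs.append(Interval(t, n_end, NREM))
            t = n_end
            if t >= 30.00 - _TOL:
                break
            r_end = min(t + r_min / 60.0, 30.00)
            ivs.append(Interval(t, r_end, REM))
            t = r_end
        first_nap = 31.00  # 7:00 of day 1
        ivs.append(Interval(30.00, first_nap, WAKE))
        resets[30.00] = 0.23
    onset = first_nap
    for i in range(12):
        nrem_end = onset + nrem_fraction_of_nap * nap_h
        ivs.append(Interval(onset, nrem_end, NREM))
        if nrem_end < onset + nap_h - _TOL:
            ivs.append(Interval(nrem_end, onset + nap_h, REM))
        if i < 11:
            ivs.append(Interval(onset + nap_h, onset + 2.0, WAKE))
        onset += 2.0
    return Schedule(tuple(ivs), mode="scheduled", s_resets=resets)
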