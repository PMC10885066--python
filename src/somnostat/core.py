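"""Parameters and closed-form kinetics of the two nested somnostats.

The model describes sleep-wake regulation with two formally identical
relaxation regulators ("somnostats"): a circadian Process S that builds up
exponentially during wake and relaxes during sleep, and an ultradian
Process s that oscillates between hysteresis bounds within sleep,
generating NREM-REM cycles.  Both are built from two primitives — an
inverse-exponential buildup toward an upper asymptote and an exponential
decay toward a lower asymptote — optionally modulated by a sinusoidal
circadian term C(t).

All times are decimal clock hours on a continuous axis (day d, hour h
-> 24*d + h), so multi-day protocols use times beyond 24.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from typing import Union

import numpy as np

__all__ = [
    "ConfigurationError",
    "UnreachableThresholdError",
    "CircadianParams",
    "SomnostatParams",
    "SetpointCoupling",
    "ModelParams",
    "circadian_term",
    "buildup",
    "decay",
    "process_S",
]

ArrayLike = Union[float, np.ndarray]


class ConfigurationError(ValueError):
    """A parameter set or schedule violates a model invariant."""


class UnreachableThresholdError(ConfigurationError):
    """Relay switching requested toward a threshold the trajectory cannot reach."""


@dataclass(frozen=True)
class CircadianParams:
    """Sinusoidal circadian modulation C(t) = A*sin(2*pi*t/tau + phi0).

    The phase offset phi0 is derived from ``phi_max``, the clock hour at
    which C(t) attains its maximum A: phi0 = pi/2 - 2*pi*phi_max/tau.

    Parameters
    ----------
    A : float
        Amplitude in indicator units (dimensionless).  ``A=0`` switches the
        modulation off, reducing the modulated process to the classical
        unmodulated somnostat.
    tau : float
        Entrained period in hours (default 24).
    phi_max : float
        Clock hour of the circadian peak, in ``[0, tau)``.
    k : float
        Impact multiplier of the subtracted circadian term.
    """

    A: float = 0.0
    tau: float = 24.0
    phi_max: float = 0.0
    k: float = 2.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ConfigurationError(f"circadian period tau must be > 0, got {self.tau}")
        if self.A < 0:
            raise ConfigurationError(f"circadian amplitude A must be >= 0, got {self.A}")
        if not 0 <= self.phi_max < self.tau:
            raise ConfigurationError(
                f"phi_max must lie in [0, tau)=[0, {self.tau}), got {self.phi_max}"
            )
        if not math.isfinite(self.k):
            raise ConfigurationError("impact multiplier k must be finite")

    @property
    def phi0(self) -> float:
        """Phase offset placing the sinusoid's maximum at clock hour ``phi_max``."""
        return math.pi / 2.0 - 2.0 * math.pi * self.phi_max / self.tau


@dataclass(frozen=True)
class SomnostatParams:
    """Asymptotes, hysteresis thresholds and time constants of one somnostat.

    A somnostat is a relay-style relaxation regulator: the regulated
    variable builds up toward ``U`` with time constant ``T_build`` and
    decays toward ``L`` with time constant ``T_decay``; ``D`` is the highest
    allowed buildup and ``B`` the lowest allowed decay (the hysteresis band).

    Instantiated once for Process S (sleep-wake cycle, indicator units,
    hours) and once for Process s (NREM-REM cycle within sleep).
    """

    U: float  # upper asymptote
    L: float  # lower asymptote
    D: float  # upper threshold: highest allowed buildup
    B: float  # lower threshold: lowest allowed decay
    T_build: float  # buildup time constant, hours
    T_decay: float  # decay time constant, hours

    def __post_init__(self) -> None:
        if not (self.L <= self.B < self.D <= self.U):
            raise ConfigurationError(
                "somnostat thresholds must satisfy L <= B < D <= U, got "
                f"L={self.L}, B={self.B}, D={self.D}, U={self.U}"
            )
        if not self.T_build > 0 or not self.T_decay > 0:
            raise ConfigurationError("time constants T_build, T_decay must be > 0")


@dataclass(frozen=True)
class SetpointCoupling:
    """How Process S drives the moving setpoint s_u(t) of Process s.

    During sleep the upper asymptote of Process s is the decaying Process S
    itself: s_u(t) relaxes from its value at sleep onset toward
    ``s_u_baseline`` with time constant ``T_set``.  The relaxation clock
    advances either only during NREM epochs (``cumulative_nrem``, the
    default, so the setpoint is frozen during REM) or with elapsed sleep
    time (``elapsed_sleep``).  After the NREM phase of cycle number
    ``freeze_after_cycle`` ends, the setpoint is held constant for the rest
    of the episode.
    """

    s_u_baseline: float = 0.70
    T_set: float = 1.40
    clock_mode: str = "cumulative_nrem"
    freeze_after_cycle: int = 4

    def __post_init__(self) -> None:
        if not self.T_set > 0:
            raise ConfigurationError(f"T_set must be > 0, got {self.T_set}")
        if self.freeze_after_cycle < 1:
            raise ConfigurationError("freeze_after_cycle must be >= 1")
        if self.clock_mode not in ("cumulative_nrem", "elapsed_sleep"):
            raise ConfigurationError(f"unknown clock_mode {self.clock_mode!r}")


def _default_S() -> SomnostatParams:
    return SomnostatParams(U=1.41, L=0.20, D=1.10, B=0.22, T_build=12.01, T_decay=1.40)


def _default_s() -> SomnostatParams:
    return SomnostatParams(U=0.70, L=-0.34, D=0.22, B=-0.30, T_build=0.22, T_decay=0.36)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the nested-doll model.

    Defaults reproduce the fitted all-night ("Sleep") parameter column:
    circadian somnostat S_u=1.41, S_b=0.22, S_l=0.20, S_d=1.10, T_b=12.01 h,
    T_d=1.40 h; ultradian somnostat s_u=0.70, s_b=-0.30, s_l=-0.34,
    s_d=0.22, t_b=0.22 h, t_d=0.36 h; circadian amplitude A=0; habitual
    sleep offset t1=7.00 and onset t2=23.00 (decimal clock hours).

    ``coupling.s_u_baseline`` is tied by default to the ultradian upper
    asymptote s_u: it is the terminal level the setpoint relaxes to.
    """

    S: SomnostatParams = field(default_factory=_default_S)
    s: SomnostatParams = field(default_factory=_default_s)
    circadian: CircadianParams = field(default_factory=CircadianParams)
    coupling: SetpointCoupling = field(default_factory=SetpointCoupling)
    t1: float = 7.00  # sleep offset: start of the habitual wake phase
    t2: float = 23.00  # sleep onset: start of the habitual sleep phase

    # flat-name <-> structured mapping (JSON schema keys)
    _FLAT = {
        "S_u": ("S", "U"), "S_l": ("S", "L"), "S_d": ("S", "D"), "S_b": ("S", "B"),
        "T_b": ("S", "T_build"), "T_d": ("S", "T_decay"),
        "s_u": ("s", "U"), "s_l": ("s", "L"), "s_d": ("s", "D"), "s_b": ("s", "B"),
        "t_b": ("s", "T_build"), "t_d": ("s", "T_decay"),
        "A": ("circadian", "A"), "tau": ("circadian", "tau"),
        "phi_max": ("circadian", "phi_max"), "k": ("circadian", "k"),
        "T_set": ("coupling", "T_set"),
        "t1": (None, "t1"), "t2": (None, "t2"),
    }

    def to_flat(self) -> dict:
        """Flat parameter dictionary using the published table's names."""
        out = {}
        for key, (block, attr) in self._FLAT.items():
            obj = self if block is None else getattr(self, block)
            out[key] = getattr(obj, attr)
        out["freeze_after_cycle"] = self.coupling.freeze_after_cycle
        out["clock_mode"] = self.coupling.clock_mode
        return out

    @classmethod
    def from_flat(cls, flat: dict, base: "ModelParams | None" = None) -> "ModelParams":
        """Build params from a flat dict; unknown keys are rejected.

        ``s_u`` sets both the ultradian upper asymptote and the setpoint
        baseline, keeping the two representations of the terminal setpoint
        level consistent.
        """
        base = base or cls()
        known = set(cls._FLAT) | {"freeze_after_cycle", "clock_mode"}
        unknown = set(flat) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        blocks = {
            "S": {f.name: getattr(base.S, f.name) for f in fields(SomnostatParams)},
            "s": {f.name: getattr(base.s, f.name) for f in fields(SomnostatParams)},
            "circadian": {f.name: getattr(base.circadian, f.name) for f in fields(CircadianParams)},
            "coupling": {f.name: getattr(base.coupling, f.name) for f in fields(SetpointCoupling)},
        }
        top = {"t1": base.t1, "t2": base.t2}
        for key, value in flat.items():
            if key == "freeze_after_cycle":
                blocks["coupling"]["freeze_after_cycle"] = int(value)
                continue
            if key == "clock_mode":
                blocks["coupling"]["clock_mode"] = str(value)
                continue
            block, attr = cls._FLAT[key]
            if block is None:
                top[attr] = float(value)
            else:
                blocks[block][attr] = float(value)
        if "s_u" in flat:
            blocks["coupling"]["s_u_baseline"] = float(flat["s_u"])
        return cls(
            S=SomnostatParams(**blocks["S"]),
            s=SomnostatParams(**blocks["s"]),
            circadian=CircadianParams(**blocks["circadian"]),
            coupling=SetpointCoupling(**blocks["coupling"]),
            **top,
        )

    def with_values(self, **flat) -> "ModelParams":
        """Return a copy with flat-named parameters replaced."""
        return self.from_flat(flat, base=self)

    def to_json(self) -> str:
        return json.dumps(self.to_flat(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_flat(json.loads(text))

    @classmethod
    def nap_defaults(cls) -> "ModelParams":
        """Fitted parameter column of the 12-nap study (morning wake onset
        6.00 with a lowest-allowed-decay value of 0.23; all else shared with
        the all-night column)."""
        return cls().with_values(S_b=0.23, t1=6.00)


def circadian_term(t: ArrayLike, p: CircadianParams) -> ArrayLike:
    """Circadian modulation C(t) = A*sin(2*pi*t/tau + phi0).

    Periodic with period ``p.tau``; the maximum A occurs at clock hour
    ``p.phi_max`` (mod tau).
    """
    t = np.asarray(t, dtype=float)
    out = p.A * np.sin(2.0 * math.pi * t / p.tau + p.phi0)
    return out if out.ndim else float(out)


def _check_elapsed(elapsed: ArrayLike, T: float) -> np.ndarray:
    if not T > 0:
        raise ValueError(f"time constant must be > 0, got {T}")
    e = np.asarray(elapsed, dtype=float)
    if np.any(e < 0):
        raise ValueError("elapsed time must be >= 0")
    return e


def buildup(elapsed: ArrayLike, asymptote: float, start: float, T: float) -> ArrayLike:
    """Inverse-exponential buildup from ``start`` toward ``asymptote``.

    value(elapsed) = asymptote - (asymptote - start) * exp(-elapsed / T)

    Equals ``start`` at elapsed=0 and approaches ``asymptote`` as elapsed
    grows; strictly increasing when start < asymptote.
    """
    e = _check_elapsed(elapsed, T)
    # start - (asymptote - start)*expm1(...) is exact at elapsed = 0
    out = start - (asymptote - start) * np.expm1(-e / T)
    return out if out.ndim else float(out)


def decay(elapsed: ArrayLike, asymptote: float, start: float, T: float) -> ArrayLike:
    """Exponential decay from ``start`` toward ``asymptote``.

    value(elapsed) = asymptote + (start - asymptote) * exp(-elapsed / T)

    Equals ``start`` at elapsed=0; strictly decreasing when
    start > asymptote.  This form satisfies the boundary condition that the
    decay departs from the phase's entry value, and reduces to the
    classical sleep-phase discharge of the two-process model.
    """
    e = _check_elapsed(elapsed, T)
    out = start + (asymptote - start) * -np.expm1(-e / T)
    return out if out.ndim else float(out)


def process_S(
    t: ArrayLike,
    phase: str,
    phase_start: float,
    entry_value: float,
    sp: SomnostatParams,
    cp: CircadianParams,
) -> ArrayLike:
    """Circadian-modulated Process S at clock time(s) ``t``.

    wake:  S(t) = [U + C(t)] - ([U + C(t)] - entry) * exp(-(t-t0)/T_build) - k*C(t)
    sleep: S(t) = [L + C(t)] + (entry - [L + C(t)]) * exp(-(t-t0)/T_decay) - k*C(t)

    where t0 = ``phase_start`` and entry = ``entry_value``, the value of the
    process at the phase transition.  With amplitude A=0 this reduces
    exactly to :func:`buildup` / :func:`decay`.
    """
    ts = np.asarray(t, dtype=float)
    if np.any(ts < phase_start):
        raise ValueError("t must be >= phase_start")
    C = np.asarray(circadian_term(ts, cp), dtype=float)
    if phase == "wake":
        asym = sp.U + C
        out = asym - (asym - entry_value) * np.exp(-(ts - phase_start) / sp.T_build)
    elif phase == "sleep":
        asym = sp.L + C
        out = asym + (entry_value - asym) * np.exp(-(ts - phase_start) / sp.T_decay)
    else:
        raise ValueError(f"phase must be 'wake' or 'sleep', got {phase!r}")
    out = out - cp.k * C
    return out if out.ndim else float(out)
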