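"""Pure update rules for the dynamical modules.

Every public function here is a stateless map from inputs to outputs; the
simulation engine composes them into synchronous per-step updates.  All
functions accept scalars or numpy arrays and broadcast elementwise.

Module types
------------
timer
    A level that relaxes linearly from 1 to 0 at rate ``1/T`` unless held.
oscillator
    A hidden phase advancing at rate ``f(tau)/P``; the functional output is
    ``o = (sin(2*pi*(phase - 1/4)) + 1) / 2``.
switch
    A write-once fate chosen either from the oscillator level (binary) or
    from a threshold mapping applied to a timer level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrequencyProfile",
    "SwitchMapping",
    "GrowthProfile",
    "PiecewiseMap",
    "timer_update",
    "oscillator_output",
    "frequency_scale",
    "oscillator_update",
    "fate_from_oscillator",
    "timer2_update",
    "fate_from_mapping",
    "pi_value",
    "elongation_gate",
    "timer_rate_feedback",
    "timer3_update",
    "growth_rate",
    "tau1_modulation",
    "oscillator_as_function",
]


class ProfileError(ValueError):
    """Raised for ill-formed profiles, mappings or control-point maps."""


# ---------------------------------------------------------------------------
# piecewise-linear helper
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseMap:
    """Piecewise-linear map on [0, 1] given as (x, y) control points."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ProfileError("piecewise map needs at least two control points")
        xs = [float(p[0]) for p in self.points]
        if sorted(xs) != xs and sorted(xs, reverse=True) != xs:
            # accept either orientation, store ascending
            raise ProfileError("control-point x values must be monotone")
        pts = tuple(sorted(((float(x), float(y)) for x, y in self.points)))
        object.__setattr__(self, "points", pts)
        xs = [p[0] for p in self.points]
        if len(set(xs)) != len(xs):
            raise ProfileError("duplicate control-point x values")
        if xs[0] > 0.0 or xs[-1] < 1.0:
            raise ProfileError("control points must cover [0, 1]")

    def __call__(self, x):
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return np.interp(x, xs, ys)

    def to_spec(self) -> list[list[float]]:
        return [[x, y] for x, y in self.points]

    @classmethod
    def from_spec(cls, spec: Sequence[Sequence[float]]) -> "PiecewiseMap":
        return cls(tuple((float(x), float(y)) for x, y in spec))


# ---------------------------------------------------------------------------
# frequency profiles
# ---------------------------------------------------------------------------

_EXP2_NORM = 1.0 - float(np.exp(-2.0))


@dataclass(frozen=True)
class FrequencyProfile:
    """Scale factor f(tau) in [0, 1] applied to a module's base rate.

    Named forms:

    ``exp2`` (default)
        ``f(tau) = (1 - exp(-2 tau)) / (1 - exp(-2))`` — saturating, with
        f(0) = 0 and f(1) = 1.
    ``uniform``
        f = 1 everywhere (no differential slowing).
    ``linear``
        f(tau) = tau.
    ``custom``
        arbitrary monotone non-decreasing piecewise-linear map with f(1) = 1.
    """

    form: str = "exp2"
    custom: PiecewiseMap | None = None

    def __post_init__(self) -> None:
        if self.form not in ("exp2", "uniform", "linear", "custom"):
            raise ProfileError(f"unknown frequency profile form: {self.form!r}")
        if self.form == "custom":
            if self.custom is None:
                raise ProfileError("custom frequency profile needs control points")
            ys = [y for _, y in self.custom.points]
            if any(b < a for a, b in zip(ys, ys[1:])):
                raise ProfileError("frequency profile must be non-decreasing")
            if not np.isclose(ys[-1], 1.0):
                raise ProfileError("frequency profile must satisfy f(1) = 1")
            if any(y < 0 for y in ys):
                raise ProfileError("frequency profile must be non-negative")

    def __call__(self, tau):
        tau = np.clip(tau, 0.0, 1.0)
        if self.form == "exp2":
            return (1.0 - np.exp(-2.0 * tau)) / _EXP2_NORM
        if self.form == "uniform":
            return np.ones_like(np.asarray(tau, dtype=float))
        if self.form == "linear":
            return np.asarray(tau, dtype=float)
        return self.custom(tau)

    def to_spec(self):
        if self.form == "custom":
            return self.custom.to_spec()
        return self.form

    @classmethod
    def from_spec(cls, spec) -> "FrequencyProfile":
        if isinstance(spec, str):
            return cls(form=spec)
        return cls(form="custom", custom=PiecewiseMap.from_spec(spec))


def frequency_scale(tau, profile: FrequencyProfile):
    """Rate multiplier for a module gated by maturation level ``tau``."""
    return profile(tau)


# ---------------------------------------------------------------------------
# switch mappings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchMapping:
    """Partition of the input domain [0, 1] into n half-open bins.

    ``thresholds`` are the n-1 strictly increasing interior bin edges;
    ``states`` labels the bins from low input to high input.  A bin edge
    belongs to the higher-input bin.  The named presets label the
    *high-input* bin state 1 so that, for a timer input that starts at 1 and
    decays, state 1 is the anterior-most fate of each pattern repeat.
    """

    thresholds: tuple[float, ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.thresholds) + 1:
            raise ProfileError("need exactly n-1 thresholds for n states")
        th = self.thresholds
        if any(not (0.0 < t < 1.0) for t in th):
            raise ProfileError("thresholds must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ProfileError("thresholds must be strictly increasing")
        if len(set(self.states)) != len(self.states):
            raise ProfileError("switch states must be distinct")
        if any(int(s) <= 0 for s in self.states):
            raise ProfileError("switch states must be positive integers")

    @property
    def n(self) -> int:
        return len(self.states)

    def __call__(self, x):
        idx = np.searchsorted(np.asarray(self.thresholds), x, side="right")
        return np.asarray(self.states)[idx]

    def to_spec(self):
        return {"thresholds": list(self.thresholds), "states": list(self.states)}

    @classmethod
    def equal_width(cls, states: Sequence[int]) -> "SwitchMapping":
        n = len(states)
        th = tuple((i + 1) / n for i in range(n - 1))
        return cls(thresholds=th, states=tuple(int(s) for s in states))

    @classmethod
    def preset(cls, name: str) -> "SwitchMapping":
        if name == "binary":
            return cls.equal_width([2, 1])
        if name == "three_state":
            # anterior (1), middle (2), posterior (3) fates, read off a
            # decaying timer: high input -> state 1.
            return cls.equal_width([3, 2, 1])
        if name == "pair_rule":
            # double-segment repeat of six distinct states; 1 and 4 are the
            # two anterior-class fates heading each triplet.
            return cls.equal_width([6, 5, 4, 3, 2, 1])
        raise ProfileError(f"unknown mapping preset: {name!r}")

    @classmethod
    def from_spec(cls, spec) -> "SwitchMapping":
        if isinstance(spec, str):
            return cls.preset(spec)
        return cls(
            thresholds=tuple(float(t) for t in spec["thresholds"]),
            states=tuple(int(s) for s in spec["states"]),
        )


# ---------------------------------------------------------------------------
# growth profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthProfile:
    """Piecewise-linear map from the axial timer level to elongation rate.

    v(0) must be exactly 0: exhaustion of the axial timer terminates
    elongation permanently.
    """

    map: PiecewiseMap

    def __post_init__(self) -> None:
        ys = [y for _, y in self.map.points]
        if any(y < 0 for y in ys):
            raise ProfileError("growth profile rates must be non-negative")
        if self.map(0.0) != 0.0:
            raise ProfileError("growth profile must satisfy v(0) = 0")

    def __call__(self, tau3):
        return self.map(tau3)

    def to_spec(self):
        return self.map.to_spec()

    @classmethod
    def from_spec(cls, spec) -> "GrowthProfile":
        return cls(PiecewiseMap.from_spec(spec))


# ---------------------------------------------------------------------------
# update rules
# ---------------------------------------------------------------------------


def timer_update(tau, held, rate_scale, T):
    """One step of a linear timer.

    Held cells stay at their current level; free cells decrease by
    ``rate_scale / T`` with a floor at 0.
    """
    dec = np.maximum(0.0, tau - np.asarray(rate_scale, dtype=float) / T)
    return np.where(held, tau, dec)


def oscillator_output(phase):
    """Functional output level of the oscillator, period 1 in phase."""
    return (np.sin(2.0 * np.pi * (np.asarray(phase, dtype=float) - 0.25)) + 1.0) / 2.0


def oscillator_update(phase, tau_gate, P, profile: FrequencyProfile):
    """Advance the unwrapped phase by ``f(tau_gate)/P``; frozen at tau = 0."""
    adv = frequency_scale(tau_gate, profile) / P
    return np.where(np.asarray(tau_gate) > 0.0, phase + adv, phase)


def fate_from_oscillator(o):
    """Binary segment-polarity fate from the oscillator level at hand-over."""
    return np.where(np.asarray(o) > 0.5, 1, 2)


def timer2_update(tau2, o, theta, T2, expressed, rate_scale=1.0):
    """Oscillator-resettable timer.

    A peak (o >= theta) resets the level to 1; otherwise it decays at
    ``rate_scale / T2`` with a floor at 0.  Outside its expression domain
    the level is simply carried.
    """
    dec = np.maximum(0.0, tau2 - np.asarray(rate_scale, dtype=float) / T2)
    active = np.where(np.asarray(o) >= theta, 1.0, dec)
    return np.where(expressed, active, tau2)


def fate_from_mapping(value, mapping: SwitchMapping):
    return mapping(value)


def pi_value(distance, lam):
    """Positional-information level at ``distance`` cell diameters anterior
    to the signal range (distance 0 = at the edge of the range)."""
    return np.maximum(0.0, 1.0 - np.asarray(distance, dtype=float) / lam)


def elongation_gate(o_posterior) -> bool:
    """True iff elongation is allowed (posterior oscillator level < 0.5)."""
    return bool(np.asarray(o_posterior) < 0.5)


def timer_rate_feedback(o, k):
    """Oscillator-on-timer feedback multiplier, exp(-k * o)."""
    return np.exp(-k * np.asarray(o, dtype=float))


def timer3_update(tau3, in_saz, T3):
    """Axial timer: ticks down inside the SAZ, stable outside it."""
    dec = np.maximum(0.0, np.asarray(tau3, dtype=float) - 1.0 / T3)
    return np.where(in_saz, dec, tau3)


def growth_rate(tau3_posterior, profile: GrowthProfile):
    return profile(tau3_posterior)


def tau1_modulation(tau3, mode: str, pmap: PiecewiseMap | None):
    """Coupling from the axial timer onto the maturation timer.

    ``rate`` mode returns a rate multiplier (>= 1 by convention: maturation
    speeds up as the axial timer runs down); ``initial`` mode returns the
    level at which the maturation timer is held while signal-positive.
    ``none`` returns the neutral value 1 for either use.
    """
    if mode == "none" or pmap is None:
        return np.ones_like(np.asarray(tau3, dtype=float))
    if mode not in ("rate", "initial"):
        raise ProfileError(f"unknown tau3->tau1 modulation mode: {mode!r}")
    return pmap(tau3)


def oscillator_as_function(tau3, m: int):
    """Oscillator output as a static periodic readout of the axial timer.

    Reuses the autonomous oscillator waveform with a compressed argument:
    ``m`` output peaks per unit of tau3.
    """
    return oscillator_output(np.asarray(m, dtype=float) * np.asarray(tau3, dtype=float))
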