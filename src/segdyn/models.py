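"""Wire the module library into the named model variants.

A :class:`Wiring` is the executable rule set the engine consumes: which
modules are active, where the switch reads its input from, which feedbacks
are on, and any "mutant" clamps.  :func:`build_model` resolves a validated
:class:`~segdyn.config.ModelConfig` into a Wiring, rejecting incompatible
option combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import CLAMPABLE, ConfigError, ModelConfig
from .dynamics import (
    FrequencyProfile,
    GrowthProfile,
    PiecewiseMap,
    SwitchMapping,
)

__all__ = [
    "Wiring",
    "build_model",
    "apply_clamp",
    "NoClockInit",
    "derive_noclock_config",
    "PRESETS",
    "preset",
    "preset_names",
    "wavefront_transcription",
]


@dataclass(frozen=True)
class Wiring:
    """Resolved, executable rule set for one model variant."""

    variant: str
    spatial: bool
    uses_osc: bool  # autonomous phase oscillator present
    osc_function_of_tau3: bool  # oscillator is a static readout of tau3
    uses_tau2: bool
    uses_tau3: bool
    uses_switch: bool
    switch_source: str  # "oscillator" | "tau2" | "none"
    freeze_readout: bool  # oscillator output stays visible after arrest
    elongation_gated: bool  # oscillator gates elongation
    timer_feedback: bool  # oscillator scales the tau1 rate by exp(-k o)
    growth_from_tau3: bool  # v read from growth_profile(posterior tau3)
    no_psc: bool  # no posterior signalling centre at all
    psc_off_on_termination: bool  # PSC decays once posterior tau3 hits 0
    freq_profile: FrequencyProfile = field(default_factory=FrequencyProfile)
    freq_profile_tau2: FrequencyProfile = field(default_factory=FrequencyProfile)
    mapping: SwitchMapping | None = None
    growth_profile: GrowthProfile | None = None
    tau1_mod_mode: str = "none"
    tau1_mod_map: PiecewiseMap | None = None
    clamps: dict = field(default_factory=dict)

    def active_modules(self) -> tuple[str, ...]:
        mods = ["tau1"]
        if self.uses_tau2:
            mods.append("tau2")
        if self.uses_tau3:
            mods.append("tau3")
        if self.uses_osc or self.osc_function_of_tau3:
            mods.append("oscillator")
        return tuple(mods)


def build_model(config: ModelConfig) -> Wiring:
    """Resolve a config into the executable wiring for the engine."""
    config.validate()
    v = config.variant
    spatial = config.saz_mode == "spatial"
    freeze = v in ("freeze", "freeze_elongation_feedback", "freeze_timer_feedback")
    uses_tau2 = v in ("clock_two_timers", "clock_three_timers", "three_timers_no_clock")
    uses_tau3 = v in ("clock_three_timers", "three_timers_no_clock")
    no_clock = v == "three_timers_no_clock"

    # the no-clock variant keeps the downstream machinery of the sequential
    # model but removes differential slowing: its "oscillator" is a readout
    # of tau3 (which is not rate-scaled), so tau2 must not be scaled either.
    ftau2 = FrequencyProfile("uniform") if no_clock else config.freq_profile_tau2_obj()

    wiring = Wiring(
        variant=v,
        spatial=spatial,
        uses_osc=not no_clock,
        osc_function_of_tau3=no_clock,
        uses_tau2=uses_tau2,
        uses_tau3=uses_tau3,
        uses_switch=not freeze,
        switch_source="none" if freeze else ("tau2" if uses_tau2 else "oscillator"),
        freeze_readout=freeze,
        elongation_gated=(v == "freeze_elongation_feedback"),
        timer_feedback=(v == "freeze_timer_feedback"),
        growth_from_tau3=(v == "clock_three_timers"),
        no_psc=no_clock,
        psc_off_on_termination=(v == "clock_three_timers"),
        freq_profile=config.freq_profile_obj(),
        freq_profile_tau2=ftau2,
        mapping=config.mapping_obj() if uses_tau2 else None,
        growth_profile=config.growth_profile_obj(),
        tau1_mod_mode=config.tau3_to_tau1_mode() if uses_tau3 else "none",
        tau1_mod_map=config.tau3_to_tau1_map() if uses_tau3 else None,
        clamps={},
    )
    for mod, val in config.clamps.items():
        wiring = apply_clamp(wiring, mod, float(val))
    return wiring


def apply_clamp(wiring: Wiring, module: str, value: float) -> Wiring:
    """Return a wiring in which ``module`` is held at ``value`` every step."""
    if module not in CLAMPABLE:
        raise ConfigError(f"unknown module {module!r}; choose from {CLAMPABLE}")
    active = wiring.active_modules()
    name = "oscillator" if module == "oscillator" else module
    if name not in active:
        raise ConfigError(
            f"module {module!r} is not present in variant {wiring.variant!r}"
        )
    clamps = dict(wiring.clamps)
    clamps[module] = float(value)
    return replace(wiring, clamps=clamps)


# ---------------------------------------------------------------------------
# simultaneous-patterning initial conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoClockInit:
    """Initial conditions for the no-clock variant matched to a sequential
    reference: a linear tau3 gradient whose per-cell slope ``s`` satisfies
    ``(1/m) / s = seg_length_target``."""

    L_final: int
    tau3_anterior: float
    tau3_posterior: float
    m: int
    T1: float
    T2: float
    T3: float
    mapping: object

    @property
    def slope(self) -> float:
        return (self.tau3_anterior - self.tau3_posterior) / (self.L_final - 1)

    def to_config(self, steps: int | None = None, **overrides) -> ModelConfig:
        cfg = ModelConfig(
            variant="three_timers_no_clock",
            L0=self.L_final,
            tau3_anterior=self.tau3_anterior,
            tau3_posterior=self.tau3_posterior,
            m=self.m,
            T1=self.T1,
            T2=self.T2,
            T3=self.T3,
            mapping=self.mapping,
            steps=int(self.T1) + 10 if steps is None else steps,
            **overrides,
        )
        return cfg.validate()


def derive_noclock_config(
    seg_length_target: float,
    m: int,
    L_final: int,
    T1: float,
    T2: float,
    T3: float,
    mapping: object = "three_state",
) -> NoClockInit:
    """Derive no-clock initial conditions reproducing a target repeat length.

    The oscillator readout has ``m`` peaks per unit of tau3, so a linear
    gradient of per-cell slope ``s = (1/m) / seg_length_target`` spaces the
    peaks ``seg_length_target`` cells apart.  The gradient is anchored at 1
    in the anterior-most cell; it is an error for it to leave [0, 1].
    """
    if seg_length_target < 2:
        raise ConfigError("seg_length_target must be >= 2 cells")
    if L_final < 2:
        raise ConfigError("L_final must be >= 2 cells")
    s = (1.0 / m) / seg_length_target
    span = s * (L_final - 1)
    if span > 1.0:
        raise ConfigError(
            f"tau3 gradient of slope {s:g}/cell leaves [0, 1] over {L_final} cells; "
            f"reduce L_final to <= {int(1.0 / s) + 1}"
        )
    return NoClockInit(
        L_final=int(L_final),
        tau3_anterior=1.0,
        tau3_posterior=1.0 - span,
        m=int(m),
        T1=T1,
        T2=T2,
        T3=T3,
        mapping=mapping,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Default parameters are documented illustrative choices, not transcriptions.
_GROWTH_RAMP = [[0.0, 0.0], [0.25, 0.1], [0.6, 0.3], [1.0, 0.3]]
_GROWTH_NEAR_CONSTANT = [[0.0, 0.0], [0.05, 0.2], [1.0, 0.2]]


def _presets() -> dict[str, ModelConfig]:
    base = dict(T1=40.0, T2=20.0, P=20.0, v=0.2, r=5, theta=0.995, lam=8.0)
    return {
        "clock_timer_temporal": ModelConfig(
            variant="clock_timer", saz_mode="temporal", steps=400, **base
        ),
        "clock_timer_spatial": ModelConfig(
            variant="clock_timer", saz_mode="spatial", steps=400, **base
        ),
        "two_timers_three_state": ModelConfig(
            variant="clock_two_timers",
            mapping="three_state",
            steps=500,
            **{**base, "T1": 80.0},
        ),
        "two_timers_pair_rule": ModelConfig(
            variant="clock_two_timers",
            mapping="pair_rule",
            steps=500,
            **{**base, "T1": 80.0, "v": 0.6},
        ),
        "freeze_baseline": ModelConfig(variant="freeze", steps=400, **base),
        "freeze_elongation_feedback": ModelConfig(
            variant="freeze_elongation_feedback", steps=400, **base
        ),
        "freeze_timer_feedback": ModelConfig(
            variant="freeze_timer_feedback", k=2.0, steps=400, **base
        ),
        "three_timers_growth": ModelConfig(
            variant="clock_three_timers",
            growth_profile=_GROWTH_RAMP,
            T3=600.0,
            steps=900,
            **{**base, "T1": 80.0},
        ),
        # T1 = 56 aligns the fixation delay (mod the effective repeat period)
        # with the sequential reference, so the repeating units match exactly.
        "no_clock": derive_noclock_config(
            seg_length_target=4, m=4, L_final=17, T1=56.0, T2=40.0, T3=160.0
        ).to_config(),
    }


PRESETS = _presets()


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset(name: str) -> ModelConfig:
    """Return a fresh, validated copy of a named preset config."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {preset_names()}")
    return PRESETS[name].copy().validate()


# ---------------------------------------------------------------------------
# idealized time-space transcription (half-cycle wavefront construction)
# ---------------------------------------------------------------------------


def wavefront_transcription(
    P: float = 20.0,
    base_speed: float = 0.2,
    multiplier: float = 1.0,
    cycles: int = 30,
    mode: str = "rising",
    dt: float = 0.01,
) -> np.ndarray:
    """Freeze synchronous sinusoidal oscillations at a moving wavefront.

    The whole field oscillates in phase ``phi(t) = t / P``.  In ``constant``
    mode the wavefront advances at ``base_speed`` cells per step throughout.
    In ``rising`` (``falling``) mode it advances at ``multiplier *
    base_speed`` only while the output level is rising from trough to peak
    (falling from peak to trough) and pauses otherwise.  Each unit-width cell
    records the oscillation phase at the moment the front passes it.

    Returns the wrapped recorded phase per cell.
    """
    if mode not in ("constant", "rising", "falling"):
        raise ValueError(f"unknown wavefront mode: {mode!r}")
    n_steps = int(round(cycles * P / dt))
    t = np.arange(n_steps) * dt
    phi = t / P
    frac = phi % 1.0
    if mode == "constant":
        speed = np.full(n_steps, base_speed)
    else:
        # output o = (sin(2 pi (phi - 1/4)) + 1)/2 rises for phi mod 1 in
        # [0, 0.5) and falls for [0.5, 1).
        moving = (frac < 0.5) if mode == "rising" else (frac >= 0.5)
        speed = np.where(moving, multiplier * base_speed, 0.0)
    position = np.concatenate([[0.0], np.cumsum(speed * dt)])
    n_cells = int(np.floor(position[-1]))
    # cell j is recorded when the front first reaches position j + 1
    cross = np.searchsorted(position, np.arange(1, n_cells + 1), side="left")
    recorded = phi[np.minimum(cross, n_steps - 1)] % 1.0
    return recorded
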