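"""Model configuration: a single flat, validated key set.

A :class:`ModelConfig` stores plain (JSON/YAML-serializable) values; parsed
profile/mapping objects are resolved lazily so that round-tripping through a
config file is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .dynamics import (
    FrequencyProfile,
    GrowthProfile,
    PiecewiseMap,
    ProfileError,
    SwitchMapping,
)

__all__ = ["ModelConfig", "ConfigError", "load_config", "dump_config", "VARIANTS"]

VARIANTS = (
    "clock_timer",
    "clock_two_timers",
    "freeze",
    "freeze_elongation_feedback",
    "freeze_timer_feedback",
    "clock_three_timers",
    "three_timers_no_clock",
)

SAZ_MODES = ("temporal", "spatial")

# which saz_modes each variant admits; three_timers_no_clock has no SAZ
# regulation at all — "temporal" is accepted as the neutral placeholder.
SAZ_SUPPORT = {
    "clock_timer": {"temporal", "spatial"},
    "clock_two_timers": {"temporal"},
    "freeze": {"temporal", "spatial"},
    "freeze_elongation_feedback": {"temporal", "spatial"},
    "freeze_timer_feedback": {"temporal", "spatial"},
    "clock_three_timers": {"temporal", "spatial"},
    "three_timers_no_clock": {"temporal"},
}

CLAMPABLE = ("tau1", "tau2", "tau3", "oscillator")


class ConfigError(ValueError):
    """Raised for schema violations, with the offending key named."""


@dataclass
class ModelConfig:
    """Complete parameterization of one simulation run.

    Durations (T1, T2, T3, P) are in time steps; v is in cells per step;
    r and lam are in cell diameters.
    """

    variant: str = "clock_timer"
    saz_mode: str = "temporal"
    T1: float = 40.0
    T2: float = 20.0
    T3: float = 600.0
    P: float = 20.0
    lam: float = 8.0
    v: float = 0.2
    r: int = 5
    theta: float = 0.995
    k: float = 2.0
    mapping: object = "three_state"
    growth_profile: object = None
    freq_profile: object = "exp2"
    freq_profile_tau2: object = None  # None -> inherit freq_profile
    tau3_to_tau1: object = "none"  # "none" | {"mode": "rate"|"initial", "points": [...]}
    clamps: dict = field(default_factory=dict)
    L0: int = 1
    steps: int = 400
    m: int = 4  # oscillator repeats per tau3 unit (no-clock variant)
    tau3_anterior: float = 1.0  # no-clock initial gradient endpoints
    tau3_posterior: float = 0.0

    # ------------------------------------------------------------------
    # parsed accessors
    # ------------------------------------------------------------------

    def mapping_obj(self) -> SwitchMapping:
        return SwitchMapping.from_spec(self.mapping)

    def growth_profile_obj(self) -> GrowthProfile | None:
        if self.growth_profile is None:
            return None
        return GrowthProfile.from_spec(self.growth_profile)

    def freq_profile_obj(self) -> FrequencyProfile:
        return FrequencyProfile.from_spec(self.freq_profile)

    def freq_profile_tau2_obj(self) -> FrequencyProfile:
        if self.freq_profile_tau2 is None:
            return self.freq_profile_obj()
        return FrequencyProfile.from_spec(self.freq_profile_tau2)

    def tau3_to_tau1_mode(self) -> str:
        if self.tau3_to_tau1 in (None, "none"):
            return "none"
        return self.tau3_to_tau1["mode"]

    def tau3_to_tau1_map(self) -> PiecewiseMap | None:
        if self.tau3_to_tau1_mode() == "none":
            return None
        return PiecewiseMap.from_spec(self.tau3_to_tau1["points"])

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------

    def validate(self) -> "ModelConfig":
        def bad(key, msg):
            raise ConfigError(f"config key {key!r}: {msg}")

        if self.variant not in VARIANTS:
            bad("variant", f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.saz_mode not in SAZ_MODES:
            bad("saz_mode", f"must be one of {SAZ_MODES}")
        if self.saz_mode not in SAZ_SUPPORT[self.variant]:
            bad(
                "saz_mode",
                f"variant {self.variant!r} does not support saz_mode {self.saz_mode!r}",
            )
        for key in ("T1", "T2", "T3", "P"):
            if getattr(self, key) < 1:
                bad(key, "durations and periods must be >= 1 time step")
        if self.v < 0:
            bad("v", "elongation rate must be >= 0")
        if int(self.r) != self.r or self.r < 1:
            bad("r", "signal range must be an integer >= 1 cell diameter")
        if not (0.0 < self.theta <= 1.0):
            bad("theta", "peak threshold must lie in (0, 1]")
        if self.lam <= 0:
            bad("lam", "SAZ length scale must be > 0")
        if self.k < 0:
            bad("k", "feedback strength must be >= 0")
        if int(self.L0) != self.L0 or self.L0 < 1:
            bad("L0", "initial length must be an integer >= 1 cell")
        if int(self.steps) != self.steps or self.steps < 0:
            bad("steps", "run length must be an integer >= 0")
        if int(self.m) != self.m or self.m < 1:
            bad("m", "oscillator repeats must be an integer >= 1")
        try:
            self.mapping_obj()
        except (ProfileError, KeyError, TypeError) as exc:
            bad("mapping", str(exc))
        try:
            self.growth_profile_obj()
        except (ProfileError, KeyError, TypeError) as exc:
            bad("growth_profile", str(exc))
        try:
            self.freq_profile_obj()
            self.freq_profile_tau2_obj()
        except (ProfileError, KeyError, TypeError) as exc:
            bad("freq_profile", str(exc))
        if self.tau3_to_tau1 not in (None, "none"):
            if not isinstance(self.tau3_to_tau1, dict) or set(self.tau3_to_tau1) != {
                "mode",
                "points",
            }:
                bad("tau3_to_tau1", 'expected "none" or {"mode": ..., "points": [...]}')
            mode = self.tau3_to_tau1["mode"]
            if mode not in ("rate", "initial"):
                bad("tau3_to_tau1", f"unknown mode {mode!r}")
            try:
                pmap = self.tau3_to_tau1_map()
            except (ProfileError, TypeError) as exc:
                bad("tau3_to_tau1", str(exc))
            ys = [y for _, y in pmap.points]
            if mode == "rate" and any(y < 1.0 for y in ys):
                bad("tau3_to_tau1", "rate-mode multipliers must be >= 1")
            if mode == "initial" and any(not (0.0 < y <= 1.0) for y in ys):
                bad("tau3_to_tau1", "initial-mode held levels must lie in (0, 1]")
        if not isinstance(self.clamps, dict):
            bad("clamps", "expected a mapping from module name to value")
        for mod, val in self.clamps.items():
            if mod not in CLAMPABLE:
                bad("clamps", f"unknown module {mod!r}; choose from {CLAMPABLE}")
            if not (0.0 <= float(val) <= 1.0):
                bad("clamps", f"clamp value for {mod!r} must lie in [0, 1]")
        if self.variant == "three_timers_no_clock":
            if not (0.0 <= self.tau3_posterior < self.tau3_anterior <= 1.0):
                bad(
                    "tau3_anterior",
                    "initial gradient must decrease strictly from anterior to "
                    "posterior within [0, 1]",
                )
        if self.variant == "clock_three_timers" and self.growth_profile is None:
            bad("growth_profile", "clock_three_timers requires a growth profile")
        return self

    # ------------------------------------------------------------------
    # (de)serialization
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def copy(self, **updates) -> "ModelConfig":
        return replace(self, **updates)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {sorted(unknown)}; known keys are {sorted(known)}"
            )
        cfg = cls(**data)
        return cfg.validate()


def load_config(path: str | Path) -> ModelConfig:
    """Load and fully validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of config keys")
    return ModelConfig.from_dict(data)


def dump_config(config: ModelConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
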