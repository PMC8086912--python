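"""Discrete-time synchronous simulation over a growing 1-D row of cells.

The embryo is an ordered array of cells (index 0 = anterior-most).  Each
step: (1) the posterior signal mask is recomputed at the current length;
(2) every module of every cell is updated from the t_n snapshot; (3) fate
hand-over (write-once switch) is applied using the just-updated values;
(4) elongation duplicates the post-update posterior-most cell via a
fractional growth accumulator.  There is no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from . import dynamics as dyn
from .config import ModelConfig

__all__ = [
    "CellState",
    "EmbryoState",
    "History",
    "signal_mask",
    "pi_field",
    "elongate",
    "step",
    "run",
    "StateError",
]

ABSENT = np.nan  # sentinel for cells not yet born


class StateError(RuntimeError):
    """Raised when an update drives a level outside [0, 1]."""


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class CellState:
    """Per-cell state vector; inactive modules carry ``None``."""

    tau1: float
    tau2: float | None
    tau3: float | None
    phase: float | None  # unwrapped, non-decreasing
    osc_out: float | None
    switch: int
    signal: bool

    @property
    def phase_wrapped(self) -> float | None:
        return None if self.phase is None else self.phase % 1.0


@dataclass
class EmbryoState:
    """Ordered cell array plus run counters.

    All per-cell quantities are parallel numpy arrays; ``L`` is their common
    length.  Arrays for modules not present in the variant are ``None``.
    """

    tau1: np.ndarray
    tau2: np.ndarray | None
    tau3: np.ndarray | None
    phase: np.ndarray | None
    osc: np.ndarray | None
    switch: np.ndarray
    signal: np.ndarray
    t: int = 0
    growth_accumulator: float = 0.0
    psc_active: bool = True

    @property
    def L(self) -> int:
        return len(self.tau1)

    def cell(self, i: int) -> CellState:
        def get(arr):
            return None if arr is None else float(arr[i])

        return CellState(
            tau1=float(self.tau1[i]),
            tau2=get(self.tau2),
            tau3=get(self.tau3),
            phase=get(self.phase),
            osc_out=get(self.osc),
            switch=int(self.switch[i]),
            signal=bool(self.signal[i]),
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def signal_mask(L: int, r: int, psc_active: bool) -> np.ndarray:
    """Boolean mask: the min(L, r) posterior-most cells, if the PSC is on."""
    if L < 1:
        raise ValueError("embryo must contain at least one cell")
    if r < 1:
        raise ValueError("signal range must be >= 1")
    mask = np.zeros(L, dtype=bool)
    if psc_active:
        mask[max(0, L - int(r)) :] = True
    return mask


def pi_field(L: int, r: int, lam: float) -> np.ndarray:
    """Positional-information levels along the axis.

    Cells at or posterior to the anterior edge of the signal range take
    value 1; anterior cells read ``max(0, 1 - d/lam)`` where d is their
    distance (in cell diameters) from that edge.  The field is anchored to
    the geometry, so it persists even if the PSC itself decays.
    """
    edge = max(0, L - int(r))
    idx = np.arange(L)
    dist = np.maximum(0, edge - idx)
    return dyn.pi_value(dist, lam)


# ---------------------------------------------------------------------------
# elongation
# ---------------------------------------------------------------------------


def elongate(embryo: EmbryoState, v_effective: float) -> int:
    """Accumulate growth and duplicate the posterior-most cell as needed.

    Returns the number of cells added.  Each addition copies every state
    variable of the posterior cell and implicitly displaces the PSC by one
    cell diameter (the signal mask is recomputed at the new length on the
    next step).
    """
    if v_effective < 0:
        raise ValueError("elongation rate must be >= 0")
    embryo.growth_accumulator += v_effective
    additions = int(np.floor(embryo.growth_accumulator))
    embryo.growth_accumulator -= additions
    if additions:
        for name in ("tau1", "tau2", "tau3", "phase", "osc", "switch", "signal"):
            arr = getattr(embryo, name)
            if arr is None:
                continue
            tail = np.repeat(arr[-1:], additions)
            setattr(embryo, name, np.concatenate([arr, tail]))
    return additions


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------


def initial_state(config: ModelConfig, wiring) -> EmbryoState:
    L0 = int(config.L0)
    psc_active = not wiring.no_psc
    sig = signal_mask(L0, int(config.r), psc_active)
    tau1 = np.ones(L0)
    if wiring.spatial:
        tau1 = pi_field(L0, int(config.r), config.lam)
    tau2 = np.ones(L0) if wiring.uses_tau2 else None
    tau3 = None
    if wiring.uses_tau3:
        if wiring.variant == "three_timers_no_clock":
            tau3 = np.linspace(config.tau3_anterior, config.tau3_posterior, L0)
        else:
            tau3 = np.ones(L0)
    phase = np.zeros(L0) if wiring.uses_osc else None
    if wiring.osc_function_of_tau3:
        osc = np.asarray(dyn.oscillator_as_function(tau3, config.m), dtype=float)
    elif wiring.uses_osc:
        osc = np.asarray(dyn.oscillator_output(phase), dtype=float) * np.ones(L0)
    else:
        osc = None
    switch = np.zeros(L0, dtype=int)
    embryo = EmbryoState(
        tau1=tau1,
        tau2=tau2,
        tau3=tau3,
        phase=phase,
        osc=osc,
        switch=switch,
        signal=sig,
        t=0,
        growth_accumulator=0.0,
        psc_active=psc_active,
    )
    _apply_clamps(embryo, wiring)
    return embryo


def _apply_clamps(embryo: EmbryoState, wiring) -> None:
    for mod, val in wiring.clamps.items():
        if mod == "oscillator":
            if embryo.osc is not None:
                embryo.osc = np.full(embryo.L, val)
        else:
            arr = getattr(embryo, mod)
            if arr is not None:
                setattr(embryo, mod, np.full(embryo.L, val))


# ---------------------------------------------------------------------------
# the synchronous step
# ---------------------------------------------------------------------------


def step(embryo: EmbryoState, config: ModelConfig, wiring) -> int:
    """Advance the embryo by one time step in place.

    Returns the number of cells added by elongation this step (the
    effective rate applied is stored on ``embryo.last_v_effective``).
    """
    L = embryo.L
    r = int(config.r)
    sig = signal_mask(L, r, embryo.psc_active)

    # t_n snapshot
    tau1_s = embryo.tau1
    tau2_s = embryo.tau2
    tau3_s = embryo.tau3
    phase_s = embryo.phase
    osc_s = embryo.osc
    switch_s = embryo.switch

    in_saz_s = tau1_s > 0.0

    # --- timer 1 / PI field -------------------------------------------------
    if wiring.spatial:
        tau1_n = pi_field(L, r, config.lam)
    else:
        rate = np.ones(L)
        if wiring.timer_feedback:
            rate = rate * dyn.timer_rate_feedback(osc_s, config.k)
        if wiring.tau1_mod_mode == "rate":
            rate = rate * dyn.tau1_modulation(tau3_s, "rate", wiring.tau1_mod_map)
        if wiring.tau1_mod_mode == "initial":
            held_level = dyn.tau1_modulation(tau3_s, "initial", wiring.tau1_mod_map)
        else:
            held_level = np.ones(L)
        free = dyn.timer_update(tau1_s, False, rate, config.T1)
        tau1_n = np.where(sig, held_level, free)

    # --- timer 3 ------------------------------------------------------------
    tau3_n = None
    if wiring.uses_tau3:
        tau3_n = dyn.timer3_update(tau3_s, in_saz_s, config.T3)

    # --- oscillator ---------------------------------------------------------
    phase_n = phase_s
    osc_n = osc_s
    o_raw = None
    if wiring.osc_function_of_tau3:
        o_raw = np.asarray(dyn.oscillator_as_function(tau3_s, config.m), dtype=float)
        osc_n = np.where(in_saz_s, o_raw, osc_s)
    elif wiring.uses_osc:
        phase_n = dyn.oscillator_update(phase_s, tau1_s, config.P, wiring.freq_profile)
        o_raw = np.asarray(dyn.oscillator_output(phase_n), dtype=float)
        if wiring.freeze_readout:
            osc_n = o_raw
        else:
            osc_n = np.where(tau1_n > 0.0, o_raw, 0.0)

    # --- timer 2 ------------------------------------------------------------
    tau2_n = None
    if wiring.uses_tau2:
        scale = dyn.frequency_scale(tau1_s, wiring.freq_profile_tau2)
        tau2_n = dyn.timer2_update(
            tau2_s, osc_s, config.theta, config.T2, in_saz_s, rate_scale=scale
        )

    # --- clamps -------------------------------------------------------------
    for mod, val in wiring.clamps.items():
        if mod == "tau1":
            tau1_n = np.full(L, val)
        elif mod == "tau2" and tau2_n is not None:
            tau2_n = np.full(L, val)
        elif mod == "tau3" and tau3_n is not None:
            tau3_n = np.full(L, val)
        elif mod == "oscillator" and osc_n is not None:
            osc_n = np.full(L, val)
            o_raw = osc_n

    # --- consistency --------------------------------------------------------
    for name, arr in (("tau1", tau1_n), ("tau2", tau2_n), ("tau3", tau3_n)):
        if arr is not None and (np.any(arr < 0.0) or np.any(arr > 1.0)):
            raise StateError(f"{name} left [0, 1] at t={embryo.t}")

    # --- fate hand-over (uses just-updated values) --------------------------
    switch_n = switch_s
    if wiring.uses_switch:
        newly = (switch_s == 0) & (tau1_s > 0.0) & (tau1_n <= 0.0)
        if np.any(newly):
            if wiring.switch_source == "oscillator":
                fates = dyn.fate_from_oscillator(o_raw)
            else:
                fates = dyn.fate_from_mapping(tau2_n, wiring.mapping)
            switch_n = np.where(newly, fates, switch_s)

    # --- commit -------------------------------------------------------------
    embryo.tau1 = tau1_n
    embryo.tau2 = tau2_n
    embryo.tau3 = tau3_n
    embryo.phase = phase_n
    embryo.osc = osc_n
    embryo.switch = switch_n
    embryo.t += 1

    # --- PSC decay on axial termination ------------------------------------
    if (
        wiring.psc_off_on_termination
        and embryo.psc_active
        and tau3_n is not None
        and tau3_n[-1] <= 0.0
    ):
        embryo.psc_active = False

    # recorded mask is the one the update used (newborn cells copy the
    # posterior cell's True entry), keeping each snapshot internally
    # consistent at its own geometry
    embryo.signal = sig if embryo.psc_active else np.zeros(L, dtype=bool)

    # --- elongation ---------------------------------------------------------
    additions = 0
    v_eff = 0.0
    if embryo.psc_active and not wiring.no_psc:
        if wiring.growth_from_tau3:
            v_eff = float(dyn.growth_rate(tau3_n[-1], wiring.growth_profile))
        else:
            v_eff = float(config.v)
        if wiring.elongation_gated and not dyn.elongation_gate(osc_n[-1]):
            v_eff = 0.0
        additions = elongate(embryo, v_eff)

    embryo.last_v_effective = v_eff
    return additions


# ---------------------------------------------------------------------------
# history
# ---------------------------------------------------------------------------


@dataclass
class History:
    """time x cell record of every active variable, with birth-aware NaNs.

    ``data`` maps variable name -> array of shape (steps + 1, L_final);
    entries are ``NaN`` strictly before a cell's birth step.  Cells never
    rearrange, so a column index is both cell identity and AP position.
    """

    data: dict
    birth: np.ndarray
    L: np.ndarray
    v_effective: np.ndarray
    additions: np.ndarray
    psc: np.ndarray
    config: ModelConfig

    @property
    def steps(self) -> int:
        return self.data["tau1"].shape[0] - 1

    @property
    def n_cells(self) -> int:
        return self.data["tau1"].shape[1]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.data)

    def state_at(self, t: int) -> SimpleNamespace:
        """Lightweight snapshot view of the embryo at step ``t``."""
        if not (0 <= t <= self.steps):
            raise IndexError(f"step {t} outside recorded range 0..{self.steps}")
        alive = int(self.L[t])

        def var(name):
            if name not in self.data:
                return None
            return self.data[name][t, :alive]

        sw = var("switch")
        return SimpleNamespace(
            t=t,
            L=alive,
            tau1=var("tau1"),
            tau2=var("tau2"),
            tau3=var("tau3"),
            phase=var("phase"),
            osc=var("osc"),
            switch=None if sw is None else sw.astype(int),
            signal=None if var("signal") is None else var("signal") > 0.5,
            psc_active=bool(self.psc[t]),
        )

    def final_pattern(self) -> np.ndarray | None:
        """Switch states at the last recorded step (int array), if present."""
        if "switch" not in self.data:
            return None
        return self.data["switch"][-1].astype(int)

    def fixation_times(self) -> np.ndarray:
        """Per cell: first step at which its fate (or frozen phase) is set.

        For switch variants this is the first step with switch != 0; for
        freeze-readout variants, the first step with tau1 == 0.  Cells never
        fixed carry -1.
        """
        if "switch" in self.data:
            fixed = np.nan_to_num(self.data["switch"], nan=0.0) > 0
        else:
            tau1 = self.data["tau1"]
            fixed = np.nan_to_num(tau1, nan=1.0) == 0.0
        any_fixed = fixed.any(axis=0)
        first = fixed.argmax(axis=0)
        return np.where(any_fixed, first, -1)


def run(config: ModelConfig, wiring=None) -> History:
    """Simulate ``config.steps`` steps and return the full History."""
    from .models import build_model  # local import to avoid a cycle

    config = config.validate()
    if wiring is None:
        wiring = build_model(config)

    embryo = initial_state(config, wiring)
    snapshots = []
    scalars = {"L": [], "v_effective": [], "additions": [], "psc": []}
    births = {i: 0 for i in range(embryo.L)}

    def record(additions=0, v_eff=0.0):
        snap = {}
        snap["tau1"] = embryo.tau1.copy()
        if embryo.tau2 is not None:
            snap["tau2"] = embryo.tau2.copy()
        if embryo.tau3 is not None:
            snap["tau3"] = embryo.tau3.copy()
        if embryo.phase is not None:
            snap["phase"] = embryo.phase.copy()
        if embryo.osc is not None:
            snap["osc"] = embryo.osc.copy()
        if wiring.uses_switch:
            snap["switch"] = embryo.switch.astype(float)
        snap["signal"] = embryo.signal.astype(float)
        snapshots.append(snap)
        scalars["L"].append(embryo.L)
        scalars["v_effective"].append(v_eff)
        scalars["additions"].append(additions)
        scalars["psc"].append(embryo.psc_active)

    record()
    for _ in range(int(config.steps)):
        prev_L = embryo.L
        additions = step(embryo, config, wiring)
        for i in range(prev_L, embryo.L):
            births[i] = embryo.t
        record(additions, embryo.last_v_effective)

    n_t = len(snapshots)
    n_c = embryo.L
    data = {}
    for name in snapshots[-1]:
        mat = np.full((n_t, n_c), ABSENT)
        for t_i, snap in enumerate(snapshots):
            row = snap[name]
            mat[t_i, : len(row)] = row
        data[name] = mat
    return History(
        data=data,
        birth=np.array([births[i] for i in range(n_c)]),
        L=np.array(scalars["L"]),
        v_effective=np.array(scalars["v_effective"]),
        additions=np.array(scalars["additions"]),
        psc=np.array(scalars["psc"], dtype=bool),
        config=config,
    )
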