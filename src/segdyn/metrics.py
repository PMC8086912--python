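"""Observables computed from simulation snapshots and histories.

Conventions (documented once, used everywhere):

* the SAZ at a snapshot = cells with tau1 > 0 (or PI > 0) that are not
  signal-positive;
* segment boundaries are transitions *into* a designated boundary state,
  scanned anterior to posterior; an onset at index 0 is never counted, so
  partial first repeats are excluded by construction;
* phase differences are computed on the engine's unwrapped phase and
  reported in cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import History

__all__ = [
    "saz_length",
    "wavefront_position",
    "saz_phase_difference",
    "segment_lengths",
    "boundary_onsets",
    "repeating_unit",
    "pattern_equivalence",
    "EquivalenceResult",
    "frozen_phases",
    "recorded_phase_distribution",
    "PhaseHistogram",
    "circular_span",
    "summary_curves",
    "SummaryCurves",
    "segments_with_formation",
    "lag_scaling",
    "LagScalingResult",
    "monotone_image",
    "completion_time",
    "transcription_repeat_length",
    "MetricError",
]


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# snapshot metrics
# ---------------------------------------------------------------------------


def saz_length(state) -> int:
    """Number of cells with tau1 (or PI) > 0, excluding signal-positive ones."""
    sig = state.signal if state.signal is not None else np.zeros(state.L, dtype=bool)
    return int(np.count_nonzero((state.tau1 > 0.0) & ~sig))


def wavefront_position(state) -> int:
    """Index of the anterior-most cell with tau1 > 0; L if all cells fated."""
    in_saz = state.tau1 > 0.0
    if not np.any(in_saz):
        return int(state.L)
    return int(np.argmax(in_saz))


def saz_phase_difference(state) -> float:
    """Unwrapped phase of the posterior-most non-signal SAZ cell minus that
    of the anterior-most SAZ cell, in cycles; NaN if the SAZ is empty."""
    sig = state.signal if state.signal is not None else np.zeros(state.L, dtype=bool)
    saz = (state.tau1 > 0.0) & ~sig
    if state.phase is None or not np.any(saz):
        return float("nan")
    idx = np.flatnonzero(saz)
    return float(state.phase[idx[-1]] - state.phase[idx[0]])


# ---------------------------------------------------------------------------
# pattern metrics
# ---------------------------------------------------------------------------


def boundary_onsets(pattern, boundary_state=1) -> np.ndarray:
    """Indices where the pattern transitions into the boundary state.

    ``boundary_state`` may be a single state or a collection (e.g. the two
    anterior-class fates of a double-segment repeat).
    """
    pattern = np.asarray(pattern)
    if np.ndim(boundary_state) == 0:
        states = {int(boundary_state)}
    else:
        states = {int(s) for s in boundary_state}
    is_b = np.isin(pattern, list(states))
    onsets = np.flatnonzero(is_b[1:] & ~is_b[:-1]) + 1
    return onsets


def segment_lengths(pattern, boundary_state=1) -> np.ndarray:
    """Distances between successive onsets of the boundary state.

    First and last partial repeats are excluded: an onset requires a genuine
    transition, and only inter-onset distances are reported.  Fewer than two
    onsets yields an empty array.
    """
    onsets = boundary_onsets(pattern, boundary_state)
    if len(onsets) < 2:
        return np.array([], dtype=int)
    return np.diff(onsets)


def repeating_unit(pattern) -> tuple[int, np.ndarray]:
    """Minimal repeating unit of the interior of a fated pattern.

    The central half of the pattern (edges trimmed by a quarter at each end)
    is scanned for the smallest period p with x[i] == x[i + p] throughout.
    The unit is canonicalized to its lexicographically minimal rotation so
    comparisons are rotation-invariant.
    """
    pattern = np.asarray(pattern)
    if len(pattern) == 0:
        raise MetricError("empty pattern")
    if np.any(pattern <= 0):
        raise MetricError("pattern contains unfated cells")
    q = len(pattern) // 4
    center = pattern[q : len(pattern) - q]
    n = len(center)
    for p in range(1, n // 2 + 1):
        if np.all(center[:-p] == center[p:]):
            return p, _canonical_rotation(center[:p])
    return n, _canonical_rotation(center)


def _canonical_rotation(unit: np.ndarray) -> np.ndarray:
    rotations = [tuple(np.roll(unit, -s)) for s in range(len(unit))]
    return np.array(min(rotations))


@dataclass(frozen=True)
class EquivalenceResult:
    equivalent: bool
    unit_a: np.ndarray
    unit_b: np.ndarray
    mismatches: int | None  # minimal over cyclic alignments; None if lengths differ

    def __bool__(self) -> bool:
        return self.equivalent


def pattern_equivalence(a, b) -> EquivalenceResult:
    """Compare the interior repeating units of two fully fated patterns."""
    pa, ua = repeating_unit(a)
    pb, ub = repeating_unit(b)
    if pa != pb:
        return EquivalenceResult(False, ua, ub, None)
    mism = min(
        int(np.count_nonzero(np.roll(ua, -s) != ub)) for s in range(pa)
    )
    return EquivalenceResult(mism == 0, ua, ub, mism)


# ---------------------------------------------------------------------------
# recorded (frozen) phases
# ---------------------------------------------------------------------------

FREEZE_VARIANTS = ("freeze", "freeze_elongation_feedback", "freeze_timer_feedback")


def frozen_phases(history: History, min_fix_time: int = 0) -> np.ndarray:
    """Wrapped phases of cells whose oscillator has been frozen.

    ``min_fix_time`` excludes cells frozen before a burn-in step.
    """
    if history.config.variant not in FREEZE_VARIANTS:
        raise MetricError(
            "recorded phases are defined only for freeze-readout variants"
        )
    fix = history.fixation_times()
    frozen = (fix >= 0) & (fix >= min_fix_time)
    final_phase = history.data["phase"][-1]
    return final_phase[frozen] % 1.0


@dataclass
class PhaseHistogram:
    """Frequency of frozen phases per bin, one row per swept parameter."""

    bin_edges: np.ndarray
    counts: np.ndarray  # shape (n_rows, n_bins)
    labels: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"[{a:.3f},{b:.3f})" for a, b in zip(self.bin_edges, self.bin_edges[1:])]
        return pd.DataFrame(self.counts, index=self.labels, columns=cols)


def recorded_phase_distribution(
    histories, labels=None, bins: int = 50, min_fix_time: int = 0
) -> PhaseHistogram:
    """Histogram of frozen phases, optionally stratified over a sweep."""
    if isinstance(histories, History):
        histories = [histories]
    if labels is None:
        labels = list(range(len(histories)))
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.zeros((len(histories), bins), dtype=int)
    for i, hist in enumerate(histories):
        ph = frozen_phases(hist, min_fix_time=min_fix_time)
        counts[i], _ = np.histogram(ph, bins=edges)
    return PhaseHistogram(bin_edges=edges, counts=counts, labels=list(labels))


def circular_span(phases) -> float:
    """Length of the smallest arc of the unit phase circle containing all
    phases (0 for a single phase, approaching 1 for full coverage)."""
    phases = np.sort(np.asarray(phases, dtype=float) % 1.0)
    if len(phases) == 0:
        raise MetricError("no phases")
    if len(phases) == 1:
        return 0.0
    gaps = np.diff(np.concatenate([phases, [phases[0] + 1.0]]))
    return float(1.0 - gaps.max())


# ---------------------------------------------------------------------------
# time-resolved summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryCurves:
    frame: pd.DataFrame  # columns: t, L, L_SAZ, v_effective, delta_phase,
    #                       wavefront, tip, seg_length_formed

    def __getitem__(self, key):
        return self.frame[key]


def summary_curves(history: History) -> SummaryCurves:
    rows = []
    for t in range(history.steps + 1):
        state = history.state_at(t)
        rows.append(
            dict(
                t=t,
                L=state.L,
                L_SAZ=saz_length(state),
                v_effective=history.v_effective[t],
                delta_phase=saz_phase_difference(state),
                wavefront=wavefront_position(state),
                tip=state.L,
                seg_length_formed=np.nan,
            )
        )
    frame = pd.DataFrame(rows)
    if "switch" in history.data:
        segs = segments_with_formation(history)
        for _, seg in segs.iterrows():
            frame.loc[frame["t"] == seg["t_formed"], "seg_length_formed"] = seg["length"]
    return SummaryCurves(frame)


def segments_with_formation(history: History, boundary_state=1) -> pd.DataFrame:
    """Per complete segment: start index, length, formation step, and the
    effective elongation rate at the formation step.

    A segment's formation step is the fixation step of its posterior-most
    cell.  Returns an empty frame for patterns with < 2 onsets.
    """
    pattern = history.final_pattern()
    if pattern is None:
        raise MetricError("variant records no switch pattern")
    fated = pattern > 0
    if not np.any(fated):
        return pd.DataFrame(columns=["start", "length", "t_formed", "v_at_formation"])
    onsets = boundary_onsets(pattern[fated], boundary_state)
    offset = int(np.argmax(fated))
    fix = history.fixation_times()
    rows = []
    for a, b in zip(onsets, onsets[1:]):
        start = offset + int(a)
        end = offset + int(b)  # exclusive
        t_formed = int(fix[start:end].max())
        rows.append(
            dict(
                start=start,
                length=end - start,
                t_formed=t_formed,
                v_at_formation=float(history.v_effective[t_formed]),
            )
        )
    return pd.DataFrame(rows, columns=["start", "length", "t_formed", "v_at_formation"])


def steady_delta_phase(history: History, window: int = 150) -> float:
    """Steady-state SAZ phase difference: the maximum over the last
    ``window`` steps, i.e. the value with the SAZ at full extension.

    The snapshot value dips each time the determination front consumes the
    anterior-most SAZ cell, by an amount set by the wavefront quantization
    (~1/v steps); sampling at full extension removes that sampling artifact
    and makes runs with different v comparable.
    """
    t0 = max(0, history.steps - window)
    vals = [
        saz_phase_difference(history.state_at(t))
        for t in range(t0, history.steps + 1)
    ]
    return float(np.nanmax(vals))


@dataclass(frozen=True)
class LagScalingResult:
    best_lag: int
    best_corr: float
    corr_at_zero: float
    informative: bool


def lag_scaling(history: History, max_lag: int = 200, boundary_state=1) -> LagScalingResult:
    """Lag maximizing the correlation between segment length at formation
    time t and L_SAZ(t - lag); flags constant-velocity runs as uninformative."""
    if max_lag >= history.steps:
        raise MetricError("lag search window must not exceed run length")
    segs = segments_with_formation(history, boundary_state)
    if len(segs) < 3:
        raise MetricError("too few complete segments for lag analysis")
    v = history.v_effective[1:]
    informative = bool(np.nanstd(v[v > 0]) > 1e-12) and segs["length"].nunique() > 1
    curves = summary_curves(history)
    lsaz = curves["L_SAZ"].to_numpy(dtype=float)
    times = segs["t_formed"].to_numpy(dtype=int)
    lengths = segs["length"].to_numpy(dtype=float)
    usable = times - max_lag >= 0
    times, lengths = times[usable], lengths[usable]
    if len(times) < 3:
        raise MetricError("too few segments after lag trimming")
    best_lag, best_corr, corr0 = 0, -np.inf, np.nan
    for lag in range(0, max_lag + 1):
        ref = lsaz[times - lag]
        if np.std(ref) == 0 or np.std(lengths) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(lengths, ref)[0, 1])
        if lag == 0:
            corr0 = corr
        if np.isfinite(corr) and corr > best_corr:
            best_lag, best_corr = lag, corr
    return LagScalingResult(best_lag, best_corr, corr0, informative)


def monotone_image(x, y) -> bool:
    """True iff (x, y) contains no strictly discordant pair — i.e. y is a
    (weakly) monotone non-decreasing image of x, ties allowed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return bool(np.all(dx * dy >= 0))


def completion_time(history: History) -> int | None:
    """First step at which every cell is fated; None if never reached."""
    if "switch" not in history.data:
        raise MetricError("variant records no switch pattern")
    sw = np.nan_to_num(history.data["switch"], nan=0.0)
    alive = ~np.isnan(history.data["tau1"])
    done = np.all((sw > 0) | ~alive, axis=1) & (history.L == history.n_cells)
    if not np.any(done):
        return None
    return int(np.argmax(done))


# ---------------------------------------------------------------------------
# idealized transcription analysis
# ---------------------------------------------------------------------------


def transcription_repeat_length(recorded_phases) -> float:
    """Modal spatial repeat length of a recorded phase pattern.

    The recorded phase increases monotonically within a repeat (it tracks
    time), so repeats are delimited by any decrease along the axis; the mode
    of the inter-wrap distances is returned (NaN if fewer than two wraps)."""
    ph = np.asarray(recorded_phases, dtype=float)
    wraps = np.flatnonzero(np.diff(ph) < -1e-6) + 1
    if len(wraps) < 2:
        return float("nan")
    d = np.diff(wraps)
    values, counts = np.unique(d, return_counts=True)
    return float(values[np.argmax(counts)])
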