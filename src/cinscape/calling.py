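"""Integer copy-number calling from binned single-cell read counts.

The caller is a four-stage pipeline per cell:

1. **normalize** — divide counts by the known per-bin GC-like bias and rescale
   so the genome-wide median ratio is 1; ratios are then in units of the
   cell's median copy signal.
2. **segment** — recursive binary segmentation per chromosome: split at the
   boundary maximising the reduction in within-segment sum of squared
   deviations, accepting a split only if the reduction exceeds
   ``gain_threshold`` times the chromosome's total sum of squares and both
   sides keep at least ``min_seg`` bins. Deterministic; breakpoints never
   cross chromosome boundaries.
3. **fit the ploidy scale** — choose the multiplicative scale s (and implied
   base ploidy) that brings segment medians closest to integers, over a grid
   of candidate base ploidies; an experimental sort gate (cells sorted for 2c
   or 4c DNA content) restricts the candidates, which is what resolves the
   inherent diploid/tetraploid ambiguity of an all-even karyotype.
4. **call** — per bin, the state is the rounded scaled segment median, clipped
   to [0, max_copy].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout
from .profiles import PopulationMatrix


class CallingError(ValueError):
    """Invalid caller input."""


GATE_CANDIDATES: dict[str | None, tuple[int, ...]] = {
    None: tuple(range(1, 9)),
    "2c": (1, 2, 3),
    "4c": (3, 4, 5),
}


@dataclass(frozen=True, eq=False)
class NormalizedProfile:
    """Per-bin copy-signal ratios, genome-wide median 1."""

    layout: GenomeLayout
    ratio: np.ndarray = field(repr=False)


@dataclass(frozen=True, eq=False)
class SegmentedProfile:
    """Piecewise-constant summary of a normalized profile.

    Segments are stored as parallel arrays of global bin bounds (half-open)
    and the median ratio of each segment; together they partition all bins
    and never span a chromosome boundary.
    """

    layout: GenomeLayout
    start_bin: np.ndarray = field(repr=False)
    end_bin: np.ndarray = field(repr=False)
    median: np.ndarray = field(repr=False)

    @property
    def n_segments(self) -> int:
        return len(self.start_bin)

    @property
    def lengths(self) -> np.ndarray:
        return self.end_bin - self.start_bin

    def per_bin_median(self) -> np.ndarray:
        out = np.empty(self.layout.n_bins)
        for s, e, m in zip(self.start_bin, self.end_bin, self.median):
            out[s:e] = m
        return out

    def to_frame(self) -> pd.DataFrame:
        names = self.layout.chrom_names
        return pd.DataFrame(
            {
                "chromosome": [names[self.layout.bin_chrom[s]] for s in self.start_bin],
                "start": self.layout.bin_start[self.start_bin],
                "end": self.layout.bin_end[self.end_bin - 1],
                "start_bin": self.start_bin,
                "end_bin": self.end_bin,
                "median": self.median,
            }
        )


def normalize_counts(counts: np.ndarray, layout: GenomeLayout,
                     gc_factor: np.ndarray | None = None) -> NormalizedProfile:
    """GC-correct and median-rescale one cell's binned counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (layout.n_bins,):
        raise CallingError(
            f"counts shape {counts.shape} does not match layout "
            f"({layout.n_bins} bins)"
        )
    if (counts < 0).any():
        raise CallingError("negative read counts")
    if not counts.any():
        raise CallingError("all-zero counts: cannot normalize")
    gc = np.ones(layout.n_bins) if gc_factor is None else np.asarray(gc_factor, float)
    if (gc <= 0).any():
        raise CallingError("gc factors must be positive")
    ratio = counts / gc
    med = np.median(ratio)
    if med <= 0:
        med = ratio[ratio > 0].mean()
    return NormalizedProfile(layout=layout, ratio=ratio / med)


def _best_split(x: np.ndarray, min_seg: int):
    """Best binary split of x: (breakpoint, SSE reduction); None if no legal split."""
    n = len(x)
    if n < 2 * min_seg:
        return None
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total_sse = c2[-1] - c1[-1] ** 2 / n
    k = np.arange(min_seg, n - min_seg + 1)  # left part x[:k]
    left_sum, left_sq = c1[k - 1], c2[k - 1]
    right_sum, right_sq = c1[-1] - left_sum, c2[-1] - left_sq
    sse = (left_sq - left_sum**2 / k) + (right_sq - right_sum**2 / (n - k))
    best = int(np.argmin(sse))
    return int(k[best]), float(total_sse - sse[best])


def _segment_block(x: np.ndarray, min_seg: int, threshold: float) -> list[int]:
    """Recursive binary segmentation; returns internal breakpoints (local bins)."""
    split = _best_split(x, min_seg)
    if split is None:
        return []
    k, reduction = split
    if reduction <= threshold or reduction <= 0:
        return []
    left = _segment_block(x[:k], min_seg, threshold)
    right = _segment_block(x[k:], min_seg, threshold)
    return left + [k] + [k + b for b in right]


def segment_bins(normalized: NormalizedProfile, min_seg: int = 3,
                 gain_threshold: float = 0.1) -> SegmentedProfile:
    """Segment each chromosome of a normalized profile; see module docstring."""
    if min_seg < 1:
        raise CallingError(f"min_seg must be >= 1, got {min_seg}")
    if gain_threshold < 0:
        raise CallingError(f"gain_threshold must be >= 0, got {gain_threshold}")
    layout = normalized.layout
    starts, ends, medians = [], [], []
    for sl in layout.chrom_slices:
        x = normalized.ratio[sl]
        total_sse = float(((x - x.mean()) ** 2).sum())
        breaks = sorted(_segment_block(x, min_seg, gain_threshold * total_sse))
        bounds = [0] + breaks + [len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            starts.append(sl.start + a)
            ends.append(sl.start + b)
            medians.append(float(np.median(x[a:b])))
    return SegmentedProfile(
        layout=layout,
        start_bin=np.asarray(starts, dtype=np.int64),
        end_bin=np.asarray(ends, dtype=np.int64),
        median=np.asarray(medians),
    )


def fit_ploidy_scale(segmented: SegmentedProfile,
                     candidate_ploidies=None,
                     ploidy_gate: str | None = None,
                     n_scale_grid: int = 99):
    """Choose the scale s mapping segment medians to integer states.

    For each candidate base ploidy P, s is searched on a fine grid under the
    constraint round(s * overall_median) == P; the cost is the segment-length
    weighted distance of scaled medians to the nearest integer. Ties between
    ploidies (e.g. a flat genome, exact under any even multiple) break toward
    the gate's nominal ploidy (2 for an ungated or 2c-sorted cell, 4 for a
    4c-sorted one), then toward the lower ploidy. Returns ``(s, base_ploidy)``.
    """
    if candidate_ploidies is None:
        candidate_ploidies = GATE_CANDIDATES[ploidy_gate]
    candidate_ploidies = sorted(set(int(p) for p in candidate_ploidies))
    if not candidate_ploidies or min(candidate_ploidies) < 1:
        raise CallingError("candidate ploidies must be a nonempty set of ints >= 1")
    if segmented.n_segments == 0 or not np.isfinite(segmented.median).all():
        raise CallingError("degenerate segmentation")
    lengths = segmented.lengths.astype(float)
    medians = segmented.median
    overall = float(
        np.median(np.repeat(medians, segmented.lengths.astype(int)))
    )
    if overall <= 0:
        raise CallingError("degenerate all-zero segmentation")

    nominal = 4 if ploidy_gate == "4c" else 2
    best: tuple[float, int, int, float] | None = None  # (cost, |P-nominal|, P, s)
    for ploidy in candidate_ploidies:
        # s constrained so the overall median rounds to this base ploidy
        s_grid = np.linspace(ploidy - 0.49, ploidy + 0.49, n_scale_grid) / overall
        scaled = s_grid[:, None] * medians[None, :]
        cost = (np.abs(scaled - np.round(scaled)) * lengths[None, :]).sum(axis=1)
        i = int(np.argmin(cost))
        cand = (float(cost[i]), abs(ploidy - nominal), ploidy, float(s_grid[i]))
        if best is None or (best[0] - cand[0] > 1e-9) or (
            abs(cand[0] - best[0]) <= 1e-9 and cand[1:3] < best[1:3]
        ):
            best = cand
    return best[3], best[2]


def call_states(segmented: SegmentedProfile, s: float,
                max_copy: int = 8) -> np.ndarray:
    """Integer states: round(s * segment median) per bin, clipped to [0, max_copy]."""
    if s <= 0:
        raise CallingError(f"scale must be positive, got {s}")
    scaled = s * segmented.per_bin_median()
    states = np.floor(scaled + 0.5)  # round half up, deterministically
    return np.clip(states, 0, max_copy).astype(np.int16)


def call_cell(counts: np.ndarray, layout: GenomeLayout,
              gc_factor: np.ndarray | None = None, min_seg: int = 3,
              gain_threshold: float = 0.1, ploidy_gate: str | None = None,
              max_copy: int = 8):
    """Full per-cell pipeline; returns ``(states, segments, s, base_ploidy)``."""
    normalized = normalize_counts(counts, layout, gc_factor)
    segments = segment_bins(normalized, min_seg=min_seg,
                            gain_threshold=gain_threshold)
    s, base = fit_ploidy_scale(segments, ploidy_gate=ploidy_gate)
    states = call_states(segments, s, max_copy=max_copy)
    return states, segments, s, base


def call_population(counts: pd.DataFrame, layout: GenomeLayout,
                    gc_factor: np.ndarray | None = None, min_seg: int = 3,
                    gain_threshold: float = 0.1,
                    ploidy_gates=None, max_copy: int = 8):
    """Call every cell of a counts matrix (rows cells, columns bins).

    ``ploidy_gates`` may be None, a single gate for all cells, or a per-cell
    sequence. Returns ``(PopulationMatrix, list of segment frames)``.
    """
    n = len(counts)
    if ploidy_gates is None or isinstance(ploidy_gates, str):
        gates = [ploidy_gates] * n
    else:
        gates = list(ploidy_gates)
        if len(gates) != n:
            raise CallingError(f"{len(gates)} gates for {n} cells")
    states, segment_frames = [], []
    for i in range(n):
        cell_states, segments, _, _ = call_cell(
            counts.iloc[i].to_numpy(), layout, gc_factor=gc_factor,
            min_seg=min_seg, gain_threshold=gain_threshold,
            ploidy_gate=gates[i], max_copy=max_copy,
        )
        states.append(cell_states)
        frame = segments.to_frame()
        frame["state"] = cell_states[segments.start_bin]
        segment_frames.append(frame)
    pop = PopulationMatrix(layout=layout, matrix=np.stack(states),
                           cell_ids=tuple(str(c) for c in counts.index))
    return pop, segment_frames
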