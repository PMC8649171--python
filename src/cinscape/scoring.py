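"""Sample-level chromosomal-instability statistics.

Three scores summarise a population of single-cell karyotypes:

* **structural** S: copy-number state transitions between adjacent bins within
  a chromosome, summed over cells and chromosomes, divided by (G * N) where G
  is the total binned genome length in Mb and N the number of cells — the
  per-Mb, per-cell burden of segmental rearrangement. Whole-chromosome
  aneuploidies contribute nothing.
* **aneuploidy** A: mean absolute deviation of the copy-number state from a
  reference ploidy psi over all cells and bins. A flat tetraploid population
  scores 2.0 against psi = 2.
* **heterogeneity** H: per bin, the fraction of cells not carrying the modal
  state, averaged over bins — cell-to-cell karyotype diversity, 0 for a
  clonal population and bounded by 1.

The deviation census flags each cell that differs from the population's
consensus karyotype over at least ``min_run`` consecutive bins of one
chromosome, and reports the deviating fraction — the per-sample statistic
used to quantify low-level ongoing instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import GenomeLayout
from .profiles import PopulationMatrix, ProfileError


@dataclass(frozen=True)
class ScoreReport:
    """Per-sample score summary."""

    n_cells: int
    structural: float
    aneuploidy: float
    heterogeneity: float
    reference_ploidy: int
    layout_id: str


def _require_cells(pop: PopulationMatrix) -> None:
    if pop.n_cells < 1:
        raise ProfileError("empty population")


def structural_score(pop: PopulationMatrix) -> float:
    """Within-chromosome state transitions per Mb per cell."""
    _require_cells(pop)
    transitions = 0
    for sl in pop.layout.chrom_slices:
        block = pop.matrix[:, sl]
        transitions += int((np.diff(block, axis=1) != 0).sum())
    return transitions / (pop.layout.total_genome_mb * pop.n_cells)


def aneuploidy_score(pop: PopulationMatrix, reference_ploidy: int = 2) -> float:
    """Mean |CN - psi| over cells and bins."""
    _require_cells(pop)
    if reference_ploidy < 1:
        raise ProfileError(f"reference ploidy must be >= 1, got {reference_ploidy}")
    return float(np.abs(pop.matrix - reference_ploidy).mean())


def _modal_counts(pop: PopulationMatrix) -> np.ndarray:
    """Per-bin count of cells carrying the modal state (ties: the max count)."""
    m = pop.matrix
    counts = np.zeros((int(m.max()) + 1, m.shape[1]), dtype=np.int64)
    for state in range(counts.shape[0]):
        counts[state] = (m == state).sum(axis=0)
    return counts.max(axis=0)


def heterogeneity_score(pop: PopulationMatrix) -> float:
    """Mean per-bin fraction of cells off the modal state; 0 for a single cell."""
    _require_cells(pop)
    if pop.n_cells == 1:
        return 0.0
    m_b = _modal_counts(pop)
    return float((1.0 - m_b / pop.n_cells).mean())


def modal_ploidy(pop: PopulationMatrix) -> int:
    """Modal copy-number state over all cells and bins (ties toward lower)."""
    _require_cells(pop)
    return int(np.bincount(pop.matrix.ravel()).argmax())


def consensus_profile(pop: PopulationMatrix) -> np.ndarray:
    """Per-bin modal state across cells.

    Ties are broken toward the state closest to the population's overall modal
    ploidy, then toward the lower state.
    """
    _require_cells(pop)
    m = pop.matrix
    max_state = int(m.max())
    counts = np.zeros((max_state + 1, m.shape[1]), dtype=np.int64)
    for state in range(max_state + 1):
        counts[state] = (m == state).sum(axis=0)
    best = counts.max(axis=0)
    ploidy = modal_ploidy(pop)
    states = np.arange(max_state + 1)
    # rank candidate states: distance to overall modal ploidy, then state value
    order = np.lexsort((states, np.abs(states - ploidy)))
    consensus = np.zeros(m.shape[1], dtype=np.int16)
    chosen = np.zeros(m.shape[1], dtype=bool)
    for state in order:
        pick = ~chosen & (counts[state] == best)
        consensus[pick] = state
        chosen |= pick
    return consensus


def deviation_census(pop: PopulationMatrix, min_run: int = 1):
    """Flag cells deviating from the consensus over >= min_run consecutive bins.

    Returns ``(flags, fraction)``: a boolean array per cell and the flagged
    fraction of the population. Runs never span chromosome boundaries.
    """
    _require_cells(pop)
    if min_run < 1:
        raise ProfileError(f"min_run must be >= 1, got {min_run}")
    consensus = consensus_profile(pop)
    diff = pop.matrix != consensus[None, :]
    flags = np.zeros(pop.n_cells, dtype=bool)
    for sl in pop.layout.chrom_slices:
        block = diff[:, sl]
        if min_run == 1:
            flags |= block.any(axis=1)
        else:
            # longest run of consecutive mismatches per cell via cumulative
            # sums reset at matches
            run = np.zeros(pop.n_cells, dtype=np.int64)
            longest = np.zeros(pop.n_cells, dtype=np.int64)
            for j in range(block.shape[1]):
                run = np.where(block[:, j], run + 1, 0)
                longest = np.maximum(longest, run)
            flags |= longest >= min_run
        if flags.all():
            break
    return flags, float(flags.mean())


def score_population(pop: PopulationMatrix, reference_ploidy: int = 2) -> ScoreReport:
    """All three scores for one sample."""
    return ScoreReport(
        n_cells=pop.n_cells,
        structural=structural_score(pop),
        aneuploidy=aneuploidy_score(pop, reference_ploidy),
        heterogeneity=heterogeneity_score(pop),
        reference_ploidy=reference_ploidy,
        layout_id=f"{len(pop.layout.chromosomes)}chrom_{pop.layout.bin_size}bp",
    )
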