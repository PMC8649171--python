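"""Generative model of chromosomal instability in a clonally expanding population.

The process starts from an established clonal population — ``carrying_capacity``
copies of the founder karyotype, the situation of a subcloned cell line at
steady state — so that drift events are recent and low-frequency, matching the
scattered subclonal deviations seen in single-cell karyotype data rather than
the 50%-frequency sub-lineages a single-cell bottleneck would create.

Cells divide for a fixed number of generations. Each division can be replaced
by a whole-genome doubling (cytokinesis failure: one daughter with every bin
doubled); otherwise the two daughters may differ from the parent by reciprocal
whole-chromosome mis-segregations (one daughter gains a copy of a chromosome,
its sister loses one) and/or a reciprocal distal segmental gain/loss from a
uniformly chosen breakpoint. Non-viable karyotypes (autosomal nullisomy, or any
state above the copy cap) die; the population is down-sampled uniformly to a
carrying capacity each generation (Wright-Fisher style), and a final uniform
sample of cells is emitted.

On top of the karyotypes the module simulates the three read-outs the analysis
consumes: overdispersed binned read counts (shallow scWGS), miFISH probe signal
counts with probe-level technical error, and per-cell DNA content (flow
cytometry; 1.0 == 2c).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout
from .mifish import MiFishCell, MiFishPanel
from .profiles import PopulationMatrix, ProfileError, validate_profile
from .genome_model import Region, region_to_bins


class SimulationError(ValueError):
    """Invalid simulation parameters or inputs."""


class ExtinctionError(RuntimeError):
    """The simulated population died out or is too small to sample."""


@dataclass(frozen=True)
class CinParameters:
    """Per-division event rates and population-process settings.

    p_mis is per chromosome per division; p_seg and p_wgd are per division.
    ``induced_wgd_generation``/``induced_wgd_fraction`` deterministically
    convert that fraction of divisions into WGDs at one generation, which is
    how the mixed diploid/tetraploid and fully tetraploid presets plant their
    doubling events at a known point in the lineage history.
    """

    p_mis: float = 0.0
    p_seg: float = 0.0
    p_wgd: float = 0.0
    generations: int = 10
    carrying_capacity: int = 300
    sample_size: int = 50
    nullisomy_lethal: bool = True
    max_copy: int = 8
    seed: int | None = None
    induced_wgd_generation: int | None = None
    induced_wgd_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_mis", "p_seg", "p_wgd", "induced_wgd_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 0:
            raise SimulationError("generations must be >= 0")
        if self.carrying_capacity < 1:
            raise SimulationError("carrying_capacity must be >= 1")
        if self.sample_size < 1 or self.sample_size > self.carrying_capacity:
            raise SimulationError(
                "sample_size must be in [1, carrying_capacity], got "
                f"{self.sample_size} (capacity {self.carrying_capacity})"
            )
        if self.max_copy < 1:
            raise SimulationError("max_copy must be >= 1")


@dataclass(frozen=True)
class FounderKaryotype:
    """Founding clone: a base ploidy plus clonal copy-number aberrations."""

    base_ploidy: int = 2
    aberrations: tuple[tuple[Region, int], ...] = ()

    def build(self, layout: GenomeLayout) -> np.ndarray:
        profile = np.full(layout.n_bins, self.base_ploidy, dtype=np.int16)
        for region, delta in self.aberrations:
            bins = region_to_bins(layout, region)
            profile[bins.start:bins.stop] += delta
        if (profile < 0).any():
            raise ProfileError(
                "founder aberrations drive copy number below zero"
            )
        return profile


@dataclass(frozen=True)
class CountModel:
    """Read-depth model for simulated shallow scWGS counts.

    Per-bin counts are negative-binomial with mean
    ``d * CN * gc_factor + background`` and variance ``dispersion * mean``
    (``dispersion == 1`` collapses to Poisson). ``gc_factor`` is a known
    multiplicative per-bin bias (flat if None).
    """

    mean_reads_per_copy_per_bin: float = 50.0
    dispersion: float = 2.0
    gc_factor: np.ndarray | None = field(default=None, repr=False)
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_reads_per_copy_per_bin <= 0:
            raise SimulationError("mean_reads_per_copy_per_bin must be > 0")
        if self.dispersion < 1.0:
            raise SimulationError(
                f"dispersion must be >= 1 (variance inflation), got {self.dispersion}"
            )
        if self.background < 0:
            raise SimulationError("background must be >= 0")
        if self.gc_factor is not None:
            gc = np.asarray(self.gc_factor, dtype=float)
            if (gc <= 0).any():
                raise SimulationError("gc factors must be positive")
            object.__setattr__(self, "gc_factor", gc)

    def gc(self, n_bins: int) -> np.ndarray:
        if self.gc_factor is None:
            return np.ones(n_bins)
        if len(self.gc_factor) != n_bins:
            raise SimulationError(
                f"gc_factor has {len(self.gc_factor)} bins, expected {n_bins}"
            )
        return self.gc_factor


def random_gc_factors(n_bins: int, sd: float = 0.1,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Mild lognormal per-bin GC-like bias, mean approximately 1."""
    rng = np.random.default_rng() if rng is None else rng
    return np.exp(rng.normal(0.0, sd, size=n_bins))


# ---------------------------------------------------------------------------
# elementary events
# ---------------------------------------------------------------------------

def apply_missegregation(parent: np.ndarray, layout: GenomeLayout,
                         chrom_index: int, direction: int = +1):
    """Reciprocal whole-chromosome mis-segregation.

    Daughter A gains one copy of the chromosome and daughter B loses one
    (swapped if ``direction`` is negative); per-bin daughter sums equal twice
    the parent. Mis-segregating a chromosome with a nullisomic bin is an error.
    """
    sl = layout.chrom_slices[chrom_index]
    if (parent[sl] < 1).any():
        raise SimulationError(
            f"cannot mis-segregate nullisomic chromosome "
            f"{layout.chrom_names[chrom_index]}"
        )
    a, b = parent.copy(), parent.copy()
    gain, lose = (a, b) if direction >= 0 else (b, a)
    gain[sl] += 1
    lose[sl] -= 1
    return a, b


def apply_segmental(parent: np.ndarray, layout: GenomeLayout, chrom_index: int,
                    break_bin: int, direction: int = +1):
    """Reciprocal distal segmental gain/loss from a within-chromosome breakpoint.

    Bins from ``break_bin`` (chromosome-local index, 1 <= break_bin < n_bins)
    to the chromosome end are gained by one daughter and lost by its sister.
    The losing daughter may go negative; such karyotypes are removed by the
    viability filter.
    """
    sl = layout.chrom_slices[chrom_index]
    n = sl.stop - sl.start
    if not (1 <= break_bin < n):
        raise SimulationError(
            f"breakpoint {break_bin} outside (0, {n}) for chromosome "
            f"{layout.chrom_names[chrom_index]}"
        )
    a, b = parent.copy(), parent.copy()
    gain, lose = (a, b) if direction >= 0 else (b, a)
    seg = slice(sl.start + break_bin, sl.stop)
    gain[seg] += 1
    lose[seg] -= 1
    return a, b


def apply_wgd(profile: np.ndarray) -> np.ndarray:
    """Whole-genome doubling: every bin's state doubled."""
    return (np.asarray(profile) * 2).astype(np.int16)


def _is_viable(cell: np.ndarray, params: CinParameters,
               autosomal: np.ndarray) -> bool:
    if (cell < 0).any() or (cell > params.max_copy).any():
        return False
    if params.nullisomy_lethal and (cell[autosomal] == 0).any():
        return False
    return True


# ---------------------------------------------------------------------------
# population process
# ---------------------------------------------------------------------------

def simulate_population(founder: FounderKaryotype, params: CinParameters,
                        layout: GenomeLayout,
                        rng: np.random.Generator | None = None) -> PopulationMatrix:
    """Branching process from a single founder cell; see module docstring.

    Deterministic for a fixed ``params.seed`` (or a supplied generator).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    founder_profile = validate_profile(founder.build(layout), layout)
    autosomal = layout.autosome_mask()
    slices = layout.chrom_slices
    n_chrom = len(slices)

    cells = [founder_profile.copy() for _ in range(params.carrying_capacity)]
    if params.induced_wgd_generation == 0 and params.induced_wgd_fraction > 0:
        # a single doubling event at establishment: a fixed fraction of the
        # starting clonal population carries the doubled founder karyotype
        k = int(round(params.induced_wgd_fraction * len(cells)))
        for i in rng.choice(len(cells), size=min(k, len(cells)), replace=False):
            cells[i] = apply_wgd(cells[i])
        cells = [c for c in cells if _is_viable(c, params, autosomal)]
    for gen in range(1, params.generations + 1):
        induced = np.zeros(len(cells), dtype=bool)
        if (params.induced_wgd_generation == gen
                and params.induced_wgd_fraction > 0):
            k = int(round(params.induced_wgd_fraction * len(cells)))
            if k > 0:
                induced[rng.choice(len(cells), size=min(k, len(cells)),
                                   replace=False)] = True
        children: list[np.ndarray] = []
        for i, parent in enumerate(cells):
            if induced[i] or rng.random() < params.p_wgd:
                child = apply_wgd(parent)
                if _is_viable(child, params, autosomal):
                    children.append(child)
                continue
            a, b = parent.copy(), parent.copy()
            mis = rng.random(n_chrom) < params.p_mis
            for ci in np.flatnonzero(mis):
                sl = slices[ci]
                if (parent[sl] < 1).any():
                    continue  # nothing to mis-segregate
                direction = 1 if rng.random() < 0.5 else -1
                gain, lose = (a, b) if direction > 0 else (b, a)
                gain[sl] += 1
                lose[sl] -= 1
            if rng.random() < params.p_seg:
                ci = int(rng.integers(n_chrom))
                sl = slices[ci]
                n = sl.stop - sl.start
                if n >= 2:
                    k = int(rng.integers(1, n))
                    direction = 1 if rng.random() < 0.5 else -1
                    gain, lose = (a, b) if direction > 0 else (b, a)
                    seg = slice(sl.start + k, sl.stop)
                    gain[seg] += 1
                    lose[seg] -= 1
            for child in (a, b):
                if _is_viable(child, params, autosomal):
                    children.append(child)
        if not children:
            raise ExtinctionError(
                f"population went extinct at generation {gen} "
                f"(all daughters non-viable)"
            )
        if len(children) > params.carrying_capacity:
            keep = np.sort(rng.choice(len(children), params.carrying_capacity,
                                      replace=False))
            children = [children[j] for j in keep]
        cells = children

    if params.sample_size > len(cells):
        raise ExtinctionError(
            f"cannot sample {params.sample_size} cells: only {len(cells)} "
            f"survive after {params.generations} generations (extinction or "
            f"near-extinction under the viability rules)"
        )
    keep = np.sort(rng.choice(len(cells), params.sample_size, replace=False))
    matrix = np.stack([cells[j] for j in keep])
    return PopulationMatrix(layout=layout, matrix=matrix)


# ---------------------------------------------------------------------------
# read-outs
# ---------------------------------------------------------------------------

def simulate_read_counts(profile: np.ndarray, model: CountModel,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Overdispersed binned read counts for one cell's copy-number profile."""
    rng = np.random.default_rng() if rng is None else rng
    profile = np.asarray(profile)
    gc = model.gc(len(profile))
    mu = model.mean_reads_per_copy_per_bin * profile * gc + model.background
    counts = np.zeros(len(profile), dtype=np.int64)
    pos = mu > 0
    if model.dispersion == 1.0:
        counts[pos] = rng.poisson(mu[pos])
    else:
        # NB with variance = dispersion * mean: size = mu/(disp-1), p = 1/disp
        size = mu[pos] / (model.dispersion - 1.0)
        counts[pos] = rng.negative_binomial(size, 1.0 / model.dispersion)
    return counts


def simulate_population_counts(pop: PopulationMatrix, model: CountModel,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Counts for every cell of a population (rows cells, columns bins)."""
    rng = np.random.default_rng() if rng is None else rng
    rows = [simulate_read_counts(pop.cell(i), model, rng)
            for i in range(pop.n_cells)]
    return pd.DataFrame(np.stack(rows), index=list(pop.cell_ids),
                        columns=pop.layout.bin_labels())


def simulate_mifish(profile: np.ndarray, panel: MiFishPanel,
                    layout: GenomeLayout, error_rate: float = 0.0,
                    rng: np.random.Generator | None = None,
                    cell_id: str = "cell_0") -> MiFishCell:
    """Probe signal counts for one cell: true CN at the probe's bin, perturbed
    by +/-1 with probability ``error_rate`` per probe (floored at zero)."""
    if not (0.0 <= error_rate <= 1.0):
        raise SimulationError(f"error_rate must be in [0, 1], got {error_rate}")
    rng = np.random.default_rng() if rng is None else rng
    true = np.asarray(profile)[panel.bin_indices(layout)].astype(np.int64)
    err = rng.random(len(true)) < error_rate
    sign = rng.integers(0, 2, size=len(true)) * 2 - 1
    observed = np.maximum(true + err * sign, 0)
    return MiFishCell(cell_id=cell_id,
                      counts=dict(zip(panel.probe_names, observed.tolist())))


def simulate_mifish_population(pop: PopulationMatrix, panel: MiFishPanel,
                               error_rate: float = 0.0,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """miFISH signal counts for every cell (rows cells, columns probes)."""
    rng = np.random.default_rng() if rng is None else rng
    cells = [
        simulate_mifish(pop.cell(i), panel, pop.layout, error_rate, rng,
                        cell_id=pop.cell_ids[i])
        for i in range(pop.n_cells)
    ]
    return pd.DataFrame([c.counts for c in cells], index=list(pop.cell_ids))


def simulate_dna_content(pop: PopulationMatrix, cv: float = 0.05,
                         g2_fraction: float = 0.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Flow-cytometry-style DNA content per cell; 1.0 == 2c.

    Base content is mean copy number over bins divided by 2; a ``g2_fraction``
    of cells are doubled (G2/M DNA content), which gives a diploid population
    2c+4c peaks and a tetraploid one 4c+8c peaks; multiplicative Gaussian
    noise with coefficient of variation ``cv``.
    """
    if cv < 0:
        raise SimulationError(f"cv must be >= 0, got {cv}")
    if not (0.0 <= g2_fraction <= 1.0):
        raise SimulationError(f"g2_fraction must be in [0, 1], got {g2_fraction}")
    rng = np.random.default_rng() if rng is None else rng
    base = pop.matrix.mean(axis=1) / 2.0
    g2 = rng.random(pop.n_cells) < g2_fraction
    base = np.where(g2, base * 2.0, base)
    if cv > 0:
        base = base * (1.0 + cv * rng.standard_normal(pop.n_cells))
    return base


def gate_by_dna_content(pop: PopulationMatrix, gate: str,
                        tolerance: float = 0.15) -> PopulationMatrix:
    """Emulate a flow sort: keep cells whose G1 DNA content matches a gate.

    ``gate`` is "2c" (content 1.0) or "4c" (content 2.0); a cell passes when
    its noise-free G1 content is within ``tolerance`` (relative) of the target.
    """
    targets = {"2c": 1.0, "4c": 2.0}
    if gate not in targets:
        raise SimulationError(f"gate must be one of {sorted(targets)}, got {gate!r}")
    content = pop.matrix.mean(axis=1) / 2.0
    keep = np.flatnonzero(np.abs(content - targets[gate]) <= tolerance * targets[gate])
    if len(keep) == 0:
        raise ExtinctionError(f"no cells fall in the {gate} sort gate")
    return pop.subset(keep)
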