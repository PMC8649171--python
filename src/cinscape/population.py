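"""Karyotype clustering, ploidy assignment and whole-genome-doubling detection.

Cells are clustered by agglomerative clustering on their integer state
vectors; the elementary karyotype distance is the mean absolute per-bin state
difference (Manhattan distance divided by the bin count), under which a
diploid and its doubled counterpart are exactly 2.0 apart, so ploidy groups
separate first and genotype within ploidy second. The default linkage is
Ward (on the euclidean embedding of the state vectors): drift in an unstable
population inevitably produces single cells several private events away from
every neighbour, and Ward's variance criterion absorbs such outliers into
their parent population before splitting clonally distinct populations,
whereas average linkage awards them singleton clusters. Average linkage on
the Manhattan distance remains available via ``linkage_method``. A WGD is
inferred between two subpopulations when the higher consensus equals twice the
lower one over at least a fraction q of bins: clonal losses acquired before
the doubling then appear as disomies on the tetraploid background. DNA-content
distributions are classified into 2c/4c/8c peak patterns; a population showing
both 4c and 8c peaks is flagged as a cycling tetraploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiles import PopulationMatrix, ProfileError
from .scoring import consensus_profile, modal_ploidy


@dataclass(frozen=True, eq=False)
class ClusterResult:
    """Hierarchical clustering of single-cell karyotypes."""

    linkage: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    consensus: dict[int, np.ndarray] = field(repr=False)
    cluster_ploidies: dict[int, int]
    cell_ids: tuple[str, ...]
    distance: str = "manhattan_per_bin"
    linkage_method: str = "ward"

    @property
    def k(self) -> int:
        return len(self.consensus)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.cell_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def karyotype_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute copy-number state difference per bin."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ProfileError(
            f"profiles have different bin counts ({a.shape} vs {b.shape})"
        )
    return float(np.abs(a.astype(float) - b.astype(float)).mean())


def cluster_karyotypes(pop: PopulationMatrix, k: int,
                       linkage_method: str = "ward") -> ClusterResult:
    """Hierarchical karyotype clustering cut to k clusters.

    Ward linkage (the default) operates on the euclidean embedding of the
    state vectors; any other linkage uses the per-bin Manhattan karyotype
    distance. Cluster labels are renumbered 1..k by the lowest member cell
    index, so output is invariant to scipy's internal label order.
    """
    if not (1 <= k <= pop.n_cells):
        raise ProfileError(
            f"k must be in [1, n_cells]; got k={k} for {pop.n_cells} cells"
        )
    if pop.n_cells == 1:
        labels = np.ones(1, dtype=int)
        linkage = np.empty((0, 4))
    elif linkage_method == "ward":
        linkage = hierarchy.linkage(pop.matrix.astype(float), method="ward")
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    else:
        dist = pdist(pop.matrix.astype(float), metric="cityblock") / pop.n_bins
        linkage = hierarchy.linkage(dist, method=linkage_method)
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber by first occurrence for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.asarray([remap[lab] for lab in labels], dtype=int)

    consensus, ploidies = {}, {}
    for lab in sorted(int(l) for l in set(labels)):
        sub = pop.subset(np.flatnonzero(labels == lab))
        consensus[lab] = consensus_profile(sub)
        ploidies[lab] = modal_ploidy(sub)
    return ClusterResult(
        linkage=linkage, labels=labels, consensus=consensus,
        cluster_ploidies=ploidies, cell_ids=pop.cell_ids,
        distance="euclidean" if linkage_method == "ward" else "manhattan_per_bin",
        linkage_method=linkage_method,
    )


def infer_cell_ploidy(profile: np.ndarray) -> int:
    """Modal copy-number state across bins (ties toward the lower state)."""
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ProfileError("empty profile")
    return int(np.bincount(profile).argmax())


def detect_wgd_relation(consensus_low: np.ndarray, consensus_high: np.ndarray,
                        match_fraction: float = 0.9):
    """Test whether one consensus is the whole-genome doubling of another.

    Returns ``(is_doubling, mask)`` where mask marks bins with
    ``high == 2 * low``; true iff the matching fraction is at least
    ``match_fraction``.
    """
    low = np.asarray(consensus_low)
    high = np.asarray(consensus_high)
    if low.shape != high.shape:
        raise ProfileError(
            f"consensus profiles have different bin counts ({low.shape} vs {high.shape})"
        )
    if not (0.0 < match_fraction <= 1.0):
        raise ProfileError(
            f"match_fraction must be in (0, 1], got {match_fraction}"
        )
    mask = high == 2 * low
    return bool(mask.mean() >= match_fraction), mask


DNA_PEAK_TARGETS = {"2c": 1.0, "4c": 2.0, "8c": 4.0}


def classify_dna_content(values, peak_tolerance: float = 0.15,
                         min_peak_fraction: float = 0.05):
    """Classify a DNA-content distribution into 2c/4c/8c peaks.

    A peak class is present when at least ``min_peak_fraction`` of cells lie
    within ``peak_tolerance`` (relative) of its target content (1.0, 2.0, 4.0
    for 2c, 4c, 8c). Returns ``(peaks, cycling_tetraploid)``; the flag is set
    when both a 4c and an 8c peak are present — a 2c+4c-only pattern is a
    normally cycling diploid and carries no flag.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ProfileError(
            f"need at least 10 DNA-content values, got {values.size}"
        )
    peaks = {
        name
        for name, target in DNA_PEAK_TARGETS.items()
        if (np.abs(values - target) <= peak_tolerance * target).mean()
        >= min_peak_fraction
    }
    cycling_tetraploid = {"4c", "8c"} <= peaks
    return peaks, cycling_tetraploid
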