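"""Multiplex interphase FISH (miFISH) clonality analysis.

miFISH reports, for each cell, an integer signal count per locus-specific
probe. This module models the assay's 20-probe panel (one centromere probe,
CCP10, plus 19 gene loci hybridised as four panels of five probes), and
implements the population-level analysis: per-cell ploidy classification,
gain/loss calls against a reference ploidy, technical-noise flagging (one or
two loci deviating from the modal pattern are within the assay's margin of
error), clonal-versus-subclonal classification of aberrations, and clone
enumeration from distinct signal patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout, LayoutError, Region, region_to_bins

PANEL_COLUMNS = ("name", "cytoband", "chromosome", "position", "group")

_KNOWN_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


class PanelError(ValueError):
    """Malformed probe panel."""


@dataclass(frozen=True, eq=False)
class MiFishPanel:
    """An ordered probe panel with genomic anchor positions."""

    probes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.probes
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise PanelError(f"panel missing columns: {sorted(missing)}")
        if df.empty:
            raise PanelError("panel has no probes")
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise PanelError(f"duplicate probe name {dup!r}")
        bad = set(df["chromosome"]) - set(_KNOWN_CHROMOSOMES)
        if bad:
            raise PanelError(f"unknown chromosome(s) in panel: {sorted(bad)}")
        oversized = df.groupby("group").size()
        oversized = oversized[oversized > 5]
        if not oversized.empty:
            raise PanelError(
                f"panel group(s) {list(oversized.index)} exceed 5 probes"
            )
        object.__setattr__(self, "probes", df.reset_index(drop=True))

    @property
    def probe_names(self) -> list[str]:
        return list(self.probes["name"])

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_groups(self) -> int:
        return self.probes["group"].nunique()

    def bin_indices(self, layout: GenomeLayout) -> np.ndarray:
        """Layout bin index anchoring each probe; raises if a probe is off-layout."""
        idx = []
        for _, row in self.probes.iterrows():
            try:
                region = Region(row["chromosome"], int(row["position"]),
                                int(row["position"]) + 1)
                bins = region_to_bins(layout, region)
            except LayoutError as exc:
                raise PanelError(f"probe {row['name']!r} off layout: {exc}") from exc
            idx.append(bins.start)
        return np.asarray(idx, dtype=np.int64)

    def expected_counts(self, profile: np.ndarray, layout: GenomeLayout) -> pd.Series:
        """Noise-free probe counts implied by a copy-number profile."""
        return pd.Series(
            np.asarray(profile)[self.bin_indices(layout)], index=self.probe_names
        )


@dataclass(frozen=True)
class MiFishCell:
    """One cell's signal counts, one non-negative integer per panel probe."""

    cell_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(int(v) < 0 for v in self.counts.values()):
            raise PanelError(f"cell {self.cell_id!r} has negative signal counts")


@dataclass(frozen=True)
class MiFishReport:
    """Population-level clonality summary.

    ``probe_status`` has one row per probe with loss/gain cell fractions and a
    clonality call per direction; ``clones`` lists distinct signal patterns
    with frequencies summing to the number of cells analysed.
    """

    n_cells: int
    n_flagged: int
    ploidy_class: pd.Series
    probe_status: pd.DataFrame
    clones: pd.DataFrame


def load_panel(path, layout: GenomeLayout | None = None) -> MiFishPanel:
    """Read a probe-panel TSV (columns name, cytoband, chromosome, position, group)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"name": str, "cytoband": str, "chromosome": str})
    if df.empty:
        raise PanelError(f"{path}: empty panel file")
    panel = MiFishPanel(probes=df)
    if layout is not None:
        panel.bin_indices(layout)  # validates anchors
    return panel


def write_panel(panel: MiFishPanel, path) -> None:
    panel.probes.to_csv(path, sep="\t", index=False,
                        columns=list(PANEL_COLUMNS))


def bundled_panel() -> MiFishPanel:
    """The 20-probe panel used throughout: CCP10 plus 19 gene loci in 4 groups."""
    ref = resources.files("cinscape.data").joinpath("mifish_panel_hg38.tsv")
    with resources.as_file(ref) as path:
        return load_panel(path)


# ---------------------------------------------------------------------------
# per-cell operations
# ---------------------------------------------------------------------------

def _as_counts(cell) -> pd.Series:
    if isinstance(cell, MiFishCell):
        return pd.Series(cell.counts, dtype=np.int64)
    return pd.Series(cell, dtype=np.int64)


def estimate_cell_ploidy(cell) -> str:
    """Classify a cell as 2c, 4c or other by its modal probe count (ties -> lower)."""
    counts = _as_counts(cell)
    if counts.empty:
        raise PanelError("cell has no probe counts")
    freq = np.bincount(counts.to_numpy())
    mode = int(freq.argmax())  # argmax takes the lowest value on ties
    return {2: "2c", 4: "4c"}.get(mode, "other")


def score_cell(cell, reference) -> pd.Series:
    """Per-probe loss/neutral/gain call relative to a reference ploidy.

    ``reference`` may be a scalar (applied to every probe) or a per-probe
    mapping; a probe missing from a per-probe reference is an error.
    """
    counts = _as_counts(cell)
    if np.isscalar(reference):
        ref = pd.Series(int(reference), index=counts.index)
    else:
        ref = pd.Series(reference, dtype=np.int64)
        missing = counts.index.difference(ref.index)
        if len(missing):
            raise PanelError(f"reference missing probe(s): {list(missing)}")
        ref = ref.reindex(counts.index)
    calls = pd.Series("neutral", index=counts.index)
    calls[counts < ref] = "loss"
    calls[counts > ref] = "gain"
    return calls


# ---------------------------------------------------------------------------
# population-level operations
# ---------------------------------------------------------------------------

def _cells_frame(cells) -> pd.DataFrame:
    if isinstance(cells, pd.DataFrame):
        df = cells
    else:
        df = pd.DataFrame(
            {c.cell_id: pd.Series(c.counts) for c in cells}
        ).T
    if df.empty:
        raise PanelError("no cells to analyse")
    return df.astype(np.int64)


def modal_pattern(cells) -> pd.Series:
    """Per-probe modal signal count across cells (ties toward the lower count)."""
    df = _cells_frame(cells)
    return df.apply(lambda col: int(np.bincount(col.to_numpy()).argmax()), axis=0)


def filter_noise(cells, noise_max: int = 2):
    """Flag cells within the assay's technical margin of error.

    A cell deviating from the sample's modal pattern at 1..``noise_max`` loci
    is flagged and contributes the modal pattern to clonality statistics; a
    cell deviating at more loci contributes its observed pattern. Returns
    ``(effective_patterns, flagged)`` where ``flagged`` is a boolean Series.
    """
    if noise_max < 0:
        raise PanelError(f"noise_max must be >= 0, got {noise_max}")
    df = _cells_frame(cells)
    mode = modal_pattern(df)
    n_dev = (df != mode).sum(axis=1)
    flagged = (n_dev > 0) & (n_dev <= noise_max)
    effective = df.copy()
    effective.loc[flagged] = mode.to_numpy()
    return effective, flagged


def enumerate_clones(cells) -> pd.DataFrame:
    """Distinct full signal patterns with frequencies.

    Sorted by decreasing frequency, then lexicographically by pattern;
    frequencies sum to the number of cells.
    """
    df = _cells_frame(cells)
    probe_cols = list(df.columns)
    clones = (
        df.groupby(probe_cols, sort=False).size().rename("n_cells").reset_index()
    )
    order = sorted(
        range(len(clones)),
        key=lambda i: (-clones.loc[i, "n_cells"],
                       tuple(clones.loc[i, probe_cols])),
    )
    return clones.iloc[order].reset_index(drop=True)


def classify_clonality(cells, reference=2, clonal_fraction: float = 0.95,
                       noise_max: int = 2) -> MiFishReport:
    """Full population analysis: ploidy classes, clonal/subclonal calls, clones.

    For each probe and direction (loss/gain relative to ``reference``), the
    aberration is *clonal* if present in >= ``clonal_fraction`` of analysed
    cells, *subclonal* if present in at least two cells but below threshold,
    and unreported (``none``) for singletons. Cells within the technical-noise
    margin (``noise_max`` deviating loci) contribute the modal pattern.
    """
    if not (0.5 < clonal_fraction <= 1.0):
        raise PanelError(
            f"clonal_fraction must be in (0.5, 1], got {clonal_fraction}"
        )
    df = _cells_frame(cells)
    effective, flagged = filter_noise(df, noise_max=noise_max)
    n = len(df)

    if np.isscalar(reference):
        ref = pd.Series(int(reference), index=df.columns)
    else:
        ref = pd.Series(reference, dtype=np.int64).reindex(df.columns)
        if ref.isna().any():
            raise PanelError(
                f"reference missing probe(s): {list(ref.index[ref.isna()])}"
            )

    rows = []
    for probe in df.columns:
        losses = int((effective[probe] < ref[probe]).sum())
        gains = int((effective[probe] > ref[probe]).sum())
        row = {"probe": probe,
               "loss_fraction": losses / n, "gain_fraction": gains / n}
        for direction, count in (("loss", losses), ("gain", gains)):
            if count / n >= clonal_fraction:
                status = "clonal"
            elif count >= 2:
                status = "subclonal"
            else:
                status = "none"
            row[f"{direction}_status"] = status
        if row["loss_status"] == "clonal":
            row["status"] = "clonal_loss"
        elif row["gain_status"] == "clonal":
            row["status"] = "clonal_gain"
        elif row["loss_status"] == "subclonal" and row["loss_fraction"] >= row["gain_fraction"]:
            row["status"] = "subclonal_loss"
        elif row["gain_status"] == "subclonal":
            row["status"] = "subclonal_gain"
        elif row["loss_status"] == "subclonal":
            row["status"] = "subclonal_loss"
        else:
            row["status"] = "neutral"
        rows.append(row)

    ploidy = df.apply(estimate_cell_ploidy, axis=1)
    return MiFishReport(
        n_cells=n,
        n_flagged=int(flagged.sum()),
        ploidy_class=ploidy,
        probe_status=pd.DataFrame(rows),
        clones=enumerate_clones(effective),
    )
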