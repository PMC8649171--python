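"""Readers and writers for the on-disk formats.

Copy-number matrices are TSV with one row per cell and one ``chrom:start-end``
column per bin (coordinates 0-based half-open, matching BED); per-cell
segments are BED5 (chrom, start, end, state, segment median). All writers emit
stable column order so reruns are bit-identical.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .genome_model import GenomeLayout, build_layout
from .profiles import PopulationMatrix

_BIN_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class FormatError(ValueError):
    """Malformed input file."""


def _parse_bin_labels(labels) -> pd.DataFrame:
    rows = []
    for i, label in enumerate(labels):
        m = _BIN_RE.match(str(label))
        if not m:
            raise FormatError(
                f"column {i}: bin header {label!r} is not 'chrom:start-end'"
            )
        rows.append((m["chrom"], int(m["start"]), int(m["end"])))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def layout_from_bin_labels(labels) -> GenomeLayout:
    """Reconstruct a layout from matrix bin headers (bins must tile chromosomes)."""
    bins = _parse_bin_labels(labels)
    sizes = (bins["end"] - bins["start"]).to_numpy()
    bin_size = int(sizes.max())
    chrom_lengths = [
        (chrom, int(group["end"].max()))
        for chrom, group in bins.groupby("chromosome", sort=False)
    ]
    layout = build_layout(chrom_lengths, bin_size)
    expected = layout.bins_frame()
    if len(expected) != len(bins) or not expected.equals(
        bins.reset_index(drop=True)
    ):
        raise FormatError(
            "bin headers do not tile their chromosomes at a fixed bin size"
        )
    return layout


def write_cn_matrix(pop: PopulationMatrix, path) -> None:
    """Write a population as a cell-by-bin TSV with a leading ``cell`` column."""
    df = pd.DataFrame(pop.matrix, index=list(pop.cell_ids),
                      columns=pop.layout.bin_labels())
    df.index.name = "cell"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_cn_matrix(path, layout: GenomeLayout | None = None) -> PopulationMatrix:
    """Read a cell-by-bin copy-number TSV.

    If ``layout`` is given, the bin headers must match it exactly; otherwise
    the layout is reconstructed from the headers. Non-integer or negative
    states are reported with their cell and bin.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: no cells")
    target = layout if layout is not None else layout_from_bin_labels(df.columns)
    expected = target.bin_labels()
    if list(df.columns) != expected:
        if len(df.columns) != len(expected):
            raise FormatError(
                f"{path}: {len(df.columns)} bin columns, layout has {len(expected)}"
            )
        first_bad = next(
            (a, b) for a, b in zip(df.columns, expected) if a != b
        )
        raise FormatError(
            f"{path}: bin header {first_bad[0]!r} does not match layout bin "
            f"{first_bad[1]!r}"
        )
    values = df.to_numpy()
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(numeric).any() or not np.equal(np.mod(numeric, 1), 0).all():
        c, b = np.argwhere(np.isnan(numeric) | (np.mod(numeric, 1) != 0))[0]
        raise FormatError(
            f"{path}: non-integer state {values[c, b]!r} for cell "
            f"{df.index[c]!r} at bin {df.columns[b]!r}"
        )
    if (numeric < 0).any():
        c, b = np.argwhere(numeric < 0)[0]
        raise FormatError(
            f"{path}: negative state for cell {df.index[c]!r} at bin "
            f"{df.columns[b]!r}"
        )
    return PopulationMatrix(
        layout=target, matrix=numeric.astype(np.int16),
        cell_ids=tuple(str(i) for i in df.index),
    )


def write_counts_matrix(counts: pd.DataFrame, path) -> None:
    df = counts.copy()
    df.index.name = "cell"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_counts_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: no cells")
    _parse_bin_labels(df.columns)
    return df


def write_segments_bed(segment_frame: pd.DataFrame, path) -> None:
    """Write one cell's segments as BED5: chrom, start, end, state, median.

    Segments must be non-overlapping within each chromosome.
    """
    required = {"chromosome", "start", "end", "state", "median"}
    missing = required - set(segment_frame.columns)
    if missing:
        raise FormatError(f"segment table missing columns {sorted(missing)}")
    for chrom, group in segment_frame.groupby("chromosome", sort=False):
        g = group.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise FormatError(f"overlapping segments on {chrom}")
    out = segment_frame[["chromosome", "start", "end", "state", "median"]]
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_segments_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "state", "median"],
    )


def write_mifish_cells(cells: pd.DataFrame, path) -> None:
    df = cells.copy()
    df.index.name = "cell"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_mifish_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: no cells")
    return df.astype(np.int64)


def write_dna_content(values, cell_ids, path) -> None:
    pd.DataFrame({"cell": list(cell_ids), "dna_content": np.asarray(values)}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_dna_content(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
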