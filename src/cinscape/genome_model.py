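"""Binned genome coordinate system.

Every object downstream — simulated karyotypes, read counts, called copy-number
states, scores — lives on a :class:`GenomeLayout`: an ordered set of chromosomes
partitioned into fixed-width bins. Coordinates are 0-based, half-open (BED
convention) throughout. The last bin of a chromosome may be shorter than
``bin_size`` so that bins tile each chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


class LayoutError(ValueError):
    """Invalid genome layout, region or coordinate."""


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise LayoutError(
                f"invalid region {self.chromosome}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )


@dataclass(frozen=True, eq=False)
class GenomeLayout:
    """Ordered chromosomes tiled into fixed-width bins.

    Attributes
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    bin_size:
        Nominal bin width in bp; the final bin of each chromosome is truncated
        to the chromosome end.
    bin_chrom, bin_start, bin_end:
        Per-bin arrays: index into ``chromosomes``, and bp coordinates.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    bin_chrom: np.ndarray = field(repr=False)
    bin_start: np.ndarray = field(repr=False)
    bin_end: np.ndarray = field(repr=False)

    # -- identity -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return self.chromosomes == other.chromosomes and self.bin_size == other.bin_size

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.bin_size))

    # -- derived quantities -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def bin_widths_bp(self) -> np.ndarray:
        return self.bin_end - self.bin_start

    @property
    def total_genome_mb(self) -> float:
        """Total binned genome length G in Mb (denominator of the structural score)."""
        return float(self.bin_widths_bp.sum()) / 1e6

    def chrom_slice(self, chromosome: str) -> slice:
        """Contiguous bin-index slice covering one chromosome."""
        idx = self._chrom_index(chromosome)
        where = np.flatnonzero(self.bin_chrom == idx)
        return slice(int(where[0]), int(where[-1]) + 1)

    @property
    def chrom_slices(self) -> list[slice]:
        """Bin-index slices for every chromosome, in layout order."""
        # bins are emitted chromosome-by-chromosome, so boundaries are the
        # positions where bin_chrom changes
        edges = np.flatnonzero(np.diff(self.bin_chrom)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [self.n_bins]))
        return [slice(int(a), int(b)) for a, b in zip(starts, ends)]

    def autosome_mask(self) -> np.ndarray:
        """Boolean per-bin mask of autosomal bins (chromosome name not X/Y-like)."""
        sex = {i for i, (name, _) in enumerate(self.chromosomes)
               if name.lstrip("chr").upper() in {"X", "Y"}}
        return ~np.isin(self.bin_chrom, list(sex))

    def _chrom_index(self, chromosome: str) -> int:
        try:
            return self.chrom_names.index(chromosome)
        except ValueError:
            raise LayoutError(f"unknown chromosome {chromosome!r}") from None

    # -- tables -------------------------------------------------------------

    def bin_labels(self) -> list[str]:
        """Per-bin labels of the form ``chrom:start-end`` (0-based half-open)."""
        names = self.chrom_names
        return [
            f"{names[c]}:{s}-{e}"
            for c, s, e in zip(self.bin_chrom, self.bin_start, self.bin_end)
        ]

    def bins_frame(self) -> pd.DataFrame:
        """Bin table as a DataFrame with BED-style columns."""
        names = self.chrom_names
        return pd.DataFrame(
            {
                "chromosome": [names[c] for c in self.bin_chrom],
                "start": self.bin_start,
                "end": self.bin_end,
            }
        )

    def to_bed(self, path) -> None:
        """Write the bin table as 3-column BED."""
        self.bins_frame().to_csv(path, sep="\t", header=False, index=False)


def build_layout(chrom_lengths, bin_size: int) -> GenomeLayout:
    """Tile chromosomes into fixed-width bins.

    Parameters
    ----------
    chrom_lengths:
        Ordered ``(name, length_bp)`` pairs; lengths must be positive and names
        unique.
    bin_size:
        Bin width in bp (> 0). A chromosome of length L yields ceil(L/bin_size)
        bins, the last one truncated at L.
    """
    chrom_lengths = [(str(n), int(l)) for n, l in chrom_lengths]
    if not chrom_lengths:
        raise LayoutError("empty chromosome list")
    if bin_size <= 0:
        raise LayoutError(f"bin_size must be positive, got {bin_size}")
    names = [n for n, _ in chrom_lengths]
    if len(set(names)) != len(names):
        raise LayoutError("duplicate chromosome names")
    for name, length in chrom_lengths:
        if length <= 0:
            raise LayoutError(f"chromosome {name!r} has non-positive length {length}")

    chrom_idx, starts, ends = [], [], []
    for i, (_, length) in enumerate(chrom_lengths):
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        chrom_idx.append(np.full(len(edges), i, dtype=np.int32))
        starts.append(edges)
        ends.append(np.minimum(edges + bin_size, length))
    return GenomeLayout(
        chromosomes=tuple(chrom_lengths),
        bin_size=int(bin_size),
        bin_chrom=np.concatenate(chrom_idx),
        bin_start=np.concatenate(starts),
        bin_end=np.concatenate(ends),
    )


def region_to_bins(layout: GenomeLayout, region: Region) -> range:
    """Contiguous bin-index range of every bin overlapping ``region``.

    Overlap uses the half-open convention: a bin [s, e) overlaps [start, end)
    iff s < end and e > start.
    """
    idx = layout._chrom_index(region.chromosome)
    length = layout.chromosomes[idx][1]
    if region.end > length:
        raise LayoutError(
            f"region {region.chromosome}:{region.start}-{region.end} extends past "
            f"chromosome end ({length} bp)"
        )
    sl = layout.chrom_slice(region.chromosome)
    starts = layout.bin_start[sl]
    ends = layout.bin_end[sl]
    hit = np.flatnonzero((starts < region.end) & (ends > region.start))
    return range(sl.start + int(hit[0]), sl.start + int(hit[-1]) + 1)


def read_chrom_lengths(path) -> list[tuple[str, int]]:
    """Read a two-column chromosome/length TSV (header required)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"chromosome", "length"}.issubset(df.columns):
        raise LayoutError(f"{path}: expected columns 'chromosome' and 'length'")
    return list(zip(df["chromosome"].astype(str), df["length"].astype(int)))


def hg38_layout(bin_size: int = 1_000_000) -> GenomeLayout:
    """Bundled hg38 primary-assembly layout: chromosomes 1-22 and X (no Y).

    The FNE1 model system is female-derived, so chromosome Y carries no signal
    and is omitted; 1 Mb bins by default.
    """
    ref = resources.files("cinscape.data").joinpath("hg38_chrom_lengths.tsv")
    with resources.as_file(ref) as path:
        return build_layout(read_chrom_lengths(path), bin_size)


def toy_layout(n_chrom: int = 2, bins_per_chrom: int = 10,
               bin_size: int = 1_000_000) -> GenomeLayout:
    """Small hand-checkable layout for tests: chrA, chrB, ... with equal bins."""
    names = [f"chr{chr(ord('A') + i)}" for i in range(n_chrom)]
    return build_layout([(n, bins_per_chrom * bin_size) for n in names], bin_size)
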