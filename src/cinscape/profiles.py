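"""Per-cell integer copy-number profiles over a binned genome.

A single-cell profile is a 1-D ``numpy`` integer array with one state per
layout bin; a population is the cells-by-bins matrix wrapped in
:class:`PopulationMatrix`, the central object of scoring, clustering and
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import GenomeLayout


class ProfileError(ValueError):
    """Invalid copy-number profile or population."""


@dataclass(frozen=True, eq=False)
class PopulationMatrix:
    """Integer copy-number states CN[c, b] for N cells over B layout bins."""

    layout: GenomeLayout
    matrix: np.ndarray = field(repr=False)
    cell_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ProfileError(f"matrix must be 2-D (cells x bins), got shape {m.shape}")
        if m.shape[1] != self.layout.n_bins:
            raise ProfileError(
                f"matrix has {m.shape[1]} columns but layout has "
                f"{self.layout.n_bins} bins"
            )
        if not np.issubdtype(m.dtype, np.integer):
            if not np.all(np.equal(np.mod(m, 1), 0)):
                raise ProfileError("copy-number states must be integers")
            m = m.astype(np.int16)
        if (m < 0).any():
            c, b = np.argwhere(m < 0)[0]
            raise ProfileError(f"negative copy-number state at cell {c}, bin {b}")
        object.__setattr__(self, "matrix", m)
        ids = tuple(self.cell_ids) if self.cell_ids else tuple(
            f"cell_{i}" for i in range(m.shape[0])
        )
        if len(ids) != m.shape[0]:
            raise ProfileError(
                f"{len(ids)} cell ids for {m.shape[0]} matrix rows"
            )
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def cell(self, i: int) -> np.ndarray:
        return self.matrix[i]

    def subset(self, indices) -> "PopulationMatrix":
        indices = np.asarray(indices)
        return PopulationMatrix(
            layout=self.layout,
            matrix=self.matrix[indices],
            cell_ids=tuple(self.cell_ids[int(i)] for i in indices),
        )


def validate_profile(profile: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """Coerce and validate a single-cell profile against a layout."""
    p = np.asarray(profile)
    if p.shape != (layout.n_bins,):
        raise ProfileError(
            f"profile shape {p.shape} does not match layout ({layout.n_bins} bins)"
        )
    if (p < 0).any():
        raise ProfileError("profile has negative copy-number states")
    return p.astype(np.int16)
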