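"""Bundled population presets emulating the study's cell-line panel.

Four presets span the observed spectrum of instability:

``fne1``
    Karyotypically stable near-diploid founder: disomic genome except clonal
    monosomies of 9p, chromosome 15 and chromosome X; event rates zero.
``p1``
    Same founder with low per-division mis-segregation/segmental rates —
    the low-level instability that appears once p53 function is lost.
``pb2``
    Moderate rates on a founder carrying additional clonal segmental losses
    (1q, 2q, 6p, 12q, 13q) and a 6q gain, with a whole-genome doubling induced
    in half the lineage partway through the expansion, yielding a mixed
    diploid/tetraploid population whose tetraploid consensus is the doubling
    of the diploid one (pre-WGD losses appear as disomies on the tetraploid
    background).
``pb3``
    A WGD at generation 1 on a founder with 1q, chromosome 4 and chromosome 16
    losses, plus elevated rates: a fully tetraploid, pervasively unstable
    population.

Event rates are not identifiable from population snapshots, so they are fixed
here once at values that reproduce the qualitative cluster structure and
deviation frequencies of the modelled populations (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .genome_model import GenomeLayout, Region, hg38_layout
from .profiles import PopulationMatrix
from .simulate import CinParameters, FounderKaryotype, simulate_population

PRESET_NAMES = ("fne1", "p1", "pb2", "pb3")

# clonal monosomies of the stable near-diploid founder: 9p, 15, X
_FNE1_ABERRATIONS = (
    (Region("chr9", 0, 43_000_000), -1),
    (Region("chr15", 0, 101_991_189), -1),
    (Region("chrX", 0, 156_040_895), -1),
)

FNE1_FOUNDER = FounderKaryotype(base_ploidy=2, aberrations=_FNE1_ABERRATIONS)

# clonal arm-level segmental losses of the mixed-ploidy lineage: 1q (COX2),
# 2q, 6p, 12q and 13q (RB1), plus a 6q gain; arm boundaries at the centromere
PB2_FOUNDER = FounderKaryotype(
    base_ploidy=2,
    aberrations=_FNE1_ABERRATIONS + (
        (Region("chr1", 125_000_000, 248_956_422), -1),
        (Region("chr2", 94_000_000, 242_193_529), -1),
        (Region("chr6", 0, 60_000_000), -1),
        (Region("chr6", 60_000_000, 120_000_000), +1),
        (Region("chr12", 38_000_000, 133_275_309), -1),
        (Region("chr13", 18_000_000, 114_364_328), -1),
    ),
)

PB3_FOUNDER = FounderKaryotype(
    base_ploidy=2,
    aberrations=_FNE1_ABERRATIONS + (
        (Region("chr1", 145_000_000, 248_956_422), -1),   # 1q loss
        (Region("chr4", 0, 190_214_555), -1),
        (Region("chr16", 0, 90_338_345), -1),
    ),
)

FOUNDERS: dict[str, FounderKaryotype] = {
    "fne1": FNE1_FOUNDER,
    "p1": FNE1_FOUNDER,
    "pb2": PB2_FOUNDER,
    "pb3": PB3_FOUNDER,
}

# sample sizes mirror the modelled scWGS cell numbers: 35 stable parental
# cells, 18 p53-deficient cells, 39 mixed-ploidy and 30 tetraploid cells
PRESET_PARAMETERS: dict[str, CinParameters] = {
    "fne1": CinParameters(
        p_mis=0.0, p_seg=0.0, p_wgd=0.0,
        generations=10, carrying_capacity=200, sample_size=35,
    ),
    "p1": CinParameters(
        p_mis=0.003, p_seg=0.002, p_wgd=0.0,
        generations=12, carrying_capacity=200, sample_size=18,
    ),
    "pb2": CinParameters(
        p_mis=0.003, p_seg=0.006, p_wgd=0.0,
        generations=12, carrying_capacity=300, sample_size=39,
        induced_wgd_generation=0, induced_wgd_fraction=0.5,
    ),
    "pb3": CinParameters(
        p_mis=0.003, p_seg=0.006, p_wgd=0.0,
        generations=12, carrying_capacity=300, sample_size=30,
        induced_wgd_generation=1, induced_wgd_fraction=1.0,
    ),
}


def preset_parameters(name: str, seed: int | None = None,
                      **overrides) -> CinParameters:
    """Parameters for a named preset, with optional field overrides."""
    if name not in PRESET_PARAMETERS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    base = PRESET_PARAMETERS[name].__dict__ | {"seed": seed} | overrides
    return CinParameters(**base)


def simulate_preset(name: str, seed: int | None = None,
                    layout: GenomeLayout | None = None,
                    **overrides) -> PopulationMatrix:
    """Simulate a named preset population on the hg38 layout (or a given one)."""
    layout = hg38_layout() if layout is None else layout
    params = preset_parameters(name, seed=seed, **overrides)
    return simulate_population(FOUNDERS[name], params, layout)
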