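#!/usr/bin/env python
"""Score the called karyotypes: CIN statistics and deviation censuses.

Computes structural, aneuploidy and heterogeneity scores per population and
the deviating-cell fraction (cells differing from the consensus karyotype);
for the mixed-ploidy population the census is additionally taken per ploidy
subpopulation against its own consensus, which is how low-level instability
is quantified without the ploidy split dominating. Because these are *called*
states, the census requires a run of at least 3 consecutive deviating bins, so
isolated single-bin caller errors do not masquerade as karyotype deviations.
Writes results/scores.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cinscape import io as cio
from cinscape.population import infer_cell_ploidy
from cinscape.presets import PRESET_NAMES
from cinscape.scoring import deviation_census, score_population

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM = Path(__file__).resolve().parent.parent / "scratch" / "simulated"


def score_one(name: str, pop) -> dict:
    report = score_population(pop)
    _, fraction = deviation_census(pop, min_run=3)
    return {
        "sample": name,
        "n_cells": pop.n_cells,
        "structural": report.structural,
        "aneuploidy": report.aneuploidy,
        "heterogeneity": report.heterogeneity,
        "deviating_fraction": fraction,
    }


def main() -> None:
    rows = []
    for name in PRESET_NAMES:
        pop = cio.read_cn_matrix(SIM / f"{name}_called_cn.tsv")
        rows.append(score_one(name, pop))
        if name == "pb2":
            ploidies = np.array([infer_cell_ploidy(pop.cell(i))
                                 for i in range(pop.n_cells)])
            for label, mask in (("pb2_diploid", ploidies < 4),
                                ("pb2_tetraploid", ploidies >= 4)):
                rows.append(score_one(label, pop.subset(np.flatnonzero(mask))))
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "scores.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(table.to_string(index=False))
    print("\nThe stable parental population shows essentially no "
          "heterogeneity or deviating cells; the p53-deficient line shows "
          "low-level CIN; the doubled populations dominate the aneuploidy "
          "score at reference ploidy 2, while whole-genome doubling alone "
          "leaves the structural score nearly untouched.")


if __name__ == "__main__":
    main()
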