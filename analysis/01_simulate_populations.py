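#!/usr/bin/env python
"""Simulate the four study-condition populations and their read-outs.

Emits, per preset (stable parental, p53-deficient low-CIN, mixed
diploid/tetraploid, fully tetraploid): the true copy-number matrix, binned
read counts, miFISH probe signal counts and DNA-content values, under
scratch/simulated/ (bulky intermediates). Downstream scripts (02-05) consume
these files and write their summary tables under results/.
"""

from pathlib import Path

import numpy as np

from cinscape import io as cio
from cinscape.mifish import bundled_panel
from cinscape.presets import PRESET_NAMES, preset_parameters, simulate_preset
from cinscape.simulate import (
    CountModel,
    simulate_dna_content,
    simulate_mifish_population,
    simulate_population_counts,
)

SEED = 20211130
OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = bundled_panel()
    rng = np.random.default_rng(SEED)
    for i, name in enumerate(PRESET_NAMES):
        params = preset_parameters(name, seed=SEED + i)
        pop = simulate_preset(name, seed=SEED + i)
        cio.write_cn_matrix(pop, OUT / f"{name}_true_cn.tsv")
        counts = simulate_population_counts(pop, CountModel(), rng=rng)
        cio.write_counts_matrix(counts, OUT / f"{name}_counts.tsv")
        mifish = simulate_mifish_population(pop, panel, error_rate=0.004,
                                            rng=rng)
        cio.write_mifish_cells(mifish, OUT / f"{name}_mifish.tsv")
        dna = simulate_dna_content(pop, cv=0.05, g2_fraction=0.3, rng=rng)
        cio.write_dna_content(dna, pop.cell_ids, OUT / f"{name}_dna.tsv")
        mean_ploidy = pop.matrix.mean()
        print(f"{name}: {pop.n_cells} cells, rates (mis/seg) = "
              f"{params.p_mis}/{params.p_seg}, mean copy number "
              f"{mean_ploidy:.2f}")
    print(f"wrote simulated populations to {OUT}")


if __name__ == "__main__":
    main()
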