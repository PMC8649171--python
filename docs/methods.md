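# Methods

`cinscape` models and analyses chromosomal instability (CIN) in clonal
epithelial cell populations at the resolution of binned single-cell
copy-number profiles. This note documents the generative model, the
copy-number caller, the population statistics, and the numerical and design
choices behind them.

## Coordinate system

All profiles live on a `GenomeLayout`: ordered chromosomes tiled into
fixed-width bins (default 1 Mb), coordinates 0-based and half-open (BED
convention). The bundled reference layout covers hg38 chromosomes 1–22 and X
(3044 bins at 1 Mb); chromosome Y is omitted because the modelled cell system
is female-derived. Bin size is a free parameter: the published analyses this
package parallels inherit their binning from upstream tooling and do not pin
a value, so 1 Mb was chosen as the conventional shallow-scWGS resolution. A
small "toy" layout (2–3 chromosomes × 10 bins) ships for hand-checkable
tests.

## Generative model of CIN

The simulator is a discrete-generation population process over integer
copy-number vectors.

**Initial state.** The process starts from `carrying_capacity` identical
copies of a founder karyotype (base ploidy plus clonal aberrations) — an
established clonal line at steady state. Starting instead from a single cell
would fix early drift events at ~50% population frequency and create deep
sub-lineage structure; the populations being emulated show scattered,
low-frequency subclonal deviations, which the clonal start reproduces.

**Per division**, for each cell independently:

* with probability `p_wgd` the division is replaced by a whole-genome
  doubling (cytokinesis failure): a single daughter with every bin doubled;
* otherwise each chromosome mis-segregates independently with probability
  `p_mis`: one daughter gains a copy of the whole chromosome, its sister
  loses one (reciprocal — per-bin daughter sums always equal twice the
  parent);
* with probability `p_seg` one reciprocal distal segmental event occurs: a
  uniformly chosen breakpoint on a uniformly chosen chromosome, the distal
  segment gained by one daughter and lost by the sister.

**Viability.** A daughter dies if any autosomal bin reaches zero copies
(`nullisomy_lethal`, default true; chromosome X monosomy and loss are
tolerated, as the founder itself is X-monosomic) or any bin exceeds
`max_copy` (default 8 — no higher state is observed in the data being
emulated). The population is down-sampled uniformly to `carrying_capacity`
each generation (Wright–Fisher style) and a final uniform sample of
`sample_size` cells is emitted. Identical parameters and seed give
bit-identical output.

**Induced WGD.** `induced_wgd_generation`/`induced_wgd_fraction`
deterministically double a fraction of cells at one generation. Generation 0
doubles a fraction of the starting clonal population — a single doubling
event at line establishment, producing a tetraploid subpopulation whose
consensus is exactly twice the diploid one (clonal losses acquired before the
doubling appear as disomies on the tetraploid background). Inducing WGD
per-cell mid-expansion instead makes the doubling polyphyletic: every doubled
lineage fixes its own doubled private drift, creating internal tetraploid
substructure that a single ancestral WGD does not produce.

**Read-outs.**

* *Binned read counts*: negative binomial with mean `d · CN · gc_factor`
  (defaults: depth `d` = 50 reads/copy/bin, a realistic shallow-scWGS depth
  at 1 Mb bins) and variance `dispersion · mean` (default 2.0; `dispersion`
  = 1 collapses to Poisson). GC-like bias factors are known inputs, flat by
  default.
* *miFISH signal counts*: the true copy number at each probe's bin, perturbed
  by ±1 with probability `error_rate` per probe (floored at 0). Default
  0.004: with 20 probes this yields ~7–8% of cells deviating at 1–2 loci,
  the observed technical-noise level of the assay on cultured cells.
* *DNA content*: mean copy number over bins divided by 2 (so 1.0 ≡ 2c), with
  a `g2_fraction` of cells doubled (G2/M) and multiplicative Gaussian noise
  of coefficient of variation `cv` (default 0.05). A `gate_by_dna_content`
  helper emulates 2c/4c flow sorting.

**Presets.** Four bundled parameter sets span the modelled conditions:

| preset | founder | rates (mis/seg per division) | WGD |
|---|---|---|---|
| `fne1` | diploid; monosomies 9p, 15, X | 0 / 0 | – |
| `p1`   | same | 0.003 / 0.002 | – |
| `pb2`  | + arm losses 1q, 2q, 6p, 12q, 13q; 6q gain | 0.003 / 0.006 | 50% at establishment |
| `pb3`  | + losses 1q, chr4, chr16 | 0.003 / 0.006 | all cells, generation 1 |

All presets run 10–12 generations at carrying capacity 200–300 and emit
35/18/39/30 cells respectively (the cell numbers of the emulated scWGS
samples). Event rates are not identifiable from a population snapshot; they
were fixed once so that a sampled lineage carries on the order of one event
(deviating-cell fractions of roughly 50–80% in the unstable lines, near the
observed censuses) and so the four presets reproduce the qualitative
karyotype-cluster structure they are meant to emulate. The segmental-heavy
rates of the `pb` presets reflect the homologous-recombination-deficient
mechanism of the lines they model.

## Copy-number calling

Per cell: counts are divided by the known GC factors and rescaled to
genome-wide median 1; each chromosome is segmented by recursive binary
splitting (split at the boundary maximising the reduction in within-segment
sum of squared deviations; accept when the reduction exceeds
`gain_threshold` × the chromosome's total sum of squares and both sides keep
`min_seg` bins — defaults 0.1 and 3). "Total variance" is resolved as the
chromosome's total SSE computed once before splitting, so the acceptance
threshold is fixed per chromosome and the procedure is deterministic. A flat
noiseless chromosome has zero total SSE and is never split.

The ploidy scale `s` is fit by grid search: for each candidate base ploidy P
(default 1–8; a 2c sort gate restricts to {1,2,3}, a 4c gate to {3,4,5}),
`s` ranges over the values for which the genome-wide median scales into
[P−0.49, P+0.49], minimising the segment-length-weighted distance of scaled
medians to integers. An all-even karyotype is exact under every even
multiple, so cost ties are broken toward the gate's nominal ploidy (2 when
ungated or 2c-sorted, 4 when 4c-sorted), then toward the lower ploidy — this
is precisely the ambiguity the experimental sort gate exists to resolve, and
calls are scale-invariant in the input counts by construction. Final states
are `round(s · segment median)` clipped to [0, `max_copy`].

At default depth and dispersion the caller recovers ≥99% of bins per cell
(median) on the stable and low-CIN presets and ≥97% on the doubled ones, and
≥90% of true event boundaries within ±1 bin; residual errors are isolated
1–3-bin segments at noise-induced spurious splits.

## Population statistics

With CN[c,b] the integer state of cell c at bin b, N cells, B bins, G the
total binned genome length in Mb and ψ the reference ploidy (default 2):

* **structural score** S = (# adjacent-bin state transitions within
  chromosomes, summed over cells) / (G · N). Whole-chromosome aneuploidies
  contribute nothing; doubling a flat genome leaves S at 0.
* **aneuploidy score** A = mean over cells and bins of |CN − ψ|. A flat
  tetraploid population scores 2.0 against ψ = 2, which is what separates
  doubled populations in the score plane.
* **heterogeneity score** H = mean over bins of (1 − m_b/N) where m_b is the
  count of cells carrying the bin's modal state (ties: the maximal count).
* **consensus karyotype**: per-bin modal state; ties break toward the state
  closest to the population's overall modal ploidy, then toward the lower
  state (determinism).
* **deviation census**: a cell is flagged when it differs from the consensus
  over ≥ `min_run` consecutive bins of one chromosome. On true (simulated)
  states `min_run` = 1 is exact; on called states the analysis scripts use
  `min_run` = 3 so isolated single-bin caller errors are not counted as
  karyotype deviations. Whether the emulated census used a run-length
  criterion is not recorded, hence the exposed parameter.

## Clustering, ploidy and WGD detection

The elementary karyotype distance is the mean absolute per-bin state
difference (Manhattan / B): zero iff identical, exactly 2.0 between a
diploid and its doubling, so ploidy dominates and genotype refines.
Hierarchical clustering defaults to **Ward linkage** on the euclidean
embedding of the state vectors. Average linkage on the Manhattan distance is
available (`linkage_method="average"`), but at event rates matching the
observed deviation censuses a population inevitably contains single cells
several private events away from every neighbour, and average linkage awards
such outliers singleton clusters before clonally distinct populations
separate; Ward's variance criterion absorbs them into their parent
population first, which is the behaviour a karyotype heatmap reader expects.
Cluster labels are renumbered by lowest member index, so results are
invariant to cell order up to that canonical relabelling.

Per-cell ploidy is the modal state over bins (ties toward lower); per-cluster
consensus profiles use the scoring module's consensus definition. The WGD
test `detect_wgd_relation(low, high, q)` reports whether
`high == 2 · low` at ≥ q of bins (default q = 0.9, tolerating post-doubling
drift); it is exact (q = 1) for any profile against its literal doubling.

DNA-content distributions are classified against the fixed peak grid
{1.0, 2.0, 4.0} ≡ {2c, 4c, 8c} with 15% relative tolerance; a peak requires
≥5% of cells, and the presence of both 4c and 8c peaks flags a cycling
tetraploid population. No mixture model is fit — the discrete peak language
matches how such histograms are read.

## miFISH analysis

The bundled panel is the assay's 20-probe set — one centromere probe (CCP10)
and 19 gene loci in four hybridisation groups of five — with representative
hg38 anchor coordinates (anchors only place probes in bins; they are not
analytic inputs). The panel file records RB1 at 13q14.2 (its source table
prints "13.14.2", a typographical variant).

Analysis: per-cell ploidy class (modal count: 2 → 2c, 4 → 4c, else other);
per-probe gain/loss calls against a reference ploidy (default 2 everywhere,
per-probe references supported for 4c samples); noise filtering (cells
deviating from the sample's modal pattern at ≤ `noise_max` loci — default 2,
the assay's stated margin of error — are flagged and contribute the modal
pattern to clonality statistics); clonality (an aberration is clonal at
≥ `clonal_fraction` of cells, default 0.95 rather than 1.0 so technical
noise cannot break a clonal call; subclonal at ≥2 cells; singletons
unreported); and clone enumeration (distinct signal vectors, sorted by
frequency then lexicographically). A consequence of the noise filter is that
a coordinated subclone deviating at ≤ `noise_max` loci is absorbed as
technical error; detecting single-locus subclones requires lowering
`noise_max`.

## What the simulator does and does not emulate

The generator reproduces: clonal founder aberrations, reciprocal
whole-chromosome and distal segmental events, single ancestral or stochastic
WGD, ploidy-dependent DNA-content distributions with G2 shoulders,
overdispersed shallow read counts with known GC bias, and probe-level miFISH
noise. It does **not** emulate: gene-specific selection, translocation
fusions (only copy-number consequences), interstitial or focal events,
replication-timing or mappability artefacts, GC estimation from sequence,
cell-cycle contamination of scWGS (cells are assumed G1-sorted), or doublets.
Passing tests therefore demonstrate correctness of the algorithms under this
event model, not performance on real sequencing artefacts.

## Reproducibility

Every stochastic component takes a `numpy` `Generator` or integer seed;
`RunConfig` carries one global seed split into per-stage substreams
(`SeedSequence.spawn`), and the fully resolved configuration is serialized
into each output directory. All writers emit stable column order, so
identical configurations reproduce byte-identical outputs.

## Problem sizes

Analyses and tests run at the study's own scale: 18–39 cells per population
(100 for caller benchmarking) over 3044 hg38 bins, 10–12 generations at
carrying capacity 200–300; property tests use the toy layouts. These sizes
were chosen because the statistics of interest (censuses, scores, cluster
recovery) are already stable there.
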