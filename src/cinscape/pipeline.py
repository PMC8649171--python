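"""End-to-end pipeline: simulate -> counts -> call -> score -> cluster -> miFISH.

A :class:`RunConfig` fully determines a run: the preset (or explicit simulator
parameters), the count model, caller, scoring, clustering and miFISH settings,
and one global seed that is deterministically split into independent per-stage
substreams. The resolved configuration is serialized into the output directory
so every output is reproducible from that file alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .calling import call_population
from .genome_model import hg38_layout
from .mifish import bundled_panel, classify_clonality
from .population import classify_dna_content, cluster_karyotypes, detect_wgd_relation
from .presets import FOUNDERS, PRESET_NAMES, preset_parameters
from .scoring import deviation_census, score_population
from .simulate import (
    CountModel,
    simulate_dna_content,
    simulate_mifish_population,
    simulate_population,
    simulate_population_counts,
)

log = logging.getLogger("cinscape")

STAGES = ("simulate", "counts", "call", "score", "cluster", "mifish")


@dataclass
class RunConfig:
    """Fully resolved parameters for one pipeline run."""

    preset: str = "fne1"
    seed: int = 0
    out_dir: str = "cinscape_run"
    bin_size: int = 1_000_000
    sample_size: int | None = None
    generations: int | None = None
    p_mis: float | None = None
    p_seg: float | None = None
    p_wgd: float | None = None
    # count model
    mean_reads_per_copy_per_bin: float = 50.0
    dispersion: float = 2.0
    # caller
    min_seg: int = 3
    gain_threshold: float = 0.1
    ploidy_gate: str | None = None
    max_copy: int = 8
    # scoring
    reference_ploidy: int = 2
    min_run: int = 1
    # clustering
    k: int = 2
    # mifish
    mifish_error_rate: float = 0.004
    clonal_fraction: float = 0.95
    noise_max: int = 2
    # dna content
    dna_cv: float = 0.05
    g2_fraction: float = 0.3
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stage span; returns result objects and output paths."""
    logging.basicConfig(level=config.log_level)
    if config.preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {config.preset!r}; choose from {PRESET_NAMES}")
    bad = set(config.stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    rngs = _stage_rngs(config.seed)
    layout = hg38_layout(config.bin_size)
    overrides = {
        key: getattr(config, key)
        for key in ("sample_size", "generations", "p_mis", "p_seg", "p_wgd")
        if getattr(config, key) is not None
    }
    params = preset_parameters(config.preset, **overrides)
    results: dict = {"out_dir": out, "params": params}

    pop = None
    if "simulate" in config.stages:
        log.info("simulate: preset=%s params=%s", config.preset, params)
        pop = simulate_population(FOUNDERS[config.preset], params, layout,
                                 rng=rngs["simulate"])
        cio.write_cn_matrix(pop, out / "true_cn_matrix.tsv")
        dna = simulate_dna_content(pop, cv=config.dna_cv,
                                   g2_fraction=config.g2_fraction,
                                   rng=rngs["simulate"])
        cio.write_dna_content(dna, pop.cell_ids, out / "dna_content.tsv")
        results.update(population=pop, dna_content=dna)
        if pop.n_cells >= 10:  # peak calling needs a minimal distribution
            peaks, cycling = classify_dna_content(dna)
            results.update(dna_peaks=peaks, cycling_tetraploid=cycling)
            log.info("simulate: %d cells; DNA peaks=%s cycling_tetraploid=%s",
                     pop.n_cells, sorted(peaks), cycling)

    counts = None
    if "counts" in config.stages and pop is not None:
        model = CountModel(
            mean_reads_per_copy_per_bin=config.mean_reads_per_copy_per_bin,
            dispersion=config.dispersion,
        )
        counts = simulate_population_counts(pop, model, rng=rngs["counts"])
        cio.write_counts_matrix(counts, out / "read_counts.tsv")
        results["counts"] = counts

    called = pop
    if "call" in config.stages and counts is not None:
        # gate each cell by its noise-free DNA content, as a sorter would
        contents = pop.matrix.mean(axis=1) / 2.0
        gates = ["4c" if c > 1.5 else "2c" for c in contents]
        called, segment_frames = call_population(
            counts, layout, min_seg=config.min_seg,
            gain_threshold=config.gain_threshold,
            ploidy_gates=gates, max_copy=config.max_copy,
        )
        cio.write_cn_matrix(called, out / "called_cn_matrix.tsv")
        seg_dir = out / "segments"
        seg_dir.mkdir(exist_ok=True)
        for cell_id, frame in zip(called.cell_ids, segment_frames):
            cio.write_segments_bed(frame, seg_dir / f"{cell_id}.bed")
        accuracy = float(np.mean(
            (called.matrix == pop.matrix).mean(axis=1)
        ))
        results.update(called=called, call_accuracy=accuracy)
        log.info("call: mean per-cell bin accuracy vs truth %.4f", accuracy)

    if "score" in config.stages and called is not None:
        report = score_population(called, reference_ploidy=config.reference_ploidy)
        flags, fraction = deviation_census(called, min_run=config.min_run)
        with open(out / "scores.json", "w") as fh:
            json.dump(asdict(report) | {"deviating_fraction": fraction}, fh,
                      indent=2, sort_keys=True)
        results.update(scores=report, deviating_fraction=fraction,
                       deviation_flags=flags)
        log.info("score: structural=%.4f aneuploidy=%.4f heterogeneity=%.4f "
                 "deviating=%.1f%%", report.structural, report.aneuploidy,
                 report.heterogeneity, 100 * fraction)

    if "cluster" in config.stages and called is not None:
        k = min(config.k, called.n_cells)
        clusters = cluster_karyotypes(called, k=k)
        (out / "clusters.newick").write_text(clusters.to_newick() + "\n")
        with open(out / "cluster_labels.tsv", "w") as fh:
            fh.write("cell\tcluster\tcluster_ploidy\n")
            for cid, lab in zip(clusters.cell_ids, clusters.labels):
                fh.write(f"{cid}\t{lab}\t{clusters.cluster_ploidies[int(lab)]}\n")
        results["clusters"] = clusters
        if clusters.k >= 2:
            by_ploidy = sorted(clusters.cluster_ploidies,
                               key=clusters.cluster_ploidies.get)
            low, high = by_ploidy[0], by_ploidy[-1]
            is_wgd, mask = detect_wgd_relation(clusters.consensus[low],
                                               clusters.consensus[high])
            results.update(wgd_relation=is_wgd,
                           wgd_match_fraction=float(mask.mean()))
            log.info("cluster: k=%d ploidies=%s wgd_relation=%s",
                     clusters.k, clusters.cluster_ploidies, is_wgd)

    if "mifish" in config.stages and pop is not None:
        panel = bundled_panel()
        cells = simulate_mifish_population(pop, panel,
                                           error_rate=config.mifish_error_rate,
                                           rng=rngs["mifish"])
        cio.write_mifish_cells(cells, out / "mifish_cells.tsv")
        report = classify_clonality(cells, clonal_fraction=config.clonal_fraction,
                                    noise_max=config.noise_max)
        report.probe_status.to_csv(out / "mifish_probe_status.tsv", sep="\t",
                                   index=False, lineterminator="\n")
        report.clones.to_csv(out / "mifish_clones.tsv", sep="\t", index=False,
                             lineterminator="\n")
        results["mifish_report"] = report
        log.info("mifish: %d cells, %d flagged within technical error, "
                 "%d clones", report.n_cells, report.n_flagged,
                 len(report.clones))

    return results
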