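import numpy as np
import pandas as pd
import pytest

from cinscape.genome_model import hg38_layout
from cinscape.mifish import (
    MiFishPanel,
    PanelError,
    bundled_panel,
    classify_clonality,
    enumerate_clones,
    estimate_cell_ploidy,
    filter_noise,
    load_panel,
    modal_pattern,
    score_cell,
    write_panel,
)
from cinscape.presets import FNE1_FOUNDER
from cinscape.simulate import simulate_mifish


@pytest.fixture(scope="module")
def panel():
    return bundled_panel()


def fne1_cells(n):
    """n cells with the stable parental pattern: all 2 except one CDKN2A copy."""
    panel = bundled_panel()
    row = {name: 2 for name in panel.probe_names}
    row["CDKN2A"] = 1
    return pd.DataFrame([dict(row) for _ in range(n)],
                        index=[f"c{i}" for i in range(n)])


class TestPanel:
    def test_bundled_panel_composition(self, panel):
        assert panel.n_probes == 20
        assert panel.n_groups == 4
        assert (panel.probes.groupby("group").size() == 5).all()
        assert "CCP10" in panel.probe_names
        assert panel.probes.set_index("name").loc["RB1", "cytoband"] == "13q14.2"

    def test_round_trip_preserves_fields(self, panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        reloaded = load_panel(path)
        pd.testing.assert_frame_equal(
            reloaded.probes[panel.probes.columns], panel.probes
        )

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("name\tcytoband\tchromosome\tposition\tgroup\n")
        with pytest.raises(PanelError):
            load_panel(path)

    def test_duplicate_names_rejected(self, panel):
        doubled = pd.concat([panel.probes, panel.probes.iloc[[0]]])
        with pytest.raises(PanelError):
            MiFishPanel(probes=doubled)

    def test_unknown_chromosome_rejected(self, panel):
        bad = panel.probes.copy()
        bad.loc[0, "chromosome"] = "chr99"
        with pytest.raises(PanelError):
            MiFishPanel(probes=bad)

    def test_oversized_group_rejected(self, panel):
        bad = panel.probes.copy()
        bad["group"] = 1  # all 20 probes in one hybridisation panel
        with pytest.raises(PanelError):
            MiFishPanel(probes=bad)

    def test_probe_bins_resolve_on_hg38(self, panel):
        layout = hg38_layout()
        bins = panel.bin_indices(layout)
        assert len(bins) == 20
        assert (bins >= 0).all() and (bins < layout.n_bins).all()

    def test_off_layout_probe_rejected(self, panel):
        from cinscape.genome_model import toy_layout

        with pytest.raises(PanelError):
            panel.bin_indices(toy_layout())


class TestCellPloidy:
    def test_parental_pattern_is_2c(self):
        cell = fne1_cells(1).iloc[0]
        assert estimate_cell_ploidy(cell) == "2c"

    def test_tetraploid_with_chr17_dosage_decrease_is_4c(self, panel):
        counts = {name: 4 for name in panel.probe_names}
        counts.update(TP53=3, NF1=4, HER2=4)
        assert estimate_cell_ploidy(counts) == "4c"

    def test_triploid_pattern_is_other(self, panel):
        counts = {name: 3 for name in panel.probe_names}
        assert estimate_cell_ploidy(counts) == "other"

    def test_even_split_ties_toward_lower(self, panel):
        counts = {name: (2 if i < 10 else 4)
                  for i, name in enumerate(panel.probe_names)}
        assert estimate_cell_ploidy(counts) == "2c"


class TestScoreCell:
    def test_parental_cell_loses_only_cdkn2a(self):
        calls = score_cell(fne1_cells(1).iloc[0], reference=2)
        assert calls["CDKN2A"] == "loss"
        assert (calls.drop("CDKN2A") == "neutral").all()

    def test_cell_equal_to_reference_all_neutral(self, panel):
        ref = {name: 3 for name in panel.probe_names}
        assert (score_cell(ref, reference=ref) == "neutral").all()

    def test_agrees_with_elementwise_oracle(self, panel, rng):
        for _ in range(20):
            counts = {n: int(rng.integers(0, 6)) for n in panel.probe_names}
            ref = {n: int(rng.integers(1, 5)) for n in panel.probe_names}
            calls = score_cell(counts, reference=ref)
            for name in panel.probe_names:
                expected = ("loss" if counts[name] < ref[name]
                            else "gain" if counts[name] > ref[name]
                            else "neutral")
                assert calls[name] == expected

    def test_missing_probe_in_reference_rejected(self):
        cell = fne1_cells(1).iloc[0]
        with pytest.raises(PanelError):
            score_cell(cell, reference={"CDKN2A": 2})


class TestNoiseFilter:
    def test_minor_deviations_flagged_but_statistics_unchanged(self, rng):
        cells = fne1_cells(100)
        noisy = rng.choice(100, size=7, replace=False)
        for i, cell in enumerate(noisy):
            probe = ["MYC", "PTEN", "KRAS", "CCND1", "NF2", "TP53", "CDH1"][i]
            cells.iloc[cell, cells.columns.get_loc(probe)] += 1
        effective, flagged = filter_noise(cells, noise_max=2)
        assert flagged.sum() == 7
        # flagged cells contribute the modal pattern, so clonality is intact
        report = classify_clonality(cells)
        cdkn2a = report.probe_status.set_index("probe").loc["CDKN2A"]
        assert cdkn2a["status"] == "clonal_loss"
        assert cdkn2a["loss_fraction"] == 1.0
        myc = report.probe_status.set_index("probe").loc["MYC"]
        assert myc["status"] == "neutral"

    def test_noise_max_zero_flags_nothing(self, rng):
        cells = fne1_cells(20)
        cells.iloc[3, 0] += 1
        _, flagged = filter_noise(cells, noise_max=0)
        assert flagged.sum() == 0

    def test_flags_agree_with_brute_force_count(self, panel, rng):
        cells = pd.DataFrame(
            rng.integers(1, 4, size=(30, panel.n_probes)),
            columns=panel.probe_names,
        )
        mode = modal_pattern(cells)
        _, flagged = filter_noise(cells, noise_max=2)
        for i in range(30):
            n_dev = sum(
                int(cells.iloc[i][p] != mode[p]) for p in panel.probe_names
            )
            assert flagged.iloc[i] == (0 < n_dev <= 2)

    def test_large_deviation_keeps_observed_pattern(self):
        cells = fne1_cells(10)
        cells.iloc[0, :5] = 4  # 5 deviating loci: beyond technical error
        effective, flagged = filter_noise(cells, noise_max=2)
        assert not flagged.iloc[0]
        assert (effective.iloc[0, :5] == 4).all()


class TestClonality:
    def test_universal_cdkn2a_loss_is_clonal(self):
        report = classify_clonality(fne1_cells(100))
        row = report.probe_status.set_index("probe").loc["CDKN2A"]
        assert row["status"] == "clonal_loss"
        assert row["loss_fraction"] == 1.0

    def test_singleton_aberration_not_reported_subclonal(self):
        cells = fne1_cells(100)
        cells.iloc[5, cells.columns.get_loc("MYC")] = 3
        # noise_max=0 so the singleton keeps its observed pattern
        report = classify_clonality(cells, noise_max=0)
        row = report.probe_status.set_index("probe").loc["MYC"]
        assert row["gain_status"] == "none"
        assert row["status"] == "neutral"

    def test_pb2m_like_clonal_losses(self, panel):
        counts = {name: 2 for name in panel.probe_names}
        counts.update(CDKN2A=1, COX2=1, RB1=1)
        cells = pd.DataFrame([dict(counts) for _ in range(80)])
        report = classify_clonality(cells)
        status = report.probe_status.set_index("probe")["status"]
        assert status["CDKN2A"] == "clonal_loss"
        assert status["COX2"] == "clonal_loss"
        assert status["RB1"] == "clonal_loss"
        assert (status.drop(["CDKN2A", "COX2", "RB1"]) == "neutral").all()

    def test_subclonal_multilocus_gain_detected(self):
        # a coordinated 3-locus subclone exceeds the technical-noise margin
        # (noise_max=2) and so survives the modal-pattern snap
        cells = fne1_cells(100)
        for probe in ("MYC", "CCND1", "KRAS"):
            cells.iloc[:30, cells.columns.get_loc(probe)] = 3
        report = classify_clonality(cells)
        status = report.probe_status.set_index("probe")
        for probe in ("MYC", "CCND1", "KRAS"):
            assert status.loc[probe, "gain_status"] == "subclonal"
            assert status.loc[probe, "gain_fraction"] == pytest.approx(0.3)

    def test_single_locus_subclone_absorbed_as_technical_noise(self):
        # a 1-locus deviation is within the assay's stated margin of error,
        # so those cells contribute the modal pattern instead
        cells = fne1_cells(100)
        cells.iloc[:30, cells.columns.get_loc("MYC")] = 3
        report = classify_clonality(cells)
        row = report.probe_status.set_index("probe").loc["MYC"]
        assert row["gain_status"] == "none"
        assert report.n_flagged == 30

    def test_invariant_to_cell_order(self, rng):
        cells = fne1_cells(60)
        cells.iloc[:20, cells.columns.get_loc("PTEN")] = 1
        shuffled = cells.sample(frac=1.0, random_state=11)
        a = classify_clonality(cells).probe_status.set_index("probe")
        b = classify_clonality(shuffled).probe_status.set_index("probe")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(PanelError):
            classify_clonality(pd.DataFrame())


class TestCloneEnumeration:
    def test_identical_cells_form_one_clone(self):
        clones = enumerate_clones(fne1_cells(25))
        assert len(clones) == 1
        assert clones["n_cells"].iloc[0] == 25

    def test_constructed_three_patterns(self, panel):
        base = {name: 2 for name in panel.probe_names}
        variant = dict(base, MYC=3)
        other = dict(base, PTEN=1)
        cells = pd.DataFrame([base, base, variant, variant, other])
        clones = enumerate_clones(cells)
        assert len(clones) == 3
        assert list(clones["n_cells"]) == [2, 2, 1]
        assert clones["n_cells"].sum() == 5

    def test_clone_count_matches_hash_set_oracle(self, panel, rng):
        cells = pd.DataFrame(
            rng.integers(1, 4, size=(1000, panel.n_probes)),
            columns=panel.probe_names,
        )
        clones = enumerate_clones(cells)
        oracle = {tuple(row) for row in cells.to_numpy()}
        assert len(clones) == len(oracle)
        assert clones["n_cells"].sum() == 1000


class TestSimulationRoundTrip:
    def test_error_free_simulation_recovers_probe_events(self, rng):
        """simulate -> score against the founder's probe states recovers
        exactly the copy-number events present at probe loci."""
        layout = hg38_layout()
        panel = bundled_panel()
        founder_profile = FNE1_FOUNDER.build(layout)
        reference = panel.expected_counts(founder_profile, layout)
        for _ in range(10):
            profile = founder_profile.copy()
            # random whole-chromosome gain
            sl = layout.chrom_slices[int(rng.integers(len(layout.chromosomes)))]
            profile[sl] += 1
            cell = simulate_mifish(profile, panel, layout, error_rate=0.0)
            calls = score_cell(cell, reference=reference)
            truth = panel.expected_counts(profile, layout)
            for name in panel.probe_names:
                expected = ("gain" if truth[name] > reference[name]
                            else "loss" if truth[name] < reference[name]
                            else "neutral")
                assert calls[name] == expected
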