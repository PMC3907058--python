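"""Synthetic study generator: founders, planted truth, inversions, studies."""

import numpy as np
import pytest
from scipy import stats

from erpool import io as pio
from erpool.forward import RecombinationMap, simulate_forward
from erpool.synth import (
    StudyConfig,
    SyntheticTruth,
    embed_inversion,
    generate_founders,
    generate_study,
    neutral_start_frequencies,
    plant_truth,
)


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = StudyConfig()
        assert cfg.n_lines == 113 and cfg.n_reps == 5
        assert cfg.census == 1000 and cfg.generations == 15
        assert cfg.pool_size == 500 and cfg.coverage_range == (35, 90)
        assert cfg.n_founder_haplotypes == 226

    def test_desk_scale_reduces_census(self):
        cfg = StudyConfig.desk_scale()
        assert cfg.census == 200 and cfg.chrom_length == 5_000_000

    def test_validation(self):
        with pytest.raises(ValueError):
            StudyConfig(census=0)


class TestFounders:
    def test_pool_shape_and_line_grouping(self, founders, founder_lines, desk_config):
        assert founders.haplotypes.shape[0] == 226
        assert founders.haplotypes.shape[1] <= desk_config.n_loci
        assert len(founder_lines) == 226 and len(set(founder_lines)) == 113

    def test_singletons_present(self, founders):
        freq = founders.haplotypes.sum(axis=0)
        assert (freq == 1).sum() > 0

    def test_folded_sfs_matches_neutral_expectation(self, founders):
        H = founders.haplotypes.shape[0]
        counts = founders.haplotypes.sum(axis=0)
        folded = np.minimum(counts, H - counts)
        # coarse-bin chi-square against the folded neutral SFS ~ 1/i + 1/(H-i)
        i = np.arange(1, H // 2 + 1)
        w = 1.0 / i + 1.0 / (H - i)
        w[-1] /= 2  # the H/2 class folds onto itself
        edges = np.array([1, 2, 3, 5, 9, 17, 33, 65, H // 2 + 1])
        obs = np.histogram(folded, bins=edges)[0]
        exp = np.array([w[(i >= lo) & (i < hi)].sum() for lo, hi in zip(edges[:-1], edges[1:])])
        exp = exp / exp.sum() * obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=len(obs) - 1) > 1e-4

    def test_sfs_start_frequency_sampler_respects_floor(self):
        f = neutral_start_frequencies(5000, min_minor=0.025, seed=1)
        assert f.min() >= 0.025 and f.max() <= 0.5


class TestPlantTruth:
    def test_zero_fraction_gives_neutral_treatment(self, founders, desk_config):
        truth = plant_truth(founders, desk_config, hot_frac=0.0, seed=1)
        assert truth.hot.empty and not truth.cold.empty

    def test_hot_rarer_than_cold_and_disjoint(self, founders, desk_config):
        truth = plant_truth(founders, desk_config, seed=2)
        assert truth.hot.p0.mean() < truth.cold.p0.mean()
        assert not set(truth.hot.locus) & set(truth.cold.locus)

    def test_stratum_shortage_raises(self, founders, desk_config):
        with pytest.raises(ValueError, match="stratum"):
            plant_truth(founders, desk_config, hot_frac=0.009, hot_freq_band=(0.49, 0.5), seed=3)

    def test_oversized_fraction_rejected(self, founders, desk_config):
        with pytest.raises(ValueError):
            plant_truth(founders, desk_config, hot_frac=0.05, seed=4)

    def test_truth_json_round_trip(self, founders, desk_config, tmp_path):
        truth = plant_truth(founders, desk_config, seed=5)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        np.testing.assert_array_equal(back.hot.locus, truth.hot.locus)
        np.testing.assert_allclose(back.cold.s, truth.cold.s)


class TestEmbedInversion:
    def test_marker_frequencies_equal_carrier_frequency(self, founders):
        updated, rec = embed_inversion(founders, (1_000_000, 2_000_000), 0.4, seed=6)
        freqs = updated.frequencies()
        for m in rec["marker_loci"]:
            assert freqs[m] == pytest.approx(rec["carrier_freq"])

    def test_suppression_keeps_carrier_markers_in_lockstep(self, founders):
        updated, rec = embed_inversion(founders, (1_000_000, 2_500_000), 0.5, seed=7)
        rmap = RecombinationMap.uniform(int(founders.positions[-1]) + 1, 20.0)
        end, _ = simulate_forward(updated, rmap, None, generations=8, seed=8)
        markers = rec["marker_loci"]
        cols = end.haplotypes[:, markers]
        assert (cols == cols[:, [0]]).all()  # no recombinant marker haplotypes

    def test_without_suppression_markers_recombine(self, founders):
        updated, rec = embed_inversion(founders, (1_000_000, 2_500_000), 0.5, seed=7, suppressed=False)
        rmap = RecombinationMap.uniform(int(founders.positions[-1]) + 1, 20.0)
        end, _ = simulate_forward(updated, rmap, None, generations=8, seed=8)
        cols = end.haplotypes[:, rec["marker_loci"]]
        assert not (cols == cols[:, [0]]).all()

    def test_carrier_freq_validated(self, founders):
        with pytest.raises(ValueError):
            embed_inversion(founders, (0, 1000), 1.5)


class TestGenerateStudy:
    @pytest.fixture(scope="class")
    def small_study(self):
        cfg = StudyConfig.desk_scale(seed=7, n_loci=6000, chrom_length=2_000_000)
        return generate_study(cfg, seed=7)

    def test_panel_layout(self, small_study):
        panel = small_study.panel
        assert panel.n_samples == 15  # 5 base + 5 hot + 5 cold
        treatments = {m.treatment for m in panel.samples}
        assert treatments == {"base", "hot", "cold"}

    def test_base_frequencies_match_founders_within_noise(self, small_study):
        founders = small_study.founders
        panel = small_study.panel
        base = panel.samples_where(treatment="base")
        alt = panel.counts[:, base, 1].sum(axis=1)
        cov = panel.coverage()[:, base].sum(axis=1)
        obs = alt / np.maximum(cov, 1)
        resid = obs - founders.frequencies()
        assert abs(resid.mean()) < 0.01
        assert np.corrcoef(obs, founders.frequencies())[0, 1] > 0.98

    def test_same_seed_byte_identical(self):
        cfg = StudyConfig.desk_scale(seed=9, n_loci=1500, chrom_length=800_000)
        a = generate_study(cfg, seed=9)
        b = generate_study(cfg, seed=9)
        assert pio.sync_text(a.panel) == pio.sync_text(b.panel)

    def test_outputs_written(self, tmp_path):
        cfg = StudyConfig.desk_scale(seed=10, n_loci=1200, chrom_length=600_000)
        generate_study(cfg, seed=10, outdir=tmp_path)
        for name in ("study.sync", "samples.tsv", "gene_models.tsv", "truth.json", "recomb_map.tsv"):
            assert (tmp_path / name).exists()

    def test_strong_planted_loci_concentrate_in_top_ranks(self, small_study):
        from erpool.cmh import cmh_scan, paired_design
        from erpool.io import filter_snps

        panel = filter_snps(small_study.panel)
        scan = cmh_scan(panel, paired_design(panel, "hot"))
        strong = small_study.truth.hot[small_study.truth.hot.s >= 0.3].pos.to_numpy() + 1
        sub = scan.table[scan.table.pos.isin(strong)]
        assert len(sub) > 0
        # surviving strong planted loci sit far above the median rank
        frac_top_decile = (sub["rank"] <= 0.1 * scan.n_snps).mean()
        assert frac_top_decile >= 0.5
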