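"""AFC histograms, Ne goodness-of-fit estimation, and empirical FDR calling."""

import numpy as np
import pytest

from erpool.cmh import cmh_scan, paired_design
from erpool.nefdr import (
    AFC_BIN_EDGES,
    afc_histogram,
    call_candidates,
    empirical_fdr_threshold,
    fit_ne,
    observed_afc_histograms,
)
from erpool.neutral import EmpiricalSamplers, simulate_neutral_panel
from erpool.synth import neutral_start_frequencies, simulate_replicated_panel


def _samplers(seed=1, n_reps=3):
    return EmpiricalSamplers.uniform(neutral_start_frequencies(20_000, seed=seed), n_reps=n_reps)


class TestAFCHistogram:
    def test_zero_change_falls_in_centre_bin(self):
        h = afc_histogram(np.full(10, 0.3), np.full(10, 0.3))
        centre = np.flatnonzero((AFC_BIN_EDGES[:-1] <= 0) & (AFC_BIN_EDGES[1:] > 0))[0]
        assert h.proportions[centre] == 1.0
        assert AFC_BIN_EDGES[centre] == pytest.approx(-0.005)
        assert AFC_BIN_EDGES[centre + 1] == pytest.approx(0.005)

    def test_bins_are_one_percent_wide_over_unit_range(self):
        widths = np.diff(AFC_BIN_EDGES)
        np.testing.assert_allclose(widths, 0.01, atol=1e-9)
        assert AFC_BIN_EDGES[0] <= -1.0 and AFC_BIN_EDGES[-1] >= 1.0

    def test_symmetric_drift_gives_symmetric_histogram(self):
        rng = np.random.default_rng(2)
        start = np.full(200_000, 0.5)
        end = start + rng.normal(0, 0.05, size=start.size)
        h = afc_histogram(start, end)
        assert np.abs(h.proportions - h.proportions[::-1]).max() < 0.01

    def test_normalised_and_errors(self):
        h = afc_histogram([0.1, 0.2], [0.2, 0.1])
        assert h.proportions.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            afc_histogram([], [])
        with pytest.raises(ValueError):
            afc_histogram([0.1], [0.1, 0.2])


class TestFitNe:
    def test_degenerate_single_grid_value(self):
        sim = simulate_neutral_panel(_samplers(), N=200, t=15, n_snps=5000, seed=3)
        hists = [afc_histogram(sim.observed_start()[:, r], sim.observed_end()[:, r]) for r in range(3)]
        fit = fit_ne(hists, _samplers(), [300], t=15, n_snps=5000, seed=4)
        assert fit.best_ne == 300 and fit.conservative_ne == 300

    def test_conservative_never_exceeds_best(self):
        for seed in range(3):
            sim = simulate_neutral_panel(_samplers(seed), N=250, t=15, n_snps=20_000, seed=seed)
            hists = [
                afc_histogram(sim.observed_start()[:, r], sim.observed_end()[:, r]) for r in range(3)
            ]
            fit = fit_ne(hists, _samplers(seed), [100, 175, 250, 400], t=15, n_snps=20_000, seed=seed)
            assert fit.conservative_ne <= fit.best_ne

    def test_recovers_simulated_ne(self):
        sim = simulate_neutral_panel(_samplers(11), N=250, t=15, n_snps=50_000, seed=11)
        hists = [afc_histogram(sim.observed_start()[:, r], sim.observed_end()[:, r]) for r in range(3)]
        fit = fit_ne(hists, _samplers(11), [125, 175, 250, 350, 500], t=15, n_snps=50_000, seed=12)
        assert abs(fit.best_ne - 250) / 250 <= 0.25

    def test_fit_profile_unimodal_for_clean_data(self):
        sim = simulate_neutral_panel(_samplers(13), N=250, t=15, n_snps=50_000, seed=13)
        hists = [afc_histogram(sim.observed_start()[:, r], sim.observed_end()[:, r]) for r in range(3)]
        fit = fit_ne(hists, _samplers(13), [60, 100, 160, 250, 400, 640, 1000], t=15, n_snps=50_000, seed=14)
        m = fit.mean_fit
        best = int(np.argmin(m))
        assert all(np.diff(m[: best + 1]) <= 0) and all(np.diff(m[best:]) >= 0)

    def test_observed_histogram_helper_matches_manual(self):
        panel, _ = simulate_replicated_panel(2000, N=250, t=15, n_reps=3, seed=15)
        hists = observed_afc_histograms(panel, "evolved")
        assert len(hists) == 3
        assert all(h.proportions.sum() == pytest.approx(1.0) for h in hists)


class TestEmpiricalFDR:
    def test_threshold_is_kth_smallest(self):
        sim_p = np.array([0.5, 0.001, 0.2, 0.01, 0.9, 0.05])
        assert empirical_fdr_threshold(sim_p, 1 / 6) == pytest.approx(0.001)
        assert empirical_fdr_threshold(sim_p, 0.5) == pytest.approx(0.05)

    def test_gamma_one_returns_max(self):
        sim_p = np.array([0.3, 0.8, 0.1])
        assert empirical_fdr_threshold(sim_p, 1.0) == pytest.approx(0.8)

    def test_unresolvable_gamma_errors(self):
        with pytest.raises(ValueError, match="simulate more"):
            empirical_fdr_threshold(np.array([0.1, 0.2]), 0.001)
        with pytest.raises(ValueError):
            empirical_fdr_threshold(np.array([]), 0.1)

    def test_membership_is_strict_and_matches_brute_force(self):
        panel, _ = simulate_replicated_panel(3000, N=250, t=15, n_reps=3, seed=16)
        scan = cmh_scan(panel, paired_design(panel, "evolved"))
        p = scan.table.pvalue.to_numpy()
        thr = np.sort(p)[50]
        cands = call_candidates(scan, thr, gamma=0.017, treatment="evolved")
        assert cands.n_candidates == int((p < thr).sum())
        assert (cands.table.pvalue < thr).all()

    def test_threshold_below_all_gives_empty_set(self):
        panel, _ = simulate_replicated_panel(500, N=250, t=15, n_reps=3, seed=17)
        scan = cmh_scan(panel, paired_design(panel, "evolved"))
        assert call_candidates(scan, 0.0, 0.001).n_candidates == 0

    def test_power_on_planted_strong_selection(self):
        """gamma=0.02 calling recovers >=80 of 100 planted loci among 1e5."""
        panel, sel = simulate_replicated_panel(
            100_000, N=250, t=15, n_reps=3, n_selected=100, s_range=(0.3, 0.5), seed=18
        )
        scan = cmh_scan(panel, paired_design(panel, "evolved"))
        null = simulate_neutral_panel(_samplers(19), N=250, t=15, n_snps=100_000, seed=19).to_site_panel()
        null_scan = cmh_scan(null, paired_design(null, "evolved"))
        thr = empirical_fdr_threshold(null_scan.table.pvalue.to_numpy(), 0.02)
        called = set(call_candidates(scan, thr, 0.02).table.pos)
        assert sum((i + 1) in called for i in sel) >= 80

    def test_candidate_count_decreases_with_simulated_ne(self):
        """Smaller null Ne -> broader null AFC -> fewer observed candidates."""
        panel, _ = simulate_replicated_panel(30_000, N=250, t=15, n_reps=3, seed=20)
        scan = cmh_scan(panel, paired_design(panel, "evolved"))
        counts = []
        for ne in (100, 250, 600):
            null = simulate_neutral_panel(_samplers(21), N=ne, t=15, n_snps=30_000, seed=21).to_site_panel()
            null_scan = cmh_scan(null, paired_design(null, "evolved"))
            thr = empirical_fdr_threshold(null_scan.table.pvalue.to_numpy(), 0.01)
            counts.append(call_candidates(scan, thr, 0.01).n_candidates)
        assert counts[0] <= counts[1] <= counts[2]
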