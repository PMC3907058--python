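"""Forward simulator: recombination maps, selection dynamics, pooling."""

import numpy as np
import pytest
from scipy import stats

from erpool.forward import (
    HaplotypePopulation,
    RecombinationMap,
    SelectionSpec,
    deterministic_trajectory,
    pool_sequence,
    selection_coefficient,
    simulate_forward,
    uniform_coverage_sampler,
)
from erpool.io import SampleMeta
from erpool.neutral import build_transition_matrix, sample_drifted_counts


def _pop(rng, n_ind=60, L=40, freq=0.5, length=500_000):
    haps = (rng.random((2 * n_ind, L)) < freq).astype(np.uint8)
    pos = np.sort(rng.choice(length, L, replace=False))
    return HaplotypePopulation(haps, pos)


class TestRecombinationMap:
    def test_total_morgans(self):
        m = RecombinationMap(starts=[0, 2_000_000], ends=[2_000_000, 5_000_000], rates_cm_mb=[2.0, 0.5])
        assert m.total_morgans == pytest.approx((2e6 * 2 + 3e6 * 0.5) / 1e8)

    def test_must_tile_without_gaps(self):
        with pytest.raises(ValueError, match="tile"):
            RecombinationMap(starts=[0, 3_000_000], ends=[2_000_000, 5_000_000], rates_cm_mb=[1, 1])
        with pytest.raises(ValueError):
            RecombinationMap(starts=[0], ends=[1000], rates_cm_mb=[-1])

    def test_breakpoints_follow_rate_density(self):
        rng = np.random.default_rng(1)
        m = RecombinationMap(starts=[0, 500_000], ends=[500_000, 1_000_000], rates_cm_mb=[9.0, 1.0])
        bp = m.sample_breakpoints(20_000, rng)
        assert (bp < 500_000).mean() == pytest.approx(0.9, abs=0.01)

    def test_tsv_round_trip(self, tmp_path):
        m = RecombinationMap(starts=[0, 10_000], ends=[10_000, 30_000], rates_cm_mb=[2.5, 0.5], chrom="2L")
        path = tmp_path / "map.tsv"
        m.to_tsv(path)
        back = RecombinationMap.from_tsv(path)
        np.testing.assert_array_equal(back.starts, m.starts)
        np.testing.assert_allclose(back.rates_cm_mb, m.rates_cm_mb)


class TestSelectionCoefficient:
    def test_worked_example_half(self):
        assert selection_coefficient(0.01, 0.30, 15) == pytest.approx(0.5, abs=0.005)

    def test_no_change_gives_zero(self):
        assert selection_coefficient(0.2, 0.2, 10) == 0.0

    def test_boundaries_rejected(self):
        for p0, p1 in [(0.0, 0.5), (0.5, 1.0), (1.0, 0.5)]:
            with pytest.raises(ValueError):
                selection_coefficient(p0, p1, 10)
        with pytest.raises(ValueError):
            selection_coefficient(0.1, 0.2, 0)

    @pytest.mark.parametrize("s", [0.05, 0.2, 0.5])
    @pytest.mark.parametrize("p0", [0.01, 0.3])
    def test_inverse_of_deterministic_model(self, s, p0):
        p1 = deterministic_trajectory(p0, s, 15)[-1]
        assert selection_coefficient(p0, p1, 15) == pytest.approx(s, rel=1e-9)


class TestSimulateForward:
    def test_zero_generations_identity(self):
        rng = np.random.default_rng(2)
        pop = _pop(rng)
        out, traj = simulate_forward(pop, RecombinationMap.uniform(500_000, 2.0), None, 0, seed=3, track_locus=0)
        np.testing.assert_array_equal(out.haplotypes, pop.haplotypes)
        assert traj.shape == (1,)

    def test_gametes_copy_parental_alleles(self):
        # two homozygous-distinct parents: every offspring haplotype must be
        # a 0/1 mosaic matching one parent at each locus (trivially true for
        # binary alleles) and census stays constant
        rng = np.random.default_rng(4)
        pop = _pop(rng, n_ind=30)
        out, _ = simulate_forward(pop, RecombinationMap.uniform(500_000, 5.0), None, 5, seed=5)
        assert out.haplotypes.shape == pop.haplotypes.shape
        assert set(np.unique(out.haplotypes)) <= {0, 1}
        assert out.generation == 5

    def test_no_recombination_preserves_founder_haplotypes(self):
        rng = np.random.default_rng(6)
        pop = _pop(rng, n_ind=40, L=30)
        out, _ = simulate_forward(pop, RecombinationMap.uniform(500_000, 0.0), None, 10, seed=7)
        founders = {tuple(h) for h in pop.haplotypes}
        for h in out.haplotypes:
            assert tuple(h) in founders

    def test_neutral_drift_variance_small_t(self):
        rng = np.random.default_rng(8)
        n_ind, t, reps = 50, 3, 250
        changes = []
        for _ in range(reps):
            pop = _pop(rng, n_ind=n_ind, L=20)
            locus = 10
            p0 = pop.haplotypes[:, locus].mean()
            out, traj = simulate_forward(
                pop, RecombinationMap.uniform(500_000, 2.0), None, t, rng=rng, track_locus=locus
            )
            changes.append(traj[-1] - p0)
        var = np.var(changes)
        expected = 0.5 * 0.5 * (1 - (1 - 1 / (2 * n_ind)) ** t)
        assert var == pytest.approx(expected, rel=0.35)

    def test_marginal_afc_exchangeable_with_transition_matrix(self):
        """Neutral forward-sim trajectories match the WF null at matched N."""
        rng = np.random.default_rng(9)
        n_ind, t, reps, L = 80, 8, 150, 20
        fwd = []
        for _ in range(reps):
            haps = np.zeros((2 * n_ind, L), dtype=np.uint8)
            haps[: n_ind, :] = 1  # every locus at exactly 0.5
            perm = rng.permutation(2 * n_ind)
            pop = HaplotypePopulation(haps[perm], np.arange(L) * 1000)
            _, traj = simulate_forward(
                pop, RecombinationMap.uniform(L * 1000, 2.0), None, t, rng=rng, track_locus=0
            )
            fwd.append(traj[-1] - 0.5)
        tm = build_transition_matrix(2 * n_ind)
        wf = sample_drifted_counts(tm, t, np.full(reps, n_ind), rng) / (2 * n_ind) - 0.5
        assert stats.ks_2samp(fwd, wf).pvalue > 0.01

    def test_selection_monotone_in_s(self):
        rng = np.random.default_rng(10)
        rises = {}
        for s in (0.0, 0.1, 0.5):
            r = []
            for _ in range(40):
                pop = _pop(rng, n_ind=60, L=10, freq=0.2)
                _, traj = simulate_forward(
                    pop, RecombinationMap.uniform(500_000, 2.0), SelectionSpec(5, s), 10, rng=rng
                )
                r.append(traj[-1] - traj[0])
            rises[s] = np.mean(r)
        assert rises[0.0] < rises[0.1] < rises[0.5]

    def test_strong_selection_band_occupancy(self):
        """s=0.5 from ~1%: runs rising 25-35% occur at a usable rate and the
        mean rise is strongly positive (the band is an inclusion criterion)."""
        rng = np.random.default_rng(11)
        n_ind, L = 125, 12
        rises = []
        for rep in range(150):
            haps = (rng.random((2 * n_ind, L)) < 0.3).astype(np.uint8)
            haps[:, 6] = 0
            haps[rng.choice(2 * n_ind, 3 if rep % 2 else 2, replace=False), 6] = 1
            pop = HaplotypePopulation(haps, np.arange(L) * 80_000)
            _, traj = simulate_forward(
                pop, RecombinationMap.uniform(L * 80_000, 2.5), SelectionSpec(6, 0.5), 15, rng=rng
            )
            rises.append(traj[-1] - traj[0])
        rises = np.asarray(rises)
        in_band = ((rises >= 0.25) & (rises <= 0.35)).mean()
        assert 0.03 <= in_band <= 0.5
        assert rises.mean() > 0.1

    def test_selected_locus_out_of_range(self):
        rng = np.random.default_rng(12)
        pop = _pop(rng)
        with pytest.raises(ValueError, match="out of range"):
            simulate_forward(pop, RecombinationMap.uniform(500_000, 2.0), SelectionSpec(9999, 0.1), 1, seed=1)


class TestPoolSequence:
    def test_fixed_locus_yields_single_allele_reads(self):
        rng = np.random.default_rng(13)
        haps = np.ones((20, 5), dtype=np.uint8)
        pop = HaplotypePopulation(haps, np.arange(5) * 100)
        panel = pool_sequence(pop, uniform_coverage_sampler(40, 60), SampleMeta("p1"), rng)
        assert (panel.counts[:, 0, 0] == 0).all()  # no ancestral reads
        assert (panel.counts[:, 0, 1] > 0).all()

    def test_expected_read_frequency_matches_population(self):
        rng = np.random.default_rng(14)
        haps = (rng.random((200, 300)) < 0.3).astype(np.uint8)
        pop = HaplotypePopulation(haps, np.arange(300) * 10)
        panel = pool_sequence(pop, uniform_coverage_sampler(80, 120), SampleMeta("p1"), rng)
        freq = panel.counts[:, 0, 1] / panel.coverage()[:, 0]
        resid = freq - pop.frequencies()
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(resid.size)

    def test_seed_reproducible(self):
        haps = (np.random.default_rng(0).random((40, 50)) < 0.5).astype(np.uint8)
        pop = HaplotypePopulation(haps, np.arange(50) * 10)
        a = pool_sequence(pop, uniform_coverage_sampler(30, 50), SampleMeta("p1"), np.random.default_rng(42))
        b = pool_sequence(pop, uniform_coverage_sampler(30, 50), SampleMeta("p1"), np.random.default_rng(42))
        np.testing.assert_array_equal(a.counts, b.counts)
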