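"""Region masks, short-intron subsets, LD-decay profiles, matched backgrounds."""

import numpy as np
import pandas as pd
import pytest

from erpool.cmh import CMHResult
from erpool.forward import RecombinationMap
from erpool.regions import (
    GenomicMask,
    build_low_ld_mask,
    ld_decay_profile,
    matched_background,
    read_bed,
    subset_short_introns,
    write_bed,
)


def _scan_from(positions, pvalues, chrom="2L"):
    df = pd.DataFrame({"chrom": chrom, "pos": positions, "statistic": 1.0, "pvalue": pvalues})
    order = np.argsort(df["pvalue"].to_numpy())
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return CMHResult(table=df)


class TestMaskConstruction:
    def test_inversion_buffer_arithmetic(self):
        mask = build_low_ld_mask(inversions={"3R": [[10_000_000, 18_000_000]]}, buffer=500_000)
        np.testing.assert_array_equal(mask.intervals["3R"], [[9_500_000, 18_500_000]])

    def test_rate_threshold_is_strict(self):
        m = RecombinationMap(
            starts=[0, 1000, 2000], ends=[1000, 2000, 3000], rates_cm_mb=[1.9, 2.0, 2.1], chrom="2L"
        )
        mask = build_low_ld_mask(recomb_map=m, rate_threshold=2.0)
        np.testing.assert_array_equal(mask.intervals["2L"], [[0, 1000]])

    def test_union_is_order_independent_and_merged(self):
        a = build_low_ld_mask(
            inversions={"X": [[100, 300]]}, buffer=0, extra_blocks={"X": [[250, 500]]}
        )
        b = build_low_ld_mask(
            inversions={"X": [[250, 500]]}, buffer=0, extra_blocks={"X": [[100, 300]]}
        )
        np.testing.assert_array_equal(a.intervals["X"], b.intervals["X"])
        np.testing.assert_array_equal(a.intervals["X"], [[100, 500]])

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(1)
        iv = np.sort(rng.choice(10_000, size=(8, 2)), axis=1)
        iv = iv[iv[:, 0] < iv[:, 1]]
        mask = GenomicMask(intervals={"2L": iv})
        pos = rng.integers(1, 10_001, size=500)  # 1-based
        got = mask.contains(np.full(500, "2L"), pos)
        expected = np.array([any(s <= p - 1 < e for s, e in iv) for p in pos])
        np.testing.assert_array_equal(got, expected)

    def test_negative_buffer_rejected(self):
        with pytest.raises(ValueError):
            build_low_ld_mask(inversions={"X": [[0, 10]]}, buffer=-1)

    def test_bed_round_trip(self, tmp_path):
        mask = GenomicMask(intervals={"2L": [[5, 10], [20, 30]]}, label="inversion")
        path = tmp_path / "m.bed"
        write_bed(mask, path)
        back = read_bed(path, label="inversion")
        np.testing.assert_array_equal(back.intervals["2L"], mask.intervals["2L"])


class TestShortIntrons:
    def test_empty_introns_empty_result(self):
        snps = pd.DataFrame({"chrom": ["2L"], "pos": [100]})
        out = subset_short_introns(snps, GenomicMask(intervals={}))
        assert out.empty

    def test_intron_inside_inversion_excluded(self):
        snps = pd.DataFrame({"chrom": ["2L", "2L"], "pos": [150, 450]})
        introns = GenomicMask(intervals={"2L": [[100, 200], [400, 500]]})
        mask = GenomicMask(intervals={"2L": [[0, 300]]})
        out = subset_short_introns(snps, introns, mask)
        assert list(out.pos) == [450]

    def test_gene_exclusion_only_shrinks(self):
        rng = np.random.default_rng(2)
        snps = pd.DataFrame({"chrom": "2L", "pos": rng.integers(1, 5000, 300)})
        introns = GenomicMask(intervals={"2L": [[0, 5000]]})
        genes = GenomicMask(intervals={"2L": [[1000, 2000]]})
        base = subset_short_introns(snps, introns)
        excl = subset_short_introns(snps, introns, exclude_gene_intervals=genes)
        assert len(excl) <= len(base)
        assert set(map(tuple, excl.values)) <= set(map(tuple, base.values))


class TestLDDecay:
    def test_uniform_p_gives_flat_profile_near_median(self):
        rng = np.random.default_rng(3)
        n = 20_000
        scan = _scan_from(np.arange(1, n + 1) * 10, rng.uniform(size=n))
        cands = scan.table.sample(50, random_state=1)[["chrom", "pos"]]
        prof = ld_decay_profile(cands, scan, window=50, flank_limit=500, seed=4)
        med = prof.table.median_nlp.dropna()
        assert np.abs(med - (-np.log10(0.5))).max() < 0.12

    def test_bin_edges_follow_window(self):
        scan = _scan_from([100, 130, 210, 400], [0.5, 0.1, 0.2, 0.9])
        prof = ld_decay_profile(scan.table.iloc[[0]][["chrom", "pos"]], scan, window=50, flank_limit=200)
        assert list(prof.table.bin_start) == [0, 50, 100, 150]
        # SNP at distance 30 -> bin [0,50); at 110 -> bin [100,150)
        assert prof.table.n_pairs.iloc[0] == 1 and prof.table.n_pairs.iloc[2] == 1

    def test_mirrored_positions_give_same_profile(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(100_000, 2000, replace=False)) + 1
        pv = rng.uniform(size=2000)
        scan = _scan_from(pos, pv)
        cands = scan.table.nsmallest(30, "pvalue")[["chrom", "pos"]]
        prof = ld_decay_profile(cands, scan, flank_limit=1000, n_boot=2, seed=6)
        mirrored = _scan_from(100_002 - pos[::-1], pv[::-1])
        m_cands = mirrored.table.nsmallest(30, "pvalue")[["chrom", "pos"]]
        m_prof = ld_decay_profile(m_cands, mirrored, flank_limit=1000, n_boot=2, seed=6)
        np.testing.assert_allclose(
            prof.table.median_nlp.to_numpy(), m_prof.table.median_nlp.to_numpy(), equal_nan=True
        )

    def test_no_flanking_snps_warns_empty(self):
        scan = _scan_from([100, 50_000], [0.1, 0.2])
        prof = ld_decay_profile(scan.table.iloc[[0]][["chrom", "pos"]], scan, flank_limit=100)
        assert prof.table.empty or prof.table.n_pairs.sum() == 0


class TestMatchedBackground:
    def _snps(self, rng, n=3000):
        return pd.DataFrame(
            {
                "chrom": np.where(rng.random(n) < 0.3, "X", "2L"),
                "pos": rng.choice(2_000_000, size=n, replace=False),
            }
        )

    def test_per_arm_counts_match(self):
        rng = np.random.default_rng(7)
        snps = self._snps(rng)
        cands = snps.sample(100, random_state=2)
        bg = matched_background(cands, snps, exclusion=200, seed=8)
        assert bg.groupby("chrom").size().to_dict() == cands.groupby("chrom").size().to_dict()

    def test_exclusion_zone_respected(self):
        rng = np.random.default_rng(9)
        snps = self._snps(rng)
        cands = snps.sample(80, random_state=3)
        bg = matched_background(cands, snps, exclusion=200, seed=10)
        for chrom, sub in bg.groupby("chrom"):
            cpos = cands[cands.chrom == chrom].pos.to_numpy()
            for p in sub.pos:
                assert np.abs(cpos - p).min() > 200

    def test_seed_reproducible(self):
        rng = np.random.default_rng(11)
        snps = self._snps(rng)
        cands = snps.sample(50, random_state=4)
        a = matched_background(cands, snps, seed=12)
        b = matched_background(cands, snps, seed=12)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_pool_names_the_arm(self):
        snps = pd.DataFrame({"chrom": "4", "pos": np.arange(1, 42) * 10})
        cands = snps.iloc[:40]
        with pytest.raises(ValueError, match="arm 4"):
            matched_background(cands, snps, exclusion=200, seed=13)
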