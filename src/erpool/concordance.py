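"""Replicate-group concordance: base-read resampling and the modified ROC.

Two independent groups of evolved replicates (e.g. the original three and two
later-sequenced ones) are each scanned with the CMH test; concordance at rank
cutoff k is the proportion of SNPs common to both groups' top-k sets whose
rising allele is the same in every replicate of both groups.

Each curve carries a simple reference diagonal, (k/n) times the genome-wide
5/5-agreement base rate, for plotting.  That diagonal is not a calibrated
null: shared start frequencies and coverage structure couple the two groups'
ranks, and drift directions are not sign-symmetric at skewed frequencies, so
even neutral data sit measurably off any closed-form diagonal.  The
calibrated chance expectation is therefore Monte Carlo, exactly as the
expected degree of reproducibility under neutrality is quantified in E&R
practice: simulate matched neutral panel pairs, compute their concordance
curves, and take per-k quantiles (:func:`simulated_null_band`).

Pseudo-base replicates are manufactured by pooling all base samples' counts,
hypergeometrically downsampling to a fraction of the reads (count-level
stand-in for read-file sampling without replacement) and partitioning the
result uniformly into two halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmh import CMHResult
from .io import SampleMeta, SitePanel, weighted_frequencies

__all__ = [
    "ROCCurve",
    "resample_base",
    "replicate_direction_signs",
    "concordance_curve",
    "simulated_null_band",
    "harmonize_scans",
    "default_k_grid",
]


def resample_base(
    base_panel: SitePanel,
    fraction: float = 2.0 / 3.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SitePanel:
    """Split pooled base reads into two pseudo-replicates.

    Per site the counts of all base samples are summed, ``fraction`` of the
    total reads are drawn without replacement (multivariate hypergeometric
    over the six sync fields), and the draw is partitioned uniformly in half.
    Expected pseudo-replicate frequency equals the combined base frequency.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    base_idx = base_panel.samples_where(treatment="base")
    if not base_idx:
        raise ValueError("panel has no base samples")
    combined = base_panel.counts[:, base_idx, :].sum(axis=1)
    n_sites = combined.shape[0]
    out = np.zeros((n_sites, 2, 6), dtype=np.int64)
    for i in range(n_sites):
        row = combined[i]
        total = int(row.sum())
        take = int(round(fraction * total))
        sampled = rng.multivariate_hypergeometric(row, take) if take > 0 else np.zeros(6, dtype=np.int64)
        half = rng.multivariate_hypergeometric(sampled, take // 2) if take > 0 else sampled
        out[i, 0] = half
        out[i, 1] = sampled - half
    samples = [
        SampleMeta("pseudo_base1", "base", 1, 0),
        SampleMeta("pseudo_base2", "base", 2, 0),
    ]
    return SitePanel(
        chrom=base_panel.chrom.copy(),
        pos=base_panel.pos.copy(),
        ref=base_panel.ref.copy(),
        counts=out,
        samples=samples,
        provenance=list(base_panel.provenance) + [{"op": "resample_base", "fraction": fraction}],
    )


def replicate_direction_signs(
    panel: SitePanel,
    design: list[tuple[int, int]],
    allele_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site, per-replicate sign of the frequency change of a fixed allele.

    Returns an (n_sites, n_replicates) array in {-1, 0, +1}; the allele
    orientation defaults to each site's overall minor allele so that signs
    are comparable across replicate groups.
    """
    if allele_idx is None:
        _, allele_idx = panel.major_minor()
    signs = np.zeros((panel.n_sites, len(design)), dtype=np.int8)
    for j, (b, e) in enumerate(design):
        p0 = weighted_frequencies(panel, allele_idx, [b])
        p1 = weighted_frequencies(panel, allele_idx, [e])
        d = p1 - p0
        signs[:, j] = np.where(np.isnan(d), 0, np.sign(d)).astype(np.int8)
    return signs


@dataclass
class ROCCurve:
    """Modified ROC: concordant top-k overlap against rank cutoffs.

    ``proportion[i]`` is |top-k(A) & top-k(B) & consistent| / k at
    ``k = k_grid[i]``; ``diagonal`` is the plotting reference
    (k/n x genome-wide consistency base rate).  A calibrated null band comes
    from :func:`simulated_null_band` over matched neutral curves.
    """

    k_grid: np.ndarray
    proportion: np.ndarray
    diagonal: np.ndarray
    n_snps: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_grid, "proportion": self.proportion, "diagonal": self.diagonal}
        )


def simulated_null_band(
    null_curves: list["ROCCurve"], level: float = 0.95
) -> pd.DataFrame:
    """Per-k chance expectation and quantile band from neutral simulations.

    ``null_curves`` are concordance curves of independently simulated neutral
    panel pairs matched to the data (same k grid); returns a table with the
    per-k mean and the (1 - level)/2 and 1 - (1 - level)/2 quantiles of the
    null proportions.
    """
    if len(null_curves) < 2:
        raise ValueError("need at least two null curves")
    k0 = null_curves[0].k_grid
    for c in null_curves[1:]:
        if not np.array_equal(c.k_grid, k0):
            raise ValueError("null curves must share the k grid")
    mat = np.vstack([c.proportion for c in null_curves])
    alpha = (1.0 - level) / 2.0
    return pd.DataFrame(
        {
            "k": k0,
            "chance": mat.mean(axis=0),
            "band_low": np.quantile(mat, alpha, axis=0),
            "band_high": np.quantile(mat, 1.0 - alpha, axis=0),
        }
    )


def default_k_grid(n: int, n_points: int = 15, k_min: int = 1000) -> np.ndarray:
    """Logarithmic rank cutoffs from ~1,000 (or n/100 if smaller) up to n."""
    lo = min(k_min, max(10, n // 100))
    grid = np.unique(np.round(np.geomspace(lo, n, n_points)).astype(int))
    return grid[grid >= 1]


def harmonize_scans(
    panel: SitePanel,
    scan_a: CMHResult,
    scan_b: CMHResult,
    signs_a: np.ndarray,
    signs_b: np.ndarray,
) -> tuple[CMHResult, CMHResult, np.ndarray, np.ndarray]:
    """Restrict two scans to their common SNP universe and align the signs.

    Each scan may have excluded a few degenerate sites of its own; the
    intersection is taken, ranks are recomputed within it, and the
    (n_sites, n_reps) sign matrices (rows aligned with ``panel``) are subset
    to match.  Row order of the outputs is the panel's (chrom, pos) order.
    """
    pan = pd.DataFrame(
        {"chrom": panel.chrom.astype(str), "pos": panel.pos, "_row": np.arange(panel.n_sites)}
    )
    common = scan_a.table[["chrom", "pos"]].astype({"chrom": str}).merge(
        scan_b.table[["chrom", "pos"]].astype({"chrom": str}), on=["chrom", "pos"]
    )

    def _restrict(scan: CMHResult) -> tuple[CMHResult, np.ndarray]:
        df = (
            scan.table.astype({"chrom": str})
            .merge(common, on=["chrom", "pos"])
            .merge(pan, on=["chrom", "pos"])
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        order = np.lexsort((df["pos"], df["chrom"], df["pvalue"]))
        ranks = np.empty(len(df), dtype=np.int64)
        ranks[order] = np.arange(1, len(df) + 1)
        df["rank"] = ranks
        rows = df.pop("_row").to_numpy()
        return CMHResult(table=df, continuity=scan.continuity, n_excluded=scan.n_excluded), rows

    ra, rows_a = _restrict(scan_a)
    rb, rows_b = _restrict(scan_b)
    return ra, rb, signs_a[rows_a], signs_b[rows_b]


def concordance_curve(
    scan_a: CMHResult,
    scan_b: CMHResult,
    signs_a: np.ndarray,
    signs_b: np.ndarray,
    k_grid: np.ndarray | None = None,
) -> ROCCurve:
    """Concordance between two replicate groups over rank cutoffs.

    ``scan_a``/``scan_b`` must cover the same SNP universe (same chrom/pos in
    the same order after each scan's exclusions); ``signs_a``/``signs_b`` are
    the per-replicate rising-direction signs from
    :func:`replicate_direction_signs` aligned to each scan's rows.
    """
    ta, tb = scan_a.table, scan_b.table
    if len(ta) != len(tb) or not (
        np.array_equal(ta["pos"].to_numpy(), tb["pos"].to_numpy())
        and np.array_equal(ta["chrom"].astype(str).to_numpy(), tb["chrom"].astype(str).to_numpy())
    ):
        raise ValueError("scans do not cover the same SNP universe")
    n = len(ta)
    if signs_a.shape[0] != n or signs_b.shape[0] != n:
        raise ValueError("direction signs are not aligned with the scans")
    if k_grid is None:
        k_grid = default_k_grid(n)
    k_grid = np.asarray(k_grid, dtype=int)
    if np.any(np.diff(k_grid) < 0):
        raise ValueError("k_grid must be non-decreasing")

    rank_a = ta["rank"].to_numpy()
    rank_b = tb["rank"].to_numpy()
    ok_a = (signs_a != 0).all(axis=1) & (np.abs(signs_a.sum(axis=1)) == signs_a.shape[1])
    ok_b = (signs_b != 0).all(axis=1) & (np.abs(signs_b.sum(axis=1)) == signs_b.shape[1])
    same_dir = np.sign(signs_a.sum(axis=1)) == np.sign(signs_b.sum(axis=1))
    concordant = ok_a & ok_b & same_dir
    base_rate = concordant.mean()

    props = np.empty(k_grid.size)
    for i, k in enumerate(k_grid):
        shared = (rank_a <= k) & (rank_b <= k) & concordant
        props[i] = shared.sum() / k
    diagonal = (k_grid / n) * base_rate
    return ROCCurve(k_grid=k_grid, proportion=props, diagonal=diagonal, n_snps=n)
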