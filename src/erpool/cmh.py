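"""Replicate-stratified Cochran-Mantel-Haenszel test for allele-count change.

Each SNP contributes one 2x2 table per replicate: rows are the base and
evolved time points, columns the counts of the two segregating alleles.  The
CMH statistic aggregates the per-stratum hypergeometric deviations

    X^2 = (|sum_k (a_k - E[a_k])| - c)^2 / sum_k Var(a_k)

with E and Var the conditional-hypergeometric moments of the top-left cell and
``c`` an optional continuity correction (0.5 when enabled, off by default).
P values come from the chi-square(1) upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SitePanel

__all__ = [
    "CMHResult",
    "DegenerateTableError",
    "cmh_statistic",
    "cmh_scan",
    "paired_design",
]


class DegenerateTableError(ValueError):
    """All strata of a table are degenerate (zero margins); test undefined."""


@dataclass
class CMHResult:
    """Ranked genome-wide CMH scan results.

    ``table`` has columns chrom, pos, statistic, pvalue, rank; ranks are a
    permutation ordered by (pvalue, chrom, pos) ascending.  Sites whose test
    was undefined (all strata degenerate) are excluded and counted in
    ``n_excluded``.
    """

    table: pd.DataFrame
    continuity: bool = False
    n_excluded: int = 0
    log: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def top_k(self, k: int) -> pd.DataFrame:
        return self.table[self.table["rank"] <= k]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _cmh_core(a, n1, n2, m1, continuity: bool):
    """Vectorised CMH over stacked strata.

    Parameters are arrays of shape (..., k): top-left cell ``a``, row totals
    ``n1`` (base), ``n2`` (evolved), and first-column total ``m1``.  Strata
    with a zero row or column margin are dropped.  Returns (stat, pvalue,
    valid) where ``valid`` is False when every stratum was degenerate.
    """
    a = np.asarray(a, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    T = n1 + n2
    m2 = T - m1
    ok = (n1 > 0) & (n2 > 0) & (m1 > 0) & (m2 > 0) & (T > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(ok, n1 * m1 / np.maximum(T, 1), 0.0)
        v = np.where(ok, n1 * n2 * m1 * m2 / (np.maximum(T, 1) ** 2 * np.maximum(T - 1, 1)), 0.0)
    num = np.abs((np.where(ok, a, 0.0) - e).sum(axis=-1))
    if continuity:
        num = np.maximum(num - 0.5, 0.0)
    den = v.sum(axis=-1)
    valid = den > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(valid, num**2 / np.maximum(den, np.finfo(float).tiny), np.nan)
    pval = np.where(valid, stats.chi2.sf(stat, df=1), np.nan)
    # identical rows give statistic 0 -> P exactly 1
    return stat, pval, valid


def cmh_statistic(strata, continuity: bool = False) -> tuple[float, float]:
    """CMH chi-square (1 df) and P value for one stratified 2x2 table.

    ``strata`` is array-like of shape (k, 2, 2): rows (base, evolved),
    columns (allele a, allele b).  Strata with a zero row or column total are
    dropped; if all strata are degenerate a :class:`DegenerateTableError` is
    raised.
    """
    arr = np.asarray(strata, dtype=float)
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise ValueError("strata must have shape (k, 2, 2)")
    if arr.shape[0] < 1:
        raise ValueError("need at least one stratum")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    a = arr[:, 0, 0][None, :]
    n1 = arr[:, 0, :].sum(axis=1)[None, :]
    n2 = arr[:, 1, :].sum(axis=1)[None, :]
    m1 = arr[:, :, 0].sum(axis=1)[None, :]
    stat, pval, valid = _cmh_core(a, n1, n2, m1, continuity)
    if not valid[0]:
        raise DegenerateTableError("all strata have a zero margin; CMH undefined")
    return float(stat[0]), float(pval[0])


def paired_design(panel: SitePanel, treatment: str, base_treatment: str = "base") -> list[tuple[int, int]]:
    """Pair base replicate i with evolved replicate i (sample index pairs).

    Raises if the replicate counts differ or replicate numbers do not match.
    """
    base = sorted(panel.samples_where(treatment=base_treatment), key=lambda i: panel.samples[i].replicate)
    evo = sorted(panel.samples_where(treatment=treatment), key=lambda i: panel.samples[i].replicate)
    if len(base) != len(evo) or not base:
        raise ValueError(
            f"unpaired design: {len(base)} {base_treatment!r} vs {len(evo)} {treatment!r} samples"
        )
    return list(zip(base, evo))


def cmh_scan(
    panel: SitePanel,
    design: list[tuple[int, int]],
    continuity: bool = False,
) -> CMHResult:
    """Genome-wide CMH scan over a panel's biallelic sites.

    ``design`` pairs base and evolved sample indices, one pair per replicate
    stratum.  Each site's two alleles are its overall major and minor; strata
    where either time point has zero coverage at the site are dropped (and
    counted in the log), and sites with no usable stratum are excluded.
    """
    if not design:
        raise ValueError("design must list at least one (base, evolved) sample pair")
    major, minor = panel.major_minor()
    base_idx = np.array([b for b, _ in design])
    evo_idx = np.array([e for _, e in design])

    maj_b = np.take_along_axis(panel.counts[:, base_idx, :4], major[:, None, None], axis=2)[:, :, 0]
    min_b = np.take_along_axis(panel.counts[:, base_idx, :4], minor[:, None, None], axis=2)[:, :, 0]
    maj_e = np.take_along_axis(panel.counts[:, evo_idx, :4], major[:, None, None], axis=2)[:, :, 0]
    min_e = np.take_along_axis(panel.counts[:, evo_idx, :4], minor[:, None, None], axis=2)[:, :, 0]

    a = maj_b
    n1 = maj_b + min_b
    n2 = maj_e + min_e
    m1 = maj_b + maj_e
    stat, pval, valid = _cmh_core(a, n1, n2, m1, continuity)
    n_excluded = int((~valid).sum())

    df = pd.DataFrame(
        {
            "chrom": panel.chrom[valid],
            "pos": panel.pos[valid],
            "statistic": stat[valid],
            "pvalue": pval[valid],
        }
    )
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].astype(str).to_numpy(), df["pvalue"].to_numpy()))
    ranks = np.empty(len(df), dtype=np.int64)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    log = []
    if n_excluded:
        log.append({"op": "cmh_scan", "excluded_degenerate_sites": n_excluded})
    return CMHResult(table=df, continuity=continuity, n_excluded=n_excluded, log=log)
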