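"""Permutation gene-set enrichment of candidate SNPs (gene-level counting).

A gene is "hit" when at least one candidate SNP falls inside its coding
interval(s); multiple candidates in one gene count once.  Significance comes
from permutations that redraw the same number of candidate positions
uniformly without replacement from the SNP universe, recomputing the number
of gene-set genes hit.  P values use greater-or-equal counting with the
add-one correction, P = (#{null >= observed} + 1) / (n_perm + 1), which keeps
P in (0, 1]; strict-greater counting without the correction is available
behind a flag.  No multiple-testing adjustment is applied across gene sets.

Only coding-region intervals are considered, never flanking sequence, and the
analysis is run over nested candidate sets of increasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmh import CMHResult

__all__ = [
    "EnrichmentResult",
    "snp_gene_index",
    "genes_hit",
    "permutation_enrichment",
    "enrichment_series",
    "DEFAULT_K_GRID",
]

# nested candidate-set sizes used for the enrichment series
DEFAULT_K_GRID = tuple(list(range(2_000, 20_001, 2_000)) + list(range(25_000, 50_001, 5_000)) + list(range(60_000, 100_001, 10_000)))


def _gene_arrays(models: pd.DataFrame):
    """Per-chromosome sorted interval arrays (start, end, gene index)."""
    gene_ids = models["gene_id"].astype(str).to_numpy()
    uniq, gidx = np.unique(gene_ids, return_inverse=True)
    by_chrom = {}
    for chrom, sub in models.groupby(models["chrom"].astype(str)):
        order = np.argsort(sub["start"].to_numpy())
        by_chrom[chrom] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
            gidx[sub.index.to_numpy()][order],
        )
    return uniq, by_chrom


def snp_gene_index(snps: pd.DataFrame, models: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Map each SNP to the gene containing it.

    Returns (gene_names, assignment) where ``assignment[i]`` indexes into
    ``gene_names`` or is -1 for intergenic SNPs.  Gene intervals are 0-based
    half-open, SNP positions 1-based; when gene intervals overlap, a SNP is
    assigned to the first containing interval in start order (overlap is
    atypical for coding-region models and is reported by the caller's tests).
    """
    uniq, by_chrom = _gene_arrays(models.reset_index(drop=True))
    chrom = snps["chrom"].astype(str).to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    assign = np.full(len(snps), -1, dtype=np.int64)
    for c, (starts, ends, gidx) in by_chrom.items():
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        i = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = (i >= 0) & (pos0[sel] < ends[np.maximum(i, 0)])
        assign[sel[ok]] = gidx[i[ok]]
    return uniq, assign


def genes_hit(snps: pd.DataFrame, models: pd.DataFrame) -> set[str]:
    """Genes whose coding interval contains at least one SNP (counted once)."""
    uniq, by_chrom = _gene_arrays(models.reset_index(drop=True))
    chrom = snps["chrom"].astype(str).to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    hit = np.zeros(uniq.size, dtype=bool)
    for c, (starts, ends, gidx) in by_chrom.items():
        p = np.sort(pos0[chrom == c])
        if p.size == 0:
            continue
        lo = np.searchsorted(p, starts, side="left")
        hi = np.searchsorted(p, ends - 1, side="right")
        hit[gidx[hi > lo]] = True
    return set(uniq[hit])


@dataclass
class EnrichmentResult:
    """Gene-level permutation enrichment for one candidate set size."""

    gene_set: str
    k: int
    observed: int
    pvalue: float
    n_perm: int
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "gene_set": self.gene_set,
            "k": self.k,
            "observed": self.observed,
            "pvalue": self.pvalue,
            "n_perm": self.n_perm,
        }


def _null_hit_counts(
    set_counts: np.ndarray, n_universe: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of the number of set genes hit by k random SNPs.

    Exact sampling: partition the universe into one block per set gene (its
    universe SNP count) plus a remainder block, draw the k candidates as a
    multivariate hypergeometric split, and count non-empty gene blocks.  Valid
    because each universe SNP belongs to at most one gene.
    """
    rest = n_universe - int(set_counts.sum())
    colors = np.concatenate([set_counts, [rest]]).astype(np.int64)
    out = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        draw = rng.multivariate_hypergeometric(colors, k)
        out[i] = int(np.count_nonzero(draw[:-1]))
    return out


def permutation_enrichment(
    candidates: pd.DataFrame,
    universe: pd.DataFrame,
    models: pd.DataFrame,
    gene_set: set[str] | list[str],
    n_perm: int = 100_000,
    seed: int | None = None,
    label: str = "",
    strict: bool = False,
    _index: tuple[np.ndarray, np.ndarray] | None = None,
) -> EnrichmentResult:
    """Permutation P value for candidate enrichment in one gene set.

    ``candidates`` must be a subset of ``universe`` (both need chrom, pos).
    When the gene set shares no genes with any SNP-bearing gene the result is
    degenerate with P = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = len(candidates)
    if k > len(universe):
        raise ValueError("candidate count exceeds the SNP universe")
    gene_set = set(map(str, gene_set))
    observed = len(genes_hit(candidates, models) & gene_set)

    names, assign = _index if _index is not None else snp_gene_index(universe, models)
    in_set = np.isin(names, list(gene_set))
    set_gene_idx = np.flatnonzero(in_set)
    set_counts = np.bincount(assign[assign >= 0], minlength=names.size)[set_gene_idx]
    if set_counts.sum() == 0:
        return EnrichmentResult(gene_set=label, k=k, observed=observed, pvalue=1.0, n_perm=n_perm, seed=seed)

    rng = np.random.default_rng(seed)
    null = _null_hit_counts(set_counts, len(universe), k, n_perm, rng)
    if strict:
        p = float(np.mean(null > observed))
        p = max(p, 1.0 / n_perm)  # keep P > 0 even under strict counting
    else:
        p = (float(np.sum(null >= observed)) + 1.0) / (n_perm + 1.0)
    return EnrichmentResult(gene_set=label, k=k, observed=observed, pvalue=p, n_perm=n_perm, seed=seed)


def enrichment_series(
    scan: CMHResult,
    k_grid,
    models: pd.DataFrame,
    gene_sets: dict[str, set[str] | list[str]],
    n_perm: int = 100_000,
    seed: int | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Enrichment over nested candidate sets (top-k for ascending k).

    Each successive candidate set aggregates the previous one plus the next
    most significant SNPs.  Returns one row per (gene set, k).
    """
    k_grid = sorted(int(k) for k in k_grid)
    if k_grid and k_grid[-1] > scan.n_snps:
        raise ValueError(f"k={k_grid[-1]} exceeds the scanned SNP count {scan.n_snps}")
    universe = scan.table[["chrom", "pos"]]
    index = snp_gene_index(universe, models)
    rng = np.random.default_rng(seed)
    rows = []
    for label, gset in gene_sets.items():
        for k in k_grid:
            res = permutation_enrichment(
                scan.top_k(k)[["chrom", "pos"]],
                universe,
                models,
                gset,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                label=label,
                strict=strict,
                _index=index,
            )
            rows.append(res.as_dict())
    return pd.DataFrame(rows)
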