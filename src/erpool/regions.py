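"""High-LD region masks, short-intron neutral proxies, and LD-decay profiles.

Putative high-LD regions are the union of segregating inversions expanded by
a buffer (500 kb by default) on each side, recombination-map intervals with a
local rate strictly below a threshold (2 cM/Mb by default), and any extra
blocks such as a known selected haplotype block; their complement is the
putative low-LD genome.  Because Pool-Seq data cannot support haplotype-phase
r2, the LD proxy around candidate SNPs is the decay of flanking -log10 P
values in non-overlapping 50-bp distance bins, compared against a background
draw matched per chromosome arm.

All intervals are 0-based half-open (BED convention); SNP positions are
1-based as in sync files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cmh import CMHResult
from .forward import RecombinationMap

__all__ = [
    "GenomicMask",
    "LDProfile",
    "build_low_ld_mask",
    "subset_short_introns",
    "ld_decay_profile",
    "matched_background",
    "read_bed",
    "write_bed",
]


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) rows (sorted output)."""
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class GenomicMask:
    """Named, merged interval set per chromosome (0-based half-open)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = "mask"

    def __post_init__(self) -> None:
        self.intervals = {
            c: _merge_intervals(np.asarray(iv, dtype=np.int64).reshape(-1, 2))
            for c, iv in self.intervals.items()
        }

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions in the mask (vectorised)."""
        chrom = np.asarray(chrom).astype(str)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(pos0.shape[0], dtype=bool)
        for c, iv in self.intervals.items():
            sel = chrom == c
            if not sel.any() or iv.size == 0:
                continue
            idx = np.searchsorted(iv[:, 0], pos0[sel], side="right") - 1
            ok = idx >= 0
            inside = np.zeros(int(sel.sum()), dtype=bool)
            inside[ok] = pos0[sel][ok] < iv[idx[ok], 1]
            out[sel] = inside
        return out

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))


def read_bed(path: str | Path, label: str = "mask") -> GenomicMask:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2], names=["chrom", "start", "end"])
    iv: dict[str, list] = {}
    for r in df.itertuples():
        iv.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
    return GenomicMask(intervals={c: np.asarray(v) for c, v in iv.items()}, label=label)


def write_bed(mask: GenomicMask, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for c in sorted(mask.intervals):
            for s, e in mask.intervals[c]:
                fh.write(f"{c}\t{s}\t{e}\t{mask.label}\n")


def build_low_ld_mask(
    inversions: dict[str, np.ndarray] | GenomicMask | None = None,
    buffer: int = 500_000,
    recomb_map: RecombinationMap | None = None,
    rate_threshold: float = 2.0,
    extra_blocks: dict[str, np.ndarray] | GenomicMask | None = None,
) -> GenomicMask:
    """Union mask of putative high-LD regions; its complement is low-LD.

    Inversion intervals are expanded by ``buffer`` bp at each end (the "within
    500 kb either side of the breakpoints" rule for contiguous inversions);
    recombination-map intervals with rate strictly below ``rate_threshold``
    cM/Mb are masked (a rate exactly at the threshold is not); extra blocks
    are included verbatim.  Union is order-independent.
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    iv: dict[str, list] = {}

    def _add(chrom: str, start: int, end: int) -> None:
        iv.setdefault(chrom, []).append((max(0, int(start)), int(end)))

    def _items(x):
        if x is None:
            return []
        if isinstance(x, GenomicMask):
            return x.intervals.items()
        return x.items()

    for chrom, rows in _items(inversions):
        for s, e in np.asarray(rows, dtype=np.int64).reshape(-1, 2):
            _add(chrom, s - buffer, e + buffer)
    if recomb_map is not None:
        low = recomb_map.rates_cm_mb < rate_threshold
        for s, e in zip(recomb_map.starts[low], recomb_map.ends[low]):
            _add(recomb_map.chrom, s, e)
    for chrom, rows in _items(extra_blocks):
        for s, e in np.asarray(rows, dtype=np.int64).reshape(-1, 2):
            _add(chrom, s, e)
    return GenomicMask(intervals={c: np.asarray(v) for c, v in iv.items()}, label="high_ld")


def subset_short_introns(
    snps: pd.DataFrame,
    introns: GenomicMask,
    mask: GenomicMask | None = None,
    exclude_gene_intervals: GenomicMask | None = None,
) -> pd.DataFrame:
    """Neutral-proxy SNPs: inside short introns, outside the high-LD mask.

    ``exclude_gene_intervals`` optionally removes intronic SNPs lying in genes
    that contain top candidates (the stricter control); exclusion can only
    shrink the set.  ``snps`` needs columns chrom and pos (1-based).
    """
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    keep = introns.contains(chrom, pos)
    if mask is not None:
        keep &= ~mask.contains(chrom, pos)
    if exclude_gene_intervals is not None:
        keep &= ~exclude_gene_intervals.contains(chrom, pos)
    return snps[keep].reset_index(drop=True)


@dataclass
class LDProfile:
    """P-value decay around focal SNPs in 50-bp distance bins (both flanks
    folded by distance)."""

    table: pd.DataFrame  # bin_start, bin_end, median_nlp, ci_low, ci_high, n_pairs
    cohort: str = ""
    window: int = 50

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ld_decay_profile(
    candidates: pd.DataFrame,
    scan: CMHResult,
    window: int = 50,
    flank_limit: int = 1000,
    cohort: str = "",
    n_boot: int = 200,
    seed: int | None = None,
) -> LDProfile:
    """Median -log10 P of SNPs flanking focal candidates, binned by distance.

    Each flanking SNP within ``flank_limit`` bp of a focal candidate is
    assigned to the distance bin [window*(b-1), window*b); both flanks fold
    onto the same bins, and a SNP near two candidates contributes to both.
    The confidence band is a bootstrap over focal candidates (95%).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(candidates) < 1:
        raise ValueError("need at least one focal candidate")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(flank_limit / window))
    tab = scan.table.reset_index(drop=True)
    nlp_all = -np.log10(tab["pvalue"].to_numpy())
    per_cand: list[tuple[np.ndarray, np.ndarray]] = []  # (bin index, nlp) pairs per focal
    for chrom, sub in tab.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        pos_s = pos[order]
        nlp_s = nlp_all[sub.index.to_numpy()][order]
        cands = candidates[candidates["chrom"].astype(str) == str(chrom)]
        for cp in cands["pos"].to_numpy():
            lo = np.searchsorted(pos_s, cp - flank_limit, side="left")
            hi = np.searchsorted(pos_s, cp + flank_limit, side="right")
            d = np.abs(pos_s[lo:hi] - cp)
            sel = (d > 0) & (d < flank_limit)  # exclude the focal SNP itself
            if sel.any():
                per_cand.append(((d[sel] // window).astype(int), nlp_s[lo:hi][sel]))
    if not per_cand:
        empty = pd.DataFrame(
            columns=["bin_start", "bin_end", "median_nlp", "ci_low", "ci_high", "n_pairs"]
        )
        return LDProfile(table=empty, cohort=cohort, window=window)

    def _medians(idx: np.ndarray) -> np.ndarray:
        bins = np.concatenate([per_cand[i][0] for i in idx])
        vals = np.concatenate([per_cand[i][1] for i in idx])
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            v = vals[bins == b]
            if v.size:
                out[b] = np.median(v)
        return out

    all_idx = np.arange(len(per_cand))
    med = _medians(all_idx)
    counts = np.bincount(np.concatenate([pc[0] for pc in per_cand]), minlength=n_bins)
    boots = np.full((n_boot, n_bins), np.nan)
    for b in range(n_boot):
        boots[b] = _medians(rng.choice(all_idx, size=all_idx.size, replace=True))
    with np.errstate(all="ignore"):
        ci_low = np.nanpercentile(boots, 2.5, axis=0)
        ci_high = np.nanpercentile(boots, 97.5, axis=0)
    table = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * window,
            "bin_end": (np.arange(n_bins) + 1) * window,
            "median_nlp": med,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "n_pairs": counts,
        }
    )
    return LDProfile(table=table, cohort=cohort, window=window)


def matched_background(
    candidates: pd.DataFrame,
    all_snps: pd.DataFrame,
    exclusion: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random background SNPs matching the candidates' per-arm distribution.

    Draws, for each chromosome arm, as many SNPs as the candidates have on
    that arm, from SNPs farther than ``exclusion`` bp from every candidate.
    Raises (naming the arm) when too few eligible SNPs remain.
    """
    rng = np.random.default_rng(seed)
    picks = []
    for chrom, cands in candidates.groupby(candidates["chrom"].astype(str)):
        need = len(cands)
        pool = all_snps[all_snps["chrom"].astype(str) == chrom]
        cpos = np.sort(cands["pos"].to_numpy())
        ppos = pool["pos"].to_numpy()
        idx = np.searchsorted(cpos, ppos)
        left = np.where(idx > 0, np.abs(ppos - cpos[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
        right = np.where(idx < cpos.size, np.abs(cpos[np.minimum(idx, cpos.size - 1)] - ppos), np.iinfo(np.int64).max)
        eligible = pool[np.minimum(left, right) > exclusion]
        if len(eligible) < need:
            raise ValueError(
                f"arm {chrom}: only {len(eligible)} eligible background SNPs for {need} candidates"
            )
        take = rng.choice(len(eligible), size=need, replace=False)
        picks.append(eligible.iloc[np.sort(take)])
    return pd.concat(picks, ignore_index=True) if picks else all_snps.iloc[:0].copy()
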