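"""Pool-Seq sync-format I/O, SNP filtering, and allele-frequency utilities.

The central observable is the :class:`SitePanel`: a per-site, per-sample table
of nucleotide counts in the PoPoolation2 "sync" dialect (tab-delimited rows of
``chrom  pos  ref  A:T:C:G:N:del`` columns, 1-based positions).  ``N`` and
deletion counts never enter allele-frequency denominators; coverage is the sum
of the four nucleotide counts.

Interval-type inputs elsewhere in the package are 0-based half-open (BED
convention); :func:`pos_to_interval` / :func:`interval_to_pos` convert.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "T", "C", "G")
SYNC_FIELDS = ("A", "T", "C", "G", "N", "del")

__all__ = [
    "SampleMeta",
    "SitePanel",
    "SyncParseError",
    "UndefinedFrequencyError",
    "read_sync",
    "write_sync",
    "read_sample_meta",
    "write_sample_meta",
    "merge_samples",
    "filter_snps",
    "weighted_frequency",
    "polarize_rising",
    "pos_to_interval",
    "interval_to_pos",
]


class SyncParseError(ValueError):
    """Raised for malformed sync input; the message names the offending line."""


class UndefinedFrequencyError(ValueError):
    """Raised when an allele frequency is requested over zero total coverage."""


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def interval_to_pos(start: int) -> int:
    """0-based half-open interval start -> 1-based position of its first base."""
    return start + 1


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one Pool-Seq sample (one sequenced pool)."""

    sample_id: str
    treatment: str = "base"  # {"base", "hot", "cold"} in the study design
    replicate: int = 1
    generation: int = 0

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.treatment == "base" and self.generation != 0:
            raise ValueError("base samples must have generation 0")


@dataclass
class SitePanel:
    """Per-site, per-sample nucleotide counts with sample metadata.

    Attributes
    ----------
    chrom, pos, ref
        Per-site arrays; ``pos`` is 1-based.  Sites are kept sorted by
        (chrom, pos).
    counts
        ``(n_sites, n_samples, 6)`` non-negative integers in sync field order
        (A, T, C, G, N, del).
    samples
        One :class:`SampleMeta` per count column.
    provenance
        Log of applied filters / transforms, newest last.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    samples: list[SampleMeta]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_samples, 6)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.samples) != self.counts.shape[1]:
            raise ValueError("sample metadata does not match count columns")
        keys = {(m.treatment, m.replicate, m.generation) for m in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("(treatment, replicate, generation) must be unique")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.counts = self.counts[order]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_index(self, sample_id: str) -> int:
        for i, m in enumerate(self.samples):
            if m.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def samples_where(self, treatment: str | None = None, generation: int | None = None) -> list[int]:
        out = []
        for i, m in enumerate(self.samples):
            if treatment is not None and m.treatment != treatment:
                continue
            if generation is not None and m.generation != generation:
                continue
            out.append(i)
        return out

    def coverage(self) -> np.ndarray:
        """(n_sites, n_samples) coverage = A+T+C+G (N/del excluded)."""
        return self.counts[:, :, :4].sum(axis=2)

    def nucleotide_totals(self) -> np.ndarray:
        """(n_sites, 4) counts per nucleotide summed over samples."""
        return self.counts[:, :, :4].sum(axis=1)

    def major_minor(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices into NUCLEOTIDES of the two highest-count alleles per site.

        Ties broken by sync field order (A < T < C < G), so the result is
        deterministic.  At monomorphic sites the minor index points at a
        zero-count allele.
        """
        totals = self.nucleotide_totals()
        # stable argsort on negated counts -> ties resolved by column order
        order = np.argsort(-totals, axis=1, kind="stable")
        return order[:, 0], order[:, 1]

    def subset_sites(self, keep: np.ndarray, note: dict | None = None) -> "SitePanel":
        prov = list(self.provenance)
        if note is not None:
            prov.append(note)
        return SitePanel(
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            counts=self.counts[keep],
            samples=list(self.samples),
            provenance=prov,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cov = self.coverage()
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "ref": self.ref})
        for j, m in enumerate(self.samples):
            df[f"cov_{m.sample_id}"] = cov[:, j]
        return df


def _parse_count_field(text: str, line_no: int) -> list[int]:
    parts = text.split(":")
    if len(parts) != 6:
        raise SyncParseError(f"line {line_no}: expected 6 ':'-separated counts, got {text!r}")
    try:
        vals = [int(p) for p in parts]
    except ValueError as exc:
        raise SyncParseError(f"line {line_no}: non-integer count in {text!r}") from exc
    if any(v < 0 for v in vals):
        raise SyncParseError(f"line {line_no}: negative count in {text!r}")
    return vals


def read_sync(path: str | Path, samples: Sequence[SampleMeta] | None = None) -> SitePanel:
    """Parse a sync file into a :class:`SitePanel`.

    Parameters
    ----------
    path
        Tab-delimited sync file: chrom, pos, ref, then one ``A:T:C:G:N:del``
        column per sample.
    samples
        Optional metadata; defaults to generic base samples ``s1..sk`` with
        replicate numbers 1..k.
    """
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    rows: list[list[list[int]]] = []
    n_cols: int | None = None
    with open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(f"line {line_no}: expected >=4 tab-delimited columns")
            if n_cols is None:
                n_cols = len(fields)
            elif len(fields) != n_cols:
                raise SyncParseError(
                    f"line {line_no}: inconsistent column count ({len(fields)} vs {n_cols})"
                )
            chroms.append(fields[0])
            try:
                poss.append(int(fields[1]))
            except ValueError as exc:
                raise SyncParseError(f"line {line_no}: non-integer position {fields[1]!r}") from exc
            refs.append(fields[2])
            rows.append([_parse_count_field(f, line_no) for f in fields[3:]])
    n_samples = (n_cols - 3) if n_cols is not None else (len(samples) if samples else 0)
    if samples is None:
        samples = [SampleMeta(sample_id=f"s{i + 1}", replicate=i + 1) for i in range(n_samples)]
    else:
        samples = list(samples)
        if rows and len(samples) != n_samples:
            raise SyncParseError(
                f"metadata lists {len(samples)} samples but file has {n_samples} count columns"
            )
    counts = np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, len(samples), 6), dtype=np.int64)
    return SitePanel(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        counts=counts,
        samples=samples,
    )


def write_sync(panel: SitePanel, path: str | Path) -> None:
    """Write a panel in canonical sync text (sites sorted by chrom, pos)."""
    with open(path, "wt") as fh:
        _write_sync_stream(panel, fh)


def _write_sync_stream(panel: SitePanel, fh) -> None:
    for i in range(panel.n_sites):
        cols = [str(panel.chrom[i]), str(panel.pos[i]), str(panel.ref[i])]
        cols += [":".join(str(c) for c in panel.counts[i, j]) for j in range(panel.n_samples)]
        fh.write("\t".join(cols) + "\n")


def sync_text(panel: SitePanel) -> str:
    buf = _io.StringIO()
    _write_sync_stream(panel, buf)
    return buf.getvalue()


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the TSV sidecar (sample_id, treatment, replicate, generation)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(str(r.sample_id), str(r.treatment), int(r.replicate), int(r.generation))
        for r in df.itertuples()
    ]


def write_sample_meta(samples: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "treatment": m.treatment,
                "replicate": m.replicate,
                "generation": m.generation,
            }
            for m in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def merge_samples(panels: Sequence[SitePanel]) -> SitePanel:
    """Column-bind panels that share an identical site list."""
    first = panels[0]
    for p in panels[1:]:
        if not (
            np.array_equal(p.pos, first.pos)
            and np.array_equal(p.chrom.astype(str), first.chrom.astype(str))
        ):
            raise ValueError("panels do not share the same site list")
    counts = np.concatenate([p.counts for p in panels], axis=1)
    samples = [m for p in panels for m in p.samples]
    return SitePanel(first.chrom, first.pos, first.ref, counts, samples)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _filter_key(min_total_count: int, coverage_quantile: float, max_third_frac: float) -> tuple:
    return ("filter_snps", int(min_total_count), float(coverage_quantile), float(max_third_frac))


def filter_snps(
    panel: SitePanel,
    min_total_count: int = 30,
    coverage_quantile: float = 0.02,
    max_third_allele_frac: float = 0.10,
) -> SitePanel:
    """Call SNPs: drop high-coverage, low-count, and non-biallelic sites.

    Rules applied (each judged against the panel as given):

    * coverage rule — drop a site if its coverage in any sample exceeds that
      sample's upper ``coverage_quantile`` empirical coverage quantile (the
      "top 2%" rule with the default 0.02), computed per sample, i.e. per
      replicate and time point;
    * minor-count rule — drop a site whose minor-allele count summed over all
      samples is below ``min_total_count`` (default 30);
    * biallelic reduction — at sites with more than two observed alleles,
      keep the two highest-count alleles; drop the site entirely if the third
      allele exceeds ``max_third_allele_frac`` of total coverage.

    The per-sample coverage thresholds are stored in the provenance record; if
    an identical filter was already applied, the recorded thresholds are
    reused, which makes the operation idempotent.
    """
    if min_total_count < 0:
        raise ValueError("min_total_count must be >= 0")
    if not (0 < coverage_quantile <= 1):
        raise ValueError("coverage_quantile must be in (0, 1]")

    key = _filter_key(min_total_count, coverage_quantile, max_third_allele_frac)
    thresholds = None
    for rec in panel.provenance:
        if rec.get("key") == key:
            thresholds = np.asarray(rec["coverage_thresholds"], dtype=float)
            break

    cov = panel.coverage()
    if thresholds is None:
        if panel.n_sites == 0:
            thresholds = np.full(panel.n_samples, np.inf)
        else:
            thresholds = np.quantile(cov, 1.0 - coverage_quantile, axis=0)
    keep_cov = ~(cov > thresholds[None, :]).any(axis=1)

    totals = panel.nucleotide_totals()
    order = np.argsort(-totals, axis=1, kind="stable")
    sorted_tot = np.take_along_axis(totals, order, axis=1)
    minor_total = sorted_tot[:, 1]
    third_total = sorted_tot[:, 2]
    site_cov = totals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        third_frac = np.where(site_cov > 0, third_total / np.maximum(site_cov, 1), 0.0)

    keep_biallelic = (minor_total > 0) & (third_frac <= max_third_allele_frac)
    keep_count = minor_total >= min_total_count
    keep = keep_cov & keep_biallelic & keep_count

    # zero out alleles beyond the top two at surviving multiallelic sites
    note = {
        "key": key,
        "op": "filter_snps",
        "min_total_count": int(min_total_count),
        "coverage_quantile": float(coverage_quantile),
        "max_third_allele_frac": float(max_third_allele_frac),
        "coverage_thresholds": [float(t) for t in thresholds],
        "n_before": int(panel.n_sites),
    }
    out = panel.subset_sites(keep, note=None)
    drop_alleles = np.ones((out.n_sites, 4), dtype=bool)
    kept_order = order[keep]
    rows = np.arange(out.n_sites)
    drop_alleles[rows, kept_order[:, 0]] = False
    drop_alleles[rows, kept_order[:, 1]] = False
    out.counts = out.counts.copy()
    out.counts[:, :, :4] *= ~drop_alleles[:, None, :]
    note["n_after"] = int(out.n_sites)
    out.provenance.append(note)
    return out


# ---------------------------------------------------------------------------
# Frequencies and polarization
# ---------------------------------------------------------------------------

def weighted_frequency(
    panel: SitePanel,
    site: int,
    allele: str | int,
    sample_indices: Sequence[int],
) -> float:
    """Coverage-weighted frequency of one allele over a sample subset.

    Returns (sum of allele counts) / (sum of coverages); equal to the
    unweighted mean of per-sample frequencies only when coverages are equal.
    """
    if len(sample_indices) == 0:
        raise ValueError("sample subset must be non-empty")
    a = NUCLEOTIDES.index(allele) if isinstance(allele, str) else int(allele)
    idx = np.asarray(sample_indices, dtype=int)
    num = panel.counts[site, idx, a].sum()
    den = panel.counts[site, idx, :4].sum()
    if den == 0:
        raise UndefinedFrequencyError(f"zero total coverage at site index {site}")
    return float(num) / float(den)


def weighted_frequencies(panel: SitePanel, allele_idx: np.ndarray, sample_indices: Sequence[int]) -> np.ndarray:
    """Vectorised coverage-weighted frequencies (NaN where coverage is zero)."""
    idx = np.asarray(sample_indices, dtype=int)
    sub = panel.counts[:, idx, :4]
    num = np.take_along_axis(sub.sum(axis=1), allele_idx[:, None], axis=1)[:, 0]
    den = sub.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def polarize_rising(
    panel: SitePanel,
    treatment: str,
    base_treatment: str = "base",
) -> pd.DataFrame:
    """Polarize biallelic SNPs by the allele rising in the derived treatment.

    For each SNP the rising allele is the one of the two segregating alleles
    whose coverage-weighted evolved frequency exceeds its weighted base
    frequency; ``p0``/``p1`` are reported for that allele.  Exact ties are
    broken toward the minor allele at base.  Monomorphic sites are excluded
    and noted in the panel provenance.

    Returns a DataFrame with columns chrom, pos, major, minor, rising, p0, p1.
    """
    base_idx = panel.samples_where(treatment=base_treatment)
    evo_idx = panel.samples_where(treatment=treatment)
    if not base_idx or not evo_idx:
        raise ValueError(f"panel lacks {base_treatment!r} or {treatment!r} samples")
    major, minor = panel.major_minor()
    p_major_base = weighted_frequencies(panel, major, base_idx)
    p_major_evo = weighted_frequencies(panel, major, evo_idx)
    p_minor_base = weighted_frequencies(panel, minor, base_idx)
    p_minor_evo = weighted_frequencies(panel, minor, evo_idx)

    totals = panel.nucleotide_totals()
    minor_total = np.take_along_axis(totals, minor[:, None], axis=1)[:, 0]
    poly = (minor_total > 0) & ~np.isnan(p_major_base) & ~np.isnan(p_major_evo)
    n_mono = int((~poly).sum())
    if n_mono:
        panel.provenance.append({"op": "polarize_rising", "excluded_monomorphic": n_mono})

    # rising = allele with evolved > base; tie -> minor allele at base
    major_rises = p_major_evo > p_major_base
    tie = p_major_evo == p_major_base
    minor_is_base_minor = p_minor_base <= p_major_base
    pick_minor = (~major_rises) | (tie & minor_is_base_minor)

    rising = np.where(pick_minor, minor, major)
    p0 = np.where(pick_minor, p_minor_base, p_major_base)
    p1 = np.where(pick_minor, p_minor_evo, p_major_evo)
    nuc = np.array(NUCLEOTIDES)
    return pd.DataFrame(
        {
            "chrom": panel.chrom[poly],
            "pos": panel.pos[poly],
            "major": nuc[major[poly]],
            "minor": nuc[minor[poly]],
            "rising": nuc[rising[poly]],
            "p0": p0[poly],
            "p1": p1[poly],
        }
    )
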