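"""Synthetic miniature E&R study with known ground truth.

Generates everything the pipeline consumes without external data: founder
haplotypes from a neutral coalescent (msprime) grouped into isofemale-like
lines, habitat-specific selected loci with skewed starting frequencies
(hot-selected alleles start rare, cold-selected at intermediate frequency),
optional recombination-suppressed inversions with carrier-private markers,
forward evolution of replicate populations under two treatments, Pool-Seq
panels in sync format, region annotations, synthetic gene models with
heat/cold gene sets, and a truth record sufficient to score any downstream
candidate set.

Default scale mirrors the study design (113 lines, 5 replicates x 2
treatments, 15 generations, census 1,000, pools of 500, 35-90x coverage);
``StudyConfig.desk_scale()`` gives a reduced single-chromosome configuration
for interactive use and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from . import io as pio
from .forward import (
    HaplotypePopulation,
    Inversion,
    RecombinationMap,
    SelectionSpec,
    deterministic_trajectory,
    pool_sequence,
    simulate_forward,
    uniform_coverage_sampler,
)
from .io import SampleMeta, SitePanel, merge_samples
from .neutral import EmpiricalSamplers, build_transition_matrix, sample_drifted_counts

__all__ = [
    "StudyConfig",
    "SyntheticTruth",
    "generate_founders",
    "plant_truth",
    "embed_inversion",
    "generate_study",
    "StudyResult",
    "neutral_start_frequencies",
    "simulate_replicated_panel",
]

# coalescent scale chosen so founder LD is short-range (~hundreds of bp),
# the regime in which lab evolution must manufacture long-range associations
_COALESCENT_NE = 50_000


@dataclass
class StudyConfig:
    """Design parameters of the (synthetic) experiment."""

    n_lines: int = 113
    haplotypes_per_line: int = 2
    n_reps: int = 5
    census: int = 1000
    generations: int = 15
    pool_size: int = 500
    coverage_range: tuple[int, int] = (35, 90)
    n_loci: int = 20_000
    chrom_length: int = 5_000_000
    chrom: str = "chr1"
    recomb_rate_cm_mb: float = 2.5
    low_recomb_fraction: float = 0.2  # map tail at reduced rate
    low_recomb_rate_cm_mb: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "haplotypes_per_line", "n_reps", "census", "pool_size", "n_loci", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @classmethod
    def desk_scale(cls, **overrides) -> "StudyConfig":
        """Reduced configuration: census 200, pools of 150, one 5 Mb chromosome."""
        defaults = dict(census=200, pool_size=150, n_loci=20_000, chrom_length=5_000_000)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def n_founder_haplotypes(self) -> int:
        return self.n_lines * self.haplotypes_per_line

    def recombination_map(self) -> RecombinationMap:
        cut = int(self.chrom_length * (1.0 - self.low_recomb_fraction))
        if cut <= 0 or cut >= self.chrom_length:
            return RecombinationMap.uniform(self.chrom_length, self.recomb_rate_cm_mb, self.chrom)
        return RecombinationMap(
            starts=[0, cut],
            ends=[cut, self.chrom_length],
            rates_cm_mb=[self.recomb_rate_cm_mb, self.low_recomb_rate_cm_mb],
            chrom=self.chrom,
        )


def generate_founders(config: StudyConfig, seed: int | None = None) -> tuple[HaplotypePopulation, np.ndarray]:
    """Founder haplotype pool from a neutral coalescent, grouped into lines.

    Returns (pool, line assignment per haplotype).  The pool holds
    ``n_lines * haplotypes_per_line`` haplotypes (226 with the defaults);
    sites are biallelic 0/1 with singletons present, as required downstream.
    If the coalescent yields more segregating sites than ``n_loci`` a random
    subset is kept; fewer are kept as-is.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    H = config.n_founder_haplotypes
    L = config.chrom_length
    a_h = float(np.sum(1.0 / np.arange(1, H)))
    mu = config.n_loci / (L * 2.0 * _COALESCENT_NE * a_h) * 1.15  # slight overshoot, then subsample
    ts = msprime.sim_ancestry(
        samples=H,
        ploidy=1,
        population_size=_COALESCENT_NE,
        sequence_length=L,
        recombination_rate=config.recomb_rate_cm_mb * 1e-8,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    geno = ts.genotype_matrix().T.astype(np.uint8)  # (H, S)
    positions = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)
    # collapse duplicate integer positions (discrete genome) and fixed columns
    freq = geno.sum(axis=0)
    keep = (freq > 0) & (freq < H)
    keep &= np.concatenate([[True], np.diff(positions) > 0])
    geno, positions = geno[:, keep], positions[keep]
    if positions.size > config.n_loci:
        sel = np.sort(rng.choice(positions.size, size=config.n_loci, replace=False))
        geno, positions = geno[:, sel], positions[sel]
    lines = np.repeat(np.arange(config.n_lines), config.haplotypes_per_line)
    pool = HaplotypePopulation(haplotypes=geno, positions=positions, chrom=config.chrom)
    return pool, lines


@dataclass
class SyntheticTruth:
    """Ground truth of the planted selection architecture."""

    hot: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["locus", "pos", "s", "p0"]))
    cold: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["locus", "pos", "s", "p0"]))
    inversions: list[dict] = field(default_factory=list)

    def selected_loci(self, treatment: str) -> np.ndarray:
        df = self.hot if treatment == "hot" else self.cold
        return df["locus"].to_numpy(dtype=np.int64)

    def selection_specs(self, treatment: str, h: float = 0.5) -> list[SelectionSpec]:
        df = self.hot if treatment == "hot" else self.cold
        return [SelectionSpec(locus=int(r.locus), s=float(r.s), h=h) for r in df.itertuples()]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hot": self.hot.to_dict(orient="records"),
            "cold": self.cold.to_dict(orient="records"),
            "inversions": self.inversions,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            hot=pd.DataFrame(payload["hot"], columns=["locus", "pos", "s", "p0"]),
            cold=pd.DataFrame(payload["cold"], columns=["locus", "pos", "s", "p0"]),
            inversions=payload["inversions"],
        )


def plant_truth(
    founders: HaplotypePopulation,
    config: StudyConfig,
    hot_frac: float = 0.002,
    cold_frac: float = 0.002,
    s_range: tuple[float, float] = (0.2, 0.5),
    seed: int | None = None,
    hot_freq_band: tuple[float, float] = (0.02, 0.15),
    cold_freq_band: tuple[float, float] = (0.2, 0.8),
) -> SyntheticTruth:
    """Choose selected loci: hot from rare founder alleles, cold intermediate.

    The asymmetric start-frequency bands emulate the observed excess of
    low-frequency rising alleles in the hot treatment and intermediate ones in
    the cold.  The hot band's lower edge (2%) keeps planted alleles above the
    SNP-calling detection floor and out of the near-certain-stochastic-loss
    regime, so planted selection is in principle recoverable.  Selected sets
    are disjoint; s is uniform over ``s_range``.
    """
    if hot_frac >= 0.01 or cold_frac >= 0.01:
        raise ValueError("selected fractions must stay below 1% of loci")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    freq = founders.frequencies()
    n_hot = int(round(hot_frac * founders.n_loci))
    n_cold = int(round(cold_frac * founders.n_loci))

    def _draw(band: tuple[float, float], n: int, taken: set[int]) -> np.ndarray:
        lo, hi = band
        pool = np.flatnonzero((freq > lo) & (freq <= hi))
        pool = pool[~np.isin(pool, list(taken))]
        if pool.size < n:
            raise ValueError(f"only {pool.size} loci in frequency stratum ({lo}, {hi}] for {n} requested")
        return np.sort(rng.choice(pool, size=n, replace=False))

    hot_loci = _draw(hot_freq_band, n_hot, set())
    cold_loci = _draw(cold_freq_band, n_cold, set(hot_loci.tolist()))

    def _table(loci: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": loci.astype(int),
                "pos": founders.positions[loci].astype(int),
                "s": rng.uniform(s_range[0], s_range[1], size=loci.size),
                "p0": freq[loci],
            }
        )

    return SyntheticTruth(hot=_table(hot_loci), cold=_table(cold_loci))


def embed_inversion(
    founders: HaplotypePopulation,
    interval: tuple[int, int],
    carrier_freq: float,
    n_markers: int = 20,
    seed: int | None = None,
    suppressed: bool = True,
) -> tuple[HaplotypePopulation, dict]:
    """Tag a carrier haplotype subset with an inversion over ``interval``.

    Recombination inside the interval is suppressed for heterokaryotypic
    meioses during forward simulation (absolute suppression, no gene flux).
    ``n_markers`` loci inside the interval are rewritten to be carrier-private
    (allele 1 exactly on carriers), so carrier-frequency dynamics are
    observable in Pool-Seq output.  Returns the updated founders and a truth
    record.
    """
    if not (0.0 < carrier_freq < 1.0):
        raise ValueError("carrier_freq must be in (0, 1)")
    start, end = int(interval[0]), int(interval[1])
    if not (0 <= start < end <= founders.positions[-1] + 1):
        raise ValueError("interval outside the chromosome")
    rng = np.random.default_rng(seed)
    H = founders.haplotypes.shape[0]
    n_car = max(1, int(round(carrier_freq * H)))
    carriers = np.zeros(H, dtype=bool)
    carriers[rng.choice(H, size=n_car, replace=False)] = True

    inside = np.flatnonzero((founders.positions >= start) & (founders.positions < end))
    if inside.size < n_markers:
        n_markers = int(inside.size)
    marker_loci = np.sort(rng.choice(inside, size=n_markers, replace=False)) if n_markers else np.array([], int)
    haps = founders.haplotypes.copy()
    for m in marker_loci:
        haps[:, m] = carriers.astype(np.uint8)

    inv = Inversion(start=start, end=end, carriers=carriers, suppressed=suppressed)
    updated = HaplotypePopulation(
        haplotypes=haps,
        positions=founders.positions,
        chrom=founders.chrom,
        generation=founders.generation,
        inversions=founders.inversions + [inv],
    )
    record = {
        "start": start,
        "end": end,
        "carrier_freq": float(carriers.mean()),
        "suppressed": bool(suppressed),
        "marker_loci": [int(m) for m in marker_loci],
        "carrier_haplotypes": [int(i) for i in np.flatnonzero(carriers)],
    }
    return updated, record


def _synthetic_gene_models(config: StudyConfig, gene_length: int = 2000, spacing: int = 5000) -> pd.DataFrame:
    starts = np.arange(0, config.chrom_length - gene_length, spacing)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(starts.size)],
            "chrom": config.chrom,
            "start": starts,
            "end": starts + gene_length,
        }
    )


def _gene_sets_from_truth(
    models: pd.DataFrame,
    founders: HaplotypePopulation,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    extra_per_set: int = 10,
) -> dict[str, list[str]]:
    """Heat/cold gene sets: genes containing planted loci plus random extras.

    The two sets are kept disjoint (uniquely associated genes only).
    """
    from .enrichment import genes_hit

    sets: dict[str, set[str]] = {}
    for label in ("hot", "cold"):
        df = truth.hot if label == "hot" else truth.cold
        snps = pd.DataFrame({"chrom": founders.chrom, "pos": df["pos"].to_numpy() + 1})
        sets[label] = genes_hit(snps, models)
    sets["hot"], sets["cold"] = sets["hot"] - sets["cold"], sets["cold"] - sets["hot"]
    all_ids = models["gene_id"].to_numpy()
    for label in ("hot", "cold"):
        other = sets["cold" if label == "hot" else "hot"]
        pool = np.array([g for g in all_ids if g not in sets[label] and g not in other])
        extra = rng.choice(pool, size=min(extra_per_set, pool.size), replace=False)
        sets[label] |= set(extra.tolist())
    return {"heat_tolerance": sorted(sets["hot"]), "cold_tolerance": sorted(sets["cold"])}


@dataclass
class StudyResult:
    """All artefacts of one synthetic study run."""

    config: StudyConfig
    truth: SyntheticTruth
    panel: SitePanel
    founders: HaplotypePopulation
    gene_models: pd.DataFrame
    gene_sets: dict[str, list[str]]
    recomb_map: RecombinationMap

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_sync(self.panel, outdir / "study.sync")
        pio.write_sample_meta(self.panel.samples, outdir / "samples.tsv")
        self.gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
        for name, genes in self.gene_sets.items():
            (outdir / f"geneset_{name}.txt").write_text("\n".join(genes) + "\n")
        self.truth.to_json(outdir / "truth.json")
        self.recomb_map.to_tsv(outdir / "recomb_map.tsv")
        with open(outdir / "inversions.bed", "wt") as fh:
            for rec in self.truth.inversions:
                fh.write(f"{self.config.chrom}\t{rec['start']}\t{rec['end']}\tinversion\n")
        low = self.recomb_map.rates_cm_mb < 2.0
        with open(outdir / "low_recomb.bed", "wt") as fh:
            for s, e in zip(self.recomb_map.starts[low], self.recomb_map.ends[low]):
                fh.write(f"{self.recomb_map.chrom}\t{s}\t{e}\tlow_recomb\n")


def generate_study(
    config: StudyConfig,
    truth: SyntheticTruth | None = None,
    founders: HaplotypePopulation | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> StudyResult:
    """Run the full synthetic study: founders -> evolution -> Pool-Seq panel.

    Each replicate index r gets its own census population assembled from the
    founder pool; the hot and cold replicate r both evolve from that base
    population (hot truth active in hot, cold truth in cold).  The base and
    generation-``config.generations`` populations are Pool-Seq'd through
    pools of ``config.pool_size`` individuals at the configured coverage.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if founders is None:
        founders, _ = generate_founders(config, seed=int(rng.integers(2**31 - 1)))
    if truth is None:
        truth = plant_truth(founders, config, seed=int(rng.integers(2**31 - 1)))
    rec_map = config.recombination_map()
    cov = uniform_coverage_sampler(*config.coverage_range)

    def _pool(pop: HaplotypePopulation, meta: SampleMeta) -> SitePanel:
        if config.pool_size < pop.n_individuals:
            idx = rng.choice(pop.n_individuals, size=config.pool_size, replace=False)
            hap_idx = np.sort(np.concatenate([2 * idx, 2 * idx + 1]))
            pop = HaplotypePopulation(
                haplotypes=pop.haplotypes[hap_idx],
                positions=pop.positions,
                chrom=pop.chrom,
                generation=pop.generation,
            )
        return pool_sequence(pop, cov, meta, rng)

    panels = []
    for r in range(1, config.n_reps + 1):
        base_pop = founders.resize(config.census, rng)
        panels.append(_pool(base_pop, SampleMeta(f"base{r}", "base", r, 0)))
        for treatment in ("hot", "cold"):
            evolved, _ = simulate_forward(
                base_pop,
                rec_map,
                sel=truth.selection_specs(treatment),
                generations=config.generations,
                rng=rng,
            )
            panels.append(
                _pool(evolved, SampleMeta(f"{treatment}{r}", treatment, r, config.generations))
            )
    panel = merge_samples(panels)
    models = _synthetic_gene_models(config)
    gene_sets = _gene_sets_from_truth(models, founders, truth, rng)
    result = StudyResult(
        config=config,
        truth=truth,
        panel=panel,
        founders=founders,
        gene_models=models,
        gene_sets=gene_sets,
        recomb_map=rec_map,
    )
    if outdir is not None:
        result.write(outdir)
    return result


# ---------------------------------------------------------------------------
# Fast site-independent panels (no linkage) for calibration-style experiments
# ---------------------------------------------------------------------------

def neutral_start_frequencies(
    n: int,
    n_copies: int = 500,
    min_minor: float = 0.025,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Start frequencies from a folded neutral site-frequency spectrum.

    Copy counts i are drawn with weight 1/i + 1/(H-i), folded to the minor
    allele and truncated below ``min_minor`` (emulating the minimum-count SNP
    filter, which at the study's coverage corresponds to a ~2% minor-allele
    frequency floor).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    i = np.arange(1, n_copies)
    w = 1.0 / i + 1.0 / (n_copies - i)
    f = i / n_copies
    minor = np.minimum(f, 1 - f)
    ok = minor >= min_minor
    w, f = w[ok], minor[ok]
    return rng.choice(f, size=n, p=w / w.sum())


def simulate_replicated_panel(
    n_snps: int,
    N: int,
    t: int,
    n_reps: int = 5,
    n_selected: int = 0,
    s_range: tuple[float, float] = (0.3, 0.5),
    coverage_range: tuple[int, int] = (35, 90),
    seed: int | None = None,
) -> tuple[SitePanel, np.ndarray]:
    """Site-independent replicated panel with optionally planted selection.

    Neutral sites follow the Wright-Fisher null (shared p0, independent drift
    per replicate, pooling noise at both time points).  Selected sites first
    move deterministically under codominant selection for t generations and
    then receive the same drift and pooling treatment, so the same rising
    allele is favoured in every replicate.  Returns the sync-ready panel and
    the planted site indices (0-based row numbers).
    """
    rng = np.random.default_rng(seed)
    samplers = EmpiricalSamplers.uniform(
        start_freqs=neutral_start_frequencies(max(n_snps, 10_000), rng=rng),
        coverage_range=coverage_range,
        n_reps=n_reps,
    )
    p0 = samplers.sample_start(n_snps, rng)
    sel_idx = np.sort(rng.choice(n_snps, size=n_selected, replace=False)) if n_selected else np.array([], int)
    p_target = p0.copy()
    if n_selected:
        s_vals = rng.uniform(s_range[0], s_range[1], size=n_selected)
        for j, (i, s) in enumerate(zip(sel_idx, s_vals)):
            p_target[i] = deterministic_trajectory(p0[i], s, t)[-1]
    matrix = build_transition_matrix(N)
    end_states0 = np.round(p_target * N).astype(np.int64)

    counts = np.zeros((n_snps, 2 * n_reps, 6), dtype=np.int64)
    for r in range(n_reps):
        end_true = sample_drifted_counts(matrix, t, end_states0, rng) / N
        cov0 = samplers.sample_coverage(r + 1, 0, n_snps, rng)
        cov1 = samplers.sample_coverage(r + 1, 1, n_snps, rng)
        c0 = rng.binomial(cov0, p0)
        c1 = rng.binomial(cov1, end_true)
        counts[:, r, 0], counts[:, r, 1] = c0, cov0 - c0
        counts[:, n_reps + r, 0], counts[:, n_reps + r, 1] = c1, cov1 - c1
    samples = [SampleMeta(f"base{r + 1}", "base", r + 1, 0) for r in range(n_reps)]
    samples += [SampleMeta(f"evolved{r + 1}", "evolved", r + 1, t) for r in range(n_reps)]
    panel = SitePanel(
        chrom=np.full(n_snps, "sim", dtype=object),
        pos=np.arange(1, n_snps + 1, dtype=np.int64),
        ref=np.full(n_snps, "A", dtype=object),
        counts=counts,
        samples=samples,
    )
    return panel, sel_idx
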