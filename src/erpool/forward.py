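"""Haplotype-based forward simulation with recombination and selection.

Populations are n diploid individuals stored as 2n biallelic haplotypes.
Each generation, every offspring draws two distinct parents with probability
proportional to fitness (multiplicative across selected loci; log-additive
genotype fitnesses 1 : e^hs : e^s), and each transmitted gamete recombines with a
Poisson number of crossovers placed by the local recombination-map density
(no crossover interference).  Chromosomal inversions suppress recombination
absolutely inside their interval in heterokaryotypic meioses.

The module also implements the log-odds selection-coefficient conversion

    s = 2 ln(p1 q0 / (p0 q1)) / dt        (q = 1 - p)

oriented so that a rising allele has positive s, and the "singleton"
long-range-LD experiment: strong selection on an allele present on a single
founder haplotype, with accepted runs (frequency rise inside a target band)
pooled into replicates and scanned with the CMH test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cmh import CMHResult, cmh_scan, paired_design
from .io import SampleMeta, SitePanel, merge_samples

__all__ = [
    "RecombinationMap",
    "HaplotypePopulation",
    "SelectionSpec",
    "selection_coefficient",
    "deterministic_trajectory",
    "simulate_forward",
    "pool_sequence",
    "singleton_ld_experiment",
    "SingletonResult",
]


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination map in cM/Mb (0-based half-open bp).

    Intervals must tile ``[0, chrom_length)`` without overlap.  The genetic
    length in Morgans of an interval of L bp at rate r cM/Mb is L * r / 1e8.
    """

    starts: np.ndarray
    ends: np.ndarray
    rates_cm_mb: np.ndarray
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates_cm_mb = np.asarray(self.rates_cm_mb, dtype=float)
        if np.any(self.rates_cm_mb < 0):
            raise ValueError("recombination rates must be >= 0")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must be non-empty")
        if np.any(self.starts[1:] != self.ends[:-1]) or (self.starts.size and self.starts[0] != 0):
            raise ValueError("intervals must tile the chromosome from 0 without gaps or overlap")
        morgans_per_bp = self.rates_cm_mb / 1e8
        self._cum_morgans = np.concatenate([[0.0], np.cumsum((self.ends - self.starts) * morgans_per_bp)])

    @classmethod
    def uniform(cls, length: int, rate_cm_mb: float, chrom: str = "chr1") -> "RecombinationMap":
        return cls(starts=[0], ends=[length], rates_cm_mb=[rate_cm_mb], chrom=chrom)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RecombinationMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            starts=df["start"].to_numpy(),
            ends=df["end"].to_numpy(),
            rates_cm_mb=df["cm_mb"].to_numpy(),
            chrom=str(df["chrom"].iloc[0]),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chrom": self.chrom, "start": self.starts, "end": self.ends, "cm_mb": self.rates_cm_mb}
        ).to_csv(path, sep="\t", index=False)

    @property
    def length_bp(self) -> int:
        return int(self.ends[-1])

    @property
    def total_morgans(self) -> float:
        return float(self._cum_morgans[-1])

    def sample_breakpoints(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n crossover positions (bp) with density proportional to local rate."""
        u = rng.random(n) * self.total_morgans
        i = np.clip(np.searchsorted(self._cum_morgans, u, side="right") - 1, 0, len(self.starts) - 1)
        span = self._cum_morgans[i + 1] - self._cum_morgans[i]
        frac = np.where(span > 0, (u - self._cum_morgans[i]) / np.maximum(span, 1e-300), 0.0)
        return (self.starts[i] + frac * (self.ends[i] - self.starts[i])).astype(np.int64)

    def local_rate(self, pos: np.ndarray) -> np.ndarray:
        i = np.clip(np.searchsorted(self.ends, pos, side="right"), 0, len(self.rates_cm_mb) - 1)
        return self.rates_cm_mb[i]


@dataclass
class Inversion:
    """A segregating inversion: carriers recombine freely among themselves,
    but crossovers inside [start, end) are suppressed in heterokaryotypes."""

    start: int
    end: int
    carriers: np.ndarray  # bool per haplotype, maintained across generations
    suppressed: bool = True


@dataclass
class HaplotypePopulation:
    """n diploid individuals as 2n biallelic haplotypes at L sorted loci."""

    haplotypes: np.ndarray  # (2n, L) uint8
    positions: np.ndarray  # (L,) bp, 0-based, sorted
    chrom: str = "chr1"
    generation: int = 0
    inversions: list[Inversion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("haplotypes must be (2n, L) matching positions")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even (diploids)")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def resize(self, n_individuals: int, rng: np.random.Generator) -> "HaplotypePopulation":
        """Assemble a census population from this haplotype pool.

        Gene copies are drawn by cycling through the pool (equal founder
        representation) with any remainder filled uniformly at random, then
        shuffled into diploids.
        """
        H = self.haplotypes.shape[0]
        need = 2 * n_individuals
        idx = np.tile(np.arange(H), need // H)
        rem = need - idx.size
        if rem:
            idx = np.concatenate([idx, rng.choice(H, size=rem, replace=False if rem <= H else True)])
        rng.shuffle(idx)
        invs = [replace(inv, carriers=inv.carriers[idx]) for inv in self.inversions]
        return HaplotypePopulation(
            haplotypes=self.haplotypes[idx],
            positions=self.positions,
            chrom=self.chrom,
            generation=self.generation,
            inversions=invs,
        )


@dataclass(frozen=True)
class SelectionSpec:
    """Selection at one locus: log-additive genotype fitnesses 1 : e^hs : e^s.

    With codominance (h = 0.5) the allele's odds multiply by exactly e^(s/2)
    per generation at any frequency, so the selection-coefficient formula
    s = 2 ln(p1 q0 / (p0 q1)) / dt inverts the deterministic dynamics
    exactly; for small s the fitnesses reduce to 1 : 1+hs : 1+s.
    """

    locus: int
    s: float
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.s < -1:
            raise ValueError("s must be >= -1")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("h must be in [0, 1]")


def selection_coefficient(p0: float, p1: float, dt: float) -> float:
    """Selection coefficient from start/end frequencies over dt generations.

    s = 2 ln(p1 q0 / (p0 q1)) / dt with q = 1 - p, positive when the allele
    rose.  Undefined at p = 0 or 1 (log divergence).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for p in (p0, p1):
        if not (0.0 < p < 1.0):
            raise ValueError("frequencies must be strictly inside (0, 1)")
    return 2.0 * math.log((p1 * (1.0 - p0)) / (p0 * (1.0 - p1))) / dt


def deterministic_trajectory(p0: float, s: float, dt: int, h: float = 0.5) -> np.ndarray:
    """Deterministic Wright-Fisher allele-frequency path under selection.

    Log-additive genotype fitnesses 1 : e^hs : e^s with random mating;
    returns the frequency at generations 0..dt.  At h = 0.5 the path from p0
    satisfies selection_coefficient(p0, p_dt, dt) == s exactly.
    """
    import math as _math

    w_het, w_hom = _math.exp(h * s), _math.exp(s)
    p = float(p0)
    out = [p]
    for _ in range(int(dt)):
        w_a = p * w_hom + (1 - p) * w_het  # marginal fitness, focal allele
        w_b = p * w_het + (1 - p)
        wbar = p * w_a + (1 - p) * w_b
        p = p * w_a / wbar
        out.append(p)
    return np.asarray(out)


def _gamete_indices(
    pop: HaplotypePopulation,
    parents: np.ndarray,
    rec_map: RecombinationMap,
    rng: np.random.Generator,
):
    """Plan one gamete per parent: start phase, crossover breakpoint loci.

    Returns (phase0, breakpoints list per gamete as locus indices).  Each
    gamete locus copies exactly one parental allele.
    """
    n = parents.shape[0]
    phase0 = rng.integers(0, 2, size=n)
    n_cross = rng.poisson(rec_map.total_morgans, size=n)
    bp_lists: list[np.ndarray | None] = [None] * n
    hetero = None
    if pop.inversions:
        hetero = []
        for inv in pop.inversions:
            if not inv.suppressed:
                hetero.append(None)
                continue
            c = inv.carriers
            hetero.append(c[2 * parents] != c[2 * parents + 1])
    for g in np.flatnonzero(n_cross):
        bp = rec_map.sample_breakpoints(n_cross[g], rng)
        if hetero is not None:
            for inv, het in zip(pop.inversions, hetero):
                if het is not None and het[g]:
                    bp = bp[(bp < inv.start) | (bp >= inv.end)]
        if bp.size:
            bp_lists[g] = np.searchsorted(pop.positions, np.sort(bp))
    return phase0, bp_lists


def _make_gametes(
    pop: HaplotypePopulation,
    parents: np.ndarray,
    rec_map: RecombinationMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Build gametes (len(parents), L) plus carried inversion flags."""
    L = pop.n_loci
    phase0, bp_lists = _gamete_indices(pop, parents, rec_map, rng)
    hapA = 2 * parents + phase0
    out = pop.haplotypes[hapA].copy()
    loci = np.arange(L)
    carrier_flags = [inv.carriers[hapA].copy() for inv in pop.inversions]
    inv_start_locus = [np.searchsorted(pop.positions, inv.start) for inv in pop.inversions]
    for g, bp_idx in enumerate(bp_lists):
        if bp_idx is None:
            continue
        phase = (phase0[g] + np.searchsorted(bp_idx, loci, side="right")) % 2
        pa, pb = 2 * parents[g], 2 * parents[g] + 1
        out[g] = np.where(phase == 0, pop.haplotypes[pa], pop.haplotypes[pb])
        for k, inv in enumerate(pop.inversions):
            li = inv_start_locus[k]
            ph = phase[li] if li < L else phase[-1] if L else 0
            carrier_flags[k][g] = inv.carriers[2 * parents[g] + ph]
    return out, carrier_flags


def _fitness(pop: HaplotypePopulation, sel: Sequence[SelectionSpec]) -> np.ndarray:
    n = pop.n_individuals
    w = np.ones(n)
    for spec in sel:
        g = pop.haplotypes[0::2, spec.locus].astype(np.int64) + pop.haplotypes[1::2, spec.locus]
        w *= np.choose(g, [1.0, math.exp(spec.h * spec.s), math.exp(spec.s)])
    return w


def simulate_forward(
    pop: HaplotypePopulation,
    rec_map: RecombinationMap,
    sel: SelectionSpec | Sequence[SelectionSpec] | None = None,
    generations: int = 15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    track_locus: int | None = None,
) -> tuple[HaplotypePopulation, np.ndarray]:
    """Evolve a population forward; returns (population, trajectory).

    The trajectory records the tracked locus's allele frequency at every
    generation 0..generations (the first selected locus by default; the
    trajectory is empty when nothing is tracked).  Census size is constant.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if sel is None:
        sel_list: list[SelectionSpec] = []
    elif isinstance(sel, SelectionSpec):
        sel_list = [sel]
    else:
        sel_list = list(sel)
    for spec in sel_list:
        if not (0 <= spec.locus < pop.n_loci):
            raise ValueError(f"selected locus {spec.locus} out of range")
    if track_locus is None and sel_list:
        track_locus = sel_list[0].locus

    cur = pop
    traj = []
    if track_locus is not None:
        traj.append(float(cur.haplotypes[:, track_locus].mean()))
    n = pop.n_individuals
    for _ in range(int(generations)):
        w = _fitness(cur, sel_list)
        total = w.sum()
        if total <= 0:
            raise RuntimeError("population fitness collapsed to zero")
        prob = w / total
        mothers = rng.choice(n, size=n, p=prob)
        fathers = rng.choice(n, size=n, p=prob)
        # redraw father where it equals the mother (two distinct parents)
        clash = fathers == mothers
        while np.any(clash):
            fathers[clash] = rng.choice(n, size=int(clash.sum()), p=prob)
            clash = fathers == mothers
        g1, f1 = _make_gametes(cur, mothers, rec_map, rng)
        g2, f2 = _make_gametes(cur, fathers, rec_map, rng)
        haps = np.empty((2 * n, cur.n_loci), dtype=np.uint8)
        haps[0::2] = g1
        haps[1::2] = g2
        invs = []
        for k, inv in enumerate(cur.inversions):
            carr = np.empty(2 * n, dtype=bool)
            carr[0::2] = f1[k]
            carr[1::2] = f2[k]
            invs.append(replace(inv, carriers=carr))
        cur = HaplotypePopulation(
            haplotypes=haps,
            positions=cur.positions,
            chrom=cur.chrom,
            generation=cur.generation + 1,
            inversions=invs,
        )
        if track_locus is not None:
            traj.append(float(cur.haplotypes[:, track_locus].mean()))
    return cur, np.asarray(traj)


def pool_sequence(
    pop: HaplotypePopulation,
    coverage_sampler: Callable[[int, np.random.Generator], np.ndarray],
    meta: SampleMeta,
    rng: np.random.Generator,
) -> SitePanel:
    """Pool-Seq a population into a one-sample sync-compatible panel.

    Per locus a coverage is drawn from ``coverage_sampler(n_loci, rng)`` and
    the derived-allele read count as Binomial(coverage, population frequency);
    allele 0 is emitted as A and allele 1 as T.  Positions become 1-based.
    """
    L = pop.n_loci
    cov = np.asarray(coverage_sampler(L, rng), dtype=np.int64)
    freq = pop.frequencies()
    alt = rng.binomial(cov, freq)
    counts = np.zeros((L, 1, 6), dtype=np.int64)
    counts[:, 0, 0] = cov - alt  # A = ancestral allele 0
    counts[:, 0, 1] = alt  # T = derived allele 1
    return SitePanel(
        chrom=np.full(L, pop.chrom, dtype=object),
        pos=pop.positions + 1,
        ref=np.full(L, "A", dtype=object),
        counts=counts,
        samples=[meta],
    )


def uniform_coverage_sampler(lo: int, hi: int) -> Callable[[int, np.random.Generator], np.ndarray]:
    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(lo, hi + 1, size=n)

    return sample


@dataclass
class SingletonResult:
    """Outcome of the singleton hitchhiking experiment."""

    scan: CMHResult
    selected_locus: int
    selected_pos: int
    carrier_haplotype: int
    candidate_positions: np.ndarray  # top-k positions, best rank first
    distances: np.ndarray  # |position - selected position| for the top-k
    accepted_rises: list[float]
    attempts: int
    carrier_alleles: np.ndarray  # founder carrier haplotype's allele at each locus
    panel: SitePanel | None = None  # pooled base + evolved samples fed to the scan


def singleton_ld_experiment(
    founders: HaplotypePopulation,
    rec_map: RecombinationMap,
    s: float,
    generations: int = 15,
    n_replicates: int = 3,
    acceptance_band: tuple[float, float] = (0.25, 0.35),
    coverage_sampler: Callable[[int, np.random.Generator], np.ndarray] | None = None,
    seed: int | None = None,
    selected_locus: int | None = None,
    top_k: int = 1000,
    max_attempts: int = 500,
    census: int | None = None,
) -> SingletonResult:
    """Strong selection on a singleton allele carried by one founder haplotype.

    Replicate forward simulations are run from the founder pool; runs whose
    singleton frequency rise falls inside ``acceptance_band`` are retained
    (all runs are retained when s == 0, the neutral control) until
    ``n_replicates`` have accumulated.  Accepted end populations are
    Pool-Seq'd alongside matched base samples and scanned with the CMH test;
    the result reports the top-k candidate positions and their distances from
    the selected site.
    """
    rng = np.random.default_rng(seed)
    if coverage_sampler is None:
        coverage_sampler = uniform_coverage_sampler(35, 90)
    freqs = founders.haplotypes.sum(axis=0)
    singletons = np.flatnonzero(freqs == 1)
    if selected_locus is None:
        if singletons.size == 0:
            raise ValueError("no singleton loci among the founders")
        centre = founders.positions[-1] // 2
        selected_locus = int(singletons[np.argmin(np.abs(founders.positions[singletons] - centre))])
    elif freqs[selected_locus] != 1:
        raise ValueError("selected locus is not a singleton (exactly one carrier haplotype)")
    carrier = int(np.flatnonzero(founders.haplotypes[:, selected_locus] == 1)[0])
    sel = SelectionSpec(locus=selected_locus, s=s) if s != 0 else None

    accepted: list[HaplotypePopulation] = []
    rises: list[float] = []
    attempts = 0
    lo, hi = acceptance_band
    while len(accepted) < n_replicates:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"acceptance band {acceptance_band} not met {n_replicates} times "
                f"within {max_attempts} attempts ({len(accepted)} accepted); "
                "widen the band, raise max_attempts, or check s"
            )
        attempts += 1
        start = founders if census is None else founders.resize(census, rng)
        end_pop, traj = simulate_forward(
            start, rec_map, sel=sel, generations=generations, rng=rng, track_locus=selected_locus
        )
        rise = float(traj[-1] - traj[0])
        if s == 0 or (lo <= rise <= hi):
            accepted.append(end_pop)
            rises.append(rise)

    panels = []
    base_pool = founders if census is None else founders  # base = founder pool
    for r, end_pop in enumerate(accepted, start=1):
        panels.append(
            pool_sequence(base_pool, coverage_sampler, SampleMeta(f"base{r}", "base", r, 0), rng)
        )
    for r, end_pop in enumerate(accepted, start=1):
        panels.append(
            pool_sequence(
                end_pop, coverage_sampler, SampleMeta(f"evolved{r}", "evolved", r, generations), rng
            )
        )
    panel = merge_samples(panels)
    scan = cmh_scan(panel, paired_design(panel, "evolved"))
    top = scan.top_k(top_k).sort_values("rank")
    sel_pos = int(founders.positions[selected_locus])
    cand_pos = top["pos"].to_numpy() - 1  # back to 0-based to match positions
    return SingletonResult(
        scan=scan,
        selected_locus=int(selected_locus),
        selected_pos=sel_pos,
        carrier_haplotype=carrier,
        candidate_positions=cand_pos,
        distances=np.abs(cand_pos - sel_pos),
        accepted_rises=rises,
        attempts=attempts,
        carrier_alleles=founders.haplotypes[carrier].copy(),
        panel=panel,
    )
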