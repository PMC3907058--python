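"""Site-independent neutral Wright-Fisher null with Pool-Seq sampling noise.

The null for the genome-wide scan is a haploid Wright-Fisher model with N
gene copies: an (N+1)x(N+1) binomial transition matrix raised to the t-th
power gives the distribution of allele counts after t generations of drift
conditional on the start frequency.  Start frequencies and per-replicate
coverages are resampled from empirical distributions, and an additional round
of binomial sampling at both time points emulates DNA pooling, capturing
coverage heterogeneity within and between replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import SampleMeta, SitePanel

__all__ = [
    "TransitionMatrixNull",
    "EmpiricalSamplers",
    "SimulatedPanel",
    "build_transition_matrix",
    "evolve_distribution",
    "simulate_neutral_panel",
    "drift_variance",
    "x_autosome_ne_ratio",
]

_MAX_DENSE_N = 5000
_POWER_CACHE: dict[tuple[int, int], np.ndarray] = {}


@dataclass
class TransitionMatrixNull:
    """Haploid Wright-Fisher transition matrix over allele-count states 0..N.

    ``T[i, j]`` is the binomial probability of j copies in the next
    generation given current frequency i/N.  States 0 and N are absorbing.
    N is interpreted as the count of gene copies; pass ``2 * Ne`` to treat a
    quoted effective size as diploid individuals.
    """

    N: int
    T: np.ndarray

    def power(self, t: int) -> np.ndarray:
        """T^t via repeated squaring (cached per (N, t))."""
        if t < 0:
            raise ValueError("t must be >= 0")
        key = (self.N, t)
        if key not in _POWER_CACHE:
            _POWER_CACHE[key] = np.linalg.matrix_power(self.T, t)
        return _POWER_CACHE[key]


def build_transition_matrix(N: int) -> TransitionMatrixNull:
    """Exact binomial transition matrix for N gene copies (N >= 2)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if N > _MAX_DENSE_N:
        raise ValueError(
            f"N={N} exceeds the dense-matrix limit ({_MAX_DENSE_N}); "
            "use a smaller N or a diffusion approximation"
        )
    j = np.arange(N + 1)
    p = j / N
    T = stats.binom.pmf(j[None, :], N, p[:, None])
    # rows are exact binomial pmfs; enforce absorbing corners against fp dust
    T[0] = 0.0
    T[0, 0] = 1.0
    T[N] = 0.0
    T[N, N] = 1.0
    return TransitionMatrixNull(N=int(N), T=T)


def evolve_distribution(matrix: TransitionMatrixNull, t: int, p0: float) -> np.ndarray:
    """Distribution over allele counts after t generations from frequency p0.

    The start state is ``round(p0 * N)`` (nearest-state rounding).  The mean
    of the returned distribution is exactly the start state frequency and the
    variance is p0(1-p0)[1 - (1 - 1/N)^t].
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be in [0, 1]")
    state = int(round(p0 * matrix.N))
    return matrix.power(t)[state]


def drift_variance(p0: float, N: int, t: int) -> float:
    """Closed-form variance of allele frequency after t generations of drift."""
    return p0 * (1.0 - p0) * (1.0 - (1.0 - 1.0 / N) ** t)


def x_autosome_ne_ratio(n_females: float = 0.5, n_males: float = 0.5) -> float:
    """Ratio of X-linked to autosomal Ne from copy-number accounting.

    Autosomes: Ne_A = 4 Nf Nm / (Nf + Nm).  X (two copies per female, one per
    male): Ne_X = 9 Nf Nm / (4 Nf + 2 Nm).  With an equal sex ratio the ratio
    is 3/4, i.e. a 25% reduction for the X.
    """
    ne_a = 4.0 * n_females * n_males / (n_females + n_males)
    ne_x = 9.0 * n_females * n_males / (4.0 * n_females + 2.0 * n_males)
    return ne_x / ne_a


@dataclass
class EmpiricalSamplers:
    """Resampling distributions for start frequencies and coverages.

    ``start_freqs`` holds the observed coverage-weighted base frequencies;
    ``coverages`` maps a (replicate, time point) key to that sample's observed
    coverage values.  Sampling draws uniformly with replacement, so each
    sampler reproduces its source histogram in expectation.
    """

    start_freqs: np.ndarray
    coverages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start_freqs = np.asarray(self.start_freqs, dtype=float)
        if self.start_freqs.size == 0:
            raise ValueError("start-frequency sampler is empty")
        self.coverages = {k: np.asarray(v, dtype=np.int64) for k, v in self.coverages.items()}
        for k, v in self.coverages.items():
            if v.size == 0:
                raise ValueError(f"coverage sampler {k!r} is empty")

    @classmethod
    def from_panel(cls, panel: SitePanel, treatment: str, base_treatment: str = "base") -> "EmpiricalSamplers":
        """Fit samplers from an observed panel for one treatment contrast."""
        from .io import weighted_frequencies

        base_idx = panel.samples_where(treatment=base_treatment)
        _, minor = panel.major_minor()
        p0 = weighted_frequencies(panel, minor, base_idx)
        cov = panel.coverage()
        covs = {}
        for i in base_idx:
            m = panel.samples[i]
            covs[(m.replicate, 0)] = cov[:, i]
        for i in panel.samples_where(treatment=treatment):
            m = panel.samples[i]
            covs[(m.replicate, 1)] = cov[:, i]
        return cls(start_freqs=p0[~np.isnan(p0)], coverages=covs)

    @classmethod
    def uniform(
        cls,
        start_freqs: np.ndarray,
        coverage_range: tuple[int, int] = (35, 90),
        n_reps: int = 3,
        grid: int = 2000,
    ) -> "EmpiricalSamplers":
        """Convenience constructor with a shared uniform coverage range."""
        lo, hi = coverage_range
        covs = {}
        for r in range(1, n_reps + 1):
            for tp in (0, 1):
                covs[(r, tp)] = np.arange(lo, hi + 1)
        return cls(start_freqs=np.asarray(start_freqs, dtype=float), coverages=covs)

    def sample_start(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.start_freqs, size=n, replace=True)

    def sample_coverage(self, replicate: int, timepoint: int, n: int, rng: np.random.Generator) -> np.ndarray:
        key = (replicate, timepoint)
        if key not in self.coverages:
            raise KeyError(f"no coverage sampler for replicate {replicate}, time point {timepoint}")
        return rng.choice(self.coverages[key], size=n, replace=True)

    @property
    def n_reps(self) -> int:
        return len({r for r, _ in self.coverages})


@dataclass
class SimulatedPanel:
    """A simulated null panel: true frequencies plus pooled observations.

    Arrays are (n_snps,) for the shared start frequency and (n_snps, n_reps)
    for everything per-replicate.  ``end_true`` holds the post-drift allele
    frequency of each replicate (replicates drift independently conditional on
    the shared p0).
    """

    p0: np.ndarray
    end_true: np.ndarray
    start_cov: np.ndarray
    start_counts: np.ndarray
    end_cov: np.ndarray
    end_counts: np.ndarray
    N: float
    t: int
    seed: int | None = None

    @property
    def n_snps(self) -> int:
        return self.p0.shape[0]

    @property
    def n_reps(self) -> int:
        return self.end_true.shape[1]

    def observed_start(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.start_cov > 0, self.start_counts / np.maximum(self.start_cov, 1), np.nan)

    def observed_end(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.end_cov > 0, self.end_counts / np.maximum(self.end_cov, 1), np.nan)

    def observed_afc(self) -> np.ndarray:
        return self.observed_end() - self.observed_start()

    def to_site_panel(self, chrom: str = "sim") -> SitePanel:
        """Export as a sync-compatible panel (alleles A/T, 1-based positions).

        Sample columns are base replicates at generation 0 followed by evolved
        replicates at generation t, so the panel flows through the identical
        ``cmh_scan`` path as real data.
        """
        n, r = self.n_snps, self.n_reps
        counts = np.zeros((n, 2 * r, 6), dtype=np.int64)
        for j in range(r):
            counts[:, j, 0] = self.start_counts[:, j]
            counts[:, j, 1] = self.start_cov[:, j] - self.start_counts[:, j]
            counts[:, r + j, 0] = self.end_counts[:, j]
            counts[:, r + j, 1] = self.end_cov[:, j] - self.end_counts[:, j]
        samples = [SampleMeta(f"base{j + 1}", "base", j + 1, 0) for j in range(r)]
        samples += [SampleMeta(f"evolved{j + 1}", "evolved", j + 1, self.t) for j in range(r)]
        return SitePanel(
            chrom=np.full(n, chrom, dtype=object),
            pos=np.arange(1, n + 1, dtype=np.int64),
            ref=np.full(n, "A", dtype=object),
            counts=counts,
            samples=samples,
        )


def sample_drifted_counts(
    matrix: TransitionMatrixNull, t: int, start_states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw end allele counts from rows of T^t, grouped by start state."""
    Tt = matrix.power(t)
    cum = np.cumsum(Tt, axis=1)
    out = np.empty(start_states.shape[0], dtype=np.int64)
    for s in np.unique(start_states):
        sel = np.flatnonzero(start_states == s)
        u = rng.random(sel.size)
        out[sel] = np.searchsorted(cum[s], u, side="right")
    return np.minimum(out, matrix.N)


def simulate_neutral_panel(
    samplers: EmpiricalSamplers,
    N: int,
    t: int,
    n_snps: int,
    n_reps: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedPanel:
    """Simulate a site-independent neutral panel with Pool-Seq noise.

    Per SNP: draw p0 from the start sampler (shared across replicates); for
    each replicate draw an independent post-drift frequency from the row of
    T^t at state round(p0*N), then draw coverages from that replicate's
    empirical distributions and pooled read counts as Binomial(coverage,
    frequency) at both time points.

    Drift is disabled when ``N`` is None or infinite (the end frequency then
    equals the start frequency and only pooling noise remains).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_reps is None:
        n_reps = samplers.n_reps
    no_drift = N is None or np.isinf(N)
    matrix = None if no_drift else build_transition_matrix(N)
    p0 = samplers.sample_start(n_snps, rng)
    start_states = None if no_drift else np.round(p0 * N).astype(np.int64)

    end_true = np.empty((n_snps, n_reps))
    start_cov = np.empty((n_snps, n_reps), dtype=np.int64)
    start_counts = np.empty_like(start_cov)
    end_cov = np.empty_like(start_cov)
    end_counts = np.empty_like(start_cov)
    reps = sorted({r for r, _ in samplers.coverages})[:n_reps]
    if len(reps) < n_reps:
        reps = list(range(1, n_reps + 1))
    for j, rep in enumerate(reps):
        if no_drift:
            end_true[:, j] = p0
        else:
            end_true[:, j] = sample_drifted_counts(matrix, t, start_states, rng) / N
        try:
            start_cov[:, j] = samplers.sample_coverage(rep, 0, n_snps, rng)
            end_cov[:, j] = samplers.sample_coverage(rep, 1, n_snps, rng)
        except KeyError as exc:
            raise ValueError("samplers not fitted for all replicates/time points") from exc
        start_counts[:, j] = rng.binomial(start_cov[:, j], p0)
        end_counts[:, j] = rng.binomial(end_cov[:, j], end_true[:, j])
    return SimulatedPanel(
        p0=p0,
        end_true=end_true,
        start_cov=start_cov,
        start_counts=start_counts,
        end_cov=end_cov,
        end_counts=end_counts,
        N=(np.inf if no_drift else int(N)),
        t=int(t),
        seed=seed,
    )
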