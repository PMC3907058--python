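"""Effective-population-size estimation and empirical-FDR candidate calling.

Ne is estimated by least-squares agreement between observed and simulated
allele-frequency-change (AFC) distributions, binned at 1% frequency change.
Candidates are called against the simulated neutral null: the threshold P* at
FDR level gamma is the largest P value among the ``ceil(gamma * n_sim)``
smallest simulated CMH P values, and candidates are the observed SNPs with
P < P* (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmh import CMHResult
from .io import SitePanel, weighted_frequencies
from .neutral import EmpiricalSamplers, simulate_neutral_panel

__all__ = [
    "AFCHistogram",
    "NeFitResult",
    "CandidateSet",
    "afc_histogram",
    "observed_afc_histograms",
    "fit_ne",
    "empirical_fdr_threshold",
    "call_candidates",
]

# 1%-wide bins centred on multiples of 0.01 so that zero change falls in the
# bin [-0.005, 0.005) and a drift-symmetric AFC distribution maps onto a
# histogram symmetric about 0.  This gives 201 bins spanning [-1.005, 1.005].
AFC_BIN_WIDTH = 0.01
AFC_BIN_EDGES = np.round(np.arange(-1.005, 1.005 + AFC_BIN_WIDTH / 2, AFC_BIN_WIDTH), 4)


@dataclass
class AFCHistogram:
    """Normalised histogram of allele-frequency changes in 1% bins."""

    proportions: np.ndarray
    edges: np.ndarray = field(default_factory=lambda: AFC_BIN_EDGES.copy())
    n: int = 0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape[0] != self.edges.shape[0] - 1:
            raise ValueError("proportions do not match bin edges")


def afc_histogram(start: np.ndarray, end: np.ndarray) -> AFCHistogram:
    """Histogram of (end - start) over the shared 1% bins, as proportions."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if start.shape != end.shape:
        raise ValueError("start and end must be paired (equal length)")
    afc = (end - start).ravel()
    afc = afc[~np.isnan(afc)]
    if afc.size == 0:
        raise ValueError("no finite allele-frequency changes to bin")
    counts, _ = np.histogram(afc, bins=AFC_BIN_EDGES)
    return AFCHistogram(proportions=counts / counts.sum(), n=int(afc.size))


def observed_afc_histograms(
    panel: SitePanel, treatment: str, base_treatment: str = "base"
) -> list[AFCHistogram]:
    """Per-replicate AFC histograms of the (overall) minor allele at base."""
    _, minor = panel.major_minor()
    base = sorted(panel.samples_where(treatment=base_treatment), key=lambda i: panel.samples[i].replicate)
    evo = sorted(panel.samples_where(treatment=treatment), key=lambda i: panel.samples[i].replicate)
    if len(base) != len(evo) or not base:
        raise ValueError("panel does not pair base and evolved replicates")
    out = []
    for b, e in zip(base, evo):
        p0 = weighted_frequencies(panel, minor, [b])
        p1 = weighted_frequencies(panel, minor, [e])
        out.append(afc_histogram(p0, p1))
    return out


@dataclass
class NeFitResult:
    """Goodness-of-fit profile over an Ne grid.

    ``mean_fit`` is the summed squared difference of binned AFC proportions,
    averaged over replicates; ``se_fit`` its standard error across replicates.
    ``best_ne`` minimises the mean fit; ``conservative_ne`` is the smallest
    grid value whose mean fit lies within ``se_factor`` standard errors of the
    best (the conservative choice, since drift strengthens as Ne falls).
    """

    grid: np.ndarray
    per_replicate: np.ndarray  # (n_grid, n_reps)
    mean_fit: np.ndarray
    se_fit: np.ndarray
    best_ne: int
    conservative_ne: int
    se_factor: float = 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ne": self.grid, "mean_fit": self.mean_fit, "se_fit": self.se_fit}
        )


def fit_ne(
    observed: list[AFCHistogram],
    samplers: EmpiricalSamplers,
    grid,
    t: int,
    n_snps: int = 100_000,
    seed: int | None = None,
    se_factor: float = 1.0,
) -> NeFitResult:
    """Estimate Ne by binned least squares against simulated AFC distributions.

    For each grid Ne a matched panel (same replicate count, same samplers) is
    simulated; per replicate the summed squared difference between observed
    and simulated binned AFC proportions is computed and averaged across
    replicates.  A degenerate single-value grid returns that value as both the
    best and the conservative estimate.
    """
    grid = np.asarray(sorted(int(g) for g in np.atleast_1d(grid)))
    if grid.size < 1:
        raise ValueError("grid must be non-empty")
    n_reps = len(observed)
    if n_reps < 1:
        raise ValueError("need at least one observed replicate histogram")
    rng = np.random.default_rng(seed)
    fits = np.empty((grid.size, n_reps))
    for gi, ne in enumerate(grid):
        sim = simulate_neutral_panel(samplers, N=int(ne), t=t, n_snps=n_snps, n_reps=n_reps, rng=rng)
        s_obs = sim.observed_start()
        e_obs = sim.observed_end()
        for r in range(n_reps):
            h = afc_histogram(s_obs[:, r], e_obs[:, r])
            fits[gi, r] = float(np.sum((h.proportions - observed[r].proportions) ** 2))
    mean_fit = fits.mean(axis=1)
    if n_reps > 1:
        se_fit = fits.std(axis=1, ddof=1) / math.sqrt(n_reps)
    else:
        se_fit = np.zeros(grid.size)
    best_i = int(np.argmin(mean_fit))
    cutoff = mean_fit[best_i] + se_factor * se_fit[best_i]
    cons_i = int(np.flatnonzero(mean_fit <= cutoff)[0])
    return NeFitResult(
        grid=grid,
        per_replicate=fits,
        mean_fit=mean_fit,
        se_fit=se_fit,
        best_ne=int(grid[best_i]),
        conservative_ne=int(grid[cons_i]),
        se_factor=se_factor,
    )


def empirical_fdr_threshold(sim_p: np.ndarray, gamma: float) -> float:
    """P* at FDR level gamma from a simulated null P-value sample.

    P* is the largest P among the ``ceil(gamma * n)`` smallest simulated P
    values; observed SNPs with P < P* are candidates.
    """
    sim_p = np.asarray(sim_p, dtype=float)
    sim_p = sim_p[~np.isnan(sim_p)]
    if sim_p.size == 0:
        raise ValueError("sim_p must be non-empty")
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    if gamma * sim_p.size < 1:
        raise ValueError(
            "gamma * len(sim_p) < 1: simulate more null SNPs to resolve this FDR level"
        )
    k = math.ceil(gamma * sim_p.size)
    if k < 1:
        raise ValueError(
            "gamma * len(sim_p) < 1: simulate more null SNPs to resolve this FDR level"
        )
    return float(np.partition(sim_p, k - 1)[k - 1])


@dataclass
class CandidateSet:
    """SNPs called at an empirical FDR level.

    Membership is the strict inequality P < threshold; ``table`` retains the
    scan's ranks so the set is reproducible from (scan, threshold).
    """

    gamma: float
    threshold: float
    treatment: str
    table: pd.DataFrame

    @property
    def n_candidates(self) -> int:
        return len(self.table)


def call_candidates(scan: CMHResult, threshold: float, gamma: float, treatment: str = "") -> CandidateSet:
    """Select observed SNPs with CMH P strictly below the simulated-null P*."""
    sub = scan.table[scan.table["pvalue"] < threshold].sort_values("rank")
    return CandidateSet(gamma=float(gamma), threshold=float(threshold), treatment=treatment, table=sub.reset_index(drop=True))
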