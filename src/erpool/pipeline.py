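"""End-to-end orchestration of the E&R analysis on observed or synthetic data.

The pipeline runs the stages in dependency order — Pool-Seq ingest and SNP
filtering, per-treatment CMH scans, Wright-Fisher null simulation, Ne fitting
and empirical-FDR candidate calling, replicate-group concordance, region
masks and LD-decay profiles, and gene-set enrichment — writing one TSV per
stage plus a markdown report.  A single global seed is expanded into
independent per-stage substreams with ``numpy.random.SeedSequence.spawn``, so
any stage can be rerun in isolation and a rerun with the same configuration
reproduces every number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .cmh import cmh_scan, paired_design
from .concordance import concordance_curve, harmonize_scans, replicate_direction_signs
from .enrichment import enrichment_series
from .nefdr import call_candidates, empirical_fdr_threshold, fit_ne, observed_afc_histograms
from .neutral import EmpiricalSamplers, simulate_neutral_panel
from .regions import build_low_ld_mask, ld_decay_profile, matched_background
from .synth import StudyConfig, generate_study

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated run configuration; serialized into every output directory."""

    outdir: str = "erpool_out"
    seed: int = 1
    sync: str | None = None  # observed mode: sync + sample metadata paths
    samples: str | None = None
    synthetic: bool = True
    study: dict = field(default_factory=dict)  # StudyConfig overrides
    treatments: tuple[str, ...] = ("hot", "cold")
    gamma: float = 0.001
    ne_grid: tuple[int, ...] = (125, 160, 200, 250, 315, 400, 500)
    n_null_snps: int = 100_000
    min_total_count: int = 30
    coverage_quantile: float = 0.02
    ld_top_k: int = 200
    enrich_k_grid: tuple[int, ...] = (500, 1000, 2000)
    enrich_n_perm: int = 2000

    def __post_init__(self) -> None:
        if not self.synthetic and (self.sync is None or self.samples is None):
            raise ValueError("observed mode requires sync and samples paths")
        if not (0 < self.gamma < 1):
            raise ValueError("gamma must be in (0, 1)")
        if len(self.ne_grid) < 1:
            raise ValueError("ne_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("treatments", "ne_grid", "enrich_k_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        for key in ("treatments", "ne_grid", "enrich_k_grid"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _stage_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as report.md)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stages = ["study", "null", "concordance", "regions", "enrichment"]
    rngs = _stage_rngs(config.seed, stages)
    log: list[str] = []
    summary: dict = {"seed": config.seed}

    def note(msg: str) -> None:
        log.append(msg)

    # --- ingest -----------------------------------------------------------
    truth = None
    if config.synthetic:
        study_cfg = StudyConfig.desk_scale(**{**config.study, "seed": int(rngs["study"].integers(2**31 - 1))})
        study = generate_study(study_cfg, outdir=out / "study")
        panel, truth = study.panel, study.truth
        note(f"synthetic study: {panel.n_sites} loci, {panel.n_samples} samples")
    else:
        panel = pio.read_sync(config.sync, samples=pio.read_sample_meta(config.samples))
        study = None
        note(f"observed panel: {panel.n_sites} sites, {panel.n_samples} samples")

    panel = pio.filter_snps(panel, config.min_total_count, config.coverage_quantile)
    note(f"after SNP filtering: {panel.n_sites} SNPs")
    if panel.n_sites == 0:
        raise RuntimeError("stage filter: no SNPs survive filtering")

    # --- per-treatment scan, null, candidates -----------------------------
    available = {m.treatment for m in panel.samples} - {"base"}
    for treatment in config.treatments:
        if treatment not in available:
            raise RuntimeError(f"stage scan: panel has no {treatment!r} samples")
        design = paired_design(panel, treatment)
        scan = cmh_scan(panel, design)
        scan.to_tsv(out / f"scan_{treatment}.tsv")
        rising = pio.polarize_rising(panel, treatment)
        rising.to_csv(out / f"rising_{treatment}.tsv", sep="\t", index=False)

        samplers = EmpiricalSamplers.from_panel(panel, treatment)
        hists = observed_afc_histograms(panel, treatment)
        ne_seed = int(rngs["null"].integers(2**31 - 1))
        fit = fit_ne(hists, samplers, config.ne_grid, t=_generations(panel, treatment), n_snps=config.n_null_snps, seed=ne_seed)
        fit.to_dataframe().to_csv(out / f"ne_fit_{treatment}.tsv", sep="\t", index=False)
        note(f"{treatment}: best Ne {fit.best_ne}, conservative Ne {fit.conservative_ne}")

        null_panel = simulate_neutral_panel(
            samplers,
            N=fit.conservative_ne,
            t=_generations(panel, treatment),
            n_snps=config.n_null_snps,
            n_reps=len(design),
            seed=int(rngs["null"].integers(2**31 - 1)),
        ).to_site_panel()
        null_scan = cmh_scan(null_panel, paired_design(null_panel, "evolved"))
        threshold = empirical_fdr_threshold(null_scan.table["pvalue"].to_numpy(), config.gamma)
        cands = call_candidates(scan, threshold, config.gamma, treatment)
        cands.table.to_csv(out / f"candidates_{treatment}.tsv", sep="\t", index=False)
        note(f"{treatment}: {cands.n_candidates} candidates at empirical FDR {config.gamma} (P* = {threshold:.3g})")
        summary[f"candidates_{treatment}"] = cands.n_candidates

        if truth is not None:
            truth_pos = set((truth.hot if treatment == "hot" else truth.cold)["pos"] + 1)
            called = set(cands.table["pos"])
            tp = len(called & truth_pos)
            precision = tp / max(len(called), 1)
            recall = tp / max(len(truth_pos), 1)
            summary[f"precision_{treatment}"] = precision
            summary[f"recall_{treatment}"] = recall
            note(f"{treatment}: precision {precision:.3f}, recall {recall:.3f} vs planted truth")

        # --- concordance (needs >= 5 replicates: 3 + 2 split) -------------
        if len(design) >= 5:
            pairs_a, pairs_b = design[:3], design[3:5]
            scan_a = cmh_scan(panel, pairs_a)
            scan_b = cmh_scan(panel, pairs_b)
            signs_a = replicate_direction_signs(panel, pairs_a)
            signs_b = replicate_direction_signs(panel, pairs_b)
            scan_a, scan_b, signs_a, signs_b = harmonize_scans(panel, scan_a, scan_b, signs_a, signs_b)
            roc = concordance_curve(scan_a, scan_b, signs_a, signs_b)
            roc.to_dataframe().to_csv(out / f"roc_{treatment}.tsv", sep="\t", index=False)
            excess = float(np.mean(roc.proportion - roc.diagonal))
            note(f"{treatment}: mean concordance excess over chance {excess:+.4f}")
            summary[f"roc_excess_{treatment}"] = excess

        # --- LD decay around top candidates -------------------------------
        top = scan.top_k(config.ld_top_k)[["chrom", "pos"]]
        profile = ld_decay_profile(top, scan, cohort=treatment, seed=int(rngs["regions"].integers(2**31 - 1)))
        profile.to_tsv(out / f"ld_profile_{treatment}.tsv")
        bg = matched_background(top, scan.table[["chrom", "pos"]], seed=int(rngs["regions"].integers(2**31 - 1)))
        bg_profile = ld_decay_profile(bg, scan, cohort="background", seed=int(rngs["regions"].integers(2**31 - 1)))
        bg_profile.to_tsv(out / f"ld_profile_{treatment}_background.tsv")

        # --- enrichment (synthetic mode has gene models) ------------------
        if study is not None:
            k_grid = [k for k in config.enrich_k_grid if k <= scan.n_snps]
            if k_grid:
                enr = enrichment_series(
                    scan,
                    k_grid,
                    study.gene_models,
                    study.gene_sets,
                    n_perm=config.enrich_n_perm,
                    seed=int(rngs["enrichment"].integers(2**31 - 1)),
                )
                enr.to_csv(out / f"enrichment_{treatment}.tsv", sep="\t", index=False)
                for r in enr.itertuples():
                    note(f"{treatment}: {r.gene_set} k={r.k} observed={r.observed} P={r.pvalue:.4g}")

    if config.synthetic and study is not None:
        mask = build_low_ld_mask(
            inversions={study.config.chrom: np.array([[r["start"], r["end"]] for r in truth.inversions]).reshape(-1, 2)},
            recomb_map=study.recomb_map,
        )
        summary["high_ld_masked_bp"] = mask.total_length()

    report = ["# erpool pipeline report", "", f"seed: {config.seed}", ""]
    report += [f"- {line}" for line in log]
    (out / "report.md").write_text("\n".join(report) + "\n")
    summary["log"] = log
    return summary


def _generations(panel, treatment: str) -> int:
    gens = {panel.samples[i].generation for i in panel.samples_where(treatment=treatment)}
    return max(gens) if gens else 0
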