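"""Genome-wide CMH scan and empirical-FDR candidate calling.

Simulates a 100,000-SNP three-replicate panel with 100 planted selected loci
over 15 generations of drift (Ne = 250) plus Pool-Seq noise, scans it with
the replicate-stratified CMH test, estimates the significance threshold from
a matched neutral simulation at an empirical FDR of 0.001, and scores the
called candidates against the planted truth.
"""

import numpy as np

from erpool.cmh import cmh_scan, paired_design
from erpool.nefdr import call_candidates, empirical_fdr_threshold
from erpool.neutral import EmpiricalSamplers, simulate_neutral_panel
from erpool.synth import neutral_start_frequencies, simulate_replicated_panel

GAMMA = 0.001

panel, planted = simulate_replicated_panel(
    n_snps=100_000, N=250, t=15, n_reps=3, n_selected=100, s_range=(0.3, 0.5), seed=11
)
scan = cmh_scan(panel, paired_design(panel, "evolved"))
print(f"scanned {scan.n_snps} SNPs; most significant P = {scan.table.pvalue.min():.3g}")

samplers = EmpiricalSamplers.uniform(neutral_start_frequencies(50_000, seed=12), (35, 90))
null = simulate_neutral_panel(samplers, N=250, t=15, n_snps=100_000, seed=13).to_site_panel()
null_p = cmh_scan(null, paired_design(null, "evolved")).table.pvalue.to_numpy()
p_star = empirical_fdr_threshold(null_p, GAMMA)
print(f"empirical FDR {GAMMA}: P* = {p_star:.3g} "
      f"(the {int(np.ceil(GAMMA * null_p.size))}-th smallest neutral P)")

cands = call_candidates(scan, p_star, GAMMA, "evolved")
hits = len(set(cands.table.pos) & set(planted + 1))
print(f"candidates called: {cands.n_candidates}; planted loci recovered: {hits}/100")
print("\nThe threshold comes from drift simulations, not a chi-square cutoff:"
      "\ndrift at Ne=250 inflates the CMH statistic, so a parametric threshold"
      "\nwould call thousands of false positives here.")
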