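"""Replicate-group concordance (modified ROC) with a simulated chance band.

Splits a five-replicate panel into independent groups of three and two,
scans each, and asks how many SNPs appear in both groups' top-k with the
same allele rising in all five replicates.  The chance expectation is
calibrated by re-running the same split on matched neutral simulations.
"""

import numpy as np

from erpool.cmh import cmh_scan
from erpool.concordance import (
    concordance_curve,
    harmonize_scans,
    replicate_direction_signs,
    simulated_null_band,
)
from erpool.synth import simulate_replicated_panel

K_GRID = np.unique(np.round(np.geomspace(200, 19_000, 10)).astype(int))


def curve(seed, n_selected):
    panel, _ = simulate_replicated_panel(20_000, N=250, t=15, n_reps=5, n_selected=n_selected, seed=seed)
    b = {panel.samples[i].replicate: i for i in panel.samples_where(treatment="base")}
    e = {panel.samples[i].replicate: i for i in panel.samples_where(treatment="evolved")}
    pairs = [(b[r], e[r]) for r in sorted(b)]
    pa, pb = pairs[:3], pairs[3:5]
    sa, sb = replicate_direction_signs(panel, pa), replicate_direction_signs(panel, pb)
    A, B, sa, sb = harmonize_scans(panel, cmh_scan(panel, pa), cmh_scan(panel, pb), sa, sb)
    return concordance_curve(A, B, sa, sb, K_GRID)


band = simulated_null_band([curve(1000 + i, 0) for i in range(15)])
selected = curve(1, 200)

table = band.assign(selected=selected.proportion)
print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\n'selected' is the concordant top-k overlap for data with 200 planted"
      "\nselected loci; 'chance' and the band come from neutral simulations."
      "\nThe selected curve sits far above the band at small k: true targets"
      "\nreplicate across independent groups, drift does not.")
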