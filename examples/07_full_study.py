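"""End-to-end synthetic study through the full pipeline.

Generates a miniature two-treatment experiment (coalescent founders, 5
replicates x 15 generations with habitat-specific selected loci, Pool-Seq),
then runs SNP filtering, CMH scans, Ne fitting, empirical-FDR candidate
calling, concordance, LD profiles, and gene-set enrichment, writing one TSV
per stage plus a markdown report.
"""

import tempfile

from erpool.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(
        outdir=tmp,
        seed=5,
        study={"n_loci": 5_000, "chrom_length": 2_500_000},
        gamma=0.01,
        ne_grid=(200, 300, 450, 700),
        n_null_snps=30_000,
        ld_top_k=50,
        enrich_k_grid=(200,),
        enrich_n_perm=1000,
    )
    summary = run_pipeline(config)

for line in summary["log"]:
    print(line)
print("\nPrecision/recall score the FDR-called candidates against the planted"
      "\ntruth. At this compressed desk scale most excess candidates are"
      "\nhitchhikers linked to true targets, so precision at the locus level"
      "\nstays low even when the scan is working exactly as designed.")
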