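# erpool

Analysis toolkit for **evolve-and-resequence (E&R) Pool-Seq experiments**:
replicated populations adapt to novel environments for a handful of
generations, pooled whole-genome sequencing yields allele counts at the
start and end, and the task is to decide which SNPs changed frequency
because of selection rather than genetic drift and sampling noise.

It is written for population geneticists analysing PoPoolation2-style sync
files — and for anyone who wants to understand why such experiments can
report thousands of "candidates" from a single selected haplotype.

## What it does

* **Pool-Seq I/O** — read/write sync format, SNP calling filters (top-2%
  coverage rule, minimum minor count 30, biallelic reduction),
  coverage-weighted frequencies, rising-allele polarization.
* **CMH scan** — the replicate-stratified Cochran–Mantel–Haenszel test,
  X² = (|Σₖ(aₖ − E[aₖ])|)² / Σₖ Var(aₖ), vectorised genome-wide.
* **Wright–Fisher null** — an (N+1)×(N+1) binomial transition matrix raised
  to the t-th power, with empirical start-frequency and coverage resampling
  and binomial pooling noise at both time points.
* **Ne estimation & empirical FDR** — least-squares fit of observed vs
  simulated allele-frequency-change histograms in 1% bins; candidate
  threshold P\* from the γ-quantile of the simulated null's CMH P values.
* **Concordance (modified ROC)** — overlap of top-k candidates between
  independent replicate groups with a rising-allele consistency rule and a
  simulation-calibrated chance band; pseudo-base resampling.
* **Haplotype forward simulator** — recombination maps in cM/Mb, selection
  with s = 2 ln(p₁q₀/(p₀q₁))/Δt semantics, inversion recombination
  suppression, and the "singleton" long-range-LD experiment.
* **Region & LD analyses** — inversion ± 500 kb masks, <2 cM/Mb regions,
  short-intron neutral proxies, P-value decay in 50-bp windows with matched
  background SNPs.
* **Gene-set enrichment** — gene-mode permutation tests over nested
  candidate sets.
* **Synthetic study generator** — a complete miniature experiment
  (coalescent founders, planted habitat-specific selection, inversions,
  Pool-Seq panels, annotations, truth record) so every stage is testable
  without downloads.

## Worked example

Scan a simulated 100,000-SNP, three-replicate experiment with 100 planted
selected loci, and call candidates at an empirical FDR of 0.001 against a
matched drift simulation (`examples/02_cmh_scan_and_candidates.py`):

```bash
$ python examples/02_cmh_scan_and_candidates.py
scanned 99992 SNPs; most significant P = 1.93e-53
empirical FDR 0.001: P* = 1.27e-07 (the 100-th smallest neutral P)
candidates called: 193; planted loci recovered: 99/100
```

The threshold is the 100th smallest P value among 10⁵ SNPs simulated under
pure drift (Ne = 250, 15 generations) plus Pool-Seq noise — not a
parametric chi-square cutoff, which drift would render wildly
anti-conservative.  Of the 193 SNPs below P\*, 99 are the planted selected
loci; the remainder is the expected false-positive load at this FDR plus
drift-extreme sites.

The other examples each demonstrate one capability and print a short
interpretation: sync I/O and filtering (01), Ne estimation (03), the
singleton hitchhiking experiment (04), replicate-group concordance (05),
gene-set enrichment (06) and the full pipeline (07).

A thin CLI wraps the same functions for shell use:

```bash
erpool simulate --out study/ --seed 1
erpool scan --sync study/study.sync --samples study/samples.tsv \
            --treatment hot --out scan_hot.tsv
erpool candidates --sync study/study.sync --samples study/samples.tsv \
            --treatment hot --gamma 0.001 --out candidates.tsv
erpool run-all --out results/ --seed 1
```

## Layout

```
src/erpool/      io, cmh, neutral, nefdr, forward, concordance,
                 regions, enrichment, synth, pipeline, cli
examples/        one narrative script per capability
docs/methods.md  models, parameter choices, numerical details, limitations
tests/           unit + property + acceptance suites
```
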