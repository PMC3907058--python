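# Methods

`erpool` implements the statistical machinery of an evolve-and-resequence
(E&R) analysis: replicated populations adapt to novel environments for a
small number of generations, pooled whole-genome sequencing (Pool-Seq)
yields per-site allele counts at two time points, and putatively selected
SNPs are those whose frequency change across replicates is too consistent
and too large to be explained by genetic drift plus sampling noise.  This
note records the models, the parameter choices, the numerical details, and
the places where the design was genuinely open.

## Data model

The central observable is the `SitePanel`: per-site, per-sample counts of
A, T, C, G, N and deletions in the PoPoolation2 "sync" dialect (1-based
positions).  Coverage is the sum of the four nucleotide counts; N and
deletion counts never enter allele-frequency denominators.  All interval
inputs (inversions, recombination maps, gene models, introns) are 0-based
half-open, BED-style; converters are provided.  Allele frequencies
aggregated over samples are always coverage-weighted: sum of allele counts
over sum of coverages, which equals the unweighted mean only at equal
coverage.

## SNP calling and filtering

`filter_snps` applies three rules, each judged against the panel as given:

* **coverage rule** — a site is removed if its coverage in any sample
  exceeds that sample's upper 2% empirical coverage quantile (quantile
  computed per sample, i.e. per replicate and time point); repeat-region
  pile-ups manifest as coverage outliers;
* **minimum count** — the minor-allele count summed over all samples must
  reach 30 (default).  At the study's aggregate coverage this corresponds to
  roughly a 2% minor-allele frequency floor;
* **biallelic reduction** — at sites with more than two observed alleles the
  two highest-count alleles are kept; the site is dropped if the third
  allele exceeds 10% of coverage.  The 10% tolerance treats a sparse third
  allele as sequencing error and a substantial one as a genuinely
  multiallelic site the downstream 2x2 machinery cannot represent.

The per-sample coverage thresholds are stored in the panel's provenance and
reused when an identical filter is re-applied, making the operation
idempotent; without this, a re-applied top-2% rule would always shave a new
top 2%.

Rising-allele polarization compares the coverage-weighted frequency of each
site's two alleles between base and evolved samples; exact ties go to the
minor allele at base (deterministic, and the orientation in which change is
detectable).

## CMH scan

Each SNP contributes one 2x2 table per replicate — rows base/evolved,
columns the two alleles — and the Cochran–Mantel–Haenszel statistic

    X^2 = (|Σ_k (a_k − E[a_k])| − c)^2 / Σ_k Var(a_k)

aggregates the conditional-hypergeometric deviations across strata, with
P values from the chi-square(1) upper tail.  The continuity correction `c`
is off by default (flag available); the tests cross-check both settings
against `statsmodels.stats.contingency_tables.StratifiedTable` to machine
precision and the single-stratum case against the closed-form
Mantel–Haenszel chi-square.  Strata in which one time point has zero
coverage are dropped from that SNP's test; SNPs with no usable stratum are
excluded and counted.  Ranks order by (P, chrom, pos), a reproducible
permutation.  Base replicate i is paired with evolved replicate i; any
fixed pairing is valid under the null, and the pairing is configurable.

## Neutral null and empirical FDR

The null is a site-independent haploid Wright–Fisher model with N gene
copies: an (N+1)x(N+1) binomial transition matrix, raised to the t-th power
(t = 15 generations by default), gives the allele-count distribution after
drift conditional on the start frequency.  N is interpreted as gene copies
(a flag reinterprets a diploid-individuals figure as 2N copies); start
frequencies off the state grid round to the nearest state; dense matrices
are supported to N ≈ 5,000.  Simulated panels draw each SNP's p0 from the
empirical distribution of coverage-weighted base frequencies, then give
**each replicate an independent drift outcome** conditional on that shared
p0 — replicates are independent populations, and sharing the drift draw
would make the CMH null non-uniform — followed by binomial pooling noise at
both time points with coverages resampled per replicate and time point from
that sample's empirical coverage distribution.

Ne is estimated by least squares between observed and simulated
allele-frequency-change (AFC) histograms: 1%-wide bins centred on multiples
of 0.01 (201 bins over [−1.005, 1.005], so zero change falls in
[−0.005, 0.005) and drift-symmetric distributions give symmetric
histograms), proportions not raw counts (replicates may differ in SNP
number), summed squared differences per replicate, averaged across
replicates.  The best-fit Ne minimises the mean; the **conservative Ne** is
the smallest grid value within one standard error (across replicates) of
the best mean — "not significantly different" needed an operational
definition, and one SE is exposed as a parameter.  Choosing the smaller Ne
strengthens simulated drift and therefore makes the FDR threshold
conservative.

Candidates are called at empirical FDR γ: P* is the largest P among the
⌈γ·n⌉ smallest P values of a simulated null scan, and candidates are
observed SNPs with P strictly below P*.  Calling is calibrated: in
null-vs-null experiments the mean candidate fraction matches γ within three
binomial standard errors (acceptance suite, 50 repetitions of 1e5 SNPs at
γ ∈ {0.001, 0.01}).

## Haplotype forward simulator

`simulate_forward` evolves n diploids stored as 2n biallelic haplotypes.
Each offspring draws two distinct parents with probability proportional to
fitness; each gamete receives Poisson(map length in Morgans) crossovers
placed by the local cM/Mb density (no interference — map-scale fidelity is
what the LD questions need).  Fitness is multiplicative across selected
loci with **log-additive genotype fitnesses 1 : e^(hs) : e^s**.  At
h = 0.5 this makes the allele's odds multiply by exactly e^(s/2) per
generation at any frequency, so the conversion

    s = 2 ln(p1 q0 / (p0 q1)) / Δt

inverts the deterministic dynamics exactly (the linear form 1 : 1+hs : 1+s
agrees only to O(s²) and is ~11% off at s = 0.5; the worked example —
1% → 30% in 15 generations ⇒ s = 0.50 — holds exactly under the
exponential form).  The formula is oriented so a rising allele has positive
s.  Neutral marginals of the simulator are exchangeable with the transition
-matrix null at matched copy number (two-sample KS in the test suite).

Founder pools come from neutral coalescent simulations (msprime) at a
population scale chosen so founder LD is short-range (~hundreds of bp),
grouped into isofemale-like lines of two haplotypes.  Census populations
are assembled by cycling through the founder pool (equal representation)
with a random remainder.

Inversions are modelled as carrier flags on haplotypes: crossovers falling
inside the inversion interval are discarded in heterokaryotypic meioses
(absolute suppression, no gene flux — a documented simplification), and
carrier-private marker loci make inversion-frequency dynamics observable in
Pool-Seq output.

The **singleton experiment** selects an allele present on exactly one
founder haplotype (s = 0.5 by default), retains runs whose singleton rise
falls in the 25–35% inclusion band, pools accepted runs into replicates,
Pool-Seqs base and evolved populations, and scans with the CMH test.  Note
the band is an inclusion criterion, not a mean: at these parameters roughly
40% of runs lose the allele despite strong selection and the mean rise is
~0.2, with ~10–25% of runs in-band.  Under a ~0.1-Morgan map, top
candidates appear megabases from the selected site with median spacings far
beyond the species' ~200 bp LD range — long-range hitchhiking, the
mechanism by which one selected haplotype masquerades as thousands of
candidates.

## Concordance (modified ROC)

Two independent replicate groups (3 + 2 by default) are scanned separately;
concordance at rank cutoff k is the proportion of SNPs in both groups'
top-k whose rising allele is identical in all five replicates.  Pseudo-base
replicates for a group lacking its own base sequencing are manufactured by
pooling base counts, hypergeometrically downsampling to two-thirds of the
reads and splitting the draw in half (count-level stand-in for read-file
sampling; unbiased in frequency).

The chance reference deserves care.  A closed-form diagonal
(k/n × agreement rate) is reported for plotting, but it is **not** a
calibrated null: the two groups share each SNP's start frequency and
coverage structure, which couples their ranks even under neutrality, and
drift directions are not sign-symmetric at skewed frequencies.  (A
sign-symmetry argument — concordant vs discordant overlap exchangeable —
fails for the same reason; both constructions were measurably miscalibrated
on neutral data.)  The calibrated band is therefore Monte Carlo: simulate
matched neutral panel pairs, compute their concordance curves, and take
per-k quantiles (`simulated_null_band`).  This mirrors how the expected
degree of neutral reproducibility is quantified in E&R practice, and it is
exact up to Monte Carlo error: fresh neutral curves fall outside the 95%
band at ≈5% of grid points, while panels with planted selection exceed it
at every small k.

## Genomic regions and LD decay

High-LD masks are the union of inversion intervals expanded by 500 kb on
each side, recombination-map intervals with local rate strictly below
2 cM/Mb, and any extra blocks (e.g. a known selected haplotype block); the
complement is the putative low-LD genome.  Short-intron SNPs inside the
low-LD complement serve as neutral proxies, optionally excluding genes that
contain top candidates.

The Pool-Seq LD proxy around candidates is the decay of flanking
−log10 P values: flanking SNPs are assigned to non-overlapping 50-bp
distance bins (bin b covers [50(b−1), 50b), both flanks folded, the focal
SNP excluded, a SNP near two candidates contributing to both), and the
per-bin median is pooled over candidates.  The 95% band is a bootstrap over
focal candidates — a construction chosen here, documented as such.
Matched background draws the same number of SNPs per chromosome arm from
outside 200 bp of any candidate.

## Gene-set enrichment

Gene-level counting over coding regions only: a gene with any number of
candidate SNPs counts once.  Significance comes from permutations drawing
the same number of SNPs uniformly without replacement from the universe.
When genes are disjoint the null is sampled exactly and cheaply as a
multivariate hypergeometric over per-gene SNP blocks; otherwise explicit
draws are used.  P = (#{null ≥ observed} + 1)/(n_perm + 1) — the add-one,
greater-or-equal form guarantees validity and P > 0; strict-greater
counting is behind a flag.  The series runs over nested candidate sets
(2,000 to 100,000 in the default 21-point grid) and no multiple-testing
adjustment is applied across gene sets.

## Synthetic study generator

`generate_study` wires everything together with known ground truth:
coalescent founders, hot-selected loci drawn from rare founder alleles
(start frequency in (0.02, 0.15]; the 2% floor keeps planted alleles above
the SNP-calling detection limit and out of near-certain stochastic loss)
and cold-selected loci from intermediate frequencies ([0.2, 0.8]) —
emulating the observed skew of rising-allele start frequencies between
treatments — with s uniform on (0.2, 0.5); five replicates per treatment,
15 generations, Pool-Seq of a 500-individual pool at 35–90x.  Defaults
mirror the study design (113 lines x 2 haplotypes, census 1,000);
`StudyConfig.desk_scale()` compresses to one 5 Mb chromosome, 2x10⁴ loci
and census 200 so a full study generates in seconds.

What the desk scale does and does not show: compressing the genome to
~0.1 Morgans makes linkage relatively far stronger than at genome scale, so
the same multi-hit founder haplotypes win in every replicate and
consistently rising hitchhikers crowd the very top ranks.  Planted strong
loci concentrate in the top decile rather than dominating the top 1%, and
locus-level precision of FDR candidate sets is low even though recall and
calibration behave.  This is the long-range-LD false-positive mechanism the
package exists to study, not a defect of the scan — but it means passing
tests at desk scale say nothing about locus-level precision at genome
scale.  The site-independent generator (`simulate_replicated_panel`), where
planted recovery is ~99%, isolates the statistical machinery from linkage.

## Numerical and reproducibility notes

* Transition matrices use exact binomial pmfs; powers via repeated squaring
  with a per-(N, t) cache; rows sum to 1 within 1e−12.
* Drifted end counts are sampled by inverse CDF grouped by start state.
* All randomness flows through `numpy.random.Generator`; the pipeline
  expands one global seed into named per-stage substreams with
  `SeedSequence.spawn`, so stages are independently rerunnable and a rerun
  is bit-identical.  msprime seeds are derived the same way and kept below
  2³¹.
* Degenerate inputs: zero-coverage frequency requests raise; all-degenerate
  CMH tables are excluded and logged; an FDR level finer than the simulated
  null can resolve (γ·n < 1) raises with instructions to enlarge the
  simulation.

## Known limitations

* The neutral null is site-independent; linked drift is available only
  through the haplotype simulator.
* Recombination uses a Poisson model without interference; inversion
  suppression is absolute.
* The Pool-Seq model is count-level (binomial reads from pool frequencies);
  no sequencing-error or mapping model.
* Diploid populations are monoecious with distinct parents; no explicit
  sexes, so X-vs-autosome expectations are provided analytically rather
  than simulated.
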