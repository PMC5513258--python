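# Methods

This note documents the models, numerical choices and limitations behind
`radpara`. The package analyses per-site base-count piles (A/C/G/T read
counts per individual) over short reference RAD loci from a small panel of
diploid individuals, and ships a synthetic generator that reproduces the
biases collapsed paralogs imprint on such data.

## Read-emission model and genotype calling

All likelihoods share one emission model. A read drawn from a gene copy
carrying base *x* is observed as *x* with probability 1 − ε and as each of
the three other bases with probability ε/3 (a single symmetric error rate;
no substitution matrix, no *per-read* quality scores — input is counts).
For an unordered diploid genotype the two copies are sampled equally, giving
P(a) = 1 − ε for homozygotes {a,a} and P(a) = P(b) = (1 − ε)/2 + ε/6 for
heterozygotes {a,b}. The multinomial coefficient is omitted everywhere; it
is constant across genotypes at a fixed pile and cancels in posteriors and
likelihood ratios. Impossible configurations (e.g. a discordant read at
ε = 0) return −∞ rather than raising.

Calling uses a flat prior over the 10 unordered genotypes: no population
allele-frequency information exists at calling time in this pipeline, and the
reference pseudo-sequence is itself assembled from the same reads, so a
reference-biased prior would be circular. A genotype is emitted when the pile
depth is at least `min_depth` and the argmax posterior is at least `th1`
(default 0.95, the threshold used throughout). Because `th1` must exceed 0.5,
a called argmax is always unique; in internal posterior computations exact
ties (possible only below any sane `th1`) resolve to the lexicographically
first genotype (AA < AC < … < TT). Depth-0 piles report an all-zero
posterior.

Consequences worth knowing at low depth: a heterozygote seen as d:0 at depth
d ≤ 5 falls below `th1` = 0.95 and goes missing rather than being miscalled
(allelic dropout appears as missingness first, false homozygosity only from
depth ≈ 6), while a single error read in a depth-4 pile (1:3) *is* confidently
called heterozygous — low calling thresholds therefore inflate the SNP count
with error artifacts, one of the phenomena the depth sweep quantifies.

## Joint ML estimation of heterozygosity and error rate

Per individual, sites are modelled as a two-component mixture: heterozygous
with probability H, homozygous otherwise, with P_hom the equal-weight average
of the 4 homozygote likelihoods and P_het the equal-weight average of the 6
heterozygote likelihoods. The objective Σ log[(1 − H)P_hom + H·P_het] is
maximised over (H, ε) ∈ [10⁻⁸, 0.25]² by alternating bounded golden-section
sweeps from (0.01, 0.01), stopping when the objective improves by < 10⁻⁶
(inner tolerance 10⁻⁸ per sweep, cap of 100 alternations). Golden section is
derivative-free and bit-reproducible; the objective is smooth and in practice
unimodal in each coordinate. H is reported as the individual's θ — the
coalescent correction that maps observed heterozygosity to a population
mutation rate in the original shotgun-diversity formulation is deliberately
not applied, so "θ" here is per-site heterozygosity. Identical count rows
are collapsed with multiplicities before optimisation (piles repeat heavily),
which changes nothing numerically and makes 2×10⁵-site fits take ~1 s.

A separate pooled estimator maximises the flat-prior genotype-marginal
likelihood, Σ log[(1/10) Σ_g L(counts | g, ε)], over ε alone, pooling all
individuals and sites; its output is the plug-in ε for calling and for the
paralogy filter. Caveat: the flat prior puts 6/10 of its mass on
heterozygotes, which absorbs part of the error-read signal, so this estimator
is biased low by roughly 30% at ~10× depth (e.g. ε̂ ≈ 0.007 for a true 0.01).
The tests assert the bracket it actually achieves. The bias is harmless
downstream — calls and LRT flags are insensitive to ε at this scale — and the
joint (H, ε) mixture estimator above is the consistent route when the error
rate itself is the quantity of interest.

## The paralogy likelihood-ratio test

For a candidate SNP with allele pair (a, b) — the two most frequent alleles
among called genotypes; ties break lexicographically — two models are fitted
to the per-individual piles, each with one free parameter:

* **One locus.** Individual i's genotype is latent in {aa, ab, bb} with
  Hardy–Weinberg weights p², 2p(1−p), (1−p)²; the likelihood marginalises the
  genotype and maximises over p ∈ [0, 1].
* **Two loci.** The site is a fixed collapsed duplication: every read in
  every individual comes from the a-carrying copy with the same shared ratio
  r, i.e. per-read emission r·E_a + (1−r)·E_b, maximised over r ∈ [0, 1].
  A per-individual r variant is deliberately rejected: with 9 individuals it
  would add 8 degrees of freedom and destroy the single-parameter contrast.

Both optimisations evaluate a 1001-point grid (vectorised) and refine the
best grid cell by golden section to 10⁻¹⁰; the refinement never returns less
than the grid maximum. Individuals below `min_depth` at the site are excluded
from both likelihoods — they are treated as no evidence, not as evidence of
absence. Sites where fewer than two individuals pass are skipped: they carry
no flag and never mark a locus paralogous.

The statistic is Λ = max(0, 2(lnL₂ − lnL₁)). The models are non-nested, so
no asymptotic distribution is exact; the χ²(1) upper tail is used as a
pragmatic reference and its conservatism is verified empirically (on
paralog-free Hardy–Weinberg simulations at ≥10× the realised false-positive
rate is well under the nominal 1%). A site is `PARA` iff p < `th2` (default
0.01) *and* lnL₂ > lnL₁; a locus is paralogous iff ≥ 1 site is `PARA`.
Multiallelic sites test every biallelic sub-pair and take the largest
statistic; the site is `PARA` if any sub-pair is.

Intuition for the test's behaviour: at a balanced collapsed site every
individual's pile is ~50:50, and the one-locus model can explain each such
individual only through the heterozygote branch, paying its Hardy–Weinberg
weight — asymptotically ~log 2 per unambiguous individual — while r = 1/2
fits exactly; power therefore scales with the number of individuals passing
the depth filter, and ~5 clean heterozygous-looking individuals already cross
`th2` = 0.01. Conversely, at sites whose minor "allele" is scattered error
reads, the free r can concentrate three bases' worth of error probability
onto one base and occasionally beats the one-locus model; such error-artifact
`PARA` flags are a real (and intended-to-be-measured) behaviour of the filter
at permissive calling depths.

## Diversity statistics

Per site, over the n called individuals only (n varies by site; missing calls
are excluded, never imputed): H_O is the heterozygous fraction; H_S is Nei's
unbiased gene diversity (2n/(2n−1))(1 − Σ p̂²) over the 2n called gene
copies, summing over all alleles at multiallelic sites; F_IS = 1 − H_O/H_S,
undefined when H_S = 0; MAF is the frequency of the second-most-frequent
allele (0 when monomorphic), with rank ties broken lexicographically.
Sequence-level θ is the mean per-site H_S over every site of the locus set —
monomorphic sites included, so loci are length-weighted — with sites lacking
two called individuals contributing 0.

The locus/SNP summary reports, separately for paralogous and non-paralogous
locus sets: locus counts, percent monomorphic / with 1–2 SNPs / with > 2 SNPs
(these three sum to 100), SNP counts, percent bi- vs multiallelic, the number
of paralogous loci containing a passing SNP, and passing SNPs as a percent of
all SNPs on paralogous loci. Mean SNPs per locus is computed over polymorphic
loci by default (configurable): the paralogous column would otherwise be
incomparable since collapsed loci are never monomorphic.

## The depth sweep

`run_depth_sweep` repeats the full analysis over calling thresholds 2×–20×
(step 2; focal depths 4× and 18×): call genotypes, detect SNPs (a site with
≥ 2 distinct alleles among called genotypes — singletons count), run the LRT
at every SNP site, classify loci, and compute θ / MAF / F_IS with and without
paralogous loci. The plug-in ε is estimated once from all piles and reused
across depths so that depth effects are not confounded with error-rate
re-estimation. A locus is "analysable" at a depth if at least one of its
sites has ≥ 2 called genotypes; `pct_para` is paralog-flagged loci as a
percent of analysable loci, which is what rises sharply with the threshold
when collapsed loci carry elevated coverage. Depths beyond the coverage
report zero counts rather than erroring.

Distribution comparisons default to the two-sided Wilcoxon rank-sum
(Mann–Whitney normal approximation with tie and continuity corrections),
because the with- and without-paralog SNP sets differ in size; the paired
signed-rank variant is available for genuinely paired samples. All-tied
inputs return p = 1.

## The synthetic generator

The generator emulates the study design the pipeline targets: 9 diploid
individuals, 100-bp RAD loci, per-site segregation probability `theta_sim`
= 0.01. At a segregating site the derived-allele count i among the 2n
sampled gene copies follows the neutral folded site-frequency spectrum
(P(i) ∝ 1/i — the standard stationary shape a MAF distribution is compared
against), and genotypes are then drawn under Hardy–Weinberg at p = i/(2n).

A fraction `paralog_fraction` = 0.2 of loci are collapsed paralogs: the
reference locus conceals `copy_number` − 1 extra diploid copies, fixed in all
individuals (segregating duplications are not modelled). Each site is a
fixed difference with probability `paralog_divergence` = 0.02, where all
duplicate copies carry one alternate base; the reference base is the first
copy's base, and truth genotypes (recorded for the reference copy) stay
homozygous there — the heterozygote-like signal exists only in the pooled
pile. Per-site, per-individual depth is Poisson(`coverage_mean` ×
`copy_number`) for collapsed loci and Poisson(`coverage_mean`) otherwise,
independent across sites (no read-level linkage — the downstream model is
strictly per-site, so haplotype structure is out of scope); each read picks
one of the 2·`copy_number` gene copies uniformly and is mis-read with
probability `error_rate` = 0.005, uniformly to the three other bases.

Defaults: `copy_number` = 3 and `coverage_mean` = 8 per copy. Three copies
put collapsed loci at ~3× the coverage of single-copy loci, matching the
2.5–3.5× ratios observed on real repeat-rich RAD data (a single duplicate
caps the ratio at 2×); 8× per copy places single-copy loci below the 18×
focal threshold and collapsed loci (~24×) above it, which is the regime where
the composition of the analysed locus set — and hence detected paralogy —
shifts strongly between the 4× and 18× focal depths. At a 3-copy divergence
site the pooled allele ratio is 1:2, still called heterozygous at ~24× depth,
so the MAF-0.5 / negative-F_IS signatures are preserved.

`emulate_assay` replays the truth genotypes at segregating sites as an
individuals × SNPs table with independent entry failures at
`assay_fail_rate` = 0.05, standing in for a single-SNP genotyping assay.
SNP validation classes follow the cluster patterns: A (both homozygotes +
heterozygote), B (one homozygote + heterozygote), C (both homozygotes),
D (one homozygote), E (heterozygote only — the collapsed-paralog signature),
F (unreadable: readable fraction < 2/3, a stated surrogate for an
instrument-driven distinction), G (all entries failed); A–C count as
validated. Concordance between an in-silico matrix and an assay matrix is
percent agreement over entries called on both sides, plus the in-silico
missing rate over assay-called entries.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: restriction-site polymorphism and null alleles,
library-size variation between individuals, read-level linkage and haplotype
structure, indels, quality-score variation along reads, segregating (rather
than fixed) duplications, and reference/assembly error. Problem sizes in the
shipped tests and acceptance run (≈ 10³ loci × 100 bp × 9 individuals, 10
depth thresholds) were chosen as the smallest at which the sampling noise of
every reported rate is comfortably below its decision margin.

## IO conventions

Internal coordinates are 0-based throughout; VCF emission converts to
1-based. The pileup-TSV dialect is `locus_id  pos  ref` followed by four
integer columns `<ind>_A <ind>_C <ind>_G <ind>_T` per individual; positions
must cover 0..L−1 uniquely per locus. SNPs are emitted as VCF 4.2 with INFO
keys `PARA` (flag), `LRTS`, `LRTP`, `MAF` and per-sample `GT` (`./.` when
missing); the reference base must be among the site's alleles or emission
fails with a consistency error. Genotype matrices are TSV with `locus:pos`
rows; summaries, sweep tables and concordance reports are CSV; run manifests
(parameters + package versions) are YAML. All randomness flows from a single
integer seed, and identical configurations produce byte-identical outputs.

## Known limitations

* The χ²(1) reference for the non-nested LRT is a calibration, not a theorem;
  it is conservative on the simulations tested but has no finite-sample
  guarantee off those conditions.
* The pooled flat-prior error estimator is biased low (see above); use the
  joint mixture estimator for error-rate inference.
* The two-locus model assumes exactly one shared contribution ratio; mixtures
  of more than two collapsed copies with unequal rates are detected only
  insofar as they resemble the two-copy pattern.
* Between-population statistics (F_ST etc.) are out of scope: the design is a
  single panel of individuals.
* At permissive depths the SNP list intentionally includes error-artifact
  sites (singleton heterozygote calls); interpret `pct_para` at low depth as
  including the filter's response to those artifacts.
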