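# Methods

## Scope and model

`mrscreen` implements the two-sample summary-statistics MR workflow
for screening genes whose expression causally influences a disease,
plus the confirmation and follow-up stages that normally surround it.
The causal model is the standard instrumental-variable one: each SNP j
must associate with the exposure (expression), be independent of
confounders, and affect the outcome only through the exposure. Under
it, each instrument's Wald ratio β̂_out,j/β̂_exp,j estimates the same
causal effect θ, and the estimators differ in how they pool ratios and
in which violations they tolerate.

## Estimators

* **Wald ratio** (J = 1): β̂_out/β̂_exp, with the first-order
  delta-method se |se_out/β̂_exp|. Exposure-side noise is ignored here
  and in all first-order weights; with instruments passing F > 10 the
  attenuation this causes is small (see Known limitations).
* **IVW**: the summation formula in the README, algebraically equal to
  (a) the inverse-variance-weighted mean of Wald ratios with weights
  β̂²_exp/se²_out and (b) a weighted regression of β̂_out on β̂_exp
  through the origin — both identities are asserted in tests to 1e-10
  relative. Fixed-effect se by default; a multiplicative
  random-effects mode scales the se by max(1, √(Q/(J−1))) and is
  opt-in, because the plain formula contains no heterogeneity
  inflation. p-values are two-sided normal.
* **MR-Egger**: weighted regression with a free intercept after
  orienting every instrument to a nonnegative exposure effect (the
  intercept is meaningless without a fixed orientation; the flip is
  not configurable). Standard errors are scaled by
  max(1, √(RSS_w/(J−2))) and referred to t(J−2). The intercept and
  its p-value form the directional-pleiotropy test.
* **Weighted median**: per-SNP ratios weighted by the inverse
  first-order ratio variance, normalized; the estimate linearly
  interpolates ratio against (s_j − w_j/2) at 0.5 where s_j are
  cumulative weights. Note this interpolated estimator returns the
  majority-weight SNP's ratio exactly only in symmetric weight
  configurations; in general it lands between support points. The se
  is the sd of the estimate over n_boot = 1000 parametric-bootstrap
  redraws of both beta vectors from their sampling distributions
  (seeded, default seed 0, bit-reproducible).

## Sensitivity battery

* **Cochran's Q** = Σ w_j (r_j − β̂_IVW)² with first-order weights;
  chi-square on J−1 df. Under a homogeneous simulation it is exactly
  chi-square conditional on the exposure estimates, which the
  calibration experiment confirms (mean/df ≈ 1.01 at 1000 replicates).
* **MR-PRESSO**: the observed statistic is the unweighted residual sum
  of squares of each β̂_out,j against β̂_exp,j times the leave-one-out
  IVW estimate. The null distribution redraws both beta vectors from
  the no-pleiotropy model n_sim times (default 1000) and recomputes
  the statistic, leave-one-out refits included. Empirical p-values use
  (1 + exceedances)/(n_sim + 1) so they can never be zero; per-SNP
  outlier p-values are Bonferroni-multiplied by J and flagged below
  0.05. J ≥ 4 is required so every leave-one-out refit keeps ≥ 3
  SNPs. The distortion test of the reference method is out of scope —
  the screening protocol uses only the global and outlier tests.
* **Leave-one-out**: IVW refits dropping one SNP at a time; rows are
  flagged when the sign or the 0.05-significance of the estimate
  changes relative to the full fit.

## Instrument selection

Fixed stage order: cis-window restriction (gene body ± 5 kb by
default — unusually narrow for a cis definition, but kept as the
protocol's stated value and configurable), significance filtering,
greedy LD clumping, F > 10 (strict). Significance is BH-FDR < 0.05
within the gene's cis set in forward mode and raw p < 5e-8 in reverse
mode, where clumping also tightens to r² = 0.001. Clumping breaks
p-value ties by (position, snp id) so results are invariant to row
order; SNP pairs absent from the LD matrix count as unlinked with a
logged warning (a strict mode errors instead).

## Harmonization

Outcome records are aligned to the exposure's effect allele: direct
match, swap (beta sign flipped, frequency mirrored), strand complement,
or complement+swap; anything else is dropped with a reason. Palindromic
SNPs (A/T, C/G) are dropped when either trait's effect-allele frequency
is missing or within 0.08 of 0.5 (configurable window); otherwise the
frequencies' minor/major sides decide the orientation. Only biallelic
SNVs are accepted at read time; positions are 1-based inclusive.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors
lABF = ½[log(1−r) + r·z²], r = w/(w+v), with prior effect-sd 0.15 for
quantitative traits and 0.2 for case/control. Single-causal-variant
configurations are summed in log space; the H3 (distinct variants)
numerator sums the M×(M−1) off-diagonal pair terms directly by
log-sum-exp rather than subtracting exponentials, so it is stable even
when the two traits' signals nearly coincide. Priors default to
p1 = p2 = 1e-4, p12 = 1e-5; with M = 1 the H3 posterior is exactly
zero. Per-SNP H4 attribution is softmax(lABF₁+lABF₂). The regional
window is gene ± 500 kb, and PP.H4 > 0.80 (strict) declares
colocalization.

## Expression follow-up

Differential expression works on log2-scale matrices (counts are
log2(x+1)-transformed): log2FC = mean(A) − mean(B), Welch t-test by
default (rank-sum optional — the choice of location test is a
convention, not a protocol constant), BH across genes, significant iff
adj p < 0.05 and |log2FC| > 1. The fold-change gate is two-sided by
design so down-regulated genes are catchable. Genes constant in both
groups get p = 1. Correlation is Pearson with the exact t-transform
p-value (S−2 df). The high/low grouping splits samples at the median
of the target gene, ties to "high" (an unstated cutpoint in the
protocol; median is the assumption). Pre-ranked GSEA uses the running
sum with |score|^weight hit increments, gene-draw permutation nulls
(exhaustively enumerated whenever C(G, k) ≤ n_perm, in which case the
p-value is the exact enumeration probability), sign-matched empirical
p, NES = ES/mean|null ES of matching sign| and a sign-stratified NES
ratio FDR.

## The synthetic-data generator

Summary statistics are drawn directly from their asymptotic sampling
distributions; no individual-level genotypes exist anywhere. Defaults
encode the study conditions the pipeline targets: a blood cis-eQTL
exposure of n = 31,684; a discovery disease GWAS of 12,366 cases /
33,609 controls; a replication GWAS of 5,931 cases / 405,386 controls
(betas are log-odds; se = 1/√(2·maf(1−maf)·n·cf(1−cf)) for
case/control traits). Per-SNP expression variance explained is drawn
log-uniformly over one decade either side of its configured center
(default 0.003), emulating the skewed strength distribution of real
cis-eQTLs; `h2_spread_decades = 0` gives equal-strength instruments
for experiments that need to isolate single-SNP behaviour. Instruments
are coded to the exposure-increasing allele, the orientation against
which directional pleiotropy is defined — with random signs a
"directional" α would be sign-balanced after Egger orientation and
undetectable by construction. Pleiotropy adds α ~ N(mean, sd) to a
configurable fraction of instruments; outliers displace observed
outcome betas by a stated number of their own standard errors.
Simulated p-values are clamped at the smallest positive float because
strong eQTL z-scores underflow the normal tail.

Regional z-scores for colocalization are multivariate normal with a
block-diagonal constant-correlation LD matrix as covariance and mean
causal_z times the causal SNP's LD column. The screening panel gives
every gene two causal eQTL variants (variance explained 4% and 1%) in
different LD blocks (block size 5, ρ = 0.6); causal genes transmit
θ × (their marginal expression effects) to the outcome, so their
exposure and outcome signals share causal variants — the colocalizing
configuration — while null genes are eQTL-only. Reverse-MR inputs are
30 independent genome-wide-significant disease loci with null effects
on every gene's expression; both cohorts' reverse analyses share the
same expression-outcome statistics, as they do when two disease GWAS
are tested against one eQTL resource, which correlates the two reverse
p-values.

What the generator does **not** emulate: realistic human LD (only
block-constant correlation), allele-frequency/effect-size coupling
beyond the se formula, sample overlap between exposure and outcome,
population stratification, winner's-curse in instrument selection, or
multi-causal-variant regional architectures beyond two planted
eQTLs. Passing tests therefore certify the statistics and the
screening logic, not robustness to those real-data pathologies.

Every simulator is a pure function of its config (seed included); a
seed plus a small stream index feeds `numpy.random.default_rng` so
simulators never share draws.

## Experiment design notes

* The parameter-recovery experiment (θ = 0.3, J = 50, 500 replicates)
  is expected to show a sub-1% attenuation of the mean estimate from
  exposure-side noise (mean F ≈ 100 under the defaults); the observed
  mean is within 0.01 of the truth and CI coverage within [0.92,
  0.97].
* The pleiotropy-robustness experiment puts directional pleiotropy
  (α ~ N(0.12, 0.02), about 7 typical outcome se) on 30% of J = 100
  instruments. The Egger intercept's power is driven by
  √J / √(1 + 1/CV²(β̂_exp)); the decade-wide strength spread gives
  CV ≈ 0.64, sized analytically for >80% power before measurement.
* The outlier-detection experiment uses equal-strength instruments
  (`h2_spread_decades = 0`, J = 20, one SNP displaced by 10 outcome
  se). The leave-one-out influence ranking compares raw estimate
  shifts, which conflate displacement with instrument weight: when
  strengths span two orders of magnitude, dropping a very strong valid
  instrument can move the estimate more than the displaced weak one,
  so isolating the displacement requires comparable weights — the
  standard design in outlier-simulation studies. MR-PRESSO's per-SNP
  test is scale-matched and flags the outlier under either design.
* Monte-Carlo p-values, coverage and recovery rates in the acceptance
  experiments use 50–1000 replicates per quantity, chosen to keep the
  full recomputation around a minute on one CPU while leaving the
  binomial noise well inside each check's tolerance band.

## Numerical choices and degenerate inputs

Log-sum-exp everywhere in colocalization (posteriors sum to 1 within
1e-12 by construction); empirical p-values never zero by the
(1+k)/(1+n) estimator; Egger refuses J < 3, PRESSO J < 4, weighted
median J < 3, Q and leave-one-out J < 2; a zero exposure beta makes
the Wald ratio a hard error; an exact-fit Egger regression keeps a
positive se through the variance floor max(1, RSS_w/(J−2)); clumping
determinism is guaranteed by the stated tie-break; BH validates its
inputs to (0, 1].

## Known limitations

First-order weights ignore exposure-side noise (weak-instrument
attenuation grows as 1/F̄); the colocalization model assumes at most
one causal variant per trait per region (no SuSiE-style extension);
the screen's candidate gate is binary at fixed thresholds rather than
a decision-theoretic ranking; report plots are not generated (tables
only); LD is consumed, never estimated from genotypes; and the
multiplicity of the expression follow-up stages is controlled within
each stage, not jointly across the whole pipeline.
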