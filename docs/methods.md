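# Methods

## Design

The package implements the summary-statistics workflow used in
drug-target proteome-wide Mendelian randomization (MR): a genetic proxy
for pharmacological modulation of a target is tested against a disease
outcome, a proteome panel is screened for proteins driven by the
exposure (step 1), the driven proteins are tested against the outcome
with their own pQTL instruments (step 2), and the surviving mediators
are quantified by product-of-coefficients mediation, probed for reverse
causation, and checked for a shared causal variant by colocalization.
All estimators assume the three instrumental-variable conditions
(relevance, independence from confounders, exclusion restriction) and
two-sample summary statistics from non-overlapping cohorts.

## Harmonization

Published GWAS report effects on arbitrary effect alleles and strands.
Harmonization aligns every outcome record to the exposure's effect
allele with a deterministic truth table: identical allele pairs are kept
(beta negated and EAF complemented when the orientation is swapped),
complementary-strand pairs are strand-flipped first, and palindromic
(A/T, C/G) pairs — for which a strand flip is indistinguishable from an
orientation swap — are resolved by allele-frequency agreement, or
dropped as ambiguous when either trait's EAF lies in 0.5 ± 0.08. The
0.42–0.58 ambiguity window is the common community convention; it is a
parameter (`palindrome_eaf_window`). Coordinates are 1-based fully
closed; the canonical dialect is tab-separated with reals at 12
significant digits, making read(write(·)) an identity at that precision.
A beta/se–p-value consistency check (observed |z| within 10% of the
normal-implied |z|, with a 0.05 absolute slack near the null) warns by
default and rejects rows under a strict flag, since real summary files
mix imputation panels and rounded p-values.

## Instruments

Selection keeps variants with p below 5e-8 and MAF above 0.01, then
prunes greedily in ascending-p order (ties broken by variant id):
a candidate is accepted only if every already-accepted variant on the
same chromosome within 10 Mb has LD r² < 0.001 when a pairwise LD table
is supplied, or if no accepted variant lies within the window at all
when it is not — a deliberate distance-only fallback, since reference
LD panels are an external resource. Strength uses the R² formula above
(algebraically β²/(β² + SE²·n), so the EAF factors cancel; they are kept
for transparency) and F = (n−2)R²/(1−R²); F < 10 drops the variant.
Window bounds are closed, covering the boundary case exactly at the
window edge. cis-pQTL selection restricts to ±500 kb around the gene's
transcription start site first.

## Estimators

All estimators operate on per-SNP Wald ratios rᵢ with first-order
weights wᵢ = (β̂ₓᵢ/seᵧᵢ)². IVW is the weighted mean (equivalently a WLS
fit of β̂ᵧ on β̂ₓ without intercept, which the tests verify against
statsmodels to 1e-10); a single instrument reduces exactly to the Wald
ratio. The random-effects variant inflates the fixed SE by
√max(1, Q/(k−1)) — multiplicative overdispersion with a floor, chosen
over additive between-SNP variance because it reduces *exactly* to fixed
effects under homogeneity, matching the fixed/random switching rule
(random only when the Q p-value < 0.05 *and* I² > 50%). IVW p-values use
the normal reference; Egger uses t with k−2 df, standard practice.
Egger orients every pair so β̂ₓ ≥ 0 (making the fit invariant to the
arbitrary choice of effect allele) and frees the intercept, which
estimates average directional pleiotropy.

The weighted median uses the mid-step cumulative-weight convention,
(cumsum(w) − w/2)/Σw with linear interpolation between adjacent order
statistics — the only interpolating reading that reproduces the ordinary
median under equal weights. Mode estimators maximize a normal-kernel
density over the ratios with Silverman bandwidth 1.06·s·k^(−1/5) scaled
by φ (default 1, the main tuning knob); s is the weighted ratio SD for
the weighted mode. Median/mode standard errors come from a seeded
parametric bootstrap (default 1000 draws) redrawing every (β̂ₓ, β̂ᵧ) from
its sampling distribution; results are bit-reproducible given
(n_boot, seed).

## Sensitivity diagnostics

Cochran's Q sums wᵢ(rᵢ − fitted)² about the IVW mean (df k−1) or the
Egger line (df k−2); I² = max(0, (Q − df)/Q)·100, floored at zero. The
global pleiotropy test computes the observed residual sum of squares
where each variant's residual is taken about the IVW fit *excluding*
that variant, builds the null by redrawing all (β̂ₓ, β̂ᵧ) from
normal(fitted, se) (default 1000 simulations), and reports the add-one
smoothed p-value (1 + #{sim ≥ obs})/(n_sim + 1); per-variant outlier
p-values come from each variant's own simulated residual distribution
with Bonferroni adjustment at α = 0.05. The distortion test is not
implemented. Radial MR regresses rᵢ√wᵢ on √wᵢ through the origin
(first-order weights only); the per-variant squared radial residuals sum
identically to Cochran's Q, and outliers exceed the χ²(1) quantile at
α/k. Leave-one-out refits IVW k times under the effects model of the
full fit.

## Screening, mediation, reverse MR

Step 1 runs exposure→protein IVW (effects model by the Q/I² rule) for
every panel protein and applies Benjamini–Hochberg FDR at 0.05 across
the panel; proteins with no overlapping instrument are logged and
skipped, never fatal. Sensitivity gates (Egger intercept p, global
pleiotropy p, Q p) are *recorded* per protein rather than excluding —
mirroring reporting practice — and become exclusions under
`strict_sensitivity`. Step 2 instruments each surviving protein with its
own genome-wide pQTLs (the exposure's instruments are excluded from the
candidate list), applies FDR across the tested set, and computes a
direction-consistency flag: the IVW and Egger slopes must agree in sign,
zero counting as inconsistent; a disagreement drops the protein from
mediation, the rule that excludes a candidate whose Egger slope opposes
its IVW slope. FDR is applied within each step separately.

Mediation multiplies β₁ (step 1) by β₂ (step 2); the SE is the
independent-samples delta method √(β₁²se₂² + β₂²se₁²) with no covariance
term, appropriate for non-overlapping source cohorts, and the mediated
proportion β₁β₂/β₃ carries a three-term delta-method CI treating β₃ as a
third independent estimate. The proportion is a ratio estimator and
inherits mild finite-sample bias of order (se₃/β₃)²; at the default
conditions this is under 0.02. Reverse MR selects instruments from the
outcome's own summary statistics and runs the full battery against the
mediator; in realistic data (and in the default scenario) some mediator
pQTLs can reach genome-wide significance for the outcome through the
mediated path and enter the reverse instrument set — the diagnostics
(heterogeneity, radial outliers) are the intended guard, as no Steiger
filtering is implemented.

## Colocalization

Per-variant evidence is the Wakefield log-ABF with prior effect SD
0.15·sd_y for quantitative traits (sd_y taken from trait metadata or
estimated from the region as the median of se·√(2n·EAF(1−EAF)), exact
for standardized phenotypes) and 0.2 on the log-odds scale for binary
traits. Hypothesis weights use priors p1 = p2 = 1e-4 and p12 = 1e-5; all
sums are log-sum-exp accumulated, so posteriors stay finite for |z| well
past 60. H3's cross-term subtraction is a log-space difference and is
set to −∞ for a single variant (two distinct causal variants are then
impossible). PP.H4 > 0.70 is the default significance rule, exposed as
`h4_threshold`.

## Synthetic data

The generator emulates the statistical shape of the study design rather
than any real cohort: a standardized quantitative exposure at biobank
scale (n = 450,000) with six instruments whose true effects are sized
relative to their sampling SE (z ∈ [7, 12], F ≈ 50–145, since real
drug-target instruments are ascertained as genome-wide significant); a
plasma panel of standardized protein traits at n = 35,559; and a binary
outcome of 47,309 cases / 930,014 controls analyzed on the log-odds
scale with the case fraction entering the effective sample size. The SE
model se = 1/√(2n·φ(1−φ)·EAF(1−EAF)) (φ = 1 for quantitative traits)
makes the R²/F formulas exact on synthetic data by construction.
Observed effects are drawn independently per variant around their true
values, so generated (β, se, p) triples are exactly internally
consistent.

The default mediation chain is β₁ = 0.96, β₂ = −0.21, direct path
β_direct = −0.62 (total β₃ = −0.8216, mediated proportion ≈ 0.245),
one mediator in a 200-protein panel — a desk-scale stand-in for a full
proteome panel; panel size is configurable upward. Each protein carries
one cis-pQTL (effect sized to an expected F near 87) inside an
LD-correlated cis region (15 variants, exponential decay 4 in index
distance) plus seven trans-pQTLs on other chromosomes; the outcome has
twelve loci of its own so reverse MR has genuine instruments, with an
optional feedback slope for reverse-causation simulations. Allele pairs
are drawn once per variant (10% palindromic) and each non-exposure
trait's presentation is randomly orientation- and strand-scrambled, so
harmonization is exercised on every run; the MAF range (0.05–0.40)
keeps palindromic instruments outside the ambiguity window, making the
scrambling lossless. What the generator does *not* model: genome-wide
LD beyond the cis region, correlated sampling noise between variants in
LD (region draws use the proper multivariate model in
`simulate_coloc_region`; the scenario's cis region draws noise
independently per variant), sample overlap between traits, imputation
error, and allele-frequency differences between cohorts. Passing tests
therefore demonstrate correctness of the estimators and pipeline under
the stated sampling model, not robustness to those real-data
complications.

The colocalization region generator draws z-vectors from
MVN(λ·Σ[:,causal], Σ) with Σᵢⱼ = exp(−|i−j|/decay) (jittered by 1e-8 on
the diagonal if Cholesky fails), back-computing β and se through the
same SE model. λ = 8 at the shared causal variant gives PP.H4 > 0.7 in
effectively all replicates; two causal variants 16 indices apart at
decay 10 (r ≈ 0.2) put the mass on H3.

## Pipeline

Stages run in a fixed order — main MR, step-1 screen, step-2 screen,
mediation, reverse MR, cis colocalization — each seeded as
`seed + fixed offset` so adding a stage never perturbs earlier ones;
per-protein seeds inside the screens derive from a CRC of the protein id
so results are independent of iteration order. A failed or empty stage
is recorded with an explicit status and its dependents are skipped.
Report tables are TSV with 10 significant digits plus a JSON provenance
sidecar (config dict, SHA-256 config hash, seed, package version);
identical configs produce byte-identical tables. The exposure instrument
list is normally supplied by the user (drug-target instruments come from
prior studies); when absent, instruments are selected from the exposure
summary statistics with the standard criteria.

## Numerical and scale choices

Simulation sizes in the test suite (e.g. 200-replicate recovery and
coverage runs, 100-replicate calibration experiments, 1000-draw null
distributions) are chosen so Monte-Carlo error is comfortably inside the
asserted bounds while the whole suite runs in well under a minute of
simulation time per property. Degenerate inputs are defined explicitly:
identical ratios give Q = 0 and q_pval = 1; a zero bandwidth (all ratios
equal) returns the common ratio; a zero total effect makes the mediated
proportion an error rather than an infinity; a single region variant
sends PP.H3 to zero. I² is floored at 0, the random-effects inflation at
1, and p-values are clipped away from exact 0.

## Known limitations

No MR-RAPS/debiased IVW, multivariable MR, Steiger directionality
filtering, distortion test, SuSiE-style multi-causal colocalization, or
LD-aware conditional analysis; multi-allelic variants and genome-build
liftover are out of scope. The mediated-proportion CI uses the delta
method throughout; bootstrap or Fieller intervals would be preferable
when the total effect is weakly estimated.
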