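# Methods

## The problem

Primary diagnostic-accuracy studies of stress testing report sensitivity
(Se), specificity (Sp) and overall accuracy against invasive coronary
angiography, usually as percentages. Pooling them properly requires the
per-study 2×2 tables and a model that respects two facts: within-study
sampling error is binomial (and asymmetric near 0 and 1), and Se and Sp
vary jointly across studies — typically with negative correlation, because
studies implicitly operate at different thresholds. The package therefore
has two stages: recover integer 2×2 tables from printed summary metrics,
then fit a bivariate binomial–normal random-effects model.

## Reconstruction of 2×2 tables

For a study of size N with printed percentages (sen, spe, acc), every
candidate number of diseased patients D ∈ {1, …, N−1} implies
TP = round(sen·D/100) and TN = round(spe·(N−D)/100) (nearest integer, half
away from zero — used everywhere counts are implied by percentages). The
selected D minimizes the squared deviation, in percentage points, of the
implied Se, Sp and accuracy from the printed values; ties are broken toward
a balanced design (smallest |2D − N|), then toward smaller D. The residual
is returned with the table and rows above a configurable threshold
(default 25 squared percentage points) are flagged, not dropped.

The printed accuracy column over-determines the problem, which is what
makes the search well-posed; it also exposes transcription noise in the
source table. One packaged row (San Román 1996, dobutamine echo) prints an
accuracy that no integer table can approach (acc ≈ spe despite sen ≪ spe,
which would require near-zero prevalence); on that row an unconstrained
enumeration over all (D, TP, TN) disagrees with the constrained search.
The constrained search is the contract; the disagreement is confined to
that provably inconsistent row (asserted in the test suite).

## The bivariate model and priors

Within study *i*, with n_Di = TP+FN diseased and n_Hi = TN+FP non-diseased,

    TP_i ~ Bin(n_Di, expit(μ_se + φ_se,i))
    TN_i ~ Bin(n_Hi, expit(μ_sp + φ_sp,i))
    (φ_se,i, φ_sp,i) ~ N₂(0, Σ),   Σ = [σ_se², ρσ_seσ_sp; ρσ_seσ_sp, σ_sp²]

Priors: μ_se, μ_sp ~ N(0, sd 10) on the logit scale; penalized-complexity
priors on both SDs — exponential with rate λ = −ln(α)/u so that
P(σ > u) = α, default (u, α) = (3, 0.05); and z = atanh(ρ) ~ N(0, sd 5).
The "large variance" normals are made concrete at sd 10 (logit) and sd 5
(Fisher-z): effectively flat over the plausible range while keeping the
posterior proper. All are configurable. Prevalence is conditioned on, never
modeled: the likelihood only sees the strata sizes.

Pooled sensitivity and specificity are expit(μ_se) and expit(μ_sp),
computed draw-wise and then summarized (posterior median, mean, equal-tailed
95% interval).

## Sampler

An adaptive random-walk Metropolis-within-Gibbs sampler runs all chains
simultaneously as an array axis (default 4 chains × 10,000 iterations,
first half burn-in, i.e. 40,000 total iterations). Per iteration:

1. all study effect pairs at once (conditionally independent given the
   hyperparameters, so the update vectorizes);
2. the fixed-effect pair (μ_se, μ_sp);
3. an interweaved location move holding each study's total logit μ + φ_i
   fixed, so the likelihood cancels and μ can travel even when per-study
   data are sharp;
4. the log-SD pair and the Fisher-z correlation, each both in centered form
   (φ fixed) and in non-centered form (whitened effects u = L⁻¹φ fixed,
   with φ rescaled along the proposal) — the ancillarity–sufficiency
   interweaving that removes the funnel coupling between σ, ρ and the
   effects;
5. a fixed wide independence proposal on z in the non-centered space, which
   returns saturated |ρ| ≈ 1 excursions to the bulk in one move.

Hyperparameter blocks run five sweeps per iteration (they cost little next
to the likelihood). Proposal scales adapt by Robbins–Monro toward ~30%
acceptance during burn-in only. Numerical guards: 1 − ρ² is computed as
sech²(z); |z| is bounded at 12 (|ρ| < 1 − 10⁻¹⁰, no posterior mass beyond)
purely to avoid floating-point saturation. With a single study the
correlation is unidentifiable and must be fixed (ρ = 0).

Convergence is judged by split-chain R-hat on every hyperparameter with
threshold 1.05 (ESS via arviz); a failing fit is returned flagged with its
full diagnostics, never silently. The sampler was cross-checked against an
independent JAGS implementation of the identical model on real reconstructed
counts (pooled estimates and hyperparameters agree to ~0.001), and against
closed-form single-proportion grid posteriors in the degenerate
no-heterogeneity limit.

## SROC and AUC

The summary ROC curve is the conditional-expectation line of the fitted
bivariate normal mapped to ROC space:
Se(f) = expit(μ_se + ρ(σ_se/σ_sp)(logit(1−f) − μ_sp)). No HSROC
reparameterization is used. The AUC integrates the curve over the *full*
f ∈ [0, 1] by the trapezoid rule on a 1999-point grid (f = 0.0005…0.9995),
endpoints filled by the curve's analytic limits; this choice is deliberate
and documented because restricting to the observed FPR range is a common
alternative, so published AUC values are treated as soft checks only. The
reported AUC is the posterior median of draw-wise AUCs (computed on a
thinned subset of ~2000 retained draws) with an equal-tailed 95% interval.
Per-study display statistics use exact Clopper–Pearson intervals.

## Heterogeneity and publication bias

I² is computed per margin on logit proportions with fixed-effect
inverse-variance weights: Q = Σw_i(θ_i − θ̄)², I² = max(0, (Q − df)/Q).
A continuity correction of 0.5 is added to all four cells only when a table
contains a zero. The Bayesian fit has no native heterogeneity measure, and
the computing convention behind published I² values is typically unstated,
so I² serves as an order-of-magnitude diagnostic here.

The Egger test regresses the standard normal deviate θ_i/√v_i on precision
1/√v_i per margin (intercept ≠ 0 ⇒ small-study asymmetry, t test with k−2
df). The generalized bivariate combination stacks both margins into one
regression (separate intercept and slope per margin) and tests the two
intercepts jointly with a 2-df Wald statistic. The cross-margin dependence
of the intercepts is estimated from the stacked regression's
study-clustered covariance (each study contributes one observation per
margin); the diagonal uses the per-margin classical variances, because the
cluster estimate's diagonal is downward-biased at meta-analysis-sized k
(few clusters, high-leverage precision values) and makes the plain cluster
Wald liberal; and the statistic is referred to F(2, k−2) rather than
chi-square(2). Calibration is verified by simulation at the symmetric
operating point Se = Sp = 0.5 — where the logit effect and its estimated
variance are uncorrelated, so the precision regression is unbiased —
type-I error within (0.02, 0.09) at nominal 0.05, and ≥80% power at k = 40
against a size-dependent selection mechanism (small unfavorable studies
suppressed) in a small-study-dominated literature. Away from that operating
point the classical Egger regression on logit proportions is intrinsically
anti-conservative (the estimated variance co-moves with the estimate — the
reason effective-sample-size funnel variants exist); that behavior is a
property of the method family, documented rather than patched, and the
packaged-data asymmetry p-values should be read accordingly.

## Robustness analyses

Leave-one-out refits the model k times with derived seeds (base + index)
and reports the min/max envelope of the pooled estimates. Subgroup analysis
fits each stratum independently with identical priors and iteration budget
(asserted in tests); single-study strata are fitted with ρ fixed at 0 and
flagged. Grouping schemes: modality, technique-within-modality, sex
subgroup (female-only iff %female = 100; missing %female counts as mixed),
region (documented country→region map), period (publication year ≤2004 vs
≥2005) and design.

The descriptive "Overall" pooling mirrors the source table's own
convention — unweighted arithmetic means of printed per-study percentages,
rounded to one decimal — verified cell-by-cell; the sample-size-weighted
variant is always reported alongside because the two conventions disagree
and neither should be chosen silently. %female pools n-weighted and age
unweighted over non-missing rows, both flagged approximate.

## Synthetic cohorts

The generator forward-simulates exactly the model the sampler targets:
latent (logit Se, logit Sp) pairs from the bivariate normal (closed-form
Cholesky factor, so ρ = ±1 degenerates to an exact line), then binomial
counts given per-study strata sizes. The random stream is split per study
index, so enlarging a cohort never reshuffles earlier studies. Defaults
(prevalence 0.5, n = 100) match the parameter-recovery conditions used in
testing: 40 studies of 100 diseased + 100 non-diseased patients at
μ_se = 1.5, μ_sp = 1.0, σ = 0.3, ρ = −0.5.

What the generator does *not* emulate: threshold drift within studies,
covariate-driven heterogeneity (age, sex mix, stenosis cutoff), imperfect
reference standards, or publication-bias selection (available only as the
explicit size-dependent filter used by the Egger power check). Passing
recovery tests therefore demonstrates correctness of the inferential
machinery under the model's own assumptions, not robustness to their
violation in real data.

## Problem sizes and budgets

The packaged analyses fit 13–57 studies per subset; a full-budget fit takes
roughly 10–20 s on one CPU, and the complete reproduction script a few
minutes. Test-suite fits use reduced budgets (typically 4 × 2,000–3,000
iterations) chosen to keep each scenario's Monte-Carlo error well below its
assertion tolerance.

## Known limitations

- Reconstructed counts are best-fit, not ground truth; pooled estimates can
  differ from fits to the authors' extracted counts by a few hundredths
  (observed for the SPECT specificity).
- The correlation ρ is weakly identified in small subsets (a dozen
  studies); its posterior can span most of (−1, 1) and mixes slowest of all
  quantities.
- Printed accuracy columns in the source table contain internal
  inconsistencies; two of its thirteen "Overall" rows do not equal the mean
  of their own study rows (documented where asserted).
- The per-estimate p-values printed alongside pooled proportions in the
  source have no stated Bayesian definition and are not reproduced.
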