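# Methods

## Model

For participant i at visit t the ICV-normalised region volume is

    y_it = x_it' β + z_it' b_i + ε_it,
    ε_it ~ N(0, σ²),    b_i = (b_0i, b_1i)' ~ MVN(0, Σ),

with fixed-effects design x_it = (1, t_it, m_it, a_it, m_it·t_it,
a_it·t_it) and random-effects design z_it = (1, t_it).  Here t_it is age
standardised to mean 0 and sd 1 across all visit rows (n−1 denominator;
the constants are retained so slopes can be back-transformed to per-year
units by dividing by the age sd), and (m_it, a_it) are the MCI/AD
indicators taken per visit, so converters change design columns
mid-follow-up with HC as the reference level.  The two regions (lateral
ventricles, hippocampus) are fitted independently; the hippocampus
response is the ICV fraction scaled by 100 so its variance components are
not vanishingly small.

Assumptions: linearity in standardised age, Gaussian errors and random
effects, homoscedastic residuals, independence between participants, and
missingness ignorable given the observed data (the likelihood simply uses
whichever visits exist).  Observations within a participant are correlated
through b_i.

## Priors and why they are autoscaled

The semiconjugate family is

    β ~ N(μ0, V0),  σ² ~ Inv-Gamma(a0, b0),  Σ ~ Inv-Wishart(ν0, S0).

β stays diffuse (μ0 = 0, V0 = 10⁶ I).  For the variance components, fixed
"vague" constants cannot be vague at every response scale: ICV-fraction
variances range over 1e-6..1e-3, so a rate like b0 = 0.001 is of the same
order as the residual sum of squares of the ventricle model and would bias
σ² upward about two-fold, while an inverse-Wishart scale near zero combines
with the |Σ|^-(ν+p+1)/2 density factor to trap a weakly identified random-
slope variance at zero (the hippocampus slope variance is identified only
through the modest within-person age spread of ≤ 4.5 years).

The default is therefore an empirically scaled weak prior, the approach
popularised by regression packages that autoscale their default priors:

* S0 = diag(v̂0, v̂1), ν0 = q + 2 = 4, where (v̂0, v̂1) are moment estimates
  of the random intercept/slope variances from per-participant least-
  squares lines on the fixed-effects residuals (participants with ≥ 3
  visits).  With ν0 = 4 the prior mean of Σ equals diag(v̂0, v̂1) at the
  weight of roughly one pseudo-participant — enough to keep the posterior
  off the Σ = 0 spike, far too little to dominate 260 participants.
* a0 = 0.001 and b0 = 0.001 · σ̂², with σ̂² the pooled within-participant
  residual variance, making the prior contribution to the posterior rate
  negligible (≤ 1e-5 of the data term).

On the default synthetic cohort this recovers every variance component
(e.g. ventricle σ²: posterior mean 4.06e-6 vs true 4e-6; hippocampus slope
variance 1.6e-4 vs true 2.25e-4, within posterior uncertainty), which a
statsmodels `MixedLM` REML fit confirms independently.  Any explicit
`ModelSpec` overrides the autoscaling — that is the sensitivity-analysis
hook, and the conjugacy tests use it to pin σ² and clamp Σ.

## Gibbs sampler

The posterior is sampled by a blocked Gibbs sweep with exact conjugate
full conditionals (no Metropolis steps):

1. β | b, σ², y — multivariate normal with precision V0⁻¹ + X'X/σ²;
2. b_i | β, Σ, σ², y_i — bivariate normal per participant, precision
   Σ⁻¹ + Z_i'Z_i/σ², vectorised across participants in closed 2×2 form;
3. σ² | β, b, y — inverse gamma with shape a0 + n/2 and rate b0 + SSR/2;
4. Σ | b — inverse Wishart with df ν0 + N and scale S0 + Σᵢ b_i b_i'.

The inverse-Wishart draw uses a Bartlett factorisation assembled entirely
from triangular factors (Σ = B B' with B = chol(scale)·A⁻ᵀ), plus a
relative 1e-12 diagonal jitter, so draws remain numerically positive
definite even in degenerate noise-free test data; 2×2 inversions likewise
go through Cholesky factors rather than determinant formulas.  Failures
raise an error naming the update and iteration.

Chains start from dispersed values (least-squares β plus noise, variance
components jittered on the log scale).  The production schedule is 2
chains × 300K iterations, 100K burn-in, thinning 50 — 8 000 retained
draws; the test profile used throughout the suite and examples is 2 × 20K,
5K burn-in, thin 10 (3 000 draws), which converges cleanly on cohorts of
this size (all R-hat < 1.01).  Draws are pooled across chains after the
diagnostic passes.  R-hat is the classic between/within variance ratio,
computed for the six β, σ² and the three free entries of Σ; rank-based
summaries of b are not monitored.  Row order (participant-major, visit-
ascending) and 1-based visit indices are fixed; reproducibility is
distributional given seeds, not bit-wise across implementations.

## Synthetic cohort

The generator emulates the study design exactly at the deterministic
level: 157/34/42 stable HC/MCI/AD participants plus converters 8 (HC→MCI),
1 (HC→AD), 2 (HC→MCI→AD) and 16 (MCI→AD) — 260 in total; at most 4 visits
1.5 years apart; per-visit retention 260/241/210/179 (69% at the final
visit, 19 single-visit participants); converters always keep four visits
and switch diagnosis at fixed visits (MCI→AD at visit 4, the others at
interior visits; configurable).  Dropout is completely at random among
stable participants given the designed counts.  Baseline ages are
truncated-normal (mean 72, sd 6, support [60, 85]) — the age span analysed
— since the source study prints no age table.  Volumes are drawn from the
model above.

Default true parameters are calibrated study conditions, not estimates:
slope separations are sized so all pairwise posterior ordering
probabilities exceed the 0.65 benchmark decisively on one default cohort
(ventricle slopes positive and increasing HC→MCI→AD; hippocampus negative
and decreasing), and means/variances are sized so Gaussian volumes stay
within their physical ranges (every cell mean ≥ 5 sd above zero).  What
the generator does **not** emulate: non-linear age trends, informative
dropout, diagnosis misclassification, scanner/site effects, or any
covariates beyond diagnosis.  Passing tests therefore demonstrate
correctness of the machinery under the stated model, not robustness to
those real-data features.

## Derived inference

**Group ordering.**  Deterioration rates per draw are β1 (HC), β1+β4
(MCI), β1+β5 (AD), preserving joint alignment; differences are summarised
by posterior means and central 95% credible intervals (empirical 2.5/97.5%
quantiles).  The ordering probability P(a slower than b) is the fraction
of draws with a strictly below b in the region's severity direction
(larger = worse for the ventricle, more negative = worse for the
hippocampus; outputs state the convention).  Exact ties count as 0; they
have measure zero for continuous draws.

**Individual ranking.**  A participant's total slope per draw is
β1 + β4·m̄_i + β5·ā_i + b_1i, with (m̄_i, ā_i) the mean observed
indicators — converters are weighted by time spent in each diagnosis (a
`last`-diagnosis rule is available).  Ranking by the total slope rather
than the raw random effect b_1i is deliberate: b_1i is zero-centred within
group and cannot produce the diagnosis clustering that the ranking is
meant to expose.  Within every retained draw all N participants are ranked
(rank 1 = worst; stable sort, ties broken by participant id), giving exact
rank permutations per draw; the worst-q membership probability uses the
threshold ceil(q·N).  Single-visit participants are ranked too — their
slope posterior is shrunken toward the group mean and is wider than that
of fully observed peers but no wider than the population slope spread.

**Diagnosis trajectories.**  Centile curves (15/25/50/75%) of pooled
observed volume over raw age are quantile regressions on a cubic B-spline
basis (2 interior knots), made monotone along age by rearrangement
(sorting fitted values over the grid — the identity for already monotone
curves) and non-crossing by rearrangement across centiles, then clipped to
the observed volume range; the top band is capped at the empirical
maximum.  Band probabilities P(V ∈ R | Dx, age) are new-individual
posterior predictives: per retained draw, the fixed-effects mean plus a
fresh random-effect pair from MVN(0, Σ_m) and residual noise (a
population-mean-only variant exists for sensitivity).  Bayes' rule then
combines them with a prevalence table P(Dx | age), linearly interpolated
between knot ages 60..85 and renormalised.  If every diagnosis has band
probability zero the posterior is undefined and an error is raised rather
than silently normalising — this can legitimately happen at the exact grid
boundary ages where adjacent centile curves may touch, so trajectory grids
are best evaluated at interior ages.  The shipped prevalence table is a
synthetic stand-in (HC declining from 0.95 at 60 to 0.62 at 85, AD rising
to 0.20) because the published age-specific rates are not redistributable;
users supply their own via CSV/config.

**Monte Carlo SE.**  The full pipeline (fit → band probabilities → Bayes
inversion) is repeated K = 10 times with independent seeds; the point
estimate is the replicate mean and the interval mean ± 1.96·sd of the K
estimates — a deliberately conservative spread (no √K division), since the
exact interval convention of the original analysis is not published.
Replicates with max R-hat ≥ 1.1 are rejected, logged and re-run with a
fresh seed.

## Validation

The posterior-predictive check replicates the whole data-generating
process per draw (fresh random effects and residuals) and reports the
fraction of observed responses inside central 95% predictive intervals;
on well-specified data this calibrates to ~0.95.  A conditional variant
that reuses each participant's own posterior random-effect draws is also
provided; it is structurally conservative (coverage ≈ 0.999 even for a
perfect model, because b_i is inferred from the very observations being
checked with only ≤ 4 visits against 2 random effects) and is useful only
for spotting gross misfit.

Two cross-validation schemes: subject-level LOOCV removes all of a
participant's visits and predicts from posterior-mean fixed effects only
(a new subject's random effects are unobservable; their prior mean 0 is
the standard choice); observation-level LOOCV removes one random visit per
participant with ≥ 2 visits in a single refit and predicts with the
participant's posterior-mean random effects.  Both report MSE in response
units.  LOOCV refits use the reduced schedule — at hundreds of refits the
production schedule would be pointless MCMC overkill, affecting only Monte
Carlo error.

## Problem sizes and numerical choices in the test suite

The suite generates all data programmatically.  Fits on the default
260-participant cohort use the 2 × 20K test schedule; the β-coverage study
uses 20 replicate cohorts at 2 × 10K iterations (2.5K burn-in, thin 10),
which leaves quantile estimates with ~1 500 draws per fit — ample for a
95% interval; smaller structural tests use 18–42-participant designs with
chains of 1.5–6K.  Tolerances follow the estimand: 3 Monte Carlo SEs for
posterior means, 10% Frobenius error for the conjugate covariance at
M = 4 000 i.i.d. draws, binomial bands for coverages, 1e-12 for exact
arithmetic, and an absolute 0.08 for the prevalence-recovery limit
(posterior-estimation error of the diagnosis offsets with ~120
participants per group plus band-probability Monte Carlo noise).

## Known limitations

* The linear-in-age mean is the modelled structure; curvature in real
  trajectories is not captured (and is out of scope here).
* Quantile curves are unpenalised spline fits; their boundary behaviour at
  ages 60 and 85 is noisy, which the rearrangement pushes to the grid ends
  rather than removing.
* Variance-component priors are empirically scaled; analyses that need a
  strictly data-independent prior should pass an explicit `ModelSpec` and
  check sensitivity.
* The prevalence table, and hence every trajectory probability, is
  synthetic by default; conclusions about real populations require real
  prevalence inputs and real cohort data.
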