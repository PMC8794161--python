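# Methods

## The estimand and the trial pipeline

Each trial of the RSVP task yields two correctness flags. T2|T1 accuracy in
a cell (participant × session × polarity × block × lag) is the proportion
of T2-correct trials **among T1-correct trials**; cells with no T1-correct
trials carry an explicit undefined value (NaN) that downstream steps refuse
to consume — nothing is imputed. AB magnitude is the long-lag minus
short-lag T2|T1 accuracy of a block; change scores are tDCS−baseline and
post−baseline per polarity; the target statistic is the partial correlation
of the anodal and cathodal tDCS−baseline deltas, with session order (which
polarity came first) as a single binary covariate.

Pipeline rules and the conventions behind them:

- **Exclusion**: a participant is dropped when first-session mean T1
  accuracy — trial-weighted across blocks and lags (total T1-correct /
  total trials) — is *strictly below* 0.63; exactly 0.63 is retained. The
  source criterion states only the cutoff; trial weighting is the natural
  reading when block trial counts vary (the blocks are time-limited), and
  reading "too low" as strict keeps the printed cutoff admissible.
- **Lag harmonization**: the earlier three-lag design (2/4/10) is mapped to
  the two-lag scheme by relabelling lag 10 → 8 and emitting a synthetic
  lag-3 row whose T2|T1 accuracy is the *unweighted* mean of the lag-2 and
  lag-4 accuracies (the blink falls off roughly linearly across those
  lags). Counts are summed for bookkeeping, but the synthetic row's
  accuracy is deliberately not the ratio of its counts.

## Correlation inference

Partial correlation = Pearson correlation of residuals after least-squares
projection of both variables on the covariates plus intercept. Degrees of
freedom are n−2−k with a t reference for p-values; confidence intervals
use the Fisher-z scale with variance 1/(n−3−k), the standard result for a
partial correlation with k covariates — this reproduces the replication
study's printed 95% CI of [−0.30, 0.33] at (r = .02, n = 40, k = 1). No
small-sample bias correction of r is applied. Constant covariate columns
are absorbed by the intercept (dropped, reducing k); collinearity of a
variable with the covariates is an error, not a silent zero.

## Replication metrics

**Small telescopes.** The SESOI is the positive r at which the two-sided
α = .05 correlation test on the original design (n = 34, k = 1) has power
1/3 under the Fisher-z normal approximation, including the far-tail
rejection term; solved by Brent bracketing to |Δpower| < 1e-8. The
inferiority test then asks whether the replication estimate is
significantly less negative than −r33%, one-sided in Fisher-z space;
equivalently, significance at α corresponds to the (1−2α) CI excluding
−r33%. When reproducing published analyses the bound is used at its
conventional two-decimal rounding (.27) by default (`sesoi_decimals`),
since published bounds are stated at that precision; the unrounded solution
is available. Note the rounded-vs-unrounded choice moves the example
p-value only within ±0.002.

**Prediction interval.** The closed form treats the difference of the two
studies' Fisher-z estimates as normal with variance
1/(n_orig−3) + 1/(n_rep−3). A simulation method is also provided: draw the
original's Fisher-z uncertainty, then draw a replication sample correlation
from the exact finite-sample distribution at that population value
(simulated as the sample correlation of n_rep bivariate-normal
observations, which *is* that distribution), and take empirical quantiles
over ≥200k seeded draws. The two methods agree to ~0.01 at these sample
sizes; both are offered because published PI software implementations vary
and at least one printed interval in this literature is reproduced by
neither closed form.

**Exact density of Pearson r.** Implemented in log space via the
Gaussian-hypergeometric form

    f(r|ρ,n) = (n−2)Γ(n−1)/(√(2π)Γ(n−½)) · (1−ρ²)^((n−1)/2) (1−r²)^((n−4)/2)
               · (1−ρr)^(−(n−3/2)) · ₂F₁(½, ½; n−½; (ρr+1)/2),

valid for non-integer n. It integrates to 1 to 1e−6 and matches 100k
directly simulated sample correlations (χ², 20 equal-probability bins).

**Replication Bayes factor.** BF_0r compares a skeptic's ρ = 0 against a
proponent whose prior is the original study's posterior under a
uniform(−1, 1) prior. Covariate adjustment enters as effective sample
sizes n−k in the exact density (the Fisher variance convention n−3−k
translated to the density's df). Integration is adaptive quadrature with
breakpoints at the posterior mode ±3, ±10 posterior SDs (so spiked
posteriors from very large n are not missed), relative tolerance well below
1e−6; a fixed 4097-point Simpson grid is available for bulk simulation and
agrees with quadrature to 1e−6 relative. How the original analysts' tooling
treated the covariate inside the BF is not determinable from summaries
alone; the n−k convention shifts the example BF by a few percent relative
to ignoring k.

**Meta-analysis.** Fixed effects only, by design: with two highly similar
studies from one population the estimand is the effect *in this pair of
studies*, and between-study variance is not estimable. "Weighting by sample
size" is implemented as inverse-variance weights in z-space, w = n−3−k;
pure-n weights move the pooled r by < 0.01 here. The pooled p uses the
normal reference; conventions for the pooled p differ across packages by
~0.01, so only the estimate and CI are emphasized.

**Pooled re-analysis.** Trial-level concatenation after harmonization,
requiring disjoint participant labels. The p-value is intentionally
withheld (`p = None`): re-testing after augmenting a sample is sequential
testing and would not control the error rate.

## The synthetic-data generator

The generator emulates the study conditions, not merely a convenient toy:
40 participants (18 anodal-first), three blocks × two sessions, 130
short-lag and 65 long-lag trials per block (fixed, not drawn — the
self-paced timing variation in real blocks is irrelevant to the estimators
under test), T1 accuracy mean .82, T2|T1 means .44 (short) and .83 (long),
matching the published descriptives. The latent model is logit-additive:

- per participant, baseline short-lag, long-lag and T1 logits are drawn
  around the population means with a common between-subject SD of **0.7**
  (chosen once from the published descriptive SDs: ≈0.17 on the proportion
  scale near p ≈ .45 corresponds to ≈0.7 logits);
- a bivariate-normal effect pair (δ_anodal, δ_cathodal) with SD **0.4**
  (≈0.10 on the proportion scale, the order of the observed change-score
  spread) and correlation `rho_true` (default −.45, the original estimate)
  is added to the short-lag logit during the matching polarity's tDCS
  block, and at full strength in the post block by default
  (`post_decay = 1`, configurable — the studies computed post−baseline
  scores without committing to an aftereffect size);
- a **0.2**-logit practice improvement applies to the short lag in
  session 2, mirroring the reported learning pattern;
- trial outcomes are independent Bernoulli draws given the cell
  probabilities (clipped to [.01, .99], clips logged). T2 correctness is
  drawn independently of T1 because only the T2|T1 conditional is
  identifiable from the scored task.

With these settings the generator incidentally reproduces the study's
exclusion behavior: the T1 between-subject spread puts roughly 5–10% of
simulated participants under the 63% cutoff, close to the 6/48 observed.

What the generator does **not** model: lag-specific psychometric curves
(lag 2 vs 3 difficulty enters only through the configured means),
RSVP timing, response-string scoring, session-to-session drift beyond the
single learning term, and any EEG signal. Passing parameter-recovery tests
therefore shows the estimators are consistent for this latent-logit data
generating process — not that the real studies' effects are real.

Because change scores are differences of noisy proportions, binomial noise
attenuates the observable correlation: at the design's 130/65 trials a true
ρ = −.45 yields an expected recovered partial correlation around −0.19
(see `attenuation_curve` and `analysis/04_attenuation.py`). This is a
feature of the design being emulated, and it is why parameter-recovery
tests assert sign and interval exclusion rather than unattenuated recovery.

## Problem sizes and numerics

Simulation-based checks use sizes chosen to make Monte-Carlo error a small
fraction of the tolerance being asserted: 20k replicates for CI coverage,
power and p-uniformity checks (MC SE ≈ 0.15–0.35% on a 95% rate), 50k for
two-study prediction-interval coverage, 100k draws for the density
goodness-of-fit, 200k draws for simulation PIs, and 500 replicate datasets
for full-pipeline parameter recovery. All are seeded; the generator is
byte-deterministic given its config.

Tie-breaks and degenerate inputs: exclusion retains the boundary case;
zero-T1-correct cells are errors downstream, never zeros; `effect_sd = 0`
and `rho_true = ±1` use an explicit Cholesky factor so the degenerate
covariance is exact; root finding brackets arctanh(r) in (1e−12, 10).

## Known limitations

- Summary-level metrics inherit the Fisher-z normal approximation; for
  n < ~15 the exact-density methods (BF, simulation PI) are preferable.
- The battery treats the original estimate as a fixed summary; it cannot
  correct for selection on significance in the original study.
- The pooled re-analysis assumes the harmonized short-lag proxy is
  comparable across designs; that is an approximation justified by the
  near-linear lag profile, not a measurement identity.
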