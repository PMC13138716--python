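# Methods

## Model

`steptraj` fits a latent class mixed model (a growth mixture model with
class-specific fixed effects and shared variance components) to weekly mean
daily step counts. Conditional on membership in latent class
g ∈ {1, …, G}, participant i's weekly mean at elapsed week t_ij is

    Y_ij | g = b0_g + b1_g t_ij + b2_g t_ij² + u_i + e_ij,

with a person-level random intercept u_i ~ N(0, σ_u²) and independent
residual e_ij ~ N(0, σ_ε²). Class membership follows a multinomial logit
with intercepts γ_g (γ_G ≡ 0), giving priors π_g = softmax(γ)_g.

Assumptions worth stating explicitly:

* the random intercept and residual variances are **shared across
  classes** — heterogeneity between classes lives entirely in the mean
  curves; a class-specific σ_u would change the covariance structure and is
  deliberately out of scope;
* the mean curves are quadratics in elapsed weeks (degree fixed at 2);
* no covariates enter the membership model and there are no random slopes.

Integrating u_i out, each participant's series is multivariate normal with
compound-symmetry covariance σ_u²J + σ_ε²I. All densities use the rank-one
closed form (inverse (I − aJ)/σ_ε² with a = σ_u²/(σ_ε² + Tσ_u²); log
determinant (T−1)log σ_ε² + log(σ_ε² + Tσ_u²)), so likelihood evaluation
is O(T) per participant and never forms a dense T×T matrix. Unbalanced
series (different T per participant) are supported; participants are
grouped by identical week vectors for vectorized evaluation.

## Estimation

Maximization of the mixture marginal log-likelihood proceeds in two
phases:

1. **EM.** E-step: Bayes-rule responsibilities in log space. M-step: the
   class curves solve a responsibility-weighted generalized least squares
   system (exact, via the compound-symmetry inverse); the membership
   logits are the log responsibilities means; the two variance components
   maximize the expected complete-data log-likelihood by a Nelder-Mead
   search on (log σ_u, log σ_ε), accepted only if it improves the
   objective. Every accepted iteration therefore cannot decrease the
   marginal log-likelihood; if floating-point noise produces a decrease
   the previous iterate is restored and the loop stops. Convergence:
   relative log-likelihood change below 1e-8, at most 500 iterations.
2. **Newton polish.** A damped Newton ascent on the full parameter vector
   (curves on a time scale mapped to [0, 1] for conditioning, free logits,
   log standard deviations) with finite-difference gradient and Hessian.
   The Hessian is ridged Marquardt-style: the ridge shrinks tenfold after
   an accepted step and grows tenfold after a rejected one; only steps
   that increase the log-likelihood are accepted. At most 25 iterations or
   until the gain falls below 1e-7.

Initialization fits each participant's own quadratic by least squares and
clusters the coefficient vectors with k-means into G groups; additional
starts (default 3, 2 in the large simulation studies) jitter the cluster
centers with a seeded generator. The best start by final log-likelihood is
polished. Label switching is resolved by re-ordering classes by descending
mean fitted curve level over the study window; modal-assignment ties break
toward the lowest (highest-level) class index. BIC uses k = 3G + (G−1) + 2
free parameters.

## Class-number selection and labeling

Candidates G = 1..5 are fitted; a candidate is admissible when every class
holds at least 5% of participants by modal assignment and every class's
mean posterior among assigned members is at least 0.90 ("approximately 90%"
is implemented as the literal cut, configurable). Among admissible
candidates the minimum-BIC model wins; exact ties go to the smaller G
(parsimony — a tie never arises in practice but the rule must be total).

Archetype labels are a rule, not an inspection: a fitted quadratic is FLAT
when its range over weeks 1..T is less than 10% of its mean level
(configurable; the published FLAT class changes <1% between half-years
while UP changes ~37%, so the margin is wide); otherwise the endpoint
slopes s(1) and s(T) decide — both ≥0 UP, both ≤0 DOWN, positive-then-
negative UP_DOWN, negative-then-positive DOWN_UP. DOWN_UP completes the
rule even though no such class appeared in the motivating cohort.

## Preprocessing

* Dual-platform duplicates: one record per participant-day, larger value
  wins (ties collapse to the common value).
* Range filter: days with fewer than 200 or more than 50,000 steps are
  dropped; 200 and 50,000 themselves are kept (strict inequalities).
* Checkup pair: the first checkup paired with the later checkup whose
  calendar-month interval lies in [10, 14] months and is closest to 12
  (day-of-month arithmetic, clamped to month ends; ties to the earlier
  date). Week 1 starts the day after the first checkup — the checkup day
  itself is excluded.
* Weekly series: week j covers days 7(j−1)+1..7j; the mean uses available
  days; any empty week excludes the participant; series are truncated at
  56 started weeks; a partial final week counts if it has ≥1 day.
* Variance filter: participants whose daily-step variance exceeds c times
  the pooled variance of all retained daily records are excluded. The
  comparison statistic behind this filter is genuinely ambiguous, so c is
  exposed (default 1, the literal reading; +inf disables it).
* Cohort: baseline BMI ≥ 25 kg/m² and age 40–74, boundaries inclusive;
  every exclusion is counted and reported.

## Outcome analysis

The outcome is an inclusive relative loss (pre − post)/pre ≥ 0.03 between
the checkups. Odds ratios come from a logistic regression (statsmodels
IRLS) of the outcome on class dummies with FLAT as reference, adjusted for
age (years), sex, mean daily steps per 1,000, smoking and medication use;
95% CIs use exp(b ± 1.959964·se) and p-values the Wald statistic.
Complete-case handling; separation or non-convergence raises an error
naming the offending term. The sensitivity analysis refits on the
medication-free subset without the medication term. Tabulated percentages
round half-up to one decimal.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: four
archetype classes (DOWN, UP_DOWN, FLAT, UP) with shares 355/193/2045/185
out of 2778 (≈0.128/0.069/0.736/0.067), quadratic mean curves derived in
closed form from the published per-class period means (weeks 1–28 vs
29–52; DOWN 8023.8→6278.0, UP_DOWN 7347.1→7763.0 with its turning point
placed at week 32, FLAT 5243.2→5270.2, UP 6469.0→8894.1 steps/day), a
Gaussian random intercept (SD 2000 steps/day), daily Gaussian noise (SD
1500 steps/day), 5% missing days, 1% low and 0.2% high artifact days
(uniform on [0, 199] and [50,001, 80,000]), and 2% dual-device duplicate
days whose second record is a uniform 30–100% fraction of the first.

The noise SDs are not published; they were calibrated once so the default
cohort reproduces the published classification regime — every class's mean
posterior ≈0.90 or higher with the 4-class model minimal in BIC — while
the between-person spread stays in the range of the published within-class
step-count SDs (≈2,800–3,950 steps/day, which mix intercept and curve
spread). Genuine (non-artifact) days are rounded and clipped into
[200, 50,000]: the clip keeps the injected artifacts exactly identical to
the out-of-range record set (useful ground truth for the range filter) at
the cost of a slight upward bias (<1%) in the weekly means of rare
low-intercept participants.

Covariates mimic the published margins: age ~ N(65, 8.1) clipped to 40–74,
57.6% men, 7.5% smokers, 63.8% on medication, pre-weight ~ N(72.1, 9.8),
BMI truncated-normal (27.2, 2.3) at ≥25. The binary outcome is drawn from
a logistic model with FLAT base rate 22.3% and class log odds ratios
ln 0.92 / ln 1.12 / 0 / ln 2.45 (DOWN/UP_DOWN/FLAT/UP) plus small centered
covariate effects (−0.005 per year of age, +0.05 for men, +0.01 per 1,000
steps, −0.05 for smoking and medication). Post-weight is generated from
the drawn binary outcome (relative loss uniform on [3%, 12%] for events,
on (−10%, 3%) otherwise) rather than from a continuous weight model — the
analysis only consumes the flag. Randomness flows through per-participant
substreams keyed by (seed, participant index), so growing or subsetting
the cohort never changes existing participants.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: app-usage behavior (missingness is
independent Bernoulli, not behavior-driven), calendar effects (seasons,
weekends, epidemic waves), autocorrelated daily noise, occupational or
dietary confounding, and any continuous dose-response between steps and
weight change beyond the configured log-odds.

## Problem sizes and numerical choices

The simulation studies use N = 400 participants × 52 weeks with 2 EM
starts per candidate G, and 20 replicate cohorts for the class-number
selection experiment — large enough for the smallest class (~27 expected
members) to clear the 5% rule in most replicates while keeping a full
search over G = 1..5 fast. In roughly one replicate in ten the smallest
true class simply samples below the 5% modal-share rule at N = 400; the
selection then honestly returns 3 classes. That is a property of the
prescribed shares and cohort size, not of the optimizer.

Degenerate inputs: empty classes during EM have their priors floored at
1e-10 before renormalization; σ_u may go to 0 (the fit degenerates to
independent residuals); σ_ε = 0 is rejected as singular. Posterior rows
are validated to sum to 1 within 1e-10.

## Known limitations

* The EM + damped-Newton scheme is this package's own faithful-contract
  reading of "modified Marquardt + Newton-Raphson" maximization; it is not
  a port of any existing mixed-model software, and on multimodal
  likelihoods different initializations can reach different local optima
  (hence multi-start).
* The published adjusted odds ratios (2.45, 0.92, 1.12) were estimated on
  a private cohort; the package verifies its estimation machinery against
  closed forms, independent optimizers and coverage simulations, not
  against those cohort-specific values.
* Two fitted classes can in principle receive the same archetype label;
  downstream dummy coding then merges them.
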