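# Methods

## Data

The built-in cohort encodes the 14 randomised trials of corticosteroids
versus control in severe sepsis / septic shock (1963–2008) as published:
per-outcome 2×2 tables (hospital mortality, shock reversal, superinfection,
GI bleeding, new-onset hyperglycemia, and shock reversal by corticotrophin
responder status where reported), arm mean ages, hydrocortisone-equivalent
total dose and days of exposure. Two transcription points deserve note:

* The mortality-table arm denominators of four trials differ from their
  published enrolment numbers (most visibly Klastersky: 66 + 39 = 105
  analysed vs 85 enrolled, unexplained in the source); the package pools
  the outcome-table counts as printed and keeps enrolment (`total_n`,
  summing to 1,991) as separate metadata.
* One trial (Tandan 2005) reports no dose metadata; its low-dose label is
  fixed from the published grouping.

Dose classification divides the total hydrocortisone-equivalent dose by
the total days of exposure *including tapering* and calls a trial
high-dose when that exceeds 1,000 mg/day. Counting taper days matters for
exactly one trial (CSG 1963: 1,050 mg over 1 day plus 2–6 taper days),
and is what makes the rule reproduce the published 5/9 split; it also
matches how the doses themselves were accumulated (total realizable dose
over total exposure). Hydrocortisone-equivalence factors follow the
standard potency table (hydrocortisone 1, prednisolone 4,
methylprednisolone 5, dexa-/betamethasone 26.7).

## Model

Pooling uses the binomial-logit hierarchical random-effects model
(odds-ratio metric):

    r_ci ~ Bin(n_ci, expit(mu_i))
    r_ti ~ Bin(n_ti, expit(mu_i + delta_i))
    delta_i ~ N(d, tau^2)

The trial baselines are exchangeable, `mu_i ~ N(m, sigma_mu^2)`. This is a
deliberate design choice rather than independent vague baselines, for two
reasons: the predictive machinery must be able to draw a *replicate
baseline* for a simulated future study, which only a baseline population
model supports; and on this cohort the exchangeable-baseline posterior
reproduces the published stratified estimates distinctly better than the
independent-baseline variant (which remains available via
`baseline="independent"`). The source analysis does not state its
baseline structure; the agreement of its printed numbers with the
exchangeable model is the evidence for this reading.

Priors (the source states none; all are configurable in `MCMCConfig`):

| parameter | prior | default rationale |
|---|---|---|
| d (pooled log-OR) | N(0, 10²) | vague on the log scale |
| tau | U(0, 2) | the published tau upper credible bounds cluster just below 2 (1.89–1.93), the signature of this prior |
| m | N(0, 10²) | vague |
| sigma_mu | U(0, 5) | generous for logit baselines |
| rd (pooled risk difference) | N(0, 1) truncated to (−1, 1) | the natural support |
| tau_rd | U(0, 1) | RD heterogeneity cannot exceed 1 |
| beta (meta-regression slope) | N(0, 10²) | vague |

On the risk-difference metric the trial effect acts on the probability
scale (`p_t = p_c + rho_i`); proposals that leave (0, 1) are rejected, so
the posterior is truncated to the feasible region rather than renormalised
per-trial.

### Meta-regression

With a fixed covariate x (mean patient age; the unweighted mean of the two
arm means, since per-arm sizes for age are unpublished), the effect model
becomes `delta_i ~ N(d + beta (x_i − x̄), tau^2)`, centred so the intercept
is the effect for an average trial. With the *baseline* covariate the
regressor is the latent `mu_i` itself (log-odds scale on the OR metric,
`expit(mu_i)` on the RD metric), centred at the population value derived
from m. Because the covariate is latent, the sampling error of observed
control rates — the source of regression-dilution bias and
regression-to-the-mean artefacts in weighted-least-squares meta-regression
— is integrated over rather than ignored; a property test confirms that a
zero true slope is not turned into a spurious negative one.

The risk-difference crossover point is summarised as the posterior of the
ratio `x* = center − rd/beta`, restricted to draws with |beta| > 10⁻³
(the retained fraction is reported, and the plug-in ratio of medians is
logged alongside for comparison); if most draws fail that cut the
crossover is declared undefined.

### Prediction

The effect in a new study is `delta_new ~ N(d, tau^2)` per retained draw.
A hypothesized trial of N patients (split evenly) additionally draws a
replicate baseline `mu_new ~ N(m, sigma_mu^2)` and binomial counts, and
records the continuity-corrected observed OR. The leave-one-out
predictive p-value for an index trial fits the model without it, simulates
replicate studies with the index trial's arm sizes, and reports the
one-sided tail probability of a replicate observed OR at least as extreme
as the index trial's, with the tail chosen *away from* the pooled median
effect. Under the null this folded statistic is uniform on (0, ½) — the
calibration the tests assert as 2p ~ U(0, 1) — and 20,000 replicates give
a Monte-Carlo SE below 0.004 near p = 0.07.

### Small-study effects

Harbord's modified score test: per trial, Z = a − m·n1/N and
V = m(N−m)n1n0 / (N²(N−1)); the test is OLS of Z/√V on √V with a
two-sided t-test of the intercept on n−2 df (statsmodels performs the
regression; an independent closed-form oracle verifies it to 10⁻¹⁰ in the
tests). Degenerate all-event/no-event trials are dropped, never imputed.
Funnel plots show the 0.5-corrected observed log-OR against its SE with
significance contours at two-sided p < 0.1, 0.05, 0.01 computed from the
null alone.

The continuity correction (0.5 added to all four cells, only when a cell
is zero) applies solely to these descriptive/frequentist quantities; the
Bayesian likelihood uses the raw counts.

## Sampler

A vectorised Metropolis-within-Gibbs scheme advances all chains
simultaneously. Per iteration: random-walk Metropolis updates of every
`mu_i` and every trial effect (jointly across trials — the conditionals
factorise), an exact conjugate draw of d (truncated-normal on the RD
metric) and of beta, a joint *translation* move shifting d and all trial
effects together (a reparameterisation whose acceptance involves only the
treated-arm likelihoods; it keeps the sampler mixing when the tau prior
pins heterogeneity near zero and the per-effect conditionals freeze),
random-walk updates of tau and sigma_mu against their uniform priors, and
a random-walk update of m. Using exact conjugate draws for the
linear-Gaussian blocks instead of random-walk steps reduces
autocorrelation at no approximation cost.

Proposal scales adapt during burn-in toward 44% acceptance
(Robbins–Monro, batches of 50) and are frozen afterwards, so the retained
draws come from a fixed-kernel chain with the correct invariant
distribution. Chains start from deliberately disparate points (pooled
effects spread over ±1, heterogeneity spread across its prior range,
baselines at jittered empirical logits). One master seed drives a single
vectorised generator; any fixed configuration is bit-reproducible. No
thinning is applied. Defaults are 3 chains × (10,000 burn-in + 100,000
retained), matching the published protocol; a 9-trial fit takes roughly
15–20 s on one CPU. Convergence is flagged by the classical Gelman–Rubin
statistic on d and tau (threshold 1.05); exceeding it marks the output
unconverged but summaries are still reported. The sampler was validated
against an independent JAGS implementation of the same models (agreement
to Monte-Carlo error on every pooled analysis) and against closed-form
limits (fixed-effect collapse, label symmetry, lognormal predictive).

## Synthetic data

The generator draws exactly the assumed hierarchy: `mu_i ~ N(m,
sigma_mu²)`, optional covariate (fixed normal, or the latent baseline
itself), `delta_i ~ N(d + beta z_i, tau²)`, uniform arm sizes, binomial
counts. Defaults (10 trials, d = 0, tau = 0.3, baselines N(0, 0.5²), arms
50–200) mirror a typical critical-care meta-analysis: moderate
heterogeneity and event probabilities near one half. What it deliberately
does not emulate: outcome-reporting selection, publication bias,
non-proportional event times, responder-status subgrouping, or
correlation between arm sizes and effects — so passing recovery and
calibration tests demonstrates correctness of the *inference machinery*
under the assumed model, not robustness to those real-data pathologies.
The latent truth travels in a JSON sidecar next to the generated CSV, so
generated files remain valid pipeline inputs.

## Numerical choices and degenerate inputs

* Empirical quantiles (type-7) for medians and central 95% intervals;
  exceedance probabilities are simple draw fractions.
* Zero cells: descriptive log-ORs add 0.5 to all four cells (error if the
  correction is explicitly 0); replicate-study simulations apply the same
  correction so every replicate OR is finite.
* A constant meta-regression covariate is accepted but logged as
  degenerate (the slope posterior is its prior).
* Trials missing a required covariate are dropped with a logged notice
  (reproducing the published 6- and 4-trial age regressions); fewer than
  three usable trials is an error.
* R-hat of identical chains is √((n−1)/n), reported as computed (no
  flooring at 1).

## Known limitations

* The published low-dose Harbord p-value (0.113) is not reproduced: the
  published formulation of the test gives 0.159 on those nine tables,
  while the same code reproduces the all-trials figure (0.143 vs 0.146).
  No standard variant (weighted fits, alternative score regressions,
  normal vs t reference) matches both printed values simultaneously; the
  canonical t-form is implemented and its output reported honestly.
* The high-dose-excluding-Schumer pooled OR and the high-dose credible
  interval in the source table resist reproduction under any prior tried
  (the printed interval is internally inconsistent with its own printed
  heterogeneity); the package reports its computed values.
* The printed ORs for hypothesized 2,000/4,000-patient studies
  (0.724/0.726) come from an unstated procedure; the replicate-study
  simulation here is one defensible reading and is logged as a reference
  point, not asserted.
* Arm-level 2×2 pooling ignores within-trial event timing; the source
  itself notes a hazard-ratio analysis was infeasible from published data.
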