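# Methods

This note documents the models, the synthetic-data generator, the estimation
machinery, and the numerical choices behind `valbandit`. It is written for a
reader who wants to know exactly what the package computes and what its
validation does and does not demonstrate.

## The task environment

The environment is a restless N-arm bandit. Each arm `a` carries two
independent, slowly drifting probabilities: `reward_p[t, a]` of emitting a win
token and `punish_p[t, a]` of emitting a loss token on trial `t`. Both are
bounded in `[0, ceiling]`; the default configuration is the 3-arm task with
200 trials and ceiling 0.75 (a 4-arm, 0.5-ceiling configuration reproduces the
older task variant's shape). Outcomes are realised independently per trial —
a choice can yield a win, a loss, both, or neither.

The drift process is not dictated by the task description, only its bounds
are; we declare it as a Gaussian random walk per (arm, outcome-type) with
per-step SD `step_sd` (default 0.03), reflecting boundaries at 0 and the
ceiling, and initial values drawn uniformly in `[0.2*ceiling, 0.8*ceiling]`.
This is the standard restless-bandit construction; the reflection keeps the
walk's marginal inside the bounds exactly, for every seed. One schedule is
generated per experiment and shared by all subjects (the held-constant
design); outcome realisations use independent per-subject streams.

## The model family

All Rescorla–Wagner variants maintain separate reward and punishment values
per arm, `Qr` and `Qp`, both initialised at zero. Outcomes are coded
`r = +1` for a win (else 0) and `l = -1` for a loss (else 0). For the chosen
arm the sensitivities scale the outcome inside the prediction error:

    delta_r = R*r - Qr(a)        Qr(a) <- Qr(a) + Arew * delta_r
    delta_p = P*l - Qp(a)        Qp(a) <- Qp(a) + Apun * delta_p

so `Qr` lives in `[0, R]` and `Qp` in `[-P, 0]`. Every unchosen arm receives
a fictive (counterfactual) update toward zero, `delta = -Q`, with the same
valence-specific learning rate — equivalent to assuming a zero outcome for
unchosen options, and producing gradual decay of their values. Choices come
from a softmax over `Qsum = Qr + Qp` at unit temperature: the sensitivities
(bounded `[0, 30]`) set the value scale, so a separate inverse temperature
would be nearly collinear with them and is deliberately absent from the core
model.

The seven registered variants:

| model | parameters | notes |
|---|---|---|
| `banditNarm_4par` | Arew, Apun, R, P | the core model above |
| `banditNarm_lapse` | + xi | policy mixed with uniform: `(1-xi)*softmax + xi/N` |
| `banditNarm_lapse_decay` | + xi, d | unchosen arms decay multiplicatively, `Q <- (1-d)Q`, replacing the fictive update |
| `banditNarm_2par_lapse` | Arew, Apun, xi | no sensitivities; outcomes enter unscaled (`R = P = 1`) |
| `banditNarm_singleA_lapse` | A, R, P, xi | one learning rate for both valences, everywhere |
| `banditNarm_delta` | A, tau | unscaled outcomes, softmax over `tau*Qsum`; with shared A and `R = P = tau` it is likelihood-identical to the 4-parameter model (tested) |
| `banditNarm_kalman_filter` | lam, theta, s0, sD, beta | Kalman tracker, below |

The Kalman variant tracks a posterior mean `m` and variance `s2` per arm
(`m = 0`, `s2 = s0^2` at trial 1). The chosen arm is updated against the
combined outcome `o = r + l` with observation variance fixed at 1
(`k = s2/(s2+1)`, `m += k*(o-m)`, `s2 *= 1-k`), then all arms take a
mean-reverting diffusion step `m <- lam*m + (1-lam)*theta`,
`s2 <- lam^2*s2 + sD^2`. Choices are a softmax over `beta*m`. The exact
update equations and bounds for this variant (and the lapse-decay rule and
the 2-parameter model's unit scaling) are declared conventions of this
package: we bound `lam, theta` in `[0, 1]`, `s0, sD` in `[0, 5]` and `beta`
in `[0, 10]`, and `tau` in `[0, 5]` for the delta model.

Missed trials (no response within the 3 s window) contribute nothing to the
likelihood and leave the value state unchanged. The softmax is computed with
max-subtraction; exact ties in choice probabilities are legal and only matter
for top-1 prediction, where the argmax breaks ties toward the lowest arm
index (documented and tested — this rule is deliberately not invariant to
arm relabelling at tied trials).

## Hierarchical estimation

For each parameter `k` with upper bound `u_k` (1 for rates and lapse/decay
terms, 30 for sensitivities):

    mu_pr[k] ~ Normal(0, 1)
    sigma[k] ~ half-Normal(0, 0.2)
    z[k, i]  ~ Normal(0, 1)                    (non-centred)
    theta[k, i] = u_k * Phi(mu_pr[k] + sigma[k] * z[k, i])

`Phi` is the standard normal CDF (probit transform), mapping the
unconstrained scale to `(0, u_k)`. The half-normal scale 0.2 applies to
every parameter's raw scale, i.e. before the `* 30` stretch for
sensitivities. The group-level mean on the natural scale is reported as
`u_k * Phi(mu_pr[k])`.

No general-purpose MCMC engine that fits this model is among the package's
dependencies, so `hierfit` ships its own sampler, built around the model's
conditional structure (a Metropolis-within-Gibbs scheme):

1. **Subject-level updates.** Component-wise Gaussian random-walk proposals
   on the z-scores, evaluated for the whole cohort in one vectorised
   likelihood pass and accepted independently per subject (valid because
   subjects are conditionally independent given the group level). Proposal
   scales are per-(subject, component) and adapt only during warmup
   (Robbins–Monro, target acceptance 0.44).
2. **Non-centred group-level moves.** Joint random-walk proposals on
   `mu_pr` (and log-scale proposals on `sigma`) with the z-scores held
   fixed, so the whole cohort's values shift together. These moves carry the
   likelihood and are what explore group-level uncertainty when the data are
   weak; with no data at all they sample the prior correctly (tested via a
   prior-predictive fit on all-missing data).
3. **Interweaved centred updates.** Holding the subject-level probit values
   `eta = mu_pr + sigma*z` fixed — which leaves the likelihood invariant —
   `mu_pr` has a conjugate normal Gibbs update and `sigma` a cheap
   Metropolis update, after which `z` is re-derived as `(eta - mu_pr)/sigma`.
   Alternating the centred and non-centred parameterisations (an
   ancillarity–sufficiency interweaving step) removes the strong coupling
   that cripples single-parameterisation random-walk samplers on hierarchies.

Defaults follow the study configuration: 4 chains, 2,000 iterations with
1,000 warmup. Convergence is summarised by the Gelman–Rubin R-hat and bulk
ESS of the group-level parameters (computed by arviz); we use the standard
R-hat < 1.1 working threshold. The random-walk kernel has no divergence
concept, so the divergence count is reported as zero. A maximum-a-posteriori
optimiser with the same priors (`fit_map`) is provided for smoke tests and
is labelled non-MCMC.

Pointwise log-likelihoods (per subject, per responded trial) are stored for
a thinned, chain-interleaved subset of draws (default 400) and feed arviz's
PSIS-LOO; `LOOIC = -2 * elpd_loo`, and model comparisons report LOOIC
relative to the best candidate (0 = best). On a tiny problem the PSIS
estimate is tested against exact leave-one-trial-out refitting.

## The synthetic cohort generator

The generator emulates the study's conditions, not any particular dataset:

- **Generating parameters** are drawn from normals truncated to the
  parameter bounds, at the published group moments (anhedonic:
  Arew 0.48/0.18, Apun 0.34/0.14, R 5.89/3.13, P 4.07/2.48; non-anhedonic:
  Arew 0.45/0.20, Apun 0.36/0.16, R 5.53/3.45, P 3.90/3.02). The original
  study's generative distribution for its recovery work was the set of
  fitted real-data parameters; a truncated normal at the published moments
  is our declared stand-in.
- **Choices** are simulated by the generative model on one shared schedule
  with independent outcome streams per subject; the true parameters ride
  along on each record for recovery scoring.
- **Questionnaire totals** (SHAPS 0–14, DARS 0–68, GAD-7 0–21, ZUNG 20–80)
  come from a Gaussian copula matched to the final-sample inter-scale
  correlations (DARS–SHAPS −0.86, DARS–GAD −0.58, ZUNG–DARS −0.75,
  ZUNG–SHAPS 0.73, ZUNG–GAD 0.81), pushed through rounded, clipped normal
  marginals. The SHAPS–GAD entry is not reported for the final sample; we
  complete the matrix with the pre-screening value 0.51 (the matrix is
  positive-definite). Group labels follow the screening rule (anhedonic:
  SHAPS > 2 and DARS ≤ 45; non-anhedonic: SHAPS = 0 and DARS > 55; the two
  are mutually exclusive by construction). Attention-check failures are an
  independent Bernoulli flag, default rate 6.5% (echoing 65/1000 exclusions
  at pre-screening).
- **Reaction times** are lognormal with median ≈ 500 ms, present only to
  exercise the RT-cleaning path (keep 200 ≤ RT ≤ 3000 ms on responded
  trials; the boundaries themselves are retained because the exclusion rule
  is strict). No RT–parameter coupling is simulated, so nothing about RT
  group effects can be learned from this generator.

What passing tests on this generator do show: the estimation machinery
recovers the parameters that generated the data, the comparison machinery
identifies the generating model family, and null cohorts do not produce
spurious credible group differences. What they do not show: anything about
real participants — real choice data have sequential dependencies, lapses,
attention drift and RT structure that the generator does not model.

## The recovery experiment

Recovery follows the study's two-stage design. A stand-in cohort (60
subjects × 200 trials by default) is drawn from the truncated-normal moments
and fitted; this fit plays the role of the real-data fit. Its posterior-mean
subject parameters — the "original" parameters — then generate a fresh
dataset on the same schedule; the model is refitted and each parameter's
generating values are correlated with the recovered posterior means. The
acceptance-scale runs use a reduced sampler configuration (2 chains, 500
warmup + 500 sampling), which the sampler's diagnostics show is converged
(R-hat < 1.1) at this size.

Two facts about this experiment are worth stating plainly. First,
recovery quality is bounded by the information in 200 trials: with
moments-generated (unshrunken) parameters, subject-level posterior
uncertainty caps the attainable correlation near r ≈ 0.93 for reward
sensitivity on typical schedules — independent per-subject maximum
likelihood does far worse (r ≈ 0.83), and longer chains do not move the
number, so this is a property of the data, not the sampler. Second, under
the two-stage design the observed correlations are r ≈ 0.89–0.93 (Arew),
0.66–0.83 (Apun), 0.94–0.97 (R) and 0.82–0.86 (P) across seeds: the
run-to-run spread straddles the lower ends of the published per-group
ranges, so a single seeded run can land marginally on either side of them.

## Behavioural metrics

Win-stay is a repeated choice on the trial after a win; lose-shift is a
changed choice on the trial after a loss; each is reported as a percentage
of its opportunities and undefined (NaN) when there are none. A trial with
both outcomes is an opportunity for both strategies, since the definitions
reference reward and punishment independently. A missed trial breaks
adjacency: neither it nor its successor contributes an opportunity, and a
missed trial also breaks a same-key run for the exclusion rule. Exclusions
flag ≥ 20-trial same-key runs (over responded trials), ≥ 20 missed trials,
or a failed attention check, and are idempotent.

Prediction accuracy replays each subject under their posterior-mean
parameters (a single replay, not per-draw averaging — the reduction rule is
a declared choice), computing choice probabilities before each observed
choice; accuracy is the percentage of responded trials where the argmax
matches the choice. Under a uniform policy on 3 arms this is 33.3% in
expectation, the chance floor used throughout.

The posterior predictive strategy check re-simulates each subject from their
fitted parameters on the same schedule and compares real vs simulated
win-stay/lose-shift per group with paired t-tests, mean differences in
percentage points, Cohen's dz, 95% CIs, and real–simulated Pearson r.

## Group inference

Group differences are assessed three ways, mirroring the study: (i) Welch
t-tests (Welch–Satterthwaite df) on subject-level posterior means; (ii) JZS
Bayes factors computed from the t statistic and group sizes by adaptive
quadrature over the default-prior g-mixture (Cauchy scale √2/2 on the
standardised effect; BF01 = 1/BF10 quantifies evidence for the null) — the
published group comparisons are reproduced from their printed t values to
within ±0.15; and (iii) the posterior difference of group-level means
(non-anhedonic minus anhedonic, draws paired by index after trimming to
equal length), summarised by the 95% highest-density interval (narrowest
contiguous window over sorted draws), the probability of direction
pd = max(P(>0), P(<0)), and a "credible" flag iff the HDI excludes zero.
Exploratory correlation tables use Pearson r on pairwise-complete
observations with Bonferroni correction over the full table (16 pairs for
the 4 subscales × 4 parameters layout).

## Numerical choices and degenerate inputs

- Softmax with max-subtraction; probabilities sum to 1 within 1e-12.
- Truncated-normal parameter sampling via the inverse-CDF method
  (scipy); zero SD collapses to the mean.
- The sampler clips `sigma` at 1e-6 to keep the z re-derivation finite;
  proposal-scale adaptation stops at the end of warmup (so the kept chain
  is a valid time-homogeneous Markov chain).
- A fit with zero sampling iterations, an empty dataset, a single-draw LOO
  input, a single-model comparison, non-PSD copula targets, out-of-bound
  moments, negative RTs, or mismatched real/simulated subject ids all raise
  errors rather than degrade silently.
- HDI requires ≥ 100 draws; zero-variance recovery cohorts report r as NaN.

## Known limitations

- The sampler is a random-walk scheme: effective sample sizes per iteration
  are far below gradient-based samplers, and the acceptance-scale
  configuration trades Monte-Carlo error for runtime. Diagnostics (R-hat,
  ESS) are always attached to fits.
- PSIS-LOO at small draw counts emits high-Pareto-k warnings on influential
  trials; comparisons at the scales used here are confirmed against exact
  refitting only on tiny problems.
- The questionnaire generator reproduces totals and their correlation
  structure, not item-level responses; the attenuation from rounding keeps
  empirical correlations within ~0.1 of the targets, no tighter.
- Win-stay/lose-shift conventions for "both"-outcome and missed-adjacent
  trials are declared here, not dictated by the task description; other
  conventions would shift the rates by small amounts.
- Simulated agents never lapse or miss trials, so the exclusion rules
  interact oddly with them: a high-sensitivity agent exploiting a good arm
  can legitimately produce a ≥ 20-trial same-key run and be flagged by the
  perseveration rule far more often than a human would. Group analyses on
  synthetic cohorts therefore retain fewer subjects than the nominal cohort
  size; this is a property of the generator, not of the exclusion logic.
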