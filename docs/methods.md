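# Methods

This note documents the models, conventions and design choices behind
`textquit`, and what the synthetic-data experiments do and do not
demonstrate.

## Scale scoring and targeting

The PMT scale has 21 items on a 1–7 Likert scale, three per construct;
a construct score is the arithmetic mean of its three items. Scoring
is all-or-nothing: a missing item rejects the whole assessment rather
than being imputed, matching an in-app capture flow where a
questionnaire cannot be submitted incomplete.

Three of the seven constructs (intrinsic rewards, extrinsic rewards,
response cost) are scored in the maladaptive direction — a high score
means *less* protected. Before merging constructs into the three
target groups we reflect those constructs (`reflect(x) = 8 − x`, an
involution on [1, 7]) so that in every merged group a lower score
means weaker protection. This makes the targeting rule — strengthen
the group with the lowest score — well-defined across
oppositely-oriented constructs. The merge is:

* `SS = mean(severity, vulnerability)`
* `RR = mean(8 − intrinsic, 8 − extrinsic, 8 − response_cost)`
* `EE = mean(self_efficacy, response_efficacy)`

Whether a deployed system would compare raw or direction-aligned
scores is genuinely open; we chose aligned scores because comparing a
raw rewards score against a raw self-efficacy score has no coherent
"weakest" interpretation. Ties are broken by a fixed priority order
(SS, then RR, then EE), configurable, so targeting is deterministic.

The 1–5 quitting-intention item is dichotomised STRONG iff score ≥ 4.
The instrument anchors are published but the cut point is not; ≥ 4
("likely" or "very likely") is the natural reading and the threshold
is a parameter.

Smoking status is MAINTAINED only if the participant denies smoking
since the last check **and**, when verification is on, expired CO is
strictly below 6 ppm. In-app evaluations are self-report only
(`verify_co=False`); CO belongs to the face-to-face outcome visits.

## Message bank

The motivational bank is partitioned into 13 atomic pools (`P-W, P-S,
P-SS, P-RR, P-EE, E-R, E-SS, E-RR, E-EE, L-R, L-SS, L-RR, L-EE`).
Narrative descriptions of this design sometimes count "14 sub-groups";
only 13 pools are operationally enumerable from the framework itself
(the count may fold in the withdrawal-management bank), so the fixture
generator uses the 13. Maintained-abstinence states carry no
stage-of-change component, so their daily pool is the PMT-group bank
alone; relapsed states union the relapse pool with the PMT-group pool.

Fixture texts embed their own pool label (e.g. `[E-RR #7]`) so that
any selection decision can be audited from a message log alone. Banks
round-trip through a canonical JSON schema and a CSV mirror with
identical columns.

## Delivery engine

Day 0 is registration, day 8 the quit day; the calendar partitions
days 0–90 into six phases and fixes evaluations at days 0, 19, 36, 45,
60, 75. Selection is rotation-without-repetition: each pool's order
is shuffled once (with the run's seeded generator) when the pool is
first entered, messages are dealt in order, and an exhausted pool is
reshuffled and restarted, with the restart logged. The generator is
used *only* for these shuffles, so a run is fully reproducible from
(seed, banks, assessment stream).

Two conventions reconcile the "two messages per day" cadence with the
absence of a stage pool for maintained abstainers: such participants
receive their PMT-group message plus a contact message; and within a
day the stage-class message precedes the PMT-group message. Both are
arbitrary but fixed for reproducibility.

The control schedule is a fixed map — message *d* of the 91-message
bank on day *d* — identical for every control participant and
independent of any assessment input.

## Trial design

* **Sample size.** Unpooled-variance normal approximation,
  `n = ⌈(z₁₋α/₂ + z₁₋β)²(p₁q₁ + p₂q₂)/(p₁ − p₂)²⌉`. At (4%, 10%,
  α = 0.05, power 0.80) this gives 280/group; the pooled-variance
  variant gives 283 and is not used.
* **Attrition.** Multiplicative inflation `⌈2n(1 + r)⌉`: 280 with 20%
  attrition gives 672. The divide-by-(1 − r) convention would give
  700 and is not used.
* **Randomization.** Simple (fair-coin) assignment within the two
  dependence strata (low vs moderate/high), one independent seeded
  stream per stratum so stratum composition does not perturb
  assignments. Pocock–Simon minimization (range imbalance, biased
  coin p = 0.75) is available for covariate balancing but off by
  default, since no specific balancing algorithm is canonical here.
* **Outcome.** Russell standard: sustained abstinence requires all
  three scheduled visits (months 1, 3, 6) present, every self-report
  negative since the quit date, and every CO strictly under 6 ppm;
  any missed visit or missing reading counts as smoking
  (intention-to-treat closure holds by construction).

## Analysis statistics

The odds ratio uses the Woolf log-normal interval,
`exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d))`; zero cells raise an error
offering the Haldane–Anscombe +0.5 correction as an explicit opt-in
rather than applying it silently. Reported rounding is 1 decimal for
percentages and 2 for OR/CI. Chi-square is Pearson with optional
Yates correction via `scipy.stats.chi2_contingency`.

`fit_logistic_irls` is a plain maximum-likelihood logistic fitter
(iteratively reweighted least squares, convergence when the max
coefficient step < 1e−8, weights floored at 1e−12). It exists as the
independent recovery oracle for simulated data; it is deliberately
not a repeated-measures model. Fitting visit-level data with working
independence is consistent for the discrete-time hazard the simulator
uses, because each risk-set row is conditionally independent given
its covariates. Repeated-measures modelling with an exchangeable
working correlation is out of scope; the long-format CSV export feeds
external tools that do it.

## Synthetic cohort

**Demographics** are drawn independently per characteristic at the
published baseline proportions of the trial population (sex 99.2%
male; age 54.8/43.1/2.1% across 18–44/45–64/>64; education
15.5/23.4/61.0%; residence 64.3% urban; 82.2% daily smokers; income
47.9/32.0/20.1%; dependence 63.6/28.2/8.2% low/moderate/high),
renormalised to sum exactly to one. Cross-characteristic correlation
is not modelled.

**Baseline construct scores** are drawn from clipped normals on
[1, 7] whose parameters are solved numerically so the *post-clipping*
mean and SD equal the configured targets (arms pooled at baseline:
severity 6.17 (1.20), vulnerability 5.37 (1.47), extrinsic 3.11
(1.45), intrinsic 4.63 (1.69), self-efficacy 4.58 (1.63), response
efficacy 5.53 (1.39), response cost 3.22 (1.59)). Clipping rather
than truncation is essential: a truncated normal is log-concave and
cannot reach the large SDs these ceiling-effect means carry, whereas
the clipped normal's point mass at the bounds can (and mirrors real
Likert pile-up at the scale ends). The 1–5 intention item defaults to
(0.05, 0.10, 0.20, 0.35, 0.30) — skewed toward quitting, as expected
of volunteers enrolling in a cessation programme; no published
distribution exists for it.

Item-level responses, when needed, are drawn as
`floor(t) + Bernoulli(frac(t))` around the construct target `t`, which
is exactly unbiased for the construct mean and stays in 1–7.

**Score dynamics** are first order. The 90-day protocol is divided
into six steps (one per inter-evaluation interval, the last running
to day 90). At each step the intervention arm's currently targeted
group shifts by `delta` in the protective direction (maladaptive
constructs move down), both arms receive N(0, 0.25²) noise per
construct, and scores clip to [1, 7]. Measurements map to snapshots:
month 0 = baseline, month 1 = after two steps, month 3 = after all
six, month 6 = one further noise-only step. There is no autoregressive
decay and no secular drift in the control arm.

**Abstinence** is a discrete-time hazard at the three follow-up
visits: conditional on abstinence so far,
`P(still abstinent) = expit(a_k + β·(x − x̄))` with `x` the current
construct scores, `x̄` the baseline means, and β fixed at
(0.113, 0.122, 0.058, −0.211, 0.751, −0.083, −0.174) for (severity,
vulnerability, extrinsic, intrinsic, self-efficacy, response
efficacy, response cost) — per-unit log odds ratios with the sign
structure the construct semantics dictate (self-efficacy strongly
protective; intrinsic rewards and response cost harmful). Relapse is
absorbing for the sustained-abstinence outcome; the in-protocol
status checks that steer messaging are separate point-abstinence
draws and may flip back.

**Verification and attrition.** Expired CO is truncated-at-zero
normal: mean 3, SD 1.5 ppm for abstainers (≈2% false-relapse at the
6 ppm cut) and mean 15, SD 5 for smokers. Each visit is missed
completely at random at 1.5% and a missed visit ends follow-up,
approximating the gentle, structureless loss (722 → ~707 → ~696 →
~690) typical of these trials.

**Calibration.** The visit intercepts (−1.67 each) and the per-step
shift (δ = 0.42) were set, by simulation at 722 participants, so the
default regime lands near 3% control and 7% intervention sustained
abstinence — the regime the design arithmetic anticipates. δ = 0.42
moves a targeted construct by ~2.5 points over the protocol, which is
larger than the arm contrasts real trials report; the model channels
the entire arm effect through the measured constructs, so matching
the outcome contrast requires a larger score contrast than reality,
where unmeasured pathways also operate. This is a known simplification.

**Parameter recovery.** `recover_parameters` refits β on the
discrete-time risk sets (visit k rows restricted to participants
abstinent through k−1, with visit fixed effects) — the same
conditional model the simulator draws from, so the estimator is
consistent and recovers the generating coefficients within sampling
error at n = 5000. δ is estimated as the arm contrast of the mean
direction-aligned per-step change on each participant's targeted
constructs. Under the null (δ = 0) this is unbiased because clipping
distorts both arms identically; for δ > 0 it is attenuated toward
zero by boundary clipping, so it is a diagnostic of effect presence
and direction, not an unbiased point estimator.

## What the experiments show — and don't

Passing tests show the pipeline's logic is internally consistent: the
arithmetic reproduces the published headline numbers exactly, the
engine obeys its scheduling contracts under replay, the interval has
nominal coverage at the trial's cell magnitudes, and the simulator's
generating parameters are recoverable from its own output. They do
not validate the behavioural model against real smokers: the
generator omits demographic–construct correlation, within-person
score autocorrelation beyond the random walk, informative dropout,
seasonal/contextual triggers, and any direct (non-construct-mediated)
message effect. Regression coefficients estimated from real trial
data are therefore covered only by sign structure and recovery
properties, never by value.

## Problem sizes and runtimes

The test suite and acceptance script use: 10⁴ draws for brute-force
targeting and interval-coverage checks, n = 5000 cohorts for
parameter recovery, 100 participants × 91 days for full engine logs,
and 100–200 replicates of the 722-participant trial for the
directional end-to-end checks. These sizes give Monte-Carlo error
comfortably inside each test's tolerance while keeping the default
run fast on a single core.
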