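"""Synthetic smoker cohort and end-to-end trial simulator.

No individual-level data from the original trial are available, so
this module generates virtual smokers whose marginals emulate the
trial population: categorical demographics drawn at the published
baseline proportions, baseline protection-motivation construct scores
drawn from moment-matched clipped normals on [1, 7], and a 1-5
quitting-intention item.

The behavioural model is deliberately simple:

* **Score dynamics** are first order.  Between consecutive in-app
  evaluations, the constructs of the currently targeted group shift by
  ``delta`` in the protective direction (intervention arm only), and
  every construct receives mean-zero Gaussian noise in both arms;
  scores are clipped to [1, 7].
* **Abstinence** is a discrete-time hazard at the three follow-up
  visits: conditional on being abstinent so far, a participant stays
  abstinent with probability ``sigmoid(a_k + beta . (x - ref))`` where
  ``x`` are the current construct scores.  The coefficient signs follow
  the construct semantics — self-efficacy protective, intrinsic
  rewards and response cost harmful — so raising protection raises the
  quit rate.  A relapse is permanent for the sustained-abstinence
  outcome.
* **Verification and attrition**: expired CO is drawn from a low-mean
  truncated normal for abstainers and a high-mean one for smokers
  (giving a small false-relapse rate at the 6 ppm cut); each visit is
  missed completely at random, and a missed visit ends follow-up.

Outcomes are adjudicated by the Russell standard via
:func:`textquit.design.russell_abstinence`, so dropouts count as
smokers and the intention-to-treat accounting closes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

from textquit.assessment import (
    CONSTRUCTS,
    ITEMS_PER_CONSTRUCT,
    LIKERT_MAX,
    LIKERT_MIN,
    PMTProfile,
    StatusReport,
)
from textquit.banks import Arm, MessageBank
from textquit.design import (
    OutcomeRecord,
    RandomizationPlan,
    randomize,
    russell_abstinence,
)
from textquit.engine import Assessment, run_protocol
from textquit.stats import TwoByTwo, fit_logistic_irls


def _normalized(raw: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(raw.values()))
    return {k: v / total for k, v in raw.items()}


#: Published baseline proportions of the trial population (both arms
#: pooled), used as generator defaults.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": _normalized({"male": 0.992, "female": 0.008}),
    "age_band": _normalized({"18-44": 0.548, "45-64": 0.431, ">64": 0.021}),
    "education": _normalized(
        {"middle_or_lower": 0.155, "high_school": 0.234, "college_or_above": 0.610}
    ),
    "residence": _normalized({"urban": 0.643, "rural": 0.357}),
    "smoking_status": _normalized({"daily": 0.822, "weekly": 0.178}),
    "income_band": _normalized({"<4000": 0.479, "4000-5999": 0.320, ">=6000": 0.201}),
    "dependence": _normalized({"LOW": 0.636, "MODERATE": 0.282, "HIGH": 0.082}),
}

#: Baseline construct means/SDs (arms pooled at month 0).
DEFAULT_CONSTRUCT_MEANS: dict[str, float] = {
    "severity": 6.17,
    "vulnerability": 5.365,
    "extrinsic_rewards": 3.11,
    "intrinsic_rewards": 4.63,
    "self_efficacy": 4.575,
    "response_efficacy": 5.525,
    "response_cost": 3.215,
}
DEFAULT_CONSTRUCT_SDS: dict[str, float] = {
    "severity": 1.20,
    "vulnerability": 1.47,
    "extrinsic_rewards": 1.45,
    "intrinsic_rewards": 1.69,
    "self_efficacy": 1.63,
    "response_efficacy": 1.385,
    "response_cost": 1.585,
}

#: Intention distribution over 1..5 for a cohort of volunteers who
#: enrolled in a quit programme (skewed toward intending to quit).
DEFAULT_INTENTION_PROBS = (0.05, 0.10, 0.20, 0.35, 0.30)


@dataclass(frozen=True)
class CohortConfig:
    n: int = 722
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHICS
    )
    construct_means: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_CONSTRUCT_MEANS
    )
    construct_sds: Mapping[str, float] = field(default_factory=lambda: DEFAULT_CONSTRUCT_SDS)
    intention_probs: Sequence[float] = DEFAULT_INTENTION_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        for var, probs in self.demographics.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"proportions for {var!r} do not sum to 1")
        if abs(sum(self.intention_probs) - 1.0) > 1e-9:
            raise ValueError("intention probabilities do not sum to 1")
        for c in CONSTRUCTS:
            if c not in self.construct_means or c not in self.construct_sds:
                raise ValueError(f"missing moments for construct {c!r}")
            if self.construct_sds[c] <= 0:
                raise ValueError(f"SD for {c!r} must be positive")


def _clipped_normal_moments(mu: float, s: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / s, (hi - mu) / s
    p_lo, p_hi = sps.norm.cdf(a), sps.norm.sf(b)
    p_mid = max(1.0 - p_lo - p_hi, 0.0)
    if p_mid <= 0:
        m = lo * p_lo + hi * p_hi
        return m, lo**2 * p_lo + hi**2 * p_hi - m**2
    tm, tv = sps.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
    m = lo * p_lo + hi * p_hi + p_mid * tm
    m2 = lo**2 * p_lo + hi**2 * p_hi + p_mid * (tv + tm**2)
    return float(m), float(m2 - m**2)


def _clipped_normal_params(mean: float, sd: float, lo: float = 1.0, hi: float = 7.0):
    """Underlying (mu, sigma) whose normal, clipped to [lo, hi], has
    the requested mean and SD.

    Clipping (rather than truncation) leaves point mass at the bounds,
    which is what lets the generator reproduce the strong ceiling
    effects of the published construct scores — a truncated normal is
    log-concave and cannot reach those (mean, SD) pairs.
    """

    def residual(p):
        mu, log_s = p
        m, v = _clipped_normal_moments(mu, float(np.exp(log_s)), lo, hi)
        return [m - mean, np.sqrt(max(v, 0.0)) - sd]

    sol = optimize.least_squares(
        residual, x0=[mean, np.log(sd * 1.5)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not sol.success or np.abs(sol.fun).max() > 1e-6:
        raise RuntimeError(
            f"moment matching failed for mean={mean}, sd={sd} on [{lo},{hi}]: "
            f"residual {np.abs(sol.fun).max():.3g}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a virtual cohort: one row per participant with categorical
    demographics, the 7 baseline construct scores and the intention
    item.  Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    data: dict[str, object] = {
        "participant_id": [f"P{i:05d}" for i in range(n)],
    }
    for var, probs in config.demographics.items():
        levels = list(probs)
        p = np.array([probs[k] for k in levels])
        data[var] = rng.choice(levels, size=n, p=p) if n else np.array([], dtype=object)
    for c in CONSTRUCTS:
        mu, s = _clipped_normal_params(config.construct_means[c], config.construct_sds[c])
        data[c] = (
            np.clip(rng.normal(mu, s, size=n), LIKERT_MIN, LIKERT_MAX)
            if n
            else np.array([])
        )
    p_int = np.asarray(config.intention_probs, dtype=float)
    data["intention"] = (
        rng.choice(np.arange(1, 6), size=n, p=p_int) if n else np.array([], dtype=int)
    )
    return pd.DataFrame(data)


def draw_item_responses(profile: PMTProfile, rng: np.random.Generator) -> dict[str, list[int]]:
    """Draw a 21-item response set whose construct means are unbiased
    for the profile's scores.

    Each item is ``floor(t) + Bernoulli(frac(t))`` for the construct's
    target ``t``, so ``E[item] = t`` exactly and items stay in 1..7.
    """
    out: dict[str, list[int]] = {}
    for c in CONSTRUCTS:
        t = min(max(getattr(profile, c), LIKERT_MIN), LIKERT_MAX)
        base = int(np.floor(t))
        frac = t - base
        items = base + (rng.random(ITEMS_PER_CONSTRUCT) < frac).astype(int)
        out[c] = [int(min(max(i, LIKERT_MIN), LIKERT_MAX)) for i in items]
    return out


#: Construct indices and protective directions of the three target
#: groups (order SS, RR, EE; direction +1 means "higher is protective").
_GROUP_IDX = (
    (np.array([0, 1]), +1.0),   # SS: severity, vulnerability
    (np.array([2, 3, 6]), -1.0),  # RR: extrinsic, intrinsic, response cost
    (np.array([4, 5]), +1.0),   # EE: self-efficacy, response efficacy
)
GROUP_NAMES = ("SS", "RR", "EE")

#: Log-odds-ratio coefficients of the abstinence hazard per unit
#: construct score, sign structure per the construct semantics
#: (protective constructs positive, maladaptive negative).
DEFAULT_ABSTINENCE_BETA: dict[str, float] = {
    "severity": 0.113,
    "vulnerability": 0.122,
    "extrinsic_rewards": 0.058,
    "intrinsic_rewards": -0.211,
    "self_efficacy": 0.751,
    "response_efficacy": -0.083,
    "response_cost": -0.174,
}

#: Number of score-evolution steps between the baseline measurement and
#: the month-3 measurement (one per inter-evaluation interval).
N_STEPS = 6
#: Measurement months and the post-step snapshot index they read.
VISIT_SNAPSHOT = {0: 0, 1: 2, 3: 6, 6: 7}


@dataclass(frozen=True)
class BehaviorParams:
    """Generating parameters of the behavioural simulation.

    ``visit_intercepts`` and ``delta`` default to values calibrated so
    a 360/arm trial lands near 3% control and 7% intervention sustained
    abstinence, the regime the design arithmetic anticipates.
    """

    abstinence_beta: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_ABSTINENCE_BETA
    )
    #: per-visit conditional log-odds intercepts (months 1, 3, 6)
    visit_intercepts: tuple[float, float, float] = (-1.67, -1.67, -1.67)
    #: per-step protective shift on the targeted group's constructs
    delta: float = 0.42
    #: per-step Gaussian score noise SD (all constructs, both arms)
    score_noise_sd: float = 0.25
    #: missing-completely-at-random probability per follow-up visit
    dropout_per_visit: float = 0.015
    #: expired-CO generative model (truncated at 0 from below)
    co_abstinent_mean: float = 3.0
    co_abstinent_sd: float = 1.5
    co_smoker_mean: float = 15.0
    co_smoker_sd: float = 5.0
    #: intercept of the in-protocol point-abstinence status checks
    status_intercept: float = -0.6
    #: hazard centering point (defaults to the baseline means)
    reference_means: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_CONSTRUCT_MEANS
    )

    def beta_array(self) -> np.ndarray:
        return np.array([self.abstinence_beta[c] for c in CONSTRUCTS])

    def ref_array(self) -> np.ndarray:
        return np.array([self.reference_means[c] for c in CONSTRUCTS])

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_per_visit < 1):
            raise ValueError("dropout_per_visit must be in [0,1)")
        if self.score_noise_sd < 0 or self.delta < 0:
            raise ValueError("delta and score_noise_sd must be non-negative")


@dataclass
class SimulationRun:
    """Everything one simulated trial produced, replayable from
    (cohort config, params, seed)."""

    cohort: pd.DataFrame
    assignments: pd.DataFrame
    snapshots: np.ndarray  # (N_STEPS + 2, n, 7) construct scores
    targets: np.ndarray  # (N_STEPS, n) target-group index per step
    outcomes: pd.DataFrame
    long_scores: pd.DataFrame
    table: TwoByTwo
    params: BehaviorParams
    seed: int
    message_logs: Optional[dict[str, list]] = None


def _target_groups(scores: np.ndarray) -> np.ndarray:
    """Vectorised weakest-group selection (ties resolved in the fixed
    order SS, RR, EE — argmin takes the first minimum)."""
    merged = np.stack(
        [
            np.where(direction > 0, 1.0, 0.0) * scores[:, idx].mean(axis=1)
            + np.where(direction > 0, 0.0, 1.0)
            * (LIKERT_MIN + LIKERT_MAX - scores[:, idx]).mean(axis=1)
            for idx, direction in _GROUP_IDX
        ],
        axis=1,
    )
    return np.argmin(merged, axis=1)


def _truncated_at_zero(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_trial(
    cohort: pd.DataFrame,
    params: BehaviorParams,
    seed: int,
    banks: Optional[Mapping[Arm, MessageBank]] = None,
    include_message_logs: bool = False,
    plan: Optional[RandomizationPlan] = None,
) -> SimulationRun:
    """Randomize the cohort, evolve construct scores over the 90-day
    protocol, draw visit-level abstinence/CO/attrition, and adjudicate
    Russell-standard outcomes.

    Message logs (the full day-by-day engine run per participant) are
    expensive and only produced when ``include_message_logs`` is set,
    in which case fixture ``banks`` must be supplied.
    """
    n = len(cohort)
    rng = np.random.default_rng([seed, 0])
    if plan is None:
        plan = RandomizationPlan(seed=int(np.random.default_rng([seed, 1]).integers(2**31)))
    arms = randomize(cohort.to_dict("records"), plan)
    is_int = np.array([a is Arm.INTERVENTION for a in arms])

    beta = params.beta_array()
    ref = params.ref_array()

    # score trajectory: snapshots[0] = baseline, snapshots[s] after step s,
    # snapshots[N_STEPS + 1] = month-6 measurement (noise-only step)
    snapshots = np.empty((N_STEPS + 2, n, len(CONSTRUCTS)))
    snapshots[0] = cohort[list(CONSTRUCTS)].to_numpy(dtype=float)
    targets = np.empty((N_STEPS, n), dtype=int)
    for step in range(1, N_STEPS + 1):
        prev = snapshots[step - 1]
        tg = _target_groups(prev)
        targets[step - 1] = tg
        nxt = prev + rng.normal(0.0, params.score_noise_sd, size=prev.shape)
        for g, (idx, direction) in enumerate(_GROUP_IDX):
            rows = is_int & (tg == g)
            if rows.any():
                nxt[np.ix_(rows, idx)] += direction * params.delta
        snapshots[step] = np.clip(nxt, LIKERT_MIN, LIKERT_MAX)
    snapshots[N_STEPS + 1] = np.clip(
        snapshots[N_STEPS] + rng.normal(0.0, params.score_noise_sd, size=(n, len(CONSTRUCTS))),
        LIKERT_MIN,
        LIKERT_MAX,
    )

    # visit-level latent abstinence (absorbing relapse), CO, attrition
    months = (1, 3, 6)
    abstinent = np.ones(n, dtype=bool)
    present = np.ones(n, dtype=bool)
    visit_cols: dict[str, np.ndarray] = {}
    for k, month in enumerate(months):
        x = snapshots[VISIT_SNAPSHOT[month]]
        eta = params.visit_intercepts[k] + (x - ref) @ beta
        abstinent = abstinent & (rng.random(n) < expit(eta))
        present = present & (rng.random(n) >= params.dropout_per_visit)
        co = np.where(
            abstinent,
            _truncated_at_zero(params.co_abstinent_mean, params.co_abstinent_sd, n, rng),
            _truncated_at_zero(params.co_smoker_mean, params.co_smoker_sd, n, rng),
        )
        visit_cols[f"present_m{month}"] = present.copy()
        visit_cols[f"smoked_m{month}"] = ~abstinent
        visit_cols[f"co_m{month}"] = co

    outcomes = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "arm": [a.value for a in arms],
            **visit_cols,
        }
    )
    outcomes["abstinent"] = [
        russell_abstinence(rec) for rec in to_outcome_records(outcomes)
    ]

    abst = outcomes["abstinent"].to_numpy()
    a = int((abst & is_int).sum())
    b = int((~abst & is_int).sum())
    c = int((abst & ~is_int).sum())
    d = int((~abst & ~is_int).sum())
    table = TwoByTwo(a=a, b=b, c=c, d=d)

    long_scores = _long_format(cohort, arms, snapshots, outcomes)
    assignments = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "arm": [a_.value for a_ in arms],
        }
    )

    run = SimulationRun(
        cohort=cohort,
        assignments=assignments,
        snapshots=snapshots,
        targets=targets,
        outcomes=outcomes,
        long_scores=long_scores,
        table=table,
        params=params,
        seed=seed,
    )
    if include_message_logs:
        if banks is None:
            raise ValueError("message logs require fixture banks")
        run.message_logs = _message_logs(run, banks, rng)
    return run


def to_outcome_records(outcomes: pd.DataFrame) -> list[OutcomeRecord]:
    """Re-express the outcome table as per-participant records for the
    Russell adjudicator (missed visits become None)."""
    records = []
    for row in outcomes.itertuples(index=False):
        visits = {}
        for month in OutcomeRecord.SCHEDULED_MONTHS:
            if not getattr(row, f"present_m{month}"):
                visits[month] = None
            else:
                visits[month] = StatusReport(
                    self_report_smoked_since_last=bool(getattr(row, f"smoked_m{month}")),
                    co_ppm=float(getattr(row, f"co_m{month}")),
                )
        records.append(OutcomeRecord(participant_id=row.participant_id, visits=visits))
    return records


def _long_format(cohort, arms, snapshots, outcomes) -> pd.DataFrame:
    n = len(cohort)
    frames = []
    abst_by_month = {
        month: ~outcomes[f"smoked_m{month}"].to_numpy() for month in (1, 3, 6)
    }
    for month, snap_idx in VISIT_SNAPSHOT.items():
        snap = snapshots[snap_idx]
        for ci, construct in enumerate(CONSTRUCTS):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": cohort["participant_id"].to_numpy(),
                        "arm": [a.value for a in arms],
                        "visit_month": month,
                        "construct": construct,
                        "score": snap[:, ci],
                        "abstinent_so_far": (
                            abst_by_month[month] if month in abst_by_month else [pd.NA] * n
                        ),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


_EVAL_SNAPSHOT = {0: 0, 19: 1, 36: 2, 45: 3, 60: 4, 75: 5}


def _message_logs(run: SimulationRun, banks, rng) -> dict[str, list]:
    """Drive the delivery engine for every participant using the
    simulated assessment stream (in-app status checks are point
    abstinence draws from the status hazard)."""
    beta = run.params.beta_array()
    ref = run.params.ref_array()
    logs: dict[str, list] = {}
    cohort = run.cohort.reset_index(drop=True)
    arm_by_pid = dict(zip(run.assignments["participant_id"], run.assignments["arm"]))
    seed_seq = np.random.default_rng([run.seed, 2])
    for i, row in enumerate(cohort.itertuples(index=False)):
        arm = Arm(arm_by_pid[row.participant_id])
        stream = {}
        for day, snap_idx in _EVAL_SNAPSHOT.items():
            profile = PMTProfile(
                **{c: float(run.snapshots[snap_idx][i, ci]) for ci, c in enumerate(CONSTRUCTS)}
            )
            if day == 0:
                stream[day] = Assessment(profile=profile, intention_score=int(row.intention))
            else:
                eta = run.params.status_intercept + (run.snapshots[snap_idx][i] - ref) @ beta
                smoked = bool(seed_seq.random() >= expit(eta))
                stream[day] = Assessment(
                    profile=profile, status=StatusReport(self_report_smoked_since_last=smoked)
                )
        logs[row.participant_id] = run_protocol(
            row.participant_id,
            arm,
            banks,
            stream,
            seed=int(seed_seq.integers(2**31)),
        )
    return logs


@dataclass(frozen=True)
class RecoveredParams:
    """Recovered hazard coefficients and intervention shift, with the
    generating truth for comparison."""

    beta_hat: np.ndarray
    beta_se: np.ndarray
    beta_true: np.ndarray
    delta_hat: float
    delta_se: float
    delta_true: float

    def beta_z(self) -> np.ndarray:
        return (self.beta_hat - self.beta_true) / self.beta_se

    def delta_interval(self, z: float = 1.96) -> tuple[float, float]:
        return self.delta_hat - z * self.delta_se, self.delta_hat + z * self.delta_se


def recover_parameters(run: SimulationRun) -> RecoveredParams:
    """Re-estimate the generating parameters from a simulated run.

    The abstinence coefficients are fit on the discrete-time hazard
    risk sets (visit k rows restricted to participants abstinent
    through visit k-1) with visit fixed effects — the same conditional
    model the simulator draws from, so the estimator is consistent.
    The intervention shift ``delta`` is the arm contrast of the mean
    direction-aligned per-step change on each participant's targeted
    constructs.
    """
    params = run.params
    ref = params.ref_array()
    outcomes = run.outcomes
    is_int = (run.assignments["arm"] == Arm.INTERVENTION.value).to_numpy()

    abst = {m: ~outcomes[f"smoked_m{m}"].to_numpy() for m in (1, 3, 6)}
    rows_X, rows_y = [], []
    at_risk = np.ones(len(outcomes), dtype=bool)
    for k, month in enumerate((1, 3, 6)):
        x = run.snapshots[VISIT_SNAPSHOT[month]][at_risk] - ref
        n_k = int(at_risk.sum())
        visit_dummies = np.zeros((n_k, 2))
        if k > 0:
            visit_dummies[:, k - 1] = 1.0
        rows_X.append(np.hstack([np.ones((n_k, 1)), visit_dummies, x]))
        rows_y.append(abst[month][at_risk].astype(float))
        at_risk = at_risk & abst[month]
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    beta_full, se_full = fit_logistic_irls(X, y)
    beta_hat, beta_se = beta_full[3:], se_full[3:]

    # delta: aligned per-step change on the targeted constructs
    aligned: dict[bool, list[np.ndarray]] = {True: [], False: []}
    for step in range(1, N_STEPS + 1):
        change = run.snapshots[step] - run.snapshots[step - 1]
        tg = run.targets[step - 1]
        for g, (idx, direction) in enumerate(_GROUP_IDX):
            sel = tg == g
            if sel.any():
                vals = direction * change[np.ix_(sel, idx)].mean(axis=1)
                aligned[True].append(vals[is_int[sel]])
                aligned[False].append(vals[~is_int[sel]])
    int_vals = np.concatenate(aligned[True])
    ctl_vals = np.concatenate(aligned[False])
    delta_hat = float(int_vals.mean() - ctl_vals.mean())
    delta_se = float(
        np.sqrt(int_vals.var(ddof=1) / len(int_vals) + ctl_vals.var(ddof=1) / len(ctl_vals))
    )
    return RecoveredParams(
        beta_hat=beta_hat,
        beta_se=beta_se,
        beta_true=params.beta_array(),
        delta_hat=delta_hat,
        delta_se=delta_se,
        delta_true=params.delta,
    )
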