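"""Trial design: randomization, sample size, outcome adjudication.

Randomization mirrors the trial protocol: participants are first
stratified by nicotine dependence (low vs moderate/high) and then
assigned by simple (fair-coin) randomization within each stratum.
Pocock-Simon minimization over configured covariates is available as
an optional alternative for streams where demographic balance matters.

Sample-size planning uses the unpooled-variance normal approximation
for two independent proportions, and attrition inflation multiplies
the recruited total by (1 + attrition rate).

The primary outcome follows the Russell standard: continuous
self-reported abstinence from the quit date, biochemically verified at
every follow-up visit (expired CO < 6 ppm), with anyone lost to
follow-up counted as a smoker (intention to treat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from textquit.assessment import CO_ABSTINENCE_PPM, StatusReport
from textquit.banks import Arm


class DependenceLevel(str, Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


#: Protocol stratification: low dependence vs moderate-or-high.
DEPENDENCE_STRATA: dict[DependenceLevel, int] = {
    DependenceLevel.LOW: 0,
    DependenceLevel.MODERATE: 1,
    DependenceLevel.HIGH: 1,
}


class RandomizationMethod(str, Enum):
    SIMPLE_WITHIN_STRATA = "SIMPLE_WITHIN_STRATA"
    MINIMIZATION = "MINIMIZATION"


@dataclass(frozen=True)
class RandomizationPlan:
    method: RandomizationMethod = RandomizationMethod.SIMPLE_WITHIN_STRATA
    balance_covariates: tuple[str, ...] = ()
    seed: int = 0
    #: biased-coin probability of taking the imbalance-minimizing arm
    minimization_p: float = 0.75


@dataclass(frozen=True)
class SampleSizeSpec:
    """Two-proportion planning inputs: anticipated control (p1) and
    intervention (p2) abstinence, two-sided alpha, power, attrition."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80
    attrition: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.p1 == self.p2:
            raise ValueError("p1 and p2 must differ")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0 < self.power < 1):
            raise ValueError(f"power must be in (0,1), got {self.power}")
        if not (0 <= self.attrition < 1):
            raise ValueError(f"attrition must be in [0,1), got {self.attrition}")


@dataclass(frozen=True)
class OutcomeRecord:
    """One participant's follow-up record: status reports at the
    month-1, month-3 and month-6 visits (None marks a missed visit)."""

    participant_id: str
    visits: Mapping[int, Optional[StatusReport]]

    SCHEDULED_MONTHS = (1, 3, 6)

    def __post_init__(self) -> None:
        missing = [m for m in self.SCHEDULED_MONTHS if m not in self.visits]
        if missing:
            raise ValueError(
                f"participant {self.participant_id}: record must list months "
                f"{self.SCHEDULED_MONTHS} (missing visits as None); lacking {missing}"
            )


def randomize(
    cohort: Sequence[Mapping],
    plan: RandomizationPlan,
) -> list[Arm]:
    """Assign each participant an arm under the plan.

    ``cohort`` is an ordered sequence of records carrying at least a
    ``dependence`` level, plus any covariates named by a minimization
    plan.  Assignment depends only on (seed, cohort order, method).
    """
    rng = np.random.default_rng(plan.seed)
    arms: list[Arm] = []
    if plan.method is RandomizationMethod.SIMPLE_WITHIN_STRATA:
        # one independent fair-coin stream per stratum
        stratum_rngs = {
            s: np.random.default_rng([plan.seed, s]) for s in set(DEPENDENCE_STRATA.values())
        }
        for rec in cohort:
            stratum = _stratum_of(rec)
            coin = stratum_rngs[stratum].integers(0, 2)
            arms.append(Arm.INTERVENTION if coin == 1 else Arm.CONTROL)
        return arms

    # Pocock-Simon minimization: assign toward the arm minimizing the
    # summed per-covariate range imbalance, with a biased coin.
    counts: dict[tuple[str, object, Arm], int] = {}
    covs = plan.balance_covariates or ("dependence",)
    for rec in cohort:
        _stratum_of(rec)  # validates the dependence label
        imbalance = {Arm.INTERVENTION: 0.0, Arm.CONTROL: 0.0}
        for arm in imbalance:
            for cov in covs:
                level = rec[cov]
                n_int = counts.get((cov, level, Arm.INTERVENTION), 0)
                n_ctl = counts.get((cov, level, Arm.CONTROL), 0)
                if arm is Arm.INTERVENTION:
                    n_int += 1
                else:
                    n_ctl += 1
                imbalance[arm] += abs(n_int - n_ctl)
        if imbalance[Arm.INTERVENTION] == imbalance[Arm.CONTROL]:
            pick = Arm.INTERVENTION if rng.random() < 0.5 else Arm.CONTROL
        else:
            best = min(imbalance, key=lambda a: imbalance[a])
            other = Arm.CONTROL if best is Arm.INTERVENTION else Arm.INTERVENTION
            pick = best if rng.random() < plan.minimization_p else other
        for cov in covs:
            key = (cov, rec[cov], pick)
            counts[key] = counts.get(key, 0) + 1
        arms.append(pick)
    return arms


def _stratum_of(rec: Mapping) -> int:
    raw = rec["dependence"]
    try:
        level = raw if isinstance(raw, DependenceLevel) else DependenceLevel(str(raw).upper())
    except ValueError as exc:
        raise ValueError(f"unknown dependence level {raw!r}") from exc
    return DEPENDENCE_STRATA[level]


def sample_size_two_props(spec: SampleSizeSpec) -> int:
    """Per-group n for a two-sided two-proportion comparison.

    Unpooled normal approximation:
    ``n = ceil((z_{1-a/2} + z_{1-b})^2 (p1 q1 + p2 q2) / (p1 - p2)^2)``.
    """
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(spec.power)
    num = (z_a + z_b) ** 2 * (spec.p1 * (1 - spec.p1) + spec.p2 * (1 - spec.p2))
    return math.ceil(num / (spec.p1 - spec.p2) ** 2)


def inflate_attrition(per_group_n: int, attrition: float) -> int:
    """Total recruitment target: ``ceil(2 n (1 + attrition))``."""
    if not (0 <= attrition < 1):
        raise ValueError(f"attrition must be in [0,1), got {attrition}")
    return math.ceil(2 * per_group_n * (1 + attrition))


def russell_abstinence(
    record: OutcomeRecord, co_threshold: float = CO_ABSTINENCE_PPM
) -> bool:
    """Russell-standard sustained abstinence at 6 months.

    True only if all three scheduled visits took place, every visit's
    self-report denies smoking since the quit date, and every visit's
    expired CO is strictly below the threshold.  A missed visit or a
    missing CO reading counts as smoking.
    """
    for month in OutcomeRecord.SCHEDULED_MONTHS:
        report = record.visits[month]
        if report is None:
            return False
        if report.self_report_smoked_since_last:
            return False
        if report.co_ppm is None or report.co_ppm >= co_threshold:
            return False
    return True
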