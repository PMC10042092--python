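"""Scoring of the in-app assessments.

The protection motivation theory (PMT) scale has 21 Likert items
(1-7), three per construct: perceived severity, perceived
vulnerability, intrinsic rewards, extrinsic rewards, self-efficacy,
response efficacy and response cost.  Construct scores are the
arithmetic means of their three items.

Because the seven constructs overlap, the intervention merges them
into three target groups — SS (severity + vulnerability), RR (rewards
and response cost) and EE (self-efficacy + response efficacy) — and
targets the group where the participant's protection is weakest.  The
maladaptive constructs (intrinsic/extrinsic rewards, response cost)
are reflected (``8 - x``) before merging so that *lower score = weaker
protection* holds uniformly and the "strengthen the lowest score" rule
is well defined.

Quitting intention is a single 1-5 item; smoking status combines a
self-report with an optional expired-CO verification (abstinent only
if CO < 6 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import Mapping, Optional, Sequence

from textquit.banks import PMTGroup, StageClass

#: Construct names, in the conventional reporting order.
CONSTRUCTS = (
    "severity",
    "vulnerability",
    "extrinsic_rewards",
    "intrinsic_rewards",
    "self_efficacy",
    "response_efficacy",
    "response_cost",
)

#: Constructs scored in the maladaptive direction (high = less protected).
MALADAPTIVE = ("intrinsic_rewards", "extrinsic_rewards", "response_cost")

ITEMS_PER_CONSTRUCT = 3
N_ITEMS = len(CONSTRUCTS) * ITEMS_PER_CONSTRUCT

LIKERT_MIN, LIKERT_MAX = 1, 7
CO_ABSTINENCE_PPM = 6.0


class Intention(str, Enum):
    STRONG = "STRONG"
    WEAK = "WEAK"


@dataclass(frozen=True)
class PMTItemResponses:
    """The raw 21-item response set, three 1-7 integers per construct."""

    responses: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        missing = [c for c in CONSTRUCTS if c not in self.responses]
        if missing:
            raise ValueError(f"missing responses for constructs: {missing}")
        extra = set(self.responses) - set(CONSTRUCTS)
        if extra:
            raise ValueError(f"unknown constructs: {sorted(extra)}")
        for construct in CONSTRUCTS:
            items = self.responses[construct]
            if len(items) != ITEMS_PER_CONSTRUCT:
                raise ValueError(
                    f"construct {construct!r} needs exactly {ITEMS_PER_CONSTRUCT} "
                    f"items, got {len(items)}"
                )
            for idx, value in enumerate(items, start=1):
                if value is None:
                    raise ValueError(f"construct {construct!r} item {idx} is missing")
                if not (LIKERT_MIN <= int(value) <= LIKERT_MAX) or int(value) != value:
                    raise ValueError(
                        f"construct {construct!r} item {idx}: response {value!r} "
                        f"outside {LIKERT_MIN}..{LIKERT_MAX}"
                    )


@dataclass(frozen=True)
class PMTProfile:
    """Per-construct mean scores, each in [1, 7]."""

    severity: float
    vulnerability: float
    extrinsic_rewards: float
    intrinsic_rewards: float
    self_efficacy: float
    response_efficacy: float
    response_cost: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (LIKERT_MIN <= v <= LIKERT_MAX):
                raise ValueError(f"{f.name} score {v} outside [{LIKERT_MIN}, {LIKERT_MAX}]")

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CONSTRUCTS}


@dataclass(frozen=True)
class MergedGroupScores:
    """Direction-aligned protection scores of the three target groups
    (lower = weaker protection = higher intervention priority)."""

    SS: float
    RR: float
    EE: float

    def as_dict(self) -> dict[PMTGroup, float]:
        return {PMTGroup.SS: self.SS, PMTGroup.RR: self.RR, PMTGroup.EE: self.EE}


@dataclass(frozen=True)
class StatusReport:
    """Follow-up smoking status: self-report plus optional CO reading."""

    self_report_smoked_since_last: bool
    co_ppm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.co_ppm is not None and self.co_ppm < 0:
            raise ValueError(f"co_ppm must be non-negative, got {self.co_ppm}")


def score_pmt(items: PMTItemResponses) -> PMTProfile:
    """Score the 21-item scale into the 7 construct means.

    No imputation: an incomplete response set is rejected at
    construction of :class:`PMTItemResponses`.
    """
    means = {
        c: sum(items.responses[c]) / ITEMS_PER_CONSTRUCT for c in CONSTRUCTS
    }
    return PMTProfile(**means)


def reflect(score: float) -> float:
    """Reverse a 1-7 Likert score (``8 - x``); an involution on [1, 7]."""
    return (LIKERT_MIN + LIKERT_MAX) - score


def merged_group_scores(profile: PMTProfile) -> MergedGroupScores:
    """Merge the 7 constructs into the 3 target-group protection scores.

    SS averages severity and vulnerability; EE averages self-efficacy
    and response efficacy; RR averages the *reflected* intrinsic
    rewards, extrinsic rewards and response cost, so that in every
    group a low score means weak protection.
    """
    ss = (profile.severity + profile.vulnerability) / 2
    rr = (
        reflect(profile.intrinsic_rewards)
        + reflect(profile.extrinsic_rewards)
        + reflect(profile.response_cost)
    ) / 3
    ee = (profile.self_efficacy + profile.response_efficacy) / 2
    return MergedGroupScores(SS=ss, RR=rr, EE=ee)


DEFAULT_TIE_ORDER = (PMTGroup.SS, PMTGroup.RR, PMTGroup.EE)


def select_target_group(
    scores: MergedGroupScores,
    tie_order: Sequence[PMTGroup] = DEFAULT_TIE_ORDER,
) -> PMTGroup:
    """The group whose protection score is lowest (the one "needing
    strengthening"); ties broken by the fixed priority order."""
    by_group = scores.as_dict()
    best = None
    for group in tie_order:
        if best is None or by_group[group] < by_group[best]:
            best = group
    assert best is not None
    return best


DEFAULT_INTENTION_THRESHOLD = 4


def classify_intention(score: int, threshold: int = DEFAULT_INTENTION_THRESHOLD) -> Intention:
    """Dichotomise the 1-5 quitting-intention item: STRONG iff
    ``score >= threshold`` (default 4)."""
    if not (1 <= score <= 5) or int(score) != score:
        raise ValueError(f"intention score must be an integer in 1..5, got {score!r}")
    return Intention.STRONG if score >= threshold else Intention.WEAK


def classify_status(report: StatusReport, verify_co: bool = True) -> StageClass:
    """MAINTAINED iff the participant denies smoking since the last
    check and, when verification is on, expired CO < 6 ppm (strict)."""
    if verify_co and report.co_ppm is None:
        raise ValueError("CO verification requested but no co_ppm reading present")
    abstinent = not report.self_report_smoked_since_last and (
        not verify_co or report.co_ppm < CO_ABSTINENCE_PPM
    )
    return StageClass.MAINTAINED if abstinent else StageClass.RELAPSED


def intention_stage(intention: Intention) -> StageClass:
    """Map the intention dichotomy to its pre-quit stage class."""
    return (
        StageClass.STRONG_INTENTION
        if intention is Intention.STRONG
        else StageClass.WEAK_INTENTION
    )
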