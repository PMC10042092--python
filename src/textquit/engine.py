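"""The 90-day per-participant delivery state machine.

Day 0 is registration, days 1-7 the pre-quitting phase, day 8 the quit
day, days 9-18 withdrawal-symptom management, days 19-36 the early and
days 37-90 the late quitting phase.  The app re-evaluates participants
on days 0, 19, 36, 45, 60 and 75: before the quit day the evaluation
classifies quitting intention (weak/strong), after it self-reported
smoking status (relapsed/maintained), and every evaluation re-selects
the protection-motivation target group from the latest scale scores.

Daily selection is rotation-without-repetition inside each message
pool: the pool order is shuffled once (seeded) when the pool is first
entered, messages are then dealt in order, and an exhausted pool is
reshuffled and restarted.  Every day delivers one or two messages;
participants who maintain abstinence (no stage-of-change pool) get a
contact message in the second slot so the two-message cadence holds.
The control arm receives a fixed 91-message schedule identical for
everyone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from textquit.assessment import (
    Intention,
    PMTProfile,
    StatusReport,
    classify_intention,
    classify_status,
    intention_stage,
    merged_group_scores,
    select_target_group,
)
from textquit.banks import (
    Arm,
    Kind,
    Message,
    MessageBank,
    Phase,
    PMTGroup,
    StageClass,
    contact_pool,
    pool_for,
)


@dataclass(frozen=True)
class ProtocolCalendar:
    """The fixed 91-day study calendar (days 0..90 inclusive)."""

    registration_day: int = 0
    pre_quit_days: range = range(1, 8)
    quit_day: int = 8
    withdrawal_days: range = range(9, 19)
    early_quit_days: range = range(19, 37)
    late_quit_days: range = range(37, 91)
    evaluation_days: tuple[int, ...] = (0, 19, 36, 45, 60, 75)

    @property
    def last_day(self) -> int:
        return self.late_quit_days[-1]


DEFAULT_CALENDAR = ProtocolCalendar()


def phase_for_day(day: int, calendar: ProtocolCalendar = DEFAULT_CALENDAR) -> Phase:
    """The unique protocol phase containing a study day."""
    if day == calendar.registration_day:
        return Phase.REGISTRATION
    if day in calendar.pre_quit_days:
        return Phase.PRE_QUIT
    if day == calendar.quit_day:
        return Phase.QUIT_DAY
    if day in calendar.withdrawal_days:
        return Phase.WITHDRAWAL
    if day in calendar.early_quit_days:
        return Phase.EARLY_QUIT
    if day in calendar.late_quit_days:
        return Phase.LATE_QUIT
    raise ValueError(f"day {day} outside the protocol window 0..{calendar.last_day}")


@dataclass
class ParticipantState:
    """Mutable per-participant delivery state.

    ``cursors`` hold, per pool key, the shuffled rotation order and the
    next position; ``history`` records the ids sent each day.
    """

    participant_id: str
    arm: Arm
    stage_class: StageClass = StageClass.WEAK_INTENTION
    pmt_group: PMTGroup = PMTGroup.SS
    intention: Intention = Intention.WEAK
    last_assessment_day: Optional[int] = None
    cursors: dict[str, dict] = field(default_factory=dict)
    history: dict[int, list[str]] = field(default_factory=dict)
    rotation_restarts: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Assessment:
    """One evaluation-day input: the re-scored profile plus either the
    intention item (before the quit day) or a status report (after)."""

    profile: PMTProfile
    intention_score: Optional[int] = None
    status: Optional[StatusReport] = None


@dataclass(frozen=True)
class LogEntry:
    participant_id: str
    day: int
    slot: int
    message_id: str
    phase: Phase
    stage_class: StageClass
    pmt_group: PMTGroup


def _pool_key(messages: Sequence[Message]) -> str:
    # pools are homogeneous; key them by the first member's identity tags
    m = messages[0]
    return f"{m.phase.value}|{m.kind.value}|{m.stage_class.value}|{m.pmt_group.value}"


def _draw(
    state: ParticipantState,
    pool: Sequence[Message],
    rng: np.random.Generator,
    pool_name: str,
) -> Message:
    """Rotation-without-repetition draw from a pool."""
    if not pool:
        raise RuntimeError(
            f"participant {state.participant_id}: required pool {pool_name!r} is empty"
        )
    key = _pool_key(pool)
    cur = state.cursors.get(key)
    if cur is None or cur["order"] != sorted(m.id for m in pool):
        order = [m.id for m in pool]
        perm = rng.permutation(len(order))
        cur = {
            "order": sorted(order),
            "sequence": [order[i] for i in perm],
            "pos": 0,
        }
        state.cursors[key] = cur
    if cur["pos"] >= len(cur["sequence"]):
        perm = rng.permutation(len(cur["sequence"]))
        cur["sequence"] = [cur["sequence"][i] for i in perm]
        cur["pos"] = 0
        state.rotation_restarts.append(key)
    msg_id = cur["sequence"][cur["pos"]]
    cur["pos"] += 1
    by_id = {m.id: m for m in pool}
    return by_id[msg_id]


def next_messages(
    state: ParticipantState,
    day: int,
    bank: MessageBank,
    rng: np.random.Generator,
    calendar: ProtocolCalendar = DEFAULT_CALENDAR,
) -> tuple[list[Message], ParticipantState]:
    """Select the intervention-arm messages for one day and log them.

    Registration, quit day and withdrawal days carry one fixed message;
    personalized days carry two — the stage-class message first, the
    PMT-group message second, with a contact message substituting for
    the absent stage-class pool while abstinence is maintained.
    """
    phase = phase_for_day(day, calendar)
    picks: list[Message] = []
    if phase in (Phase.REGISTRATION, Phase.QUIT_DAY, Phase.WITHDRAWAL):
        pool = [m for m in bank.messages if m.phase is phase and m.kind is Kind.FIXED]
        picks.append(_draw(state, pool, rng, phase.value))
    elif phase is Phase.PRE_QUIT:
        stage = intention_stage(state.intention)
        stage_pool = pool_for(bank, phase, stage, PMTGroup.NONE)
        group_pool = pool_for(bank, phase, StageClass.NONE, state.pmt_group)
        picks.append(_draw(state, stage_pool, rng, f"P-{stage.value}"))
        picks.append(_draw(state, group_pool, rng, f"P-{state.pmt_group.value}"))
    else:  # EARLY_QUIT / LATE_QUIT
        group_pool = pool_for(bank, phase, StageClass.NONE, state.pmt_group)
        if state.stage_class is StageClass.RELAPSED:
            stage_pool = pool_for(bank, phase, StageClass.RELAPSED, PMTGroup.NONE)
            picks.append(_draw(state, stage_pool, rng, f"{phase.value}-R"))
            picks.append(_draw(state, group_pool, rng, f"{phase.value}-{state.pmt_group.value}"))
        else:
            picks.append(_draw(state, group_pool, rng, f"{phase.value}-{state.pmt_group.value}"))
            contacts = contact_pool(bank, phase)
            if contacts:
                picks.append(_draw(state, contacts, rng, f"{phase.value}-CONTACT"))
    state.history[day] = [m.id for m in picks]
    return picks, state


def apply_evaluation(
    state: ParticipantState,
    day: int,
    assessment: Assessment,
    calendar: ProtocolCalendar = DEFAULT_CALENDAR,
    strict: bool = True,
    verify_co: bool = False,
) -> ParticipantState:
    """Apply an evaluation-day assessment to the participant state.

    Before the quit day the intention item updates the weak/strong
    classification; from day 19 the status report updates the
    relapsed/maintained classification.  Every evaluation re-selects
    the target group as the weakest merged protection score.  In-app
    status checks are self-report only by default (``verify_co=False``);
    CO verification belongs to the face-to-face outcome visits.
    """
    if day not in calendar.evaluation_days:
        msg = f"day {day} is not an evaluation day {calendar.evaluation_days}"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    if day < calendar.quit_day:
        if assessment.intention_score is None:
            raise ValueError(f"evaluation on day {day} requires the intention item")
        state.intention = classify_intention(assessment.intention_score)
        state.stage_class = intention_stage(state.intention)
    else:
        if assessment.status is None:
            raise ValueError(f"evaluation on day {day} requires a status report")
        state.stage_class = classify_status(assessment.status, verify_co=verify_co)
    state.pmt_group = select_target_group(merged_group_scores(assessment.profile))
    state.last_assessment_day = day
    return state


def schedule_control(
    bank: MessageBank, calendar: ProtocolCalendar = DEFAULT_CALENDAR
) -> dict[int, list[Message]]:
    """The fixed control-arm schedule: message *d* of the 91-message
    bank on study day *d*, identical for every control participant."""
    n_days = calendar.last_day + 1
    if len(bank.messages) > 2 * n_days or len(bank.messages) < (n_days + 1) // 2:
        raise ValueError(
            f"control bank of {len(bank.messages)} messages cannot cover "
            f"{n_days} days at 1-2 messages/day"
        )
    schedule: dict[int, list[Message]] = {d: [] for d in range(n_days)}
    for i, message in enumerate(bank.messages):
        schedule[i % n_days].append(message)
    return schedule


def run_protocol(
    participant_id: str,
    arm: Arm,
    banks: Mapping[Arm, MessageBank],
    assessment_stream: Mapping[int, Assessment],
    seed: int,
    calendar: ProtocolCalendar = DEFAULT_CALENDAR,
) -> list[LogEntry]:
    """Run one participant through days 0..90 and return the full log.

    The intervention arm consumes the assessment stream on each
    evaluation day (a missing entry is an error); the control arm
    ignores it and replays the fixed schedule.  The log is replayable:
    identical inputs and seed reproduce it exactly.
    """
    log: list[LogEntry] = []
    if arm is Arm.CONTROL:
        schedule = schedule_control(banks[Arm.CONTROL], calendar)
        for day in range(calendar.last_day + 1):
            for slot, m in enumerate(schedule[day], start=1):
                log.append(
                    LogEntry(participant_id, day, slot, m.id, phase_for_day(day, calendar),
                             StageClass.NONE, PMTGroup.NONE)
                )
        return log

    rng = np.random.default_rng(seed)
    state = ParticipantState(participant_id=participant_id, arm=arm)
    for day in range(calendar.last_day + 1):
        if day in calendar.evaluation_days:
            if day not in assessment_stream:
                raise ValueError(
                    f"participant {participant_id}: no assessment supplied for "
                    f"evaluation day {day}"
                )
            apply_evaluation(state, day, assessment_stream[day], calendar)
        picks, state = next_messages(state, day, banks[Arm.INTERVENTION], rng, calendar)
        for slot, m in enumerate(picks, start=1):
            log.append(
                LogEntry(participant_id, day, slot, m.id, phase_for_day(day, calendar),
                         state.stage_class, state.pmt_group)
            )
    return log


_LOG_COLUMNS = ["participant_id", "day", "slot", "message_id", "phase", "stage_class", "pmt_group"]


def write_log(log: Sequence[LogEntry], path: Union[str, Path]) -> None:
    """Export a message log as CSV (columns fixed, UTF-8)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LOG_COLUMNS)
        for e in log:
            writer.writerow(
                [e.participant_id, e.day, e.slot, e.message_id,
                 e.phase.value, e.stage_class.value, e.pmt_group.value]
            )
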