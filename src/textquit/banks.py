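"""Three-layer message bank: data model, file formats, fixture generator.

The intervention's content is organised in three layers:

1. **Phase** — where the participant is in the 90-day calendar
   (registration, pre-quit days 1-7, quit day 8, withdrawal days 9-18,
   early quitting days 19-36, late quitting days 37-90).
2. **Stage class** — the stage-of-change label that selects the message
   strategy: weak vs strong quitting intention before the quit day,
   relapsed vs maintained abstinence after it.
3. **PMT group** — the protection-motivation target group the message
   tries to strengthen: SS (severity/susceptibility), RR (rewards and
   response cost), EE (self-efficacy and response efficacy).

A motivational message lives in exactly one atomic pool, named by the
conventional labels ``P-W, P-S, P-SS, P-RR, P-EE, E-R, E-SS, E-RR,
E-EE, L-R, L-SS, L-RR, L-EE`` (13 pools).  The control arm uses a flat
bank of 91 fixed, non-personalized messages.
"""

from __future__ import annotations

import csv
import json
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
from pydantic import BaseModel, field_validator, model_validator


class Phase(str, Enum):
    REGISTRATION = "REGISTRATION"
    PRE_QUIT = "PRE_QUIT"
    QUIT_DAY = "QUIT_DAY"
    WITHDRAWAL = "WITHDRAWAL"
    EARLY_QUIT = "EARLY_QUIT"
    LATE_QUIT = "LATE_QUIT"


#: Phases whose daily selection depends on the participant's state.
PERSONALIZED_PHASES = (Phase.PRE_QUIT, Phase.EARLY_QUIT, Phase.LATE_QUIT)


class StageClass(str, Enum):
    WEAK_INTENTION = "WEAK_INTENTION"
    STRONG_INTENTION = "STRONG_INTENTION"
    RELAPSED = "RELAPSED"
    MAINTAINED = "MAINTAINED"
    NONE = "NONE"


class PMTGroup(str, Enum):
    SS = "SS"
    RR = "RR"
    EE = "EE"
    NONE = "NONE"


class Kind(str, Enum):
    MOTIVATIONAL = "MOTIVATIONAL"
    CONTACT = "CONTACT"
    FIXED = "FIXED"


class Arm(str, Enum):
    INTERVENTION = "INTERVENTION"
    CONTROL = "CONTROL"


class BankValidationError(ValueError):
    """A bank file parsed but violated a structural invariant."""


_PHASE_PREFIX = {Phase.PRE_QUIT: "P", Phase.EARLY_QUIT: "E", Phase.LATE_QUIT: "L"}
_STAGE_SUFFIX = {
    StageClass.WEAK_INTENTION: "W",
    StageClass.STRONG_INTENTION: "S",
    StageClass.RELAPSED: "R",
}

#: The 13 atomic motivational pool labels of the intervention bank.
BANK_LABELS = (
    "P-W", "P-S", "P-SS", "P-RR", "P-EE",
    "E-R", "E-SS", "E-RR", "E-EE",
    "L-R", "L-SS", "L-RR", "L-EE",
)


class Message(BaseModel):
    """One text unit, tagged by phase, stage class and PMT group."""

    model_config = {"frozen": True}

    id: str
    phase: Phase
    stage_class: StageClass = StageClass.NONE
    pmt_group: PMTGroup = PMTGroup.NONE
    kind: Kind = Kind.MOTIVATIONAL
    text: str = ""

    @model_validator(mode="after")
    def _check_layering(self) -> "Message":
        if self.phase in (Phase.REGISTRATION, Phase.QUIT_DAY, Phase.WITHDRAWAL):
            if self.stage_class is not StageClass.NONE or self.pmt_group is not PMTGroup.NONE:
                raise ValueError(
                    f"message {self.id!r}: phase {self.phase.value} is not "
                    "personalized; stage_class and pmt_group must be NONE"
                )
        if self.kind is Kind.MOTIVATIONAL:
            if self.phase is Phase.PRE_QUIT:
                ok = (
                    self.stage_class in (StageClass.WEAK_INTENTION, StageClass.STRONG_INTENTION)
                ) != (self.pmt_group is not PMTGroup.NONE)
                if not ok or self.stage_class in (StageClass.RELAPSED, StageClass.MAINTAINED):
                    raise ValueError(
                        f"message {self.id!r}: pre-quit motivational messages carry "
                        "exactly one of an intention label (W/S) or a PMT group"
                    )
            elif self.phase in (Phase.EARLY_QUIT, Phase.LATE_QUIT):
                ok = (self.stage_class is StageClass.RELAPSED) != (
                    self.pmt_group is not PMTGroup.NONE
                )
                if not ok or self.stage_class in (
                    StageClass.WEAK_INTENTION,
                    StageClass.STRONG_INTENTION,
                    StageClass.MAINTAINED,
                ):
                    raise ValueError(
                        f"message {self.id!r}: post-quit motivational messages carry "
                        "exactly one of the relapse label or a PMT group"
                    )
        return self

    @property
    def label(self) -> str:
        """Atomic pool label (e.g. ``'E-RR'``), or ``''`` for unpooled kinds."""
        prefix = _PHASE_PREFIX.get(self.phase)
        if prefix is None or self.kind is not Kind.MOTIVATIONAL:
            return ""
        if self.pmt_group is not PMTGroup.NONE:
            return f"{prefix}-{self.pmt_group.value}"
        suffix = _STAGE_SUFFIX.get(self.stage_class)
        return f"{prefix}-{suffix}" if suffix else ""


class MessageBank(BaseModel):
    """A validated collection of messages for one trial arm."""

    arm: Arm
    version: str = "1"
    messages: list[Message]

    @field_validator("messages")
    @classmethod
    def _non_empty(cls, v: list[Message]) -> list[Message]:
        if not v:
            raise ValueError("a bank must contain at least one message")
        return v

    @model_validator(mode="after")
    def _check_bank(self) -> "MessageBank":
        seen: set[str] = set()
        dupes = []
        for m in self.messages:
            if m.id in seen:
                dupes.append(m.id)
            seen.add(m.id)
        if dupes:
            raise ValueError(f"duplicated message ids: {sorted(set(dupes))}")
        if self.arm is Arm.CONTROL:
            bad = [
                m.id
                for m in self.messages
                if m.kind is not Kind.FIXED
                or m.stage_class is not StageClass.NONE
                or m.pmt_group is not PMTGroup.NONE
            ]
            if bad:
                raise ValueError(
                    f"control bank messages must be FIXED and unpersonalized; offending ids: {bad}"
                )
            if len(self.messages) != 91:
                raise ValueError(
                    f"control bank must hold exactly 91 messages, got {len(self.messages)}"
                )
        return self

    def by_kind(self, kind: Kind) -> list[Message]:
        return [m for m in self.messages if m.kind is kind]

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.messages:
            lab = m.label
            if lab:
                counts[lab] = counts.get(lab, 0) + 1
        return counts


_CSV_COLUMNS = ["id", "phase", "stage_class", "pmt_group", "kind", "text"]


def load_bank(path: Union[str, Path], arm: Arm) -> MessageBank:
    """Load and validate a message bank from a JSON or CSV file.

    The JSON dialect is ``{"arm", "version", "messages": [...]}``; the
    CSV dialect mirrors the message record columns and takes ``arm``
    from the argument.  Raises :class:`BankValidationError` on any
    structural violation and ``ValueError`` on unparseable input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() == ".csv":
            with path.open(newline="", encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh))
            payload = {"arm": arm.value, "version": "1", "messages": rows}
        else:
            payload = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, csv.Error) as exc:
        raise ValueError(f"cannot parse bank file {path}: {exc}") from exc
    if payload.get("arm", arm.value) != arm.value:
        raise BankValidationError(
            f"bank file {path} declares arm {payload['arm']!r}, expected {arm.value!r}"
        )
    payload["arm"] = arm.value
    try:
        return MessageBank.model_validate(payload)
    except ValueError as exc:
        raise BankValidationError(str(exc)) from exc


def save_bank(bank: MessageBank, path: Union[str, Path]) -> None:
    """Write a bank to JSON or CSV (chosen by extension), UTF-8."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for m in bank.messages:
                writer.writerow({c: getattr(m, c).value if c in ("phase", "stage_class", "pmt_group", "kind") else getattr(m, c) for c in _CSV_COLUMNS})
    else:
        path.write_text(
            json.dumps(bank.model_dump(mode="json"), indent=1, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )


def _label_fields(label: str) -> tuple[Phase, StageClass, PMTGroup]:
    prefix, suffix = label.split("-")
    phase = {v: k for k, v in _PHASE_PREFIX.items()}[prefix]
    if suffix in PMTGroup.__members__ and suffix != "NONE":
        return phase, StageClass.NONE, PMTGroup(suffix)
    stage = {v: k for k, v in _STAGE_SUFFIX.items()}[suffix]
    return phase, stage, PMTGroup.NONE


# Fixed single-purpose texts the engine needs outside the motivational pools.
_REGISTRATION_TEXT = (
    "[REG] Welcome to the programme. Over the next three months we will "
    "support you to quit; your quit day is day 8."
)
_QUIT_DAY_TEXT = "[Q] Today is your quit day: not a single puff from now on."
_N_WITHDRAWAL = 10
_N_CONTACT = 200
_N_MOTIVATIONAL = 200


def generate_fixture_banks(seed: int) -> tuple[MessageBank, MessageBank]:
    """Generate deterministic placeholder intervention and control banks.

    The intervention bank holds exactly 200 motivational placeholder
    messages spread over the 13 atomic pool labels (every pool
    non-empty), ~200 contact messages, the fixed registration and
    quit-day texts and a small withdrawal-management pool.  The control
    bank holds exactly 91 fixed messages.  Placeholder texts embed
    their own label so selections are auditable in logs.
    """
    rng = np.random.default_rng(seed)

    base, extra = divmod(_N_MOTIVATIONAL, len(BANK_LABELS))
    counts = {lab: base for lab in BANK_LABELS}
    # deterministically (per seed) pick which labels absorb the remainder
    for lab in rng.choice(len(BANK_LABELS), size=extra, replace=False):
        counts[BANK_LABELS[lab]] += 1

    messages: list[Message] = [
        Message(id="REG-1", phase=Phase.REGISTRATION, kind=Kind.FIXED, text=_REGISTRATION_TEXT),
        Message(id="Q-1", phase=Phase.QUIT_DAY, kind=Kind.FIXED, text=_QUIT_DAY_TEXT),
    ]
    for i in range(1, _N_WITHDRAWAL + 1):
        messages.append(
            Message(
                id=f"W-{i}",
                phase=Phase.WITHDRAWAL,
                kind=Kind.FIXED,
                text=f"[W #{i}] Withdrawal-management tip placeholder {i}.",
            )
        )
    for label, n in counts.items():
        phase, stage, group = _label_fields(label)
        for i in range(1, n + 1):
            messages.append(
                Message(
                    id=f"{label}-{i}",
                    phase=phase,
                    stage_class=stage,
                    pmt_group=group,
                    kind=Kind.MOTIVATIONAL,
                    text=f"[{label} #{i}] Motivational placeholder for pool {label}.",
                )
            )
    half = _N_CONTACT // 2
    for i in range(1, _N_CONTACT + 1):
        phase = Phase.EARLY_QUIT if i <= half else Phase.LATE_QUIT
        messages.append(
            Message(
                id=f"C-{i}",
                phase=phase,
                kind=Kind.CONTACT,
                text=f"[C #{i}] Contact/support placeholder {i}.",
            )
        )
    intervention = MessageBank(arm=Arm.INTERVENTION, version=f"fixture-seed{seed}", messages=messages)

    control_msgs = [
        Message(
            id=f"CTRL-{i}",
            phase=Phase.LATE_QUIT,
            kind=Kind.FIXED,
            text=f"[CTRL #{i}] Standard cessation advice placeholder {i}.",
        )
        for i in range(1, 92)
    ]
    control = MessageBank(arm=Arm.CONTROL, version=f"fixture-seed{seed}", messages=control_msgs)
    return intervention, control


def pool_for(
    bank: MessageBank,
    phase: Phase,
    stage_class: StageClass,
    pmt_group: PMTGroup,
) -> list[Message]:
    """The day's motivational pool for a participant state.

    For personalized phases the pool is the union of the stage-class
    bank and the PMT-group bank of that phase, e.g. pre-quit weak
    intention targeting SS draws from P-W and P-SS.  Maintained
    abstinence carries no stage-of-change component, so its pool is the
    PMT-group bank alone.  Order follows the bank's message order, so
    the result is stable.
    """
    if phase not in PERSONALIZED_PHASES:
        raise ValueError(f"phase {phase.value} is not personalized; no pool applies")
    want_stage: set[StageClass] = set()
    if phase is Phase.PRE_QUIT:
        if stage_class in (StageClass.WEAK_INTENTION, StageClass.STRONG_INTENTION):
            want_stage.add(stage_class)
    elif stage_class is StageClass.RELAPSED:
        want_stage.add(StageClass.RELAPSED)
    return [
        m
        for m in bank.messages
        if m.kind is Kind.MOTIVATIONAL
        and m.phase is phase
        and (m.stage_class in want_stage or (pmt_group is not PMTGroup.NONE and m.pmt_group is pmt_group))
    ]


def contact_pool(bank: MessageBank, phase: Phase) -> list[Message]:
    """Contact messages available in a phase (fills the second daily
    slot for participants maintaining abstinence)."""
    return [m for m in bank.messages if m.kind is Kind.CONTACT and m.phase is phase]
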