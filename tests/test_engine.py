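"""Calendar, daily selection, evaluations, rotation and replayability."""

import numpy as np
import pytest

from textquit.assessment import CONSTRUCTS, PMTProfile, StatusReport
from textquit.banks import Arm, Kind, Phase, PMTGroup, StageClass, pool_for
from textquit.engine import (
    DEFAULT_CALENDAR,
    Assessment,
    ParticipantState,
    apply_evaluation,
    next_messages,
    phase_for_day,
    run_protocol,
    schedule_control,
)


def flat_profile(value=4.0, **overrides):
    vals = {c: value for c in CONSTRUCTS}
    vals.update(overrides)
    return PMTProfile(**vals)


def full_stream(profile=None, smoked=False, intention=5):
    profile = profile or flat_profile()
    stream = {0: Assessment(profile=profile, intention_score=intention)}
    for d in (19, 36, 45, 60, 75):
        stream[d] = Assessment(
            profile=profile, status=StatusReport(self_report_smoked_since_last=smoked)
        )
    return stream


class TestCalendar:
    @pytest.mark.parametrize(
        "day,phase",
        [
            (0, Phase.REGISTRATION),
            (1, Phase.PRE_QUIT),
            (7, Phase.PRE_QUIT),
            (8, Phase.QUIT_DAY),
            (9, Phase.WITHDRAWAL),
            (18, Phase.WITHDRAWAL),
            (19, Phase.EARLY_QUIT),
            (36, Phase.EARLY_QUIT),
            (37, Phase.LATE_QUIT),
            (90, Phase.LATE_QUIT),
        ],
    )
    def test_phase_boundaries(self, day, phase):
        assert phase_for_day(day) is phase

    def test_every_day_maps_to_exactly_one_phase(self):
        phases = [phase_for_day(d) for d in range(91)]
        assert len(phases) == 91
        order = [
            Phase.REGISTRATION, Phase.PRE_QUIT, Phase.QUIT_DAY,
            Phase.WITHDRAWAL, Phase.EARLY_QUIT, Phase.LATE_QUIT,
        ]
        # monotone in phase order: indices never decrease
        idx = [order.index(p) for p in phases]
        assert idx == sorted(idx)

    @pytest.mark.parametrize("day", [-1, 91, 1000])
    def test_out_of_range_days_rejected(self, day):
        with pytest.raises(ValueError, match="outside"):
            phase_for_day(day)

    def test_evaluation_days_inside_window(self):
        assert all(0 <= d <= 90 for d in DEFAULT_CALENDAR.evaluation_days)


class TestNextMessages:
    def test_pre_quit_weak_ss_draws_from_both_pools(self, fixture_banks, rng):
        state = ParticipantState("p", Arm.INTERVENTION,
                                 stage_class=StageClass.WEAK_INTENTION,
                                 pmt_group=PMTGroup.SS)
        picks, _ = next_messages(state, 3, fixture_banks[Arm.INTERVENTION], rng)
        assert [m.label for m in picks] == ["P-W", "P-SS"]

    def test_quit_day_sends_the_single_fixed_message(self, fixture_banks, rng):
        state = ParticipantState("p", Arm.INTERVENTION)
        picks, _ = next_messages(state, 8, fixture_banks[Arm.INTERVENTION], rng)
        assert len(picks) == 1 and picks[0].phase is Phase.QUIT_DAY

    def test_withdrawal_days_send_one_fixed_message(self, fixture_banks, rng):
        state = ParticipantState("p", Arm.INTERVENTION)
        for day in range(9, 19):
            picks, _ = next_messages(state, day, fixture_banks[Arm.INTERVENTION], rng)
            assert len(picks) == 1 and picks[0].phase is Phase.WITHDRAWAL

    def test_maintained_gets_group_plus_contact(self, fixture_banks, rng):
        state = ParticipantState("p", Arm.INTERVENTION,
                                 stage_class=StageClass.MAINTAINED,
                                 pmt_group=PMTGroup.RR)
        picks, _ = next_messages(state, 40, fixture_banks[Arm.INTERVENTION], rng)
        assert [m.kind for m in picks] == [Kind.MOTIVATIONAL, Kind.CONTACT]
        assert picks[0].label == "L-RR"

    def test_relapsed_gets_relapse_then_group(self, fixture_banks, rng):
        state = ParticipantState("p", Arm.INTERVENTION,
                                 stage_class=StageClass.RELAPSED,
                                 pmt_group=PMTGroup.EE)
        picks, _ = next_messages(state, 20, fixture_banks[Arm.INTERVENTION], rng)
        assert [m.label for m in picks] == ["E-R", "E-EE"]

    def test_rotation_without_repetition_until_exhaustion(self, fixture_banks):
        bank = fixture_banks[Arm.INTERVENTION]
        n_pool = bank.label_counts()["P-SS"]
        state = ParticipantState("p", Arm.INTERVENTION,
                                 stage_class=StageClass.STRONG_INTENTION,
                                 pmt_group=PMTGroup.SS)
        rng = np.random.default_rng(0)
        seen = []
        for day in [1, 2, 3, 4, 5, 6, 7] * 10:
            picks, _ = next_messages(state, day, bank, rng)
            seen.append(picks[1].id)
        # within each full pass over the pool, no repeats
        for start in range(0, len(seen) - n_pool + 1, n_pool):
            window = seen[start : start + n_pool]
            assert len(set(window)) == n_pool
        assert state.rotation_restarts  # exhaustion was logged

    def test_same_seed_same_state_identical_selection(self, fixture_banks):
        bank = fixture_banks[Arm.INTERVENTION]
        picks = []
        for _ in range(2):
            state = ParticipantState("p", Arm.INTERVENTION)
            rng = np.random.default_rng(77)
            days = [next_messages(state, d, bank, rng)[0] for d in range(91)]
            picks.append([[m.id for m in day] for day in days])
        assert picks[0] == picks[1]


class TestApplyEvaluation:
    def test_day0_updates_intention_and_target(self):
        state = ParticipantState("p", Arm.INTERVENTION)
        profile = flat_profile(self_efficacy=1.5, response_efficacy=1.5)
        apply_evaluation(state, 0, Assessment(profile=profile, intention_score=5))
        assert state.stage_class is StageClass.STRONG_INTENTION
        assert state.pmt_group is PMTGroup.EE

    def test_post_quit_evaluation_flips_status(self):
        state = ParticipantState("p", Arm.INTERVENTION, stage_class=StageClass.MAINTAINED)
        report = StatusReport(self_report_smoked_since_last=True)
        apply_evaluation(state, 19, Assessment(profile=flat_profile(), status=report))
        assert state.stage_class is StageClass.RELAPSED

    def test_non_evaluation_day_strict_vs_lenient(self):
        state = ParticipantState("p", Arm.INTERVENTION)
        a = Assessment(profile=flat_profile(), intention_score=3)
        with pytest.raises(ValueError, match="not an evaluation day"):
            apply_evaluation(state, 5, a)
        with pytest.warns(UserWarning):
            apply_evaluation(state, 5, a, strict=False)

    def test_idempotent_on_identical_inputs(self):
        state = ParticipantState("p", Arm.INTERVENTION)
        a = Assessment(profile=flat_profile(), intention_score=2)
        apply_evaluation(state, 0, a)
        snap = (state.stage_class, state.pmt_group, state.intention)
        apply_evaluation(state, 0, a)
        assert (state.stage_class, state.pmt_group, state.intention) == snap

    def test_missing_inputs_named(self):
        state = ParticipantState("p", Arm.INTERVENTION)
        with pytest.raises(ValueError, match="intention"):
            apply_evaluation(state, 0, Assessment(profile=flat_profile()))
        with pytest.raises(ValueError, match="status"):
            apply_evaluation(state, 19, Assessment(profile=flat_profile()))


class TestControlSchedule:
    def test_covers_all_days_and_all_messages(self, fixture_banks):
        schedule = schedule_control(fixture_banks[Arm.CONTROL])
        assert set(schedule) == set(range(91))
        assert all(1 <= len(v) <= 2 for v in schedule.values())
        used = {m.id for msgs in schedule.values() for m in msgs}
        assert used == {m.id for m in fixture_banks[Arm.CONTROL].messages}

    def test_identical_for_every_participant(self, fixture_banks):
        logs = [
            run_protocol(pid, Arm.CONTROL, fixture_banks, {}, seed=s)
            for pid, s in [("c1", 1), ("c2", 999)]
        ]
        assert [(e.day, e.message_id) for e in logs[0]] == [
            (e.day, e.message_id) for e in logs[1]
        ]


class TestRunProtocol:
    def test_log_covers_91_days_with_1_to_2_messages(self, fixture_banks):
        log = run_protocol("p", Arm.INTERVENTION, fixture_banks, full_stream(), seed=4)
        by_day = {}
        for e in log:
            by_day.setdefault(e.day, []).append(e)
        assert set(by_day) == set(range(91))
        assert all(1 <= len(v) <= 2 for v in by_day.values())
        assert 91 <= len(log) <= 182

    def test_missing_evaluation_day_is_an_error_naming_the_day(self, fixture_banks):
        stream = full_stream()
        del stream[45]
        with pytest.raises(ValueError, match="day 45"):
            run_protocol("p", Arm.INTERVENTION, fixture_banks, stream, seed=4)

    def test_replay_reproduces_log_exactly(self, fixture_banks):
        a = run_protocol("p", Arm.INTERVENTION, fixture_banks, full_stream(), seed=11)
        b = run_protocol("p", Arm.INTERVENTION, fixture_banks, full_stream(), seed=11)
        assert a == b

    def test_personalized_picks_lie_in_the_declared_pool(self, fixture_banks):
        """Log-replay oracle: every motivational pick on a personalized
        day belongs to pool_for at the state the log recorded."""
        profile = flat_profile(severity=2.0, vulnerability=2.0)  # SS weakest
        log = run_protocol(
            "p", Arm.INTERVENTION, fixture_banks, full_stream(profile=profile, smoked=True),
            seed=21,
        )
        bank = fixture_banks[Arm.INTERVENTION]
        by_id = {m.id: m for m in bank.messages}
        for e in log:
            if e.phase in (Phase.PRE_QUIT, Phase.EARLY_QUIT, Phase.LATE_QUIT):
                m = by_id[e.message_id]
                if m.kind is Kind.CONTACT:
                    continue
                pool = pool_for(bank, e.phase, e.stage_class, e.pmt_group)
                assert e.message_id in {p.id for p in pool}

    def test_status_change_redirects_next_day_pool(self, fixture_banks):
        profile = flat_profile()
        stream = full_stream(profile=profile, smoked=False)
        stream[19] = Assessment(
            profile=profile, status=StatusReport(self_report_smoked_since_last=True)
        )
        log = run_protocol("p", Arm.INTERVENTION, fixture_banks, stream, seed=2)
        day20 = [e for e in log if e.day == 20]
        bank = fixture_banks[Arm.INTERVENTION]
        by_id = {m.id: m for m in bank.messages}
        labels = {by_id[e.message_id].label for e in day20}
        assert "E-R" in labels
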