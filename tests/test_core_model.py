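"""Session/block/trial lifecycle, numbering and event hooks."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialkit import (
    LifecycleError,
    ManualClock,
    SessionState,
    TrialStatus,
    create_session,
)


def make_session(**kwargs):
    clock = ManualClock()
    session = create_session(
        kwargs.pop("experiment_name", "exp"),
        kwargs.pop("ppid", "P01"),
        kwargs.pop("session_num", 1),
        kwargs.pop("settings", None),
        clock=clock,
    )
    return session, clock


class TestCreation:
    def test_new_session_is_created_and_empty(self):
        session, _ = make_session()
        assert session.state is SessionState.CREATED
        assert session.blocks == []

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"experiment_name": ""},
            {"ppid": ""},
            {"session_num": 0},
            {"session_num": -3},
        ],
    )
    def test_invalid_identity_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_session(**kwargs)

    def test_root_setting_resolvable_from_any_trial(self):
        session, _ = make_session(settings={"manipulation": False})
        session.create_block(3)
        session.create_block(2)
        assert all(t.settings.get("manipulation") is False
                   for t in session.trials)


class TestNumbering:
    @pytest.mark.parametrize(
        "block_sizes", [[5, 5], [0], [3, 0, 4], [1], [2, 2, 2, 2]]
    )
    def test_numbering_matches_recount_oracle(self, block_sizes):
        """Block and trial numbers are exactly 1..N in creation order."""
        session, _ = make_session()
        for n in block_sizes:
            session.create_block(n)
        assert [b.block_num for b in session.blocks] == list(
            range(1, len(block_sizes) + 1))
        trials = list(session.trials)
        assert [t.trial_num for t in trials] == list(
            range(1, sum(block_sizes) + 1))

    def test_trial_numbers_run_across_blocks(self):
        session, _ = make_session()
        session.create_block(5)
        session.create_block(5)
        third = session.create_block(1)
        assert third.trials[0].trial_num == 11
        assert [t.trial_num for t in session.blocks[1].trials] == [6, 7, 8, 9, 10]

    def test_individual_trial_creation_continues_numbering(self):
        session, _ = make_session()
        block = session.create_block(2)
        extra = block.create_trial()  # adaptive/staircase extension
        assert extra.trial_num == 3

    def test_create_block_after_end_is_refused(self):
        session, _ = make_session()
        session.end()
        with pytest.raises(LifecycleError):
            session.create_block(1)


class TestLifecycle:
    def test_begin_end_sets_ordered_timestamps(self):
        session, clock = make_session()
        (trial,) = session.create_block(1).trials
        trial.begin()
        assert trial.start_time == pytest.approx(0.0)
        clock.advance(1.5)
        trial.end()
        assert trial.status is TrialStatus.DONE
        assert trial.end_time > trial.start_time

    def test_first_begin_promotes_session(self):
        session, _ = make_session()
        (trial,) = session.create_block(1).trials
        assert session.state is SessionState.CREATED
        trial.begin()
        assert session.state is SessionState.IN_PROGRESS
        assert session.clock_origin is not None

    @pytest.mark.parametrize("sequence", ["begin_begin", "end_only", "end_end",
                                          "begin_on_done"])
    def test_illegal_transitions_raise(self, sequence):
        session, clock = make_session()
        (trial,) = session.create_block(1).trials
        with pytest.raises(LifecycleError):
            if sequence == "begin_begin":
                trial.begin(); trial.begin()
            elif sequence == "end_only":
                trial.end()
            elif sequence == "end_end":
                trial.begin(); clock.advance(1); trial.end(); trial.end()
            elif sequence == "begin_on_done":
                trial.begin(); clock.advance(1); trial.end(); trial.begin()

    def test_end_time_exceeds_start_even_without_clock_advance(self):
        session, _ = make_session()
        (trial,) = session.create_block(1).trials
        trial.begin()
        trial.end()  # clock never moved
        assert trial.end_time > trial.start_time

    def test_results_accepted_in_progress_and_done_only(self):
        session, clock = make_session()
        t1, t2 = session.create_block(2).trials
        with pytest.raises(LifecycleError):
            t1.add_result("response", 1)
        t1.begin()
        t1.add_result("response", 16)
        clock.advance(1)
        t1.end()
        t1.add_result("score", 0.5)  # post-hoc scoring on a done trial
        assert t1.results == {"response": 16, "score": 0.5}
        assert t2.results == {}

    def test_result_overwrite_last_wins_single_column(self):
        session, _ = make_session()
        (trial,) = session.create_block(1).trials
        trial.begin()
        trial.add_result("response", 1)
        trial.add_result("response", 2)
        assert trial.results == {"response": 2}
        assert session.result_names == ["response"]

    def test_result_columns_union_in_first_seen_order(self):
        session, clock = make_session()
        t1, t2 = session.create_block(2).trials
        t1.begin(); t1.add_result("a", 1); clock.advance(1); t1.end()
        t2.begin(); t2.add_result("b", 2); t2.add_result("a", 3)
        clock.advance(1); t2.end()
        assert session.result_names == ["a", "b"]

    def test_end_session_twice_raises(self):
        session, _ = make_session()
        session.end()
        with pytest.raises(LifecycleError):
            session.end()

    def test_state_transitions_each_at_most_once(self):
        session, _ = make_session()
        (trial,) = session.create_block(1).trials
        trial.begin()
        with pytest.raises(LifecycleError):
            session.begin()
        session.end()
        with pytest.raises(LifecycleError):
            trial.begin()  # new begins refused after session end


class TestEvents:
    def test_hooks_fire_once_per_trial_in_registration_order(self):
        session, clock = make_session()
        calls = []
        session.events.register("on_session_begin", lambda s: calls.append("sb"))
        session.events.register("on_trial_begin", lambda t: calls.append(("b", t.trial_num)))
        session.events.register("on_trial_begin", lambda t: calls.append(("b2", t.trial_num)))
        session.events.register("on_trial_end", lambda t: calls.append(("e", t.trial_num)))
        session.events.register("on_session_end", lambda s: calls.append("se"))
        for trial in session.create_block(3).trials:
            trial.begin()
            clock.advance(1)
            trial.end()
        session.end()
        begins = [c for c in calls if isinstance(c, tuple) and c[0] == "b"]
        ends = [c for c in calls if isinstance(c, tuple) and c[0] == "e"]
        assert len(begins) == len(ends) == 3
        assert calls[0] == "sb" and calls[-1] == "se"
        assert calls[1] == ("b", 1) and calls[2] == ("b2", 1)

    def test_failing_hook_is_contained(self):
        session, clock = make_session()
        seen = []

        def bad(trial):
            raise RuntimeError("boom")

        session.events.register("on_trial_begin", bad)
        session.events.register("on_trial_begin", seen.append)
        (trial,) = session.create_block(1).trials
        trial.begin()  # must not raise
        assert seen == [trial]
        clock.advance(1)
        trial.end()
        assert trial.status is TrialStatus.DONE

    def test_unknown_event_name_rejected(self):
        session, _ = make_session()
        with pytest.raises(ValueError):
            session.events.register("on_frobnicate", print)


@given(ops=st.lists(st.sampled_from(["block", "begin", "end", "result"]),
                    max_size=60))
def test_random_operation_sequences_preserve_invariants(ops):
    """No operation sequence yields status regression or end <= start.

    Invalid operations are attempted verbatim and must raise without
    corrupting state.
    """
    session, clock = make_session()
    for op in ops:
        clock.advance(0.25)
        try:
            if op == "block":
                session.create_block(1)
            elif op == "begin":
                trial = next(iter(session.trials), None)
                if trial is not None:
                    trial = next((t for t in session.trials
                                  if t.status is TrialStatus.NOT_STARTED), trial)
                    trial.begin()  # may be a re-begin: must raise cleanly
            elif op == "end":
                trial = next((t for t in session.trials
                              if t.status is TrialStatus.IN_PROGRESS), None)
                if trial is not None:
                    trial.end()
            elif op == "result":
                for trial in session.trials:
                    trial.add_result("r", 1)
        except LifecycleError:
            pass
    nums = [t.trial_num for t in session.trials]
    assert nums == list(range(1, len(nums) + 1))
    for trial in session.trials:
        if trial.start_time is not None and trial.end_time is not None:
            assert trial.end_time > trial.start_time
        if trial.status is TrialStatus.NOT_STARTED:
            assert trial.start_time is None and trial.results == {}
        if trial.status is TrialStatus.DONE:
            assert trial.start_time is not None and trial.end_time is not None
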