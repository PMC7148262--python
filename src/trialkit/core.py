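"""Session-block-trial experiment model.

A :class:`Session` is one complete run of an experiment by one participant.
It owns an ordered list of :class:`Block` objects, each owning an ordered
list of :class:`Trial` objects. Block numbers are 1..len(blocks) in creation
order; trial numbers are *session-global* positive integers (a second
five-trial block continues 6..10). Trials carry begin/end timestamps in
seconds since session begin, taken from an injectable clock (a monotonic
wall clock by default, or a :class:`ManualClock` driven by a simulation).

Lifecycle events (session begin/end, trial begin/end) invoke registered
hooks in registration order; a hook that raises is logged and skipped so a
buggy callback cannot corrupt experiment state mid-run.

Durable output is delegated to an attached writer (see
:mod:`trialkit.datastore`); the core model never touches the filesystem
itself.
"""

from __future__ import annotations

import enum
import logging
import math
import time
from typing import Any, Callable, Iterator, Mapping

from .errors import LifecycleError
from .settings import SettingsNode

__all__ = [
    "SessionState",
    "TrialStatus",
    "EventRegistry",
    "ManualClock",
    "Session",
    "Block",
    "Trial",
    "create_session",
]

log = logging.getLogger("trialkit")


class SessionState(enum.Enum):
    CREATED = "created"
    IN_PROGRESS = "in_progress"
    ENDED = "ended"


class TrialStatus(enum.Enum):
    NOT_STARTED = "not_started"
    IN_PROGRESS = "in_progress"
    DONE = "done"


class EventRegistry:
    """Ordered lifecycle hooks.

    Hooks receive the relevant object (Session or Trial). Exceptions raised
    by a hook are caught and logged; remaining hooks still fire.
    """

    EVENTS = ("on_session_begin", "on_trial_begin", "on_trial_end", "on_session_end")

    def __init__(self) -> None:
        self._hooks: dict[str, list[Callable[[Any], None]]] = {
            name: [] for name in self.EVENTS
        }

    def register(self, event: str, hook: Callable[[Any], None]) -> None:
        if event not in self._hooks:
            raise ValueError(f"unknown event {event!r}; expected one of {self.EVENTS}")
        self._hooks[event].append(hook)

    def fire(self, event: str, obj: Any) -> None:
        for hook in self._hooks[event]:
            try:
                hook(obj)
            except Exception:
                log.exception("hook for %s raised; continuing", event)


class ManualClock:
    """Explicitly advanced clock for simulated or scripted sessions."""

    def __init__(self, t: float = 0.0):
        self.t = float(t)

    def __call__(self) -> float:
        return self.t

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ValueError("cannot advance a clock backwards")
        self.t += dt

    def set(self, t: float) -> None:
        self.t = float(t)


class Trial:
    """A single stimulus-response unit with timestamps, settings and results.

    Results may be added while the trial is in progress or after it is done
    (post-hoc scoring); adding to a never-begun trial is a lifecycle error.
    """

    def __init__(self, session: "Session", block: "Block", trial_num: int,
                 settings: Mapping[str, Any] | None = None):
        self.session = session
        self.block = block
        self.trial_num = trial_num
        self.status = TrialStatus.NOT_STARTED
        self.start_time: float | None = None
        self.end_time: float | None = None
        self.results: dict[str, Any] = {}
        self.settings = SettingsNode(settings, parent=block.settings, level="trial")

    @property
    def block_num(self) -> int:
        return self.block.block_num

    def begin(self) -> None:
        """Start the trial: timestamp it and fire ``on_trial_begin``.

        The first begin of the session promotes it created -> in_progress
        (firing ``on_session_begin``).
        """
        if self.status is not TrialStatus.NOT_STARTED:
            raise LifecycleError(
                f"trial {self.trial_num} already begun (status {self.status.value})"
            )
        session = self.session
        if session.state is SessionState.ENDED:
            raise LifecycleError("cannot begin a trial in an ended session")
        if session.state is SessionState.CREATED:
            session.begin()
        self.start_time = session.time_now()
        self.status = TrialStatus.IN_PROGRESS
        for tracker in session.trackers:
            tracker.begin_trial(self)
        session.events.fire("on_trial_begin", self)

    def end(self) -> None:
        """End the trial, fire ``on_trial_end`` and flush tracker buffers."""
        if self.status is not TrialStatus.IN_PROGRESS:
            raise LifecycleError(
                f"trial {self.trial_num} is not in progress (status {self.status.value})"
            )
        session = self.session
        t = session.time_now()
        assert self.start_time is not None
        if t <= self.start_time:
            # A coarse clock can tick twice in one instant; keep end > begin.
            t = math.nextafter(self.start_time, math.inf)
        self.end_time = t
        self.status = TrialStatus.DONE
        session.events.fire("on_trial_end", self)
        for tracker in session.trackers:
            task = tracker.flush_trial(self, session.writer)
            if session.writer is not None and task is not None:
                session.writer.enqueue(task)

    def add_result(self, name: str, value: Any) -> None:
        """Record an observation; the column registers session-wide."""
        if self.status is TrialStatus.NOT_STARTED:
            raise LifecycleError(
                f"cannot add result {name!r} to trial {self.trial_num}: not begun"
            )
        if not name:
            raise ValueError("result name must be nonempty")
        self.results[name] = value
        self.session.register_result_name(name)

    def __repr__(self) -> str:
        return (f"Trial(num={self.trial_num}, block={self.block_num}, "
                f"status={self.status.value})")


class Block:
    """An ordered group of consecutive trials sharing a manipulation."""

    def __init__(self, session: "Session", block_num: int,
                 settings: Mapping[str, Any] | None = None):
        self.session = session
        self.block_num = block_num
        self.trials: list[Trial] = []
        self.settings = SettingsNode(settings, parent=session.settings, level="block")

    def create_trial(self, settings: Mapping[str, Any] | None = None) -> Trial:
        """Append one trial (supports adaptive/staircase designs)."""
        if self.session.state is SessionState.ENDED:
            raise LifecycleError("cannot create trials in an ended session")
        trial = Trial(self.session, self, self.session._next_trial_num(), settings)
        self.trials.append(trial)
        return trial

    def __repr__(self) -> str:
        return f"Block(num={self.block_num}, n_trials={len(self.trials)})"


class Session:
    """One full run of an experiment by one participant.

    Parameters
    ----------
    experiment_name, ppid
        Nonempty identifiers; together with ``session_num`` they determine
        the on-disk layout experiment/participant/session.
    session_num
        Positive integer session counter for this participant.
    settings
        Session-level settings (root of the cascade unless a profile is
        applied).
    clock
        Zero-argument callable returning seconds; defaults to
        ``time.monotonic``. Trial timestamps are reported relative to the
        clock value at session begin.
    """

    def __init__(
        self,
        experiment_name: str,
        ppid: str,
        session_num: int,
        settings: Mapping[str, Any] | None = None,
        clock: Callable[[], float] | None = None,
    ):
        if not experiment_name or not isinstance(experiment_name, str):
            raise ValueError("experiment_name must be a nonempty string")
        if not ppid or not isinstance(ppid, str):
            raise ValueError("ppid must be a nonempty string")
        if not isinstance(session_num, int) or session_num < 1:
            raise ValueError("session_num must be a positive integer")
        self.experiment_name = experiment_name
        self.ppid = ppid
        self.session_num = session_num
        self.settings = SettingsNode(settings, level="session")
        self.blocks: list[Block] = []
        self.state = SessionState.CREATED
        self.events = EventRegistry()
        self.clock = clock if clock is not None else time.monotonic
        self.clock_origin: float | None = None  # wall time at session begin
        self.trackers: list[Any] = []
        self.writer: Any | None = None  # duck-typed; see datastore.SessionStore
        self.settings_to_log: list[str] = []
        self._result_names: dict[str, None] = {}  # ordered set
        self._trial_count = 0
        self._t0: float | None = None

    # -- structure ----------------------------------------------------------

    def create_block(self, n_trials: int = 0,
                     settings: Mapping[str, Any] | None = None) -> Block:
        """Append a block containing ``n_trials`` fresh trials."""
        if self.state is SessionState.ENDED:
            raise LifecycleError("cannot create blocks in an ended session")
        if n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        block = Block(self, len(self.blocks) + 1, settings)
        self.blocks.append(block)
        for _ in range(n_trials):
            block.create_trial()
        return block

    def _next_trial_num(self) -> int:
        self._trial_count += 1
        return self._trial_count

    @property
    def trials(self) -> Iterator[Trial]:
        """All trials in creation (= numbering) order."""
        for block in self.blocks:
            yield from block.trials

    def get_trial(self, trial_num: int) -> Trial:
        for trial in self.trials:
            if trial.trial_num == trial_num:
                return trial
        raise KeyError(f"no trial numbered {trial_num}")

    def register_result_name(self, name: str) -> None:
        self._result_names.setdefault(name)

    @property
    def result_names(self) -> list[str]:
        """Result columns in first-seen order across the whole session."""
        return list(self._result_names)

    def apply_profile(self, mapping: Mapping[str, Any]) -> None:
        """Merge a settings profile below the session level.

        Profile values are resolvable from every trial but are overridden
        by programmatic session settings; applying the same profile twice
        is a no-op.
        """
        if self.settings.parent is None:
            self.settings.parent = SettingsNode(mapping, level="profile")
        else:
            self.settings.parent.update(mapping)

    # -- lifecycle ----------------------------------------------------------

    def begin(self) -> None:
        if self.state is not SessionState.CREATED:
            raise LifecycleError(f"session already {self.state.value}")
        self.clock_origin = time.time()
        self._t0 = self.clock()
        self.state = SessionState.IN_PROGRESS
        log.info("session begin: %s/%s/S%03d",
                 self.experiment_name, self.ppid, self.session_num)
        self.events.fire("on_session_begin", self)

    def time_now(self) -> float:
        """Seconds since session begin on the session clock."""
        if self._t0 is None:
            raise LifecycleError("session has not begun")
        return self.clock() - self._t0

    def end(self) -> None:
        """End the session: write behavioral data, drain the queue.

        Allowed from ``created`` as well (a session abandoned before any
        trial still produces a header-only behavioral file).
        """
        if self.state is SessionState.ENDED:
            raise LifecycleError("session already ended")
        if self.writer is not None:
            self.writer.write_behavioral(self)
            self.writer.drain()
            for task, exc in self.writer.failures:
                log.error("write failed for %s: %s", task.path, exc)
        self.state = SessionState.ENDED
        log.info("session end: %s/%s/S%03d",
                 self.experiment_name, self.ppid, self.session_num)
        self.events.fire("on_session_end", self)
        if self.writer is not None:
            self.writer.close()

    def __repr__(self) -> str:
        return (f"Session({self.experiment_name!r}, {self.ppid!r}, "
                f"{self.session_num}, state={self.state.value})")


def create_session(experiment_name: str, ppid: str, session_num: int,
                   settings: Mapping[str, Any] | None = None,
                   clock: Callable[[], float] | None = None) -> Session:
    """Create a new session in state ``created`` with zero blocks."""
    return Session(experiment_name, ppid, session_num, settings, clock)
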