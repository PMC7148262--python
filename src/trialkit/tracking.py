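"""Per-trial continuous measurement at an externally driven sampling rate.

A :class:`Tracker` buffers rows of time-varying measurements while a trial
is in progress and flushes one CSV file per trial when the trial ends
(``<tracker>_T<trial_num:03d>.csv`` in the session directory), so each
continuous file joins its behavioral row on ``trial_num``.

The library never owns a frame loop: whoever drives the experiment (a
simulation clock here; a display loop in an interactive application) calls
:meth:`Tracker.record` once per tick. Times are seconds since *trial*
begin and must be strictly increasing within a trial.

Coordinate convention for the pose tracker: positions in meters with y up
and z anterior-posterior, x lateral; rotations are Euler angles in degrees.
Units are never auto-converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

from .core import TrialStatus
from .datastore import WriteTask, rows_to_csv_bytes
from .errors import LifecycleError, RejectedSampleError

__all__ = ["TrajectorySample", "Tracker", "PoseTracker"]


@dataclass(frozen=True)
class TrajectorySample:
    """One time-stamped pose row: position (m) and Euler rotation (deg)."""

    time: float
    pos_x: float
    pos_y: float
    pos_z: float
    rot_x: float = 0.0
    rot_y: float = 0.0
    rot_z: float = 0.0


class Tracker:
    """Buffers rows of measured values over time, one buffer per trial.

    Parameters
    ----------
    name
        Tracker name; becomes the file-name prefix of per-trial output.
    fields
        Measured field names after the leading ``time`` column, e.g.
        ``("pressure",)`` for a one-channel pressure-pad tracker.
    """

    def __init__(self, name: str, fields: Sequence[str]):
        if not name:
            raise ValueError("tracker name must be nonempty")
        if not fields:
            raise ValueError("tracker needs at least one measured field")
        self.name = name
        self.header: tuple[str, ...] = ("time", *fields)
        self._rows: list[tuple[float, ...]] = []
        self._current_trial: Any | None = None
        self._last_time: float | None = None

    # Called by core.Trial.begin via the session's tracker list.
    def begin_trial(self, trial: Any) -> None:
        self._current_trial = trial
        self._rows = []
        self._last_time = None

    def record(self, time: float, values: Sequence[float]) -> None:
        """Append one row at trial-relative ``time`` (strictly increasing)."""
        trial = self._current_trial
        if trial is None or trial.status is not TrialStatus.IN_PROGRESS:
            raise LifecycleError(
                f"tracker {self.name!r}: cannot record outside an in-progress trial"
            )
        if self._last_time is not None and time <= self._last_time:
            raise RejectedSampleError(
                f"tracker {self.name!r}: time {time} is not after {self._last_time}"
            )
        if time < 0:
            raise RejectedSampleError(
                f"tracker {self.name!r}: time must be nonnegative, got {time}"
            )
        values = tuple(values)
        if len(values) != len(self.header) - 1:
            raise ValueError(
                f"tracker {self.name!r}: expected {len(self.header) - 1} "
                f"values, got {len(values)}"
            )
        self._rows.append((time, *values))
        self._last_time = time

    @property
    def n_buffered(self) -> int:
        return len(self._rows)

    def filename(self, trial_num: int) -> str:
        return f"{self.name}_T{trial_num:03d}.csv"

    def flush_trial(self, trial: Any, writer: Any | None) -> WriteTask | None:
        """Hand the trial's buffer to the data store as one WriteTask.

        With no writer attached the buffer is simply discarded. An empty
        buffer still yields a header-only file, so every trial of a tracked
        session has a continuous-data artifact.
        """
        rows, self._rows = self._rows, []
        self._current_trial = None
        self._last_time = None
        if writer is None:
            return None
        path = writer.session_dir / self.filename(trial.trial_num)
        return WriteTask(path, rows_to_csv_bytes(self.header, rows))


class PoseTracker(Tracker):
    """Position + rotation tracker (the head-tracking use case)."""

    FIELDS = ("pos_x", "pos_y", "pos_z", "rot_x", "rot_y", "rot_z")

    def __init__(self, name: str = "head_pose"):
        super().__init__(name, self.FIELDS)

    def record_sample(self, sample: TrajectorySample) -> None:
        self.record(sample.time, (sample.pos_x, sample.pos_y, sample.pos_z,
                                  sample.rot_x, sample.rot_y, sample.rot_z))
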