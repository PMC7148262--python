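"""Output layout, deferred durable writes, behavioral CSV, participant registry.

All session files live under ``base_dir/experiment/ppid/S<session_num:03d>``
so that one participant's sessions share a directory and two experiments
never collide. Writes are *deferred*: producers enqueue
:class:`WriteTask` objects onto a single background worker thread, so the
experiment loop is never blocked by disk latency, and :meth:`WriteQueue.drain`
(called by ``Session.end``) blocks until every queued file is durably on
disk. Tasks are written strictly in enqueue order, so re-writes of one
destination resolve to the last enqueued payload.

Post-write hooks on a task fire (with the written path) only after a
successful write; they are the extension point for shipping files elsewhere
(e.g. an uploader) without any network code in the core.

File naming: ``trial_results.csv`` (behavioral, one row per begun trial),
``<tracker>_T<trial:03d>.csv`` (continuous, written by
:mod:`trialkit.tracking`), ``log.txt`` (session lifecycle log), and
``participant_list.csv`` (registry, directly under ``base_dir``).

CSV dialect everywhere: comma delimiter, ``.`` decimal point, LF line
endings, header row always present, minimal quoting; times with 3 decimals,
booleans as lower-case ``true``/``false``.
"""

from __future__ import annotations

import csv
import io
import logging
import os
import queue
import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

from .errors import (
    MissingSettingError,
    PathEscapeError,
    SessionExistsError,
)

__all__ = [
    "SessionPaths",
    "WriteTask",
    "WriteQueue",
    "SessionStore",
    "ParticipantRegistry",
    "format_cell",
    "rows_to_csv_bytes",
    "BEHAVIORAL_FILENAME",
    "PARTICIPANT_LIST_FILENAME",
    "IDENTITY_COLUMNS",
]

log = logging.getLogger("trialkit")

BEHAVIORAL_FILENAME = "trial_results.csv"
PARTICIPANT_LIST_FILENAME = "participant_list.csv"
LOG_FILENAME = "log.txt"

#: Columns present in every behavioral file, before settings/result columns.
IDENTITY_COLUMNS = (
    "experiment", "ppid", "session_num",
    "trial_num", "block_num", "start_time", "end_time",
)

_TIME_COLUMNS = {"start_time", "end_time"}


def _sanitize_component(name: str, what: str) -> str:
    if not name:
        raise ValueError(f"{what} must be nonempty")
    bad = {os.sep, "/", "\\"}
    if any(ch in name for ch in bad) or name in (".", ".."):
        raise ValueError(f"{what} {name!r} must not contain path separators")
    return name


@dataclass(frozen=True)
class SessionPaths:
    """Derived directory layout: base_dir / experiment / ppid / S###."""

    base_dir: Path
    experiment_name: str
    ppid: str
    session_num: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_dir", Path(self.base_dir))
        _sanitize_component(self.experiment_name, "experiment_name")
        _sanitize_component(self.ppid, "ppid")
        if self.session_num < 1:
            raise ValueError("session_num must be >= 1")

    @property
    def session_dir(self) -> Path:
        return (self.base_dir / self.experiment_name / self.ppid
                / f"S{self.session_num:03d}")

    @property
    def behavioral_path(self) -> Path:
        return self.session_dir / BEHAVIORAL_FILENAME

    @property
    def log_path(self) -> Path:
        return self.session_dir / LOG_FILENAME


@dataclass
class WriteTask:
    """A pending durable write: destination, payload, post-write hooks."""

    path: Path
    payload: bytes
    hooks: list[Callable[[Path], None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.path = Path(self.path)


def format_cell(value: Any, column: str | None = None) -> str:
    """Serialize one CSV cell: bools lower-case, times to 3 decimals."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if column in _TIME_COLUMNS:
            return f"{value:.3f}"
        return f"{value:.12g}"
    return str(value)


def rows_to_csv_bytes(header: Sequence[str],
                      rows: Iterable[Sequence[Any]]) -> bytes:
    """Serialize a header and rows to CSV bytes in the package dialect."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(header)
    for row in rows:
        writer.writerow([format_cell(v, c) for v, c in zip(row, header)])
    return buf.getvalue().encode("utf-8")


class WriteQueue:
    """FIFO deferred writer backed by one daemon worker thread.

    Destinations must resolve inside ``root``; anything else is refused
    before it reaches the queue. A failed write never raises into the
    producer: it is recorded in :attr:`failures` and surfaced when the
    session ends.
    """

    _STOP = object()

    def __init__(self, root: Path):
        self.root = Path(root).resolve()
        self.failures: list[tuple[WriteTask, Exception]] = []
        self._queue: queue.Queue[Any] = queue.Queue()
        self._closed = False
        self._worker = threading.Thread(target=self._run, daemon=True,
                                        name="trialkit-writer")
        self._worker.start()

    def enqueue(self, task: WriteTask) -> None:
        if self._closed:
            raise RuntimeError("write queue is closed")
        resolved = Path(task.path).resolve()
        if not resolved.is_relative_to(self.root):
            raise PathEscapeError(
                f"destination {task.path} escapes output root {self.root}"
            )
        self._queue.put(task)

    def drain(self) -> None:
        """Block until every previously enqueued task is durably written."""
        self._queue.join()

    def close(self) -> None:
        """Drain, then stop the worker thread. Idempotent."""
        if self._closed:
            return
        self._closed = True
        self.drain()
        self._queue.put(self._STOP)
        self._worker.join()

    def _run(self) -> None:
        while True:
            task = self._queue.get()
            if task is self._STOP:
                self._queue.task_done()
                return
            try:
                self._write(task)
                for hook in task.hooks:
                    try:
                        hook(task.path)
                    except Exception:
                        log.exception("post-write hook failed for %s", task.path)
            except Exception as exc:
                self.failures.append((task, exc))
            finally:
                self._queue.task_done()

    @staticmethod
    def _write(task: WriteTask) -> None:
        task.path.parent.mkdir(parents=True, exist_ok=True)
        with open(task.path, "wb") as fh:
            fh.write(task.payload)
            fh.flush()
            os.fsync(fh.fileno())


class SessionStore:
    """Binds a session to its output directory and deferred write queue.

    Creating the store claims the session directory (refusing a collision
    with previously collected data unless ``overwrite=True``), attaches a
    ``log.txt`` handler for the package logger, and registers itself as the
    session's writer so trial/tracker flushes route through the queue.
    """

    def __init__(self, base_dir: str | Path, session: Any,
                 overwrite: bool = False):
        self.paths = SessionPaths(Path(base_dir), session.experiment_name,
                                  session.ppid, session.session_num)
        session_dir = self.paths.session_dir
        if session_dir.exists() and any(session_dir.iterdir()):
            if not overwrite:
                raise SessionExistsError(
                    f"{session_dir} already contains data; "
                    "pass overwrite=True to replace it"
                )
        session_dir.mkdir(parents=True, exist_ok=True)
        self.queue = WriteQueue(Path(base_dir))
        self._log_handler = logging.FileHandler(self.paths.log_path,
                                                encoding="utf-8")
        self._log_handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(self._log_handler)
        session.writer = self

    # Writer protocol used by core.Session / tracking.Tracker ---------------

    @property
    def session_dir(self) -> Path:
        return self.paths.session_dir

    @property
    def failures(self) -> list[tuple[WriteTask, Exception]]:
        return self.queue.failures

    def enqueue(self, task: WriteTask) -> None:
        self.queue.enqueue(task)

    def drain(self) -> None:
        self.queue.drain()

    def close(self) -> None:
        self.queue.close()
        log.removeHandler(self._log_handler)
        self._log_handler.close()

    def write_behavioral(self, session: Any) -> Path:
        """Serialize one row per begun trial and enqueue the write."""
        header, rows = behavioral_table(session)
        self.enqueue(WriteTask(self.paths.behavioral_path,
                               rows_to_csv_bytes(header, rows)))
        return self.paths.behavioral_path


def behavioral_table(session: Any) -> tuple[list[str], list[list[Any]]]:
    """Build the behavioral header and rows for a session.

    Columns: the identity columns, then the session's ``settings_to_log``
    (resolved per trial through the cascade), then result columns in
    first-seen order. The column set is identical on every row; cells with
    no value are blank.
    """
    header = list(IDENTITY_COLUMNS) + list(session.settings_to_log) \
        + session.result_names
    rows: list[list[Any]] = []
    for trial in session.trials:
        if trial.start_time is None:
            continue  # never begun: no behavioral row
        row: list[Any] = [
            session.experiment_name, session.ppid, session.session_num,
            trial.trial_num, trial.block_num,
            trial.start_time, trial.end_time,
        ]
        for key in session.settings_to_log:
            try:
                row.append(trial.settings.get(key))
            except MissingSettingError:
                row.append(None)
        for name in session.result_names:
            row.append(trial.results.get(name))
        rows.append(row)
    return header, rows


class ParticipantRegistry:
    """Participant demographics, one row per ppid, persisted as CSV.

    The column set is the union of all demographic fields ever seen, in
    first-seen order after ``ppid``. Upserting an existing participant
    updates/extends their fields (e.g. height measured later in the task).
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._records: dict[str, dict[str, Any]] = {}
        self._columns: dict[str, None] = {}
        if self.path.exists():
            self._load()

    def _load(self) -> None:
        with open(self.path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                ppid = row.pop("ppid")
                self._records[ppid] = {k: v for k, v in row.items() if v != ""}
                for key in row:
                    self._columns.setdefault(key)

    def upsert(self, ppid: str, demographics: Mapping[str, Any] | None = None,
               **fields: Any) -> None:
        if not ppid:
            raise ValueError("ppid must be nonempty")
        record = self._records.setdefault(ppid, {})
        for key, value in {**(demographics or {}), **fields}.items():
            record[key] = value
            self._columns.setdefault(key)

    def get(self, ppid: str) -> dict[str, Any]:
        try:
            return dict(self._records[ppid])
        except KeyError:
            raise KeyError(f"no participant {ppid!r} in registry") from None

    def __contains__(self, ppid: str) -> bool:
        return ppid in self._records

    def __len__(self) -> int:
        return len(self._records)

    def save(self) -> Path:
        header = ["ppid", *self._columns]
        rows = [[ppid, *(record.get(col) for col in self._columns)]
                for ppid, record in self._records.items()]
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_bytes(rows_to_csv_bytes(header, rows))
        return self.path
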