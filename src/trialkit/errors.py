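"""Exception hierarchy.

Everything raised deliberately by trialkit derives from :class:`TrialkitError`
so callers can catch framework errors without swallowing programming errors.
"""

from __future__ import annotations


class TrialkitError(Exception):
    """Base class for all trialkit errors."""


class LifecycleError(TrialkitError):
    """An operation was attempted in an illegal session/trial state."""


class MissingSettingError(TrialkitError, KeyError):
    """A setting was not found at any level of the cascade."""

    def __init__(self, key: str, levels_searched: list[str]):
        self.key = key
        self.levels_searched = list(levels_searched)
        super().__init__(
            f"setting {key!r} not found; searched levels: "
            + " -> ".join(levels_searched)
        )

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class InvalidProfileError(TrialkitError):
    """A settings profile was readable but is not a JSON object."""


class PathEscapeError(TrialkitError):
    """A write destination resolved outside the output directory tree."""


class SessionExistsError(TrialkitError):
    """The session directory already holds data and overwrite was not set."""


class RejectedSampleError(TrialkitError):
    """A continuous-data row violated the strictly-increasing-time contract."""
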