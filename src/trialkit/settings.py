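"""Hierarchical settings with upward cascade.

Experimental parameters (independent variables) live in a chain of
:class:`SettingsNode` objects — trial -> block -> session -> optional
profile. A lookup that misses at one level cascades upward, so a parameter
can be stored "gross" (once, at the session) or "fine" (on a single trial
that deviates) within the same mechanism. A miss at every level raises
:class:`~trialkit.errors.MissingSettingError` naming the key and the levels
searched, so typos surface immediately instead of silently yielding a
default.

Profiles are plain JSON objects loaded from a file, a file-like object, or
any zero-argument callable returning JSON text (so a remote fetcher can be
injected in place of a local file).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Callable, Iterator, Mapping

from .errors import InvalidProfileError, MissingSettingError

__all__ = ["SettingsNode", "load_profile"]


class SettingsNode:
    """One level of the settings cascade: a local mapping plus a parent link.

    Parameters
    ----------
    local
        Initial key -> value mapping for this level. Values must be
        JSON-serializable (checked on assignment).
    parent
        The next level up, or None at the root.
    level
        Human-readable level name ("trial", "block", "session", "profile"),
        used in error messages.
    """

    __slots__ = ("local", "parent", "level")

    def __init__(
        self,
        local: Mapping[str, Any] | None = None,
        parent: "SettingsNode | None" = None,
        level: str = "session",
    ):
        self.local: dict[str, Any] = {}
        self.parent = parent
        self.level = level
        for key, value in (local or {}).items():
            self.set(key, value)

    # -- resolution ---------------------------------------------------------

    def chain(self) -> Iterator["SettingsNode"]:
        """Yield nodes from this level upward to the root."""
        node: SettingsNode | None = self
        seen: set[int] = set()
        while node is not None:
            if id(node) in seen:  # defensive: parent links must be acyclic
                raise ValueError("settings parent chain contains a cycle")
            seen.add(id(node))
            yield node
            node = node.parent

    def get(self, key: str) -> Any:
        """Resolve ``key``, cascading upward; raise if absent everywhere."""
        if not key:
            raise ValueError("setting key must be a nonempty string")
        for node in self.chain():
            if key in node.local:
                return node.local[key]
        raise MissingSettingError(key, [node.level for node in self.chain()])

    def __getitem__(self, key: str) -> Any:
        return self.get(key)

    def __contains__(self, key: str) -> bool:
        return any(key in node.local for node in self.chain())

    # -- mutation -----------------------------------------------------------

    def set(self, key: str, value: Any) -> None:
        """Set ``key`` locally, shadowing any ancestor value for this subtree."""
        if not key or not isinstance(key, str):
            raise ValueError("setting key must be a nonempty string")
        try:
            json.dumps(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"setting {key!r}: value is not JSON-serializable: {exc}"
            ) from exc
        self.local[key] = value

    def __setitem__(self, key: str, value: Any) -> None:
        self.set(key, value)

    def update(self, mapping: Mapping[str, Any]) -> None:
        for key, value in mapping.items():
            self.set(key, value)

    def __repr__(self) -> str:
        return f"SettingsNode(level={self.level!r}, local={self.local!r})"


ProfileSource = str | Path | Callable[[], str]


def load_profile(source: ProfileSource | Any) -> dict[str, Any]:
    """Load a settings profile and return its mapping.

    ``source`` may be a filesystem path, an open text file, or a callable
    returning JSON text. The document root must be a single JSON object;
    malformed JSON propagates as :class:`json.JSONDecodeError` (which carries
    the error position), and a non-object root raises
    :class:`InvalidProfileError`.
    """
    if callable(source):
        text = source()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    obj = json.loads(text)
    if not isinstance(obj, dict):
        raise InvalidProfileError(
            f"profile root must be a JSON object, got {type(obj).__name__}"
        )
    return obj
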