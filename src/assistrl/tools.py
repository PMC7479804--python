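"""Support-tool selection from gaze dwell and per-user usage frequencies.

When the agent decides to help, the concrete tool to trigger is the one the
user has used most often for the content type (text or image) gazed at the
longest during the last window. Usage counts live in a local per-user
profile and are incremented on every trigger, including manual ones, so the
selector keeps learning the user's preferences from corrections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

from .windows import CONTENT_TYPES

__all__ = [
    "ToolProfile",
    "NoToolError",
    "UnknownToolError",
    "select_tool",
    "record_usage",
    "load_profiles",
    "save_profiles",
]

#: dwell summary: content type -> cumulative fixation milliseconds
DwellSummary = Dict[str, float]


class NoToolError(LookupError):
    """No tool is available for any content type (caller may fall back to ASK)."""


class UnknownToolError(KeyError):
    """record_usage called with a tool_id absent from the profile set."""


@dataclass
class ToolProfile:
    tool_id: str
    content_type: str
    usage_count: int = 0

    def __post_init__(self) -> None:
        if self.content_type not in CONTENT_TYPES:
            raise ValueError(f"unknown content type {self.content_type!r}")
        if self.usage_count < 0:
            raise ValueError("usage_count must be non-negative")


def _best_tool(candidates: Sequence[ToolProfile]) -> str:
    # max usage first, then lexicographically smallest id for reproducibility
    return min(candidates, key=lambda p: (-p.usage_count, p.tool_id)).tool_id


def select_tool(dwell: DwellSummary, profiles: Iterable[ToolProfile]) -> str:
    """Pick the tool to trigger for the content type dwelt on the longest.

    Dwell ties prefer text; usage ties prefer the lexicographically smallest
    tool id. If the winning content type has no tools the other type is
    tried; an empty profile set raises :class:`NoToolError`.
    """
    profiles = list(profiles)
    if not profiles:
        raise NoToolError("no tools in profile")
    seen = set()
    for p in profiles:
        if p.tool_id in seen:
            raise ValueError(f"duplicate tool_id {p.tool_id!r}")
        seen.add(p.tool_id)

    # text wins dwell ties (listed first in CONTENT_TYPES)
    order = sorted(CONTENT_TYPES,
                   key=lambda ct: -float(dwell.get(ct, 0.0)))
    for ct in order:
        candidates = [p for p in profiles if p.content_type == ct]
        if candidates:
            return _best_tool(candidates)
    raise NoToolError("no tools in profile")


def record_usage(profiles: Iterable[ToolProfile], tool_id: str) -> None:
    """Increment the usage count of ``tool_id`` (monotone, in place)."""
    for p in profiles:
        if p.tool_id == tool_id:
            p.usage_count += 1
            return
    raise UnknownToolError(tool_id)


def save_profiles(profiles: Iterable[ToolProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"tool_id": p.tool_id, "content_type": p.content_type,
              "usage_count": p.usage_count} for p in profiles],
            fh, indent=1)


def load_profiles(path) -> List[ToolProfile]:
    with open(path) as fh:
        arr = json.load(fh)
    return [ToolProfile(tool_id=o["tool_id"], content_type=o["content_type"],
                        usage_count=int(o.get("usage_count", 0))) for o in arr]
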