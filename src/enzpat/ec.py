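"""EC numbers: the four-level hierarchical enzyme classification.

An EC number has the form ``class.subclass.sub-subclass.serial``
(e.g. ``1.1.1.1`` for alcohol dehydrogenase).  Trailing levels may be
unspecified, written ``-`` (e.g. ``1.1.1.-`` or ``1.-.-.-``); once a level
is unspecified all deeper levels must be unspecified as well, and the top
level (the class) is always specified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

Level = Optional[int]

#: Regex for EC tokens as they appear in description lines, e.g. "EC 1.1.1.1"
#: or "EC 2.2.27.-".  Unspecified tails use "-".
EC_TOKEN_RE = re.compile(r"EC[ =]\s*(\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:\d+|-))")


class ECParseError(ValueError):
    """Raised when a string is not a valid EC number."""


@dataclass(frozen=True)
class ECNumber:
    """A four-level EC classifier with per-level "unspecified" markers."""

    levels: tuple[Level, Level, Level, Level]

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ECParseError(f"EC number needs 4 levels, got {self.levels!r}")
        if self.levels[0] is None:
            raise ECParseError("EC class (level 1) must be specified")
        seen_unspecified = False
        for lv in self.levels:
            if lv is None:
                seen_unspecified = True
            else:
                if seen_unspecified:
                    raise ECParseError(
                        f"specified level after unspecified one in {self.levels!r}"
                    )
                if not (isinstance(lv, int) and lv > 0):
                    raise ECParseError(f"EC levels must be positive ints: {self.levels!r}")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if not 1 <= len(parts) <= 4:
            raise ECParseError(f"cannot parse EC number {text!r}")
        levels: list[Level] = []
        for part in parts:
            part = part.strip()
            if part == "-" or part == "":
                levels.append(None)
            elif part.isdigit():
                levels.append(int(part))
            else:
                raise ECParseError(f"cannot parse EC number {text!r}")
        levels.extend([None] * (4 - len(levels)))
        return cls(tuple(levels))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return ".".join("-" if lv is None else str(lv) for lv in self.levels)

    def __repr__(self) -> str:  # compact, reads like the domain notation
        return f"EC({self})"

    @property
    def sub_subclass(self) -> tuple[Level, Level, Level]:
        """The first three levels (e.g. ``(1, 1, 1)`` for ``1.1.1.*``)."""
        return self.levels[:3]

    @property
    def n_specified(self) -> int:
        return sum(1 for lv in self.levels if lv is not None)

    @property
    def is_fully_specified(self) -> bool:
        return self.n_specified == 4

    @property
    def sort_key(self) -> tuple[int, int, int, int]:
        # unspecified sorts before any specified serial at the same prefix
        return tuple(-1 if lv is None else lv for lv in self.levels)  # type: ignore[return-value]

    def truncated(self, n_levels: int) -> "ECNumber":
        """Copy with everything below ``n_levels`` marked unspecified."""
        if not 1 <= n_levels <= 4:
            raise ValueError("n_levels must be in 1..4")
        levels = self.levels[:n_levels] + (None,) * (4 - n_levels)
        return ECNumber(levels)  # type: ignore[arg-type]


def extract_ec_tokens(text: str) -> list[str]:
    """EC strings from free text, in order of appearance, deduplicated."""
    seen: list[str] = []
    for match in EC_TOKEN_RE.finditer(text):
        token = match.group(1)
        if token not in seen:
            seen.append(token)
    return seen


def format_ec_set(ecs) -> str:
    """Serialize a set of ECNumbers as a semicolon-joined, sorted string."""
    return ";".join(str(e) for e in sorted(ecs, key=lambda e: e.sort_key))


def parse_ec_set(text: str) -> frozenset[ECNumber]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(ECNumber.parse(tok) for tok in text.split(";") if tok.strip())
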