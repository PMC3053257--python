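"""Mapping heading/subheading context onto the 26 phenotype areas.

Clinical-synopsis headings are free text and drift across records
("Head" vs "Head and Neck", "Respiratory" vs "Airways").  Phrase
comparison is only meaningful between phrases from the same body
system, so every heading is normalized and mapped to one or more of 26
manually defined areas.  Area 1 is reserved for syndrome names and area
26 ("Misc") is the non-clusterable fallback for unmatched headings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

__all__ = [
    "AreaTable",
    "AreaConfigError",
    "MISC_AREA",
    "SYNDROME_NAME_AREA",
    "load_area_table",
    "default_area_table",
    "map_to_areas",
    "normalize_heading",
]

SYNDROME_NAME_AREA = 1
MISC_AREA = 26


class AreaConfigError(ValueError):
    """The area table config violates the table invariants."""


@dataclass
class AreaTable:
    """Areas plus (heading pattern, subheading pattern) -> area-id rules."""

    areas: list[tuple[int, str]]
    rules: dict[tuple[str, Optional[str]], frozenset[int]] = field(default_factory=dict)

    @property
    def area_names(self) -> dict[int, str]:
        return dict(self.areas)

    def validate(self) -> None:
        ids = [i for i, _ in self.areas]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AreaConfigError(f"duplicate area_id(s): {dupes}")
        names = {name.lower() for _, name in self.areas}
        if "misc" not in names or MISC_AREA not in ids:
            raise AreaConfigError("area table must define area 26 'Misc'")
        known = set(ids)
        for pattern, targets in self.rules.items():
            missing = targets - known
            if missing:
                raise AreaConfigError(f"rule {pattern!r} targets unknown area(s) {sorted(missing)}")
            if not targets:
                raise AreaConfigError(f"rule {pattern!r} targets no area")


_PUNCT = re.compile(r"[^\w\s]")


def normalize_heading(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_PUNCT.sub(" ", text.lower()).split())


def map_to_areas(heading: str, subheading: Optional[str], table: AreaTable) -> set[int]:
    """Map a heading (and optional subheading) to its area ids.

    Matching is case-insensitive on the normalized heading text; the
    subheading, when present, refines the mapping (union of the heading
    rule and the subheading rule).  Unmatched context falls back to the
    Misc area, so the mapping is total.
    """
    if not heading.strip():
        raise ValueError("heading must be nonempty")
    hits: set[int] = set()
    h = normalize_heading(heading)
    s = normalize_heading(subheading) if subheading else None
    for key in [(h, s), (h, None)] + ([(s, None)] if s else []):
        if key in table.rules:
            hits |= table.rules[key]
    return hits or {MISC_AREA}


_AREA_LINE = re.compile(r"^area\s+(\d+)\s+(.+?)\s*$")


def _parse_area_config(text: str, source: str) -> AreaTable:
    areas: list[tuple[int, str]] = []
    rules: dict[tuple[str, Optional[str]], frozenset[int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _AREA_LINE.match(line)
        if m:
            areas.append((int(m.group(1)), m.group(2)))
            continue
        if "->" not in line:
            raise AreaConfigError(f"{source}:{lineno}: expected 'pattern -> area ids', got {line!r}")
        lhs, _, rhs = line.partition("->")
        try:
            targets = frozenset(int(part) for part in rhs.split(","))
        except ValueError as exc:
            raise AreaConfigError(f"{source}:{lineno}: bad area id list {rhs.strip()!r}") from exc
        heading_pat, _, sub_pat = lhs.partition("|")
        key = (normalize_heading(heading_pat), normalize_heading(sub_pat) or None)
        rules[key] = rules.get(key, frozenset()) | targets
    table = AreaTable(areas, rules)
    table.validate()
    return table


def load_area_table(path: str | Path) -> AreaTable:
    """Load an area table from a config file (format documented in areas.cfg)."""
    path = Path(path)
    return _parse_area_config(path.read_text("utf-8"), str(path))


def default_area_table() -> AreaTable:
    """The packaged 26-area table reconstructed from the published area names."""
    text = resources.files("phenonorm.data").joinpath("areas.cfg").read_text("utf-8")
    return _parse_area_config(text, "areas.cfg")
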