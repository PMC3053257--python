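"""Reading and writing clinical-synopsis corpora.

A corpus is a list of :class:`ClinicalSynopsisRecord`, each mirroring the
structure of an OMIM-style Clinical Synopsis entry: a numeric record id, a
syndrome name, and an ordered list of phenotype phrases, each carrying its
heading and optional subheading context.

Two plain-text dialects are supported:

``cs-text``
    Records start with ``#<record_id> <NAME>``.  A ``[Heading]`` or
    ``[Heading/Subheading]`` line opens a context block; each following
    non-empty line holds one or more phenotype phrases separated by ``;``.

``tsv``
    One phrase per row with columns
    ``record_id  name  heading  subheading  phrase`` (UTF-8, LF, header row).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalSynopsisRecord",
    "CorpusFormat",
    "CorpusParseError",
    "Entry",
    "read_corpus",
    "write_corpus",
]

CorpusFormat = Literal["cs-text", "tsv"]


class CorpusParseError(ValueError):
    """A corpus file does not conform to its declared dialect."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Entry:
    """One phenotype phrase with its heading/subheading context."""

    heading: str
    subheading: Optional[str]
    phrase: str

    def __post_init__(self) -> None:
        if not self.heading.strip():
            raise ValueError("entry heading must be nonempty")
        if not self.phrase.strip():
            raise ValueError("entry phrase must be nonempty")
        if "\n" in self.phrase or "\r" in self.phrase:
            raise ValueError("phrase must not contain line breaks")


@dataclass
class ClinicalSynopsisRecord:
    """One syndrome: id, name, and its clinical-synopsis phrase entries."""

    record_id: str
    name: str
    entries: list[Entry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not re.fullmatch(r"\d{6}", self.record_id):
            raise ValueError(f"record_id must be a 6-digit string, got {self.record_id!r}")
        if not self.name.strip():
            raise ValueError("record name must be nonempty")


_RECORD_HEADER = re.compile(r"^#(\d{6})\s+(.+?)\s*$")
_CONTEXT_LINE = re.compile(r"^\[([^\[\]/]+)(?:/([^\[\]/]+))?\]\s*$")


def read_corpus(path: str | Path, format: CorpusFormat = "cs-text") -> list[ClinicalSynopsisRecord]:
    """Read a corpus file in the ``cs-text`` or ``tsv`` dialect.

    Phrases are whitespace-trimmed; in ``cs-text``, semicolon-separated
    alternates on one line become separate entries.  Empty phrases (after
    trimming) are skipped with a logged warning.  Malformed structure raises
    :class:`CorpusParseError` naming the offending line.
    """
    path = Path(path)
    if format == "cs-text":
        return _read_cs_text(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown corpus format: {format!r}")


def _read_cs_text(path: Path) -> list[ClinicalSynopsisRecord]:
    records: list[ClinicalSynopsisRecord] = []
    seen_ids: set[str] = set()
    current: Optional[ClinicalSynopsisRecord] = None
    heading: Optional[str] = None
    subheading: Optional[str] = None
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = _RECORD_HEADER.match(line)
                if not m:
                    raise CorpusParseError(
                        f"malformed record header {line!r} "
                        "(expected '#<6-digit id> <NAME>')",
                        lineno,
                    )
                rid, name = m.group(1), m.group(2)
                if rid in seen_ids:
                    raise CorpusParseError(f"duplicate record id {rid}", lineno)
                seen_ids.add(rid)
                current = ClinicalSynopsisRecord(rid, name)
                records.append(current)
                heading = subheading = None
                continue
            if line.lstrip().startswith("["):
                m = _CONTEXT_LINE.match(line.strip())
                if not m:
                    raise CorpusParseError(f"malformed heading line {line!r}", lineno)
                if current is None:
                    raise CorpusParseError("heading line before any record header", lineno)
                heading = m.group(1).strip()
                subheading = m.group(2).strip() if m.group(2) else None
                if not heading:
                    raise CorpusParseError("empty heading", lineno)
                continue
            # phrase line
            if current is None:
                raise CorpusParseError("phrase line before any record header", lineno)
            if heading is None:
                raise CorpusParseError("phrase line before any [Heading] line", lineno)
            for part in line.split(";"):
                phrase = part.strip()
                if not phrase:
                    logger.warning("%s:%d: empty phrase skipped", path, lineno)
                    continue
                current.entries.append(Entry(heading, subheading, phrase))
    return records


_TSV_COLUMNS = ["record_id", "name", "heading", "subheading", "phrase"]


def _read_tsv(path: Path) -> list[ClinicalSynopsisRecord]:
    records: list[ClinicalSynopsisRecord] = []
    by_id: dict[str, ClinicalSynopsisRecord] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header != _TSV_COLUMNS:
            raise CorpusParseError(
                f"bad TSV header {header!r}, expected {_TSV_COLUMNS}", 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_TSV_COLUMNS):
                raise CorpusParseError(f"expected {len(_TSV_COLUMNS)} columns, got {len(row)}", lineno)
            rid, name, heading, subheading, phrase = (c.strip() for c in row)
            if not re.fullmatch(r"\d{6}", rid):
                raise CorpusParseError(f"malformed record id {rid!r}", lineno)
            rec = by_id.get(rid)
            if rec is None:
                rec = ClinicalSynopsisRecord(rid, name)
                by_id[rid] = rec
                records.append(rec)
            elif rec.name != name:
                raise CorpusParseError(
                    f"record {rid} given two names ({rec.name!r} vs {name!r})", lineno
                )
            if not phrase:
                logger.warning("%s:%d: empty phrase skipped", path, lineno)
                continue
            if not heading:
                raise CorpusParseError("empty heading", lineno)
            rec.entries.append(Entry(heading, subheading or None, phrase))
    return records


def write_corpus(
    records: Iterable[ClinicalSynopsisRecord],
    path: str | Path,
    format: CorpusFormat = "cs-text",
) -> None:
    """Write records so that :func:`read_corpus` round-trips them exactly."""
    path = Path(path)
    if format == "cs-text":
        _write_cs_text(records, path)
    elif format == "tsv":
        _write_tsv(records, path)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


def _write_cs_text(records: Iterable[ClinicalSynopsisRecord], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f"#{rec.record_id} {rec.name}\n")
            context: Optional[tuple[str, Optional[str]]] = None
            for entry in rec.entries:
                key = (entry.heading, entry.subheading)
                if key != context:
                    if entry.subheading:
                        fh.write(f"[{entry.heading}/{entry.subheading}]\n")
                    else:
                        fh.write(f"[{entry.heading}]\n")
                    context = key
                fh.write(entry.phrase + "\n")


def _write_tsv(records: Iterable[ClinicalSynopsisRecord], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for rec in records:
            for entry in rec.entries:
                writer.writerow(
                    [rec.record_id, rec.name, entry.heading, entry.subheading or "", entry.phrase]
                )
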