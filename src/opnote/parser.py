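"""Section-header detection, canonicalization and note segmentation.

Operative notes in the EHR are assembled from a template whose sections are
introduced by short headers (``INDICATIONS:``, ``OPERATIVE DETAILS:`` ...),
but the surface form of a header varies by template vintage and by surgeon
("OPERATIVE TECHNIQUE", "Procedure Description", ...).  This module

1. detects candidate headers by a surface convention (a line-initial run of
   1-5 words ending in a colon, either predominantly uppercase or short
   title-case),
2. canonicalizes each detected header against a user-supplied alias map by
   exact case-insensitive lookup, falling back to normalized indel
   (Levenshtein-ratio) similarity for typos, and
3. splits the note into sections and extracts a requested target section.

Unparseable notes are *data*, not errors: a :class:`SectionedNote` carries a
status of ``parsed`` or exactly one failure reason (``no_header``,
``malformed_header``, ``unrecognized_header``), so a corpus parse reports a
failure taxonomy rather than crashing.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .io import OperativeNote

__all__ = [
    "HeaderAliasMap",
    "SectionedNote",
    "Segment",
    "indel_similarity",
    "detect_headers",
    "candidate_header_lines",
    "canonicalize_header",
    "extract_section",
    "parse_corpus",
    "write_sections_jsonl",
    "write_parse_report",
    "DEFAULT_ALIAS_MAP",
]

# Parse statuses
PARSED = "parsed"
NO_HEADER = "no_header"
MALFORMED_HEADER = "malformed_header"
UNRECOGNIZED_HEADER = "unrecognized_header"
FAILURE_REASONS = (UNRECOGNIZED_HEADER, NO_HEADER, MALFORMED_HEADER)


def indel_similarity(a: str, b: str) -> float:
    """Normalized indel similarity: ``2*LCS(a,b) / (len(a)+len(b))``.

    Equivalent to ``1 - indel_distance/(len(a)+len(b))`` where the indel
    distance allows insertions and deletions only.  Returns 1.0 for two empty
    strings.
    """
    n, m = len(a), len(b)
    if n + m == 0:
        return 1.0
    if n == 0 or m == 0:
        return 0.0
    # single-row LCS DP; headers are short so O(n*m) is fine
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return 2.0 * prev[m] / (n + m)


@dataclass(frozen=True)
class HeaderAliasMap:
    """Canonical section names plus the variant headers that map to them.

    Alias lookup is case-insensitive; every canonical name is implicitly an
    alias of itself.  ``fuzzy_threshold`` is the minimum normalized indel
    similarity for a non-exact match.
    """

    canonical_names: tuple[str, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)
    fuzzy_threshold: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.fuzzy_threshold <= 1.0:
            raise ValueError("fuzzy_threshold must be in [0, 1]")
        canon = {c.lower() for c in self.canonical_names}
        norm = {}
        for alias, target in self.aliases.items():
            if target.lower() not in canon:
                raise ValueError(f"alias {alias!r} maps to unknown canonical {target!r}")
            key = alias.lower().strip()
            if key in norm and norm[key] != target.lower():
                raise ValueError(f"alias {alias!r} maps to two canonical names")
            norm[key] = target.lower()
        object.__setattr__(self, "_norm_aliases", norm)
        object.__setattr__(self, "canonical_names", tuple(c.lower() for c in self.canonical_names))

    def lookup_table(self) -> dict[str, str]:
        """All known alias strings (lowercased), including canonical names."""
        table = {c: c for c in self.canonical_names}
        table.update(self._norm_aliases)  # type: ignore[attr-defined]
        return table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HeaderAliasMap":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(
            canonical_names=tuple(d["canonical_names"]),
            aliases=dict(d.get("aliases", {})),
            fuzzy_threshold=float(d.get("fuzzy_threshold", 0.85)),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "canonical_names": list(self.canonical_names),
            "aliases": dict(self.aliases),
            "fuzzy_threshold": self.fuzzy_threshold,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


#: Default alias map covering the template dialects seen in practice.
DEFAULT_ALIAS_MAP = HeaderAliasMap(
    canonical_names=("indications", "operative findings", "operative details"),
    aliases={
        "indication": "indications",
        "indications for procedure": "indications",
        "preoperative diagnosis": "indications",
        "findings": "operative findings",
        "intraoperative findings": "operative findings",
        "operative detail": "operative details",
        "operative technique": "operative details",
        "procedure description": "operative details",
        "description of procedure": "operative details",
        "procedure in detail": "operative details",
    },
)


# A candidate header line: 1-5 words then a colon at line start.  Case is not
# constrained here; the surface convention below decides well-formedness.
_CANDIDATE_RE = re.compile(
    r"^(?P<head>[A-Za-z][A-Za-z0-9'/&.-]*(?:[ \t]+[A-Za-z0-9'/&.-]+){0,4}):",
    re.MULTILINE,
)


def _is_well_formed(head: str) -> bool:
    """Surface convention for a real header.

    Either >=80% of alphabetic characters are uppercase, or the run is
    title-case (every word starts with an uppercase letter) and at most 40
    characters long.  Lowercase or in-line pseudo-headers fail.
    """
    alpha = [c for c in head if c.isalpha()]
    if not alpha:
        return False
    upper_frac = sum(c.isupper() for c in alpha) / len(alpha)
    if upper_frac >= 0.8:
        return True
    words = head.split()
    title_case = all(w[0].isupper() for w in words if w[0].isalpha())
    return title_case and len(head) <= 40


def candidate_header_lines(text: str) -> list[tuple[int, str]]:
    """All line-initial 1-5 word runs ending in a colon, regardless of case."""
    return [(m.start(), m.group("head")) for m in _CANDIDATE_RE.finditer(text)]


def detect_headers(text: str) -> list[tuple[int, str]]:
    """Detect well-formed headers: ``(char offset, header text without colon)``.

    Positions are strictly increasing; an empty list signals no header.
    """
    return [
        (pos, head)
        for pos, head in candidate_header_lines(text)
        if _is_well_formed(head)
    ]


def canonicalize_header(raw: str, alias_map: HeaderAliasMap) -> Optional[str]:
    """Map a raw header string to its canonical section name, or ``None``.

    Exact (case-insensitive) alias hits win; otherwise the canonical name of
    the best-scoring alias with similarity >= ``fuzzy_threshold``.
    """
    key = raw.strip().rstrip(":").strip().lower()
    if not key:
        return None
    table = alias_map.lookup_table()
    if key in table:
        return table[key]
    best_score, best_canon = 0.0, None
    for alias, canon in sorted(table.items()):
        score = indel_similarity(key, alias)
        if score > best_score:
            best_score, best_canon = score, canon
    if best_score >= alias_map.fuzzy_threshold:
        return best_canon
    return None


@dataclass(frozen=True)
class Segment:
    """One raw segment of a note: the header that opened it (None for the
    preamble before the first header), its canonical name if recognized, and
    the untrimmed body text up to the next header."""

    raw_header: Optional[str]
    canonical: Optional[str]
    body: str


@dataclass(frozen=True)
class SectionedNote:
    """A note split at detected headers, or a typed parse failure.

    ``status == "parsed"`` iff the requested target section is present with a
    non-empty body.  ``sections`` maps canonical section names to trimmed
    bodies (first occurrence wins); ``segments`` preserves the full note so
    that headers + bodies concatenate back to the original text.
    """

    note_id: str
    status: str
    sections: Mapping[str, str] = field(default_factory=dict)
    segments: tuple[Segment, ...] = ()
    target: Optional[str] = None

    @property
    def target_text(self) -> Optional[str]:
        if self.target is None:
            return None
        return self.sections.get(self.target)

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "status": self.status,
            "target": self.target,
            "sections": dict(self.sections),
        }


def split_segments(text: str) -> list[Segment]:
    """Split *text* at well-formed headers without canonicalization."""
    headers = detect_headers(text)
    segments: list[Segment] = []
    if not headers:
        return [Segment(None, None, text)]
    first_pos = headers[0][0]
    if first_pos > 0:
        segments.append(Segment(None, None, text[:first_pos]))
    for i, (pos, head) in enumerate(headers):
        body_start = pos + len(head) + 1  # skip the colon
        body_end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        segments.append(Segment(head, None, text[body_start:body_end]))
    return segments


def extract_section(
    note: OperativeNote,
    target: str,
    alias_map: HeaderAliasMap = DEFAULT_ALIAS_MAP,
) -> SectionedNote:
    """Extract the *target* canonical section from a note.

    Failure precedence: ``no_header`` (no candidate header lines at all) >
    ``malformed_header`` (candidate lines exist, none satisfies the surface
    convention) > ``unrecognized_header`` (well-formed headers exist but none
    canonicalizes to the target with a non-empty body).
    """
    target = target.lower()
    if target not in alias_map.canonical_names:
        raise ValueError(f"target {target!r} is not a canonical name in the alias map")

    text = note.text or ""
    headers = detect_headers(text)
    if not headers:
        status = NO_HEADER if not candidate_header_lines(text) else MALFORMED_HEADER
        return SectionedNote(
            note_id=note.note_id,
            status=status,
            segments=tuple(split_segments(text)),
            target=target,
        )

    segments = [
        Segment(seg.raw_header, canonicalize_header(seg.raw_header, alias_map), seg.body)
        if seg.raw_header is not None
        else seg
        for seg in split_segments(text)
    ]
    sections: dict[str, str] = {}
    for seg in segments:
        if seg.canonical is not None and seg.canonical not in sections:
            sections[seg.canonical] = seg.body.strip()

    status = PARSED if sections.get(target) else UNRECOGNIZED_HEADER
    return SectionedNote(
        note_id=note.note_id,
        status=status,
        sections=sections,
        segments=tuple(segments),
        target=target,
    )


def parse_corpus(
    notes: Sequence[OperativeNote],
    target: str,
    alias_map: HeaderAliasMap = DEFAULT_ALIAS_MAP,
) -> tuple[list[SectionedNote], dict[str, int]]:
    """Parse every note; return sectioned notes plus per-status counts."""
    sectioned = [extract_section(n, target, alias_map) for n in notes]
    counts = {PARSED: 0, UNRECOGNIZED_HEADER: 0, NO_HEADER: 0, MALFORMED_HEADER: 0}
    for s in sectioned:
        counts[s.status] += 1
    return sectioned, counts


def write_sections_jsonl(sectioned: Iterable[SectionedNote], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for s in sectioned:
            fh.write(json.dumps(s.to_dict(), sort_keys=True) + "\n")


def write_parse_report(sectioned: Iterable[SectionedNote], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "status"])
        for s in sectioned:
            writer.writerow([s.note_id, s.status])
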