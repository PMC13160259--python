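"""Note records and JSONL / plain-text corpus input-output.

A corpus is a list of :class:`OperativeNote`.  On disk it is JSONL: one JSON
object per line with keys ``note_id``, ``patient_id``, ``text`` and optional
``labels`` (a :class:`~opnote.taxonomy.LabelRecord` dict), ``cpt_codes``,
``age_years``, ``is_synthetic`` and ``injected_failure``.  A directory of
plain-text files (filename stem = note id) is also accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .taxonomy import LabelRecord

__all__ = ["OperativeNote", "read_notes_jsonl", "write_notes_jsonl", "read_notes_dir"]


@dataclass(frozen=True)
class OperativeNote:
    """One operative note with identifiers and optional gold labels.

    ``is_synthetic`` marks augmentation notes: they may be used for model
    training but are never placed in evaluation (test) folds.
    ``injected_failure`` is generator bookkeeping — the parse-failure reason a
    synthetic note was constructed to trigger, if any.
    """

    note_id: str
    patient_id: str
    text: str
    gold_labels: Optional[LabelRecord] = None
    cpt_codes: tuple[str, ...] = ()
    age_years: Optional[float] = None
    is_synthetic: bool = False
    injected_failure: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be non-empty")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    def with_text(self, text: str, injected_failure: Optional[str] = None) -> "OperativeNote":
        return replace(self, text=text, injected_failure=injected_failure)

    def to_dict(self) -> dict:
        d: dict = {
            "note_id": self.note_id,
            "patient_id": self.patient_id,
            "text": self.text,
        }
        if self.gold_labels is not None:
            d["labels"] = self.gold_labels.to_dict()
        if self.cpt_codes:
            d["cpt_codes"] = list(self.cpt_codes)
        if self.age_years is not None:
            d["age_years"] = self.age_years
        if self.is_synthetic:
            d["is_synthetic"] = True
        if self.injected_failure is not None:
            d["injected_failure"] = self.injected_failure
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OperativeNote":
        return cls(
            note_id=str(d["note_id"]),
            patient_id=str(d["patient_id"]),
            text=d.get("text", ""),
            gold_labels=LabelRecord.from_dict(d["labels"]) if "labels" in d else None,
            cpt_codes=tuple(str(c) for c in d.get("cpt_codes", ())),
            age_years=d.get("age_years"),
            is_synthetic=bool(d.get("is_synthetic", False)),
            injected_failure=d.get("injected_failure"),
        )


def read_notes_jsonl(path: str | Path) -> list[OperativeNote]:
    """Read a JSONL corpus.  Non-UTF-8 bytes are replaced, never fatal."""
    notes = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            note = OperativeNote.from_dict(d)
            if note.note_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate note_id {note.note_id!r}")
            seen.add(note.note_id)
            notes.append(note)
    return notes


def write_notes_jsonl(notes: Iterable[OperativeNote], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps(note.to_dict(), sort_keys=True) + "\n")


def read_notes_dir(directory: str | Path, patient_id: str = "unknown") -> list[OperativeNote]:
    """Read a directory of ``*.txt`` files, one note per file (stem = note id)."""
    directory = Path(directory)
    notes = []
    for p in sorted(directory.glob("*.txt")):
        text = p.read_text(encoding="utf-8", errors="replace")
        notes.append(OperativeNote(note_id=p.stem, patient_id=patient_id, text=text))
    return notes
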