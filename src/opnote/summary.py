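"""Dataset characteristics and procedure-code distribution reporting.

CPT codes are notoriously imprecise for cleft and craniofacial procedures —
alveolar bone grafting has no dedicated code at all — so identical
procedures are coded many different ways.  ``code_distribution`` quantifies
that variability for any labeled corpus: per procedure label, a table of
(code, count, percent) rows sorted by count.  ``dataset_characteristics``
produces the corpus-description numbers (notes, patients, procedures,
multi-procedure notes, age summary, per-class counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import OperativeNote

__all__ = ["CodeDistribution", "code_distribution", "dataset_characteristics"]


def _percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal (table convention)."""
    if total == 0:
        return 0.0
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CodeDistribution:
    """Ordered (code, count, percent) rows for one procedure label.

    Rows are sorted by count descending, ties by code ascending; percents
    are of ``total`` and rounded half-up to one decimal.
    """

    total: int
    rows: tuple[tuple[str, int, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["code", "count", "percent"])

    def to_markdown(self) -> str:
        lines = ["| CPT code | Procedures, n | % |", "| --- | --- | --- |"]
        for code, count, pct in self.rows:
            lines.append(f"| {code} | {count} | {pct} |")
        return "\n".join(lines)


def code_distribution(
    records: Iterable[tuple[str, str]],
) -> dict[str, CodeDistribution]:
    """Build per-label CPT code distributions from (label, code) records."""
    by_label: dict[str, dict[str, int]] = {}
    for label, code in records:
        if not code:
            raise ValueError(f"empty code for label {label!r}")
        by_label.setdefault(label, {})
        by_label[label][code] = by_label[label].get(code, 0) + 1
    out = {}
    for label, counts in by_label.items():
        total = sum(counts.values())
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rows = tuple((code, n, _percent(n, total)) for code, n in ordered)
        out[label] = CodeDistribution(total=total, rows=rows)
    return out


@dataclass(frozen=True)
class DatasetCharacteristics:
    n_notes: int
    n_patients: int
    n_procedures: int
    n_multi_procedure_notes: int
    n_synthetic: int
    age_mean: Optional[float]
    age_sd: Optional[float]
    age_min: Optional[float]
    age_max: Optional[float]
    per_class_counts: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_notes": self.n_notes,
            "n_patients": self.n_patients,
            "n_procedures": self.n_procedures,
            "n_multi_procedure_notes": self.n_multi_procedure_notes,
            "n_synthetic": self.n_synthetic,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "per_class_counts": dict(self.per_class_counts),
        }


def dataset_characteristics(
    notes: Sequence[OperativeNote],
    include_synthetic: bool = False,
) -> DatasetCharacteristics:
    """Corpus description: notes, patients, procedure counts, ages.

    Procedures are counted with multiplicity over primary labels; a
    multi-procedure note carries >= 2 primary labels.  Synthetic
    augmentation notes are excluded by default (they describe no real
    cohort) but tallied in ``n_synthetic`` either way.
    """
    n_synthetic = sum(1 for n in notes if n.is_synthetic)
    if not include_synthetic:
        notes = [n for n in notes if not n.is_synthetic]
    per_class: dict[str, int] = {}
    n_procedures = 0
    n_multi = 0
    for n in notes:
        if n.gold_labels is None:
            continue
        labels = n.gold_labels.primary
        n_procedures += len(labels)
        if len(labels) >= 2:
            n_multi += 1
        for c in labels:
            per_class[c] = per_class.get(c, 0) + 1
    ages = [n.age_years for n in notes if n.age_years is not None]
    return DatasetCharacteristics(
        n_notes=len(notes),
        n_patients=len({n.patient_id for n in notes}),
        n_procedures=n_procedures,
        n_multi_procedure_notes=n_multi,
        n_synthetic=n_synthetic,
        age_mean=float(np.mean(ages)) if ages else None,
        age_sd=float(np.std(ages, ddof=1)) if len(ages) > 1 else None,
        age_min=float(min(ages)) if ages else None,
        age_max=float(max(ages)) if ages else None,
        per_class_counts=dict(sorted(per_class.items())),
    )
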