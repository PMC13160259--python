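"""Label taxonomy and label records for the three-level procedure hierarchy.

The hierarchy classifies an operative note at three levels of granularity:

* **primary** — which procedure types the note documents (multilabel; a
  single anesthetic event frequently covers several procedures, e.g. a cleft
  lip repair performed alongside a limited-tip rhinoplasty);
* **subtype** — for procedure types that are staged, whether the documented
  procedure is a primary (first-time) repair or a revision;
* **technique** — the named surgical technique (e.g. Fisher anatomic-subunit
  repair for cleft lip; Furlow double-opposing Z-plasty for cleft palate).

Subtype and technique levels exist only for the primary classes where the
distinction is clinically meaningful and observable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "LabelTaxonomy",
    "LabelRecord",
    "DEFAULT_TAXONOMY",
    "PRIMARY_CLASSES",
]

#: Canonical primary procedure classes, in reporting order.
PRIMARY_CLASSES = (
    "cleft_lip",
    "abg",
    "cleft_palate",
    "vpi",
    "rhinoplasty",
    "other",
)


@dataclass(frozen=True)
class LabelTaxonomy:
    """The class sets at each level of the cascade.

    ``subtype_classes`` and ``technique_classes`` are keyed by primary class;
    a primary class absent from a mapping has no classifier at that level.
    """

    primary_classes: tuple[str, ...] = PRIMARY_CLASSES
    subtype_classes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "cleft_lip": ("primary", "revision"),
            "abg": ("primary", "revision"),
        }
    )
    technique_classes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "cleft_lip": (
                "fisher",
                "modified_rotation_advancement",
                "mulliken",
                "other",
            ),
            "cleft_palate": (
                "von_langenbeck",
                "bardach",
                "veau_wardill_kilner",
                "furlow",
                "sommerlad",
                "other",
            ),
            "vpi": (
                "cleft_palate_revision",
                "sphincteroplasty_pharyngoplasty",
            ),
        }
    )

    def __post_init__(self) -> None:
        primaries = set(self.primary_classes)
        if len(primaries) != len(self.primary_classes):
            raise ValueError("primary classes must be distinct")
        for name, mapping in (
            ("subtype", self.subtype_classes),
            ("technique", self.technique_classes),
        ):
            for parent, classes in mapping.items():
                if parent not in primaries:
                    raise ValueError(
                        f"{name} parent {parent!r} is not a primary class"
                    )
                if not classes or len(set(classes)) != len(classes):
                    raise ValueError(
                        f"{name} classes for {parent!r} must be non-empty and distinct"
                    )

    def validate_record(self, record: "LabelRecord") -> None:
        """Raise ``ValueError`` if *record* is not valid under this taxonomy."""
        primaries = set(self.primary_classes)
        for c in record.primary:
            if c not in primaries:
                raise ValueError(f"unknown primary class {c!r}")
        for parent, sub in record.subtype.items():
            if parent not in record.primary:
                raise ValueError(f"subtype for absent primary class {parent!r}")
            allowed = self.subtype_classes.get(parent)
            if allowed is None or sub not in allowed:
                raise ValueError(f"invalid subtype {sub!r} for {parent!r}")
        for parent, tech in record.technique.items():
            if parent not in record.primary:
                raise ValueError(f"technique for absent primary class {parent!r}")
            allowed = self.technique_classes.get(parent)
            if allowed is None or tech not in allowed:
                raise ValueError(f"invalid technique {tech!r} for {parent!r}")


@dataclass(frozen=True)
class LabelRecord:
    """Gold or predicted labels for one note.

    ``primary`` is a (possibly empty) frozenset of primary classes;
    ``subtype`` and ``technique`` map a primary class to its single
    subtype/technique label and may only mention classes present in
    ``primary``.
    """

    primary: frozenset[str] = frozenset()
    subtype: Mapping[str, str] = field(default_factory=dict)
    technique: Mapping[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "primary": sorted(self.primary),
            "subtype": dict(sorted(self.subtype.items())),
            "technique": dict(sorted(self.technique.items())),
        }

    @classmethod
    def from_dict(cls, d: Optional[Mapping]) -> "LabelRecord":
        if d is None:
            return cls()
        return cls(
            primary=frozenset(d.get("primary", ())),
            subtype=dict(d.get("subtype", {})),
            technique=dict(d.get("technique", {})),
        )


#: Default taxonomy used throughout the package.
DEFAULT_TAXONOMY = LabelTaxonomy()
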