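"""Deterministic template-based generator of gold-labeled operative-note corpora.

The generator is the hermetic stand-in for a real single-institution corpus:
it emulates the *structure* of such a corpus — per-class note counts,
frequent multi-procedure notes, EHR header dialects, a small fraction of
unparseable notes, long repetitive bodies with low lexical diversity — while
the text itself is assembled from fixed sentence banks, never from patient
data or a language model.  Everything is driven by a single seed, so two
runs with the same config produce byte-identical corpora.

Knobs that matter downstream:

* ``vocabulary_overlap`` in [0, 1] blends class-conditioned sentence draws
  with a pooled bank drawn from every class.  At 0 the classes have
  distinct vocabularies and the corpus is separable by construction; at 1
  the class-text association is destroyed and any classifier should fall to
  chance.
* ``subtype_overlap`` applies the same blending per parent class to the
  primary-vs-revision cue sentences only, reproducing the clinical failure
  mode where primary and revision procedures are documented in
  near-identical language.
* ``failure_rates`` rewrites a seeded subset of notes to trigger exactly one
  parser failure reason each (headers deleted, lowercased, or replaced by
  well-formed but unknown strings), with the intended reason recorded for
  later exact accounting.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .io import OperativeNote
from .taxonomy import DEFAULT_TAXONOMY, LabelRecord, LabelTaxonomy

__all__ = [
    "GeneratorConfig",
    "Verbosity",
    "AugmentationSpec",
    "generate_corpus",
    "assign_patients",
    "inject_failures",
    "paper_scale_config",
    "tiny_config",
]


# ---------------------------------------------------------------------------
# sentence banks

BOILERPLATE = (
    "The patient was brought to the operating room and placed in the supine position.",
    "General endotracheal anesthesia was induced without complication.",
    "The patient was prepped and draped in the usual sterile fashion.",
    "A surgical time out was performed and the correct site was confirmed.",
    "Local anesthetic with epinephrine was infiltrated and adequate time was allowed for hemostasis.",
    "Hemostasis was achieved with bipolar electrocautery.",
    "The wound was irrigated with warm saline solution.",
    "Antibiotic ointment was applied to the incision.",
    "The patient tolerated the procedure well and was transferred to the recovery room in stable condition.",
    "Estimated blood loss was minimal.",
    "Sponge and needle counts were correct at the end of the case.",
    "All instruments were accounted for at the conclusion of the procedure.",
    "The airway was suctioned and the patient was extubated in the operating room.",
    "No intraoperative complications were encountered.",
    "The anesthesia team monitored the patient throughout the case.",
    "Sterile dressings were applied.",
    "The family was updated in the waiting area after the procedure.",
    "Care was taken to protect the eyes with lubricant and tape.",
    "The throat pack was removed prior to emergence.",
    "Postoperative instructions were reviewed with the family.",
    "The patient was positioned with a shoulder roll and the head slightly extended.",
    "Preoperative antibiotics were administered prior to incision.",
    "The surgical field was injected with lidocaine with epinephrine.",
    "Closure was performed in layers with absorbable suture.",
    "Interrupted sutures were placed to approximate the skin edges.",
    "A small amount of bleeding was controlled with gentle pressure.",
    "The procedure was completed without difficulty.",
    "Intravenous fluids were administered by the anesthesia team.",
    "The patient remained hemodynamically stable throughout.",
    "Photographs were obtained for the medical record.",
    "The operative site was marked and verified against the consent form.",
    "A moistened gauze sponge was placed over the field between steps.",
    "The tissue planes were developed bluntly with a fine elevator.",
    "Meticulous attention was paid to the vascular pedicle during dissection.",
    "A single dose of dexamethasone was given to reduce postoperative swelling.",
    "The oropharynx was inspected and cleared of secretions.",
    "The endotracheal tube position was rechecked after final positioning.",
    "Loupes were worn for magnification during the fine dissection.",
    "The knots were buried to minimize irritation of the overlying tissue.",
    "A pediatric anesthesiologist managed the airway throughout the case.",
    "The drapes were removed and the skin was cleaned of residual prep solution.",
    "The specimen was sent to pathology for routine examination.",
    "Warming measures maintained normothermia for the duration of surgery.",
    "The recovery nurses received a full handoff at the bedside.",
    "Deep dermal stitches were followed by a running subcuticular layer.",
    "A nasal trumpet was available but not required at emergence.",
    "The urinary catheter was removed at the end of the procedure.",
    "Ophthalmic lubricant was reapplied before transfer off the table.",
    "The arms were tucked and padded at the sides with foam supports.",
    "Compression stockings were in place for the duration of the operation.",
    "The case proceeded according to the preoperative plan without deviation.",
    "Scar massage instructions were included in the discharge packet.",
    "The resident assisted under direct supervision for portions of the closure.",
    "The field was reexamined for bleeding after irrigation and suction.",
    "Topical thrombin was available on the field but was not needed.",
    "A soft diet was recommended for the first postoperative week.",
    "Arm restraints were applied per protocol before leaving the room.",
    "Follow up was arranged in the outpatient clinic within two weeks.",
    "The consent was reviewed with the family on the morning of surgery.",
    "The monitors were applied and baseline vital signs were recorded.",
    "A second surgical count was completed before skin closure.",
    "The bed was turned ninety degrees to facilitate surgical access.",
    "An oral gastric tube decompressed the stomach before emergence.",
    "The head of the bed was elevated slightly to reduce venous congestion.",
    "Bacitracin was applied along the suture line at the conclusion.",
    "The anesthetic record was reviewed and signed at the end of the case.",
    "A fluid bolus was administered to support perfusion during induction.",
    "The scrub technician confirmed the instrument trays were complete.",
    "Blood pressure remained within an acceptable range for age.",
    "The temperature probe confirmed normothermia at the close of surgery.",
    "Emergence from anesthesia was smooth and without laryngospasm.",
    "The safety strap was positioned across the thighs before incision.",
    "A preincision briefing reviewed the anticipated steps of the operation.",
    "The suction canisters were inspected to corroborate the estimated loss.",
    "All medications on the field were labeled according to protocol.",
    "The surgical site was reexamined before the dressings were placed.",
    "The parents verbalized understanding of the postoperative plan.",
    "Pain was managed with weight based dosing of analgesics.",
    "The child was transported to recovery with supplemental oxygen.",
    "The final sponge count matched the initial tally exactly.",
    "A humidified circuit was used to protect the small airway.",
    "The team debriefed on equipment needs at the end of the case.",
    "The operative tray was passed off for reprocessing after closure.",
    "Clear liquids were to be offered once fully awake in recovery.",
    "The intravenous line was secured with a transparent dressing.",
    "A warm blanket was placed before transfer to the recovery bay.",
    "The anesthesia machine passed its checks before the patient entered.",
    "The nursing documentation was completed contemporaneously.",
    "The surgeon remained present until the patient left the room.",
)

CLASS_SENTENCES: dict[str, tuple[str, ...]] = {
    "cleft_lip": (
        "Attention was turned to the cleft lip where the vermilion border was marked.",
        "The philtral columns were tattooed with methylene blue and the cupid bow peaks were identified.",
        "The orbicularis oris muscle was dissected and reapproximated across the cleft.",
        "The cheiloplasty markings were confirmed with calipers before incision.",
        "Mucosal flaps were elevated along the cleft margin of the lip.",
    ),
    "abg": (
        "The alveolar cleft was exposed through gingival incisions.",
        "Cancellous bone was harvested from the iliac crest through a small incision.",
        "The bone graft was packed into the alveolar cleft defect.",
        "Gingivoperiosteal flaps were advanced to cover the graft.",
        "The nasal floor was reconstructed to seal the oronasal communication.",
    ),
    "cleft_palate": (
        "The palatal shelves were infiltrated and mucoperiosteal flaps were designed.",
        "The levator veli palatini muscle was dissected free of its abnormal insertion.",
        "The nasal mucosa was closed followed by the oral mucosa in a water tight fashion.",
        "The hard palate cleft was closed with minimal tension.",
        "The hamulus was identified and the tensor tendon was addressed.",
    ),
    "vpi": (
        "Velopharyngeal function was assessed with the palate at rest and during phonation.",
        "The velopharyngeal port was visualized with red rubber catheters retracting the palate.",
        "Persistent hypernasality prompted operative correction of velopharyngeal insufficiency.",
    ),
    "rhinoplasty": (
        "A limited tip rhinoplasty was performed through an open approach.",
        "The nasal tip cartilages were exposed and reshaped with interdomal tip sutures.",
        "The alar base was repositioned to improve tip symmetry.",
        "A columellar strut graft was placed to support the nasal tip.",
        "The nasal tip was refined with a conservative cephalic trim of the alar cartilage.",
        "Alar rim contour was reassessed after each nasal tip suture was placed.",
    ),
    "other": (
        "Bilateral myringotomies were performed and tympanostomy tubes were placed.",
        "Retained sutures were removed under brief mask anesthesia.",
        "Dental rehabilitation with restorations was completed under general anesthesia.",
        "Examination under anesthesia was performed with cerumen removal.",
        "An ophthalmologic examination under anesthesia was completed.",
        "The gastrostomy site was inspected and the tube was exchanged.",
    ),
}

TECHNIQUE_SENTENCES: dict[tuple[str, str], tuple[str, ...]] = {
    ("cleft_lip", "fisher"): (
        "The anatomic subunit approximation technique of Fisher was used to design the repair.",
        "Fisher markings respecting the philtral subunit were drawn.",
    ),
    ("cleft_lip", "modified_rotation_advancement"): (
        "A modified rotation advancement flap was designed to lengthen the medial lip element.",
        "The rotation advancement markings were adjusted at the columellar base.",
    ),
    ("cleft_lip", "mulliken"): (
        "A Mulliken repair of the bilateral cleft lip was performed with prolabial unwinding.",
        "Bilateral markings per Mulliken were made with attention to the median tubercle.",
    ),
    ("cleft_lip", "other"): (
        "A straight line closure of the lip was elected.",
        "An adhesion cheiloplasty was performed as a staged approach.",
    ),
    ("cleft_palate", "von_langenbeck"): (
        "Bipedicled mucoperiosteal flaps were elevated in the manner of von Langenbeck.",
        "Lateral relaxing incisions were made preserving the anterior pedicles per von Langenbeck.",
    ),
    ("cleft_palate", "bardach"): (
        "A two flap palatoplasty per Bardach was performed.",
        "Bardach style flaps based on the greater palatine vessels were elevated.",
    ),
    ("cleft_palate", "veau_wardill_kilner"): (
        "A Veau Wardill Kilner pushback palatoplasty was performed.",
        "The pushback technique of Veau Wardill and Kilner was used to retroposition the palate.",
    ),
    ("cleft_palate", "furlow"): (
        "A Furlow double opposing z plasty was designed with the oral flap based posteriorly.",
        "The double opposing z plasty of Furlow was used to lengthen the palate.",
    ),
    ("cleft_palate", "sommerlad"): (
        "A Sommerlad radical intravelar veloplasty was performed under the operating microscope.",
        "The velar musculature was retropositioned per Sommerlad.",
    ),
    ("cleft_palate", "other"): (
        "A less common palatoplasty variant was used for this repair.",
        "An alveolar extension palatoplasty variant was elected.",
    ),
    ("vpi", "cleft_palate_revision"): (
        "The prior palatoplasty scar was excised and the palate was re repaired with muscle retropositioning.",
        "The previous palatal repair was taken down and the levator sling was reconstructed.",
    ),
    ("vpi", "sphincteroplasty_pharyngoplasty"): (
        "A superiorly based pharyngeal flap was elevated and inset into the soft palate.",
        "A sphincter pharyngoplasty was performed using the posterior tonsillar pillars.",
    ),
}

SUBTYPE_CUES: dict[tuple[str, str], tuple[str, ...]] = {
    ("cleft_lip", "primary"): (
        "No prior lip repair had been performed.",
        "This was the initial cheiloplasty for this patient.",
    ),
    ("cleft_lip", "revision"): (
        "The prior cheiloplasty scar was excised and revised.",
        "A whistle deformity from the previous lip repair was corrected.",
    ),
    ("abg", "primary"): (
        "No previous grafting of the alveolus had been performed.",
        "This was the first bone grafting procedure for the alveolar cleft.",
    ),
    ("abg", "revision"): (
        "The previous alveolar bone graft had resorbed and required repeat grafting.",
        "Regrafting of the alveolar cleft was undertaken after prior graft loss.",
    ),
}

INDICATION_PHRASES: dict[str, tuple[str, ...]] = {
    "cleft_lip": ("unilateral cleft lip", "an incomplete cleft lip deformity"),
    "abg": ("an alveolar cleft requiring bone grafting",),
    "cleft_palate": ("a cleft of the secondary palate",),
    "vpi": ("velopharyngeal insufficiency with hypernasal speech",),
    "rhinoplasty": ("a cleft nasal deformity",),
    "other": ("recurrent otitis media and related concerns", "routine interval care under anesthesia"),
}

FINDINGS_SENTENCES = (
    "Findings were consistent with the preoperative diagnosis.",
    "Anatomy was as expected for the known anomaly.",
    "The tissues were healthy and well perfused.",
    "Examination confirmed the planned pathology.",
)

SURGEON_SURNAMES = (
    "Alvarez", "Barker", "Chen", "Dominguez", "Ellison", "Farouk", "Grant",
    "Huang", "Ibrahim", "Jensen", "Kovacs", "Lindqvist", "Moreau", "Nakamura",
    "Okafor", "Petrov", "Quinn", "Rossi", "Singh", "Tanaka", "Urbina",
    "Vasquez", "Whitfield", "Xu", "Yamada", "Zielinski",
)

#: Well-formed but unknown header replacements (never canonicalizable).
UNKNOWN_HEADERS = ("ADDENDUM BLOCK", "RECORD LOCATOR", "COSIGN QUEUE")

#: Header dialects: canonical section -> surface form, with sampling weights.
DEFAULT_HEADER_DIALECTS: tuple[tuple[dict[str, str], float], ...] = (
    (
        {"indications": "INDICATIONS", "operative findings": "OPERATIVE FINDINGS",
         "operative details": "OPERATIVE DETAILS"},
        0.50,
    ),
    (
        {"indications": "INDICATIONS", "operative findings": "FINDINGS",
         "operative details": "OPERATIVE TECHNIQUE"},
        0.25,
    ),
    (
        {"indications": "Indications", "operative findings": "Operative Findings",
         "operative details": "Procedure Description"},
        0.15,
    ),
    (  # typo dialect: exercises the fuzzy-matching path
        {"indications": "INDICATION", "operative findings": "INTRAOPERATIVE FINDINGS",
         "operative details": "OPERATIVE DETALS"},
        0.10,
    ),
)

FAILURE_REASONS = ("unrecognized_header", "no_header", "malformed_header")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class Verbosity:
    """Operative-details body length targets, in words.

    Lengths are drawn from a lognormal with the given median, the sigma
    implied by mean/median, and clipped to [min, max].
    """

    mean_words: float = 244.0
    median_words: float = 223.0
    min_words: int = 5
    max_words: int = 809

    def __post_init__(self) -> None:
        if not self.min_words <= self.median_words <= self.max_words:
            raise ValueError("verbosity targets must satisfy min <= median <= max")
        if self.mean_words < self.median_words:
            raise ValueError("lognormal verbosity requires mean >= median")

    @property
    def sigma(self) -> float:
        return math.sqrt(max(0.0, 2.0 * math.log(self.mean_words / self.median_words)))


@dataclass(frozen=True)
class AugmentationSpec:
    """A block of synthetic-flagged rare-class notes."""

    primary: str
    count: int
    subtype: Optional[str] = None
    technique: Optional[str] = None


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 7
    #: (label set, note count) pairs; label sets may repeat a class never.
    combos: tuple[tuple[tuple[str, ...], int], ...] = ()
    #: per primary class: subtype -> count (summing to the class total), or None
    subtype_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    #: per primary class: technique -> count (summing to the class total), or None
    technique_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    augmentation: tuple[AugmentationSpec, ...] = ()
    header_dialects: tuple[tuple[dict[str, str], float], ...] = DEFAULT_HEADER_DIALECTS
    #: reason -> rate in [0, 1) or absolute count (>= 1)
    failure_rates: Mapping[str, float] = field(default_factory=dict)
    verbosity: Verbosity = Verbosity()
    vocabulary_overlap: float = 0.02
    subtype_overlap: Mapping[str, float] = field(default_factory=dict)
    shared_boilerplate_fraction: float = 0.70
    #: notes-per-patient value -> probability
    notes_per_patient: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 3: 0.15, 4: 0.15}
    )
    signal_sentences_per_procedure: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.vocabulary_overlap <= 1.0:
            raise ValueError("vocabulary_overlap must be in [0, 1]")
        for r in self.failure_rates:
            if r not in FAILURE_REASONS:
                raise ValueError(f"unknown failure reason {r!r}")
        for classes, count in self.combos:
            if count < 0:
                raise ValueError("combo counts must be non-negative")
            if len(set(classes)) != len(classes):
                raise ValueError(f"label set {classes} repeats a class")

    # -- derived ----------------------------------------------------------

    def class_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for classes, count in self.combos:
            for c in classes:
                totals[c] = totals.get(c, 0) + count
        return totals

    def n_notes(self) -> int:
        return sum(count for _, count in self.combos)

    def validate(self, taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY) -> None:
        known = set(taxonomy.primary_classes)
        for classes, _ in self.combos:
            unknown = set(classes) - known
            if unknown:
                raise ValueError(f"unknown label combination: {sorted(unknown)}")
        totals = self.class_totals()
        for cls, alloc in self.subtype_counts.items():
            if sum(alloc.values()) != totals.get(cls, 0):
                raise ValueError(
                    f"subtype counts for {cls!r} sum to {sum(alloc.values())}, "
                    f"expected {totals.get(cls, 0)}"
                )
            allowed = set(taxonomy.subtype_classes.get(cls, ()))
            if set(alloc) - allowed:
                raise ValueError(f"unknown subtype(s) for {cls!r}: {sorted(set(alloc) - allowed)}")
        for cls, alloc in self.technique_counts.items():
            if sum(alloc.values()) != totals.get(cls, 0):
                raise ValueError(
                    f"technique counts for {cls!r} sum to {sum(alloc.values())}, "
                    f"expected {totals.get(cls, 0)}"
                )
            allowed = set(taxonomy.technique_classes.get(cls, ()))
            if set(alloc) - allowed:
                raise ValueError(f"unknown technique(s) for {cls!r}: {sorted(set(alloc) - allowed)}")

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "combos": [{"classes": list(c), "count": n} for c, n in self.combos],
            "subtype_counts": {k: dict(v) for k, v in self.subtype_counts.items()},
            "technique_counts": {k: dict(v) for k, v in self.technique_counts.items()},
            "augmentation": [
                {"primary": a.primary, "count": a.count,
                 "subtype": a.subtype, "technique": a.technique}
                for a in self.augmentation
            ],
            "failure_rates": dict(self.failure_rates),
            "verbosity": {
                "mean_words": self.verbosity.mean_words,
                "median_words": self.verbosity.median_words,
                "min_words": self.verbosity.min_words,
                "max_words": self.verbosity.max_words,
            },
            "vocabulary_overlap": self.vocabulary_overlap,
            "subtype_overlap": dict(self.subtype_overlap),
            "shared_boilerplate_fraction": self.shared_boilerplate_fraction,
            "notes_per_patient": {int(k): float(v) for k, v in self.notes_per_patient.items()},
            "signal_sentences_per_procedure": self.signal_sentences_per_procedure,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        kwargs: dict = {"seed": int(d.get("seed", 7))}
        kwargs["combos"] = tuple(
            (tuple(item["classes"]), int(item["count"])) for item in d.get("combos", [])
        )
        kwargs["subtype_counts"] = d.get("subtype_counts", {})
        kwargs["technique_counts"] = d.get("technique_counts", {})
        kwargs["augmentation"] = tuple(
            AugmentationSpec(
                primary=a["primary"], count=int(a["count"]),
                subtype=a.get("subtype"), technique=a.get("technique"),
            )
            for a in d.get("augmentation", [])
        )
        kwargs["failure_rates"] = d.get("failure_rates", {})
        if "verbosity" in d:
            kwargs["verbosity"] = Verbosity(**d["verbosity"])
        for key in ("vocabulary_overlap", "shared_boilerplate_fraction",
                    "signal_sentences_per_procedure"):
            if key in d:
                kwargs[key] = d[key]
        if "subtype_overlap" in d:
            kwargs["subtype_overlap"] = d["subtype_overlap"]
        if "notes_per_patient" in d:
            kwargs["notes_per_patient"] = {int(k): float(v) for k, v in d["notes_per_patient"].items()}
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# text assembly


def _pick(rng: np.random.Generator, bank: Sequence[str]) -> str:
    return bank[int(rng.integers(len(bank)))]


_ALL_CLASS_SENTENCES = tuple(
    s for bank in CLASS_SENTENCES.values() for s in bank
) + tuple(s for bank in TECHNIQUE_SENTENCES.values() for s in bank)


def _class_sentence(rng: np.random.Generator, bank: Sequence[str], overlap: float) -> str:
    """Draw from *bank*, or from the all-class pool with probability *overlap*."""
    if overlap > 0 and rng.random() < overlap:
        return _pick(rng, _ALL_CLASS_SENTENCES)
    return _pick(rng, bank)


@dataclass
class _NoteSkeleton:
    index: int
    labels: LabelRecord
    is_synthetic: bool = False


def _assemble_text(
    skel: _NoteSkeleton,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> str:
    dialects, weights = zip(*config.header_dialects)
    w = np.asarray(weights, dtype=float)
    dialect = dialects[int(rng.choice(len(dialects), p=w / w.sum()))]

    classes = sorted(skel.labels.primary)
    order = [classes[i] for i in rng.permutation(len(classes))]

    # indications; age skewed young (most cleft procedures are staged in
    # infancy and childhood), clipped to 0-19 years
    age = int(min(19.0, rng.gamma(1.0, 4.0)))
    phrases = [_pick(rng, INDICATION_PHRASES[c]) for c in order]
    indication = (
        f"The patient is a {age} year old child with "
        + " and ".join(phrases)
        + " presenting for operative management."
    )
    finding = _pick(rng, FINDINGS_SENTENCES)

    # operative details: per-procedure signal block, then filler to target.
    # A note keeps returning to its own procedures' vocabulary — a Furlow
    # palatoplasty note mentions the z-plasty repeatedly — so class,
    # technique and subtype-cue sentences all recur in proportion to length.
    overlap = config.vocabulary_overlap

    def draw_subtype_cue(cls: str, sub: str) -> str:
        sub_overlap = config.subtype_overlap.get(cls, overlap)
        if sub_overlap > 0 and rng.random() < sub_overlap:
            pooled = tuple(
                s for (c, _), b in SUBTYPE_CUES.items() if c == cls for s in b
            )
            return _pick(rng, pooled)
        return _pick(rng, SUBTYPE_CUES[(cls, sub)])

    def draw_for_class(cls: str) -> str:
        """One sentence conditioned on this note's labels for *cls*."""
        sub = skel.labels.subtype.get(cls)
        tech = skel.labels.technique.get(cls)
        banks: list[tuple[str, tuple[str, ...]]] = [("class", CLASS_SENTENCES[cls])]
        if tech is not None:
            # heavily weighted: a note about a named technique keeps naming it
            bank = TECHNIQUE_SENTENCES[(cls, tech)]
            banks.append(("technique", bank * 4))
        if sub is not None:
            banks.append(("subtype", SUBTYPE_CUES[(cls, sub)]))
        total = sum(len(b) for _, b in banks)
        r = int(rng.integers(total))
        for kind, bank in banks:
            if r < len(bank):
                if kind == "subtype":
                    return draw_subtype_cue(cls, sub)
                return _class_sentence(rng, bank, overlap)
            r -= len(bank)
        raise AssertionError("unreachable")

    sentences: list[str] = []
    for cls in order:
        for _ in range(config.signal_sentences_per_procedure):
            sentences.append(_class_sentence(rng, CLASS_SENTENCES[cls], overlap))
        sub = skel.labels.subtype.get(cls)
        if sub is not None:
            sentences.append(draw_subtype_cue(cls, sub))
        tech = skel.labels.technique.get(cls)
        if tech is not None:
            for _ in range(2):
                sentences.append(
                    _class_sentence(rng, TECHNIQUE_SENTENCES[(cls, tech)], overlap)
                )

    verb = config.verbosity
    target = int(round(float(rng.lognormal(math.log(verb.median_words), verb.sigma))))
    target = max(verb.min_words, min(verb.max_words, target))
    words = " ".join(sentences).split()
    while len(words) < target:
        if rng.random() < config.shared_boilerplate_fraction:
            s = _pick(rng, BOILERPLATE)
        else:
            s = draw_for_class(order[int(rng.integers(len(order)))])
        words.extend(s.split())
    body = " ".join(words[:target])

    text = (
        f"{dialect['indications']}:\n{indication}\n\n"
        f"{dialect['operative findings']}:\n{finding}\n\n"
        f"{dialect['operative details']}:\n{body}\n"
    )
    return text, float(age)


# ---------------------------------------------------------------------------
# corpus construction


def _build_skeletons(
    config: GeneratorConfig,
    taxonomy: LabelTaxonomy,
    rng: np.random.Generator,
) -> list[_NoteSkeleton]:
    """Expand combos into per-note label records with exact counts."""
    totals = config.class_totals()
    # per-class pools of (subtype, technique) assignments, shuffled
    pools: dict[str, list[tuple[Optional[str], Optional[str]]]] = {}
    for cls, total in totals.items():
        subs: list[Optional[str]] = []
        if cls in config.subtype_counts:
            for sub, cnt in sorted(config.subtype_counts[cls].items()):
                subs.extend([sub] * cnt)
        else:
            subs = [None] * total
        techs: list[Optional[str]] = []
        if cls in config.technique_counts:
            for tech, cnt in sorted(config.technique_counts[cls].items()):
                techs.extend([tech] * cnt)
        else:
            techs = [None] * total
        subs = [subs[i] for i in rng.permutation(total)]
        techs = [techs[i] for i in rng.permutation(total)]
        pools[cls] = list(zip(subs, techs))

    skeletons: list[_NoteSkeleton] = []
    idx = 0
    for classes, count in config.combos:
        for _ in range(count):
            subtype: dict[str, str] = {}
            technique: dict[str, str] = {}
            for cls in classes:
                sub, tech = pools[cls].pop()
                if sub is not None:
                    subtype[cls] = sub
                if tech is not None:
                    technique[cls] = tech
            rec = LabelRecord(
                primary=frozenset(classes), subtype=subtype, technique=technique
            )
            taxonomy.validate_record(rec)
            skeletons.append(_NoteSkeleton(index=idx, labels=rec))
            idx += 1
    # fixed shuffle so label combos are not contiguous in note-id order
    skeletons = [skeletons[i] for i in rng.permutation(len(skeletons))]
    for new_idx, s in enumerate(skeletons):
        s.index = new_idx
    return skeletons


def generate_corpus(
    config: GeneratorConfig,
    taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY,
) -> list[OperativeNote]:
    """Generate the full corpus: labeled notes, patients, injected failures,
    and synthetic-flagged augmentation notes (appended last).

    Note counts per label combination match the config exactly; output is
    byte-identical for identical (config, seed).
    """
    config.validate(taxonomy)
    seq = np.random.SeedSequence(config.seed)
    rng_labels, rng_text, rng_patients, rng_failures, rng_aug = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )

    skeletons = _build_skeletons(config, taxonomy, rng_labels)
    width = max(4, len(str(len(skeletons))))
    notes = []
    for skel in skeletons:
        text, age = _assemble_text(skel, config, rng_text)
        notes.append(
            OperativeNote(
                note_id=f"note{skel.index:0{width}d}",
                patient_id="unassigned",
                text=text,
                gold_labels=skel.labels,
                age_years=age,
            )
        )
    notes = assign_patients(notes, config.notes_per_patient, rng_patients)

    if config.failure_rates:
        eligible = [
            n.note_id for n in notes
            if n.gold_labels is not None and n.gold_labels.primary == frozenset({"other"})
        ]
        notes = inject_failures(notes, config.failure_rates, rng_failures, eligible)

    # augmentation: synthetic-flagged rare-class notes on dedicated patients
    aug_notes: list[OperativeNote] = []
    for spec_idx, aug in enumerate(config.augmentation):
        for i in range(aug.count):
            rec = LabelRecord(
                primary=frozenset({aug.primary}),
                subtype={aug.primary: aug.subtype} if aug.subtype else {},
                technique={aug.primary: aug.technique} if aug.technique else {},
            )
            taxonomy.validate_record(rec)
            skel = _NoteSkeleton(index=len(notes) + len(aug_notes), labels=rec,
                                 is_synthetic=True)
            text, age = _assemble_text(skel, config, rng_aug)
            aug_notes.append(
                OperativeNote(
                    note_id=f"synth{spec_idx}_{i:03d}",
                    patient_id=f"synthpt_{spec_idx}_{i:03d}",
                    text=text,
                    gold_labels=rec,
                    age_years=age,
                    is_synthetic=True,
                )
            )
    return notes + aug_notes


def assign_patients(
    notes: Sequence[OperativeNote],
    notes_per_patient: Mapping[int, float],
    rng: np.random.Generator | int,
) -> list[OperativeNote]:
    """Group notes into patients and stamp patient ids.

    Patient sizes are drawn from ``notes_per_patient`` (value -> probability)
    until all notes are covered.  Every note of a multi-note patient gains a
    patient-specific attending-surgeon sentence, so grouped cross-validation
    is measurably harder than note-level cross-validation.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    sizes_bank = sorted(notes_per_patient)
    probs = np.asarray([notes_per_patient[s] for s in sizes_bank], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("notes_per_patient probabilities must be positive")
    probs = probs / probs.sum()

    n = len(notes)
    order = list(rng.permutation(n))
    sizes: list[int] = []
    covered = 0
    while covered < n:
        s = sizes_bank[int(rng.choice(len(sizes_bank), p=probs))]
        sizes.append(min(s, n - covered))
        covered += sizes[-1]

    out = list(notes)
    width = max(4, len(str(len(sizes))))
    pos = 0
    for p_idx, size in enumerate(sizes):
        pid = f"pt{p_idx:0{width}d}"
        members = order[pos: pos + size]
        pos += size
        style = SURGEON_SURNAMES[p_idx % len(SURGEON_SURNAMES)]
        for note_pos in members:
            note = out[note_pos]
            text = note.text
            if size > 1:
                sentence = (
                    f"Attending {style} was present and scrubbed for the entirety of the case."
                )
                # swap trailing filler words for the style sentence so the
                # body stays on its sampled word-count target
                lines = text.rstrip("\n").split("\n")
                body_words = lines[-1].split()
                k = len(sentence.split())
                if len(body_words) > k + 10:
                    body_words = body_words[:-k]
                lines[-1] = " ".join(body_words + sentence.split())
                text = "\n".join(lines) + "\n"
            out[note_pos] = replace(note, patient_id=pid, text=text)
    return out


_HEADER_LINE_RE = re.compile(r"^(?P<head>[A-Za-z][A-Za-z0-9'/&. -]{0,60}?):", re.MULTILINE)


def _rewrite_headers(text: str, reason: str, rng: np.random.Generator) -> str:
    """Rewrite every header line so the parser fails with exactly *reason*."""
    if reason == "no_header":
        return _HEADER_LINE_RE.sub("", text)
    if reason == "malformed_header":
        return _HEADER_LINE_RE.sub(lambda m: m.group("head").lower() + ":", text)
    if reason == "unrecognized_header":
        return _HEADER_LINE_RE.sub(
            lambda m: UNKNOWN_HEADERS[int(rng.integers(len(UNKNOWN_HEADERS)))] + ":",
            text,
        )
    raise ValueError(f"unknown failure reason {reason!r}")


def inject_failures(
    notes: Sequence[OperativeNote],
    failure_rates: Mapping[str, float],
    rng: np.random.Generator | int,
    eligible_ids: Optional[Sequence[str]] = None,
) -> list[OperativeNote]:
    """Rewrite a seeded subset of notes to trigger parser failures.

    Rates < 1 are fractions of ``len(notes)`` (rounded to the nearest
    count); values >= 1 are absolute counts.  Reasons are applied to
    disjoint note subsets drawn from ``eligible_ids`` (default: all notes);
    the intended reason is recorded on each rewritten note.
    """
    n = len(notes)
    counts: dict[str, int] = {}
    for reason in FAILURE_REASONS:  # fixed order for determinism
        rate = failure_rates.get(reason, 0.0)
        if rate < 0:
            raise ValueError("failure rates must be non-negative")
        counts[reason] = int(round(rate * n)) if rate < 1 else int(round(rate))
    total = sum(counts.values())
    if total == 0:
        return list(notes)

    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    pool = list(eligible_ids) if eligible_ids is not None else [n_.note_id for n_ in notes]
    if total > len(pool):
        raise ValueError(f"{total} failures requested but only {len(pool)} eligible notes")
    chosen = [pool[i] for i in rng.permutation(len(pool))[:total]]
    assignment: dict[str, str] = {}
    start = 0
    for reason in FAILURE_REASONS:
        for nid in chosen[start: start + counts[reason]]:
            assignment[nid] = reason
        start += counts[reason]

    out = []
    for note in notes:
        reason = assignment.get(note.note_id)
        if reason is None:
            out.append(note)
        else:
            out.append(note.with_text(_rewrite_headers(note.text, reason, rng), reason))
    return out


# ---------------------------------------------------------------------------
# bundled configurations


def paper_scale_config(seed: int = 7) -> GeneratorConfig:
    """Full-scale default corpus: 656 notes (630 parseable), matching the
    emulated study's per-class procedure totals (100 cleft lip, 105 ABG,
    104 cleft palate, 32 VPI, 36 rhinoplasty, 581 other over the parsed
    cohort), 184 multi-procedure notes, 958 procedures, 26 injected parse
    failures (3 unrecognized / 8 absent / 15 malformed headers), plus
    synthetic-flagged augmentation of the rare revision categories.

    The label-set table is exact by construction: failures are injected only
    into single-procedure "other" notes so the parsed cohort retains the
    target distribution.
    """
    combos: list[tuple[tuple[str, ...], int]] = [
        # singles (the 26 extra "other" notes will absorb the injected failures)
        (("other",), 397 + 26),
        (("cleft_lip",), 8),
        (("abg",), 22),
        (("cleft_palate",), 14),
        (("vpi",), 3),
        (("rhinoplasty",), 2),
        # doubles: each cleft-class procedure accompanied by an "other" procedure
        (("cleft_lip", "other"), 20),
        (("abg", "other"), 18),
        (("cleft_palate", "other"), 30),
        (("vpi", "other"), 8),
        (("rhinoplasty", "other"), 4),
        # triples
        (("cleft_lip", "abg", "other"), 16),
        (("cleft_lip", "rhinoplasty", "other"), 20),
        (("cleft_palate", "vpi", "other"), 16),
        (("cleft_palate", "abg", "other"), 12),
        # quadruples
        (("cleft_lip", "abg", "cleft_palate", "other"), 27),
        (("cleft_lip", "abg", "vpi", "other"), 2),
        (("abg", "cleft_palate", "vpi", "other"), 1),
        (("cleft_lip", "abg", "rhinoplasty", "other"), 5),
        (("cleft_lip", "cleft_palate", "rhinoplasty", "other"), 2),
        (("abg", "cleft_palate", "rhinoplasty", "other"), 1),
        (("abg", "vpi", "rhinoplasty", "other"), 1),
        (("cleft_palate", "vpi", "rhinoplasty", "other"), 1),
    ]
    return GeneratorConfig(
        seed=seed,
        combos=tuple(combos),
        subtype_counts={
            "cleft_lip": {"primary": 91, "revision": 9},
            "abg": {"primary": 96, "revision": 9},
        },
        technique_counts={
            "cleft_lip": {
                "fisher": 40, "modified_rotation_advancement": 30,
                "mulliken": 15, "other": 15,
            },
            "cleft_palate": {
                "furlow": 30, "von_langenbeck": 25, "bardach": 20,
                "veau_wardill_kilner": 12, "sommerlad": 10, "other": 7,
            },
            "vpi": {"sphincteroplasty_pharyngoplasty": 26, "cleft_palate_revision": 6},
        },
        augmentation=(
            AugmentationSpec(primary="cleft_lip", subtype="revision", count=9),
            AugmentationSpec(primary="abg", subtype="revision", count=9),
            AugmentationSpec(primary="vpi", technique="cleft_palate_revision", count=6),
        ),
        failure_rates={
            "unrecognized_header": 3, "no_header": 8, "malformed_header": 15,
        },
    )


def tiny_config(seed: int = 7) -> GeneratorConfig:
    """Small fast corpus (60 notes, short bodies) for smoke tests."""
    return GeneratorConfig(
        seed=seed,
        combos=(
            (("cleft_lip",), 8),
            (("abg",), 8),
            (("cleft_palate",), 8),
            (("vpi",), 6),
            (("rhinoplasty",), 6),
            (("other",), 12),
            (("cleft_lip", "rhinoplasty"), 6),
            (("abg", "other"), 6),
        ),
        subtype_counts={
            "cleft_lip": {"primary": 10, "revision": 4},
            "abg": {"primary": 10, "revision": 4},
        },
        technique_counts={
            "cleft_lip": {"fisher": 6, "modified_rotation_advancement": 4,
                          "mulliken": 2, "other": 2},
            "cleft_palate": {"furlow": 3, "von_langenbeck": 2, "bardach": 2,
                             "sommerlad": 1},
            "vpi": {"sphincteroplasty_pharyngoplasty": 4, "cleft_palate_revision": 2},
        },
        verbosity=Verbosity(mean_words=70.0, median_words=64.0, min_words=5, max_words=250),
    )
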