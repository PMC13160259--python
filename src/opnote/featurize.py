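"""Negation-preserving token filtering and TF-IDF featurization.

The pipeline from raw section text to model features is:

``preprocess`` — lowercase alphabetic tokenization, lemmatization, and stop
word removal with a negation whitelist.  Clinically load-bearing negations
("no", "not", "without" — e.g. "no fistula was identified") survive
filtering even though generic stop lists would drop them.

``build_ngrams`` — unigrams plus bigrams of adjacent *post-filter* tokens,
so that multiword clinical concepts ("water tight", "iliac crest") become
single features.

``fit_tfidf`` / ``transform`` — a fixed, fully specified TF-IDF dialect:
raw term counts, smoothed idf ``ln((1+N)/(1+df)) + 1``, L2 normalization,
and vocabulary truncation to the ``max_features`` terms with the highest
total corpus count (ties broken lexicographically).  Fitting consults the
training documents only; transforming ignores out-of-vocabulary terms.

Lemmatization is pluggable: any ``str -> str`` callable may be passed.  The
bundled default is a deterministic lookup-plus-suffix lemmatizer so results
do not depend on an external NLP model version; an adapter to a full
pipeline (e.g. a spaCy ``Language``) can be dropped in via ``lemmatizer=``.
"""

from __future__ import annotations

import json
import math
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "TokenStream",
    "TfidfModel",
    "CorpusStats",
    "DEFAULT_STOP_WORDS",
    "DEFAULT_NEGATION_WHITELIST",
    "default_lemmatizer",
    "preprocess",
    "build_ngrams",
    "fit_tfidf",
    "transform",
    "transform_corpus",
    "corpus_stats",
    "save_vectors_mtx",
]

# ---------------------------------------------------------------------------
# configuration: stop list and negation whitelist

#: Fixed English stop list (~290 words).  Generic function words only; domain
#: terms are never stopped.  Negations are *in* this list and rescued by the
#: whitelist so that the whitelist is the single switch controlling them.
DEFAULT_STOP_WORDS = frozenset("""
a about above across after afterwards again against all almost alone along
already also although always am among amongst an and another any anyhow
anyone anything anyway anywhere are around as at back be became because
become becomes becoming been before beforehand behind being below beside
besides between beyond both bottom but by call can cannot could did do does
doing done down due during each eg either else elsewhere enough etc even
ever every everyone everything everywhere except few fifteen fifty fill
find fire first five for former formerly forty found four from front full
further get give go had has have he hence her here hereafter hereby herein
hereupon hers herself him himself his how however hundred i ie if in inc
indeed into is it its itself just keep last latter latterly least less ltd
made many may me meanwhile might mine more moreover most mostly move much
must my myself name namely neither never nevertheless next nine no nobody
none noone nor not nothing now nowhere of off often on once one only onto
or other others otherwise our ours ourselves out over own part per perhaps
please put rather re same see seem seemed seeming seems serious several she
should show side since six sixty so some somehow someone something
sometime sometimes somewhere still such ten than that the their them
themselves then thence there thereafter thereby therefore therein thereupon
these they third this those though three through throughout thru thus to
together too top toward towards twelve twenty two un under until up upon us
very via was we well were what whatever when whence whenever where whereas
whereafter whereby wherein whereupon wherever whether which while whither
who whoever whole whom whose why will with within without would yet you
your yours yourself yourselves
""".split())

#: Negation terms preserved despite appearing in the stop list.
DEFAULT_NEGATION_WHITELIST = frozenset({"no", "not", "without", "never", "non"})


# ---------------------------------------------------------------------------
# bundled deterministic lemmatizer

# Irregulars and e-restoring forms that the suffix rules below cannot recover.
_LEMMA_LOOKUP = {
    "placed": "place", "places": "place", "placing": "place",
    "closed": "close", "closing": "close", "closure": "closure",
    "sutured": "suture", "suturing": "suture", "sutures": "suture",
    "incised": "incise", "incising": "incise",
    "excised": "excise", "excising": "excise",
    "elevated": "elevate", "elevating": "elevate",
    "approximated": "approximate", "approximating": "approximate",
    "advanced": "advance", "advancing": "advance",
    "rotated": "rotate", "rotating": "rotate",
    "mobilized": "mobilize", "mobilizing": "mobilize",
    "undermined": "undermine", "undermining": "undermine",
    "irrigated": "irrigate", "irrigating": "irrigate",
    "infiltrated": "infiltrate", "infiltrating": "infiltrate",
    "injected": "inject", "injecting": "inject",
    "achieved": "achieve", "achieving": "achieve",
    "obtained": "obtain", "obtaining": "obtain",
    "prepared": "prepare", "preparing": "prepare",
    "prepped": "prep", "draped": "drape", "draping": "drape",
    "tolerated": "tolerate", "used": "use", "using": "use",
    "made": "make", "making": "make", "given": "give", "taken": "take",
    "noted": "note", "noting": "note",
    "completed": "complete", "completing": "complete",
    "created": "create", "creating": "create",
    "extubated": "extubate", "intubated": "intubate",
    "induced": "induce", "secured": "secure", "securing": "secure",
    "removed": "remove", "removing": "remove",
    "everted": "evert", "denuded": "denude",
    "measured": "measure", "measuring": "measure",
    "men": "man", "women": "woman", "children": "child", "teeth": "tooth",
    "feet": "foot", "mucosae": "mucosa",
}

_VOWELS = set("aeiou")


def default_lemmatizer(token: str) -> str:
    """Deterministic lookup + suffix lemmatizer for lowercase alphabetic tokens.

    Rules, first match wins: explicit lookup table; ``-ies/-ied`` -> ``-y``;
    ``-sses`` -> ``-ss``; ``-es`` after a sibilant-like ending -> stripped;
    ``-ing``/``-ed`` stripped with doubled-consonant repair; plural ``-s``
    stripped.  Anything else is returned unchanged.
    """
    w = token
    if w in _LEMMA_LOOKUP:
        return _LEMMA_LOOKUP[w]
    if len(w) > 4 and (w.endswith("ies") or w.endswith("ied")):
        return w[:-3] + "y"
    if len(w) > 4 and w.endswith("sses"):
        return w[:-2]
    if len(w) > 3 and w.endswith("es") and w[-3] in "sxz" or w.endswith(("ches", "shes")):
        return w[:-2]
    for suffix in ("ing", "ed"):
        if len(w) > len(suffix) + 2 and w.endswith(suffix):
            stem = w[: -len(suffix)]
            if (
                len(stem) >= 3
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and stem[-1] not in "ls"
            ):
                stem = stem[:-1]
            return stem
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


# ---------------------------------------------------------------------------
# preprocessing

_TOKEN_RE = re.compile(r"[A-Za-z]+")


@dataclass(frozen=True)
class TokenStream:
    """Ordered post-filter lemmas for one note section."""

    note_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def preprocess(
    text: str,
    note_id: str = "",
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS,
    negation_whitelist: frozenset[str] = DEFAULT_NEGATION_WHITELIST,
    lemmatizer: Callable[[str], str] = default_lemmatizer,
) -> TokenStream:
    """Tokenize, filter and lemmatize one section body.

    Only purely alphabetic character runs are kept (digits, punctuation and
    mixed tokens like "3-0" are dropped), lowercased, checked against the
    stop list (whitelisted negations survive), then lemmatized.
    """
    out = []
    for raw in _TOKEN_RE.findall(text):
        tok = raw.lower()
        if tok in stop_words and tok not in negation_whitelist:
            continue
        out.append(lemmatizer(tok))
    return TokenStream(note_id=note_id, tokens=tuple(out))


def build_ngrams(tokens: Sequence[str] | TokenStream) -> list[str]:
    """Unigrams followed by bigrams of adjacent post-filter tokens."""
    if isinstance(tokens, TokenStream):
        tokens = tokens.tokens
    unigrams = list(tokens)
    bigrams = [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]
    return unigrams + bigrams


# ---------------------------------------------------------------------------
# TF-IDF

@dataclass
class TfidfModel:
    """Fitted TF-IDF vocabulary and idf weights.

    ``vocabulary`` maps term -> column index, columns in lexicographic term
    order; ``idf[j]`` is the weight of the term at column ``j`` under the
    smoothed convention ``ln((1+N)/(1+df)) + 1`` (always >= 1).
    """

    vocabulary: dict[str, int]
    idf: np.ndarray
    max_features: int = 500
    ngram_range: tuple[int, int] = (1, 2)
    n_train_docs: int = 0

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)

    def feature_names(self) -> list[str]:
        names = [""] * len(self.vocabulary)
        for term, j in self.vocabulary.items():
            names[j] = term
        return names

    def to_json(self, path: str | Path) -> None:
        d = {
            "vocabulary": self.vocabulary,
            "idf": self.idf.tolist(),
            "max_features": self.max_features,
            "ngram_range": list(self.ngram_range),
            "n_train_docs": self.n_train_docs,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TfidfModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            vocabulary={k: int(v) for k, v in d["vocabulary"].items()},
            idf=np.asarray(d["idf"], dtype=float),
            max_features=int(d["max_features"]),
            ngram_range=tuple(d["ngram_range"]),
            n_train_docs=int(d["n_train_docs"]),
        )


def fit_tfidf(
    train_docs: Sequence[TokenStream],
    max_features: int = 500,
) -> TfidfModel:
    """Fit vocabulary and idf on training documents only.

    Vocabulary = the ``max_features`` n-gram terms with the highest total
    corpus count, ties broken lexicographically (ascending).  Raises
    ``ValueError`` if no document yields any term.
    """
    if not train_docs:
        raise ValueError("fit_tfidf requires a non-empty training corpus")
    total_counts: dict[str, int] = {}
    df: dict[str, int] = {}
    for doc in train_docs:
        terms = build_ngrams(doc)
        for t in terms:
            total_counts[t] = total_counts.get(t, 0) + 1
        for t in set(terms):
            df[t] = df.get(t, 0) + 1
    if not total_counts:
        raise ValueError("no features: all training documents are empty")
    selected = sorted(total_counts, key=lambda t: (-total_counts[t], t))[:max_features]
    vocab = {t: j for j, t in enumerate(sorted(selected))}
    n = len(train_docs)
    idf = np.empty(len(vocab))
    for t, j in vocab.items():
        idf[j] = math.log((1.0 + n) / (1.0 + df[t])) + 1.0
    return TfidfModel(vocabulary=vocab, idf=idf, max_features=max_features, n_train_docs=n)


def transform(doc: TokenStream, model: TfidfModel) -> np.ndarray:
    """TF-IDF vector for one document: raw count x idf, then L2 normalization.

    Out-of-vocabulary terms are ignored; a document with no in-vocabulary
    term maps to the zero vector.
    """
    vec = np.zeros(model.n_features)
    for t in build_ngrams(doc):
        j = model.vocabulary.get(t)
        if j is not None:
            vec[j] += 1.0
    vec *= model.idf
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def transform_corpus(docs: Sequence[TokenStream], model: TfidfModel) -> sp.csr_matrix:
    """Stack :func:`transform` over a corpus into a sparse CSR matrix."""
    rows = [transform(d, model) for d in docs]
    return sp.csr_matrix(np.vstack(rows)) if rows else sp.csr_matrix((0, model.n_features))


def save_vectors_mtx(
    matrix: sp.spmatrix,
    note_ids: Sequence[str],
    mtx_path: str | Path,
    index_path: str | Path,
) -> None:
    """Write vectors as MatrixMarket plus a row-index CSV (row, note_id)."""
    mtx_path, index_path = Path(mtx_path), Path(index_path)
    mtx_path.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix))
    with open(index_path, "w", encoding="utf-8") as fh:
        fh.write("row,note_id\n")
        for i, nid in enumerate(note_ids):
            fh.write(f"{i},{nid}\n")


# ---------------------------------------------------------------------------
# corpus statistics

@dataclass(frozen=True)
class CorpusStats:
    total_tokens: int
    unique_tokens: int
    type_token_ratio_pct: float
    mean_words: float
    median_words: float
    min_words: int
    max_words: int

    def to_dict(self) -> dict:
        return {
            "total_tokens": self.total_tokens,
            "unique_tokens": self.unique_tokens,
            "type_token_ratio_pct": self.type_token_ratio_pct,
            "mean_words": self.mean_words,
            "median_words": self.median_words,
            "min_words": self.min_words,
            "max_words": self.max_words,
        }


def corpus_stats(docs: Sequence[TokenStream] | Sequence[Sequence[str]]) -> CorpusStats:
    """Token totals, lexical diversity and per-document word-count summary.

    Type-token ratio is ``100 * unique / total`` (percent).  Accepts either
    :class:`TokenStream` objects or plain token lists, so it can summarize
    raw word tokens as well as post-filter lemmas.
    """
    if not docs:
        raise ValueError("corpus_stats requires a non-empty corpus")
    token_lists = [d.tokens if isinstance(d, TokenStream) else list(d) for d in docs]
    lengths = [len(t) for t in token_lists]
    total = sum(lengths)
    unique = len({tok for toks in token_lists for tok in toks})
    ttr = 100.0 * unique / total if total else 0.0
    return CorpusStats(
        total_tokens=total,
        unique_tokens=unique,
        type_token_ratio_pct=ttr,
        mean_words=float(statistics.mean(lengths)),
        median_words=float(statistics.median(lengths)),
        min_words=min(lengths),
        max_words=max(lengths),
    )
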