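"""DDI sentence processing: TF-IDF label extraction and label vectorization.

A DDI sentence mentioning two drugs is turned into a small set of
descriptor labels (e.g. ``{enhance, toxicity, bleeding}``) by ranking its
content tokens with TF-IDF over the corpus and keeping the top *n* (default
5).  The union of selected labels forms the label vocabulary ``L``; a
triple's label set is then encoded as a binary indicator vector over ``L``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

# A compact English stop-word list; override via the ``stopwords`` arguments.
DEFAULT_STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by can could did do does doing down during
each few for from further had has have having he her here hers herself him
himself his how i if in into is it its itself just me more most my myself no
nor not now of off on once only or other our ours ourselves out over own same
she should so some such than that the their theirs them themselves then there
these they this those through to too under until up very was we were what when
where which while who whom why will with you your yours yourself yourselves
may might must shall would
""".split())

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@dataclass
class DDIDocument:
    """One DDI sentence, tokenized: two drug mentions plus content tokens."""

    doc_id: str
    drug_u: str
    drug_v: str
    tokens: list[str]


class LabelVocabulary:
    """Fixed ordered vocabulary of DDI descriptor labels."""

    def __init__(self, labels: list[str]):
        if len(set(labels)) != len(labels):
            raise ValueError("vocabulary labels must be distinct")
        self.labels: list[str] = list(labels)
        self.index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelVocabulary) and other.labels == self.labels

    @classmethod
    def from_file(cls, path: str) -> "LabelVocabulary":
        with open(path, encoding="utf-8") as fh:
            labels = [line.strip() for line in fh if line.strip()]
        return cls(labels)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for lab in self.labels:
                fh.write(lab + "\n")


def vectorize(labels: set[str] | frozenset[str], vocabulary: LabelVocabulary) -> np.ndarray:
    """Binary indicator vector s over the vocabulary: s_i = 1 iff label i is present."""
    s = np.zeros(len(vocabulary), dtype=np.float64)
    for lab in labels:
        if lab not in vocabulary:
            raise KeyError(f"label {lab!r} not in vocabulary")
        s[vocabulary.index[lab]] = 1.0
    return s


def unvectorize(s: np.ndarray, vocabulary: LabelVocabulary) -> frozenset[str]:
    return frozenset(vocabulary.labels[i] for i in np.flatnonzero(s > 0.5))


def preprocess(text: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> list[str]:
    """Lowercase, strip punctuation, tokenize, drop stop-words; order preserved."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]


def tf_idf_scores(corpus: list[DDIDocument]) -> dict[str, dict[str, float]]:
    """Per-document TF-IDF: tf(t,d) = count/|d|, idf(t) = ln(N / df(t)).

    Natural (unsmoothed) variant.  Documents with no tokens contribute to N
    but receive an empty score map.
    """
    if not corpus:
        raise ValueError("empty corpus")
    n_docs = len(corpus)
    df: dict[str, int] = {}
    for doc in corpus:
        for tok in set(doc.tokens):
            df[tok] = df.get(tok, 0) + 1
    out: dict[str, dict[str, float]] = {}
    for doc in corpus:
        scores: dict[str, float] = {}
        if doc.tokens:
            length = len(doc.tokens)
            counts: dict[str, int] = {}
            for tok in doc.tokens:
                counts[tok] = counts.get(tok, 0) + 1
            for tok, cnt in counts.items():
                scores[tok] = (cnt / length) * np.log(n_docs / df[tok])
        out[doc.doc_id] = scores
    return out


def select_top_labels(doc_scores: dict[str, float], n: int) -> list[str]:
    """The n highest-scoring tokens; ties broken lexicographically."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranked = sorted(doc_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tok for tok, _ in ranked[:n]]


def extract_labels(
    corpus: list[DDIDocument], n: int = 5
) -> tuple["LabelVocabulary", dict[str, list[str]]]:
    """Top-n TF-IDF labels per document and the resulting vocabulary.

    Drug mention tokens are excluded from a document's candidates — a drug
    name is not a DDI descriptor.  The vocabulary lists all selected labels
    in sorted order.
    """
    scores = tf_idf_scores(corpus)
    doc_labels: dict[str, list[str]] = {}
    for doc in corpus:
        mentions = {doc.drug_u.lower(), doc.drug_v.lower()}
        candidates = {t: sc for t, sc in scores[doc.doc_id].items() if t not in mentions}
        doc_labels[doc.doc_id] = select_top_labels(candidates, n)
    vocab = LabelVocabulary(sorted({lab for labs in doc_labels.values() for lab in labs}))
    return vocab, doc_labels


# ---------------------------------------------------------------------------
# Drug-name normalization via an alias table
# ---------------------------------------------------------------------------

class AliasTable:
    """Case-insensitive map from raw drug name to canonical entity id."""

    def __init__(self, aliases: dict[str, str]):
        self._map = {k.lower(): v for k, v in aliases.items()}

    @classmethod
    def from_file(cls, path: str) -> "AliasTable":
        aliases = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 fields")
                aliases[fields[0].strip()] = fields[1].strip()
        return cls(aliases)

    def get(self, name: str) -> str | None:
        return self._map.get(name.lower())


def normalize_drug(name: str, aliases: AliasTable) -> str | None:
    """Canonical entity id for a raw drug name, or None when unknown.

    A name that is already a canonical id maps to itself.
    """
    hit = aliases.get(name)
    if hit is not None:
        return hit
    if name in set(aliases._map.values()):
        return name
    return None


def load_corpus(path: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> list[DDIDocument]:
    """Read ``doc_id<TAB>drug_u<TAB>drug_v<TAB>sentence`` TSV into documents."""
    docs: list[DDIDocument] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            doc_id, u, v, sentence = fields
            if doc_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(DDIDocument(doc_id, u, v, preprocess(sentence, stopwords)))
    return docs
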