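"""Drug knowledge-graph domain model.

A drug KG combines two kinds of triples over typed entities (drugs,
proteins, pathways, phenotypes):

* *basic triples* ``(head, relation, tail)`` — biological facts such as
  ``(etanercept, hasTarget, lymphotoxin-alpha)``;
* *rich DDI triples* ``(drug_u, {labels}, drug_v)`` — a drug-drug
  interaction described by a non-empty set of labels drawn from a fixed
  vocabulary (e.g. ``{enhance, toxic, bleeding}``).

DDI relations are undirected pharmacologically but are stored
direction-expanded: every interacting pair appears as two directed triples
with identical label sets, which is what the embedding trainer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .text import LabelVocabulary

ENTITY_KINDS = ("drug", "protein", "pathway", "phenotype")

#: Relation name -> (head kind, tail kind).  The five biological relation
#: types of the default schema; extensible by passing a custom mapping.
DEFAULT_SCHEMA: dict[str, tuple[str, str]] = {
    "hasTarget": ("drug", "protein"),
    "hasEnzyme": ("drug", "protein"),
    "hasTransporter": ("drug", "protein"),
    "isPresentIn": ("protein", "pathway"),
    "isImplicatedIn": ("pathway", "phenotype"),
}


class TripleFileError(ValueError):
    """Malformed triple file (bad field count, unknown relation...)."""


class KGValidationError(ValueError):
    """A KG invariant is violated (unknown label, self-interaction...)."""


@dataclass(frozen=True)
class Entity:
    id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise KGValidationError(
                f"entity {self.id!r}: kind must be one of {ENTITY_KINDS}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class BasicTriple:
    head: str
    relation: str
    tail: str


@dataclass(frozen=True)
class RichDDITriple:
    """Directed multi-label DDI relation between two distinct drugs."""

    drug_u: str
    labels: frozenset[str]
    drug_v: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", frozenset(self.labels))
        if not self.labels:
            raise KGValidationError(
                f"DDI triple ({self.drug_u}, {self.drug_v}): empty label set"
            )
        if self.drug_u == self.drug_v:
            raise KGValidationError(f"self-interaction not allowed: {self.drug_u}")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) undirected pair key."""
        return tuple(sorted((self.drug_u, self.drug_v)))  # type: ignore[return-value]


@dataclass
class DrugKG:
    """Entities plus basic triples and direction-expanded rich DDI triples."""

    entities: dict[str, Entity]
    basic: list[BasicTriple]
    ddi: list[RichDDITriple]
    vocabulary: LabelVocabulary

    @property
    def drugs(self) -> list[str]:
        return [e.id for e in self.entities.values() if e.kind == "drug"]

    def undirected_pairs(self) -> dict[tuple[str, str], frozenset[str]]:
        """Map canonical pair -> label set, one entry per undirected DDI."""
        out: dict[tuple[str, str], frozenset[str]] = {}
        for t in self.ddi:
            out[t.pair] = t.labels
        return out


@dataclass
class DDISplit:
    """Train KG plus held-out positive DDI triples and sampled negative pairs."""

    train_kg: DrugKG
    test_positives: list[RichDDITriple]
    test_negatives: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Triple-file I/O.  Dialect: UTF-8 TSV, one triple per line, '#' comments and
# blank lines ignored.  Rich DDI label sets use '|' as the label separator.
# ---------------------------------------------------------------------------

def load_basic_triples(
    path: str, schema: dict[str, tuple[str, str]] | None = None
) -> list[BasicTriple]:
    """Read ``head<TAB>relation<TAB>tail`` lines; relations must be in *schema*."""
    if schema is None:
        schema = DEFAULT_SCHEMA
    triples: list[BasicTriple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TripleFileError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            head, rel, tail = (f.strip() for f in fields)
            if rel not in schema:
                raise TripleFileError(
                    f"{path}:{lineno}: unknown relation {rel!r} "
                    f"(schema: {sorted(schema)})"
                )
            triples.append(BasicTriple(head, rel, tail))
    return triples


def load_ddi_triples(path: str) -> list[RichDDITriple]:
    """Read ``drug_u<TAB>label1|label2|...<TAB>drug_v`` lines."""
    triples: list[RichDDITriple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TripleFileError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            u, labels, v = (f.strip() for f in fields)
            label_set = frozenset(s.strip() for s in labels.split("|") if s.strip())
            if not label_set:
                raise TripleFileError(f"{path}:{lineno}: empty label set")
            triples.append(RichDDITriple(u, label_set, v))
    return triples


def write_basic_triples(path: str, triples: list[BasicTriple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def write_ddi_triples(path: str, triples: list[RichDDITriple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.drug_u}\t{'|'.join(sorted(t.labels))}\t{t.drug_v}\n")


# ---------------------------------------------------------------------------
# KG construction
# ---------------------------------------------------------------------------

def infer_entities(
    basic: list[BasicTriple],
    ddi: list[RichDDITriple],
    schema: dict[str, tuple[str, str]] | None = None,
) -> dict[str, Entity]:
    """Infer entity kinds from the relation schema and DDI membership.

    ``hasTarget`` implies a drug head and protein tail, and so on; drugs in
    DDI triples are always of kind drug.  Conflicting kind assignments raise.
    """
    if schema is None:
        schema = DEFAULT_SCHEMA
    kinds: dict[str, str] = {}

    def assign(eid: str, kind: str) -> None:
        prev = kinds.get(eid)
        if prev is not None and prev != kind:
            raise KGValidationError(
                f"entity {eid!r} inferred as both {prev!r} and {kind!r}"
            )
        kinds[eid] = kind

    for t in basic:
        hk, tk = schema[t.relation]
        assign(t.head, hk)
        assign(t.tail, tk)
    for t in ddi:
        assign(t.drug_u, "drug")
        assign(t.drug_v, "drug")
    return {eid: Entity(eid, kind) for eid, kind in kinds.items()}


def build_kg(
    basic: list[BasicTriple],
    ddi: list[RichDDITriple],
    vocabulary: LabelVocabulary,
    entities: dict[str, Entity] | None = None,
    schema: dict[str, tuple[str, str]] | None = None,
) -> DrugKG:
    """Assemble a validated :class:`DrugKG`.

    DDI inputs may be given in one or both directions; the result stores
    every interacting pair as exactly two directed triples with identical
    label sets.  Duplicates are removed.  A pair supplied twice with
    *different* label sets is a validation error.
    """
    if entities is None:
        entities = infer_entities(basic, ddi, schema)

    for t in ddi:
        unknown = t.labels - set(vocabulary.labels)
        if unknown:
            raise KGValidationError(
                f"DDI ({t.drug_u}, {t.drug_v}): labels not in vocabulary: {sorted(unknown)}"
            )
        for d in (t.drug_u, t.drug_v):
            if entities[d].kind != "drug":
                raise KGValidationError(f"DDI endpoint {d!r} is not a drug entity")

    for t in basic:
        for eid in (t.head, t.tail):
            if eid not in entities:
                raise KGValidationError(f"basic triple references unknown entity {eid!r}")

    # direction expansion with per-pair label consistency
    by_pair: dict[tuple[str, str], frozenset[str]] = {}
    for t in ddi:
        prev = by_pair.get(t.pair)
        if prev is not None and prev != t.labels:
            raise KGValidationError(
                f"pair {t.pair} given twice with different label sets"
            )
        by_pair[t.pair] = t.labels
    expanded = []
    for (a, b), labels in by_pair.items():
        expanded.append(RichDDITriple(a, labels, b))
        expanded.append(RichDDITriple(b, labels, a))

    basic_dedup = list(dict.fromkeys(basic))
    return DrugKG(entities=entities, basic=basic_dedup, ddi=expanded,
                  vocabulary=vocabulary)


# ---------------------------------------------------------------------------
# Train / test split
# ---------------------------------------------------------------------------

def split_ddi(kg: DrugKG, rate: float, seed: int) -> DDISplit:
    """Hold out ``round(rate * n_pairs)`` undirected DDI pairs for testing.

    Both directed triples of a held-out pair leave the training KG together.
    An equal number of negative drug pairs — pairs with no DDI anywhere in
    the full KG, self-pairs excluded — is sampled uniformly without
    replacement.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    pairs = sorted(kg.undirected_pairs())
    if rate > 0 and not pairs:
        raise ValueError("KG has no DDI pairs to split")
    rng = np.random.default_rng(seed)
    n_test = round(rate * len(pairs))
    test_idx = set(rng.choice(len(pairs), size=n_test, replace=False).tolist()) if n_test else set()
    test_pairs = {pairs[i] for i in test_idx}

    pair_labels = kg.undirected_pairs()
    test_positives = []
    for a, b in sorted(test_pairs):
        labels = pair_labels[(a, b)]
        test_positives.append(RichDDITriple(a, labels, b))
        test_positives.append(RichDDITriple(b, labels, a))

    train_ddi = [t for t in kg.ddi if t.pair not in test_pairs]
    train_kg = DrugKG(entities=kg.entities, basic=list(kg.basic),
                      ddi=train_ddi, vocabulary=kg.vocabulary)

    negatives = sample_non_ddi_pairs(kg, n_test, rng)
    return DDISplit(train_kg=train_kg, test_positives=test_positives,
                    test_negatives=negatives)


def sample_non_ddi_pairs(
    kg: DrugKG,
    n: int,
    rng: np.random.Generator,
    exclude: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Uniformly sample *n* distinct drug pairs with no DDI in the full KG."""
    drugs = sorted(kg.drugs)
    positive = set(kg.undirected_pairs())
    if exclude:
        positive = positive | {tuple(sorted(p)) for p in exclude}
    n_drugs = len(drugs)
    n_candidates = n_drugs * (n_drugs - 1) // 2 - len(positive)
    if n > max(n_candidates, 0):
        raise ValueError(
            f"cannot sample {n} negative pairs: only {n_candidates} non-DDI pairs exist"
        )
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    while len(out) < n:
        i, j = rng.integers(0, n_drugs, size=2)
        if i == j:
            continue
        pair = tuple(sorted((drugs[i], drugs[j])))
        if pair in positive or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)  # type: ignore[arg-type]
    return out
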