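"""Synthetic drug KGs and DDI corpora with known planted structure.

The generator emulates, at desk scale, the regime of a Bio2RDF-style drug
KG plus a DDI sentence corpus:

* Entities follow the biological schema chain drug -> protein -> pathway ->
  phenotype; every entity receives a latent vector and basic triples are
  laid out so the tail latent equals head latent + relation latent up to
  Gaussian noise (``noise_sd``) — the translational structure the basic
  triple encoder assumes.  Group anchors live on a 2-D integer lattice
  embedded in latent space and relation translations are lattice shifts, so
  the set of exactly consistent triples can be enumerated; the requested
  number of basic triples is a uniform subsample of it (a config error is
  raised when the lattice cannot supply that many).
* Drugs are partitioned into interaction classes ("clusters").  Each class
  is split into a perpetrator and a victim role, mirroring mechanism-based
  DDIs (e.g. enzyme inhibitors versus their substrates), and DDI pairs are
  drawn perpetrator x victim within a class.  The two role anchors of a
  class differ by a class-specific lattice offset, so the translation
  ``v - u`` of a DDI pair identifies its class.  Each class owns a coherent
  subset of the label vocabulary; a pair's labels are drawn mostly from its
  class pool (within-class weight 0.8, cross-class 0.05), giving the sparse
  co-occurring label clusters the autoencoder is meant to pick up.
* The corpus writer emits one synthetic sentence per DDI pair whose content
  tokens are the pair's true labels plus stop-word filler, so the TF-IDF
  pipeline can recover the planted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kg import (DEFAULT_SCHEMA, BasicTriple, DrugKG, RichDDITriple, build_kg)
from .model import ModelParameters, build_parameters
from .text import DDIDocument, LabelVocabulary


@dataclass
class SyntheticConfig:
    """Defaults give a 200-entity KG with 2000 basic triples, 100 DDI pairs
    over a 50-label vocabulary in 5 interaction classes."""

    n_drugs: int = 80
    n_proteins: int = 75
    n_pathways: int = 30
    n_phenotypes: int = 15
    n_relations: int = 5
    n_basic: int = 2000
    n_ddi_pairs: int = 100
    vocab_size: int = 50
    n_clusters: int = 5
    labels_per_ddi: int = 5
    noise_sd: float = 0.05
    latent_dim: int = 20
    in_cluster_weight: float = 0.8
    cross_cluster_weight: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_proteins", "n_pathways", "n_phenotypes",
                     "n_relations", "n_basic", "n_ddi_pairs", "vocab_size",
                     "n_clusters", "labels_per_ddi", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.labels_per_ddi > self.vocab_size:
            raise ValueError("labels_per_ddi cannot exceed vocab_size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_relations > 5:
            raise ValueError("the biological schema defines at most 5 relation types")
        if self.vocab_size // self.n_clusters < 1:
            raise ValueError("vocab_size must provide at least one label per cluster")
        if self.labels_per_ddi > self.vocab_size // self.n_clusters and \
                self.cross_cluster_weight == 0:
            raise ValueError("labels_per_ddi exceeds the cluster label pool")


@dataclass
class GroundTruth:
    latent: dict[str, np.ndarray]            # entity id -> latent vector
    relation_latent: dict[str, np.ndarray]   # relation id -> translation vector
    drug_cluster: dict[str, int]
    cluster_labels: dict[int, list[str]]
    ddi_pairs: list[tuple[str, str, frozenset[str]]]  # (perpetrator, victim, labels)


_RELATION_ORDER = ["hasTarget", "hasEnzyme", "hasTransporter",
                   "isPresentIn", "isImplicatedIn"]


def _lattice_layout(config: SyntheticConfig, rng: np.random.Generator):
    """Place perpetrator/victim group anchors on distinct 2-D lattice points
    such that the victim-minus-perpetrator offset is distinct per cluster."""
    n_pts = 2 * config.n_clusters
    side = int(np.ceil(np.sqrt(n_pts))) + 1
    cells = [(i, j) for i in range(side) for j in range(side)]
    for _ in range(200):
        idx = rng.permutation(len(cells))[:n_pts]
        pts = [cells[i] for i in idx]
        perp = pts[: config.n_clusters]
        vict = pts[config.n_clusters:]
        deltas = [(v[0] - p[0], v[1] - p[1]) for p, v in zip(perp, vict)]
        if len(set(deltas)) == config.n_clusters:
            return perp, vict
    raise ValueError("could not place cluster anchors with distinct offsets")


def generate_kg(config: SyntheticConfig) -> tuple[DrugKG, GroundTruth]:
    """Sample a drug KG with planted translational and label-cluster
    structure; reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    k = config.latent_dim
    if k < 2:
        raise ValueError("latent_dim must be >= 2")
    relations = _RELATION_ORDER[: config.n_relations]
    drug_rels = [r for r in relations if DEFAULT_SCHEMA[r][0] == "drug"]

    # 2-D lattice basis embedded in latent space; relation translations are
    # lattice shifts, so exact consistency can be enumerated.  Components are
    # quantized to multiples of 2^-20 so that every small-integer lattice
    # combination is exact in float64 and zero-noise triples score exactly b1.
    q, _ = np.linalg.qr(rng.standard_normal((k, 2)))
    q = np.round(q * 2**20) / 2**20
    e1, e2 = q[:, 0], q[:, 1]
    lattice = lambda ij: ij[0] * e1 + ij[1] * e2
    drug_shift = (1, 0)      # shared by the three drug->protein relations
    path_shift = (0, 1)      # isPresentIn
    phen_shift = (1, 1)      # isImplicatedIn
    rel_shift = {r: drug_shift for r in drug_rels}
    rel_shift.update({"isPresentIn": path_shift, "isImplicatedIn": phen_shift})
    rel_vec = {r: lattice(s) for r, s in rel_shift.items() if r in relations}

    perp_pts, vict_pts = _lattice_layout(config, rng)
    group_pts = {(c, 0): perp_pts[c] for c in range(config.n_clusters)}
    group_pts.update({(c, 1): vict_pts[c] for c in range(config.n_clusters)})
    group_keys = sorted(group_pts)

    jitter = lambda: rng.normal(0.0, config.noise_sd, k)
    drugs = [f"drug{i:03d}" for i in range(config.n_drugs)]
    drug_cluster = {d: i % config.n_clusters for i, d in enumerate(drugs)}
    drug_role = {d: (i // config.n_clusters) % 2 for i, d in enumerate(drugs)}
    latent: dict[str, np.ndarray] = {}
    drug_groups: dict[tuple[int, int], list[str]] = {g: [] for g in group_keys}
    for d in drugs:
        g = (drug_cluster[d], drug_role[d])
        latent[d] = lattice(group_pts[g]) + jitter()
        drug_groups[g].append(d)

    def shifted(pt, sh):
        return (pt[0] + sh[0], pt[1] + sh[1])

    # proteins sit one drug-shift downstream of a group anchor; pathways and
    # phenotypes chain further along their own shifts
    prot_pts = sorted({shifted(group_pts[g], drug_shift) for g in group_keys})
    proteins = [f"prot{i:03d}" for i in range(config.n_proteins)]
    prot_at: dict[tuple[int, int], list[str]] = {pt: [] for pt in prot_pts}
    for i, p in enumerate(proteins):
        pt = prot_pts[i % len(prot_pts)]
        latent[p] = lattice(pt) + jitter()
        prot_at[pt].append(p)

    path_pts = sorted({shifted(pt, path_shift) for pt in prot_pts})
    pathways = [f"path{i:03d}" for i in range(config.n_pathways)]
    path_at: dict[tuple[int, int], list[str]] = {pt: [] for pt in path_pts}
    for i, w in enumerate(pathways):
        pt = path_pts[i % len(path_pts)]
        latent[w] = lattice(pt) + jitter()
        path_at[pt].append(w)

    phen_src_pts = sorted({shifted(pt, phen_shift) for pt in path_pts})
    phenotypes = [f"phen{i:03d}" for i in range(config.n_phenotypes)]
    phen_src: dict[str, tuple[int, int]] = {}
    for i, qid in enumerate(phenotypes):
        pt = path_pts[i % len(path_pts)]
        phen_src[qid] = pt
        latent[qid] = lattice(shifted(pt, phen_shift)) + jitter()

    # enumerate every exactly consistent triple, then subsample
    candidates: list[BasicTriple] = []
    group_at = {}
    for g, pt in group_pts.items():
        group_at.setdefault(pt, []).append(g)
    for pt, plist in prot_at.items():
        src_pt = (pt[0] - drug_shift[0], pt[1] - drug_shift[1])
        for g in group_at.get(src_pt, []):
            for r in drug_rels:
                for d in drug_groups[g]:
                    for p in plist:
                        candidates.append(BasicTriple(d, r, p))
    if "isPresentIn" in relations:
        for pt, wlist in path_at.items():
            src_pt = (pt[0] - path_shift[0], pt[1] - path_shift[1])
            for p in prot_at.get(src_pt, []):
                for w in wlist:
                    candidates.append(BasicTriple(p, "isPresentIn", w))
    if "isImplicatedIn" in relations:
        for qid, src_pt in phen_src.items():
            for w in path_at.get(src_pt, []):
                candidates.append(BasicTriple(w, "isImplicatedIn", qid))
    if len(candidates) < config.n_basic:
        raise ValueError(
            f"config supports at most {len(candidates)} consistent basic "
            f"triples, {config.n_basic} requested")
    order = rng.permutation(len(candidates))[: config.n_basic]
    basic = sorted((candidates[i] for i in order),
                   key=lambda t: (t.relation, t.head, t.tail))

    # label vocabulary partitioned into per-cluster pools
    vocab_labels = [f"label{i:02d}" for i in range(config.vocab_size)]
    vocabulary = LabelVocabulary(vocab_labels)
    pool_size = config.vocab_size // config.n_clusters
    cluster_labels = {
        c: vocab_labels[c * pool_size: (c + 1) * pool_size]
        for c in range(config.n_clusters)
    }

    # DDI pairs: perpetrator x victim within a cluster, labels mostly from
    # the cluster pool
    ddi_pairs: list[tuple[str, str, frozenset[str]]] = []
    seen_pairs: set[tuple[str, str]] = set()
    attempts = 0
    while len(ddi_pairs) < config.n_ddi_pairs and attempts < 100 * config.n_ddi_pairs:
        attempts += 1
        c = int(rng.integers(0, config.n_clusters))
        perp_pool = drug_groups.get((c, 0), [])
        vict_pool = drug_groups.get((c, 1), [])
        if not perp_pool or not vict_pool:
            continue
        u = perp_pool[rng.integers(0, len(perp_pool))]
        v = vict_pool[rng.integers(0, len(vict_pool))]
        key = tuple(sorted((u, v)))
        if u == v or key in seen_pairs:
            continue
        weights = np.full(config.vocab_size, config.cross_cluster_weight)
        for lab in cluster_labels[c]:
            weights[vocabulary.index[lab]] = config.in_cluster_weight
        weights /= weights.sum()
        chosen = rng.choice(config.vocab_size, size=config.labels_per_ddi,
                            replace=False, p=weights)
        labels = frozenset(vocab_labels[i] for i in chosen)
        seen_pairs.add(key)
        ddi_pairs.append((u, v, labels))
    if len(ddi_pairs) < config.n_ddi_pairs:
        raise ValueError("could not place the requested number of DDI pairs")

    ddi = [RichDDITriple(u, labels, v) for u, v, labels in ddi_pairs]
    kg = build_kg(basic, ddi, vocabulary)
    truth = GroundTruth(latent=latent, relation_latent=rel_vec,
                        drug_cluster=drug_cluster, cluster_labels=cluster_labels,
                        ddi_pairs=ddi_pairs)
    return kg, truth


def params_from_truth(truth: GroundTruth, kg: DrugKG) -> ModelParameters:
    """Generating latents loaded as model parameters with identity
    projections — with noise_sd=0 every basic triple then scores exactly b1."""
    return build_parameters(entities=dict(truth.latent),
                            relations=dict(truth.relation_latent))


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_FILLERS = ["the", "of", "with", "and", "may", "be", "is", "to", "in", "a"]
_SHARED = ["coadministration", "interaction", "patients"]


def generate_corpus(config: SyntheticConfig, truth: GroundTruth,
                    fillers: list[str] | None = None,
                    shared: list[str] | None = None) -> list[DDIDocument]:
    """One synthetic sentence per DDI pair; content tokens are the pair's
    planted labels (repeated 1-2 times) plus corpus-wide *shared* words.
    *fillers* are stop-words: they appear in the raw sentence but are
    removed again by preprocessing, so with both lists empty the document
    tokens are exactly the planted labels."""
    rng = np.random.default_rng(config.seed + 1)
    if fillers is None:
        fillers = _FILLERS
    if shared is None:
        shared = _SHARED
    docs: list[DDIDocument] = []
    for i, (u, v, labels) in enumerate(truth.ddi_pairs):
        tokens: list[str] = []
        for lab in sorted(labels):
            tokens.extend([lab] * int(rng.integers(1, 3)))
        tokens.extend(shared)
        order = rng.permutation(len(tokens))
        tokens = [tokens[j] for j in order]
        content = [t for t in tokens if t not in set(fillers)]
        docs.append(DDIDocument(doc_id=f"doc{i:04d}", drug_u=u, drug_v=v,
                                tokens=content))
    return docs


def corpus_to_tsv(path: str, config: SyntheticConfig, truth: GroundTruth) -> None:
    """Write the corpus as the raw-sentence TSV the text pipeline reads."""
    rng = np.random.default_rng(config.seed + 1)
    with open(path, "w", encoding="utf-8") as fh:
        for i, (u, v, labels) in enumerate(truth.ddi_pairs):
            words: list[str] = []
            for lab in sorted(labels):
                words.extend([lab] * int(rng.integers(1, 3)))
            words.extend(_SHARED)
            words.extend(_FILLERS[: int(rng.integers(3, len(_FILLERS)))])
            order = rng.permutation(len(words))
            sentence = f"{u} " + " ".join(words[j] for j in order) + f" {v}"
            fh.write(f"doc{i:04d}\t{u}\t{v}\t{sentence}\n")
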