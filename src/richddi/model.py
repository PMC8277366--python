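"""Joint translation-based embedding of a drug KG and multi-label DDI relations.

The model embeds entities and relations of the drug KG into low-dimensional
spaces and couples them with an autoencoder over DDI label sets:

* **Basic triples** are scored TransR-style: each relation ``r`` owns a
  projection matrix ``M_r`` (k x d) and a translation vector ``r``; the score
  is ``z_bte = b1 - ||h M_r + r - t M_r||`` under an L1 or L2 norm.
* **Rich DDI triples** share one projection ``M_l`` for both drug slots; the
  relation embedding ``l`` is produced by the encoder half of a deep
  autoencoder applied to the binary label-set vector ``s``:
  ``z_dte = b2 - ||u M_l + l - v M_l||``.
* **Reconstruction**: the decoder half maps ``l`` back to a reconstruction
  ``s_hat``; the score ``z_rcl = b3 - ||(s - s_hat) (.) x||`` up-weights the
  (rare) nonzero components with ``x_i = beta > 1`` so the decoder does not
  collapse to predicting all-zeros.

All three likelihoods are trained with a sampled sigmoid surrogate
(``log sigma(z_pos) + sum log sigma(-z_neg)`` over ``c`` corrupted triples per
slot), plus hinge soft constraints ``[||.||^2 - 1]_+`` that keep embedding
norms near the unit ball.  The joint objective is maximized with Adam over
random mini-batches.  Gradients are derived analytically (numpy only) and are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .kg import BasicTriple, DrugKG, RichDDITriple
from .text import LabelVocabulary, vectorize

CHECKPOINT_FORMAT = "richddi-checkpoint-1"


class SamplingError(RuntimeError):
    """Negative sampling cannot produce a valid corruption."""


class TrainingDivergenceError(RuntimeError):
    """The objective became non-finite during training."""

    def __init__(self, iteration: int):
        super().__init__(f"objective became non-finite at iteration {iteration}")
        self.iteration = iteration


# ---------------------------------------------------------------------------
# Hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class Hyperparameters:
    """Model and training configuration.

    Defaults follow the best grid-searched configuration of the joint model:
    lr=0.001, gamma=0.01, k=100, b1=b2=5, b3=1, c=10 negatives per positive,
    L1 dissimilarity, 1000 iterations.  The relation dimension ``d`` defaults
    to ``k``; the nonzero-reconstruction weight ``beta`` defaults to 5.
    """

    k: int = 100
    d: int | None = None
    b1: float = 5.0
    b2: float = 5.0
    b3: float = 1.0
    beta: float = 5.0
    c: int = 10
    gamma: float = 0.01
    lr: float = 0.001
    norm: str = "L1"
    ae_hidden: int | None = None  # width of the autoencoder hidden layers
    dropout: float = 0.2
    iterations: int = 1000
    batch_size: int = 128
    seed: int = 0
    filtered_sampling: bool = True

    def __post_init__(self) -> None:
        if self.d is None:
            self.d = self.k
        if self.k < 1 or self.d < 1:
            raise ValueError("k and d must be >= 1")
        if self.beta <= 1:
            raise ValueError(f"beta must be > 1, got {self.beta}")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.norm not in ("L1", "L2"):
            raise ValueError(f"norm must be 'L1' or 'L2', got {self.norm!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderParameters:
    """Symmetric deep autoencoder over label vectors.

    ``weights[i]`` has shape (out, in); layers 0..code_layer_index-1 form the
    encoder (tanh), the rest the decoder (tanh hidden, logistic output).  The
    code activation is the DDI relation embedding ``l``.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    code_layer_index: int

    @property
    def n_layers(self) -> int:
        return len(self.weights)


@dataclass
class ModelParameters:
    entity_ids: list[str]
    relation_ids: list[str]
    arrays: dict[str, np.ndarray]
    n_labels: int
    ae_widths: list[int]
    # entity/relation pairs observed in training basic triples, and drug
    # entities observed in DDI triples -- the soft-constraint term ranges
    # over exactly these projections
    obs_e: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    obs_r: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    ddi_drug_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        self.relation_index = {r: i for i, r in enumerate(self.relation_ids)}

    # convenient named views ------------------------------------------------
    @property
    def E(self) -> np.ndarray:
        return self.arrays["E"]

    @property
    def R(self) -> np.ndarray:
        return self.arrays["R"]

    @property
    def M(self) -> np.ndarray:
        return self.arrays["M"]

    @property
    def Ml(self) -> np.ndarray:
        return self.arrays["Ml"]

    @property
    def ae(self) -> AutoencoderParameters:
        n = len(self.ae_widths) - 1
        return AutoencoderParameters(
            weights=[self.arrays[f"ae_W{i}"] for i in range(n)],
            biases=[self.arrays[f"ae_b{i}"] for i in range(n)],
            code_layer_index=n // 2,
        )

    def entity_vec(self, eid: str) -> np.ndarray:
        if eid not in self.entity_index:
            raise KeyError(f"unknown entity {eid!r}")
        return self.E[self.entity_index[eid]]

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {name: np.zeros_like(a) for name, a in self.arrays.items()}


def ae_widths(n_labels: int, hp: Hyperparameters) -> list[int]:
    """Layer widths |L| -> m -> d -> m -> |L| with m = max(d, |L|//2)."""
    m = hp.ae_hidden if hp.ae_hidden is not None else max(hp.d, n_labels // 2)
    return [n_labels, m, hp.d, m, n_labels]


def init_params(kg: DrugKG, hp: Hyperparameters,
                rng: np.random.Generator | None = None) -> ModelParameters:
    """Seeded initialization: small-uniform embeddings, near-identity
    projections, Glorot autoencoder weights."""
    if rng is None:
        rng = np.random.default_rng(hp.seed)
    entity_ids = sorted(kg.entities)
    relation_ids = sorted({t.relation for t in kg.basic})
    n_e, n_r = len(entity_ids), len(relation_ids)
    L = len(kg.vocabulary)
    k, d = hp.k, hp.d

    arrays: dict[str, np.ndarray] = {}
    arrays["E"] = rng.uniform(-6 / np.sqrt(k), 6 / np.sqrt(k), size=(n_e, k))
    arrays["R"] = rng.uniform(-6 / np.sqrt(d), 6 / np.sqrt(d), size=(n_r, d))
    eye = np.eye(k, d)
    arrays["M"] = eye[None, :, :] + 0.01 * rng.standard_normal((n_r, k, d))
    arrays["Ml"] = eye + 0.01 * rng.standard_normal((k, d))
    widths = ae_widths(L, hp)
    for i in range(len(widths) - 1):
        fan_in, fan_out = widths[i], widths[i + 1]
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        arrays[f"ae_W{i}"] = rng.uniform(-lim, lim, size=(fan_out, fan_in))
        arrays[f"ae_b{i}"] = np.zeros(fan_out)

    eidx = {e: i for i, e in enumerate(entity_ids)}
    ridx = {r: i for i, r in enumerate(relation_ids)}
    obs = sorted({(eidx[t.head], ridx[t.relation]) for t in kg.basic}
                 | {(eidx[t.tail], ridx[t.relation]) for t in kg.basic})
    obs_e = np.array([p[0] for p in obs], dtype=np.int64)
    obs_r = np.array([p[1] for p in obs], dtype=np.int64)
    ddi_drugs = sorted({eidx[t.drug_u] for t in kg.ddi} | {eidx[t.drug_v] for t in kg.ddi})
    return ModelParameters(
        entity_ids=entity_ids, relation_ids=relation_ids, arrays=arrays,
        n_labels=L, ae_widths=widths,
        obs_e=obs_e, obs_r=obs_r,
        ddi_drug_idx=np.array(ddi_drugs, dtype=np.int64),
    )


def build_parameters(
    entities: dict[str, np.ndarray],
    relations: dict[str, np.ndarray] | None = None,
    proj: dict[str, np.ndarray] | None = None,
    proj_ddi: np.ndarray | None = None,
    ae: AutoencoderParameters | None = None,
    n_labels: int = 0,
) -> ModelParameters:
    """Assemble parameters from explicit arrays (tests, planted ground truth).

    Projections default to the identity.  The soft-constraint observation
    sets are left empty; callers that need them fill them in.
    """
    entity_ids = sorted(entities)
    relations = relations or {}
    relation_ids = sorted(relations)
    k = len(next(iter(entities.values())))
    d = len(next(iter(relations.values()))) if relations else k
    arrays: dict[str, np.ndarray] = {
        "E": np.array([entities[e] for e in entity_ids], dtype=np.float64),
        "R": (np.array([relations[r] for r in relation_ids], dtype=np.float64)
              if relations else np.zeros((0, d))),
        "Ml": np.eye(k, d) if proj_ddi is None else np.asarray(proj_ddi, dtype=np.float64),
    }
    if proj is None:
        arrays["M"] = np.repeat(np.eye(k, d)[None], len(relation_ids), axis=0)
    else:
        arrays["M"] = np.array([proj[r] for r in relation_ids], dtype=np.float64)
    widths = [n_labels]
    if ae is not None:
        widths = [ae.weights[0].shape[1]] + [W.shape[0] for W in ae.weights]
        for i, (W, b) in enumerate(zip(ae.weights, ae.biases)):
            arrays[f"ae_W{i}"] = np.asarray(W, dtype=np.float64)
            arrays[f"ae_b{i}"] = np.asarray(b, dtype=np.float64)
        n_labels = widths[-1]
    return ModelParameters(entity_ids=entity_ids, relation_ids=relation_ids,
                           arrays=arrays, n_labels=n_labels, ae_widths=widths)


# ---------------------------------------------------------------------------
# Numerics helpers
# ---------------------------------------------------------------------------

def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return -np.logaddexp(0.0, -np.asarray(x, dtype=np.float64))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return np.exp(_log_sigmoid(x))


def _norm_and_grad(res: np.ndarray, norm: str) -> tuple[np.ndarray, np.ndarray]:
    """(||res||, d||res||/dres) along the last axis; L1 uses the sign
    subgradient, L2 is guarded at zero."""
    if norm == "L1":
        return np.abs(res).sum(axis=-1), np.sign(res)
    n = np.linalg.norm(res, axis=-1)
    safe = np.where(n == 0.0, 1.0, n)
    g = res / safe[..., None]
    return n, np.where(n[..., None] == 0.0, 0.0, g)


# ---------------------------------------------------------------------------
# Scoring (public operations)
# ---------------------------------------------------------------------------

def score_basic(params: ModelParameters, triple: BasicTriple, hp: Hyperparameters) -> float:
    """z_bte = b1 - ||h M_r + r - t M_r||; bounded above by b1."""
    if triple.relation not in params.relation_index:
        raise KeyError(f"unknown relation {triple.relation!r}")
    ri = params.relation_index[triple.relation]
    Mr = params.M[ri]
    res = params.entity_vec(triple.head) @ Mr + params.R[ri] - params.entity_vec(triple.tail) @ Mr
    n, _ = _norm_and_grad(res, hp.norm)
    return float(hp.b1 - n)


def score_ddi(params: ModelParameters, u: str, l_emb: np.ndarray, v: str,
              hp: Hyperparameters) -> float:
    """z_dte = b2 - ||u M_l + l - v M_l||; bounded above by b2."""
    res = params.entity_vec(u) @ params.Ml + l_emb - params.entity_vec(v) @ params.Ml
    n, _ = _norm_and_grad(res, hp.norm)
    return float(hp.b2 - n)


def conditional_probability(
    params: ModelParameters,
    triple: BasicTriple,
    slot: str,
    candidates: list[str],
    hp: Hyperparameters,
) -> np.ndarray:
    """Softmax over z_bte with each candidate substituted into *slot*."""
    if not candidates:
        raise ValueError("candidate set is empty")
    if slot not in ("head", "relation", "tail"):
        raise ValueError(f"slot must be head/relation/tail, got {slot!r}")
    z = np.array([
        score_basic(params, replace(triple, **{slot: cand}), hp) for cand in candidates
    ])
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Autoencoder forward / backward
# ---------------------------------------------------------------------------

def _mlp_forward(weights, biases, activations, dropout_flags, X, dropout,
                 training, rng):
    """Generic MLP pass with inverted dropout; returns (output, caches)."""
    caches = []
    h = np.atleast_2d(np.asarray(X, dtype=np.float64))
    for W, b, act, drop in zip(weights, biases, activations, dropout_flags):
        a = h @ W.T + b
        out = np.tanh(a) if act == "tanh" else _sigmoid(a)
        mask = None
        if drop and training and dropout > 0.0 and rng is not None:
            mask = (rng.random(out.shape) >= dropout) / (1.0 - dropout)
        caches.append((h, out, mask, act, W))
        h = out if mask is None else out * mask
    return h, caches


def _mlp_backward(caches, d_out, grads, names):
    """Backprop through `_mlp_forward` caches; accumulates into *grads* and
    returns the gradient with respect to the input."""
    for (inp, out, mask, act, W), (wname, bname) in zip(reversed(caches), reversed(names)):
        if mask is not None:
            d_out = d_out * mask
        if act == "tanh":
            da = d_out * (1.0 - out**2)
        else:  # logistic
            da = d_out * out * (1.0 - out)
        grads[wname] += da.T @ inp
        grads[bname] += da.sum(axis=0)
        d_out = da @ W
    return d_out


def _encoder_spec(ae: AutoencoderParameters):
    ci = ae.code_layer_index
    acts = ["tanh"] * ci
    drops = [True] * (ci - 1) + [False]  # never drop the code layer
    return ae.weights[:ci], ae.biases[:ci], acts, drops


def _decoder_spec(ae: AutoencoderParameters):
    ci = ae.code_layer_index
    n_dec = ae.n_layers - ci
    acts = ["tanh"] * (n_dec - 1) + ["sigmoid"]
    drops = [True] * (n_dec - 1) + [False]
    return ae.weights[ci:], ae.biases[ci:], acts, drops


def encode_labels(ae: AutoencoderParameters, s: np.ndarray, dropout: float = 0.0,
                  training: bool = False,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Encoder half: tanh layers down to the code; the code is the DDI
    relation embedding l.  Dropout acts on hidden layers when *training*."""
    s = np.asarray(s, dtype=np.float64)
    W, b, acts, drops = _encoder_spec(ae)
    if s.shape[-1] != W[0].shape[1]:
        raise ValueError(f"label vector length {s.shape[-1]} != {W[0].shape[1]}")
    out, _ = _mlp_forward(W, b, acts, drops, s, dropout, training, rng)
    return out[0] if s.ndim == 1 else out


def decode_labels(ae: AutoencoderParameters, l_emb: np.ndarray) -> np.ndarray:
    """Decoder half: tanh hidden layers, logistic output in (0,1)^|L|."""
    l_emb = np.asarray(l_emb, dtype=np.float64)
    W, b, acts, drops = _decoder_spec(ae)
    if l_emb.shape[-1] != W[0].shape[1]:
        raise ValueError(f"code length {l_emb.shape[-1]} != {W[0].shape[1]}")
    out, _ = _mlp_forward(W, b, acts, drops, l_emb, 0.0, False, None)
    return out[0] if l_emb.ndim == 1 else out


def reconstruction_weights(s: np.ndarray, beta: float) -> np.ndarray:
    """x_i = beta where s_i = 1, else 1 (beta > 1)."""
    if beta <= 1:
        raise ValueError(f"beta must be > 1, got {beta}")
    s = np.asarray(s)
    return np.where(s > 0.5, float(beta), 1.0)


def reconstruction_score(s: np.ndarray, s_hat: np.ndarray, x: np.ndarray,
                         b3: float, norm: str = "L1") -> float:
    """z_rcl = b3 - ||(s - s_hat) (.) x||."""
    s, s_hat, x = (np.asarray(a, dtype=np.float64) for a in (s, s_hat, x))
    if not (s.shape == s_hat.shape == x.shape):
        raise ValueError("s, s_hat, x must have identical shapes")
    n, _ = _norm_and_grad((s - s_hat) * x, norm)
    return float(b3 - n)


# ---------------------------------------------------------------------------
# Regularizer (soft constraints)
# ---------------------------------------------------------------------------

def regularizer(params: ModelParameters, gamma: float) -> float:
    """gamma * sum of hinge penalties [||.||^2 - 1]_+ over entity vectors,
    relation vectors, and the observed projected entities (e M_r and drug
    M_l projections)."""
    if gamma == 0.0:
        return 0.0
    c = np.maximum((params.E**2).sum(axis=1) - 1.0, 0.0).sum()
    c += np.maximum((params.R**2).sum(axis=1) - 1.0, 0.0).sum()
    if len(params.obs_e):
        p = np.einsum("ik,ikd->id", params.E[params.obs_e], params.M[params.obs_r])
        c += np.maximum((p**2).sum(axis=1) - 1.0, 0.0).sum()
    if len(params.ddi_drug_idx):
        p = params.E[params.ddi_drug_idx] @ params.Ml
        c += np.maximum((p**2).sum(axis=1) - 1.0, 0.0).sum()
    return float(gamma * c)


# ---------------------------------------------------------------------------
# Negative sampling (public per-triple operation)
# ---------------------------------------------------------------------------

def sample_negatives(
    triple: BasicTriple | RichDDITriple,
    slot: str,
    c: int,
    kg: DrugKG,
    rng: np.random.Generator,
    filtered: bool = True,
):
    """c corrupted copies of *triple* with *slot* refilled uniformly.

    Corruptions that reproduce a triple present in *kg* are rejected
    (``filtered=True``, the default).  For rich DDI triples the head/tail
    pools are the drug entities and a relation corruption substitutes the
    label set of a different DDI triple.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    if c == 0:
        return []
    if isinstance(triple, BasicTriple):
        existing = {(t.head, t.relation, t.tail) for t in kg.basic} if filtered else set()
        if slot in ("head", "tail"):
            pool = sorted(kg.entities)
        elif slot == "relation":
            pool = sorted({t.relation for t in kg.basic})
        else:
            raise ValueError(f"bad slot {slot!r}")
        cands = []
        for x in pool:
            cand = replace(triple, **{slot: x})
            if (cand.head, cand.relation, cand.tail) in existing:
                continue
            cands.append(cand)
        if not cands:
            raise SamplingError(f"no valid corruption for slot {slot!r}")
        idx = rng.integers(0, len(cands), size=c)
        return [cands[i] for i in idx]

    # RichDDITriple
    pairs = set(kg.undirected_pairs()) if filtered else set()
    if slot in ("head", "tail"):
        pool = sorted(kg.drugs)
        cands = []
        for x in pool:
            u, v = (x, triple.drug_v) if slot == "head" else (triple.drug_u, x)
            if u == v or tuple(sorted((u, v))) in pairs:
                continue
            cands.append(RichDDITriple(u, triple.labels, v))
        if not cands:
            raise SamplingError(f"no valid drug corruption for slot {slot!r}")
        idx = rng.integers(0, len(cands), size=c)
        return [cands[i] for i in idx]
    if slot == "relation":
        others = sorted({t.labels for t in kg.ddi if t.labels != triple.labels},
                        key=sorted)
        if not others:
            raise SamplingError("no alternative label sets to corrupt with")
        idx = rng.integers(0, len(others), size=c)
        return [RichDDITriple(triple.drug_u, others[i], triple.drug_v) for i in idx]
    raise ValueError(f"bad slot {slot!r}")


def negative_sampling_objective(params, positive, negatives, hp) -> float:
    """log sigma(z_pos) + sum log sigma(-z_neg) for one positive triple."""

    def z(t):
        if isinstance(t, BasicTriple):
            return score_basic(params, t, hp)
        u, l_emb, v = t
        return score_ddi(params, u, l_emb, v, hp)

    total = float(_log_sigmoid(z(positive)))
    for neg in negatives:
        total += float(_log_sigmoid(-z(neg)))
    return total


# ---------------------------------------------------------------------------
# Batch assembly (index-based, vectorized)
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Index-coded positives plus pre-drawn negatives for one step.

    Keeping the negatives inside the batch makes the objective a
    deterministic function of the parameters, which is what both Adam and
    the finite-difference gradient check need.
    """

    bh: np.ndarray  # (nb,) head entity indices
    br: np.ndarray  # (nb,) relation indices
    bt: np.ndarray  # (nb,) tail entity indices
    bh_neg: np.ndarray  # (nb, c)
    bt_neg: np.ndarray  # (nb, c)
    br_neg: np.ndarray  # (nb, c_r) corrupted relations (c_r may be 0)
    du: np.ndarray  # (nd,)
    dv: np.ndarray  # (nd,)
    ds: np.ndarray  # (nd, L) label vectors
    du_neg: np.ndarray  # (nd, c)
    dv_neg: np.ndarray  # (nd, c)
    ds_rel_neg: np.ndarray  # (nd, c_l, L) corrupted label vectors
    ds_flip: np.ndarray  # (nd, c, L) flipped label vectors (reconstruction)

    @property
    def n_basic(self) -> int:
        return len(self.bh)

    @property
    def n_ddi(self) -> int:
        return len(self.du)


class TrainContext:
    """Pre-indexed training KG: triple arrays, label matrix, filter sets."""

    def __init__(self, kg: DrugKG, params: ModelParameters):
        self.kg = kg
        eidx, ridx = params.entity_index, params.relation_index
        self.bh = np.array([eidx[t.head] for t in kg.basic], dtype=np.int64)
        self.br = np.array([ridx[t.relation] for t in kg.basic], dtype=np.int64)
        self.bt = np.array([eidx[t.tail] for t in kg.basic], dtype=np.int64)
        self.du = np.array([eidx[t.drug_u] for t in kg.ddi], dtype=np.int64)
        self.dv = np.array([eidx[t.drug_v] for t in kg.ddi], dtype=np.int64)
        self.S = (np.array([vectorize(t.labels, kg.vocabulary) for t in kg.ddi])
                  if kg.ddi else np.zeros((0, len(kg.vocabulary))))
        gid_map: dict[frozenset, int] = {}
        self.label_gid = np.array(
            [gid_map.setdefault(t.labels, len(gid_map)) for t in kg.ddi],
            dtype=np.int64)
        self.basic_set = set(zip(self.bh.tolist(), self.br.tolist(), self.bt.tolist()))
        self.pair_set = {tuple(sorted(p)) for p in zip(self.du.tolist(), self.dv.tolist())}
        self.drug_idx = np.array(sorted({eidx[d] for d in kg.drugs}), dtype=np.int64)
        self.n_entities = len(params.entity_ids)
        self.n_relations = len(params.relation_ids)
        L = len(kg.vocabulary)
        self.n_flips = max(1, min(5, round(L / 10)))


def _resample_where(draw, pool, bad_fn, rng, max_rounds=30):
    """Redraw entries of *draw* from *pool* while bad_fn flags them.

    Best-effort: a slot for which no valid corruption exists (every filler
    reproduces a training triple) keeps its last draw — an occasional
    false-negative corruption is standard in sampled KG training and
    preferable to aborting the step.
    """
    for _ in range(max_rounds):
        bad = bad_fn(draw)
        if not bad.any():
            break
        draw = draw.copy()
        draw[bad] = pool[rng.integers(0, len(pool), size=int(bad.sum()))]
    return draw


def make_batch(ctx: TrainContext, hp: Hyperparameters,
               rng: np.random.Generator,
               basic_idx: np.ndarray | None = None,
               ddi_idx: np.ndarray | None = None) -> Batch:
    """Draw a mini-batch of positives and all their negatives."""
    nB, nT = len(ctx.bh), len(ctx.du)
    if basic_idx is None or ddi_idx is None:
        total = nB + nT
        n_d = min(nT, max(1, round(hp.batch_size * nT / total))) if nT else 0
        n_b = min(nB, max(1, hp.batch_size - n_d)) if nB else 0
        basic_idx = rng.choice(nB, size=n_b, replace=False) if n_b else np.zeros(0, np.int64)
        ddi_idx = rng.choice(nT, size=n_d, replace=False) if n_d else np.zeros(0, np.int64)

    bh, br, bt = ctx.bh[basic_idx], ctx.br[basic_idx], ctx.bt[basic_idx]
    nb, c = len(bh), hp.c
    ent_pool = np.arange(ctx.n_entities)
    filt = hp.filtered_sampling

    def corrupt_entities(fixed_r, fixed_other, is_head):
        draw = rng.integers(0, ctx.n_entities, size=(nb, c))

        def bad(d):
            flat = d.ravel()
            rr = np.repeat(fixed_r, c)
            oo = np.repeat(fixed_other, c)
            if is_head:
                hit = [(x, r, o) in ctx.basic_set for x, r, o in zip(flat, rr, oo)]
            else:
                hit = [(o, r, x) in ctx.basic_set for x, r, o in zip(flat, rr, oo)]
            return np.array(hit).reshape(d.shape) if filt else np.zeros(d.shape, bool)

        return _resample_where(draw, ent_pool, bad, rng) if nb else draw

    bh_neg = corrupt_entities(br, bt, True) if nb and c else np.zeros((nb, 0), np.int64)
    bt_neg = corrupt_entities(br, bh, False) if nb and c else np.zeros((nb, 0), np.int64)
    if nb and c and ctx.n_relations > 1:
        rel_pool = np.arange(ctx.n_relations)
        draw = rng.integers(0, ctx.n_relations, size=(nb, c))

        def bad_rel(d):
            flat = d.ravel()
            hh = np.repeat(bh, c)
            tt = np.repeat(bt, c)
            same = flat == np.repeat(br, c)
            if filt:
                hit = np.array([(h, r, t) in ctx.basic_set
                                for h, r, t in zip(hh, flat, tt)])
                return (same | hit).reshape(d.shape)
            return same.reshape(d.shape)

        br_neg = _resample_where(draw, rel_pool, bad_rel, rng)
    else:
        br_neg = np.zeros((nb, 0), np.int64)

    du, dv = ctx.du[ddi_idx], ctx.dv[ddi_idx]
    ds = ctx.S[ddi_idx] if len(ddi_idx) else np.zeros((0, ctx.S.shape[1] if ctx.S.size else 0))
    nd = len(du)
    drug_pool = ctx.drug_idx

    def corrupt_drugs(fixed):
        draw = drug_pool[rng.integers(0, len(drug_pool), size=(nd, c))]

        def bad(d):
            flat = d.ravel()
            oo = np.repeat(fixed, c)
            self_pair = flat == oo
            if filt:
                hit = np.array([tuple(sorted((x, o))) in ctx.pair_set
                                for x, o in zip(flat, oo)])
                return (self_pair | hit).reshape(d.shape)
            return self_pair.reshape(d.shape)

        return _resample_where(draw, drug_pool, bad, rng)

    du_neg = corrupt_drugs(dv) if nd and c else np.zeros((nd, 0), np.int64)
    dv_neg = corrupt_drugs(du) if nd and c else np.zeros((nd, 0), np.int64)

    # relation (label-set) corruption: label vector of a different DDI triple
    if nd and c and len(np.unique(ctx.label_gid)) > 1:
        all_idx = np.arange(len(ctx.du))
        draw = rng.integers(0, len(all_idx), size=(nd, c))

        def bad_lab(d):
            return ctx.label_gid[d.ravel()].reshape(d.shape) == \
                ctx.label_gid[ddi_idx][:, None]

        draw = _resample_where(draw, all_idx, bad_lab, rng)
        ds_rel_neg = ctx.S[draw]
    else:
        ds_rel_neg = np.zeros((nd, 0, ds.shape[1] if ds.size else 0))

    # reconstruction negatives: flip a few components of s
    L = ds.shape[1] if ds.size else 0
    if nd and c and L:
        ds_flip = np.repeat(ds[:, None, :], c, axis=1).copy()
        for i in range(nd):
            for j in range(c):
                pos = rng.choice(L, size=ctx.n_flips, replace=False)
                ds_flip[i, j, pos] = 1.0 - ds_flip[i, j, pos]
    else:
        ds_flip = np.zeros((nd, 0, L))

    return Batch(bh=bh, br=br, bt=bt, bh_neg=bh_neg, bt_neg=bt_neg,
                 br_neg=br_neg, du=du, dv=dv, ds=ds, du_neg=du_neg,
                 dv_neg=dv_neg, ds_rel_neg=ds_rel_neg, ds_flip=ds_flip)


# ---------------------------------------------------------------------------
# Joint objective and analytic gradient
# ---------------------------------------------------------------------------

def objective_and_grad(
    params: ModelParameters,
    batch: Batch,
    hp: Hyperparameters,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Joint objective O = L_bte + L_dte + L_rcl - gamma*C and its gradient.

    The returned gradient is the *ascent* direction dO/dtheta.  With
    ``training=True`` dropout masks are drawn from *rng* and the gradient is
    exact for the realized masks.
    """
    E, R, M, Ml = params.E, params.R, params.M, params.Ml
    n_r = len(params.relation_ids)
    grads = params.zero_grads()
    O = 0.0

    # projections of every entity under every relation (+ the DDI projection)
    P = np.einsum("ek,rkd->red", E, M) if n_r else np.zeros((0, len(E), 0))
    Pl = E @ Ml
    dP = np.zeros_like(P)
    dPl = np.zeros_like(Pl)

    # ---- basic-triple terms ------------------------------------------------
    nb = batch.n_basic
    if nb:
        res = P[batch.br, batch.bh] + R[batch.br] - P[batch.br, batch.bt]
        n, g = _norm_and_grad(res, hp.norm)
        z = hp.b1 - n
        O += 3.0 * _log_sigmoid(z).sum()
        w = 3.0 * _sigmoid(-z)  # dO/dz, one surrogate per slot
        A = (w[:, None]) * (-g)  # dO/dres
        np.add.at(dP, (batch.br, batch.bh), A)
        np.add.at(dP, (batch.br, batch.bt), -A)
        np.add.at(grads["R"], batch.br, A)

        def neg_term(res_neg, rid, hidx, tidx):
            nonlocal O
            nn, gg = _norm_and_grad(res_neg, hp.norm)
            zz = hp.b1 - nn
            O += _log_sigmoid(-zz).sum()
            ww = -_sigmoid(zz)
            AA = ww[..., None] * (-gg)
            np.add.at(dP, (rid, hidx), AA)
            np.add.at(dP, (rid, tidx), -AA)
            np.add.at(grads["R"], np.asarray(rid).ravel(),
                      AA.reshape(-1, AA.shape[-1]))

        if batch.bh_neg.shape[1]:
            rid = np.broadcast_to(batch.br[:, None], batch.bh_neg.shape)
            tid = np.broadcast_to(batch.bt[:, None], batch.bh_neg.shape)
            res_n = P[rid, batch.bh_neg] + R[rid] - P[rid, tid]
            neg_term(res_n, rid, batch.bh_neg, tid)
        if batch.bt_neg.shape[1]:
            rid = np.broadcast_to(batch.br[:, None], batch.bt_neg.shape)
            hid = np.broadcast_to(batch.bh[:, None], batch.bt_neg.shape)
            res_n = P[rid, hid] + R[rid] - P[rid, batch.bt_neg]
            neg_term(res_n, rid, hid, batch.bt_neg)
        if batch.br_neg.shape[1]:
            hid = np.broadcast_to(batch.bh[:, None], batch.br_neg.shape)
            tid = np.broadcast_to(batch.bt[:, None], batch.br_neg.shape)
            res_n = P[batch.br_neg, hid] + R[batch.br_neg] - P[batch.br_neg, tid]
            neg_term(res_n, batch.br_neg, hid, tid)

    # ---- DDI-triple and reconstruction terms -------------------------------
    nd = batch.n_ddi
    enc_caches = dec_caches = None
    if nd:
        ae = params.ae
        Wenc, benc, acts_e, drops_e = _encoder_spec(ae)
        Wdec, bdec, acts_d, drops_d = _decoder_spec(ae)
        l_pos, enc_caches = _mlp_forward(Wenc, benc, acts_e, drops_e, batch.ds,
                                         hp.dropout, training, rng)
        dl_pos = np.zeros_like(l_pos)

        res = Pl[batch.du] + l_pos - Pl[batch.dv]
        n, g = _norm_and_grad(res, hp.norm)
        z = hp.b2 - n
        O += 3.0 * _log_sigmoid(z).sum()
        w = 3.0 * _sigmoid(-z)
        A = w[:, None] * (-g)
        np.add.at(dPl, batch.du, A)
        np.add.at(dPl, batch.dv, -A)
        dl_pos += A

        c_u = batch.du_neg.shape[1]
        if c_u:
            res_n = Pl[batch.du_neg] + l_pos[:, None, :] - Pl[batch.dv][:, None, :]
            nn, gg = _norm_and_grad(res_n, hp.norm)
            zz = hp.b2 - nn
            O += _log_sigmoid(-zz).sum()
            AA = (-_sigmoid(zz))[..., None] * (-gg)
            np.add.at(dPl, batch.du_neg, AA)
            np.add.at(dPl, np.broadcast_to(batch.dv[:, None], batch.du_neg.shape), -AA)
            dl_pos += AA.sum(axis=1)
        if batch.dv_neg.shape[1]:
            res_n = Pl[batch.du][:, None, :] + l_pos[:, None, :] - Pl[batch.dv_neg]
            nn, gg = _norm_and_grad(res_n, hp.norm)
            zz = hp.b2 - nn
            O += _log_sigmoid(-zz).sum()
            AA = (-_sigmoid(zz))[..., None] * (-gg)
            np.add.at(dPl, np.broadcast_to(batch.du[:, None], batch.dv_neg.shape), AA)
            np.add.at(dPl, batch.dv_neg, -AA)
            dl_pos += AA.sum(axis=1)

        c_l = batch.ds_rel_neg.shape[1]
        relneg_caches = None
        if c_l:
            S_neg = batch.ds_rel_neg.reshape(nd * c_l, -1)
            l_neg, relneg_caches = _mlp_forward(Wenc, benc, acts_e, drops_e, S_neg,
                                                hp.dropout, training, rng)
            res_n = (Pl[batch.du][:, None, :] + l_neg.reshape(nd, c_l, -1)
                     - Pl[batch.dv][:, None, :])
            nn, gg = _norm_and_grad(res_n, hp.norm)
            zz = hp.b2 - nn
            O += _log_sigmoid(-zz).sum()
            AA = (-_sigmoid(zz))[..., None] * (-gg)
            np.add.at(dPl, np.broadcast_to(batch.du[:, None], (nd, c_l)), AA)
            np.add.at(dPl, np.broadcast_to(batch.dv[:, None], (nd, c_l)), -AA)
            dl_neg = AA.reshape(nd * c_l, -1)
            _mlp_backward(relneg_caches, dl_neg, grads,
                          [(f"ae_W{i}", f"ae_b{i}") for i in range(ae.code_layer_index)])

        # reconstruction surrogate
        s_hat, dec_caches = _mlp_forward(Wdec, bdec, acts_d, drops_d, l_pos,
                                         hp.dropout, training, rng)
        x = reconstruction_weights(batch.ds, hp.beta)
        res_r = (batch.ds - s_hat) * x
        n_r_, g_r = _norm_and_grad(res_r, hp.norm)
        z_r = hp.b3 - n_r_
        O += _log_sigmoid(z_r).sum()
        d_s_hat = (_sigmoid(-z_r))[:, None] * (g_r * x)
        c_f = batch.ds_flip.shape[1]
        if c_f:
            x_f = reconstruction_weights(batch.ds_flip, hp.beta)
            res_f = (batch.ds_flip - s_hat[:, None, :]) * x_f
            n_f, g_f = _norm_and_grad(res_f, hp.norm)
            z_f = hp.b3 - n_f
            O += _log_sigmoid(-z_f).sum()
            d_s_hat += ((-_sigmoid(z_f))[..., None] * (g_f * x_f)).sum(axis=1)

        ci = ae.code_layer_index
        dec_names = [(f"ae_W{i}", f"ae_b{i}") for i in range(ci, ae.n_layers)]
        dl_pos += _mlp_backward(dec_caches, d_s_hat, grads, dec_names)
        enc_names = [(f"ae_W{i}", f"ae_b{i}") for i in range(ci)]
        _mlp_backward(enc_caches, dl_pos, grads, enc_names)

    # ---- soft constraints --------------------------------------------------
    if hp.gamma > 0.0:
        sq = (E**2).sum(axis=1)
        act = sq > 1.0
        O -= hp.gamma * np.maximum(sq - 1.0, 0.0).sum()
        grads["E"][act] -= hp.gamma * 2.0 * E[act]
        if len(R):
            sq = (R**2).sum(axis=1)
            act = sq > 1.0
            O -= hp.gamma * np.maximum(sq - 1.0, 0.0).sum()
            grads["R"][act] -= hp.gamma * 2.0 * R[act]
        if len(params.obs_e):
            p = P[params.obs_r, params.obs_e]
            sq = (p**2).sum(axis=1)
            act = sq > 1.0
            O -= hp.gamma * np.maximum(sq - 1.0, 0.0).sum()
            if act.any():
                A = np.zeros_like(p)
                A[act] = -hp.gamma * 2.0 * p[act]
                np.add.at(dP, (params.obs_r, params.obs_e), A)
        if len(params.ddi_drug_idx):
            p = Pl[params.ddi_drug_idx]
            sq = (p**2).sum(axis=1)
            act = sq > 1.0
            O -= hp.gamma * np.maximum(sq - 1.0, 0.0).sum()
            if act.any():
                A = np.zeros_like(p)
                A[act] = -hp.gamma * 2.0 * p[act]
                np.add.at(dPl, params.ddi_drug_idx, A)

    # fold projection-space gradients back onto E, M, Ml
    for r in range(n_r):
        grads["E"] += dP[r] @ M[r].T
        grads["M"][r] += E.T @ dP[r]
    grads["E"] += dPl @ Ml.T
    grads["Ml"] += E.T @ dPl

    return float(O), grads


def joint_objective(
    params: ModelParameters,
    basic_batch: list[BasicTriple],
    ddi_batch: list[RichDDITriple],
    hp: Hyperparameters,
    kg: DrugKG,
    rng: np.random.Generator,
) -> float:
    """Sampled joint objective for explicit triple lists (negatives drawn
    from *rng*).  The trainer uses :func:`objective_and_grad` directly."""
    ctx = TrainContext(kg, params)
    tb = {(t.head, t.relation, t.tail): i for i, t in enumerate(kg.basic)}
    td = {(t.drug_u, t.drug_v): i for i, t in enumerate(kg.ddi)}
    bidx = np.array([tb[(t.head, t.relation, t.tail)] for t in basic_batch], np.int64)
    didx = np.array([td[(t.drug_u, t.drug_v)] for t in ddi_batch], np.int64)
    batch = make_batch(ctx, hp, rng, basic_idx=bidx, ddi_idx=didx)
    value, _ = objective_and_grad(params, batch, hp)
    return value


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingState:
    objective_trace: list[float] = field(default_factory=list)
    iteration: int = 0
    seed: int = 0


class Adam:
    """Standard Adam in ascent convention (maximizes the objective)."""

    def __init__(self, arrays: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            self.arrays[name] += self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(kg: DrugKG, hp: Hyperparameters) -> tuple[ModelParameters, TrainingState]:
    """Adam ascent on the joint objective over random mini-batches.

    Fully reproducible: all randomness (init, batch selection, negative
    sampling, dropout) flows from ``hp.seed``.
    """
    if not kg.basic or not kg.ddi:
        raise ValueError("training needs at least one basic and one DDI triple")
    rng = np.random.default_rng(hp.seed)
    params = init_params(kg, hp, rng)
    ctx = TrainContext(kg, params)
    adam = Adam(params.arrays, hp.lr)
    state = TrainingState(seed=hp.seed)
    for it in range(hp.iterations):
        batch = make_batch(ctx, hp, rng)
        value, grads = objective_and_grad(params, batch, hp, training=True, rng=rng)
        if not np.isfinite(value):
            raise TrainingDivergenceError(it)
        adam.step(grads)
        state.objective_trace.append(value)
        state.iteration = it + 1
    return params, state


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_model(path: str, params: ModelParameters, hp: Hyperparameters,
               vocabulary: LabelVocabulary) -> None:
    """Single-archive checkpoint (npz): arrays + JSON metadata; bit-exact
    round trip."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "entity_ids": params.entity_ids,
        "relation_ids": params.relation_ids,
        "n_labels": params.n_labels,
        "ae_widths": params.ae_widths,
        "labels": vocabulary.labels,
        "hp": {k: v for k, v in vars(hp).items()},
    }
    payload = dict(params.arrays)
    payload["_obs_e"] = params.obs_e
    payload["_obs_r"] = params.obs_r
    payload["_ddi_drug_idx"] = params.ddi_drug_idx
    payload["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path: str) -> tuple[ModelParameters, Hyperparameters, LabelVocabulary]:
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    meta = json.loads(bytes(data["_meta"]).decode())
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unrecognized checkpoint format {meta.get('format')!r}")
    arrays = {k: data[k] for k in data.files if not k.startswith("_")}
    params = ModelParameters(
        entity_ids=meta["entity_ids"], relation_ids=meta["relation_ids"],
        arrays=arrays, n_labels=meta["n_labels"], ae_widths=meta["ae_widths"],
        obs_e=data["_obs_e"], obs_r=data["_obs_r"],
        ddi_drug_idx=data["_ddi_drug_idx"],
    )
    hp = Hyperparameters(**meta["hp"])
    return params, hp, LabelVocabulary(meta["labels"])
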