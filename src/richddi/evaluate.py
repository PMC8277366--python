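"""Link prediction of DDI label sets and the full evaluation protocol.

Prediction: for a drug pair (u, v) the candidate relation embedding is the
translation ``l = v M_l - u M_l``; decoding it yields a score per vocabulary
label.  Evaluation follows the standard knowledge-base-completion protocol:
raw and filtered MeanRank / Hits@k over held-out multi-label DDI triples
("filtered" removes the other correct labels of the same triple before
ranking), plus a binary DDI classification task from concatenated entity
embeddings with ROC / precision-recall curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (auc, average_precision_score,
                             precision_recall_curve, roc_curve)

from .kg import DDISplit, RichDDITriple, sample_non_ddi_pairs
from .model import ModelParameters, decode_labels
from .text import LabelVocabulary


@dataclass
class RankingResult:
    triple: RichDDITriple
    raw_ranks: dict[str, int]       # correct label -> rank among all |L|
    filtered_ranks: dict[str, int]  # rank with other correct labels removed


@dataclass
class EvaluationReport:
    mean_rank_raw: float
    mean_rank_filtered: float
    hits_at_k_raw: dict[int, float]       # percentage (x100 convention)
    hits_at_k_filtered: dict[int, float]
    n_triples: int
    n_correct_labels: int

    def to_dict(self) -> dict:
        return {
            "mean_rank_raw": self.mean_rank_raw,
            "mean_rank_filtered": self.mean_rank_filtered,
            "hits_at_k_raw": {str(k): v for k, v in self.hits_at_k_raw.items()},
            "hits_at_k_filtered": {str(k): v for k, v in self.hits_at_k_filtered.items()},
            "n_triples": self.n_triples,
            "n_correct_labels": self.n_correct_labels,
        }


@dataclass
class BinaryEvalResult:
    roc_points: np.ndarray  # (n, 2) columns: FPR, TPR
    pr_points: np.ndarray   # (n, 2) columns: recall, precision
    auroc: float
    aupr: float


# ---------------------------------------------------------------------------
# Link prediction
# ---------------------------------------------------------------------------

def predict_relation_embedding(params: ModelParameters, u: str, v: str) -> np.ndarray:
    """Translation-predicted relation embedding l = v M_l - u M_l."""
    return (params.entity_vec(v) - params.entity_vec(u)) @ params.Ml


def predict_labels(
    params: ModelParameters,
    l_emb: np.ndarray,
    vocabulary: LabelVocabulary,
    top_n: int | None = None,
    threshold: float | None = None,
) -> list[tuple[str, float]]:
    """Decode l and return (label, score) pairs ranked by score descending.

    Exactly one of *top_n* / *threshold* selects the cut.
    """
    if (top_n is None) == (threshold is None):
        raise ValueError("specify exactly one of top_n or threshold")
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    if threshold is not None and not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    s_hat = decode_labels(params.ae, l_emb)
    order = sorted(range(len(s_hat)), key=lambda i: (-s_hat[i], vocabulary.labels[i]))
    ranked = [(vocabulary.labels[i], float(s_hat[i])) for i in order]
    if top_n is not None:
        return ranked[:top_n]
    return [(lab, sc) for lab, sc in ranked if sc >= threshold]


def predict_pair(params: ModelParameters, u: str, v: str,
                 vocabulary: LabelVocabulary, top_n: int = 5) -> list[tuple[str, float]]:
    """End-to-end: translation embedding for (u, v), decoded and ranked."""
    return predict_labels(params, predict_relation_embedding(params, u, v),
                          vocabulary, top_n=top_n)


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def _rank(scores: np.ndarray, idx: int) -> int:
    """Pessimistic competition rank: strictly-higher count plus the full tie
    group (a constant decoder cannot inflate Hits)."""
    s = scores[idx]
    return int((scores > s).sum() + (scores == s).sum())


def rank_from_scores(scores: np.ndarray, triple: RichDDITriple,
                     vocabulary: LabelVocabulary) -> RankingResult:
    """Raw and filtered ranks of a triple's correct labels from one score
    vector over the whole vocabulary; the filtered rank removes the other
    correct labels from the candidate list first."""
    scores = np.asarray(scores, dtype=float)
    correct_idx = {lab: vocabulary.index[lab] for lab in sorted(triple.labels)}
    raw = {lab: _rank(scores, i) for lab, i in correct_idx.items()}
    filtered = {}
    for lab, i in correct_idx.items():
        keep = np.ones(len(scores), dtype=bool)
        keep[[j for l2, j in correct_idx.items() if l2 != lab]] = False
        sub_idx = int(keep[:i].sum())  # position of lab among kept candidates
        filtered[lab] = _rank(scores[keep], sub_idx)
    return RankingResult(triple=triple, raw_ranks=raw, filtered_ranks=filtered)


def rank_labels(
    params: ModelParameters,
    test: RichDDITriple,
    vocabulary: LabelVocabulary,
) -> RankingResult:
    """Raw and filtered ranks of every correct label of one test triple.

    Candidates are all |L| vocabulary labels scored by decoding the
    translation-predicted relation embedding.
    """
    l_emb = predict_relation_embedding(params, test.drug_u, test.drug_v)
    scores = decode_labels(params.ae, l_emb)
    return rank_from_scores(scores, test, vocabulary)


def aggregate_metrics(results: list[RankingResult], ks: list[int]) -> EvaluationReport:
    """MeanRank = mean over all correct-label ranks; Hits@k = 100 x share of
    ranks <= k; raw and filtered computed separately."""
    if not results:
        raise ValueError("no ranking results to aggregate")
    raw = np.array([r for res in results for r in res.raw_ranks.values()], dtype=float)
    filt = np.array([r for res in results for r in res.filtered_ranks.values()], dtype=float)
    return EvaluationReport(
        mean_rank_raw=float(raw.mean()),
        mean_rank_filtered=float(filt.mean()),
        hits_at_k_raw={k: 100.0 * int((raw <= k).sum()) / len(raw)
                       for k in ks},
        hits_at_k_filtered={k: 100.0 * int((filt <= k).sum()) / len(filt)
                            for k in ks},
        n_triples=len(results),
        n_correct_labels=len(raw),
    )


def evaluate_ranking(params: ModelParameters, split: DDISplit,
                     vocabulary: LabelVocabulary,
                     ks: list[int] = (1, 5, 10)) -> EvaluationReport:
    results = [rank_labels(params, t, vocabulary) for t in split.test_positives]
    return aggregate_metrics(results, list(ks))


# ---------------------------------------------------------------------------
# Binary DDI classification
# ---------------------------------------------------------------------------

def binary_features(params: ModelParameters, u: str, v: str) -> np.ndarray:
    """Concatenated entity embeddings (u-vector, v-vector), length 2k."""
    return np.concatenate([params.entity_vec(u), params.entity_vec(v)])


def binary_curves(y_true: np.ndarray, scores: np.ndarray) -> BinaryEvalResult:
    """ROC (trapezoidal area) and PR (step-wise area) from scores."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y_true, scores)
    prec, rec, _ = precision_recall_curve(y_true, scores)
    return BinaryEvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
        auroc=float(auc(fpr, tpr)),
        aupr=float(average_precision_score(y_true, scores)),
    )


def binary_evaluate(
    params: ModelParameters,
    split: DDISplit,
    classifier_seed: int = 0,
) -> BinaryEvalResult:
    """Logistic regression on concatenated embeddings.

    Training positives are the train-KG DDI pairs; training negatives are
    non-DDI pairs sampled disjointly from the test negatives, equal in count
    to the positives.  Evaluation uses the held-out positive and negative
    test pairs.  Pairs are canonicalized (sorted order) before feature
    concatenation.
    """
    rng = np.random.default_rng(classifier_seed)
    train_pos = sorted(split.train_kg.undirected_pairs())
    if not train_pos or not split.test_positives or not split.test_negatives:
        raise ValueError("split must contain train positives and test pairs of both classes")
    test_pos = sorted({t.pair for t in split.test_positives})
    train_neg = sample_non_ddi_pairs(
        split.train_kg, len(train_pos), rng,
        exclude=set(split.test_negatives) | set(test_pos))
    feats = lambda pairs: np.array([binary_features(params, a, b) for a, b in pairs])
    X_train = np.vstack([feats(train_pos), feats(train_neg)])
    y_train = np.concatenate([np.ones(len(train_pos)), np.zeros(len(train_neg))])
    if len(set(y_train)) < 2:
        raise ValueError("degenerate training data: single class")
    clf = LogisticRegression(max_iter=2000, random_state=classifier_seed)
    clf.fit(X_train, y_train)
    test_pairs = list(test_pos) + [tuple(sorted(p)) for p in split.test_negatives]
    y_test = np.concatenate([np.ones(len(test_pos)), np.zeros(len(split.test_negatives))])
    scores = clf.predict_proba(feats(test_pairs))[:, 1]
    return binary_curves(y_test, scores)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def write_ranks_tsv(path: str, results: list[RankingResult]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_u\tdrug_v\tlabel\traw_rank\tfiltered_rank\n")
        for res in results:
            for lab in sorted(res.raw_ranks):
                fh.write(f"{res.triple.drug_u}\t{res.triple.drug_v}\t{lab}\t"
                         f"{res.raw_ranks[lab]}\t{res.filtered_ranks[lab]}\n")


def write_curve_tsv(path: str, points: np.ndarray, header: tuple[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in points:
            fh.write(f"{row[0]:.6f}\t{row[1]:.6f}\n")
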