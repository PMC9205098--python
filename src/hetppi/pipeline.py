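"""PPI prediction pipeline: feature aggregation, pair assembly, negative
sampling, classifiers and leakage-controlled 5-fold cross-validation.

Positives are the known protein-protein interaction edges; negatives are
protein pairs drawn from the complement of the positive set.  For every
fold the test-fold PPIs are removed from the network *before* the embedder
is trained, so no test interaction is visible to either the embedding or
the classifier — the leakage guard is asserted, not assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import comb
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .hetnet import HeteroNetwork, NodeRef, TypedEdge, remove_edges
from .inter_view import KMER_DIM, SequenceRecord, kmer_vector
from .line_embed import LineConfig, intra_view_features, train_line

logger = logging.getLogger(__name__)

Pair = tuple[NodeRef, NodeRef]

CLASSIFIERS = ("RF", "SVM", "LR", "NB", "AdaBoost", "XGBoost")
PAIR_MODES = ("ordered_concat", "hadamard", "average", "abs_diff")


# ---------------------------------------------------------------------------
# aggregation


def _activation(name: str) -> Callable[[np.ndarray], np.ndarray]:
    if name == "identity":
        return lambda x: x
    if name == "sigmoid":
        return lambda x: 1.0 / (1.0 + np.exp(-x))
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class AggregationConfig:
    """How the sequence (inter-view) and network (intra-view) vectors are
    fused into one protein representation.

    ``concat`` stacks the two vectors; ``sum`` zero-pads the shorter one and
    adds them elementwise.  ``W``/``b`` apply an optional linear projection
    (identity pass-through when ``W`` is None), followed by ``activation``.
    """

    mode: str = "concat"
    W: np.ndarray | None = None
    b: np.ndarray | None = None
    activation: str = "identity"

    def __post_init__(self) -> None:
        if self.mode not in ("concat", "sum"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        _activation(self.activation)


def aggregate(
    e_inter: np.ndarray, e_intra: np.ndarray, cfg: AggregationConfig | None = None
) -> np.ndarray:
    """Fuse one protein's two view vectors per the aggregation config."""
    cfg = cfg or AggregationConfig()
    e_inter = np.asarray(e_inter, dtype=float)
    e_intra = np.asarray(e_intra, dtype=float)
    if cfg.mode == "concat":
        x = np.concatenate([e_inter, e_intra])
    else:  # sum: zero-pad the shorter vector
        n = max(len(e_inter), len(e_intra))
        a = np.pad(e_inter, (0, n - len(e_inter)))
        b = np.pad(e_intra, (0, n - len(e_intra)))
        x = a + b
    if cfg.W is not None:
        W = np.asarray(cfg.W, dtype=float)
        if W.shape[1] != len(x):
            raise ValueError(f"projection W has {W.shape[1]} columns, input has {len(x)}")
        x = W @ x
        if cfg.b is not None:
            x = x + np.asarray(cfg.b, dtype=float)
    return _activation(cfg.activation)(x)


def pair_feature(e_a: np.ndarray, e_b: np.ndarray, mode: str = "ordered_concat") -> np.ndarray:
    """Combine two protein representations into one classifier input.

    ``ordered_concat`` stacks the vectors as given (callers pass them in
    canonical node-id order, making the result well defined); the other
    modes are symmetric by construction.
    """
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if e_a.shape != e_b.shape:
        raise ValueError(f"pair vectors differ in length: {e_a.shape} vs {e_b.shape}")
    if mode == "ordered_concat":
        return np.concatenate([e_a, e_b])
    if mode == "hadamard":
        return e_a * e_b
    if mode == "average":
        return (e_a + e_b) / 2.0
    if mode == "abs_diff":
        return np.abs(e_a - e_b)
    raise ValueError(f"unknown pair mode {mode!r}; expected one of {PAIR_MODES}")


# ---------------------------------------------------------------------------
# sampling and folds


def _canonical_pair(a: NodeRef, b: NodeRef) -> Pair:
    return (a, b) if a <= b else (b, a)


def sample_negatives(
    net: HeteroNetwork,
    n: int,
    exclude: Iterable[Pair] = (),
    seed: int | np.random.Generator = 0,
) -> set[Pair]:
    """Draw ``n`` distinct protein pairs that are neither known PPIs nor in
    ``exclude`` — the negative class of the classification task."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins = net.proteins()
    p = len(proteins)
    forbidden: set[Pair] = {_canonical_pair(e.u, e.v) for e in net.ppi_edges()}
    forbidden |= {_canonical_pair(a, b) for a, b in exclude}
    available = comb(p, 2) - len(forbidden)
    if n > available:
        raise ValueError(f"requested {n} negatives but only {available} pairs are available")
    chosen: set[Pair] = set()
    if comb(p, 2) <= 4 * max(n, 1) or comb(p, 2) <= 10_000:
        # small universe: enumerate the complement and subsample exactly
        complement = [
            (proteins[i], proteins[j])
            for i in range(p)
            for j in range(i + 1, p)
            if (proteins[i], proteins[j]) not in forbidden
        ]
        idx = rng.choice(len(complement), size=n, replace=False)
        return {complement[int(i)] for i in sorted(idx)}
    while len(chosen) < n:
        k = max(64, int((n - len(chosen)) * 1.5))
        ii = rng.integers(0, p, size=k)
        jj = rng.integers(0, p, size=k)
        for i, j in zip(ii, jj):
            if i == j or len(chosen) >= n:
                continue
            pair = _canonical_pair(proteins[int(i)], proteins[int(j)])
            if pair not in forbidden and pair not in chosen:
                chosen.add(pair)
    return chosen


@dataclass
class FoldSplit:
    """One cross-validation fold: edge-disjoint positives plus sampled
    negatives, sized 1:1 with the corresponding positive sets."""

    fold_id: int
    test_positives: set[TypedEdge]
    train_positives: set[TypedEdge]
    test_negatives: set[Pair]
    train_negatives: set[Pair]


def make_folds(
    positives: Iterable[TypedEdge],
    k: int = 5,
    *,
    net: HeteroNetwork,
    seed: int = 0,
) -> list[FoldSplit]:
    """Split the positive PPIs into ``k`` near-equal test sets and attach
    per-fold negatives.

    The test sets partition the positives with sizes differing by at most
    one.  Negatives are sampled fresh per fold from the non-PPI complement,
    with the train negatives disjoint from that fold's test negatives.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    positives = sorted(positives, key=lambda e: (e.u, e.v))
    if len(positives) < k:
        raise ValueError(f"need at least k={k} positives, got {len(positives)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    chunks = np.array_split(order, k)
    folds = []
    for fold_id, chunk in enumerate(chunks):
        test_pos = {positives[i] for i in chunk}
        train_pos = set(positives) - test_pos
        test_neg = sample_negatives(net, len(test_pos), seed=rng)
        train_neg = sample_negatives(net, len(train_pos), exclude=test_neg, seed=rng)
        folds.append(FoldSplit(fold_id, test_pos, train_pos, test_neg, train_neg))
    return folds


# ---------------------------------------------------------------------------
# classifiers


def fit_classifier(X: np.ndarray, y: np.ndarray, kind: str = "RF", seed: int = 0):
    """Fit one of the supported classifiers; RF with library defaults is the
    reference model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if kind == "RF":
        model = RandomForestClassifier(random_state=seed)
    elif kind == "SVM":
        model = SVC(probability=True, random_state=seed)
    elif kind == "LR":
        model = LogisticRegression(max_iter=1000, random_state=seed)
    elif kind == "NB":
        model = GaussianNB()
    elif kind == "AdaBoost":
        model = AdaBoostClassifier(random_state=seed)
    elif kind == "XGBoost":
        from xgboost import XGBClassifier  # optional dependency

        model = XGBClassifier(random_state=seed, eval_metric="logloss")
    else:
        raise ValueError(f"unknown classifier {kind!r}; expected one of {CLASSIFIERS}")
    model.fit(X, y)
    return model


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Probability of the positive (interacting) class, in [0, 1]."""
    return model.predict_proba(np.asarray(X, dtype=float))[:, 1]


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


METRIC_NAMES = ("acc", "sen", "pre", "auc", "aupr")


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    as_printed: bool = False,
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Confusion counts at ``threshold`` plus Acc/Sen/Pre/AUC/AUPR.

    Acc = (TP+TN)/total and Pre = TP/(TP+FP).  Sensitivity is the standard
    recall TP/(TP+FN); ``as_printed=True`` instead evaluates the literal
    TP/(TN+TP) variant for audit (see docs/methods.md on this formula).
    AUC uses the rank (Mann-Whitney) formulation and AUPR the
    precision-recall step integral; both require both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    cc = ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )
    metrics: dict[str, float] = {}
    metrics["acc"] = (cc.TP + cc.TN) / cc.total if cc.total else float("nan")
    sen_den = (cc.TN + cc.TP) if as_printed else (cc.TP + cc.FN)
    metrics["sen"] = cc.TP / sen_den if sen_den else float("nan")
    metrics["pre"] = cc.TP / (cc.TP + cc.FP) if (cc.TP + cc.FP) else float("nan")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC/AUPR undefined with a single label class")
    metrics["auc"] = float(roc_auc_score(labels, scores))
    metrics["aupr"] = float(average_precision_score(labels, scores))
    return cc, metrics


@dataclass
class MetricsReport:
    """Per-fold metrics, their mean and standard deviation, and (optionally)
    the raw fold scores for curve plotting or recalibration."""

    folds: list[dict[str, float]]
    fold_predictions: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def overall(self) -> dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.folds])) for m in METRIC_NAMES}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(np.std([f[m] for f in self.folds])) for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=str(f["fold"]), **{m: f[m] for m in METRIC_NAMES}) for f in self.folds]
        rows.append(dict(fold="overall", **self.overall))
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "overall": self.overall,
            "std": self.std,
        }


# ---------------------------------------------------------------------------
# optional trainable projection (one-layer link-prediction head)


def fit_projection(
    features: Mapping[NodeRef, np.ndarray],
    pairs: Sequence[Pair],
    labels: Sequence[int],
    out_dim: int,
    *,
    activation: str = "sigmoid",
    learning_rate: float = 0.05,
    epochs: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the aggregation projection (W, b) as the input layer of a
    logistic link-prediction head: each protein is mapped to
    sigma(W x + b) and a pair is scored by the dot product of its two
    projected vectors, trained with logistic loss on the given pairs.
    Off by default; the identity pass-through is the reference behaviour.
    """
    rng = np.random.default_rng(seed)
    act = _activation(activation)
    nodes = sorted({n for p in pairs for n in p})
    X = np.stack([features[n] for n in nodes])
    idx = {n: i for i, n in enumerate(nodes)}
    a_idx = np.array([idx[a] for a, _ in pairs])
    b_idx = np.array([idx[b] for _, b in pairs])
    y = np.asarray(labels, dtype=float)
    in_dim = X.shape[1]
    W = (rng.random((out_dim, in_dim)) - 0.5) / in_dim
    b = np.zeros(out_dim)
    for _ in range(epochs):
        Z = X @ W.T + b  # (n, out)
        H = act(Z)
        s = np.einsum("nd,nd->n", H[a_idx], H[b_idx])
        p = 1.0 / (1.0 + np.exp(-s))
        g_s = p - y  # dLoss/ds
        gH = np.zeros_like(H)
        np.add.at(gH, a_idx, g_s[:, None] * H[b_idx])
        np.add.at(gH, b_idx, g_s[:, None] * H[a_idx])
        gZ = gH * (H * (1 - H) if activation == "sigmoid" else (Z > 0) if activation == "relu" else 1.0)
        W -= learning_rate * (gZ.T @ X) / len(pairs)
        b -= learning_rate * gZ.mean(axis=0)
    return W, b


# ---------------------------------------------------------------------------
# cross-validation


def _derive_seed(seed: int, offset: int) -> int:
    return (seed * 9973 + offset) % (2**31 - 1)


def cross_validate(
    net: HeteroNetwork,
    sequences: Iterable[SequenceRecord],
    *,
    line_cfg: LineConfig | None = None,
    agg_cfg: AggregationConfig | None = None,
    classifier: str = "RF",
    features: str = "both",
    pair_mode: str = "ordered_concat",
    k: int = 5,
    seed: int = 0,
    as_printed: bool = False,
    keep_predictions: bool = True,
) -> MetricsReport:
    """Leakage-controlled k-fold evaluation of the PPI predictor.

    Per fold: the test-fold PPIs are removed from the network, the LINE
    embedder is retrained on the remainder, protein representations are
    assembled (``features`` selects 'inter', 'intra' or 'both'), a
    classifier is fit on train positives+negatives and scored on the
    held-out pairs.  The report carries the five fold rows plus their mean
    and standard deviation.
    """
    if features not in ("inter", "intra", "both"):
        raise ValueError(f"features must be 'inter', 'intra' or 'both', got {features!r}")
    line_cfg = line_cfg or LineConfig()
    agg_cfg = agg_cfg or AggregationConfig()
    positives = net.ppi_edges()
    if not positives:
        raise ValueError("network contains no protein-protein edges")
    proteins = net.proteins()

    inter: dict[NodeRef, np.ndarray] = {}
    if features in ("inter", "both"):
        by_id = {}
        for rec in sequences:
            by_id[rec.protein_id] = rec
        missing = 0
        for prot in proteins:
            if prot.id in by_id:
                inter[prot] = kmer_vector(by_id[prot.id])
            else:
                inter[prot] = np.zeros(KMER_DIM)
                missing += 1
        if missing:
            logger.warning("%d proteins missing from FASTA: all-zero inter-view vectors", missing)

    folds = make_folds(positives, k, net=net, seed=_derive_seed(seed, 1))
    fold_rows: list[dict[str, float]] = []
    predictions: list[tuple[np.ndarray, np.ndarray]] = []
    for fold in folds:
        train_net = remove_edges(net, fold.test_positives)
        # leakage guard: no test PPI survives in the embedding network
        assert not (fold.test_positives & train_net.edges)

        if features in ("intra", "both"):
            fold_line_cfg = replace(line_cfg, seed=_derive_seed(seed, 100 + fold.fold_id))
            first, second = train_line(train_net, fold_line_cfg)
            intra = intra_view_features(first, second, proteins)
        else:
            intra = {}

        def represent(prot: NodeRef) -> np.ndarray:
            if features == "inter":
                return inter[prot]
            if features == "intra":
                return intra[prot]
            return aggregate(inter[prot], intra[prot], agg_cfg)

        reps = {prot: represent(prot) for prot in proteins}

        def assemble(pos_edges: set[TypedEdge], neg_pairs: set[Pair]):
            pairs = [ _canonical_pair(e.u, e.v) for e in sorted(pos_edges, key=lambda e: (e.u, e.v)) ]
            pairs += sorted(neg_pairs)
            y = np.array([1] * len(pos_edges) + [0] * len(neg_pairs))
            X = np.stack([pair_feature(reps[a], reps[b], pair_mode) for a, b in pairs])
            return pairs, X, y

        train_pairs, X_train, y_train = assemble(fold.train_positives, fold.train_negatives)
        test_pairs, X_test, y_test = assemble(fold.test_positives, fold.test_negatives)
        # leakage guard: train and test pair sets are disjoint
        assert not (set(train_pairs) & set(test_pairs))

        model = fit_classifier(X_train, y_train, classifier, seed=_derive_seed(seed, 200 + fold.fold_id))
        scores = predict_scores(model, X_test)
        _, metrics = compute_metrics(scores, y_test, as_printed=as_printed)
        fold_rows.append({"fold": fold.fold_id, **metrics})
        if keep_predictions:
            predictions.append((scores, y_test))
        logger.info("fold %d: %s", fold.fold_id, {m: round(metrics[m], 4) for m in METRIC_NAMES})
    return MetricsReport(fold_rows, predictions)
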