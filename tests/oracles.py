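"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (dictionaries, explicit loops,
full-batch gradient descent) kept separate from the package code paths
they are used to check.
"""

from __future__ import annotations

import numpy as np

from hetppi.inter_view import REDUCED_ALPHABET


def kmer_oracle(seq: str) -> np.ndarray:
    """Count 3-mer windows into a dict keyed by the literal triplet string."""
    groups = ["0123"[REDUCED_ALPHABET[c]] if c in REDUCED_ALPHABET else "?" for c in seq.upper()]
    counts: dict[str, int] = {}
    n = 0
    for i in range(len(groups) - 2):
        triplet = "".join(groups[i : i + 3])
        if "?" in triplet:
            continue
        counts[triplet] = counts.get(triplet, 0) + 1
        n += 1
    vec = np.zeros(64)
    for triplet, c in counts.items():
        idx = int(triplet, base=4)
        vec[idx] = c / n
    return vec


def confusion_oracle(scores, labels, threshold=0.5):
    tp = tn = fp = fn = 0
    for s, y in zip(scores, labels):
        if s >= threshold and y == 1:
            tp += 1
        elif s >= threshold and y == 0:
            fp += 1
        elif s < threshold and y == 1:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def auc_oracle(scores, labels) -> float:
    """AUC by explicit concordant-pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                concordant += 1
            elif p == q:
                concordant += 0.5
    return concordant / total


def aupr_oracle(scores, labels) -> float:
    """Average precision by the precision-recall step sum."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    ap = 0.0
    tp = 0
    for rank, y in enumerate(labels, start=1):
        if y == 1:
            tp += 1
            ap += (tp / rank) / n_pos
    return ap


def exact_softmax_second_order(
    adjacency: dict[int, set[int]], n: int, dim: int, seed: int,
    lr: float = 0.5, iters: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch gradient ascent on the exact softmax second-order
    objective sum over directed edges (i -> j) of log P(j | i), with
    P(j | i) = exp(c_j . v_i) / sum_k exp(c_k . v_i)."""
    rng = np.random.default_rng(seed)
    V = (rng.random((n, dim)) - 0.5) / dim
    C = (rng.random((n, dim)) - 0.5) / dim
    edges = [(i, j) for i in adjacency for j in adjacency[i]]
    for _ in range(iters):
        gV = np.zeros_like(V)
        gC = np.zeros_like(C)
        for i, j in edges:
            logits = C @ V[i]
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            gV[i] += C[j] - p @ C
            gC += np.outer(-p, V[i])
            gC[j] += V[i]
        V += lr * gV / len(edges)
        C += lr * gC / len(edges)
    return V, C
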