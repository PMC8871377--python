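"""Independent brute-force oracles used to validate the implementation.

Everything here is written in the most literal way possible (python loops
over explicit definitions) and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_k_distance(o, refs, k: int) -> float:
    """k-th smallest distance from o to the reference points (full sort)."""
    return sorted(dist(o, r) for r in refs)[k - 1]


def brute_neighborhood(o, refs, k: int) -> list[int]:
    """Indices of all reference points within the k-distance (ties included)."""
    kd = brute_k_distance(o, refs, k)
    return [i for i, r in enumerate(refs) if dist(o, r) <= kd]


def brute_reach_dist(p, o_idx: int, refs, k: int) -> float:
    """max{k-distance(o), d(p, o)} with o's own k-distance leave-self-out."""
    others = [r for i, r in enumerate(refs) if i != o_idx]
    return max(brute_k_distance(refs[o_idx], others, k), dist(p, refs[o_idx]))


def brute_lrd(p, refs, k: int, exclude: int | None = None) -> float:
    """Local reachability density of an external point p (or refs[exclude] itself)."""
    cand = [(i, r) for i, r in enumerate(refs) if i != exclude]
    kd = sorted(dist(p, r) for _, r in cand)[k - 1]
    nb = [i for i, r in cand if dist(p, r) <= kd]
    total = sum(brute_reach_dist(p, i, refs, k) for i in nb)
    return math.inf if total == 0 else len(nb) / total


def brute_lof(p, refs, k: int, exclude: int | None = None) -> float:
    """LOF of p against refs; sentinel rules inf/inf = 1, finite/inf = 0."""
    cand = [(i, r) for i, r in enumerate(refs) if i != exclude]
    kd = sorted(dist(p, r) for _, r in cand)[k - 1]
    nb = [i for i, r in cand if dist(p, r) <= kd]
    lrd_p = brute_lrd(p, refs, k, exclude=exclude)
    ratios = []
    for i in nb:
        lrd_o = brute_lrd(refs[i], refs, k, exclude=i)
        if math.isinf(lrd_p):
            ratios.append(1.0 if math.isinf(lrd_o) else 0.0)
        elif math.isinf(lrd_o):
            ratios.append(math.inf)
        else:
            ratios.append(lrd_o / lrd_p)
    return float(np.mean(ratios))


def brute_fit_scores(refs, k: int) -> list[float]:
    """Leave-self-out LOF score of every reference point."""
    return [brute_lof(refs[i], refs, k, exclude=i) for i in range(len(refs))]


def pair_count_auc(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly (ties = 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def softmax_loss_by_hand(features, labels, W, b) -> float:
    """Mean -log p(true class) evaluated term by term with explicit exps."""
    total = 0.0
    for f, y in zip(features, labels):
        logits = [sum(fi * W[i][j] for i, fi in enumerate(f)) + b[j] for j in range(len(b))]
        denom = sum(math.exp(z) for z in logits)
        total += -math.log(math.exp(logits[y]) / denom)
    return total / len(labels)
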