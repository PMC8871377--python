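"""Local Outlier Factor, implemented from first principles.

LOF compares the local density of a point with the local densities of its
neighbors.  Writing ``k-distance(o)`` for the distance from ``o`` to its
k-th nearest neighbor and ``N_k(p)`` for the k-distance neighborhood
(every reference point within ``k-distance(p)`` — ties included, so
``|N_k| >= k``):

    reach-dist_k(p, o) = max{ k-distance(o), d(p, o) }
    lrd_k(p)           = |N_k(p)| / sum_{o in N_k(p)} reach-dist_k(p, o)
    LOF_k(p)           = mean_{o in N_k(p)}  lrd_k(o) / lrd_k(p)

Scores near 1 mean the point sits at the same density as its neighbors;
scores well above 1 mark outliers.  Two modes are provided: *fit* mode
scores each reference point against the others (leave-self-out), and
*novelty* mode scores external queries against a fixed reference set —
the detector's Stage 2, where the reference set is the normal-image
feature population and any query scoring above the threshold is called
AMD.

Degenerate duplicate clusters (all reachability distances zero) get the
conventional sentinel ``lrd = +inf``, with ratio arithmetic
``inf/inf := 1`` and ``finite/inf := 0``.

Neighbor search is exact (full pairwise distances): reference sets here
are at most tens of thousands of points and exactness is what the
oracle-equivalence guarantees rest on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .data import BinaryLabel


@dataclass
class ReferenceFeatureSet:
    """The reference population LOF scores against (rows = feature vectors)."""

    points: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("reference features must all be finite")
        if self.metric not in ("euclidean", "cosine"):
            raise ValueError("metric must be 'euclidean' or 'cosine'")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class LOFParams:
    """k-neighborhood size and decision threshold.

    ``threshold`` is either a fixed positive float or the string ``"auto"``,
    in which case tau is calibrated as the ``quantile``-th quantile of LOF
    scores of normal calibration points (see :func:`calibrate_threshold`).
    """

    k: int = 20
    threshold: Union[float, str] = "auto"
    quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ValueError("threshold must be a positive float or 'auto'")
        elif self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("quantile must lie in (0, 1]")


@dataclass
class LOFResult:
    score: float
    decision: BinaryLabel
    neighborhood_size: int


def _distances(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    return cdist(np.atleast_2d(a), np.atleast_2d(b), metric=metric)


def _check_k(k: int, available: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if available < k:
        raise ValueError(f"k={k} needs at least k reference neighbors, have {available}")


# ---------------------------------------------------------------------------
# elementary quantities on one query point (novelty semantics: the query is
# never a member of the reference set; fit mode passes the set minus self)
# ---------------------------------------------------------------------------

def k_distance(o: np.ndarray, refs: ReferenceFeatureSet, k: int) -> float:
    """Distance from ``o`` to its k-th nearest reference point."""
    _check_k(k, refs.n)
    d = _distances(o, refs.points, refs.metric)[0]
    return float(np.sort(d)[k - 1])


def k_neighborhood(o: np.ndarray, refs: ReferenceFeatureSet, k: int) -> np.ndarray:
    """Indices of all reference points within ``k_distance(o)`` (ties included)."""
    _check_k(k, refs.n)
    d = _distances(o, refs.points, refs.metric)[0]
    kd = np.sort(d)[k - 1]
    return np.flatnonzero(d <= kd)


def reach_dist(p: np.ndarray, o_index: int, refs: ReferenceFeatureSet, k: int) -> float:
    """max{k-distance(o), d(p, o)} for reference member ``o`` (leave-self-out k-distance)."""
    o = refs.points[o_index]
    others = ReferenceFeatureSet(np.delete(refs.points, o_index, axis=0), refs.metric)
    kd_o = k_distance(o, others, k)
    d_po = float(_distances(p, o, refs.metric)[0, 0])
    return max(kd_o, d_po)


def lrd(p: np.ndarray, refs: ReferenceFeatureSet, k: int) -> float:
    """Local reachability density of an external point ``p``; +inf for duplicates."""
    lof_obj = LOF(k=k, metric=refs.metric).fit(refs.points)
    return float(lof_obj._query_lrd(np.atleast_2d(p))[0][0])


def lof_score(p: np.ndarray, refs: ReferenceFeatureSet, k: int) -> float:
    """LOF of an external point ``p`` against the reference set."""
    lof_obj = LOF(k=k, metric=refs.metric).fit(refs.points)
    return float(lof_obj.score_samples(np.atleast_2d(p))[0])


# ---------------------------------------------------------------------------
# batch engine
# ---------------------------------------------------------------------------

def _lrd_from(reach: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """lrd = |N| / sum(reach); 0/0-style duplicate clusters map to +inf."""
    with np.errstate(divide="ignore"):
        return np.where(reach > 0, counts / np.where(reach > 0, reach, 1.0), np.inf)


def _ratio_mean(lrd_neighbors: np.ndarray, lrd_self: float) -> float:
    """Mean of lrd(o)/lrd(p) under the sentinel rules inf/inf=1, finite/inf=0."""
    if np.isinf(lrd_self):
        ratios = np.where(np.isinf(lrd_neighbors), 1.0, 0.0)
    else:
        ratios = lrd_neighbors / lrd_self
    return float(np.mean(ratios))


class LOF:
    """Exact LOF in fit and novelty modes.

    ``fit(X)`` precomputes, for every reference point (with itself
    excluded from its own candidate neighbors), its k-distance,
    neighborhood and lrd.  ``score_samples(Q)`` then scores external
    queries without ever inserting them into the reference set;
    ``fit_scores()`` returns the leave-self-out LOF of each reference
    point, used for threshold calibration and the symmetry properties.
    """

    def __init__(self, k: int = 20, metric: str = "euclidean"):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.metric = metric

    def fit(self, X: np.ndarray) -> "LOF":
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[0] < self.k + 1:
            raise ValueError(
                f"reference set needs at least k+1 = {self.k + 1} points, have {X.shape[0]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("reference features must all be finite")
        self.X = X
        n = X.shape[0]
        D = _distances(X, X, self.metric)
        np.fill_diagonal(D, np.inf)  # leave-self-out
        D_sorted = np.sort(D, axis=1)
        self.kdist = D_sorted[:, self.k - 1]
        self.neighborhoods = [np.flatnonzero(D[i] <= self.kdist[i]) for i in range(n)]
        reach_sums = np.empty(n)
        counts = np.empty(n)
        for i, nb in enumerate(self.neighborhoods):
            reach = np.maximum(self.kdist[nb], D[i, nb])
            reach_sums[i] = reach.sum()
            counts[i] = len(nb)
        self.ref_lrd = _lrd_from(reach_sums, counts)
        self._fit_scores: np.ndarray | None = None
        return self

    # -- fit mode --------------------------------------------------------
    def fit_scores(self) -> np.ndarray:
        """Leave-self-out LOF score of every reference point."""
        if self._fit_scores is None:
            scores = np.empty(self.X.shape[0])
            for i, nb in enumerate(self.neighborhoods):
                scores[i] = _ratio_mean(self.ref_lrd[nb], self.ref_lrd[i])
            self._fit_scores = scores
        return self._fit_scores

    # -- novelty mode ----------------------------------------------------
    def _query_lrd(self, Q: np.ndarray):
        Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
        if Q.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"query dimension {Q.shape[1]} does not match reference {self.X.shape[1]}"
            )
        D = _distances(Q, self.X, self.metric)
        kd = np.sort(D, axis=1)[:, self.k - 1]
        lrds, neighborhoods = [], []
        for i in range(Q.shape[0]):
            nb = np.flatnonzero(D[i] <= kd[i])
            reach = np.maximum(self.kdist[nb], D[i, nb])
            s = reach.sum()
            lrds.append(np.inf if s == 0 else len(nb) / s)
            neighborhoods.append(nb)
        return np.array(lrds), neighborhoods

    def score_samples(self, Q: np.ndarray) -> np.ndarray:
        """LOF score per query, each scored independently against the references."""
        lrd_q, neighborhoods = self._query_lrd(Q)
        return np.array(
            [_ratio_mean(self.ref_lrd[nb], lq) for lq, nb in zip(lrd_q, neighborhoods)]
        )

    def neighborhood_sizes(self, Q: np.ndarray) -> np.ndarray:
        _, neighborhoods = self._query_lrd(Q)
        return np.array([len(nb) for nb in neighborhoods])


def calibrate_threshold(
    refs: ReferenceFeatureSet,
    params: LOFParams,
    calibration_scores: np.ndarray | None = None,
) -> float:
    """Resolve the decision threshold tau.

    A numeric ``params.threshold`` is returned as-is.  With ``"auto"``,
    tau is the ``params.quantile`` quantile of normal-population LOF
    scores: by default the reference set's own leave-self-out fit-mode
    scores, or, when provided, novelty-mode scores of held-out normal
    points (``calibration_scores``).
    """
    if not isinstance(params.threshold, str):
        return float(params.threshold)
    if calibration_scores is not None and len(calibration_scores) > 0:
        scores = np.asarray(calibration_scores, dtype=np.float64)
    else:
        scores = LOF(k=params.k, metric=refs.metric).fit(refs.points).fit_scores()
    finite = scores[np.isfinite(scores)]
    if len(finite) == 0:
        return 1.0
    return float(np.quantile(finite, params.quantile))


def score_queries(
    queries: np.ndarray,
    refs: ReferenceFeatureSet,
    params: LOFParams = LOFParams(),
    threshold: float | None = None,
) -> list[LOFResult]:
    """Score external queries and classify each as NORMAL or AMD.

    Queries are scored independently (novelty mode — a query never joins
    the reference set), so the batch result does not depend on query
    order.  ``decision`` is AMD iff the score exceeds tau.
    """
    if params.k >= refs.n:
        raise ValueError(f"k={params.k} must be smaller than the reference size {refs.n}")
    tau = calibrate_threshold(refs, params) if threshold is None else float(threshold)
    model = LOF(k=params.k, metric=refs.metric).fit(refs.points)
    Q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    lrd_q, neighborhoods = model._query_lrd(Q)
    results = []
    for lq, nb in zip(lrd_q, neighborhoods):
        s = _ratio_mean(model.ref_lrd[nb], lq)
        decision = BinaryLabel.AMD if s > tau else BinaryLabel.NORMAL
        results.append(LOFResult(score=float(s), decision=decision, neighborhood_size=len(nb)))
    return results
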