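"""The two scoring engines and the overall dispatch rule.

Network method — *inclined potential*.  For a query protein Q in a
weighted PPI network, the potential of Q toward category mu is the sum of
the edge confidence weights from Q to its annotated neighbours that carry
mu:

    p_mu(Q) = sum_i w(Q, P_i) * [mu in functions(P_i)]

Guilt by association: the more confidently Q interacts with proteins of a
given function, the more likely Q performs that function itself.  The 24
scores are then arranged in descending order to give the 1st-order,
2nd-order, ... predictions.

Sequence method — hybrid-property nearest neighbour.  Candidate proteins
are compared by the cosine similarity of their 132-feature descriptors;
category mu scores the best similarity among training proteins that carry
mu (or, configurably, the sum of similarities over all carriers).

Dispatch: a query that is a network node with at least one annotated
neighbour is scored by the network method; otherwise, if a feature vector
is available, by the hybrid method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ProtfunError, UnpredictableError

__all__ = [
    "PotentialProfile",
    "rank_functions",
    "inclined_potential",
    "cosine_similarity",
    "hybrid_potential",
    "predict_overall",
]


@dataclass
class PotentialProfile:
    """Per-category scores plus their descending ranking.

    ``scores[i]`` is the potential toward category ``i + 1``; ``ranking``
    is a permutation of 1..n_categories sorted by non-increasing score.
    ``tie_groups`` lists the categories involved in each tied score (only
    groups of size >= 2).  A profile built from no evidence at all (an
    isolated node, or a training set carrying no categories) is flagged
    ``unpredictable``.
    """

    scores: np.ndarray
    ranking: tuple[int, ...]
    tie_groups: tuple[tuple[int, ...], ...] = ()
    unpredictable: bool = False
    method: Optional[str] = None
    query: Optional[str] = None

    def score(self, category: int) -> float:
        return float(self.scores[category - 1])

    def top(self, k: int = 1) -> tuple[int, ...]:
        return self.ranking[:k]


def rank_functions(scores: Union[np.ndarray, list], tie: str = "index",
                   rng: Optional[np.random.Generator] = None,
                   unpredictable: Optional[bool] = None,
                   method: Optional[str] = None,
                   query: Optional[str] = None) -> PotentialProfile:
    """Arrange category scores in descending order.

    Ties are broken by ascending category index (``tie="index"``, the
    deterministic default) or shuffled within each tied group by a seeded
    generator (``tie="random"``), mirroring random assignment of equal
    scores.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    order = sorted(range(1, n + 1), key=lambda c: (-scores[c - 1], c))
    tie_groups = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1] - 1] == scores[order[i] - 1]:
            j += 1
        if j > i:
            tie_groups.append(tuple(order[i:j + 1]))
        i = j + 1
    if tie == "random":
        if rng is None:
            raise ValueError("tie='random' requires a seeded rng")
        order_arr = np.array(order)
        pos = {c: k for k, c in enumerate(order)}
        for grp in tie_groups:
            idx = np.array([pos[c] for c in grp])
            order_arr[idx] = rng.permutation(list(grp))
        order = list(order_arr)
    elif tie != "index":
        raise ValueError(f"unknown tie rule {tie!r}")
    if unpredictable is None:
        unpredictable = not np.any(scores != 0)
    return PotentialProfile(
        scores=scores,
        ranking=tuple(int(c) for c in order),
        tie_groups=tuple(tie_groups),
        unpredictable=unpredictable,
        method=method,
        query=query,
    )


def inclined_potential(query: str, net: nx.Graph,
                       ann: Mapping[str, frozenset],
                       n_categories: int = 24,
                       tie: str = "index",
                       rng: Optional[np.random.Generator] = None) -> PotentialProfile:
    """Score a network node against every category by summed edge weights.

    The query's own annotations are never consulted (there is no
    self-interaction, and during jackknifing they are the very thing
    being predicted); neighbours absent from ``ann`` contribute nothing.
    An all-zero profile (no annotated neighbour) is flagged unpredictable.
    """
    if query not in net:
        raise KeyError(f"query {query!r} is not a node of the network")
    scores = np.zeros(n_categories)
    for nbr in net.neighbors(query):
        if nbr == query or nbr not in ann:
            continue
        w = net[query][nbr]["weight"]
        for mu in ann[nbr]:
            scores[mu - 1] += w
    return rank_functions(scores, tie=tie, rng=rng, method="network", query=query)


def cosine_similarity(u: Union[pd.Series, np.ndarray],
                      v: Union[pd.Series, np.ndarray]) -> float:
    """Cosine of the angle between two feature vectors.

    For the nonnegative percent-valued hybrid descriptors this lies in
    [0, 1]; general vectors may score negative.
    """
    if isinstance(u, pd.Series) and isinstance(v, pd.Series):
        if not u.index.equals(v.index):
            raise ProtfunError("feature vectors have mismatched names/order")
    ua, va = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ProtfunError(f"shape mismatch {ua.shape} vs {va.shape}")
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("cosine similarity undefined for zero vectors")
    return float(ua @ va / (nu * nv))


def _similarities(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(query)
    if qn == 0:
        raise DegenerateInputError("zero-norm query vector")
    norms = np.linalg.norm(matrix, axis=1)
    sims = np.zeros(len(matrix))
    ok = norms > 0
    sims[ok] = matrix[ok] @ query / (norms[ok] * qn)
    return sims


def hybrid_potential(query: Union[pd.Series, np.ndarray],
                     training: pd.DataFrame,
                     ann: Mapping[str, frozenset],
                     n_categories: int = 24,
                     agg: str = "max",
                     tie: str = "index",
                     rng: Optional[np.random.Generator] = None,
                     query_id: Optional[str] = None) -> PotentialProfile:
    """Score a feature vector against every category by nearest-neighbour
    cosine similarity to annotated training proteins.

    ``agg="max"`` (default) scores category mu by the best similarity
    among training proteins carrying mu; ``agg="sum"`` accumulates
    similarity over all carriers.  Categories carried by no training
    protein score 0.
    """
    if len(training) == 0:
        raise ProtfunError("empty training set")
    if agg not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    if isinstance(query, pd.Series) and not query.index.equals(training.columns):
        raise ProtfunError("query feature names do not match the training matrix")
    sims = _similarities(np.asarray(query, dtype=float),
                         training.to_numpy(dtype=float))
    carriers: dict[int, list[int]] = {}
    for i, pid in enumerate(training.index):
        for mu in ann.get(pid, ()):
            carriers.setdefault(mu, []).append(i)
    scores = np.zeros(n_categories)
    for mu, idx in carriers.items():
        s = sims[idx]
        scores[mu - 1] = s.max() if agg == "max" else s.sum()
    return rank_functions(
        scores, tie=tie, rng=rng, unpredictable=not carriers,
        method="hybrid", query=query_id,
    )


def predict_overall(query: str, net: Optional[nx.Graph],
                    ann: Mapping[str, frozenset],
                    features: Optional[pd.DataFrame] = None,
                    query_vector: Optional[pd.Series] = None,
                    n_categories: int = 24,
                    agg: str = "max",
                    tie: str = "index",
                    rng: Optional[np.random.Generator] = None) -> PotentialProfile:
    """Dispatch a query to the network or the hybrid method.

    The network method is used when the query is a network node with at
    least one annotated neighbour; otherwise the hybrid method runs on
    ``query_vector`` (or the query's row of ``features``) against the
    remaining feature rows.  A query resolvable by neither raises
    :class:`UnpredictableError`.
    """
    if net is not None and query in net:
        has_evidence = any(
            nbr in ann and nbr != query for nbr in net.neighbors(query)
        )
        if has_evidence:
            return inclined_potential(query, net, ann, n_categories, tie, rng)
    vec = query_vector
    train = features
    if vec is None and features is not None and query in features.index:
        vec = features.loc[query]
        train = features.drop(index=query)
    if vec is not None and train is not None and len(train):
        train = train.loc[[pid for pid in train.index if pid != query]]
        return hybrid_potential(
            vec, train, ann, n_categories, agg=agg, tie=tie, rng=rng,
            query_id=query,
        )
    raise UnpredictableError(
        f"query {query!r} has no annotated network neighbourhood and no "
        "feature vector; cannot predict"
    )
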