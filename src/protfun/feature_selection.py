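"""Mutual information, mRMR ranking, and incremental feature selection.

mRMR (minimum redundancy, maximum relevance) greedily orders features so
that each newly selected feature has high mutual information (MI) with
the prediction targets and low MI with the features selected before it:

    score(f) = D(f) - R(f),   D(f) = relevance,  R(f) = mean MI with
                                                  already-selected features

For multi-label targets the relevance of a feature is defined here as the
*mean* MI between the feature and each binary category indicator (a
``max`` alternative is available); this reduces to plain single-target
relevance when there is one label column.  MI is the empirical plug-in
estimate in natural log units, computed on discretized (default
equal-frequency 3-bin) feature codes.

Incremental feature selection (IFS) then evaluates the nested prefixes
S_1 c S_2 c ... of the mRMR order with a leave-one-out jackknife of the
nearest-neighbour predictor and picks the smallest prefix whose
first-order accuracy attains the curve's maximum (the apogee).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .errors import ProtfunError
from .evaluate import jackknife_hybrid

__all__ = [
    "DiscretizedMatrix",
    "RankedFeatures",
    "IFSCurve",
    "discretize",
    "label_matrix",
    "mutual_information",
    "mrmr_rank",
    "ifs_select",
]


@dataclass
class DiscretizedMatrix:
    """Integer state codes per feature plus the bin edges that made them."""

    states: pd.DataFrame            # proteins x features, small ints
    edges: dict[str, np.ndarray]    # feature -> interior bin edges

    @property
    def features(self) -> list[str]:
        return list(self.states.columns)


def discretize(features: pd.DataFrame, n_bins: int = 3) -> DiscretizedMatrix:
    """Equal-frequency binning of each feature column.

    Interior edges are the 1/n_bins quantiles of the column; duplicate
    edges collapse, so constant columns code to a single state and
    low-cardinality columns occupy fewer states.  Codes are re-labelled
    densely from 0.
    """
    if len(features) < 2:
        raise ProtfunError("need at least 2 rows to discretize")
    states = {}
    edges = {}
    qs = np.arange(1, n_bins) / n_bins
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        e = np.unique(np.quantile(x, qs))
        codes = np.searchsorted(e, x, side="left")
        # dense relabel: occupied states -> 0..k-1
        _, codes = np.unique(codes, return_inverse=True)
        states[col] = codes
        edges[col] = e
    return DiscretizedMatrix(
        states=pd.DataFrame(states, index=features.index), edges=edges
    )


def label_matrix(ann: Mapping[str, frozenset], ids: Sequence[str],
                 n_categories: int = 24) -> pd.DataFrame:
    """Binary protein x category indicator matrix aligned with ``ids``."""
    mat = np.zeros((len(ids), n_categories), dtype=int)
    for i, pid in enumerate(ids):
        for mu in ann.get(pid, ()):
            mat[i, mu - 1] = 1
    return pd.DataFrame(mat, index=list(ids),
                        columns=[f"cat{c}" for c in range(1, n_categories + 1)])


def mutual_information(x, y) -> float:
    """Empirical mutual information of two discrete vectors, in nats.

    Plug-in estimate over the joint frequency table; symmetric and
    nonnegative, 0 for independent or constant inputs.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ProtfunError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ProtfunError("empty vectors")
    return float(max(mutual_info_score(x, y), 0.0))


@dataclass
class RankedFeatures:
    """An mRMR selection order with its per-step diagnostics."""

    order: list[str]            # feature names, selection order
    relevance: np.ndarray       # D at the step each feature was selected
    redundancy: np.ndarray      # R at that step
    score: np.ndarray           # D - R at that step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.order) + 1),
            "feature": self.order,
            "relevance": self.relevance,
            "redundancy": self.redundancy,
            "score": self.score,
        }).set_index("rank")


def mrmr_rank(dm: DiscretizedMatrix, labels: pd.DataFrame,
              relevance: str = "mean") -> RankedFeatures:
    """Greedy mRMR ordering of all features.

    Relevance of a feature is the mean (or, with ``relevance="max"``,
    the maximum) MI between the feature and the binary label columns;
    redundancy is the mean MI with the already-selected features (0 in
    the first round, so the first pick maximizes relevance alone).  Ties
    break to the earlier column.
    """
    feats = dm.features
    if not feats:
        raise ProtfunError("no features to rank")
    if relevance not in ("mean", "max"):
        raise ValueError(f"unknown relevance mode {relevance!r}")
    X = {f: dm.states[f].to_numpy() for f in feats}
    lab_cols = [labels[c].to_numpy() for c in labels.columns]
    rel = {}
    for f in feats:
        mis = [mutual_information(X[f], y) for y in lab_cols]
        rel[f] = float(np.mean(mis)) if relevance == "mean" else float(np.max(mis))

    order: list[str] = []
    d_out, r_out, s_out = [], [], []
    remaining = list(feats)
    mi_sum = {f: 0.0 for f in feats}  # running sum of MI with selected
    while remaining:
        n_sel = len(order)
        best, best_score = None, -np.inf
        for f in remaining:  # order preserves column order -> tie to earlier
            red = mi_sum[f] / n_sel if n_sel else 0.0
            s = rel[f] - red
            if s > best_score:
                best, best_score = f, s
        red_best = mi_sum[best] / n_sel if n_sel else 0.0
        order.append(best)
        d_out.append(rel[best])
        r_out.append(red_best)
        s_out.append(best_score)
        remaining.remove(best)
        for f in remaining:
            mi_sum[f] += mutual_information(X[f], X[best])
    return RankedFeatures(
        order=order,
        relevance=np.array(d_out),
        redundancy=np.array(r_out),
        score=np.array(s_out),
    )


@dataclass
class IFSCurve:
    """First-order jackknife accuracy for each nested feature prefix."""

    sizes: np.ndarray       # prefix sizes 1..M
    accuracy: np.ndarray    # Lambda_1 percent per prefix
    optimum: int            # smallest prefix size attaining the maximum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_features": self.sizes, "lambda1_percent": self.accuracy}
        ).set_index("n_features")


def ifs_select(features: pd.DataFrame, ann: Mapping[str, frozenset],
               ranked: RankedFeatures, n_categories: int = 24,
               agg: str = "max", max_size: Optional[int] = None) -> IFSCurve:
    """Evaluate nested prefixes of an mRMR order and find the apogee.

    For each prefix S_i of the ranked features, proteins are recoded to
    the first i features and the leave-one-out nearest-neighbour
    jackknife is run; the optimum is the smallest i whose first-order
    accuracy Lambda_1 equals the curve's maximum.
    """
    missing = set(features.columns) - set(ranked.order)
    if missing:
        raise ProtfunError(f"ranking does not cover features {sorted(missing)[:5]}")
    m = len(ranked.order) if max_size is None else min(max_size, len(ranked.order))
    sizes = np.arange(1, m + 1)
    acc = np.empty(m)
    for i in sizes:
        report = jackknife_hybrid(
            features, ann, feature_subset=ranked.order[:i],
            n_categories=n_categories, agg=agg,
        )
        acc[i - 1] = report.lambda1
    optimum = int(sizes[int(np.argmax(acc))])  # argmax returns first max
    return IFSCurve(sizes=sizes, accuracy=acc, optimum=optimum)
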