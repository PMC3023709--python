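"""Jackknife harnesses and multi-order accuracy statistics.

Because proteins are multi-label, a single top-1 accuracy undersells a
ranked prediction.  Three statistics summarise a set of per-protein
category rankings against truth:

* **j-th order accuracy** ``Lambda_j = 100 * N_j / N`` — the percentage
  of proteins whose j-th ranked category is one of their true functions
  (j = 1..24).
* **mean function count** ``m_bar`` — the average true-function-set
  size; ``k = ceil(m_bar)`` is the natural prediction depth.
* **coverage** ``Phi(k)`` — the percentage of proteins whose *entire*
  truth set lies within their top-k ranked categories.

Both prediction methods are evaluated by leave-one-out jackknifing: the
network harness hides each node's annotations in turn (its edges remain,
since neighbours' predictions-by-association depend on them); the hybrid
harness holds each protein's vector out of the training matrix in turn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ProtfunError
from .predict import PotentialProfile, hybrid_potential, inclined_potential

__all__ = [
    "EvaluationReport",
    "order_accuracy",
    "mean_function_count",
    "coverage_probability",
    "aggregate_report",
    "jackknife_network",
    "jackknife_hybrid",
]


@dataclass
class EvaluationReport:
    """Aggregated multi-order jackknife statistics.

    ``lambdas[j-1]`` is Lambda_j in percent; ``n_correct[j-1]`` the raw
    count N_j.  ``unpredictable`` lists proteins whose profile carried no
    evidence; they stay in the denominator N and count as misses at every
    order.  ``detail`` holds one row per protein: method, top-k ranking,
    truth, first-order hit and coverage flags.
    """

    lambdas: np.ndarray
    n_total: int
    n_correct: np.ndarray
    mean_functions: float
    k: int
    coverage: float
    unpredictable: tuple[str, ...]
    detail: pd.DataFrame

    @property
    def lambda1(self) -> float:
        return float(self.lambdas[0])

    def lambda_(self, j: int) -> float:
        return float(self.lambdas[j - 1])

    def summary(self) -> str:
        lines = [
            f"N = {self.n_total}   mean functions = {self.mean_functions:.2f}"
            f"   k = {self.k}   Phi(k) = {self.coverage:.2f}%",
            f"unpredictable: {len(self.unpredictable)}",
        ]
        lines += [
            f"Lambda_{j:<2d} = {self.lambdas[j - 1]:6.2f}%"
            for j in range(1, len(self.lambdas) + 1)
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#N\t{self.n_total}\n")
            fh.write(f"#mean_functions\t{self.mean_functions:.6g}\n")
            fh.write(f"#k\t{self.k}\n")
            fh.write(f"#coverage_at_k\t{self.coverage:.6g}\n")
            fh.write(f"#unpredictable\t{len(self.unpredictable)}\n")
            fh.write("order\tlambda_percent\tn_correct\n")
            for j in range(1, len(self.lambdas) + 1):
                fh.write(f"{j}\t{self.lambdas[j - 1]:.6g}\t{self.n_correct[j - 1]}\n")


def order_accuracy(rankings: Mapping[str, Sequence[int]],
                   truth: Mapping[str, frozenset], j: int,
                   n_categories: int = 24) -> float:
    """Percent of proteins whose j-th ranked category is a true function."""
    if not 1 <= j <= n_categories:
        raise ProtfunError(f"order {j} outside 1..{n_categories}")
    if not rankings:
        raise ProtfunError("no rankings to evaluate")
    hits = sum(
        1 for pid, rank in rankings.items()
        if len(rank) >= j and rank[j - 1] in truth[pid]
    )
    return 100.0 * hits / len(rankings)


def mean_function_count(truth: Mapping[str, frozenset]) -> float:
    """Arithmetic mean of true function-set sizes."""
    if not truth:
        raise ProtfunError("empty annotation set")
    return sum(len(v) for v in truth.values()) / len(truth)


def coverage_probability(rankings: Mapping[str, Sequence[int]],
                         truth: Mapping[str, frozenset], k: int,
                         n_categories: int = 24) -> float:
    """Percent of proteins whose whole truth set is inside their top k."""
    if not 1 <= k <= n_categories:
        raise ProtfunError(f"k = {k} outside 1..{n_categories}")
    covered = sum(
        1 for pid, rank in rankings.items()
        if truth[pid] <= set(rank[:k])
    )
    return 100.0 * covered / len(rankings)


def aggregate_report(profiles: Mapping[str, PotentialProfile],
                     truth: Mapping[str, frozenset],
                     n_categories: int = 24) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from per-protein profiles.

    Unpredictable profiles (no evidence) count as misses at every order
    and are excluded from coverage credit, but remain in every
    denominator.
    """
    if not profiles:
        raise ProtfunError("no profiles to aggregate")
    n = len(profiles)
    n_correct = np.zeros(n_categories, dtype=int)
    unpredictable = tuple(sorted(
        pid for pid, prof in profiles.items() if prof.unpredictable
    ))
    eval_truth = {pid: truth[pid] for pid in profiles}
    m_bar = mean_function_count(eval_truth)
    k = math.ceil(m_bar)
    covered = 0
    rows = []
    for pid, prof in profiles.items():
        t = truth[pid]
        if not prof.unpredictable:
            for j, cat in enumerate(prof.ranking):
                if cat in t:
                    n_correct[j] += 1
            cov = t <= set(prof.ranking[:k])
            covered += cov
        else:
            cov = False
        rows.append({
            "protein": pid,
            "method": prof.method,
            "unpredictable": prof.unpredictable,
            "top_k": ",".join(str(c) for c in prof.ranking[:k]),
            "truth": ",".join(str(c) for c in sorted(t)),
            "first_order_hit": (not prof.unpredictable) and prof.ranking[0] in t,
            "covered_at_k": bool(cov),
        })
    return EvaluationReport(
        lambdas=100.0 * n_correct / n,
        n_total=n,
        n_correct=n_correct,
        mean_functions=m_bar,
        k=k,
        coverage=100.0 * covered / n,
        unpredictable=unpredictable,
        detail=pd.DataFrame(rows).set_index("protein"),
    )


def jackknife_network(net: nx.Graph, ann: Mapping[str, frozenset],
                      n_categories: int = 24, tie: str = "index",
                      rng: Optional[np.random.Generator] = None) -> EvaluationReport:
    """Leave-one-out evaluation of the inclined-potential scorer.

    Each annotated node is predicted with its own annotations hidden;
    its edges remain in place, since every neighbour's contribution is
    read from the neighbour's own labels.
    """
    profiles = {}
    for node in net.nodes:
        if node not in ann:
            continue
        held = {pid: cats for pid, cats in ann.items() if pid != node}
        profiles[node] = inclined_potential(
            node, net, held, n_categories, tie=tie, rng=rng
        )
    if not profiles:
        raise ProtfunError("no annotated nodes to jackknife")
    return aggregate_report(profiles, ann, n_categories)


def jackknife_hybrid(features: pd.DataFrame, ann: Mapping[str, frozenset],
                     feature_subset: Optional[Sequence[str]] = None,
                     n_categories: int = 24, agg: str = "max",
                     tie: str = "index",
                     rng: Optional[np.random.Generator] = None) -> EvaluationReport:
    """Leave-one-out evaluation of the hybrid nearest-neighbour scorer,
    optionally restricted to a feature subset (for incremental feature
    selection)."""
    if len(features) < 2:
        raise ProtfunError("need at least 2 proteins for a jackknife")
    mat = features[list(feature_subset)] if feature_subset is not None else features
    profiles = {}
    for pid in mat.index:
        if pid not in ann:
            continue
        train = mat.drop(index=pid)
        held = {q: cats for q, cats in ann.items() if q != pid}
        profiles[pid] = hybrid_potential(
            mat.loc[pid], train, held, n_categories, agg=agg, tie=tie,
            rng=rng, query_id=pid,
        )
    if not profiles:
        raise ProtfunError("no annotated proteins to jackknife")
    return aggregate_report(profiles, ann, n_categories)
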