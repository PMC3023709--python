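"""Seeded generators of annotated networks, feature tables and sequences.

The generators produce inputs carrying exactly the statistical structure
each prediction method assumes, so the whole pipeline can be exercised
and calibrated without any database downloads:

* ``generate_network`` — a weighted undirected interaction network whose
  edges preferentially join proteins sharing a function ("homophily"
  parameter h: h = 1 places edges only between function-sharing pairs,
  h = 0 places them uniformly at random), with STRING-like confidence
  weights.
* ``generate_feature_table`` — a feature matrix with planted informative
  features (label-conditional mean shifts of a configurable effect
  size), redundant features (noisy copies of informative ones) and pure
  noise features.
* ``generate_sequences`` — random canonical protein sequences with a
  configurable hydrophobic composition bias, plus optional consistent
  synthetic residue annotations.

Every generator is a pure function of its :class:`SyntheticConfig`,
including the seed.  Multi-label function sets are drawn as independent
per-category Bernoulli indicators calibrated so the mean set size equals
``label_rate`` (empty sets are redrawn), reflecting that most proteins
perform more than one function.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .alphabets import fallback_residue_annotation
from .errors import ValidationError
from .io import CANONICAL_AA, ProteinRecord

__all__ = ["SyntheticConfig", "generate_network", "generate_feature_table",
           "generate_sequences"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the three generators.

    Defaults mirror a mid-size curated PPI/annotation corpus: 24
    functional categories with a mean of 3.14 functions per protein,
    STRING-style confidence scores in 150-999, and a network dense
    enough for a mean degree of about 10 at 200 proteins.
    """

    seed: int = 0
    n_proteins: int = 200
    n_categories: int = 24
    label_rate: float = 3.14      # mean functions per protein
    homophily: float = 0.95       # P(edge joins a function-sharing pair)
    edge_density: float = 0.05    # fraction of all unordered pairs
    weight_range: tuple[float, float] = (150.0, 999.0)
    n_informative: int = 10
    n_redundant: int = 5
    n_noise: int = 20
    effect_size: float = 5.0      # informative-feature mean shift, in sd units
    seq_length_range: tuple[int, int] = (50, 200)
    hydrophobic_bias: float = 1.0  # weight multiplier for C,L,V,I,M,F,W

    def __post_init__(self) -> None:
        if not 0.0 <= self.homophily <= 1.0:
            raise ValidationError("homophily must lie in [0, 1]")
        if self.n_proteins < 2 or self.n_categories < 1:
            raise ValidationError("need >= 2 proteins and >= 1 category")
        if not 1.0 <= self.label_rate <= self.n_categories:
            raise ValidationError("label_rate must lie in [1, n_categories]")
        if self.edge_density <= 0 or self.edge_density > 1:
            raise ValidationError("edge_density must lie in (0, 1]")
        if self.weight_range[0] <= 0 or self.weight_range[1] < self.weight_range[0]:
            raise ValidationError("weight_range must be positive and ordered")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValidationError("feature counts must be nonnegative")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be nonnegative")

    def header_comments(self) -> list[str]:
        """The config as '#'-comment lines for embedding in fixtures."""
        return [f" cfg {k}={v}" for k, v in asdict(self).items()]


def _draw_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, frozenset]:
    """Independent per-category Bernoulli label sets, empty sets redrawn.

    The Bernoulli rate is calibrated so the *post-rejection* mean set
    size equals ``label_rate``: with per-category rate p over K
    categories the conditional mean given a non-empty set is
    Kp / (1 - (1-p)^K), solved for p by bisection.
    """
    K = cfg.n_categories
    target = cfg.label_rate

    if target <= 1.0:
        # degenerate calibration (the conditional mean is > 1 for any
        # positive rate): draw exactly one uniform category per protein
        return {
            f"sp{i:04d}": frozenset({int(rng.integers(K)) + 1})
            for i in range(cfg.n_proteins)
        }

    def conditional_mean(p: float) -> float:
        return K * p / (1.0 - (1.0 - p) ** K) if p > 0 else 1.0

    lo, hi = 1e-12, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if conditional_mean(mid) < target:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)

    labels: dict[str, frozenset] = {}
    for i in range(cfg.n_proteins):
        while True:
            mask = rng.random(K) < p
            if mask.any():
                break
        labels[f"sp{i:04d}"] = frozenset(int(c) + 1 for c in np.flatnonzero(mask))
    return labels


def generate_network(cfg: SyntheticConfig) -> tuple[nx.Graph, dict[str, frozenset]]:
    """A weighted homophilous network plus its annotation set.

    Edges are placed one at a time: with probability ``homophily`` the
    next edge is drawn uniformly from the yet-unused pairs sharing at
    least one function, otherwise uniformly from all yet-unused pairs.
    Nodes left isolated afterwards get one extra edge (to a sharing
    partner where possible) so that every node is jackknifable.  Weights
    are uniform in ``weight_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _draw_labels(cfg, rng)
    ids = sorted(ann)
    n = len(ids)
    n_pairs = n * (n - 1) // 2
    target = int(round(cfg.edge_density * n_pairs))
    if target < 1 or target > n_pairs:
        raise ValidationError(
            f"edge_density {cfg.edge_density} infeasible for {n} proteins"
        )

    lab = np.zeros((n, cfg.n_categories), dtype=bool)
    for i, pid in enumerate(ids):
        for mu in ann[pid]:
            lab[i, mu - 1] = True
    share = (lab @ lab.T) > 0
    iu, ju = np.triu_indices(n, k=1)
    sharing_pairs = np.flatnonzero(share[iu, ju])
    all_pairs = np.arange(len(iu))

    chosen: set[int] = set()
    guard = 0
    while len(chosen) < target and guard < 50 * target:
        guard += 1
        pool = sharing_pairs if (rng.random() < cfg.homophily
                                 and len(sharing_pairs)) else all_pairs
        k = int(rng.integers(len(pool)))
        chosen.add(int(pool[k]))
    net = nx.Graph()
    net.add_nodes_from(ids)
    lo, hi = cfg.weight_range
    for k in sorted(chosen):
        a, b = ids[iu[k]], ids[ju[k]]
        net.add_edge(a, b, weight=float(rng.uniform(lo, hi)))
    # reconnect isolated nodes so every node has at least one neighbour
    for i, pid in enumerate(ids):
        if net.degree(pid) == 0:
            partners = np.flatnonzero(share[i])
            partners = partners[partners != i]
            if len(partners) and rng.random() < cfg.homophily:
                j = int(rng.choice(partners))
            else:
                j = int(rng.choice([x for x in range(n) if x != i]))
            net.add_edge(pid, ids[j], weight=float(rng.uniform(lo, hi)))
    return net, ann


def generate_feature_table(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """A feature matrix with planted structure plus its annotation set.

    Informative feature j is tied to category ``(j mod K) + 1`` and has
    mean ``effect_size`` for proteins carrying that category, 0
    otherwise, with unit Gaussian noise.  Redundant features are
    informative features plus N(0, 0.1) noise; noise features are pure
    N(0, 1).
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _draw_labels(cfg, rng)
    ids = sorted(ann)
    n = len(ids)
    K = cfg.n_categories
    lab = np.zeros((n, K))
    for i, pid in enumerate(ids):
        for mu in ann[pid]:
            lab[i, mu - 1] = 1.0

    cols: dict[str, np.ndarray] = {}
    informative = []
    for j in range(cfg.n_informative):
        cat = j % K
        col = cfg.effect_size * lab[:, cat] + rng.normal(0.0, 1.0, n)
        name = f"informative_{j:02d}_cat{cat + 1}"
        cols[name] = col
        informative.append(col)
    for j in range(cfg.n_redundant):
        if informative:
            base = informative[j % len(informative)]
            cols[f"redundant_{j:02d}"] = base + rng.normal(0.0, 0.1, n)
        else:
            cols[f"redundant_{j:02d}"] = rng.normal(0.0, 1.0, n)
    for j in range(cfg.n_noise):
        cols[f"noise_{j:02d}"] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(cols, index=ids), ann


def generate_sequences(cfg: SyntheticConfig,
                       with_annotations: bool = False) -> list[ProteinRecord]:
    """Random canonical protein sequences.

    ``hydrophobic_bias`` multiplies the sampling weight of the
    hydrophobic residues C, L, V, I, M, F, W; lengths are uniform in
    ``seq_length_range``.  With ``with_annotations`` each record also
    carries deterministic synthetic secondary-structure and
    solvent-accessibility labels (from the heuristic fallbacks, so they
    are self-consistent across calls).
    """
    rng = np.random.default_rng(cfg.seed)
    aas = list(CANONICAL_AA)
    w = np.ones(len(aas))
    for i, aa in enumerate(aas):
        if aa in "CLVIMFW":
            w[i] = cfg.hydrophobic_bias
    w /= w.sum()
    lo, hi = cfg.seq_length_range
    records = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length, p=w))
        rec = ProteinRecord(id=f"sp{i:04d}", sequence=seq)
        if with_annotations:
            rec.residue_annotations["secondary_structure"] = \
                fallback_residue_annotation(rec, "secondary_structure", quiet=True)
            rec.residue_annotations["solvent_accessibility"] = \
                fallback_residue_annotation(rec, "solvent_accessibility", quiet=True)
        records.append(rec)
    return records
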