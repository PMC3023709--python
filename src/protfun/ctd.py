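"""Hybrid-property (CTD + amino-acid composition) featurization.

A protein sequence is first translated, property by property, into a
string over that property's 2- or 3-letter group alphabet.  Three kinds of
descriptor are then computed per property:

* **Composition (C)** — the percentage of each group letter in the
  translated string.
* **Transition (T)** — for each unordered group pair, the percentage of
  the *differing* adjacent position pairs whose two letters are that
  pair.  The denominator is the number of adjacent positions whose
  letters differ, not the number of all adjacent positions.
* **Distribution (D)** — for each group, the positions (as percent of
  translated length) of its first occurrence and of the occurrences at
  the 25%, 50%, 75% and 100% occurrence quantiles, the quantile index
  taken as ``ceil(q * n)`` over the group's n occurrences.

Three-group properties contribute 3 C + 3 T + 15 D = 21 features; the
two-group solvent-accessibility alphabet contributes its first (buried)
group's C and D and the single pair's T, i.e. 1 + 1 + 5 = 7.  Together
with the 20 amino-acid composition percentages the full descriptor has
5 * 21 + 7 + 20 = 132 named components, all on a 0-100 percent scale.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabets import DEFAULT_ALPHABETS, PropertyAlphabet, fallback_residue_annotation
from .errors import DegenerateInputError, MissingAnnotationError, ValidationError
from .io import CANONICAL_AA, ProteinRecord

__all__ = [
    "translate_sequence",
    "composition_features",
    "transition_features",
    "transition_counts",
    "distribution_features",
    "distribution_landmarks",
    "aac_features",
    "featurize",
    "featurize_all",
    "feature_names",
    "dedupe_vectors",
    "N_FEATURES",
]

_D_LANDMARKS = ("first", "q25", "q50", "q75", "q100")
_QUANTILES = (0.25, 0.50, 0.75)


def translate_sequence(record: ProteinRecord, alphabet: PropertyAlphabet,
                       allow_fallback: bool = False) -> str:
    """Translate a sequence into the alphabet's group letters.

    Noncanonical residues are dropped from the output (and hence from
    position numbering); for annotation-backed alphabets their aligned
    labels are dropped with them.
    """
    seq = record.sequence
    if alphabet.annotation_backed:
        labels = record.residue_annotations.get(alphabet.annotation_key)
        if labels is None:
            if not allow_fallback:
                raise MissingAnnotationError(
                    f"record {record.id!r} has no {alphabet.annotation_key!r} "
                    "annotation; supply one or enable the heuristic fallback"
                )
            labels = fallback_residue_annotation(record, alphabet.annotation_key)
        bad = set(labels) - set(alphabet.groups)
        if bad:
            raise ValidationError(
                f"annotation {alphabet.annotation_key!r} of {record.id!r} uses "
                f"letters {sorted(bad)} outside groups {alphabet.groups}"
            )
        return "".join(
            lab for aa, lab in zip(seq, labels) if aa in CANONICAL_AA
        )
    return "".join(alphabet.mapping[aa] for aa in seq if aa in CANONICAL_AA)


def composition_features(group_seq: str, alphabet: PropertyAlphabet) -> np.ndarray:
    """Percent composition of each group letter; sums to 100."""
    if not group_seq:
        raise DegenerateInputError("empty translated sequence")
    L = len(group_seq)
    return np.array(
        [100.0 * group_seq.count(g) / L for g in alphabet.groups]
    )


def transition_counts(group_seq: str) -> tuple[dict[frozenset, int], int]:
    """Counts of adjacent differing letter pairs and their total K."""
    counts: dict[frozenset, int] = {}
    k = 0
    for a, b in zip(group_seq, group_seq[1:]):
        if a != b:
            k += 1
            key = frozenset((a, b))
            counts[key] = counts.get(key, 0) + 1
    return counts, k


def transition_features(group_seq: str, alphabet: PropertyAlphabet) -> np.ndarray:
    """Percent frequency of each unordered group pair among the adjacent
    position pairs whose letters differ.

    With K differing adjacent pairs, pair {g, h} scores
    ``100 * count(g<->h) / K``; if the string has no transitions at all
    (K = 0) every value is 0.
    """
    if not group_seq:
        raise DegenerateInputError("empty translated sequence")
    counts, k = transition_counts(group_seq)
    if k == 0:
        return np.zeros(len(alphabet.pairs))
    return np.array(
        [100.0 * counts.get(frozenset(p), 0) / k for p in alphabet.pairs]
    )


def group_positions(group_seq: str, group: str) -> list[int]:
    """1-based positions of a group letter in the translated string."""
    return [i + 1 for i, g in enumerate(group_seq) if g == group]


def distribution_landmarks(group_seq: str, group: str) -> tuple[int, ...]:
    """The five landmark positions (1-based) of a group: first occurrence
    and the occurrences at the ceil(q*n) indices for q = 25/50/75/100%.

    A group absent from the string yields (0, 0, 0, 0, 0).
    """
    pos = group_positions(group_seq, group)
    n = len(pos)
    if n == 0:
        return (0, 0, 0, 0, 0)
    idx = [1] + [math.ceil(q * n) for q in _QUANTILES] + [n]
    return tuple(pos[i - 1] for i in idx)


def distribution_features(group_seq: str, alphabet: PropertyAlphabet) -> np.ndarray:
    """Per-group 5-tuples of landmark positions as percent of length."""
    if not group_seq:
        raise DegenerateInputError("empty translated sequence")
    L = len(group_seq)
    out = []
    for g in alphabet.groups:
        out.extend(100.0 * p / L for p in distribution_landmarks(group_seq, g))
    return np.array(out)


def aac_features(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: percent of each canonical residue among the
    canonical residues (noncanonical letters are excluded from both the
    numerator and the denominator)."""
    canon = [aa for aa in record.sequence if aa in CANONICAL_AA]
    if not canon:
        raise DegenerateInputError(
            f"record {record.id!r} has no canonical residues"
        )
    n = len(canon)
    return np.array([100.0 * canon.count(aa) / n for aa in CANONICAL_AA])


def _property_block_names(alphabet: PropertyAlphabet) -> list[str]:
    p = alphabet.name
    if len(alphabet.groups) == 2:
        g = alphabet.groups[0]
        a, b = alphabet.pairs[0]
        return ([f"{p}.C.{g}"] + [f"{p}.T.{a}{b}"]
                + [f"{p}.D.{g}.{lm}" for lm in _D_LANDMARKS])
    names = [f"{p}.C.{g}" for g in alphabet.groups]
    names += [f"{p}.T.{a}{b}" for a, b in alphabet.pairs]
    for g in alphabet.groups:
        names += [f"{p}.D.{g}.{lm}" for lm in _D_LANDMARKS]
    return names


def feature_names(alphabets: Sequence[PropertyAlphabet] = DEFAULT_ALPHABETS) -> list[str]:
    """The fixed, deterministic 132-name feature order."""
    names: list[str] = []
    for alph in alphabets:
        names.extend(_property_block_names(alph))
    names.extend(f"aac.{aa}" for aa in CANONICAL_AA)
    return names


N_FEATURES = len(feature_names())  # 132


def _property_block(record: ProteinRecord, alphabet: PropertyAlphabet,
                    allow_fallback: bool) -> np.ndarray:
    gseq = translate_sequence(record, alphabet, allow_fallback=allow_fallback)
    C = composition_features(gseq, alphabet)
    T = transition_features(gseq, alphabet)
    D = distribution_features(gseq, alphabet)
    if len(alphabet.groups) == 2:
        # only the first (buried) group's C and D enter the descriptor
        return np.concatenate([C[:1], T, D[:5]])
    return np.concatenate([C, T, D])


def featurize(record: ProteinRecord,
              alphabets: Sequence[PropertyAlphabet] = DEFAULT_ALPHABETS,
              allow_fallback: bool = False) -> pd.Series:
    """Compute the full named hybrid-property descriptor of one protein.

    Returns a :class:`pandas.Series` of 132 percent values in the fixed
    property order (hydrophobicity, secondary structure, solvent
    accessibility, van der Waals volume, polarity, polarizability, then
    amino-acid composition).
    """
    blocks = [
        _property_block(record, alph, allow_fallback) for alph in alphabets
    ]
    blocks.append(aac_features(record))
    return pd.Series(
        np.concatenate(blocks), index=feature_names(alphabets), name=record.id
    )


def featurize_all(records: Iterable[ProteinRecord],
                  alphabets: Sequence[PropertyAlphabet] = DEFAULT_ALPHABETS,
                  allow_fallback: bool = False) -> pd.DataFrame:
    """Feature matrix (proteins x 132) for a collection of records."""
    rows = [featurize(r, alphabets, allow_fallback) for r in records]
    if not rows:
        raise DegenerateInputError("no records to featurize")
    return pd.DataFrame(rows)


def dedupe_vectors(table: pd.DataFrame,
                   annotations: Mapping[str, frozenset],
                   decimals: Optional[int] = None) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply the two coding-vector filtering rules to a feature matrix.

    1. Proteins sharing an identical coding vector but carrying
       *different* function sets are all removed — the representation
       cannot tell them apart, so keeping any of them would poison a
       nearest-neighbour model.
    2. Of proteins sharing both the vector and the function set, only one
       representative (the lexicographically smallest id) is kept.

    Returns the filtered table and a report of ``(protein id, reason)``
    removals.  ``decimals`` optionally rounds vectors before comparison.
    """
    missing = [pid for pid in table.index if pid not in annotations]
    if missing:
        raise ValidationError(
            f"proteins without annotations cannot be filtered: {missing[:5]}"
        )
    values = table.round(decimals) if decimals is not None else table
    groups: dict[tuple, list[str]] = {}
    for pid in table.index:
        groups.setdefault(tuple(values.loc[pid]), []).append(pid)

    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for members in groups.values():
        if len(members) == 1:
            keep.append(members[0])
            continue
        funcs = {pid: frozenset(annotations[pid]) for pid in members}
        if len(set(funcs.values())) > 1:
            removed.extend(
                (pid, "identical vector, conflicting functions") for pid in members
            )
            continue
        rep = min(members)
        keep.append(rep)
        removed.extend(
            (pid, f"duplicate of {rep}") for pid in members if pid != rep
        )
    keep_sorted = [pid for pid in table.index if pid in set(keep)]
    return table.loc[keep_sorted], removed
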