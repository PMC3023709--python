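"""Property-group alphabets for the hybrid-property descriptor.

Each of the six per-residue properties partitions the amino acids (or the
predicted per-residue states) into two or three groups, following the
classic Dubchak-style coding used for CTD descriptors:

* hydrophobicity: polar / neutral / hydrophobic
* normalized van der Waals volume: small / medium / large
* polarity: low / medium / high
* polarizability: low / medium / high
* secondary structure: helix / sheet / coil (per-residue annotation)
* solvent accessibility: buried / exposed (per-residue annotation)

The four sequence-intrinsic partitions are shipped as data below; the two
structure-derived properties are read from per-residue annotation files
(the output of external structure/accessibility predictors) or, when none
are available, from the deterministic heuristics at the bottom of this
module, which are clearly flagged and are *not* equivalent to running a
real predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError
from .io import CANONICAL_AA, ProteinRecord

__all__ = [
    "PropertyAlphabet",
    "DEFAULT_ALPHABETS",
    "HYDROPHOBICITY",
    "SECONDARY_STRUCTURE",
    "SOLVENT_ACCESSIBILITY",
    "VDW_VOLUME",
    "POLARITY",
    "POLARIZABILITY",
    "fallback_residue_annotation",
]


def _expand(groups: dict[str, str]) -> dict[str, str]:
    """Invert {group letter: residues} into {residue: group letter}."""
    mapping: dict[str, str] = {}
    for letter, residues in groups.items():
        for aa in residues:
            if aa in mapping:
                raise ValidationError(f"residue {aa} assigned to two groups")
            mapping[aa] = letter
    return mapping


@dataclass(frozen=True)
class PropertyAlphabet:
    """A 2- or 3-group alphabet over amino acids or residue states.

    ``mapping`` translates each canonical amino acid to its group letter;
    annotation-backed alphabets (``mapping is None``) instead read group
    letters directly from ``record.residue_annotations[annotation_key]``.
    """

    name: str
    groups: tuple[str, ...]
    mapping: Optional[dict[str, str]] = None
    annotation_key: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.groups) not in (2, 3):
            raise ValidationError(f"{self.name}: need 2 or 3 groups")
        if self.mapping is not None:
            covered = set(self.mapping)
            if covered != set(CANONICAL_AA):
                raise ValidationError(
                    f"{self.name}: mapping must partition the 20 canonical "
                    f"amino acids, missing {set(CANONICAL_AA) - covered}"
                )
            if set(self.mapping.values()) - set(self.groups):
                raise ValidationError(f"{self.name}: mapping uses unknown group letters")
        elif self.annotation_key is None:
            raise ValidationError(f"{self.name}: need a mapping or an annotation key")

    @property
    def annotation_backed(self) -> bool:
        return self.mapping is None

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Unordered group pairs in canonical order.

        Three groups (a, b, c) yield the pairs (a,b), (b,c), (a,c); two
        groups yield the single pair (a, b).
        """
        g = self.groups
        if len(g) == 2:
            return ((g[0], g[1]),)
        return ((g[0], g[1]), (g[1], g[2]), (g[0], g[2]))


# Hydrophobicity tripartition (polar / neutral / hydrophobic); verified
# against a hand-translated reference sequence in the test suite.
HYDROPHOBICITY = PropertyAlphabet(
    name="hydrophobicity",
    groups=("H", "N", "P"),
    mapping=_expand({
        "P": "RKEDQN",
        "N": "GASTPHY",
        "H": "CLVIMFW",
    }),
)

# Normalized van der Waals volume: 0-2.78 / 2.95-4.0 / 4.03-8.08.
VDW_VOLUME = PropertyAlphabet(
    name="vdw_volume",
    groups=("1", "2", "3"),
    mapping=_expand({
        "1": "GASCTPD",
        "2": "NVEQIL",
        "3": "MHKFRYW",
    }),
)

# Polarity: 4.9-6.2 / 8.0-9.2 / 10.4-13.0.
POLARITY = PropertyAlphabet(
    name="polarity",
    groups=("1", "2", "3"),
    mapping=_expand({
        "1": "LIFWCMVY",
        "2": "PATGS",
        "3": "HQRKNED",
    }),
)

# Polarizability: 0-0.108 / 0.128-0.186 / 0.219-0.409.
POLARIZABILITY = PropertyAlphabet(
    name="polarizability",
    groups=("1", "2", "3"),
    mapping=_expand({
        "1": "GASDT",
        "2": "CPNVEQIL",
        "3": "KMHFRYW",
    }),
)

SECONDARY_STRUCTURE = PropertyAlphabet(
    name="secondary_structure",
    groups=("H", "E", "C"),  # helix / sheet / coil
    annotation_key="secondary_structure",
)

SOLVENT_ACCESSIBILITY = PropertyAlphabet(
    name="solvent_accessibility",
    groups=("B", "X"),  # buried / exposed
    annotation_key="solvent_accessibility",
)

#: The six alphabets in the fixed descriptor order (AAC comes last).
DEFAULT_ALPHABETS: tuple[PropertyAlphabet, ...] = (
    HYDROPHOBICITY,
    SECONDARY_STRUCTURE,
    SOLVENT_ACCESSIBILITY,
    VDW_VOLUME,
    POLARITY,
    POLARIZABILITY,
)


# --------------------------------------------------------------------------
# Heuristic fallbacks for the two annotation-backed properties.

# Chou-Fasman conformational propensities: P(helix), P(sheet), P(turn).
# The turn propensity stands in for coil.
_CHOU_FASMAN: dict[str, tuple[float, float, float]] = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "E": (1.51, 0.37, 0.74),
    "Q": (1.11, 1.10, 0.98), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.14, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}

# Kyte-Doolittle hydropathy index.
_KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_ACC_WINDOW = 9  # residues; edge-truncated


def fallback_residue_annotation(record: ProteinRecord, property_name: str,
                                quiet: bool = False) -> str:
    """Deterministic heuristic per-residue labels for structure properties.

    * ``secondary_structure``: per-residue argmax of the Chou-Fasman
      helix/sheet/turn propensities (turn read as coil; ties break to
      coil).  Noncanonical residues label as coil.
    * ``solvent_accessibility``: buried (B) when the mean Kyte-Doolittle
      hydropathy over a 9-residue edge-truncated window is positive, else
      exposed (X).  Noncanonical residues contribute 0 to the window mean.

    These are crude single-sequence heuristics, not structure predictors;
    the call is logged as heuristic so downstream reports can flag it.
    """
    if property_name not in ("secondary_structure", "solvent_accessibility"):
        raise ValidationError(
            f"no fallback for property {property_name!r}; only "
            "secondary_structure and solvent_accessibility are annotation-backed"
        )
    if not quiet:
        warnings.warn(
            f"using heuristic {property_name} labels for record "
            f"{record.id!r}; supply predictor output for faithful features",
            stacklevel=2,
        )
    seq = record.sequence
    if property_name == "secondary_structure":
        out = []
        for aa in seq:
            if aa not in _CHOU_FASMAN:
                out.append("C")
                continue
            ph, pe, pc = _CHOU_FASMAN[aa]
            best = max(ph, pe, pc)
            if pc == best:          # ties break to coil
                out.append("C")
            elif ph == best:
                out.append("H")
            else:
                out.append("E")
        return "".join(out)

    scores = [_KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq]
    half = _ACC_WINDOW // 2
    out = []
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        window = scores[lo:hi]
        out.append("B" if sum(window) / len(window) > 0 else "X")
    return "".join(out)
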