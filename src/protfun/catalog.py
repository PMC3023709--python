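"""The functional-category label space.

Predictions are multi-label over the 24 top-level FunCat categories: a
protein may perform several functions at once, and every scorer in this
package returns one score per category, ranked.  The catalogue maps the
integer indices 1..24 used in annotation files to category names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

# Top-level FunCat functional categories, indexed 1..24.
FUNCAT_TOP_LEVEL: tuple[tuple[int, str], ...] = (
    (1, "METABOLISM"),
    (2, "ENERGY"),
    (3, "CELL CYCLE AND DNA PROCESSING"),
    (4, "TRANSCRIPTION"),
    (5, "PROTEIN SYNTHESIS"),
    (6, "PROTEIN FATE (folding, modification, destination)"),
    (7, "PROTEIN WITH BINDING FUNCTION OR COFACTOR REQUIREMENT (structural or catalytic)"),
    (8, "REGULATION OF METABOLISM AND PROTEIN FUNCTION"),
    (9, "CELLULAR TRANSPORT, TRANSPORT FACILITIES AND TRANSPORT ROUTES"),
    (10, "CELLULAR COMMUNICATION/SIGNAL TRANSDUCTION MECHANISM"),
    (11, "CELL RESCUE, DEFENSE AND VIRULENCE"),
    (12, "INTERACTION WITH THE ENVIRONMENT"),
    (13, "SYSTEMIC INTERACTION WITH THE ENVIRONMENT"),
    (14, "TRANSPOSABLE ELEMENTS, VIRAL AND PLASMID PROTEINS"),
    (15, "CELL FATE"),
    (16, "DEVELOPMENT (Systemic)"),
    (17, "BIOGENESIS OF CELLULAR COMPONENTS"),
    (18, "CELL TYPE DIFFERENTIATION"),
    (19, "TISSUE DIFFERENTIATION"),
    (20, "ORGAN DIFFERENTIATION"),
    (21, "SUBCELLULAR LOCALIZATION"),
    (22, "CELL TYPE LOCALIZATION"),
    (23, "TISSUE LOCALIZATION"),
    (24, "ORGAN LOCALIZATION"),
)


@dataclass(frozen=True)
class FunctionCatalog:
    """Ordered index -> name table for the functional categories.

    Indices must form the contiguous range 1..n with no duplicates; the
    default catalogue is the 24-category FunCat top level.
    """

    entries: tuple[tuple[int, str], ...] = field(default=FUNCAT_TOP_LEVEL)

    def __post_init__(self) -> None:
        indices = [i for i, _ in self.entries]
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError(
                "catalog indices must be contiguous 1..n without gaps or "
                f"duplicates, got {indices!r}"
            )
        if not indices:
            raise ValidationError("catalog must contain at least one category")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def indices(self) -> range:
        return range(1, len(self.entries) + 1)

    def name(self, index: int) -> str:
        if not 1 <= index <= len(self.entries):
            raise ValidationError(f"category index {index} outside 1..{len(self)}")
        return self.entries[index - 1][1]

    def validate_index(self, index: int) -> int:
        if not isinstance(index, int) or not 1 <= index <= len(self.entries):
            raise ValidationError(f"category index {index!r} outside 1..{len(self)}")
        return index


#: The default 24-category catalogue used throughout.
DEFAULT_CATALOG = FunctionCatalog()
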