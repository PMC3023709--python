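"""Readers and writers for the external formats the toolkit touches.

Formats
-------
* FASTA protein sequences (via Biopython).
* Residue-annotation files: FASTA-like, header = protein id, body = one
  label letter per residue (e.g. H/E/C for secondary structure, B/X for
  buried/exposed solvent accessibility).
* Weighted edge lists: three whitespace- or tab-separated columns
  ``id_a id_b weight``, ``#`` comments, STRING-style confidence scores.
* Annotation tables: two tab-separated columns ``id`` and a
  comma-separated list of category indices.
* Two-column id-mapping tables.

All readers tolerate CRLF line endings and trailing blank lines.
Annotation sets are plain ``dict[str, frozenset[int]]``; networks are
:class:`networkx.Graph` instances with a positive ``weight`` attribute on
every edge and no self-loops (a protein does not interact with itself, so
the weight of a node with itself is implicitly zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
from Bio import SeqIO

from .catalog import DEFAULT_CATALOG, FunctionCatalog
from .errors import AmbiguousMappingError, FormatError, ValidationError

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Noncanonical letters tolerated in sequences but flagged and excluded
#: from featurization: unknown (X), ambiguity codes (B, Z, J) and the
#: rare translated residues selenocysteine (U) and pyrrolysine (O).
NONCANONICAL_AA = "XBZUOJ"

AnnotationSet = dict  # protein id -> frozenset of category indices


@dataclass
class ProteinRecord:
    """A protein sequence plus optional per-residue property annotations.

    ``residue_annotations`` maps a property name (``secondary_structure``
    or ``solvent_accessibility``) to a label string aligned position by
    position with ``sequence``.
    """

    id: str
    sequence: str
    residue_annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = "".join(self.sequence.split()).upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        allowed = set(CANONICAL_AA) | set(NONCANONICAL_AA)
        bad = sorted(set(self.sequence) - allowed)
        if bad:
            raise FormatError(
                f"record {self.id!r} contains invalid residue letters {bad}"
            )
        for prop, labels in self.residue_annotations.items():
            if len(labels) != len(self.sequence):
                raise ValidationError(
                    f"residue annotation {prop!r} of record {self.id!r} has "
                    f"length {len(labels)}, expected {len(self.sequence)}"
                )

    @property
    def noncanonical(self) -> frozenset[str]:
        """Noncanonical residue letters present in the sequence."""
        return frozenset(self.sequence) & frozenset(NONCANONICAL_AA)

    @property
    def has_noncanonical(self) -> bool:
        return bool(self.noncanonical)


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased with whitespace stripped.  Noncanonical
    residues are retained on the record and exposed through
    ``record.noncanonical``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path],
                header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f";{line}\n")
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def read_residue_annotations(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA-like per-residue label file into ``{id: labels}``."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate id {rec.id!r} in residue annotation file")
        out[rec.id] = str(rec.seq).upper()
    return out


def attach_residue_annotations(records: Sequence[ProteinRecord],
                               property_name: str,
                               labels: Mapping[str, str]) -> None:
    """Attach labels from a residue-annotation file to matching records."""
    for rec in records:
        if rec.id in labels:
            lab = labels[rec.id]
            if len(lab) != len(rec.sequence):
                raise ValidationError(
                    f"annotation length {len(lab)} != sequence length "
                    f"{len(rec.sequence)} for record {rec.id!r}"
                )
            rec.residue_annotations[property_name] = lab


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_annotations(path: Union[str, Path],
                     catalog: FunctionCatalog = DEFAULT_CATALOG) -> AnnotationSet:
    """Read a protein -> functional-category annotation table.

    Each row is ``id<TAB>c1,c2,...`` with category indices valid in
    *catalog*.  Duplicate rows for the same protein are unioned with a
    warning.
    """
    path = Path(path)
    out: dict[str, frozenset[int]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        pid, cats_field = parts[0].strip(), parts[1].strip()
        if not cats_field:
            raise ValidationError(f"{path}:{lineno}: empty category list for {pid!r}")
        try:
            cats = frozenset(int(tok) for tok in cats_field.split(","))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer category: {exc}") from exc
        for c in cats:
            catalog.validate_index(c)
        if pid in out:
            warnings.warn(
                f"duplicate annotation rows for {pid!r}: taking the union",
                stacklevel=2,
            )
            cats = out[pid] | cats
        out[pid] = cats
    if not out:
        raise FormatError(f"no annotation rows found in {path}")
    return out


def write_annotations(ann: Mapping[str, frozenset], path: Union[str, Path],
                      header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"#{line}\n")
        for pid in sorted(ann):
            cats = ",".join(str(c) for c in sorted(ann[pid]))
            fh.write(f"{pid}\t{cats}\n")


def read_edge_list(path: Union[str, Path]) -> nx.Graph:
    """Read a 3-column weighted edge list into an undirected network.

    Duplicate rows for the same unordered pair collapse to the maximum
    weight with a warning; self-pairs are dropped with a warning (no
    self-interaction).  Weights must be strictly positive; they are kept
    on whatever scale the file uses (STRING 0-1000 combined scores or
    normalized 0-1 confidences) since all downstream rankings are
    invariant to a uniform positive rescaling.
    """
    path = Path(path)
    net = nx.Graph()
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        a, b, wtok = parts
        try:
            w = float(wtok)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric weight {wtok!r}") from exc
        if w <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive weight {w}")
        if a == b:
            warnings.warn(f"self-interaction {a!r} dropped", stacklevel=2)
            net.add_node(a)
            continue
        if net.has_edge(a, b):
            old = net[a][b]["weight"]
            if old != w:
                warnings.warn(
                    f"duplicate edge {a!r}-{b!r}: keeping max weight "
                    f"{max(old, w)}", stacklevel=2,
                )
            net[a][b]["weight"] = max(old, w)
        else:
            net.add_edge(a, b, weight=w)
    return net


def write_edge_list(net: nx.Graph, path: Union[str, Path],
                    header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"#{line}\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\t{net[a][b]['weight']:g}\n")


def read_id_map(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column old-id -> new-id table.

    An old id mapping to several distinct new ids is an ambiguity error:
    there is no principled way to pick one, so we refuse to guess.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    ambiguous: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        old, new = parts
        if old in mapping and mapping[old] != new:
            ambiguous.add(old)
        mapping[old] = new
    if ambiguous:
        raise AmbiguousMappingError(
            "ids map to multiple targets: " + ", ".join(sorted(ambiguous))
        )
    return mapping


def apply_id_map(obj, map_path: Union[str, Path]):
    """Translate protein ids in records, annotations or a network.

    Unmapped ids are retained unchanged and reported.  Returns
    ``(translated_object, unmapped_ids)``.
    """
    mapping = read_id_map(map_path)

    if isinstance(obj, nx.Graph):
        unmapped = sorted(n for n in obj.nodes if n not in mapping)
        relabeled = nx.relabel_nodes(obj, {n: mapping.get(n, n) for n in obj.nodes})
        return relabeled, unmapped
    if isinstance(obj, Mapping):
        unmapped = sorted(k for k in obj if k not in mapping)
        return {mapping.get(k, k): v for k, v in obj.items()}, unmapped
    if isinstance(obj, Sequence):
        unmapped = sorted(r.id for r in obj if r.id not in mapping)
        out = []
        for rec in obj:
            out.append(ProteinRecord(
                id=mapping.get(rec.id, rec.id),
                sequence=rec.sequence,
                residue_annotations=dict(rec.residue_annotations),
            ))
        return out, unmapped
    raise TypeError(f"cannot apply id map to object of type {type(obj)!r}")
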