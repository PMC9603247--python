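"""Reading and writing peptide datasets and per-residue property tables.

Peptides live in plain FASTA; binary activity labels (1 = anticancer
peptide, 0 = inactive) are carried either as a ``|<label>`` suffix on the
FASTA header or in a two-column ``id<TAB>label`` sidecar table.
Physicochemical property tables are TSV: one row per published index,
one column per standard residue, ``NA`` for values the index does not
define.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the fixed column/encoding order used
#: throughout the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol appended when a peptide is shorter than the target length.
PAD = "X"

VALID_SYMBOLS = frozenset(ALPHABET + PAD)
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

_NA_MARKERS = {"NA", "N/A", "NAN", ""}


class SequenceAlphabetError(ValueError):
    """Raised when FASTA entries contain symbols outside the 21-letter set.

    Carries a per-record rejection report in :attr:`rejections`.
    """

    def __init__(self, rejections: list[dict]):
        self.rejections = rejections
        details = "; ".join(
            f"{r['id']}: invalid symbol(s) {sorted(r['symbols'])}" for r in rejections
        )
        super().__init__(f"{len(rejections)} record(s) rejected: {details}")


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide sequence with an optional binary label.

    ``original_length`` is set by length normalization and records the
    pre-padding/truncation length, needed when composition features are
    computed relative to the raw sequence.
    """

    id: str
    sequence: str
    label: int | None = None
    original_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_SYMBOLS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid symbol(s) {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _resolve_label(raw_id: str, label_map: Mapping[str, int] | None):
    """Split a ``id|label`` header and/or look the id up in a sidecar map."""
    rec_id, label = raw_id, None
    if "|" in raw_id:
        head, _, tail = raw_id.rpartition("|")
        if tail in ("0", "1"):
            rec_id, label = head, int(tail)
    if label_map is not None and rec_id in label_map:
        label = int(label_map[rec_id])
    return rec_id, label


def parse_fasta(
    path: str | Path,
    label_map: Mapping[str, int] | None = None,
    require_labels: bool = False,
) -> tuple[list[PeptideRecord], list[dict]]:
    """Parse FASTA into records plus a rejection report.

    Returns ``(records, rejections)`` where each rejection is a dict with
    the offending ``id`` and the set of invalid ``symbols``. Sequences are
    uppercased; labels come from a ``|label`` header suffix or *label_map*.
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    rejections: list[dict] = []
    seen: set[str] = set()
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"{path}: empty or not a FASTA file")
    for entry in entries:
        rec_id, label = _resolve_label(entry.id, label_map)
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        seq = str(entry.seq).upper()
        bad = set(seq) - VALID_SYMBOLS
        if bad:
            rejections.append({"id": rec_id, "symbols": bad})
            continue
        if require_labels and label is None:
            raise ValueError(f"{path}: no label resolvable for record {rec_id!r}")
        records.append(PeptideRecord(id=rec_id, sequence=seq, label=label))
    return records, rejections


def read_fasta(
    path: str | Path,
    label_map: Mapping[str, int] | None = None,
    require_labels: bool = False,
) -> list[PeptideRecord]:
    """Read a FASTA file, raising :class:`SequenceAlphabetError` on any
    record with symbols outside the 21-letter alphabet."""
    records, rejections = parse_fasta(path, label_map, require_labels)
    if rejections:
        raise SequenceAlphabetError(rejections)
    return records


def write_fasta(records: Sequence[PeptideRecord], path: str | Path,
                include_labels: bool = True) -> None:
    """Write records to FASTA, encoding labels as a ``|label`` header suffix."""
    path = Path(path)
    out = []
    for rec in records:
        name = rec.id
        if include_labels and rec.label is not None:
            name = f"{rec.id}|{rec.label}"
        out.append(SeqRecord(Seq(rec.sequence), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` sidecar table (optional header)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        rec_id, raw = parts
        if lineno == 1 and raw.lower() in ("label", "y", "class"):
            continue
        labels[rec_id] = int(raw)
    return labels


def write_label_table(records: Sequence[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} has no label")
            fh.write(f"{rec.id}\t{rec.label}\n")


@dataclass(frozen=True)
class PropertyTable:
    """A set of per-residue physicochemical indices.

    ``values`` is shaped (n_properties, 20), columns ordered as
    :data:`ALPHABET`; rows with missing values are dropped at load time so
    the table never contains NA.
    """

    property_ids: tuple[str, ...]
    values: np.ndarray  # (n_properties, 20), float64
    dropped: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValueError("property values must be (n_properties, 20)")
        if values.shape[0] != len(self.property_ids):
            raise ValueError("property_ids and values row count differ")
        if np.isnan(values).any():
            raise ValueError("property table contains missing values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "property_ids", tuple(self.property_ids))

    @property
    def n_properties(self) -> int:
        return self.values.shape[0]

    def residue_profile(self, aa: str) -> np.ndarray:
        """All property values for one residue (a length-n_properties vector)."""
        return self.values[:, AA_TO_INDEX[aa]]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PropertyTable)
            and self.property_ids == other.property_ids
            and np.allclose(self.values, other.values)
        )


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a TSV property table, dropping rows with any missing value.

    Layout: optional ``#`` comments, optional header row, then one row per
    property: ``property_id`` followed by 20 numeric (or NA) residue columns
    in :data:`ALPHABET` order.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    dropped: list[str] = []
    n_data_rows = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "property_id":
            continue
        if len(parts) != 21:
            raise ValueError(
                f"{path}:{lineno}: expected 21 columns (id + 20 residues), "
                f"got {len(parts)}"
            )
        n_data_rows += 1
        raw = parts[1:]
        if any(v.strip().upper() in _NA_MARKERS for v in raw):
            dropped.append(parts[0])
            continue
        ids.append(parts[0])
        rows.append([float(v) for v in raw])
    if not n_data_rows:
        raise ValueError(f"{path}: no property rows found")
    if dropped:
        logger.info(
            "%s: dropped %d of %d properties with missing values",
            path, len(dropped), n_data_rows,
        )
    if not rows:
        raise ValueError(f"{path}: every property row contains missing values")
    return PropertyTable(tuple(ids), np.array(rows, dtype=float),
                         dropped=tuple(dropped))


def save_property_table(table: PropertyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("property_id\t" + "\t".join(ALPHABET) + "\n")
        for pid, row in zip(table.property_ids, table.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def default_property_table() -> PropertyTable:
    """The property table shipped with the package: ten classic published
    per-residue scales (hydropathy, hydrophilicity, mass, charge, ...)."""
    from importlib.resources import files

    return load_property_table(files("acp_ada").joinpath("data/aa_properties.tsv"))


def matrix_fingerprint(x: np.ndarray) -> str:
    """Stable SHA-1 fingerprint of a numeric matrix (shape + contents)."""
    x = np.ascontiguousarray(np.asarray(x, dtype=float))
    h = hashlib.sha1()
    h.update(str(x.shape).encode())
    h.update(x.tobytes())
    return h.hexdigest()


__all__ = [
    "ALPHABET", "PAD", "VALID_SYMBOLS", "AA_TO_INDEX",
    "PeptideRecord", "PropertyTable", "SequenceAlphabetError",
    "parse_fasta", "read_fasta", "write_fasta",
    "read_label_table", "write_label_table",
    "load_property_table", "save_property_table", "default_property_table",
    "matrix_fingerprint",
]
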