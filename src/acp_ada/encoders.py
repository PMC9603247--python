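"""Feature encodings for fixed-length peptides.

Three blocks are concatenated into one numeric vector per peptide:

* **BPF** — a binary profile of the first ``k`` N-terminal residues, one
  20-way one-hot group per position (pad symbol X -> all-zero group);
  captures residue order at the N-terminus.
* **AAINDEX** — each residue replaced by its physicochemical index values
  and flattened residue-major to an ``Lx * n_properties`` vector; a
  feature-selection step (see :mod:`acp_ada.selection`) reduces this to
  ``n_selected`` columns.
* **AAC** — the 20-vector of residue-type frequencies.

At the defaults (k=7, 50 selected physicochemical columns) a peptide is
represented by 140 + 50 + 20 = 210 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AA_TO_INDEX, ALPHABET, PAD, PeptideRecord, PropertyTable
from .selection import SelectionModel, apply_selection

DEFAULT_BLOCKS = ("bpf", "aaindex", "aac")


@dataclass(frozen=True)
class EncoderConfig:
    """Encoding hyperparameters.

    ``aac_denominator`` controls the composition normalizer: ``"nonpad"``
    divides by the number of non-X residues of the normalized sequence
    (frequencies always sum to 1); ``"original"`` divides by the
    pre-normalization length. ``scale_properties`` z-scores each property
    across the 20 residues before encoding (off by default; indices are
    used as published).
    """

    Lx: int = 50
    k_bpf: int = 7
    n_selected: int = 50
    aac_denominator: str = "nonpad"
    scale_properties: bool = False

    def __post_init__(self) -> None:
        if self.Lx < 1 or self.k_bpf < 1 or self.n_selected < 1:
            raise ValueError("Lx, k_bpf and n_selected must be positive")
        if self.k_bpf > self.Lx:
            raise ValueError("k_bpf must not exceed Lx")
        if self.aac_denominator not in ("nonpad", "original"):
            raise ValueError("aac_denominator must be 'nonpad' or 'original'")


@dataclass
class FeatureMatrix:
    """A samples x features matrix with named contiguous blocks.

    ``blocks`` maps block name to a ``(start, stop)`` column range;
    ``provenance`` (optional) tags each row ``"original"`` or
    ``"pseudo:<source row>"`` after augmentation.
    """

    X: np.ndarray
    blocks: dict[str, tuple[int, int]]
    feature_names: list[str] = field(default_factory=list)
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.feature_names and len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.blocks[name]
        return self.X[:, start:stop]

    def to_dataframe(self) -> pd.DataFrame:
        names = self.feature_names or [f"f_{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=names)
        if self.provenance is not None:
            df.insert(0, "provenance", self.provenance)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_normalized(record: PeptideRecord, Lx: int) -> None:
    if len(record.sequence) != Lx:
        raise ValueError(
            f"record {record.id!r} has length {len(record.sequence)}, "
            f"expected normalized length {Lx}"
        )


def encode_bpf(record: PeptideRecord, config: EncoderConfig) -> np.ndarray:
    """One-hot profile of the first ``k_bpf`` residues (20 entries per
    position, alphabet order; X gives an all-zero group)."""
    _check_normalized(record, config.Lx)
    out = np.zeros(20 * config.k_bpf)
    for i, aa in enumerate(record.sequence[: config.k_bpf]):
        if aa != PAD:
            out[20 * i + AA_TO_INDEX[aa]] = 1.0
    return out


def _table_values(table: PropertyTable, config: EncoderConfig) -> np.ndarray:
    vals = table.values
    if config.scale_properties:
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        vals = (vals - mu) / sd
    return vals


def encode_aaindex_full(record: PeptideRecord, table: PropertyTable,
                        config: EncoderConfig) -> np.ndarray:
    """Residue-major flattening of the per-residue property profiles.

    Entry ``i * n_properties + p`` holds property ``p`` of residue ``i``;
    the pad symbol contributes zeros. Output length ``Lx * n_properties``.
    """
    _check_normalized(record, config.Lx)
    vals = _table_values(table, config)
    n_props = table.n_properties
    out = np.zeros(config.Lx * n_props)
    for i, aa in enumerate(record.sequence):
        if aa != PAD:
            out[i * n_props:(i + 1) * n_props] = vals[:, AA_TO_INDEX[aa]]
    return out


def encode_aac(record: PeptideRecord, config: EncoderConfig) -> np.ndarray:
    """Residue-type frequencies over the non-X residues (alphabet order)."""
    counts = np.zeros(20)
    n_nonpad = 0
    for aa in record.sequence:
        if aa != PAD:
            counts[AA_TO_INDEX[aa]] += 1
            n_nonpad += 1
    if config.aac_denominator == "original":
        denom = (record.original_length if record.original_length is not None
                 else n_nonpad)
    else:
        denom = n_nonpad
    if denom == 0:
        raise ValueError(f"record {record.id!r}: all-pad sequence, "
                         "composition undefined")
    return counts / denom


def encode_bpf_matrix(records: Sequence[PeptideRecord],
                      config: EncoderConfig) -> np.ndarray:
    return np.array([encode_bpf(r, config) for r in records]).reshape(
        len(records), 20 * config.k_bpf)


def encode_aaindex_matrix(records: Sequence[PeptideRecord], table: PropertyTable,
                          config: EncoderConfig) -> np.ndarray:
    return np.array([encode_aaindex_full(r, table, config) for r in records]
                    ).reshape(len(records), config.Lx * table.n_properties)


def encode_aac_matrix(records: Sequence[PeptideRecord],
                      config: EncoderConfig) -> np.ndarray:
    return np.array([encode_aac(r, config) for r in records]).reshape(
        len(records), 20)


def block_dimensions(config: EncoderConfig,
                     blocks: Sequence[str] = DEFAULT_BLOCKS) -> dict[str, int]:
    dims = {"bpf": 20 * config.k_bpf, "aaindex": config.n_selected, "aac": 20}
    return {b: dims[b] for b in blocks}


def encode_dataset(
    records: Sequence[PeptideRecord],
    table: PropertyTable,
    selection: SelectionModel | None,
    config: EncoderConfig,
    blocks: Sequence[str] = DEFAULT_BLOCKS,
) -> tuple[FeatureMatrix, np.ndarray | None]:
    """Encode records into the concatenated block feature matrix.

    *selection* (a fitted column selector over the raw
    ``Lx * n_properties`` space) is required whenever ``"aaindex"`` is in
    *blocks*. Returns the matrix plus the label vector (``None`` when any
    record is unlabeled).
    """
    blocks = tuple(blocks)
    if not blocks or any(b not in DEFAULT_BLOCKS for b in blocks):
        raise ValueError(f"blocks must be a non-empty subset of {DEFAULT_BLOCKS}")
    if "aaindex" in blocks:
        if selection is None:
            raise ValueError("a fitted SelectionModel is required for the "
                             "aaindex block")
        if selection.n_features_in != config.Lx * table.n_properties:
            raise ValueError(
                f"selection was fitted on {selection.n_features_in} columns "
                f"but Lx * n_properties = {config.Lx * table.n_properties}"
            )
        if len(selection.selected_indices) != config.n_selected:
            raise ValueError(
                f"selection keeps {len(selection.selected_indices)} columns, "
                f"config expects n_selected={config.n_selected}"
            )

    parts: list[np.ndarray] = []
    names: list[str] = []
    block_ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for b in blocks:
        if b == "bpf":
            part = encode_bpf_matrix(records, config)
            names += [f"bpf_{j}" for j in range(part.shape[1])]
        elif b == "aaindex":
            raw = encode_aaindex_matrix(records, table, config)
            part = apply_selection(raw, selection)
            names += [f"aaindex_sel_{j}" for j in range(part.shape[1])]
        else:
            part = encode_aac_matrix(records, config)
            names += [f"aac_{aa}" for aa in ALPHABET]
        parts.append(part)
        block_ranges[b] = (offset, offset + part.shape[1])
        offset += part.shape[1]

    X = (np.hstack(parts) if records
         else np.empty((0, sum(p.shape[1] for p in parts))))
    y = None
    if records and all(r.label is not None for r in records):
        y = np.array([r.label for r in records], dtype=int)
    return FeatureMatrix(X, block_ranges, names), y


__all__ = [
    "EncoderConfig", "FeatureMatrix", "DEFAULT_BLOCKS", "block_dimensions",
    "encode_bpf", "encode_aaindex_full", "encode_aac",
    "encode_bpf_matrix", "encode_aaindex_matrix", "encode_aac_matrix",
    "encode_dataset",
]
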