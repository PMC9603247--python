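"""Length normalization: pad short peptides with X, truncate long ones.

Fixed-length input is required by the positional encodings; the original
length is kept on the record so composition features can refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .io import PAD, PeptideRecord


@dataclass(frozen=True)
class LengthConfig:
    """Target peptide length. 40, 50 and 60 are the benchmark grid values;
    any positive length is accepted."""

    Lx: int = 50

    def __post_init__(self) -> None:
        if self.Lx < 1:
            raise ValueError("Lx must be >= 1")


def normalize_length(record: PeptideRecord, config: LengthConfig) -> PeptideRecord:
    """Return a copy of *record* whose sequence has length exactly ``Lx``.

    Shorter sequences keep their residues as a prefix and are padded with
    ``X``; longer ones keep only the first ``Lx`` residues (N-terminal
    prefix). The pre-normalization length is stored in
    ``original_length`` (idempotent: an already-normalized record keeps
    its recorded original length).
    """
    Lx = config.Lx
    original = (record.original_length if record.original_length is not None
                else len(record.sequence))
    seq = record.sequence
    if len(seq) < Lx:
        seq = seq + PAD * (Lx - len(seq))
    elif len(seq) > Lx:
        seq = seq[:Lx]
    return replace(record, sequence=seq, original_length=original)


def normalize_records(records: Sequence[PeptideRecord],
                      config: LengthConfig) -> list[PeptideRecord]:
    return [normalize_length(rec, config) for rec in records]


__all__ = ["LengthConfig", "normalize_length", "normalize_records"]
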