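"""Synthetic labeled peptide datasets for offline testing and benchmarking.

Real anticancer peptides are short (roughly 10-60 residues) amphipathic
cationic sequences, so the generator plants a composition signal: the
positive class is enriched in lysine/arginine with a mild hydrophobic
boost, the negative class mildly enriched in acidic residues. Sequences
are drawn i.i.d. per residue from the class frequency vector with
lengths uniform on a range — there is no motif or positional structure,
so these fixtures exercise the pipeline, not ACP biology.

Also provides a synthetic stand-in generator for a full-size per-residue
property table (hundreds of index rows, some with missing values) used
to test NA filtering and the high-dimensional encoding path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ALPHABET, AA_TO_INDEX, PeptideRecord, write_fasta, write_label_table


def biased_frequencies(boosts: dict[str, float]) -> tuple[float, ...]:
    w = np.ones(20)
    for aa, factor in boosts.items():
        w[AA_TO_INDEX[aa]] *= factor
    return tuple(w / w.sum())

#: Default class compositions: cationic, mildly hydrophobic positives vs
#: mildly acidic negatives.
POSITIVE_FREQS = biased_frequencies(
    {"K": 6.0, "R": 5.0, "L": 1.8, "F": 1.5, "I": 1.5, "A": 1.3})
NEGATIVE_FREQS = biased_frequencies({"D": 2.0, "E": 2.0, "S": 1.3, "G": 1.3})

#: Strongly separated compositions for end-to-end benchmark runs: a
#: pronounced cationic/acidic split that any competent pipeline should
#: classify near-perfectly.
STRONG_POSITIVE_FREQS = biased_frequencies(
    {"K": 10.0, "R": 8.0, "L": 2.0, "F": 1.5})
STRONG_NEGATIVE_FREQS = biased_frequencies(
    {"D": 5.0, "E": 5.0, "S": 1.5, "G": 1.5})


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset shape and class composition.

    Presets match the benchmark dataset sizes: ``acp740-like`` (376
    positives / 364 negatives) and ``acp240-like`` (129 / 111).
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (10, 60)
    pos_freqs: tuple[float, ...] = POSITIVE_FREQS
    neg_freqs: tuple[float, ...] = NEGATIVE_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg < 1:
            raise ValueError("need at least one record")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length range")
        for name, freqs in (("pos_freqs", self.pos_freqs),
                            ("neg_freqs", self.neg_freqs)):
            freqs = np.asarray(freqs, dtype=float)
            if freqs.shape != (20,) or (freqs < 0).any() or \
                    not np.isclose(freqs.sum(), 1.0):
                raise ValueError(f"{name} must be 20 non-negative values "
                                 "summing to 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SyntheticConfig":
        sizes = {"acp740-like": (376, 364), "acp240-like": (129, 111),
                 "strong-bias-200": (100, 100)}
        if name not in sizes:
            raise ValueError(f"unknown preset {name!r}; options: {sorted(sizes)}")
        n_pos, n_neg = sizes[name]
        if name == "strong-bias-200":
            return cls(n_pos=n_pos, n_neg=n_neg, seed=seed,
                       pos_freqs=STRONG_POSITIVE_FREQS,
                       neg_freqs=STRONG_NEGATIVE_FREQS)
        return cls(n_pos=n_pos, n_neg=n_neg, seed=seed)


def generate_dataset(config: SyntheticConfig) -> list[PeptideRecord]:
    """Draw a labeled peptide set; deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    letters = np.array(list(ALPHABET))
    records: list[PeptideRecord] = []
    for cls, n, freqs, prefix in (
        (1, config.n_pos, config.pos_freqs, "pos"),
        (0, config.n_neg, config.neg_freqs, "neg"),
    ):
        p = np.asarray(freqs, dtype=float)
        p = p / p.sum()
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=p))
            records.append(PeptideRecord(id=f"{prefix}_{i + 1:04d}",
                                         sequence=seq, label=cls))
    return records


def write_dataset(records: Sequence[PeptideRecord], fasta_path: str | Path,
                  labels_path: str | Path | None = None) -> None:
    """Write records as FASTA (labels in headers) plus an optional sidecar
    label table."""
    write_fasta(records, fasta_path)
    if labels_path is not None:
        write_label_table(records, labels_path)


def write_synthetic_property_table(
    path: str | Path,
    n_properties: int = 544,
    n_na_rows: int = 13,
    seed: int = 0,
) -> None:
    """Write a synthetic stand-in for a full-size per-residue index table.

    Emits *n_properties* rows of standard-normal values over the 20
    residues, of which *n_na_rows* (deterministically chosen) contain at
    least one ``NA`` cell; loading the file therefore yields
    ``n_properties - n_na_rows`` complete properties. Values carry no
    physicochemical meaning — synthetic by construction, sized to match
    the scale of the public index databases.
    """
    if not 0 <= n_na_rows <= n_properties:
        raise ValueError("n_na_rows must be in [0, n_properties]")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_properties, 20)).round(3)
    na_rows = rng.choice(n_properties, size=n_na_rows, replace=False)
    with open(path, "w") as fh:
        fh.write("# synthetic property table (standard-normal values)\n")
        fh.write("property_id\t" + "\t".join(ALPHABET) + "\n")
        for i in range(n_properties):
            cells = [f"{v:.3f}" for v in values[i]]
            if i in na_rows:
                for j in rng.choice(20, size=int(rng.integers(1, 4)),
                                    replace=False):
                    cells[j] = "NA"
            fh.write(f"syn_{i + 1:04d}\t" + "\t".join(cells) + "\n")


__all__ = ["biased_frequencies", "SyntheticConfig", "generate_dataset",
           "write_dataset", "write_synthetic_property_table",
           "POSITIVE_FREQS", "NEGATIVE_FREQS",
           "STRONG_POSITIVE_FREQS", "STRONG_NEGATIVE_FREQS"]
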