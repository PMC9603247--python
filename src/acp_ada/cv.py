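"""Stratified k-fold cross-validation of the full pipeline, plus the
(length x augmentation) grid and feature/classifier ablation runners.

Per fold the chain is: length-normalize -> encode blocks -> fit mRMR on
the training rows only (default; a "global" policy fitting once on the
full set is available for replication) -> augment the training rows only
-> train -> score the held-out fold. Selection, augmentation and
training never see held-out rows under the default policy; fold
membership depends only on the labels and the fold seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augment import AugmentationConfig, augment_training_set
from .encoders import (
    DEFAULT_BLOCKS,
    EncoderConfig,
    FeatureMatrix,
    encode_aac_matrix,
    encode_aaindex_matrix,
    encode_bpf_matrix,
)
from .io import ALPHABET, PeptideRecord, PropertyTable, matrix_fingerprint
from .metrics import MetricReport, compute_metrics, confusion
from .model import ModelConfig, predict, train
from .preprocess import LengthConfig, normalize_records
from .selection import SelectionModel, apply_selection, fit_mrmr

METRIC_KEYS = ("acc", "pre", "sen", "spe", "mcc")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    ``selection_policy`` — ``"per_fold"`` (fit mRMR inside each training
    fold; leakage-safe default) or ``"global"`` (fit once on all rows).
    ``feature_blocks`` — which encoder blocks to concatenate.
    """

    n_folds: int = 5
    fold_seed: int = 42
    selection_policy: str = "per_fold"
    feature_blocks: tuple[str, ...] = DEFAULT_BLOCKS
    augment: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.selection_policy not in ("per_fold", "global"):
            raise ValueError("selection_policy must be 'per_fold' or 'global'")
        blocks = tuple(self.feature_blocks)
        if not blocks or any(b not in DEFAULT_BLOCKS for b in blocks):
            raise ValueError(
                f"feature_blocks must be a non-empty subset of {DEFAULT_BLOCKS}")
        object.__setattr__(self, "feature_blocks", blocks)


@dataclass
class CVReport:
    """Per-fold metrics with their mean/std and full run provenance."""

    fold_reports: list[MetricReport]
    provenance: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean([getattr(r, k) for r in self.fold_reports]))
                for k in METRIC_KEYS}

    @property
    def std(self) -> dict[str, float]:
        return {k: float(np.std([getattr(r, k) for r in self.fold_reports]))
                for k in METRIC_KEYS}

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": self.mean,
            "std": self.std,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _assemble(blocks: Sequence[str], parts: dict[str, np.ndarray],
              selection: SelectionModel | None,
              rows: np.ndarray) -> FeatureMatrix:
    """Concatenate the requested blocks for the given row subset, applying
    the column selection to the raw physicochemical block."""
    mats: list[np.ndarray] = []
    names: list[str] = []
    ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for b in blocks:
        if b == "aaindex":
            mat = apply_selection(parts["aaindex"][rows], selection)
            names += [f"aaindex_sel_{j}" for j in range(mat.shape[1])]
        else:
            mat = parts[b][rows]
            if b == "bpf":
                names += [f"bpf_{j}" for j in range(mat.shape[1])]
            else:
                names += [f"aac_{aa}" for aa in ALPHABET]
        mats.append(mat)
        ranges[b] = (offset, offset + mat.shape[1])
        offset += mat.shape[1]
    return FeatureMatrix(np.hstack(mats), ranges, names)


def _encode_parts(records, table, enc_cfg, blocks):
    parts: dict[str, np.ndarray] = {}
    if "bpf" in blocks:
        parts["bpf"] = encode_bpf_matrix(records, enc_cfg)
    if "aaindex" in blocks:
        parts["aaindex"] = encode_aaindex_matrix(records, table, enc_cfg)
    if "aac" in blocks:
        parts["aac"] = encode_aac_matrix(records, enc_cfg)
    return parts


def run_cv(
    records: Sequence[PeptideRecord],
    table: PropertyTable,
    length_cfg: LengthConfig = LengthConfig(),
    enc_cfg: EncoderConfig | None = None,
    model_cfg: ModelConfig = ModelConfig(),
    cv_cfg: CVConfig = CVConfig(),
    aug_cfg: AugmentationConfig = AugmentationConfig(),
) -> CVReport:
    """Stratified k-fold evaluation of the pipeline on labeled records."""
    if enc_cfg is None:
        enc_cfg = EncoderConfig(Lx=length_cfg.Lx)
    if enc_cfg.Lx != length_cfg.Lx:
        raise ValueError("LengthConfig.Lx and EncoderConfig.Lx disagree")
    if any(r.label is None for r in records):
        raise ValueError("cross-validation requires labeled records")
    y = np.array([r.label for r in records], dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv_cfg.n_folds:
        raise ValueError(
            f"each class needs >= {cv_cfg.n_folds} members, got {counts.tolist()}")

    normalized = normalize_records(records, length_cfg)
    blocks = cv_cfg.feature_blocks
    parts = _encode_parts(normalized, table, enc_cfg, blocks)

    global_selection = None
    if "aaindex" in blocks and cv_cfg.selection_policy == "global":
        global_selection = fit_mrmr(parts["aaindex"], y, enc_cfg.n_selected)

    skf = StratifiedKFold(n_splits=cv_cfg.n_folds, shuffle=True,
                          random_state=cv_cfg.fold_seed)
    fold_reports: list[MetricReport] = []
    fold_info: list[dict] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        selection = None
        if "aaindex" in blocks:
            selection = (global_selection
                         if cv_cfg.selection_policy == "global"
                         else fit_mrmr(parts["aaindex"][tr], y[tr],
                                       enc_cfg.n_selected))
        fm_tr = _assemble(blocks, parts, selection, tr)
        fm_te = _assemble(blocks, parts, selection, te)
        y_tr = y[tr]
        n_before = fm_tr.n_samples
        if cv_cfg.augment and aug_cfg.n_percent > 0:
            fold_aug = replace(aug_cfg, seed=aug_cfg.seed + fold)
            fm_tr, y_tr = augment_training_set(fm_tr, y_tr, fold_aug)
        fitted = train(fm_tr, y_tr, model_cfg,
                       selection_fingerprint=(selection.fingerprint
                                              if selection else ""))
        pred, _ = predict(fitted, fm_te)
        fold_reports.append(compute_metrics(confusion(y[te], pred)))
        fold_info.append({
            "fold": fold,
            "test_indices": [int(i) for i in te],
            "n_train_before_augment": int(n_before),
            "n_train_after_augment": int(fm_tr.n_samples),
            "selection_indices": (list(selection.selected_indices)
                                  if selection else None),
        })

    provenance = {
        "n_records": len(records),
        "class_counts": counts.tolist(),
        "length_config": asdict(length_cfg),
        "encoder_config": asdict(enc_cfg),
        "model_config": asdict(model_cfg),
        "cv_config": asdict(cv_cfg),
        "augment_config": asdict(aug_cfg) if cv_cfg.augment else None,
        "folds": fold_info,
    }
    return CVReport(fold_reports, provenance)


@dataclass
class GridResult:
    """CV reports keyed by (Lx, N%) with the best cell by mean MCC."""

    reports: dict[tuple[int, float], CVReport]
    best: tuple[int, float]

    def to_table(self, percent: bool = True) -> pd.DataFrame:
        rows = []
        for (lx, n), report in self.reports.items():
            mean = report.mean
            scale = 100.0 if percent else 1.0
            rows.append({
                "Lx": lx, "N%": n,
                **{f"{k.upper()}%" if percent else k.upper():
                   round(mean[k] * scale, 2 if percent else 4)
                   for k in METRIC_KEYS},
            })
        return pd.DataFrame(rows)


def run_grid(
    records: Sequence[PeptideRecord],
    table: PropertyTable,
    lx_values: Sequence[int] = (40, 50, 60),
    n_values: Sequence[float] = (100, 200, 300),
    enc_cfg: EncoderConfig | None = None,
    model_cfg: ModelConfig = ModelConfig(),
    cv_cfg: CVConfig = CVConfig(),
    aug_cfg: AugmentationConfig = AugmentationConfig(),
) -> GridResult:
    """Evaluate every (Lx, N%) grid cell; records are re-encoded from the
    raw sequences for each Lx. The best cell maximizes mean MCC."""
    if not lx_values or not n_values:
        raise ValueError("grid must contain at least one (Lx, N%) cell")
    reports: dict[tuple[int, float], CVReport] = {}
    for lx in lx_values:
        cell_enc = (replace(enc_cfg, Lx=lx) if enc_cfg is not None
                    else EncoderConfig(Lx=lx))
        for n in n_values:
            cell_aug = replace(aug_cfg, n_percent=n)
            cell_cv = replace(cv_cfg, augment=n > 0)
            reports[(lx, float(n))] = run_cv(
                records, table, LengthConfig(Lx=lx), cell_enc,
                model_cfg, cell_cv, cell_aug)
    best = max(reports, key=lambda key: (reports[key].mean["mcc"],
                                         -lx_values.index(key[0])))
    return GridResult(reports, best)


def run_ablation(
    records: Sequence[PeptideRecord],
    table: PropertyTable,
    combos: Sequence[Sequence[str]] = (
        ("bpf",), ("aaindex",), ("aac",),
        ("bpf", "aaindex"), ("bpf", "aac"), ("aaindex", "aac"),
        ("bpf", "aaindex", "aac"),
    ),
    classifiers: Sequence[str] = ("ADA",),
    length_cfg: LengthConfig = LengthConfig(),
    enc_cfg: EncoderConfig | None = None,
    model_cfg: ModelConfig = ModelConfig(),
    cv_cfg: CVConfig = CVConfig(),
    aug_cfg: AugmentationConfig = AugmentationConfig(),
    augmentation: Sequence[bool] = (False, True),
) -> pd.DataFrame:
    """Feature-combination x classifier x augmentation sweep; one CV row
    per cell with the mean metrics."""
    if not combos or any(not c for c in combos):
        raise ValueError("combos must be non-empty feature subsets")
    rows = []
    for combo in combos:
        combo = tuple(combo)
        for name in classifiers:
            for aug_on in augmentation:
                cell_cv = replace(cv_cfg, feature_blocks=combo, augment=aug_on)
                cell_model = replace(model_cfg, classifier=name)
                report = run_cv(records, table, length_cfg, enc_cfg,
                                cell_model, cell_cv, aug_cfg)
                rows.append({
                    "features": "+".join(b.upper() for b in combo),
                    "classifier": name,
                    "augmented": aug_on,
                    **{k.upper(): round(report.mean[k], 4)
                       for k in METRIC_KEYS},
                })
    return pd.DataFrame(rows)


__all__ = ["CVConfig", "CVReport", "GridResult",
           "run_cv", "run_grid", "run_ablation", "METRIC_KEYS"]
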