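"""Minimum-redundancy maximum-relevance (mRMR) column selection.

Greedy forward selection over the raw physicochemical encoding: the
first pick maximizes relevance to the binary label; every later pick
maximizes relevance minus the mean redundancy with the columns already
chosen (the difference criterion). Three scoring variants are provided:

``corr`` (default)
    relevance = |point-biserial Pearson correlation| between column and
    binary label; redundancy = |Pearson correlation| between columns.
    Both terms live in [0, 1], so the difference criterion penalizes an
    exact duplicate of an already-selected column below any weakly
    informative one. For binary labels this relevance is a monotone
    transform of the ANOVA F statistic, so single-column ranking is
    unchanged; unlike F it cannot blow up to infinity on a perfectly
    separating column.
``f_stat``
    classic FCD: relevance = one-way ANOVA F statistic (unbounded;
    perfect separators are capped at a large sentinel), redundancy as
    above.
``mi``
    relevance and redundancy are mutual information after quantile
    binning of each column.

Criterion ties break toward the lower mean redundancy, then the lower
column index, so selection is fully deterministic and an exact duplicate
of a selected column (whose relevance and redundancy cancel exactly)
always loses a tie to a less redundant candidate. Zero-variance columns
get relevance 0 and redundancy 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.metrics import mutual_info_score

from .io import matrix_fingerprint


@dataclass(frozen=True)
class SelectionModel:
    """A fitted column selector.

    ``selected_indices`` is ordered by selection step; ``scores`` holds
    the criterion value at each step. ``fingerprint`` identifies the
    training matrix so downstream encoders can detect mismatched reuse.
    """

    selected_indices: tuple[int, ...]
    scores: tuple[float, ...]
    n_features_in: int
    method: str = "corr"
    fingerprint: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.selected_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selected indices must be distinct")
        if any(i < 0 or i >= self.n_features_in for i in idx):
            raise ValueError("selected index out of range")
        object.__setattr__(self, "selected_indices", idx)
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "selected_indices": list(self.selected_indices),
            "scores": list(self.scores),
            "n_features_in": self.n_features_in,
            "method": self.method,
            "fingerprint": self.fingerprint,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SelectionModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(tuple(d["selected_indices"]), tuple(d["scores"]),
                   d["n_features_in"], d.get("method", "corr"),
                   d.get("fingerprint", ""))


def _quantile_bin(col: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(col, np.unique(edges))


def _relevance(X: np.ndarray, y: np.ndarray, method: str,
               n_bins: int) -> np.ndarray:
    if method == "corr":
        Xc = X - X.mean(axis=0)
        yc = (y - y.mean()).astype(float)
        denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(Xc.T @ yc) / denom
        return np.nan_to_num(r, nan=0.0)
    if method == "f_stat":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, _ = f_classif(X, y)
        # a perfectly separating column has zero within-class variance
        return np.nan_to_num(f, nan=0.0, posinf=1e12)
    rel = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        rel[j] = mutual_info_score(y, _quantile_bin(X[:, j], n_bins))
    return rel


def fit_mrmr(X: np.ndarray, y: np.ndarray, n_selected: int,
             method: str = "corr", n_bins: int = 10) -> SelectionModel:
    """Greedily select *n_selected* columns of *X* by the mRMR difference
    criterion against binary labels *y*.

    Raises if only one class is present, if *n_selected* exceeds the
    column count, or if no column carries any label signal (constant
    matrix): with every relevance zero any pick would be arbitrary.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("mRMR needs at least two samples and both classes")
    n, D = X.shape
    if not 1 <= n_selected <= D:
        raise ValueError(f"n_selected must be in [1, {D}]")
    if method not in ("corr", "f_stat", "mi"):
        raise ValueError("method must be 'corr', 'f_stat' or 'mi'")

    rel = _relevance(X, y, method, n_bins)
    if np.all(rel == 0):
        raise ValueError("no column is relevant to the label "
                         "(constant or label-independent matrix)")

    # running sum of redundancy of every column against the selected set
    red_sum = np.zeros(D)
    selected: list[int] = []
    scores: list[float] = []
    available = np.ones(D, dtype=bool)

    if method in ("corr", "f_stat"):
        Xc = X - X.mean(axis=0)
        norms = np.sqrt((Xc ** 2).sum(axis=0))
    else:
        binned = np.column_stack([_quantile_bin(X[:, j], n_bins)
                                  for j in range(D)])

    for step in range(n_selected):
        red_mean = red_sum / step if step else np.zeros(D)
        crit = np.where(available, rel - red_mean, -np.inf)
        best = crit.max()
        tol = 1e-12 * max(1.0, abs(best))
        tied = np.flatnonzero(crit >= best - tol)
        # ties: lower redundancy wins, then lower index
        j = int(tied[np.lexsort((tied, red_mean[tied]))[0]])
        selected.append(j)
        scores.append(float(crit[j]))
        available[j] = False
        if step + 1 < n_selected:
            if method in ("corr", "f_stat"):
                denom = norms * norms[j]
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = np.abs(Xc.T @ Xc[:, j]) / denom
                red_sum += np.nan_to_num(corr, nan=0.0)
            else:
                red_sum += np.array([
                    mutual_info_score(binned[:, k], binned[:, j])
                    for k in range(D)
                ])

    return SelectionModel(tuple(selected), tuple(scores), D, method,
                          fingerprint=matrix_fingerprint(X))


def apply_selection(X: np.ndarray, model: SelectionModel) -> np.ndarray:
    """Extract the selected columns, in selection order."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"selection was fitted on {model.n_features_in}"
        )
    return X[:, list(model.selected_indices)]


__all__ = ["SelectionModel", "fit_mrmr", "apply_selection"]
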