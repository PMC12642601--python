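"""Split-half cross-validated representational similarity analysis.

For a chosen trial grouping (action, hand, direction, or the full 12
conditions) and comparison (within intention, within observation, or
cross-format), each trial is reshaped into a feature vector by
concatenating the 100 ms bins of a fixed window (default 1-2 s) across
units.  For each random split, trials are halved within every condition;
half-averaged condition vectors are correlated (Pearson) between the two
independent halves -- within a format for the within-format matrices and
between formats for the cross matrix -- and the matrices are averaged over
splits.  The structure statistic is mean(diagonal) - mean(off-diagonal);
its null distribution comes from shuffling condition labels independently
within each format before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import INTENTION, OBSERVATION, TaskDesign
from .session import BinnedRates

COMPARISONS = (INTENTION, OBSERVATION, "cross")


@dataclass
class RSAResult:
    """Averaged similarity matrix plus the diagonal - off-diagonal statistic."""

    matrix: np.ndarray
    levels: Tuple[str, ...]
    comparison: str
    grouping: str
    structure_stat: float
    n_splits: int
    window: Tuple[float, float]


def _group_levels(trials: pd.DataFrame, design: TaskDesign, grouping: str) -> Tuple[np.ndarray, Tuple[str, ...]]:
    if grouping == "all12" or grouping == "condition":
        labels = design.condition_labels(trials).to_numpy()
        levels = tuple("|".join(c) for c in design.conditions())
    else:
        labels = trials[grouping].astype(str).to_numpy()
        levels = tuple(design.factors[grouping])
    return labels, levels


def _features(
    rates: BinnedRates, window: Tuple[float, float], unit_idx: np.ndarray
) -> np.ndarray:
    bins = rates.bins_in(window)
    X = rates.values[np.ix_(unit_idx, np.arange(rates.n_trials), bins)]
    # trials x (units * bins): concatenate time and unit dimensions
    return X.transpose(1, 0, 2).reshape(rates.n_trials, -1)


def _unit_indices(rates: BinnedRates, units: Optional[Sequence[str]]) -> np.ndarray:
    if units is None:
        return np.arange(rates.n_units)
    uid = list(rates.unit_ids)
    return np.array([uid.index(u) for u in units], dtype=int)


def _split_mean_pairs(
    X: np.ndarray,
    labels: np.ndarray,
    levels: Sequence[str],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Half-averaged pattern per level for two disjoint halves (A, B)."""
    A = np.empty((len(levels), X.shape[1]))
    B = np.empty_like(A)
    for i, lev in enumerate(levels):
        idx = np.where(labels == lev)[0]
        if idx.size < 2:
            raise ValueError(f"condition {lev!r} has fewer than 2 trials")
        perm = rng.permutation(idx)
        half = (perm.size + 1) // 2  # odd counts: extra trial on side A
        A[i] = X[perm[:half]].mean(axis=0)
        B[i] = X[perm[half:]].mean(axis=0)
    return A, B


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    Az /= np.linalg.norm(Az, axis=1, keepdims=True) + 1e-300
    Bz /= np.linalg.norm(Bz, axis=1, keepdims=True) + 1e-300
    return Az @ Bz.T


def structure_stat(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(np.diag(matrix).mean() - matrix[off].mean())


def _rsa_matrix_once(
    X: np.ndarray,
    fmt: np.ndarray,
    labels: np.ndarray,
    levels: Sequence[str],
    comparison: str,
    n_splits: int,
    rng: np.random.Generator,
) -> np.ndarray:
    acc = np.zeros((len(levels), len(levels)))
    int_idx = fmt == INTENTION
    obs_idx = fmt == OBSERVATION
    for _ in range(n_splits):
        if comparison == "cross":
            A, _ = _split_mean_pairs(X[int_idx], labels[int_idx], levels, rng)
            _, B = _split_mean_pairs(X[obs_idx], labels[obs_idx], levels, rng)
        else:
            sel = int_idx if comparison == INTENTION else obs_idx
            A, B = _split_mean_pairs(X[sel], labels[sel], levels, rng)
        acc += _corr_matrix(A, B)
    return acc / n_splits


def split_half_rsa(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    units: Optional[Sequence[str]] = None,
    grouping: str = "action",
    comparison: str = "cross",
    n_splits: int = 500,
    window: Tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
) -> RSAResult:
    """Split-half RSA matrix averaged over ``n_splits`` random splits."""
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {COMPARISONS}")
    inc = trials["included"].to_numpy(dtype=bool)
    sub = trials[inc]
    X = _features(rates, window, _unit_indices(rates, units))[inc]
    labels, levels = _group_levels(sub, design, grouping)
    fmt = sub["format"].to_numpy()
    rng = np.random.default_rng(seed)
    M = _rsa_matrix_once(X, fmt, labels, levels, comparison, n_splits, rng)
    return RSAResult(
        matrix=M,
        levels=levels,
        comparison=comparison,
        grouping=grouping,
        structure_stat=structure_stat(M),
        n_splits=n_splits,
        window=window,
    )


def rsa_permutation_test(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    units: Optional[Sequence[str]] = None,
    grouping: str = "action",
    comparison: str = "cross",
    n_splits: int = 500,
    n_perm: int = 1000,
    window: Tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
) -> Dict[str, object]:
    """Permutation p for the structure statistic.

    Condition labels are shuffled independently within each format before
    trial splitting; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    res = split_half_rsa(rates, trials, design, units, grouping, comparison, n_splits, window, seed)
    inc = trials["included"].to_numpy(dtype=bool)
    sub = trials[inc]
    X = _features(rates, window, _unit_indices(rates, units))[inc]
    labels, levels = _group_levels(sub, design, grouping)
    fmt = sub["format"].to_numpy()
    rng = np.random.default_rng(seed + 1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        lab = labels.copy()
        for f in np.unique(fmt):
            m = fmt == f
            lab[m] = rng.permutation(lab[m])
        M = _rsa_matrix_once(X, fmt, lab, levels, comparison, n_splits, rng)
        null[k] = structure_stat(M)
    p = float((1 + (null >= res.structure_stat).sum()) / (n_perm + 1))
    return {"result": res, "p": p, "null_stats": null, "observed": res.structure_stat}


def _lower_triangle(M: np.ndarray, include_diag: bool = False) -> np.ndarray:
    k = 0 if include_diag else -1
    return M[np.tril_indices_from(M, k=k)]


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def window_robustness(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    units: Optional[Sequence[str]] = None,
    grouping: str = "action",
    comparison: str = "cross",
    windows: Sequence[Tuple[float, float]] = ((0.0, 1.0), (0.5, 1.0), (1.5, 2.5), (2.0, 3.0)),
    ref_window: Tuple[float, float] = (1.0, 2.0),
    n_splits: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """RSA per alternative window + lower-triangle correlation to the
    reference-window matrix (NaN when a triangle is degenerate/constant)."""
    ref = split_half_rsa(rates, trials, design, units, grouping, comparison, n_splits, ref_window, seed)
    rows = []
    for w in windows:
        res = split_half_rsa(rates, trials, design, units, grouping, comparison, n_splits, tuple(w), seed)
        r = _safe_pearson(_lower_triangle(res.matrix), _lower_triangle(ref.matrix))
        rows.append({"window": f"[{w[0]},{w[1]})", "r_vs_reference": r, "structure_stat": res.structure_stat})
    return pd.DataFrame(rows)


def all_units_control(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    relevant_units: Sequence[str],
    grouping: str = "action",
    comparison: str = "cross",
    n_splits: int = 500,
    window: Tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
) -> Dict[str, object]:
    """Correlation between the all-units and relevant-units RSA matrices
    (lower triangles plus diagonals)."""
    if len(relevant_units) == 0:
        raise ValueError("relevant unit set is empty")
    a = split_half_rsa(rates, trials, design, None, grouping, comparison, n_splits, window, seed)
    b = split_half_rsa(rates, trials, design, relevant_units, grouping, comparison, n_splits, window, seed)
    r = _safe_pearson(_lower_triangle(a.matrix, True), _lower_triangle(b.matrix, True))
    return {"r": r, "all_units": a, "relevant_units": b}
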