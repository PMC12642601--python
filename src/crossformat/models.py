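"""Cross-format linear-model taxonomy of single units.

Each unit's window-averaged responses (1-2 s after trial onset) across the
12 conditions x 2 formats are fit by a family of linear models that differ
in which task factors they use and whether coefficients are shared across
the intention and observation formats:

``null`` (constant only), ``invariant`` (action + hand + direction, shared),
``action3`` / ``hand`` / ``direction`` (one shared factor), ``action6``
(the six action x direction combinations, shared), ``mixed`` (all main
effects and interactions, i.e. the full 12 condition cells, shared),
``idiosyncratic`` (full condition cells with separate coefficients per
format), and ``single_intention`` / ``single_observation`` (factor terms in
one format only, per-format intercepts).

Units are assigned to the model with the highest pooled five-fold
cross-validated R-squared (stratified over condition x format cells, ties
broken toward fewer parameters), then gated: cv R-squared > 0.01, a
trial-shuffle permutation p < 0.05 after Benjamini-Hochberg FDR across
units, and best model not the null.  Units failing any gate are labeled
``unselective``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .design import INTENTION, OBSERVATION, TaskDesign
from .session import BinnedRates

MODEL_NAMES = (
    "null",
    "invariant",
    "action3",
    "hand",
    "direction",
    "action6",
    "mixed",
    "idiosyncratic",
    "single_intention",
    "single_observation",
)

SINGLE_FORMAT_MODELS = ("single_intention", "single_observation")


def window_means(rates: BinnedRates, window: Tuple[float, float] = (1.0, 2.0)) -> np.ndarray:
    """Per-unit, per-trial mean net rate over ``window`` (units x trials)."""
    bins = rates.bins_in(window)
    if bins.size == 0:
        raise ValueError(f"analysis window {window} contains no bins")
    return rates.values[:, :, bins].mean(axis=2)


def condition_means(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    window: Tuple[float, float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Mean net rate per (format, condition) cell; units x 24 columns.

    Raises if any condition x format cell has no included trials, naming it.
    """
    Y = window_means(rates, window)
    inc = trials["included"].to_numpy(dtype=bool)
    labels = design.condition_labels(trials)
    cols = {}
    for fmt in design.formats:
        for cond in design.conditions():
            name = "|".join(cond)
            sel = inc & (trials["format"] == fmt).to_numpy() & (labels == name).to_numpy()
            if not sel.any():
                raise ValueError(f"missing cell: format={fmt!r}, condition={name!r}")
            cols[(fmt, name)] = Y[:, sel].mean(axis=1)
    uid = rates.unit_ids if rates.unit_ids is not None else np.arange(rates.n_units).astype(str)
    out = pd.DataFrame(cols, index=uid)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["format", "condition"])
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _dummies(values: pd.Series, levels: Sequence[str]) -> np.ndarray:
    """Drop-first dummy coding with a declared level order."""
    cat = pd.Categorical(values, categories=list(levels))
    d = pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float)
    return d


def _cell_dummies(trials: pd.DataFrame, design: TaskDesign) -> np.ndarray:
    labels = design.condition_labels(trials)
    order = ["|".join(c) for c in design.conditions()]
    return _dummies(labels, order)


def build_design_matrix(model: str, trials: pd.DataFrame, design: TaskDesign) -> np.ndarray:
    """Trial-level design matrix (including intercept) for one model."""
    n = len(trials)
    intercept = np.ones((n, 1))
    factors = design.factors
    main = {f: _dummies(trials[f], levels) for f, levels in factors.items()}
    additive = np.hstack([main[f] for f in factors])
    fmt_col = (trials["format"] == OBSERVATION).to_numpy(dtype=float)[:, None]
    if model == "null":
        return intercept
    if model == "invariant":
        return np.hstack([intercept, additive])
    if model == "action3":
        return np.hstack([intercept, main["action"]])
    if model == "hand":
        return np.hstack([intercept, main["hand"]])
    if model == "direction":
        if "direction" not in factors:
            raise ValueError("design has no direction factor")
        return np.hstack([intercept, main["direction"]])
    if model == "action6":
        if "direction" not in factors:
            raise ValueError("design has no direction factor")
        combo = trials["action"].astype(str) + "|" + trials["direction"].astype(str)
        order = [f"{a}|{d}" for a in factors["action"] for d in factors["direction"]]
        return np.hstack([intercept, _dummies(combo, order)])
    if model == "mixed":
        return np.hstack([intercept, _cell_dummies(trials, design)])
    if model == "idiosyncratic":
        cells = _cell_dummies(trials, design)
        is_int = (trials["format"] == INTENTION).to_numpy(dtype=float)[:, None]
        is_obs = 1.0 - is_int
        return np.hstack([intercept, fmt_col, cells * is_int, cells * is_obs])
    if model in ("single_intention", "single_observation"):
        which = INTENTION if model == "single_intention" else OBSERVATION
        mask = (trials["format"] == which).to_numpy(dtype=float)[:, None]
        return np.hstack([intercept, fmt_col, additive * mask])
    raise ValueError(f"unknown model {model!r}")


def model_param_count(model: str, design: TaskDesign) -> int:
    levels = {f: len(v) for f, v in design.factors.items()}
    n_cells = int(np.prod(list(levels.values())))
    add = sum(v - 1 for v in levels.values())
    return {
        "null": 1,
        "invariant": 1 + add,
        "action3": levels.get("action", 2),
        "hand": 1 + (levels.get("hand", 2) - 1),
        "direction": 1 + (levels.get("direction", 2) - 1),
        "action6": 1 + (levels.get("action", 1) * levels.get("direction", 1) - 1),
        "mixed": n_cells,
        "idiosyncratic": 2 * n_cells,
        "single_intention": 2 + add,
        "single_observation": 2 + add,
    }[model]


def applicable_models(design: TaskDesign) -> List[str]:
    out = []
    for m in MODEL_NAMES:
        if m in ("direction", "action6") and "direction" not in design.factors:
            continue
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# cross-validated fitting
# ---------------------------------------------------------------------------


def _cell_labels(trials: pd.DataFrame, design: TaskDesign) -> np.ndarray:
    return (trials["format"].astype(str) + "#" + design.condition_labels(trials)).to_numpy()


def make_folds(
    trials: pd.DataFrame, design: TaskDesign, folds: int = 5, seed: int = 0, n_repeats: int = 1
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified folds balanced over the condition x format cells.

    With ``n_repeats > 1`` the 5-fold assignment is redrawn that many times
    and all folds are concatenated (repeated stratified k-fold); pooling the
    held-out sums of squares over repeats stabilizes model selection among
    nested models without changing what is estimated.
    """
    labels = _cell_labels(trials, design)
    min_cell = pd.Series(labels).value_counts().min()
    if min_cell < folds:
        warnings.warn(f"smallest cell has {min_cell} trials; reducing folds {folds} -> {min_cell}")
        folds = int(min_cell)
    if folds < 2:
        raise ValueError("need at least 2 trials per condition x format cell")
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 100003 * r)
        out.extend(skf.split(np.zeros(len(labels)), labels))
    return out


def _pooled_cv_r2(
    X: np.ndarray, Y: np.ndarray, splits: Sequence[Tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Pooled held-out R-squared per column of ``Y`` (trials x series).

    Per fold: OLS on training trials; held-out residual and total sums of
    squares are accumulated over folds (totals about the training mean) and
    pooled into R^2 = 1 - SS_res / SS_tot.  Can be negative.
    """
    ss_res = np.zeros(Y.shape[1])
    ss_tot = np.zeros(Y.shape[1])
    for tr, te in splits:
        P = np.linalg.pinv(X[tr])
        B = P @ Y[tr]
        resid = Y[te] - X[te] @ B
        ss_res += (resid**2).sum(axis=0)
        ss_tot += ((Y[te] - Y[tr].mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return np.where(ss_tot > 0, r2, 0.0)


def fit_models_cv(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    window: Tuple[float, float] = (1.0, 2.0),
    folds: int = 5,
    seed: int = 0,
    models: Optional[Sequence[str]] = None,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Pooled CV R-squared per unit and model (units x models DataFrame)."""
    models = list(models) if models is not None else applicable_models(design)
    inc = trials["included"].to_numpy(dtype=bool)
    sub = trials[inc]
    Y = window_means(rates, window)[:, inc].T  # trials x units
    splits = make_folds(sub, design, folds, seed, n_repeats)
    out = {}
    for m in models:
        X = build_design_matrix(m, sub, design)
        out[m] = _pooled_cv_r2(X, Y, splits)
    uid = rates.unit_ids if rates.unit_ids is not None else np.arange(rates.n_units).astype(str)
    return pd.DataFrame(out, index=uid)


def best_model(cv_r2_row: pd.Series, design: TaskDesign) -> str:
    """Highest CV R-squared; exact ties go to the fewer-parameter model."""
    items = sorted(cv_r2_row.items(), key=lambda kv: model_param_count(kv[0], design))
    best_name, best_val = items[0]
    for name, val in items[1:]:
        if val > best_val:
            best_name, best_val = name, val
    return best_name


def permutation_gate(
    y: np.ndarray,
    X,
    splits: Sequence[Tuple[np.ndarray, np.ndarray]],
    observed_r2: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """One-tailed permutation p for one unit's winning model.

    The response vector is shuffled across trials with the design fixed;
    p = (1 + #{null R^2 >= observed}) / (n_perm + 1).  ``X`` is the winning
    model's design matrix, or a list of matrices, in which case each shuffle
    is scored by the best R^2 over the whole family (full-refit variant,
    which also nulls out the selection step).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = y.size
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[idx].T  # trials x n_perm
    designs = X if isinstance(X, (list, tuple)) else [X]
    null = np.max([_pooled_cv_r2(Xm, Yp, splits) for Xm in designs], axis=0)
    return float((1 + (null >= observed_r2).sum()) / (n_perm + 1))


@dataclass
class UnitClassification:
    """Per-unit taxonomy with the three-gate selectivity rule applied."""

    table: pd.DataFrame  # unit_id, best_model, cv_r2, perm_p, fdr_significant, label
    q: float
    r2_threshold: float

    def label_counts(self) -> pd.Series:
        return self.table["label"].value_counts()


def classify_population(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    window: Tuple[float, float] = (1.0, 2.0),
    folds: int = 5,
    n_perm: int = 1000,
    q: float = 0.05,
    r2_threshold: float = 0.01,
    seed: int = 0,
    perm_refit_all: bool = False,
    n_repeats: int = 10,
) -> UnitClassification:
    """Fit the model family, permutation-gate, FDR-correct, and label units.

    ``perm_refit_all`` re-fits the whole model family on every shuffle (the
    null then accounts for model selection); the default permutes only the
    winning model, the literal reading of the published procedure.
    """
    inc = trials["included"].to_numpy(dtype=bool)
    sub = trials[inc]
    Y = window_means(rates, window)[:, inc]
    splits = make_folds(sub, design, folds, seed, n_repeats)
    models = applicable_models(design)
    cv = fit_models_cv(rates, trials, design, window, folds, seed, models, n_repeats)
    rows = []
    designs = {m: build_design_matrix(m, sub, design) for m in models}
    all_designs = [designs[m] for m in models]
    for u, (uid, row) in enumerate(cv.iterrows()):
        bm = best_model(row, design)
        r2 = float(row[bm])
        Xp = all_designs if perm_refit_all else designs[bm]
        p = permutation_gate(Y[u], Xp, splits, r2, n_perm=n_perm, seed=seed + 7919 * (u + 1))
        rows.append({"unit_id": uid, "best_model": bm, "cv_r2": r2, "perm_p": p})
    table = pd.DataFrame(rows)
    rej, _, _, _ = multipletests(table["perm_p"], alpha=q, method="fdr_bh")
    table["fdr_significant"] = rej
    ok = (table["cv_r2"] > r2_threshold) & table["fdr_significant"] & (table["best_model"] != "null")
    table["label"] = np.where(ok, table["best_model"], "unselective")
    return UnitClassification(table=table, q=q, r2_threshold=r2_threshold)


def task_relevant_subset(classification: UnitClassification) -> List[str]:
    """Units neither unselective nor best fit by a single-format model."""
    t = classification.table
    bad = set(SINGLE_FORMAT_MODELS) | {"unselective"}
    return t.loc[~t["label"].isin(bad), "unit_id"].tolist()
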