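"""Time-resolved LDA decoding within and across formats.

Within-format decoding averages adjacent 100 ms bins into non-overlapping
200 ms windows, then runs 10-fold stratified cross-validation; within each
fold PCA is fitted on the training trials stacked across all windows
(components to 95% variance, capped at 50), both sets are projected, and a
linear discriminant classifier is trained/tested per window.  Cross-time
decoding trains at each window and tests at all windows, yielding a
train x test generalization matrix whose diagonal equals the standard
timecourse.  Cross-format decoding trains on every trial of one format
(per 100 ms bin, PCA fixed at the top 50 components) and tests on the
other format at every bin, with per-cell permutation p-values from
shuffled test labels and Bonferroni correction over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .design import (
    DISSOCIATION_NOPROBE,
    DISSOCIATION_PROBE,
    INTENTION,
    OBSERVATION,
    TaskDesign,
    derive_video_labels,
)
from .session import BinnedRates


@dataclass
class DecodingResult:
    accuracies: np.ndarray           # mean accuracy per window
    per_fold: np.ndarray             # folds x windows
    window_centers_s: np.ndarray
    classes: np.ndarray
    confusion: np.ndarray            # row-normalized, at the peak window
    label_def: str = ""

    @property
    def chance(self) -> float:
        return 1.0 / len(self.classes)

    @property
    def peak_window_s(self) -> float:
        return float(self.window_centers_s[int(np.argmax(self.accuracies))])

    @property
    def peak_accuracy(self) -> float:
        return float(self.accuracies.max())


@dataclass
class GeneralizationMap:
    matrix: np.ndarray               # train windows x test windows
    train_centers_s: np.ndarray
    test_centers_s: np.ndarray
    direction: str = "within"
    p: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None  # True => significant after Bonferroni
    n_perm: int = 0
    alpha: float = 0.05

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum()) if self.mask is not None else 0


def get_labels(trials: pd.DataFrame, design: TaskDesign, label_def: str) -> np.ndarray:
    """Trial labels for a named classification problem."""
    if label_def in design.factor_names:
        return trials[label_def].astype(str).to_numpy()
    if label_def in ("condition", "condition12", "condition16"):
        return design.condition_labels(trials).to_numpy()
    if label_def == "instructed":
        return (trials["action"].astype(str) + "|" + trials["hand"].astype(str)).to_numpy()
    if label_def == "video":
        v = derive_video_labels(trials)
        return (v["video_action"].astype(str) + "|" + v["video_hand"].astype(str)).to_numpy()
    if label_def == "trialtype16":
        return (
            trials["action"].astype(str)
            + "|"
            + trials["hand"].astype(str)
            + "|"
            + trials["conflict"].astype(str)
        ).to_numpy()
    if label_def in trials.columns:
        return trials[label_def].astype(str).to_numpy()
    raise ValueError(f"unknown label definition {label_def!r}")


def windowed_features(
    rates: BinnedRates, window_bins: int = 2, t_min: float = 0.0, t_max: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """(trials x features x windows) array of window-mean net rates."""
    start = int(np.searchsorted(rates.bin_centers_s, t_min))
    stop = rates.n_bins if t_max is None else int(np.searchsorted(rates.bin_centers_s, t_max))
    starts = np.arange(start, stop - window_bins + 1, window_bins)
    X = np.stack([rates.values[:, :, s : s + window_bins].mean(axis=2) for s in starts], axis=2)
    centers = rates.bin_centers_s[starts] - rates.bin_width_s / 2 + window_bins * rates.bin_width_s / 2
    return X.transpose(1, 0, 2), centers  # trials x units x windows


def _choose_k(pca: PCA, var_keep: Optional[float], max_pc: int) -> int:
    if var_keep is None:
        return min(max_pc, pca.n_components_)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_keep) + 1)
    return min(k, max_pc, pca.n_components_)


def _fit_pca(X_stack: np.ndarray, max_pc: int) -> PCA:
    n_comp = min(X_stack.shape[0], X_stack.shape[1])
    return PCA(n_components=n_comp, svd_solver="full").fit(X_stack)


def _engine(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    var_keep: Optional[float],
    max_pc: int,
    seed: int,
    cross_time: bool,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared CV core: per-fold train x test accuracy plus pooled confusion.

    Returns (acc: folds x W x W [or folds x W diagonal when not cross_time],
    classes, confusion at the diagonal peak).
    """
    classes, y_int = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("decoding needs at least two classes")
    counts = np.bincount(y_int)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} trials; need >= folds ({folds})"
        )
    n_tr, n_feat, n_win = X.shape
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = np.zeros((folds, n_win, n_win)) if cross_time else np.zeros((folds, n_win))
    pred_peak: List[Tuple[np.ndarray, np.ndarray]] = []
    preds_all = np.full((folds, n_win, n_tr), -1, dtype=int)
    for f, (tr, te) in enumerate(skf.split(X[:, :, 0], y_int)):
        stack = X[tr].transpose(0, 2, 1).reshape(-1, n_feat)
        pca = _fit_pca(stack, max_pc)
        k = _choose_k(pca, var_keep, max_pc)
        W = pca.components_[:k]
        mu = pca.mean_
        proj = lambda A: (A - mu) @ W.T
        for w in range(n_win):
            lda = LinearDiscriminantAnalysis()
            lda.fit(proj(X[tr, :, w]), y_int[tr])
            if cross_time:
                for v in range(n_win):
                    pred = lda.predict(proj(X[te, :, v]))
                    acc[f, w, v] = (pred == y_int[te]).mean()
                    if v == w:
                        preds_all[f, w, te] = pred
            else:
                pred = lda.predict(proj(X[te, :, w]))
                acc[f, w] = (pred == y_int[te]).mean()
                preds_all[f, w, te] = pred
    diag = acc.mean(axis=0)
    diag = np.diag(diag) if cross_time else diag
    peak = int(np.argmax(diag))
    # confusion pooled over folds at the peak window (each trial tested once)
    conf = np.zeros((classes.size, classes.size))
    for f in range(folds):
        m = preds_all[f, peak] >= 0
        np.add.at(conf, (y_int[m], preds_all[f, peak, m]), 1)
    row = conf.sum(axis=1, keepdims=True)
    conf = np.divide(conf, row, out=np.zeros_like(conf), where=row > 0)
    return acc, classes, conf


def decode_timecourse(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    label_def: str = "action",
    format: Optional[str] = None,
    window_bins: int = 2,
    folds: int = 10,
    var_keep: Optional[float] = 0.95,
    max_pc: int = 50,
    seed: int = 0,
    t_max: Optional[float] = None,
) -> DecodingResult:
    """Within-format time-resolved decoding (PCA + LDA, stratified CV)."""
    sel = trials["included"].to_numpy(dtype=bool)
    if format is not None:
        sel = sel & (trials["format"] == format).to_numpy()
    X, centers = windowed_features(rates, window_bins, t_max=t_max)
    y = get_labels(trials, design, label_def)
    acc, classes, conf = _engine(X[sel], y[sel], folds, var_keep, max_pc, seed, cross_time=False)
    return DecodingResult(
        accuracies=acc.mean(axis=0),
        per_fold=acc,
        window_centers_s=centers,
        classes=classes,
        confusion=conf,
        label_def=label_def,
    )


def cross_time_decode(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    label_def: str = "action",
    format: Optional[str] = None,
    window_bins: int = 2,
    folds: int = 10,
    var_keep: Optional[float] = 0.95,
    max_pc: int = 50,
    seed: int = 0,
    t_max: Optional[float] = None,
) -> GeneralizationMap:
    """Train at each window, test at all windows (within-format)."""
    sel = trials["included"].to_numpy(dtype=bool)
    if format is not None:
        sel = sel & (trials["format"] == format).to_numpy()
    X, centers = windowed_features(rates, window_bins, t_max=t_max)
    y = get_labels(trials, design, label_def)
    acc, _, _ = _engine(X[sel], y[sel], folds, var_keep, max_pc, seed, cross_time=True)
    return GeneralizationMap(
        matrix=acc.mean(axis=0), train_centers_s=centers, test_centers_s=centers, direction="within"
    )


def _perm_accuracies(
    preds: np.ndarray, y_int: np.ndarray, n_classes: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Accuracy of fixed predictions against shuffled labels.

    ``preds`` is (cells, n_trials); one map-wide label shuffle per iteration.
    Returns (cells, n_perm).
    """
    n = y_int.size
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y_int[idx]  # n_perm x n
    acc = np.zeros((preds.shape[0], n_perm))
    for c in range(n_classes):
        acc += (preds == c).astype(np.float32) @ (Yp == c).astype(np.float32).T
    return acc / n


def cross_format_decode(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    label_def: str = "action",
    train_format: str = INTENTION,
    n_perm: int = 1000,
    max_pc: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    window_bins: int = 1,
) -> GeneralizationMap:
    """Train on one format, test on the other, per time bin.

    PCA (top ``max_pc`` components, fitted on the full training-format data
    across all bins) defines a common space; an LDA trained at each training
    bin is evaluated at every test bin.  Per-cell permutation p-values come
    from shuffling test-set labels (one map-wide shuffle per iteration) and
    are Bonferroni-corrected over all train x test cells.
    """
    test_format = OBSERVATION if train_format == INTENTION else INTENTION
    inc = trials["included"].to_numpy(dtype=bool)
    tr_sel = inc & (trials["format"] == train_format).to_numpy()
    te_sel = inc & (trials["format"] == test_format).to_numpy()
    if not tr_sel.any() or not te_sel.any():
        raise ValueError("both formats must be present")
    X, centers = windowed_features(rates, window_bins)
    y = get_labels(trials, design, label_def)
    classes, y_int = np.unique(y, return_inverse=True)
    n_win = X.shape[2]
    stack = X[tr_sel].transpose(0, 2, 1).reshape(-1, X.shape[1])
    pca = _fit_pca(stack, max_pc)
    k = min(max_pc, pca.n_components_)
    W, mu = pca.components_[:k], pca.mean_
    proj = lambda A: (A - mu) @ W.T
    yte = y_int[te_sel]
    preds = np.zeros((n_win * n_win, yte.size), dtype=int)
    for w in range(n_win):
        lda = LinearDiscriminantAnalysis()
        lda.fit(proj(X[tr_sel, :, w]), y_int[tr_sel])
        for v in range(n_win):
            preds[w * n_win + v] = lda.predict(proj(X[te_sel, :, v]))
    obs = (preds == yte).mean(axis=1)
    rng = np.random.default_rng(seed)
    null = _perm_accuracies(preds, yte, classes.size, n_perm, rng)
    p = (1 + (null >= obs[:, None]).sum(axis=1)) / (n_perm + 1)
    n_cells = n_win * n_win
    return GeneralizationMap(
        matrix=obs.reshape(n_win, n_win),
        train_centers_s=centers,
        test_centers_s=centers,
        direction=f"{train_format}->{test_format}",
        p=p.reshape(n_win, n_win),
        mask=(p < alpha / n_cells).reshape(n_win, n_win),
        n_perm=n_perm,
        alpha=alpha,
    )


DISSOCIATION_SOURCES = ("instructed", "video", "trialtype16", "conflict")


def dissociation_decode(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    source: str = "instructed",
    format: Optional[str] = None,
    exclude_probe_period: bool = True,
    **kwargs,
) -> DecodingResult:
    """Decoding with trials relabeled by the instructed cues, the observed
    video, the 16 trial types, or the conflict type (dissociation tasks)."""
    if design.variant not in (DISSOCIATION_NOPROBE, DISSOCIATION_PROBE):
        raise ValueError("dissociation decoding requires a dissociation-variant session")
    if source not in DISSOCIATION_SOURCES:
        raise ValueError(f"source must be one of {DISSOCIATION_SOURCES}")
    t_max = None
    if exclude_probe_period and design.variant == DISSOCIATION_PROBE:
        t_max = design.event_times_s.get("probe_onset", 2.5)
    return decode_timecourse(
        rates, trials, design, label_def=source, format=format, t_max=t_max, **kwargs
    )


def sessionwise_decode(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    label_defs: Sequence[str] = ("action", "hand", "direction"),
    format: Optional[str] = INTENTION,
    **kwargs,
) -> pd.DataFrame:
    """Peak decoding accuracy per session and task variable."""
    rows = []
    for sess, sub in trials.groupby("session_id"):
        idx = sub.index.to_numpy()
        r = BinnedRates(
            rates.values[:, idx], rates.bin_centers_s, rates.bin_width_s,
            rates.baseline_window_s, rates.window_s, rates.unit_ids,
        )
        for ld in label_defs:
            res = decode_timecourse(r, sub.reset_index(drop=True), design, ld, format=format, **kwargs)
            rows.append({"session_id": sess, "variable": ld, "peak_accuracy": res.peak_accuracy})
    return pd.DataFrame(rows)
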