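"""Population-geometry analyses: shared-space PCA trajectories, Procrustes
alignment between formats, and UMAP trial embeddings with condition ellipses.

Condition-averaged timecourses (-0.5 to 2.5 s, 100 ms bins) from both
formats are stacked into one (conditions x time) x units matrix; the top
three principal components of that combined stack define a single shared
space into which every trajectory is projected, so intention and
observation geometry can be compared directly.  Per condition, the
intention and observation trajectories are aligned by classical Procrustes
(optimal translation, rotation -- reflections allowed by default -- and
isotropic scaling); the normalized residual disparity d in [0, 1] measures
cross-format geometric dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .design import INTENTION, OBSERVATION, TaskDesign
from .session import BinnedRates


@dataclass
class TrajectorySet:
    """Per (level, format) trajectories (time x 3) in the shared PC space."""

    trajectories: Dict[Tuple[str, str], np.ndarray]
    components: np.ndarray            # units x 3
    times: np.ndarray
    variance_explained: Dict[str, np.ndarray]  # combined: top-3 fractions; per-format: captured fraction
    grouping: str


@dataclass
class ProcrustesReport:
    table: pd.DataFrame  # level, d
    transforms: Dict[str, dict]


@dataclass
class EmbeddingReport:
    coords: np.ndarray                # trials x 2
    trial_index: np.ndarray
    ellipses: pd.DataFrame            # level, format, cx, cy, axis1/2 (scaled eigvecs)
    seed: int


def _unit_indices(rates: BinnedRates, units: Optional[Sequence[str]]) -> np.ndarray:
    if units is None:
        return np.arange(rates.n_units)
    uid = list(rates.unit_ids)
    return np.array([uid.index(u) for u in units], dtype=int)


def pca_trajectories(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    units: Optional[Sequence[str]] = None,
    grouping: str = "action",
    window: Tuple[float, float] = (-0.5, 2.5),
    n_components: int = 3,
) -> TrajectorySet:
    """Shared-space PC trajectories per (grouping level, format).

    ``rates`` must cover ``window`` (bin it with ``bin_rates(...,
    window=(-0.5, 3.0))`` or similar).  Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    uidx = _unit_indices(rates, units)
    if uidx.size < n_components:
        raise ValueError(f"need >= {n_components} units to span {n_components} components")
    bins = rates.bins_in(window)
    if bins.size == 0 or rates.bin_centers_s[bins[0]] - rates.bin_width_s / 2 > window[0] + 1e-9:
        raise ValueError(f"binned rates do not cover the trajectory window {window}")
    times = rates.bin_centers_s[bins]
    inc = trials["included"].to_numpy(dtype=bool)
    levels = list(design.factors[grouping])
    groups: Dict[Tuple[str, str], np.ndarray] = {}
    for fmt in (INTENTION, OBSERVATION):
        for lev in levels:
            sel = inc & (trials["format"] == fmt).to_numpy() & (trials[grouping] == lev).to_numpy()
            if not sel.any():
                raise ValueError(f"no trials for {grouping}={lev!r} in format {fmt!r}")
            groups[(lev, fmt)] = rates.values[np.ix_(uidx, np.where(sel)[0], bins)].mean(axis=1).T  # time x units
    stack = np.vstack(list(groups.values()))
    mean = stack.mean(axis=0)
    Xc = stack - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = Vt[:n_components].T  # units x k
    for j in range(W.shape[1]):  # sign convention
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    var_total = (Xc**2).sum()
    combined = (S[:n_components] ** 2) / var_total
    ve: Dict[str, np.ndarray] = {"combined": combined}
    for fmt in (INTENTION, OBSERVATION):
        Xf = np.vstack([groups[(lev, fmt)] for lev in levels]) - mean
        ve[fmt] = np.array([((Xf @ W) ** 2).sum() / (Xf**2).sum()])
    trajs = {k: (v - mean) @ W for k, v in groups.items()}
    return TrajectorySet(trajectories=trajs, components=W, times=times, variance_explained=ve, grouping=grouping)


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = True
) -> Tuple[float, dict]:
    """Normalized Procrustes disparity between two trajectories.

    Both inputs (time x dim) are centered and scaled to unit Frobenius norm;
    ``b`` is then rotated (optionally including reflections) and isotropically
    scaled onto ``a``.  d = 1 - (sum of singular values)^2 lies in [0, 1],
    is 0 iff the trajectories match exactly up to the allowed transform, and
    is symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectories must have equal shapes")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    A, B = a - mu_a, b - mu_b
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("constant trajectory: Procrustes scaling undefined")
    A, B = A / na, B / nb
    if np.array_equal(A, B):  # d(a, a) = 0 exactly, by definition
        return 0.0, {"rotation": np.eye(a.shape[1]), "scale": na / nb,
                     "translation": mu_a, "source_mean": mu_b}
    R, s = orthogonal_procrustes(B, A)
    if not allow_reflection and np.linalg.det(R) < 0:
        U, sv, Vt = np.linalg.svd(B.T @ A)
        D = np.eye(R.shape[0])
        D[-1, -1] = -1
        R = U @ D @ Vt
        s = float(sv[:-1].sum() - sv[-1])
    d = float(1.0 - s**2)
    transform = {"rotation": R, "scale": float(s * na / nb), "translation": mu_a, "source_mean": mu_b}
    return max(d, 0.0), transform


def procrustes_report(traj: TrajectorySet, allow_reflection: bool = True) -> ProcrustesReport:
    """Cross-format Procrustes distance for every grouping level."""
    levels = sorted({lev for lev, _ in traj.trajectories})
    rows, transforms = [], {}
    for lev in levels:
        d, tf = procrustes_distance(
            traj.trajectories[(lev, INTENTION)], traj.trajectories[(lev, OBSERVATION)], allow_reflection
        )
        rows.append({"level": lev, "d": d})
        transforms[lev] = tf
    return ProcrustesReport(table=pd.DataFrame(rows), transforms=transforms)


def all_units_geometry_control(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    grouping: str = "action",
    window: Tuple[float, float] = (-0.5, 2.5),
) -> ProcrustesReport:
    """Procrustes distances with the task-relevant unit filter removed."""
    traj = pca_trajectories(rates, trials, design, units=None, grouping=grouping, window=window)
    return procrustes_report(traj)


def _ellipse(points: np.ndarray, n_sd: float = 2.0) -> dict:
    c = points.mean(axis=0)
    cov = np.cov(points.T)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    axes = vecs * n_sd * np.sqrt(np.maximum(vals, 0))
    return {
        "cx": c[0],
        "cy": c[1],
        "ax1_x": axes[0, 0],
        "ax1_y": axes[1, 0],
        "ax2_x": axes[0, 1],
        "ax2_y": axes[1, 1],
    }


def embed_trials(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    units: Optional[Sequence[str]] = None,
    grouping: str = "action",
    window: Tuple[float, float] = (1.0, 2.0),
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "cosine",
    seed: int = 0,
) -> EmbeddingReport:
    """Joint UMAP embedding of intention and observation trials with
    per-(level, format) covariance ellipses."""
    import umap

    uidx = _unit_indices(rates, units)
    inc = trials["included"].to_numpy(dtype=bool)
    idx = np.where(inc)[0]
    if idx.size < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} trials for the embedding")
    bins = rates.bins_in(window)
    X = rates.values[np.ix_(uidx, idx, bins)].mean(axis=2).T  # trials x units
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist, metric=metric, random_state=seed)
    coords = reducer.fit_transform(X)
    sub = trials.iloc[idx]
    rows = []
    for (lev, fmt), grp in sub.groupby([grouping, "format"], observed=True):
        pos = sub.index.get_indexer(grp.index)
        if len(pos) < 3:
            continue
        rows.append({"level": lev, "format": fmt, **_ellipse(coords[pos])})
    return EmbeddingReport(coords=coords, trial_index=idx, ellipses=pd.DataFrame(rows), seed=seed)
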