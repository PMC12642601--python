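"""Baseline-comparison responsiveness, response latency, and format overlap.

A unit (or high-gamma channel) is *responsive* to a condition when its
activity in overlapping 200 ms windows (100 ms step, from stimulus onset)
differs from the pre-stimulus baseline in at least three consecutive windows
at a Bonferroni-corrected paired t-test threshold (alpha / number of
windows).  Latency is the center of the first window of the earliest such
run.  Because binned rates are already baseline-subtracted per trial, the
paired test reduces to a one-sample t-test of the windowed net rate
against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import TaskDesign
from .session import BinnedRates


@dataclass
class ResponsivenessResult:
    """Per (unit, condition, format) responsiveness flags and latencies."""

    table: pd.DataFrame           # unit_id, region, format, condition, responsive, latency_s
    pvalues: np.ndarray           # units x conditions x windows
    window_centers_s: np.ndarray
    format: str
    alpha: float
    n_windows: int

    def responsive_any(self) -> pd.DataFrame:
        """Per unit: responsive to at least one condition in this format."""
        g = self.table.groupby(["unit_id", "region"], sort=False)["responsive"].any()
        return g.reset_index().rename(columns={"responsive": "responsive_any"})


def _window_values(rates: BinnedRates, window_len: float = 0.2, step: float = 0.1) -> Tuple[np.ndarray, np.ndarray]:
    """(units x trials x windows) mean net rate in overlapping windows.

    Windows start at 0 and advance by ``step``; windows that would cross the
    end of the binned range are dropped.
    """
    per_win = int(round(window_len / rates.bin_width_s))
    per_step = int(round(step / rates.bin_width_s))
    start_bin = int(np.searchsorted(rates.bin_centers_s, 0.0))
    n_avail = rates.n_bins - start_bin
    starts = np.arange(start_bin, rates.n_bins - per_win + 1, per_step)
    vals = np.stack([rates.values[:, :, s : s + per_win].mean(axis=2) for s in starts], axis=2)
    left_edges = rates.bin_centers_s[starts] - rates.bin_width_s / 2
    centers = left_edges + window_len / 2
    return vals, centers


def _runs_of_significance(sig: np.ndarray, min_run: int = 3) -> Tuple[bool, int]:
    """(responsive, index of first window of the earliest qualifying run)."""
    count = 0
    for i, s in enumerate(sig):
        count = count + 1 if s else 0
        if count >= min_run:
            return True, i - min_run + 1
    return False, -1


def test_responsiveness(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    format: str,
    units: Optional[pd.DataFrame] = None,
    grouping: str = "condition",
    alpha: float = 0.05,
    sided: str = "two-sided",
    window_len: float = 0.2,
    step: float = 0.1,
    min_run: int = 3,
) -> ResponsivenessResult:
    """Window-wise baseline comparison per condition for one format.

    ``grouping`` is ``"condition"`` (full factorial cells) or a factor name,
    in which case trials are grouped by that factor's levels.  ``sided`` is
    ``"two-sided"`` (default, conservative) or ``"greater"`` (responses above
    baseline only).
    """
    vals, centers = _window_values(rates, window_len, step)
    n_windows = centers.size
    thr = alpha / n_windows
    inc = trials["included"].to_numpy(dtype=bool) & (trials["format"] == format).to_numpy()
    if grouping == "condition":
        labels = design.condition_labels(trials)
    else:
        labels = trials[grouping].astype(str)
    conds = sorted(labels[inc].unique())
    n_units = rates.n_units
    unit_ids = rates.unit_ids if rates.unit_ids is not None else np.arange(n_units).astype(str)
    regions = (
        units.set_index("unit_id").loc[unit_ids, "region"].to_numpy()
        if units is not None
        else np.array(["NA"] * n_units)
    )
    pvals = np.full((n_units, len(conds), n_windows), np.nan)
    rows = []
    for ci, cond in enumerate(conds):
        sel = inc & (labels == cond).to_numpy()
        if sel.sum() < 2:
            warnings.warn(f"condition {cond!r} has <2 trials in format {format!r}; skipped")
            continue
        x = vals[:, sel, :]  # units x trials x windows
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_1samp(x, 0.0, axis=1)
        if sided == "greater":
            p = np.where(t > 0, p / 2, 1 - p / 2)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance windows: not significant
        pvals[:, ci, :] = p
        sig = p < thr
        for u in range(n_units):
            responsive, first = _runs_of_significance(sig[u], min_run)
            rows.append(
                {
                    "unit_id": unit_ids[u],
                    "region": regions[u],
                    "format": format,
                    "condition": cond,
                    "responsive": responsive,
                    "latency_s": centers[first] if responsive else np.nan,
                }
            )
    return ResponsivenessResult(
        table=pd.DataFrame(rows),
        pvalues=pvals,
        window_centers_s=centers,
        format=format,
        alpha=alpha,
        n_windows=n_windows,
    )


def format_overlap(
    res_intention: ResponsivenessResult, res_observation: ResponsivenessResult
) -> pd.DataFrame:
    """Counts of units responsive in intention only / observation only / both.

    The three counts partition the units responsive in at least one format,
    reported per region.
    """
    a = res_intention.responsive_any().rename(columns={"responsive_any": "int_any"})
    b = res_observation.responsive_any().rename(columns={"responsive_any": "obs_any"})
    m = a.merge(b, on=["unit_id", "region"], how="outer").fillna(False)
    m["category"] = np.select(
        [m.int_any & m.obs_any, m.int_any, m.obs_any],
        ["both", "intention_only", "observation_only"],
        default="neither",
    )
    out = (
        m[m.category != "neither"]
        .groupby(["region", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["intention_only", "observation_only", "both"], fill_value=0)
    )
    return out.reset_index()


def compare_latencies(results: Sequence[ResponsivenessResult]) -> Dict[str, object]:
    """One-way ANOVA of response latencies across regions (single format).

    Each responsive (unit, condition) pair contributes one latency.  Regions
    with fewer than two latencies are excluded with a warning; fewer than two
    usable regions raises.
    """
    table = pd.concat([r.table for r in results], ignore_index=True)
    lat = table[table.responsive].dropna(subset=["latency_s"])
    groups, medians = [], {}
    for region, sub in lat.groupby("region"):
        if len(sub) < 2:
            warnings.warn(f"region {region!r} has <2 latencies; excluded from ANOVA")
            continue
        groups.append(sub["latency_s"].to_numpy())
        medians[region] = float(sub["latency_s"].median())
    if len(groups) < 2:
        raise ValueError("latency comparison needs >=2 regions with >=2 latencies each")
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p": float(p), "medians": medians, "n_per_region": {k: len(v) for k, v in zip(medians, groups)}}
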