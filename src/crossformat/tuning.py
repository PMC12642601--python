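"""Time-resolved factorial ANOVA tuning profiles.

For each unit (or high-gamma channel) and each non-overlapping 500 ms bin,
a fixed-effects factorial ANOVA (type-II sums of squares, so mildly
unbalanced tables are handled) tests main effects of the task factors and
all their interactions on per-trial bin-mean rates.  A unit counts as tuned
to a main effect only when that effect is significant and no interaction
involving it is; units with any significant interaction are counted under
"interaction".  The Bonferroni divisor is the number of units/channels
tested (the convention used for the published tuning profiles), switchable
to per-bin or no correction.

The ANOVA itself is computed from precomputed orthonormal design bases so
that thousands of (unit, bin) cells reduce to matrix products; it is
cross-checked against statsmodels' ``anova_lm`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import TaskDesign
from .session import BinnedRates

_RANK_TOL = 1e-9


def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > _RANK_TOL * s[0]).sum()) if s.size else 0
    return u[:, :r]


class FactorialAnova:
    """Type-II factorial ANOVA with a fixed design, applied to many responses."""

    def __init__(self, trials: pd.DataFrame, factors: Sequence[str]):
        self.factors = list(factors)
        for f in self.factors:
            if trials[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has a single observed level")
        n = len(trials)
        blocks: Dict[str, np.ndarray] = {}
        for f in self.factors:
            d = pd.get_dummies(trials[f], drop_first=True).to_numpy(dtype=float)
            blocks[f] = d
        self.terms: List[Tuple[str, ...]] = []
        for k in range(1, len(self.factors) + 1):
            self.terms.extend(combinations(self.factors, k))
        self._term_cols: Dict[Tuple[str, ...], np.ndarray] = {}
        for term in self.terms:
            cols = blocks[term[0]]
            for f in term[1:]:
                cols = np.einsum("ni,nj->nij", cols, blocks[f]).reshape(n, -1)
            self._term_cols[term] = cols
        intercept = np.ones((n, 1))
        full_X = np.hstack([intercept] + [self._term_cols[t] for t in self.terms])
        self._Q_full = _orth_basis(full_X)
        self.df_resid = n - self._Q_full.shape[1]
        if self.df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        # per term: bases of the type-II reduced model (all terms not
        # containing this term) and of reduced + term
        self._pairs: Dict[Tuple[str, ...], Tuple[np.ndarray, np.ndarray, int]] = {}
        for term in self.terms:
            others = [t for t in self.terms if not set(term) <= set(t)]
            Xr = np.hstack([intercept] + [self._term_cols[t] for t in others]) if others else intercept
            Qr = _orth_basis(Xr)
            Qrt = _orth_basis(np.hstack([Xr, self._term_cols[term]]))
            df_t = Qrt.shape[1] - Qr.shape[1]
            self._pairs[term] = (Qr, Qrt, df_t)

    @staticmethod
    def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return (Y**2).sum(axis=0) - ((Q.T @ Y) ** 2).sum(axis=0)

    def run(self, Y: np.ndarray) -> Dict[Tuple[str, ...], Tuple[np.ndarray, np.ndarray]]:
        """F and p per term for responses ``Y`` (n_trials x n_series)."""
        Y = np.atleast_2d(Y.T).T  # ensure 2-D, trials first
        rss_full = self._rss(self._Q_full, Y)
        mse = rss_full / self.df_resid
        out = {}
        for term, (Qr, Qrt, df_t) in self._pairs.items():
            ss = self._rss(Qr, Y) - self._rss(Qrt, Y)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = (ss / df_t) / mse
            p = stats.f.sf(F, df_t, self.df_resid)
            p = np.where(np.isfinite(F), p, 1.0)
            out[term] = (F, p)
        return out


@dataclass
class TuningTimecourse:
    """Per-(series, bin, effect) p-values and per-bin tuned-unit counts."""

    table: pd.DataFrame   # id, bin_center_s, effect, F, p, significant
    counts: pd.DataFrame  # bin_center_s x category counts
    alpha_threshold: float
    bin_centers_s: np.ndarray


def term_name(term: Tuple[str, ...]) -> str:
    return ":".join(term)


def anova_timecourse(
    rates: BinnedRates,
    trials: pd.DataFrame,
    design: TaskDesign,
    format: Optional[str] = None,
    factors: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    divisor: str = "units",
    bin_width: float = 0.5,
    ids: Optional[Sequence[str]] = None,
) -> TuningTimecourse:
    """Tuning timecourse over non-overlapping ``bin_width`` bins from onset.

    ``divisor`` selects the Bonferroni correction: ``"units"`` (alpha divided
    by the number of series tested; default), ``"bins"``, or ``"none"``.
    """
    factors = list(factors) if factors is not None else list(design.factor_names)
    sel = trials["included"].to_numpy(dtype=bool)
    if format is not None:
        sel = sel & (trials["format"] == format).to_numpy()
    sub = trials[sel]
    engine = FactorialAnova(sub, factors)
    per = int(round(bin_width / rates.bin_width_s))
    start = int(np.searchsorted(rates.bin_centers_s, 0.0))
    starts = np.arange(start, rates.n_bins - per + 1, per)
    centers = rates.bin_centers_s[starts] - rates.bin_width_s / 2 + bin_width / 2
    n_units = rates.n_units
    if ids is None:
        ids = rates.unit_ids if rates.unit_ids is not None else np.arange(n_units).astype(str)
    if divisor == "units":
        thr = alpha / n_units
    elif divisor == "bins":
        thr = alpha / len(starts)
    elif divisor == "none":
        thr = alpha
    else:
        raise ValueError(f"unknown divisor rule {divisor!r}")
    rows = []
    count_rows = []
    interactions = [t for t in engine.terms if len(t) > 1]
    for b, s in enumerate(starts):
        Y = rates.values[:, sel, s : s + per].mean(axis=2).T  # trials x units
        res = engine.run(Y)
        sig = {t: res[t][1] < thr for t in engine.terms}
        for term in engine.terms:
            F, p = res[term]
            for u in range(n_units):
                rows.append(
                    {
                        "id": ids[u],
                        "bin_center_s": centers[b],
                        "effect": term_name(term),
                        "F": F[u],
                        "p": p[u],
                        "significant": bool(sig[term][u]),
                    }
                )
        any_inter = np.zeros(n_units, dtype=bool)
        for t in interactions:
            any_inter |= sig[t]
        counts = {"interaction": int(any_inter.sum())}
        for f in factors:
            inter_with_f = np.zeros(n_units, dtype=bool)
            for t in interactions:
                if f in t:
                    inter_with_f |= sig[t]
            counts[f] = int((sig[(f,)] & ~inter_with_f).sum())
        count_rows.append({"bin_center_s": centers[b], **counts})
    return TuningTimecourse(
        table=pd.DataFrame(rows),
        counts=pd.DataFrame(count_rows).set_index("bin_center_s"),
        alpha_threshold=thr,
        bin_centers_s=centers,
    )
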