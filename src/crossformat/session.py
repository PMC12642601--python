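"""Session containers, the HDF5 session store, and firing-rate binning.

A *session* is one recording day: a trial table, per-unit spike times per
trial, and optionally per-channel LFP sampled uniformly (canonically 1 kHz).
Spike times are seconds relative to trial onset (the hand cue).  The store is
one HDF5 file per session (groups ``/meta``, ``/units``, ``/spikes`` and
optionally ``/lfp``) plus a sidecar RFC-4180 CSV trial table next to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .design import TaskDesign, validate_trial_table


@dataclass
class SpikeSession:
    """Sorted spike times per (unit, trial) plus unit metadata.

    ``units`` has columns ``unit_id``, ``region`` and ``quality`` (quality
    factor 1-4; 1-2 are well isolated single units).  Quality is carried as
    metadata only and never enters any computation.  ``spikes[u][t]`` is the
    sorted array of spike times of unit ``u`` on the trial in row ``t`` of
    the session's trial table.
    """

    units: pd.DataFrame
    spikes: List[List[np.ndarray]]

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.spikes[0]) if self.spikes else 0


@dataclass
class LFPSession:
    """Per-channel voltage traces, shape (channels, trials, samples)."""

    channels: pd.DataFrame
    data: np.ndarray
    fs: float = 1000.0
    t_start: float = -0.5

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.fs


@dataclass
class BinnedRates:
    """Baseline-subtracted firing rates: units x trials x bins (spikes/s).

    Each entry is the in-bin rate minus that trial's mean baseline rate
    (baseline window defaults to [-0.5, 0) s), the common currency of all
    downstream spiking analyses.
    """

    values: np.ndarray
    bin_centers_s: np.ndarray
    bin_width_s: float = 0.1
    baseline_window_s: Tuple[float, float] = (-0.5, 0.0)
    window_s: Tuple[float, float] = (0.0, 3.0)
    unit_ids: Optional[np.ndarray] = None

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def bins_in(self, window: Tuple[float, float]) -> np.ndarray:
        """Indices of bins whose full extent lies inside ``window``."""
        half = self.bin_width_s / 2
        lo = self.bin_centers_s - half
        hi = self.bin_centers_s + half
        eps = 1e-9
        return np.where((lo >= window[0] - eps) & (hi <= window[1] + eps))[0]


def bin_rates(
    spikes: SpikeSession,
    design: Optional[TaskDesign] = None,
    window: Tuple[float, float] = (0.0, 3.0),
    bin_width: float = 0.1,
    baseline: Tuple[float, float] = (-0.5, 0.0),
    trial_window: Tuple[float, float] = (-0.5, 3.0),
) -> BinnedRates:
    """Bin spike trains into net (baseline-subtracted) rates.

    ``values[u, t, b] = count_in_bin / bin_width - baseline_count / baseline_len``.
    Bins tile ``window`` exactly; a spike outside ``trial_window`` raises.
    """
    if design is not None:
        trial_window = design.trial_window_s
    n_bins = int(round((window[1] - window[0]) / bin_width))
    if abs(n_bins * bin_width - (window[1] - window[0])) > 1e-9:
        raise ValueError("bin width must tile the analysis window exactly")
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    base_len = baseline[1] - baseline[0]
    n_units, n_trials = spikes.n_units, spikes.n_trials
    values = np.zeros((n_units, n_trials, n_bins))
    for u in range(n_units):
        for t in range(n_trials):
            st = np.asarray(spikes.spikes[u][t], dtype=float)
            if st.size == 0:
                continue
            if st.min() < trial_window[0] - 1e-9 or st.max() > trial_window[1] + 1e-9:
                raise ValueError(
                    f"unit {u} trial {t}: spike time outside trial window {trial_window}"
                )
            counts = np.diff(np.searchsorted(st, edges))
            nbase = np.searchsorted(st, baseline[1]) - np.searchsorted(st, baseline[0])
            values[u, t] = counts / bin_width - nbase / base_len
    centers = edges[:-1] + bin_width / 2
    uid = spikes.units["unit_id"].to_numpy()
    return BinnedRates(values, centers, bin_width, baseline, window, unit_ids=uid)


# ---------------------------------------------------------------------------
# HDF5 session store
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


class SchemaError(RuntimeError):
    """The session file does not follow the documented layout."""


def _trials_csv_path(path: Path) -> Path:
    return path.with_suffix(".trials.csv")


def save_session(
    path,
    design: TaskDesign,
    trials: pd.DataFrame,
    spikes: SpikeSession,
    lfp: Optional[LFPSession] = None,
    ground_truth: Optional[dict] = None,
) -> Path:
    """Write a session store: one HDF5 file + sidecar trial-table CSV."""
    path = Path(path)
    validate_trial_table(design, trials)
    if spikes.n_trials != len(trials):
        raise ValueError("spike trains and trial table disagree on trial count")
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["variant"] = design.variant
        meta.attrs["reps_per_condition"] = design.reps_per_condition
        meta.attrs["trial_window_s"] = design.trial_window_s
        meta.attrs["formats"] = json.dumps(list(design.formats))
        meta.attrs["factors"] = json.dumps({k: list(v) for k, v in design.factors.items()})
        meta.attrs["event_times_s"] = json.dumps(design.event_times_s)
        if ground_truth is not None:
            meta.attrs["ground_truth"] = json.dumps(ground_truth)
        g = f.create_group("units")
        g.create_dataset("unit_id", data=spikes.units["unit_id"].astype(str).to_numpy(), dtype=_STR)
        g.create_dataset("region", data=spikes.units["region"].astype(str).to_numpy(), dtype=_STR)
        g.create_dataset("quality", data=spikes.units["quality"].to_numpy(dtype=np.int64))
        # ragged spikes: concatenated times + (units*trials + 1) offsets, unit-major
        flat, offsets = [], [0]
        for u in range(spikes.n_units):
            for t in range(spikes.n_trials):
                st = np.asarray(spikes.spikes[u][t], dtype=np.float64)
                flat.append(st)
                offsets.append(offsets[-1] + st.size)
        sg = f.create_group("spikes")
        sg.create_dataset("times", data=np.concatenate(flat) if flat else np.empty(0))
        sg.create_dataset("offsets", data=np.asarray(offsets, dtype=np.int64))
        sg.attrs["n_units"] = spikes.n_units
        sg.attrs["n_trials"] = spikes.n_trials
        sg.attrs["units"] = "seconds relative to trial onset (hand cue)"
        if lfp is not None:
            lg = f.create_group("lfp")
            lg.create_dataset("data", data=lfp.data)
            lg.attrs["fs"] = lfp.fs
            lg.attrs["t_start"] = lfp.t_start
            lg.attrs["units"] = "microvolts, trial-aligned"
            lg.create_dataset("channel_id", data=lfp.channels["channel_id"].astype(str).to_numpy(), dtype=_STR)
            lg.create_dataset("region", data=lfp.channels["region"].astype(str).to_numpy(), dtype=_STR)
    trials.to_csv(_trials_csv_path(path), index=False)
    return path


def load_session(path):
    """Load a session store; returns (design, trials, spikes, lfp_or_None)."""
    path = Path(path)
    csv = _trials_csv_path(path)
    if not csv.exists():
        raise SchemaError(f"missing sidecar trial table {csv.name}")
    trials = pd.read_csv(csv)
    trials["included"] = trials["included"].astype(bool)
    if "relevance" in trials.columns:
        trials["relevance"] = trials["relevance"].astype(bool)
    with h5py.File(path, "r") as f:
        for group in ("meta", "units", "spikes"):
            if group not in f:
                raise SchemaError(f"session file lacks required group '/{group}'")
        meta = f["meta"].attrs
        design = TaskDesign(
            variant=str(meta["variant"]),
            factors={k: tuple(v) for k, v in json.loads(meta["factors"]).items()},
            formats=tuple(json.loads(meta["formats"])),
            event_times_s=json.loads(meta["event_times_s"]),
            trial_window_s=tuple(float(x) for x in meta["trial_window_s"]),
            reps_per_condition=int(meta["reps_per_condition"]),
        )
        units = pd.DataFrame(
            {
                "unit_id": f["units/unit_id"].asstr()[:],
                "region": f["units/region"].asstr()[:],
                "quality": f["units/quality"][:],
            }
        )
        times = f["spikes/times"][:]
        offsets = f["spikes/offsets"][:]
        n_units = int(f["spikes"].attrs["n_units"])
        n_trials = int(f["spikes"].attrs["n_trials"])
        trains: List[List[np.ndarray]] = []
        k = 0
        for u in range(n_units):
            row = []
            for t in range(n_trials):
                row.append(times[offsets[k] : offsets[k + 1]])
                k += 1
            trains.append(row)
        spikes = SpikeSession(units=units, spikes=trains)
        lfp = None
        if "lfp" in f:
            channels = pd.DataFrame(
                {"channel_id": f["lfp/channel_id"].asstr()[:], "region": f["lfp/region"].asstr()[:]}
            )
            lfp = LFPSession(
                channels=channels,
                data=f["lfp/data"][:],
                fs=float(f["lfp"].attrs["fs"]),
                t_start=float(f["lfp"].attrs["t_start"]),
            )
    validate_trial_table(design, trials)
    return design, trials, spikes, lfp


def load_ground_truth(path) -> Optional[dict]:
    """Planted ground truth stored with a synthetic session, if any."""
    with h5py.File(Path(path), "r") as f:
        meta = f["meta"].attrs
        return json.loads(meta["ground_truth"]) if "ground_truth" in meta else None
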