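"""Synthetic sessions with planted, ground-truth coding structure.

The generator emulates the statistical structure the downstream analyses
assume rather than biophysics: units are inhomogeneous Poisson processes
whose rate is a baseline plus a boxcar response gated by an *archetype* --
which task factors the unit cares about and whether that tuning is shared
across formats, format-specific, idiosyncratic, or gated by behavioral
relevance.  LFP channels are 1/f noise plus 60 Hz line contamination plus a
band-limited high-gamma carrier whose amplitude is modulated in the
channel's preferred condition.

Defaults: 10 spikes/s baseline, 15 spikes/s peak effect, response onset
0.6 s after the hand cue lasting 1.4 s (so the whole 1-2 s analysis window
is covered), and observation responses at half the intention amplitude for
shared archetypes (``observation_gain = 0.5``), matching the qualitative
finding that observation responses are reduced relative to intention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import (
    DISSOCIATION_NOPROBE,
    DISSOCIATION_PROBE,
    INTENTION,
    MAIN,
    OBSERVATION,
    TaskDesign,
    derive_video_labels,
    make_task_design,
)
from .session import LFPSession, SpikeSession

ARCHETYPES = (
    "unselective",
    "invariant",
    "shared_action3",
    "shared_action6",
    "shared_hand",
    "shared_direction",
    "mixed",
    "idiosyncratic",
    "single_intention",
    "single_observation",
    "gated_observer",
)

#: archetypes whose effect is scaled by ``observation_gain`` in observation
_SHARED = {
    "invariant",
    "shared_action3",
    "shared_action6",
    "shared_hand",
    "shared_direction",
    "mixed",
}


@dataclass
class UnitArchetypeSpec:
    """Ground-truth coding scheme of one synthetic unit."""

    archetype: str
    baseline_rate: float = 10.0
    effect_size: float = 15.0
    latency_s: float = 0.6
    response_duration_s: float = 1.4
    observation_gain: float = 0.5
    region: str = "SPL"
    quality: int = 1
    preferred: Dict[str, str] = field(default_factory=dict)
    weights: Optional[Dict[str, List[float]]] = None  # per-format condition weights (mixed/idiosyncratic)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.baseline_rate < 0 or self.baseline_rate + self.effect_size < 0:
            raise ValueError("implied firing rate is negative")
        if not (0.0 <= self.latency_s < 3.0):
            raise ValueError("latency must lie in [0, 3) s")


@dataclass
class LFPChannelSpec:
    """Ground truth for one synthetic LFP channel."""

    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    line_amp_60hz: float = 2.0
    hg_band_hz: Tuple[float, float] = (73.0, 144.0)
    hg_carrier_amp: float = 0.5
    hg_modulation_depth: float = 1.0
    hg_latency_s: float = 0.6
    hg_duration_s: float = 1.4
    tuned_factor: Optional[str] = None
    tuned_level: Optional[str] = None
    region: str = "SPL"

    def __post_init__(self) -> None:
        if self.hg_modulation_depth < 0:
            raise ValueError("modulation depth must be >= 0")


def make_design(
    variant: str = MAIN,
    reps_per_condition: int = 12,
    n_sessions: int = 1,
    seed: int = 0,
) -> Tuple[TaskDesign, pd.DataFrame]:
    """Balanced, seed-shuffled trial table for ``variant``.

    Every condition appears exactly ``reps_per_condition`` times per block
    (format) per session; trial order is shuffled within each session.
    ``relevance`` marks trials on which the video content is behaviorally
    relevant: observation blocks and every probe-variant trial.
    """
    if reps_per_condition < 1:
        raise ValueError("reps_per_condition must be >= 1")
    design = make_task_design(variant, reps_per_condition)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sessions):
        recs = []
        for fmt in design.formats:
            for cond in design.conditions():
                for _ in range(reps_per_condition):
                    recs.append((fmt,) + cond)
        order = rng.permutation(len(recs))
        for tid, k in enumerate(order):
            fmt, *levels = recs[k]
            relevance = fmt == OBSERVATION or variant == DISSOCIATION_PROBE
            rows.append(
                {
                    "trial_id": tid,
                    "session_id": f"S{s}",
                    "format": fmt,
                    **dict(zip(design.factor_names, levels)),
                    "included": True,
                    "relevance": relevance,
                }
            )
    return design, pd.DataFrame(rows)


def archetype_population(
    counts: Dict[str, int],
    seed: int = 0,
    region: str = "SPL",
    latency_range: Optional[Tuple[float, float]] = None,
    duration_range: Optional[Tuple[float, float]] = None,
    **overrides,
) -> List[UnitArchetypeSpec]:
    """Build a population spec list, one entry per unit, preferences random.

    ``latency_range`` / ``duration_range`` draw per-unit response onsets and
    durations uniformly (heterogeneous temporal profiles, as in real cortical
    populations — required for trajectory geometry to be non-degenerate);
    omitted, every unit uses the archetype defaults.  Gated observers lock to
    the video period regardless (onset drawn after video start).
    """
    rng = np.random.default_rng(seed)
    specs: List[UnitArchetypeSpec] = []
    for arch, n in counts.items():
        for _ in range(n):
            kw = dict(overrides)
            if arch == "gated_observer":
                kw.setdefault("latency_s", rng.uniform(1.5, 1.9) if latency_range else 1.6)
                kw.setdefault("response_duration_s", 0.9)
            else:
                if latency_range is not None:
                    kw.setdefault("latency_s", float(rng.uniform(*latency_range)))
                if duration_range is not None:
                    kw.setdefault("response_duration_s", float(rng.uniform(*duration_range)))
            specs.append(UnitArchetypeSpec(archetype=arch, region=region, **kw))
    rng.shuffle(specs)
    return specs


def _condition_weights(spec: UnitArchetypeSpec, design: TaskDesign, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Per-format weight in [0, 1] for each of the design's conditions."""
    conds = design.conditions()
    names = design.factor_names
    levels = design.factors

    def pick(factor: str) -> str:
        if factor not in spec.preferred:
            spec.preferred[factor] = str(rng.choice(levels[factor]))
        return spec.preferred[factor]

    n = len(conds)
    fmts = list(design.formats)
    w = {f: np.zeros(n) for f in fmts}
    a = spec.archetype
    if a == "unselective":
        for f in fmts:
            w[f][:] = 1.0
    elif a == "invariant":
        pa, ph = pick("action"), pick("hand")
        pd_ = pick("direction") if "direction" in names else None
        for i, c in enumerate(conds):
            d = dict(zip(names, c))
            parts = [d["action"] == pa, d["hand"] == ph]
            if pd_ is not None:
                parts.append(d["direction"] == pd_)
            val = sum(parts) / len(parts)
            for f in fmts:
                w[f][i] = val
    elif a in ("shared_action3", "single_intention", "single_observation", "gated_observer"):
        pa = pick("action")
        for i, c in enumerate(conds):
            val = float(dict(zip(names, c))["action"] == pa)
            for f in fmts:
                w[f][i] = val
    elif a == "shared_action6":
        pa, pd_ = pick("action"), pick("direction")
        for i, c in enumerate(conds):
            d = dict(zip(names, c))
            val = float(d["action"] == pa and d["direction"] == pd_)
            for f in fmts:
                w[f][i] = val
    elif a == "shared_hand":
        ph = pick("hand")
        for i, c in enumerate(conds):
            val = float(dict(zip(names, c))["hand"] == ph)
            for f in fmts:
                w[f][i] = val
    elif a == "shared_direction":
        pdir = pick("direction" if "direction" in names else "conflict")
        key = "direction" if "direction" in names else "conflict"
        for i, c in enumerate(conds):
            val = float(dict(zip(names, c))[key] == pdir)
            for f in fmts:
                w[f][i] = val
    elif a in ("mixed", "idiosyncratic"):
        if spec.weights is None:
            shared = rng.uniform(0, 1, n)
            spec.weights = {}
            for f in fmts:
                vals = rng.uniform(0, 1, n) if a == "idiosyncratic" else shared
                spec.weights[f] = [float(x) for x in vals]
        for f in fmts:
            w[f] = np.asarray(spec.weights[f], dtype=float)
    else:  # pragma: no cover
        raise AssertionError(a)
    return w


def _trial_modulation(
    spec: UnitArchetypeSpec, design: TaskDesign, trials: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Effect multiplier in [0, 1] for every trial."""
    a = spec.archetype
    if a == "gated_observer":
        # responds to the *video's* action, only when behaviorally relevant
        if "action" not in spec.preferred:
            spec.preferred["action"] = str(rng.choice(design.factors["action"]))
        pa = spec.preferred["action"]
        if "conflict" in trials.columns:
            video_action = derive_video_labels(trials)["video_action"].to_numpy()
        else:
            video_action = trials["action"].to_numpy()
        return (video_action == pa).astype(float) * trials["relevance"].to_numpy(dtype=float)
    w = _condition_weights(spec, design, rng)
    conds = {c: i for i, c in enumerate(design.conditions())}
    idx = np.array([conds[tuple(r)] for r in trials[list(design.factor_names)].itertuples(index=False)])
    fmt = trials["format"].to_numpy()
    out = np.empty(len(trials))
    for f in np.unique(fmt):
        out[fmt == f] = w[f][idx[fmt == f]]
    if a == "single_intention":
        out[fmt != INTENTION] = 0.0
    elif a == "single_observation":
        out[fmt != OBSERVATION] = 0.0
    elif a in _SHARED:
        out[fmt == OBSERVATION] *= spec.observation_gain
    # unselective: identical response everywhere, no format scaling (true null
    # for condition structure while still being "responsive")
    return out


def _poisson_train(
    rng: np.random.Generator,
    baseline: float,
    effect: float,
    onset: float,
    offset: float,
    window: Tuple[float, float],
) -> np.ndarray:
    """Sample one trial: piecewise-constant rate = baseline + effect boxcar."""
    lo, hi = window
    segs = [(lo, onset, baseline), (onset, offset, baseline + effect), (offset, hi, baseline)]
    times = []
    for a, b, rate in segs:
        a, b = max(a, lo), min(b, hi)
        if b <= a or rate <= 0:
            continue
        n = rng.poisson(rate * (b - a))
        if n:
            times.append(rng.uniform(a, b, n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def simulate_spikes(
    design: TaskDesign,
    trials: pd.DataFrame,
    archetypes: Sequence[UnitArchetypeSpec],
    seed: int = 0,
) -> Tuple[SpikeSession, dict]:
    """Inhomogeneous-Poisson spike trains with planted archetype structure.

    Returns the session plus a JSON-serializable ground-truth record (one
    entry per unit: archetype, parameters, and the drawn preferences).
    """
    rng = np.random.default_rng(seed)
    lo, hi = design.trial_window_s
    trains: List[List[np.ndarray]] = []
    gt_units = []
    for u, spec in enumerate(archetypes):
        mod = _trial_modulation(spec, design, trials, rng)
        onset = spec.latency_s
        offset = min(onset + spec.response_duration_s, hi)
        row = [
            _poisson_train(rng, spec.baseline_rate, spec.effect_size * m, onset, offset, (lo, hi))
            for m in mod
        ]
        trains.append(row)
        gt_units.append({"unit_id": f"u{u:04d}", **asdict(spec)})
    units = pd.DataFrame(
        {
            "unit_id": [g["unit_id"] for g in gt_units],
            "region": [s.region for s in archetypes],
            "quality": [s.quality for s in archetypes],
        }
    )
    return SpikeSession(units=units, spikes=trains), {"units": gt_units}


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2)
    phase = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n)
    return x / (x.std() + 1e-30)


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: Tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(freqs.size, dtype=complex)
    spec[mask] = np.exp(1j * rng.uniform(0, 2 * np.pi, mask.sum()))
    x = np.fft.irfft(spec, n)
    return x / (x.std() + 1e-30)


def simulate_lfp(
    design: TaskDesign,
    trials: pd.DataFrame,
    channels: Sequence[LFPChannelSpec],
    fs: float = 1000.0,
    seed: int = 0,
) -> LFPSession:
    """1/f noise + 60 Hz line + condition-modulated high-gamma carrier.

    The high-gamma carrier's amplitude envelope is 1 at baseline and
    ``1 + depth`` inside the response window on trials matching the channel's
    preferred condition (all trials if ``tuned_factor`` is None and depth > 0).
    """
    if fs < 500:
        raise ValueError("sampling rate must be >= 500 Hz for a [73, 144] Hz carrier")
    rng = np.random.default_rng(seed)
    lo, hi = design.trial_window_s
    n = int(round((hi - lo) * fs))
    t = lo + np.arange(n) / fs
    n_trials = len(trials)
    data = np.zeros((len(channels), n_trials, n), dtype=np.float32)
    for c, spec in enumerate(channels):
        if spec.tuned_factor is None:
            match = np.ones(n_trials, dtype=bool)
        else:
            match = (trials[spec.tuned_factor] == spec.tuned_level).to_numpy()
        on = spec.hg_latency_s
        off = min(on + spec.hg_duration_s, hi)
        box = (t >= on) & (t < off)
        for k in range(n_trials):
            x = spec.noise_amp * _pink_noise(rng, n, fs, spec.noise_exponent)
            x += spec.line_amp_60hz * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
            env = np.ones(n)
            if match[k]:
                env[box] += spec.hg_modulation_depth
            x += spec.hg_carrier_amp * env * _band_noise(rng, n, fs, spec.hg_band_hz)
            data[c, k] = x
    chan_df = pd.DataFrame(
        {"channel_id": [f"ch{c:03d}" for c in range(len(channels))], "region": [s.region for s in channels]}
    )
    return LFPSession(channels=chan_df, data=data, fs=fs, t_start=lo)


def lfp_ground_truth(channels: Sequence[LFPChannelSpec]) -> dict:
    return {"channels": [asdict(s) for s in channels]}
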