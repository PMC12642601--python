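"""LFP preprocessing, Morlet time-frequency power, and the unified
high-gamma envelope.

Preprocessing: spectrum-interpolation suppression of 60 Hz line noise and
harmonics, a zero-phase 2 Hz IIR high-pass, and rejection of trials whose
broadband RMS amplitude exceeds two standard deviations of the session
mean.  Time-frequency power (60-120 Hz grid) uses 7-cycle Morlet wavelets,
with the first and last 100 ms of each trial discarded and power divided,
per frequency and trial, by its pre-stimulus baseline mean.

The unified high-gamma (HG) envelope follows the multi-band analytic
amplitude approach: after common-average referencing within a region, the
signal is passed through eight Gaussian bandpass filters with
log-spaced centers ``73 * (144/73)**(i/7)`` Hz and full-width-half-max
bandwidth at 20% of each center; per band the analytic amplitude is
resampled to 100 Hz, z-scored, and soft-clipped (tanh), and the first left
singular vector across bands is retained as the per-channel HG estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .design import TaskDesign
from .session import BinnedRates, LFPSession

HG_F_LO = 73.0
HG_F_HI = 144.0
HG_N_BANDS = 8


def hg_band_centers(n_bands: int = HG_N_BANDS, f_lo: float = HG_F_LO, f_hi: float = HG_F_HI) -> np.ndarray:
    """Logarithmically spaced band centers, f_lo * (f_hi/f_lo)**(i/(n-1))."""
    i = np.arange(n_bands)
    return f_lo * (f_hi / f_lo) ** (i / (n_bands - 1))


@dataclass
class TFPower:
    """Baseline-normalized Morlet power: channels x trials x freqs x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray


@dataclass
class HGEnvelope:
    """Unified high-gamma amplitude: channels x trials x times, z-scored."""

    env: np.ndarray
    fs: float
    t_start: float

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.env.shape[2]) / self.fs

    def to_binned(self, bin_width: float = 0.1, baseline: Tuple[float, float] = (-0.4, 0.0)) -> BinnedRates:
        """Rebin the envelope like net firing rates so the responsiveness and
        tuning engines apply unchanged at the channel level."""
        t = self.times
        t0 = 0.0
        per = int(round(bin_width * self.fs))
        start = int(np.searchsorted(t, t0))
        n_bins = (self.env.shape[2] - start) // per
        vals = self.env[:, :, start : start + n_bins * per]
        vals = vals.reshape(vals.shape[0], vals.shape[1], n_bins, per).mean(axis=3)
        bsel = (t >= baseline[0]) & (t < baseline[1])
        base = self.env[:, :, bsel].mean(axis=2, keepdims=True)
        centers = t[start] + bin_width * (np.arange(n_bins) + 0.5)
        return BinnedRates(
            values=vals - base,
            bin_centers_s=centers,
            bin_width_s=bin_width,
            baseline_window_s=baseline,
            window_s=(float(t[start]), float(t[start] + n_bins * bin_width)),
            unit_ids=None,
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _spectrum_interpolate(x: np.ndarray, fs: float, f0: float, half_bw: float = 1.0) -> np.ndarray:
    """Replace magnitudes around ``f0`` (and harmonics) with the mean of the
    flanking bands, keeping phases (per-trace FFT surgery)."""
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    for h in np.arange(f0, fs / 2, f0):
        band = (freqs >= h - half_bw) & (freqs <= h + half_bw)
        flank = ((freqs >= h - 3 * half_bw) & (freqs < h - half_bw)) | (
            (freqs > h + half_bw) & (freqs <= h + 3 * half_bw)
        )
        if not band.any() or not flank.any():
            continue
        target = np.abs(X[..., flank]).mean(axis=-1, keepdims=True)
        mag = np.abs(X[..., band])
        scale = np.divide(target, mag, out=np.ones_like(mag), where=mag > 0)
        X[..., band] = X[..., band] * scale
    return np.fft.irfft(X, n, axis=-1)


def preprocess_lfp(
    lfp: LFPSession,
    line_freq: float = 60.0,
    hp_cutoff: float = 2.0,
    artifact_sd: float = 2.0,
) -> Tuple[LFPSession, np.ndarray]:
    """Line-noise suppression, zero-phase 2 Hz high-pass, artifact flags.

    Returns the filtered session and a boolean array marking trials whose
    broadband RMS exceeds ``artifact_sd`` standard deviations of the session
    mean (to be merged into the trial table's ``included`` column).
    """
    fs = lfp.fs
    n = lfp.data.shape[2]
    sos = signal.butter(4, hp_cutoff, btype="highpass", fs=fs, output="sos")
    padlen = 3 * (2 * 4 + 1)
    if n <= padlen:
        raise ValueError("trial shorter than the high-pass filter warm-up")
    x = _spectrum_interpolate(lfp.data.astype(float), fs, line_freq)
    x = signal.sosfiltfilt(sos, x, axis=-1)
    rms = np.sqrt((x**2).mean(axis=2)).mean(axis=0)  # per trial, averaged over channels
    flagged = rms > rms.mean() + artifact_sd * rms.std()
    out = LFPSession(channels=lfp.channels.copy(), data=x.astype(np.float32), fs=fs, t_start=lfp.t_start)
    return out, flagged


def morlet_power(
    lfp: LFPSession,
    freqs: Optional[np.ndarray] = None,
    n_cycles: float = 7.0,
    baseline: Tuple[float, float] = (-0.5, 0.0),
    trim_s: float = 0.1,
) -> TFPower:
    """7-cycle Morlet power, edge-trimmed and baseline-normalized per trial."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs) if freqs is not None else np.arange(60.0, 121.0, 2.0)
    data = lfp.data.transpose(1, 0, 2).astype(float)  # epochs x channels x times
    power = tfr_array_morlet(data, sfreq=lfp.fs, freqs=freqs, n_cycles=n_cycles, output="power", verbose=False)
    times = lfp.t_start + np.arange(lfp.data.shape[2]) / lfp.fs
    keep = (times >= times[0] + trim_s) & (times <= times[-1] - trim_s)
    power = power[..., keep]
    times = times[keep]
    bsel = (times >= baseline[0]) & (times < baseline[1])
    if not bsel.any():
        raise ValueError("baseline window missing from the trimmed trial")
    base = power[..., bsel].mean(axis=-1, keepdims=True)
    power = power / base
    return TFPower(power=power.transpose(1, 0, 2, 3), freqs=freqs, times=times)


def _gaussian_analytic_band(x: np.ndarray, fs: float, fc: float, frac_bw: float = 0.2) -> np.ndarray:
    """Analytic amplitude of a Gaussian (in frequency) bandpass at ``fc``.

    The filter magnitude is a Gaussian centered at ``fc`` with FWHM equal to
    ``frac_bw * fc``; the analytic signal is formed in one pass by zeroing
    negative frequencies, so the magnitude of the inverse transform is the
    band's Hilbert envelope.
    """
    n = x.shape[-1]
    freqs = np.fft.fftfreq(n, 1 / fs)
    sigma = frac_bw * fc / (2 * np.sqrt(2 * np.log(2)))
    H = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
    H[freqs < 0] = 0.0
    analytic = np.fft.ifft(np.fft.fft(x, axis=-1) * 2 * H, axis=-1)
    return np.abs(analytic)


def hg_unified_envelope(
    lfp: LFPSession,
    out_fs: float = 100.0,
    n_bands: int = HG_N_BANDS,
    f_lo: float = HG_F_LO,
    f_hi: float = HG_F_HI,
    frac_bw: float = 0.2,
    car: bool = True,
    tanh_scale: float = 3.0,
) -> HGEnvelope:
    """Unified high-gamma envelope per channel (first singular vector across
    the eight band envelopes), z-scored per channel."""
    data = lfp.data.astype(float)
    if car:
        for region, idx in lfp.channels.groupby("region").groups.items():
            cols = lfp.channels.index.get_indexer(idx)
            if len(cols) < 2:
                warnings.warn(f"region {region!r} has <2 channels; CAR skipped")
                continue
            data[cols] -= data[cols].mean(axis=0, keepdims=True)
    centers = hg_band_centers(n_bands, f_lo, f_hi)
    q = int(round(lfp.fs / out_fs))
    n_ch, n_trials, n_samp = data.shape
    n_out = int(np.ceil(n_samp / q))
    unified = np.zeros((n_ch, n_trials, n_out))
    for c in range(n_ch):
        bands = np.empty((n_bands, n_trials, n_out))
        for b, fc in enumerate(centers):
            env = _gaussian_analytic_band(data[c], lfp.fs, fc, frac_bw)
            env = signal.resample_poly(env, 1, q, axis=-1)
            bands[b] = env
        # z-score each band over all trials and timepoints, then soft-clip
        mu = bands.mean(axis=(1, 2), keepdims=True)
        sd = bands.std(axis=(1, 2), keepdims=True)
        zero = sd[:, 0, 0] == 0
        if zero.any():
            warnings.warn(f"channel {c}: {int(zero.sum())} degenerate band(s); set to zero")
        bands = np.divide(bands - mu, sd, out=np.zeros_like(bands), where=sd > 0)
        bands = tanh_scale * np.tanh(bands / tanh_scale)
        M = bands.reshape(n_bands, -1).T  # (trials*time) x bands
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        u1 = U[:, 0] * S[0]
        if Vt[0].mean() < 0:  # SVD sign: positive mean band loading
            u1 = -u1
        unified[c] = u1.reshape(n_trials, n_out)
    mu = unified.mean(axis=(1, 2), keepdims=True)
    sd = unified.std(axis=(1, 2), keepdims=True)
    unified = np.divide(unified - mu, sd, out=np.zeros_like(unified), where=sd > 0)
    return HGEnvelope(env=unified, fs=out_fs, t_start=lfp.t_start)


def hg_channel_selection(
    env: HGEnvelope,
    trials: pd.DataFrame,
    task_window: Tuple[float, float] = (1.0, 2.0),
    baseline_window: Tuple[float, float] = (0.0, 0.5),
    alpha: float = 0.05,
) -> np.ndarray:
    """Indices of channels whose HG differs between task and baseline windows
    (two-sided paired t-test per channel, p < alpha)."""
    t = env.times
    inc = trials["included"].to_numpy(dtype=bool)
    task = env.env[:, inc][:, :, (t >= task_window[0]) & (t < task_window[1])].mean(axis=2)
    base = env.env[:, inc][:, :, (t >= baseline_window[0]) & (t < baseline_window[1])].mean(axis=2)
    keep = []
    for c in range(env.env.shape[0]):
        _, p = stats.ttest_rel(task[c], base[c])
        if np.isfinite(p) and p < alpha:
            keep.append(c)
    return np.asarray(keep, dtype=int)


def hg_features(
    env: HGEnvelope, channels: Optional[np.ndarray] = None, window_s: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """(trials x channels x windows) mean HG in non-overlapping windows
    spanning the whole trial (-0.5 to 3 s by default)."""
    ch = np.arange(env.env.shape[0]) if channels is None else channels
    per = int(round(window_s * env.fs))
    n_win = env.env.shape[2] // per
    X = env.env[ch, :, : n_win * per].reshape(len(ch), env.env.shape[1], n_win, per).mean(axis=3)
    centers = env.t_start + window_s * (np.arange(n_win) + 0.5)
    return X.transpose(1, 0, 2), centers


def hg_decode(
    env: HGEnvelope,
    trials: pd.DataFrame,
    design: TaskDesign,
    label_def: str = "action",
    format: Optional[str] = None,
    channels: Optional[np.ndarray] = None,
    window_s: float = 0.5,
    folds: int = 10,
    var_keep: Optional[float] = 0.95,
    max_pc: int = 50,
    seed: int = 0,
):
    """Within-format LDA decoding of the unified HG envelope (500 ms windows)."""
    from .decoding import DecodingResult, _engine, get_labels

    if channels is not None and len(channels) == 0:
        raise ValueError("no task-relevant channels to decode from")
    X, centers = hg_features(env, channels, window_s)
    sel = trials["included"].to_numpy(dtype=bool)
    if format is not None:
        sel = sel & (trials["format"] == format).to_numpy()
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


def hg_cross_format_decode(
    env: HGEnvelope,
    trials: pd.DataFrame,
    design: TaskDesign,
    label_def: str = "action",
    train_format: str = "intention",
    channels: Optional[np.ndarray] = None,
    window_s: float = 0.5,
    n_perm: int = 1000,
    max_pc: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Cross-format LDA decoding of HG, 500 ms windows, permutation + Bonferroni."""
    from .decoding import GeneralizationMap, _fit_pca, _perm_accuracies, get_labels
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X, centers = hg_features(env, channels, window_s)
    test_format = "observation" if train_format == "intention" else "intention"
    inc = trials["included"].to_numpy(dtype=bool)
    tr_sel = inc & (trials["format"] == train_format).to_numpy()
    te_sel = inc & (trials["format"] == test_format).to_numpy()
    y = get_labels(trials, design, label_def)
    classes, y_int = np.unique(y, return_inverse=True)
    n_win = X.shape[2]
    stack = X[tr_sel].transpose(0, 2, 1).reshape(-1, X.shape[1])
    pca = _fit_pca(stack, max_pc)
    k = min(max_pc, pca.n_components_)
    W, mu = pca.components_[:k], pca.mean_
    yte = y_int[te_sel]
    preds = np.zeros((n_win * n_win, yte.size), dtype=int)
    for w in range(n_win):
        lda = LinearDiscriminantAnalysis()
        lda.fit((X[tr_sel, :, w] - mu) @ W.T, y_int[tr_sel])
        for v in range(n_win):
            preds[w * n_win + v] = lda.predict((X[te_sel, :, v] - mu) @ W.T)
    obs = (preds == yte).mean(axis=1)
    rng = np.random.default_rng(seed)
    null = _perm_accuracies(preds, yte, classes.size, n_perm, rng)
    p = (1 + (null >= obs[:, None]).sum(axis=1)) / (n_perm + 1)
    return GeneralizationMap(
        matrix=obs.reshape(n_win, n_win),
        train_centers_s=centers,
        test_centers_s=centers,
        direction=f"{train_format}->{test_format}",
        p=p.reshape(n_win, n_win),
        mask=(p < alpha / (n_win * n_win)).reshape(n_win, n_win),
        n_perm=n_perm,
        alpha=alpha,
    )


def hg_responsiveness(env: HGEnvelope, trials: pd.DataFrame, design: TaskDesign, format: str, **kwargs):
    """Channel-level responsiveness on the binned HG envelope."""
    from .responsiveness import test_responsiveness

    return test_responsiveness(env.to_binned(), trials, design, format, **kwargs)


def hg_tuning(env: HGEnvelope, trials: pd.DataFrame, design: TaskDesign, **kwargs):
    """Channel-level tuning ANOVA on the binned HG envelope."""
    from .tuning import anova_timecourse

    return anova_timecourse(env.to_binned(), trials, design, **kwargs)
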