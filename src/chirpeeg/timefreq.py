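"""Morlet wavelet time-frequency analysis of chirp epochs.

The bank covers integer frequencies 1-100 Hz with a complex Morlet whose
"parameter" c (default 10) is the frequency-to-spectral-bandwidth ratio:
sigma_t = c / (2*pi*f), so sigma_f = f / c and the 40-Hz kernel has a 4-Hz
spectral sd.  Kernels have unit L2 norm and are truncated at +/-4 sigma_t.

Inter-trial phase coherence at each (f, t) is the mean resultant length of
the per-trial unit phasors F_k/|F_k| of the complex coefficients: 1 for
perfect phase locking, approaching 1/sqrt(n) under uniform phases.  Induced
(non-phase-locked) power removes the trial-averaged evoked waveform before
transforming.  Maps are binned to the 100 x 625 analysis matrix used for
cluster statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .preprocess import EpochArray
from .synthgen import ValidationError

log = logging.getLogger(__name__)


@dataclass
class WaveletBank:
    center_freqs: np.ndarray
    c: float
    fs: float
    kernels: list[np.ndarray]       # complex, unit L2 norm, odd length

    @property
    def sigma_t(self) -> np.ndarray:
        return self.c / (2.0 * np.pi * self.center_freqs)

    @property
    def sigma_f(self) -> np.ndarray:
        return self.center_freqs / self.c

    def edge_validity(self, n_times: int) -> np.ndarray:
        """freqs x times mask, False within 2 sigma_t of either epoch edge
        (where the kernel support leaks past the data)."""
        idx = np.arange(n_times)
        margin = np.ceil(2.0 * self.sigma_t * self.fs).astype(int)
        return (idx[None, :] >= margin[:, None]) & \
               (idx[None, :] < n_times - margin[:, None])


def build_wavelet_bank(freqs: Sequence[float] | None = None, c: float = 10.0,
                       fs: float = 625.0) -> WaveletBank:
    """Complex Morlet kernels psi_f(t) = g(t; sigma_t) exp(i 2 pi f t)."""
    if freqs is None:
        freqs = np.arange(1.0, 101.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2.0:
        raise ValidationError("top wavelet frequency at or above Nyquist")
    if c <= 5.0:
        raise ValidationError("Morlet parameter must exceed 5 for admissibility")
    kernels = []
    for f in freqs:
        sigma_t = c / (2.0 * np.pi * f)
        half = int(math.ceil(4.0 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        psi = np.exp(-t**2 / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
        psi /= np.linalg.norm(psi)
        kernels.append(psi)
    return WaveletBank(center_freqs=freqs, c=c, fs=fs, kernels=kernels)


@dataclass
class TrialCoefficients:
    """Complex wavelet coefficients, trials x freqs x times."""

    F: np.ndarray
    freqs: np.ndarray
    fs: float
    validity: np.ndarray            # freqs x times edge mask

    @property
    def n(self) -> int:
        return self.F.shape[0]


@dataclass
class TimeFrequencyMap:
    values: np.ndarray              # freqs x time bins
    kind: str                       # itpc | induced_power | total_power
    n_trials: int
    epoch_span: float               # seconds covered by the time axis
    freqs: np.ndarray
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "itpc":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < -1e-9 or v.max() > 1.0 + 1e-9):
                raise ValidationError("ITPC values must lie in [0, 1]")


def select_signal(ep: EpochArray, selector) -> np.ndarray:
    """Kept-trials x time series for a region (time-domain channel average),
    a channel label, a channel index, or an explicit index list."""
    keep = ~ep.rejected
    data = ep.epochs[keep]
    if isinstance(selector, str):
        if selector in set(ep.region_assignment.values()):
            chans = ep.region_channels(selector)
        elif selector in ep.channel_labels:
            chans = [ep.channel_labels.index(selector)]
        else:
            raise ValidationError(f"unknown region or channel {selector!r}")
    elif isinstance(selector, int):
        chans = [selector]
    else:
        chans = list(selector)
    if not chans:
        raise ValidationError("empty channel selection")
    return data[:, chans, :].mean(axis=1)


def _convolve_bank(x: np.ndarray, bank: WaveletBank) -> np.ndarray:
    """Same-length complex convolution of trials x time with every kernel."""
    n_trials, T = x.shape
    kmax = max(len(k) for k in bank.kernels)
    nfft = next_fast_len(T + kmax - 1)
    K = np.zeros((len(bank.kernels), nfft), dtype=np.complex128)
    starts = []
    for i, ker in enumerate(bank.kernels):
        K[i, :len(ker)] = ker
        starts.append((len(ker) - 1) // 2)
    Kf = fft(K, axis=1)
    out = np.empty((n_trials, len(bank.kernels), T), dtype=np.complex64)
    for k in range(n_trials):
        Xf = fft(x[k], n=nfft)
        full = ifft(Xf[None, :] * Kf, axis=1)
        for i, s in enumerate(starts):
            out[k, i] = full[i, s:s + T]
    return out


def transform_epochs(ep: EpochArray, bank: WaveletBank,
                     selector) -> TrialCoefficients:
    """Complex Morlet coefficients of the selected signal, rejected trials
    excluded.  A region selector averages the region's channels in the time
    domain before transforming."""
    if ep.n_kept < 1:
        raise ValidationError("no non-rejected trials to transform")
    if abs(ep.fs - bank.fs) > 1e-9:
        raise ValidationError("wavelet bank fs does not match epochs")
    x = select_signal(ep, selector)
    F = _convolve_bank(x, bank)
    return TrialCoefficients(
        F=F, freqs=bank.center_freqs.copy(), fs=ep.fs,
        validity=bank.edge_validity(x.shape[1]),
    )


def compute_itpc(tc: TrialCoefficients) -> TimeFrequencyMap:
    """Mean resultant length of per-trial unit phasors at each (f, t).

    Coefficients with zero magnitude carry no phase and are excluded from
    that point's sum, with n adjusted accordingly.
    """
    if tc.n < 2:
        raise ValidationError("ITPC undefined for fewer than 2 trials")
    mag = np.abs(tc.F)
    nonzero = mag > 0
    phasors = np.where(nonzero, tc.F / np.where(nonzero, mag, 1.0), 0.0)
    counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        itpc = np.abs(phasors.sum(axis=0)) / counts
    itpc = np.where(counts >= 2, itpc, np.nan)
    return TimeFrequencyMap(
        values=itpc.astype(np.float64), kind="itpc", n_trials=tc.n,
        epoch_span=tc.F.shape[2] / tc.fs, freqs=tc.freqs.copy(),
        validity=tc.validity.copy(),
    )


def induced_power(ep: EpochArray, bank: WaveletBank, selector,
                  baseline_window: tuple[float, float] = (-0.5, 0.0)
                  ) -> TimeFrequencyMap:
    """Non-phase-locked single-trial power, baseline corrected.

    The trial-averaged evoked waveform is subtracted from each trial in the
    time domain before transforming; |F|^2 is averaged across trials and
    each frequency row expressed as percent change from its mean over the
    pre-stimulus baseline window.
    """
    if ep.n_kept < 2:
        raise ValidationError("induced power needs >= 2 non-rejected trials")
    x = select_signal(ep, selector)
    rms_total = float(np.sqrt(np.mean(x**2)))
    x = x - x.mean(axis=0, keepdims=True)
    # all-evoked input leaves only rounding noise: no meaningful baseline
    if rms_total > 0 and np.sqrt(np.mean(x**2)) < 1e-7 * rms_total:
        raise ValidationError(
            "degenerate baseline: all power is evoked, induced power is zero")
    F = _convolve_bank(x, bank)
    power = (np.abs(F) ** 2).mean(axis=0).astype(np.float64)
    times = np.arange(x.shape[1]) / ep.fs - ep.t0_offset
    lo, hi = baseline_window
    sel = (times >= lo) & (times < hi)
    if not sel.any():
        raise ValidationError("baseline window outside the epoch")
    base = power[:, sel].mean(axis=1)
    if np.any(base <= 0):
        raise ValidationError("degenerate baseline: zero mean power")
    values = 100.0 * (power - base[:, None]) / base[:, None]
    return TimeFrequencyMap(
        values=values, kind="induced_power", n_trials=x.shape[0],
        epoch_span=x.shape[1] / ep.fs, freqs=bank.center_freqs.copy(),
        validity=bank.edge_validity(x.shape[1]),
    )


def bin_to_matrix(tfmap: TimeFrequencyMap, n_time_bins: int = 625) -> TimeFrequencyMap:
    """Average non-overlapping time blocks down to the analysis matrix
    (100 x 625 for the default epoch; 1875 native samples -> 3 per bin).
    Trailing samples that do not fill a block are folded into the last bin."""
    n_freqs, T = tfmap.values.shape
    if T < n_time_bins:
        raise ValidationError(f"native time axis ({T}) shorter than {n_time_bins} bins")
    per = T // n_time_bins
    rem = T - per * n_time_bins
    main = tfmap.values[:, :per * n_time_bins].reshape(n_freqs, n_time_bins, per)
    binned = main.mean(axis=2)
    if rem:
        log.info("folding %d trailing samples into the last time bin", rem)
        tail = tfmap.values[:, per * (n_time_bins - 1):]
        binned[:, -1] = tail.mean(axis=1)
    validity = None
    if tfmap.validity is not None:
        vmain = tfmap.validity[:, :per * n_time_bins].reshape(n_freqs, n_time_bins, per)
        validity = vmain.all(axis=2)
        if rem:
            validity[:, -1] = tfmap.validity[:, per * (n_time_bins - 1):].all(axis=1)
    return TimeFrequencyMap(
        values=binned, kind=tfmap.kind, n_trials=tfmap.n_trials,
        epoch_span=tfmap.epoch_span, freqs=tfmap.freqs.copy(),
        validity=validity,
    )


def chirp_ridge_indices(tfmap: TimeFrequencyMap, stim, t0_offset: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(freq indices, time-bin indices) where the sweep crosses each
    integer frequency, for reading ITPC along the chirp diagonal."""
    n_bins = tfmap.values.shape[1]
    bin_dt = tfmap.epoch_span / n_bins
    fi, ti = [], []
    f0, f1 = stim.sweep_frequencies()
    lo, hi = min(f0, f1), max(f0, f1)
    for i, f in enumerate(tfmap.freqs):
        if not lo <= f <= hi:
            continue
        t = t0_offset + stim.time_at_frequency(float(f))
        b = int(t / bin_dt)
        if 0 <= b < n_bins:
            fi.append(i)
            ti.append(b)
    return np.array(fi), np.array(ti)
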