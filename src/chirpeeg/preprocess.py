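"""Preprocessing chain: down-sampling, notch filtering, segmentation,
artifact rejection and the animal-exclusion / outlier rules.

All filters are applied forward-backward (zero phase) so that event
latencies — and therefore the phase quantities computed downstream — are
unshifted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal, stats

from .synthgen import EventTable, Recording, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArtifactCriteria:
    """Rejection limits: absolute amplitude, per-sample gradient, and
    max-min range within a sliding window.  Defaults are typical rodent-EEG
    screening values; all configurable."""

    amplitude_limit: float = 500.0    # uV
    gradient_limit: float = 50.0      # uV per sample
    maxmin_limit: float = 300.0       # uV
    maxmin_window: float = 200.0      # ms

    def __post_init__(self) -> None:
        for name in ("amplitude_limit", "gradient_limit", "maxmin_limit",
                     "maxmin_window"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class SegmentSet:
    """Fixed-length contiguous resting segments with a rejection mask."""

    segments: np.ndarray            # n_segments x channels x L
    segment_onsets: np.ndarray      # sample index of each segment start
    rejected: np.ndarray            # bool per segment
    fs: float
    channel_labels: list[str]
    region_assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rejected) != self.segments.shape[0]:
            raise ValidationError("rejection mask does not match segment count")

    @property
    def data(self) -> np.ndarray:
        return self.segments

    @property
    def n_kept(self) -> int:
        return int(np.sum(~self.rejected))

    def region_channels(self, region: str) -> list[int]:
        return [i for i, c in enumerate(self.channel_labels)
                if self.region_assignment[c] == region]


@dataclass
class EpochArray:
    """Per-trial chirp epochs; t=0 is the onset of the modulated portion,
    preceded by ``t0_offset`` seconds of pre-window."""

    epochs: np.ndarray              # n_trials x channels x T
    t0_offset: float
    rejected: np.ndarray
    fs: float
    channel_labels: list[str]
    region_assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rejected) != self.epochs.shape[0]:
            raise ValidationError("rejection mask does not match trial count")

    @property
    def data(self) -> np.ndarray:
        return self.epochs

    @property
    def n_kept(self) -> int:
        return int(np.sum(~self.rejected))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.epochs.shape[2]) / self.fs - self.t0_offset

    def region_channels(self, region: str) -> list[int]:
        return [i for i, c in enumerate(self.channel_labels)
                if self.region_assignment[c] == region]


# ---------------------------------------------------------------------------
# filters


def downsample(rec: Recording, target_fs: float = 625.0) -> Recording:
    """Anti-aliased integer-factor decimation with zero-phase FIR.

    The low-pass cutoff sits at 0.9x the new Nyquist so content below
    0.8x Nyquist passes within 1%; events are re-indexed to the new rate.
    """
    ratio = rec.fs / target_fs
    q = round(ratio)
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValidationError(
            f"fs {rec.fs} is not an integer multiple of {target_fs}; "
            "resample to a compatible rate first"
        )
    if q == 1:
        return replace(rec, samples=rec.samples.copy())
    cutoff = 0.9 * (target_fs / 2.0)
    taps = signal.firwin(129, cutoff, fs=rec.fs)
    filtered = signal.filtfilt(taps, [1.0], rec.samples, axis=1)
    out = filtered[:, ::q]
    events = EventTable(
        onsets=np.round(rec.events.onsets / q).astype(np.int64),
        kinds=list(rec.events.kinds),
        stimuli=list(rec.events.stimuli),
    )
    return Recording(
        fs=target_fs,
        samples=out,
        channel_labels=list(rec.channel_labels),
        region_assignment=dict(rec.region_assignment),
        events=events,
    )


def notch_filter(rec: Recording, freq: float = 60.0,
                 bandwidth: float = 5.0) -> Recording:
    """Zero-phase IIR notch; -3 dB points at freq +/- bandwidth/2 per pass."""
    if freq >= rec.fs / 2.0:
        raise ValidationError(f"notch frequency {freq} at or above Nyquist")
    b, a = signal.iirnotch(freq, freq / bandwidth, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.samples, axis=1)
    return replace(rec, samples=out)


# ---------------------------------------------------------------------------
# segmentation


def segment_resting(rec: Recording, seg_len: float = 1.0) -> SegmentSet:
    """Non-overlapping contiguous segments from the start; remainder dropped."""
    L = round(seg_len * rec.fs)
    n_seg = rec.n_samples // L
    if n_seg == 0:
        log.warning("recording shorter than one %.3g-s segment; zero segments",
                    seg_len)
    segs = rec.samples[:, :n_seg * L].reshape(rec.n_channels, n_seg, L)
    segs = np.ascontiguousarray(np.swapaxes(segs, 0, 1))
    return SegmentSet(
        segments=segs,
        segment_onsets=np.arange(n_seg, dtype=np.int64) * L,
        rejected=np.zeros(n_seg, dtype=bool),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        region_assignment=dict(rec.region_assignment),
    )


def epoch_chirp(rec: Recording, pre_s: float = 0.5,
                post_s: float = 0.5) -> EpochArray:
    """One epoch per chirp event, [-pre_s, chirp_duration + post_s) around
    the onset of the modulated portion (the level ramp precedes it).

    Trials whose window falls outside the recording are dropped with a
    warning.  With the default 2-s chirp and 0.5-s margins the epoch is 3 s.
    """
    if not len(rec.events):
        raise ValidationError("recording has no events to epoch")
    stim = rec.events.stimuli[0]
    T = round((pre_s + stim.chirp_duration + post_s) * rec.fs)
    pre_n = round(pre_s * rec.fs)
    epochs = []
    for onset, s in zip(rec.events.onsets, rec.events.stimuli):
        if (s.chirp_duration, s.ramp_duration) != (stim.chirp_duration,
                                                   stim.ramp_duration):
            raise ValidationError("mixed stimulus durations in one session")
        mod_onset = onset + round(s.ramp_duration * rec.fs)
        start = mod_onset - pre_n
        if start < 0 or start + T > rec.n_samples:
            log.warning("dropping trial at sample %d: window outside recording",
                        onset)
            continue
        epochs.append(rec.samples[:, start:start + T])
    if not epochs:
        raise ValidationError("no trial fits inside the recording")
    arr = np.stack(epochs)
    return EpochArray(
        epochs=arr,
        t0_offset=pre_s,
        rejected=np.zeros(arr.shape[0], dtype=bool),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        region_assignment=dict(rec.region_assignment),
    )


# ---------------------------------------------------------------------------
# artifact rejection


def _criterion_mask(data: np.ndarray, fs: float,
                    crit: ArtifactCriteria) -> np.ndarray:
    """Boolean per segment/epoch: any channel violates any criterion."""
    amp_bad = np.any(np.abs(data) > crit.amplitude_limit, axis=(1, 2))
    grad = np.abs(np.diff(data, axis=2))
    grad_bad = np.any(grad > crit.gradient_limit, axis=(1, 2)) if grad.size else \
        np.zeros(data.shape[0], dtype=bool)
    win = max(2, round(crit.maxmin_window / 1000.0 * fs))
    win = min(win, data.shape[2])
    mx = ndimage.maximum_filter1d(data, size=win, axis=2, mode="nearest")
    mn = ndimage.minimum_filter1d(data, size=win, axis=2, mode="nearest")
    mm_bad = np.any(mx - mn > crit.maxmin_limit, axis=(1, 2))
    return amp_bad | grad_bad | mm_bad


def detect_artifacts(x: SegmentSet | EpochArray,
                     crit: ArtifactCriteria | None = None):
    """Return a copy of ``x`` with its rejection mask OR-ed with the
    amplitude / gradient / max-min criteria (any-channel rule)."""
    if crit is None:
        crit = ArtifactCriteria()
    bad = _criterion_mask(x.data, x.fs, crit)
    return replace(x, rejected=x.rejected | bad)


def exclusion_decision(rejected: np.ndarray) -> tuple[str, float]:
    """Animal-level rule: exclude iff strictly more than 30% rejected."""
    rejected = np.asarray(rejected, dtype=bool)
    if rejected.size == 0:
        raise ValidationError("empty rejection mask")
    frac = float(np.mean(rejected))
    return ("exclude" if frac > 0.30 else "keep"), frac


# ---------------------------------------------------------------------------
# outlier screening


def _grubbs_critical(n: int, alpha: float) -> float:
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))


def grubbs_outlier(values, alpha: float = 0.05) -> list[int]:
    """Iterated two-sided Grubbs test; returns indices removed, in order.

    At most one value is removed per iteration (the most extreme), until no
    remaining value exceeds the critical G at the given alpha or fewer than
    three values remain.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValidationError("Grubbs test needs a 1-D sample of n >= 3")
    active = list(range(len(values)))
    removed: list[int] = []
    while len(active) >= 3:
        x = values[active]
        sd = np.std(x, ddof=1)
        if sd == 0:
            break
        g = np.abs(x - np.mean(x)) / sd
        i_max = int(np.argmax(g))
        if g[i_max] > _grubbs_critical(len(x), alpha):
            removed.append(active.pop(i_max))
        else:
            break
    return removed
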