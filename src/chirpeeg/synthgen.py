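"""Synthetic 30-channel mouse EEG with known ground truth.

Generates recordings with the statistical structure the downstream analysis
assumes: a 1/f background with configurable per-band power gains, 60-Hz line
noise, occasional high-amplitude artifacts, and chirp-evoked
envelope-following responses whose per-trial phase jitter is von Mises with a
concentration chosen to hit a target population phase-locking factor.  Every
generator is deterministic given the scenario seed; independent named
substreams keep the background realization invariant when artifacts or trials
are added.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special

REGIONS = ("LF", "RF", "LM", "RM", "LT", "RT")

#: canonical band edges, Hz; all half-open [lo, hi) except high_gamma, closed
#: at 100.  The 55-65 Hz gap guards the mains notch.
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 55.0),
    "high_gamma": (65.0, 100.0),
}

_STREAMS = {"background": 0, "trials": 1, "artifacts": 2}


class ValidationError(ValueError):
    """Raised when a scenario, stimulus or operation input is inconsistent."""


@dataclass(frozen=True)
class ChirpStimulus:
    """Amplitude-modulated broadband chirp: a level ramp then a linear sweep.

    The sound is broadband noise whose level ramps 0 -> 100% over
    ``ramp_duration`` and is then amplitude modulated for ``chirp_duration``
    by a sinusoid whose frequency sweeps linearly between ``f_start`` and
    ``f_end`` (up) or the reverse (down), at the given modulation depth.
    """

    ramp_duration: float = 1.0
    chirp_duration: float = 2.0
    f_start: float = 1.0
    f_end: float = 100.0
    direction: str = "up"
    modulation_depth: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ramp_duration) and self.ramp_duration >= 0):
            raise ValidationError("ramp_duration must be finite and >= 0")
        if not (math.isfinite(self.chirp_duration) and self.chirp_duration > 0):
            raise ValidationError("chirp_duration must be finite and > 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValidationError("modulation_depth must lie in [0, 1]")
        if self.direction not in ("up", "down"):
            raise ValidationError("direction must be 'up' or 'down'")
        if self.f_start >= self.f_end:
            raise ValidationError("f_start must be below f_end")

    @property
    def duration(self) -> float:
        return self.ramp_duration + self.chirp_duration

    def sweep_frequencies(self) -> tuple[float, float]:
        """(start, end) instantaneous modulation frequency of the sweep."""
        if self.direction == "up":
            return self.f_start, self.f_end
        return self.f_end, self.f_start

    def time_at_frequency(self, f: float) -> float:
        """Time (s, from modulation onset) when the sweep crosses ``f``."""
        f0, f1 = self.sweep_frequencies()
        lo, hi = min(f0, f1), max(f0, f1)
        if not lo <= f <= hi:
            raise ValidationError(f"{f} Hz outside the {lo}-{hi} Hz sweep")
        return self.chirp_duration * (f - f0) / (f1 - f0)


@dataclass(frozen=True)
class SimScenario:
    """Everything that defines one simulated animal/condition.

    ``band_gain`` multiplies the mean background PSD inside each canonical
    band (linear power units); ``plf_profile`` maps modulation frequency to
    the target population phase-locking factor r in [0, 1) of the evoked
    response.  ``background_rms`` is the RMS (uV) the background would have
    with all band gains at 1; gains then scale in-band power exactly.
    """

    label: str = "default"
    n_channels: int = 30
    region_assignment: dict[str, str] | None = None
    fs: float = 1250.0
    one_over_f_exponent: float = 1.0
    band_gain: dict[str, float] = field(default_factory=dict)
    plf_profile: dict[float, float] = field(default_factory=lambda: {40.0: 0.5})
    evoked_gain: float = 40.0
    background_rms: float = 15.0
    line_noise_amp: float = 5.0
    artifact_rate: float = 2.0
    artifact_amp: float = 800.0
    n_trials: int = 300
    iti_range: tuple[float, float] = (1.0, 1.5)
    resting_duration: float = 300.0
    stimulus: ChirpStimulus = field(default_factory=ChirpStimulus)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("evoked_gain", "background_rms", "line_noise_amp",
                     "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValidationError("iti_range lower bound exceeds upper bound")
        for f, r in self.plf_profile.items():
            if not 0.0 <= r < 1.0:
                raise ValidationError(f"plf_profile[{f}]={r} outside [0, 1)")
        for g in self.band_gain.values():
            if g < 0:
                raise ValidationError("band gains must be >= 0")
        if self.region_assignment is None:
            object.__setattr__(
                self, "region_assignment", default_region_assignment(self.n_channels)
            )
        labels = self.channel_labels
        missing = [c for c in labels if c not in self.region_assignment]
        if missing:
            raise ValidationError(f"region_assignment misses channels {missing}")

    @property
    def channel_labels(self) -> list[str]:
        if self.region_assignment is not None and len(self.region_assignment) == self.n_channels:
            return list(self.region_assignment)
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent substream of the scenario RNG."""
        key = _STREAMS[stream]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


def default_region_assignment(n_channels: int) -> dict[str, str]:
    """Channels in blocks over LF,RF,LM,RM,LT,RT (5 per region for 30)."""
    per = max(1, math.ceil(n_channels / len(REGIONS)))
    out: dict[str, str] = {}
    for i in range(n_channels):
        out[f"ch{i:02d}"] = REGIONS[min(i // per, len(REGIONS) - 1)]
    return out


@dataclass
class EventTable:
    """Stimulus onsets (sample of sound/ramp start) with their stimuli."""

    onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    kinds: list[str] = field(default_factory=list)
    stimuli: list[ChirpStimulus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if len(self.onsets) != len(self.kinds) or len(self.onsets) != len(self.stimuli):
            raise ValidationError("event columns differ in length")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValidationError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class Recording:
    """Continuous multichannel EEG: channels x time samples in microvolts."""

    fs: float
    samples: np.ndarray
    channel_labels: list[str]
    region_assignment: dict[str, str]
    events: EventTable = field(default_factory=EventTable)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.samples.ndim != 2:
            raise ValidationError("samples must be channels x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValidationError("channel_labels do not match sample rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if len(self.events):
            total = self.events.onsets[-1] + round(
                self.events.stimuli[-1].duration * self.fs
            )
            if total > self.samples.shape[1]:
                # tolerated (e.g. truncated acquisitions); epoching drops
                # trials whose window leaves the recording
                logging.getLogger(__name__).warning(
                    "last event extends past end of recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def region_channels(self, region: str) -> list[int]:
        return [
            i for i, c in enumerate(self.channel_labels)
            if self.region_assignment[c] == region
        ]


# ---------------------------------------------------------------------------
# chirp envelope


def _sweep_phase(stim: ChirpStimulus, t: np.ndarray) -> np.ndarray:
    """Phase of the AM sinusoid at times t (s from modulation onset)."""
    f0, f1 = stim.sweep_frequencies()
    rate = (f1 - f0) / stim.chirp_duration
    return 2.0 * np.pi * (f0 * t + 0.5 * rate * t**2)


def make_chirp_envelope(stim: ChirpStimulus, fs: float) -> np.ndarray:
    """Unit-amplitude sound-level envelope: linear ramp then AM sweep.

    Returns values in [0, 1] of length round(duration * fs): a linear rise
    0 -> 1 over the ramp, then (1 + depth*cos(phi(t))) / 2 where the
    instantaneous modulation frequency sweeps linearly across the chirp.
    """
    f_hi = max(stim.f_start, stim.f_end)
    if fs <= 2.0 * f_hi:
        raise ValidationError(f"fs={fs} must exceed twice the top sweep frequency")
    n_total = round(stim.duration * fs)
    n_ramp = round(stim.ramp_duration * fs)
    env = np.empty(n_total)
    env[:n_ramp] = np.arange(n_ramp) / max(n_ramp, 1)
    t = np.arange(n_total - n_ramp) / fs
    env[n_ramp:] = 0.5 * (1.0 + stim.modulation_depth * np.cos(_sweep_phase(stim, t)))
    return env


def chirp_oscillation(stim: ChirpStimulus, fs: float,
                      phase_offset: np.ndarray | float = 0.0) -> np.ndarray:
    """Zero-mean oscillatory component of the AM envelope over the sweep.

    Length round(chirp_duration * fs); amplitude depth/2, so the full
    envelope equals 1/2 + this (after the ramp).  ``phase_offset`` may be a
    scalar or per-sample array (radians), which is how trial-specific phase
    jitter enters.
    """
    n = round(stim.chirp_duration * fs)
    t = np.arange(n) / fs
    return 0.5 * stim.modulation_depth * np.cos(_sweep_phase(stim, t) + phase_offset)


# ---------------------------------------------------------------------------
# von Mises phase-locking calibration


def kappa_from_r(r: float) -> float:
    """Von Mises concentration with mean resultant length r = I1(k)/I0(k)."""
    if not 0.0 <= r < 1.0:
        raise ValidationError("r must lie in [0, 1)")
    if r < 1e-8:
        return 0.0
    if r > 0.999:
        # asymptotic A(k) ~ 1 - 1/(2k)
        return 0.5 / (1.0 - r)
    f = lambda k: special.i1e(k) / special.i0e(k) - r
    return float(optimize.brentq(f, 1e-9, 2.0 / (1.0 - r) + 10.0))


def resultant_length(kappa: float) -> float:
    """Population mean resultant length of a von Mises(kappa) sample."""
    if kappa == 0.0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def _circular_interp(theta: np.ndarray, t_knots: np.ndarray,
                     t: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of angles along the shortest arc."""
    if len(theta) == 1:
        return np.full_like(t, theta[0], dtype=float)
    dtheta = np.angle(np.exp(1j * np.diff(theta)))  # wrapped steps
    unwrapped = np.concatenate([[theta[0]], theta[0] + np.cumsum(dtheta)])
    return np.interp(t, t_knots, unwrapped)


def trial_phase_offsets(scn: SimScenario, n_samples: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-sample phase offset (radians) over the sweep for one trial.

    Phases are drawn von Mises(0, kappa(r_f)) at each plf_profile knot
    frequency and circularly interpolated across the knots' sweep-crossing
    times, so the population phase-locking factor equals the profile exactly
    at the knots (and for a constant single-knot profile, everywhere).
    """
    stim = scn.stimulus
    freqs = np.array(sorted(scn.plf_profile))
    t_knots = np.array([stim.time_at_frequency(f) for f in freqs])
    order = np.argsort(t_knots)
    t_knots = t_knots[order]
    kappas = np.array([kappa_from_r(scn.plf_profile[f]) for f in freqs])[order]
    theta = np.array([
        rng.vonmises(0.0, k) if k > 0 else rng.uniform(-np.pi, np.pi)
        for k in kappas
    ])
    t = np.arange(n_samples) / scn.fs
    return _circular_interp(theta, t_knots, t)


# ---------------------------------------------------------------------------
# background


def _band_gain_profile(freqs: np.ndarray, band_gain: dict[str, float]) -> np.ndarray:
    gains = np.ones_like(freqs)
    for band, g in band_gain.items():
        lo, hi = DEFAULT_BANDS[band]
        sel = (freqs >= lo) & ((freqs < hi) | ((hi == 100.0) & (freqs <= hi)))
        gains[sel] = g
    return gains


def simulate_background(scn: SimScenario, duration: float | None = None,
                        rng: np.random.Generator | None = None) -> Recording:
    """Resting-state background: shaped 1/f noise + band gains + line noise.

    Gaussian noise is spectrally shaped to 1/f^beta over 0.5-500 Hz in the
    Fourier domain; within each canonical band the PSD is additionally
    multiplied by band_gain[band].  The amplitude normalization is computed
    with all gains at 1, so gains scale in-band power by exactly their value.
    A 60-Hz sinusoid of amplitude line_noise_amp with a random phase per
    channel is added last.
    """
    if duration is None:
        duration = scn.resting_duration
    if not duration > 0:
        raise ValidationError("duration must be positive")
    if rng is None:
        rng = scn.rng("background")
    n = round(duration * scn.fs)
    freqs = np.fft.rfftfreq(n, 1.0 / scn.fs)
    beta = scn.one_over_f_exponent
    in_band = (freqs >= 0.5) & (freqs <= 500.0)
    base = np.zeros_like(freqs)
    base[in_band] = freqs[in_band] ** (-beta / 2.0)

    # unit-variance normalization of the gain=1 shape (see docstring)
    mult = np.full(len(freqs), 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    var1 = float(np.sum(mult * base**2)) / n
    amp = base * (scn.background_rms / math.sqrt(var1))
    amp = amp * np.sqrt(_band_gain_profile(freqs, scn.band_gain))

    data = np.empty((scn.n_channels, n))
    t = np.arange(n) / scn.fs
    for ch in range(scn.n_channels):
        white = rng.standard_normal(n)
        shaped = np.fft.irfft(np.fft.rfft(white) * amp, n=n)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data[ch] = shaped + scn.line_noise_amp * np.sin(2.0 * np.pi * 60.0 * t + phase)
    return Recording(
        fs=scn.fs,
        samples=data,
        channel_labels=scn.channel_labels,
        region_assignment=dict(scn.region_assignment),
    )


# ---------------------------------------------------------------------------
# chirp session

_LEAD_IN_S = 2.0  # quiet padding before the first train and after the last


def simulate_chirp_session(scn: SimScenario) -> Recording:
    """Chirp-train session: background plus phase-jittered evoked responses.

    Each of n_trials trains adds, to every channel, evoked_gain times the
    oscillatory component of the AM envelope with a per-trial von Mises
    phase offset (see trial_phase_offsets).  Inter-onset gaps are the
    stimulus duration plus Uniform(iti_range).  Onset events mark the start
    of the sound (ramp start); the modulated portion begins one ramp later.
    """
    rng = scn.rng("trials")
    stim = scn.stimulus
    stim_n = round(stim.duration * scn.fs)
    itis = rng.uniform(scn.iti_range[0], scn.iti_range[1], size=scn.n_trials)
    onsets = np.empty(scn.n_trials, dtype=np.int64)
    pos = round(_LEAD_IN_S * scn.fs)
    for k in range(scn.n_trials):
        onsets[k] = pos
        pos += stim_n + round(itis[k] * scn.fs)
    n_total = pos + round(_LEAD_IN_S * scn.fs)
    if onsets[-1] + stim_n > n_total:
        raise ValidationError("session too short to fit all trials")

    rec = simulate_background(scn, duration=n_total / scn.fs)
    kind = f"chirp_{stim.direction}"
    ramp_n = round(stim.ramp_duration * scn.fs)
    chirp_n = round(stim.chirp_duration * scn.fs)
    for k in range(scn.n_trials):
        offs = trial_phase_offsets(scn, chirp_n, rng)
        wave = scn.evoked_gain * chirp_oscillation(stim, scn.fs, offs)
        start = onsets[k] + ramp_n
        rec.samples[:, start:start + chirp_n] += wave
    rec.events = EventTable(
        onsets=onsets,
        kinds=[kind] * scn.n_trials,
        stimuli=[stim] * scn.n_trials,
    )
    return rec


# ---------------------------------------------------------------------------
# artifacts


@dataclass(frozen=True)
class ArtifactInterval:
    start: int
    stop: int
    channel: int
    amplitude: float


def inject_artifacts(rec: Recording, scn: SimScenario
                     ) -> tuple[Recording, list[ArtifactInterval]]:
    """Add transient high-amplitude deflections at Poisson times.

    Each artifact is a raised-cosine bump of peak amplitude artifact_amp and
    duration uniform in 50-300 ms on one random channel.  Returns a new
    recording plus the ground-truth interval list; artifact_rate=0 returns
    the input unchanged.
    """
    if scn.artifact_rate < 0:
        raise ValidationError("artifact_rate must be >= 0")
    if scn.artifact_rate == 0:
        return rec, []
    rng = scn.rng("artifacts")
    minutes = rec.duration / 60.0
    count = rng.poisson(scn.artifact_rate * minutes)
    out = replace(rec, samples=rec.samples.copy())
    truth: list[ArtifactInterval] = []
    for _ in range(count):
        dur_n = round(rng.uniform(0.05, 0.30) * rec.fs) | 1  # odd: exact peak
        start = int(rng.integers(0, max(1, rec.n_samples - dur_n)))
        ch = int(rng.integers(0, rec.n_channels))
        tau = np.arange(dur_n) / (dur_n - 1)
        bump = scn.artifact_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
        out.samples[ch, start:start + dur_n] += bump
        truth.append(ArtifactInterval(start, start + dur_n, ch, scn.artifact_amp))
    truth.sort(key=lambda a: a.start)
    return out, truth
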