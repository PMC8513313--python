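"""Resting-state spectral analysis.

Each artifact-free 1-s segment is Hanning-windowed, zero-padded to 2 s to
realize a 0.5-Hz grid, and turned into a one-sided power spectral density
(uV^2/Hz) with window power compensation; densities are averaged across
segments and restricted to 1-100 Hz.  Band summaries are mean densities
over the canonical bands (delta 1-4, theta 4-8, alpha 8-13, beta 13-30,
low gamma 30-55, high gamma 65-100 Hz; 55-65 Hz is deliberately
uncovered), averaged over each region's channels, and are usually reported
as ratios to a reference (control) group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import SegmentSet
from .synthgen import DEFAULT_BANDS, REGIONS, ValidationError


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency intervals; half-open [lo, hi) except the last band,
    which closes at the top of the analysis range."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (l0, h0), (l1, h1) in zip(edges, edges[1:]):
            if l1 < h0:
                raise ValidationError("band intervals overlap")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        top = max(h for _, h in self.bands.values())
        sel = (freqs >= lo) & (freqs < hi)
        if hi == top:
            sel |= freqs == hi
        return sel


@dataclass
class PowerSpectrum:
    """Per-channel PSD on the 0.5-Hz grid over 1-100 Hz."""

    freqs: np.ndarray               # Hz
    psd: np.ndarray                 # channels x freqs, uV^2/Hz
    n_segments_used: int
    channel_labels: list[str]
    region_assignment: dict[str, str]

    def region_channels(self, region: str) -> list[int]:
        return [i for i, c in enumerate(self.channel_labels)
                if self.region_assignment[c] == region]


def _segment_psds(segs: SegmentSet, use_rejected: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(freqs, per-segment PSD array kept_segments x channels x freqs)."""
    keep = np.ones(len(segs.rejected), bool) if use_rejected else ~segs.rejected
    data = segs.segments[keep]
    if data.shape[0] == 0:
        raise ValidationError("all segments rejected; subject should be excluded")
    L = data.shape[2]
    nfft = 2 * L  # zero-pad 1-s segments to 2 s -> 0.5-Hz bins
    freqs, psd = signal.periodogram(
        data, fs=segs.fs, window="hann", nfft=nfft, detrend="constant",
        scaling="density", axis=2,
    )
    sel = (freqs >= 1.0) & (freqs <= 100.0)
    return freqs[sel], psd[..., sel]


def resting_psd(segs: SegmentSet) -> PowerSpectrum:
    """Average one-sided PSD across non-rejected segments, 1-100 Hz."""
    freqs, psd = _segment_psds(segs)
    return PowerSpectrum(
        freqs=freqs,
        psd=psd.mean(axis=0),
        n_segments_used=psd.shape[0],
        channel_labels=list(segs.channel_labels),
        region_assignment=dict(segs.region_assignment),
    )


def band_powers(ps: PowerSpectrum, bands: BandDefinition | None = None,
                regions: Sequence[str] = REGIONS,
                mode: str = "mean") -> pd.DataFrame:
    """Region x band summary of a PSD.

    ``mode='mean'`` (default) reports the mean density in the band, making
    bands of different widths comparable; ``mode='integral'`` reports the
    integrated power (density times the 0.5-Hz bin width).
    """
    if bands is None:
        bands = BandDefinition()
    rows = []
    df = float(np.median(np.diff(ps.freqs)))
    for region in regions:
        chans = ps.region_channels(region)
        if not chans:
            raise ValidationError(f"region {region} has no channels")
        region_psd = ps.psd[chans].mean(axis=0)
        for band in bands.names:
            sel = bands.mask(ps.freqs, band)
            if not sel.any():
                raise ValidationError(f"frequency grid does not cover band {band}")
            value = region_psd[sel].mean() if mode == "mean" else \
                region_psd[sel].sum() * df
            rows.append({"region": region, "band": band, "value": value})
    return pd.DataFrame(rows)


def band_power_table(subject_spectra: Iterable[tuple[str, str, PowerSpectrum]],
                     bands: BandDefinition | None = None,
                     regions: Sequence[str] = REGIONS) -> pd.DataFrame:
    """Tidy table (subject, group, region, band, value) across subjects."""
    frames = []
    for subject, group, ps in subject_spectra:
        df = band_powers(ps, bands, regions)
        df.insert(0, "group", group)
        df.insert(0, "subject", subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def normalize_to_reference(tbl: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Add a ``ratio`` column: value / reference-group mean per region x band."""
    ref = tbl[tbl["group"] == reference_group]
    if ref.empty:
        raise ValidationError(f"reference group {reference_group!r} not in table")
    ref_means = ref.groupby(["region", "band"])["value"].mean()
    if (ref_means == 0).any():
        raise ValidationError("reference mean is zero for some region x band")
    out = tbl.copy()
    out["ratio"] = out.apply(
        lambda r: r["value"] / ref_means[(r["region"], r["band"])], axis=1)
    return out


def power_coupling(segs: SegmentSet,
                   pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
                   bands: BandDefinition | None = None) -> pd.DataFrame:
    """Pearson correlation of per-segment band powers between (band, region)
    pairs, across non-rejected segments; two-sided p from the t transform."""
    if bands is None:
        bands = BandDefinition()
    freqs, psd = _segment_psds(segs)     # kept x channels x freqs
    if psd.shape[0] < 3:
        raise ValidationError("power coupling needs >= 3 non-rejected segments")

    def series(band: str, region: str) -> np.ndarray:
        chans = segs.region_channels(region)
        if not chans:
            raise ValidationError(f"region {region} has no channels")
        sel = bands.mask(freqs, band)
        return psd[:, chans][:, :, sel].mean(axis=(1, 2))

    rows = []
    for (band_a, region_a), (band_b, region_b) in pairs:
        a, b = series(band_a, region_a), series(band_b, region_b)
        if np.std(a) == 0 or np.std(b) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(a, b)
        rows.append({
            "band_a": band_a, "region_a": region_a,
            "band_b": band_b, "region_b": region_b,
            "r": r, "p": p, "n_segments": len(a),
        })
    return pd.DataFrame(rows)
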