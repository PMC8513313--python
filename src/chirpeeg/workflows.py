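"""End-to-end drivers chaining the pipeline stages.

These are the entry points the analysis scripts and the acceptance checks
share: simulate (or load) a recording, preprocess it, and reduce it to the
band-power table or the binned ITPC matrix.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import spectral as sp
from . import timefreq as tf
from .clusterstats import GroupedMaps
from .synthgen import Recording, SimScenario, simulate_background, simulate_chirp_session


def preprocess_recording(rec: Recording, target_fs: float = 625.0,
                         notch_freq: float = 60.0) -> Recording:
    """Down-sample then zero-phase notch filter."""
    return pp.notch_filter(pp.downsample(rec, target_fs), notch_freq)


def resting_segments(rec: Recording,
                     criteria: pp.ArtifactCriteria | None = None
                     ) -> pp.SegmentSet:
    """Preprocess, segment into 1-s pieces, and mark artifacts."""
    clean = preprocess_recording(rec)
    return pp.detect_artifacts(pp.segment_resting(clean), criteria)


def subject_spectrum(scn: SimScenario) -> sp.PowerSpectrum:
    """Simulated resting recording -> artifact-screened average PSD."""
    rec = simulate_background(scn)
    return sp.resting_psd(resting_segments(rec))


def cohort_band_table(cohort: Iterable[tuple[str, str, SimScenario]],
                      reference_group: str) -> pd.DataFrame:
    """Tidy band-power table with control ratios for a simulated cohort.

    ``cohort`` yields (subject, group, scenario) triples; ratios are taken
    to the named reference group's mean per region x band.
    """
    spectra = [(subj, group, subject_spectrum(scn))
               for subj, group, scn in cohort]
    tbl = sp.band_power_table(spectra)
    return sp.normalize_to_reference(tbl, reference_group)


def session_epochs(scn: SimScenario,
                   criteria: pp.ArtifactCriteria | None = None
                   ) -> pp.EpochArray:
    """Simulated chirp session -> preprocessed, artifact-screened epochs."""
    rec = simulate_chirp_session(scn)
    clean = preprocess_recording(rec)
    return pp.detect_artifacts(pp.epoch_chirp(clean), criteria)


def session_itpc_matrix(scn: SimScenario, region: str = "LF",
                        n_time_bins: int = 625,
                        bank: tf.WaveletBank | None = None
                        ) -> tf.TimeFrequencyMap:
    """Simulated chirp session -> binned ITPC matrix for one region."""
    ep = session_epochs(scn)
    if bank is None:
        bank = tf.build_wavelet_bank(fs=ep.fs)
    tc = tf.transform_epochs(ep, bank, region)
    return tf.bin_to_matrix(tf.compute_itpc(tc), n_time_bins)


def cohort_itpc_maps(cohort: Sequence[tuple[str, SimScenario]],
                     region: str = "LF") -> GroupedMaps:
    """Per-subject ITPC matrices stacked for the cluster test.

    ``cohort`` is a sequence of (group_label, scenario); the shared edge
    validity mask excludes bins where any subject's wavelet leaks past the
    epoch.
    """
    maps, labels, validity = [], [], None
    bank = None
    for group, scn in cohort:
        ep = session_epochs(scn)
        if bank is None:
            bank = tf.build_wavelet_bank(fs=ep.fs)
        tc = tf.transform_epochs(ep, bank, region)
        m = tf.bin_to_matrix(tf.compute_itpc(tc))
        maps.append(m.values)
        labels.append(group)
        validity = m.validity if validity is None else (validity & m.validity)
    return GroupedMaps(maps=np.stack(maps), group_labels=np.array(labels),
                       validity_mask=validity)
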