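# Methods

This package implements, as tested library code, a complete analysis chain
for awake-mouse multichannel EEG experiments built around two measurements:
resting-state spectral band power over six cortical regions, and inter-trial
phase coherence (ITPC) of the envelope-following response to an
amplitude-modulated "chirp" stimulus. Because the pipeline is meant to be
verifiable without any recorded data, it ships with a synthetic-recording
generator whose ground-truth parameters the analysis must recover; the
generator is first-class, tested code, not a fixture.

## Recording model

A recording is a channels × time array in microvolts with a sampling rate,
a channel → region map over {LF, RF, LM, RM, LT, RT} (left/right frontal,
medial, temporal), and an event table of stimulus onsets. The emulated
acquisition is a 30-channel skull-surface grid sampled at 1250 Hz with a
0.5–500 Hz acquisition band-pass; the default region map assigns five
consecutive channels per region and is fully configurable, since real grids
differ.

## Chirp stimulus

The stimulus is broadband noise whose level ramps linearly 0 → 100% over
1 s (avoiding onset transients) and is then amplitude modulated for 2 s at
100% depth by a sinusoid whose frequency sweeps linearly over 1–100 Hz
(up or down). `make_chirp_envelope` returns the sound-level envelope
(ramp, then `(1 + depth·cos φ(t))/2` with `φ̇(t)/2π` the linear sweep);
`chirp_oscillation` returns its zero-mean oscillatory part, which is what
the simulated brain follows.

## Synthetic data generator

Each simulated animal/condition is a `SimScenario`. Its components:

- **Background.** Gaussian noise spectrally shaped to `1/f^β` over
  0.5–500 Hz in the Fourier domain (default β = 1), with the mean PSD inside
  each canonical band multiplied by a configurable `band_gain` (this is
  where a "genotype" gamma elevation lives). `background_rms` (default
  15 µV) sets the RMS the background would have with all gains at 1; the
  normalization is computed at gain 1 so that gains scale in-band power by
  exactly their nominal value, which is what makes band-gain recovery an
  exact calibration target. A 60-Hz sinusoid (default 5 µV, random phase
  per channel) models mains pickup.
- **Evoked response.** The neural response is modeled as
  envelope-following: each chirp train adds
  `evoked_gain × chirp_oscillation` (default gain 40 µV, i.e. 20 µV peak
  oscillation) to every channel. Per trial, the oscillation carries a phase
  offset drawn von Mises(0, κ); κ is solved numerically from
  `r = I₁(κ)/I₀(κ)` so that the population mean resultant length of the
  trial phases — hence the asymptotic ITPC — equals the scenario's
  phase-locking profile `r(f)`. With a constant (single-knot) profile this
  holds at every frequency of the sweep. With multiple knots, phases are
  drawn independently per knot and circularly interpolated along the
  sweep's crossing times: the population PLF is then exact at the knots and
  biased upward between knots of equal r (the interpolated angle of two
  independent draws is more concentrated than either draw). Step profiles
  used for injected group differences place knots only at band edges, so
  the bias only deepens the injected contrast.
  The default gain puts the evoked component well above the in-band
  background noise at the ridge, so the von Mises draw — not additive
  noise — dominates the measured phase; residual additive noise and the
  sweep's passage through the wavelet band attenuate measured ridge ITPC by
  roughly 5% relative, which is inside the 3-standard-error recovery
  tolerance at n = 300 trials.
- **Trains.** 300 trains by default, inter-train interval uniform on
  [1, 1.5] s (the distribution is a modeling choice; only "randomly varied"
  is specified by the emulated protocol), a 2-s quiet lead-in/out, onsets
  logged at the ramp start.
- **Artifacts.** Raised-cosine bumps (peak `artifact_amp`, default 800 µV;
  duration uniform 50–300 ms, forced to an odd sample count so the peak is
  hit exactly) at Poisson times (default 2/min) on one random channel each.
  Any shape exceeding the rejection criteria would do; the generator also
  returns the ground-truth interval list for recovery tests.
- **Determinism.** All draws come from named substreams
  (background/trials/artifacts) spawned from the scenario seed, so adding
  artifacts or changing trial parameters never alters the background
  realization, and an identical scenario reproduces the recording
  bit-for-bit.

What the generator does **not** emulate: non-stationarity of state
(sleep/wake transitions), electrode drift and impedance changes, spatially
correlated noise across channels, true broadband-carrier acoustics (the
neural transfer from carrier to EEG is collapsed into the
envelope-following assumption), and any behavior-EEG coupling. Passing
recovery tests therefore demonstrates correctness of the analysis under
the model's assumptions, not robustness to everything real data can do.

## Preprocessing

Recordings are decimated 1250 → 625 Hz behind a zero-phase FIR low-pass
(129 taps, cutoff at 0.9× the new Nyquist; content below 0.8× Nyquist
passes within 1%), then notch filtered at 60 Hz with a zero-phase IIR notch
(−3 dB width 5 Hz per pass). All filtering is forward–backward because the
downstream quantity of interest is phase.

Resting data are cut into contiguous non-overlapping 1-s segments
(remainder dropped); chirp sessions into 3-s epochs from 0.5 s before the
onset of the modulated portion to 0.5 s after its end (the 1-s level ramp
precedes the epoch's t = 0; the pre-window therefore overlaps the ramp's
final 0.5 s, which is the only reading consistent with a 3-s total).

Artifact screening rejects a segment/epoch when any channel violates any
of: |amplitude| > 500 µV, per-sample gradient > 50 µV, or max–min within a
sliding 200-ms window > 300 µV. The numeric limits are typical
rodent-screening values and configurable; the validation tests inject
artifacts far above threshold, so the defaults are not load-bearing.
Rejection is per segment across channels (any-channel rule). An animal is
excluded when **strictly more than 30%** of its segments/epochs are
rejected; exactly 30% keeps. Subject-level summary values can additionally
be screened with an iterated two-sided Grubbs test (α = 0.05, one removal
per iteration), the procedure behind standard outlier calculators.

## Resting spectra

Each kept 1-s segment is mean-detrended, Hanning-windowed, zero-padded to
2 s (realizing 0.5-Hz bins while honoring 1-s segmentation), and converted
to a one-sided PSD in µV²/Hz with window power compensation
(`2|X|²/(fs·Σw²)`); segment PSDs are averaged and restricted to 1–100 Hz.
Band powers are the **mean** density over each band — delta 1–4, theta
4–8, alpha 8–13, beta 13–30, low gamma 30–55, high gamma 65–100 Hz; the
55–65 Hz mains guard band never contributes — averaged over each region's
channels (mean-mode makes bands of different widths comparable; an
integral mode exists). Group tables report each value as a ratio to the
reference-group mean of the same region × band cell. Cross-band power
coupling is the Pearson correlation of per-segment band-power series
between two (band, region) pairs, with the two-sided p from the t
transform.

## Time–frequency analysis

The wavelet bank covers integer frequencies 1–100 Hz with complex Morlets
`g(t; σ_t)·exp(i2πft)`, unit L2 norm, truncated at ±4σ_t. The Morlet
parameter c = 10 is interpreted as the frequency-to-spectral-bandwidth
ratio (≈ cycles): σ_t = c/(2πf), σ_f = f/c, so the 40-Hz kernel has a 4-Hz
spectral sd. Epochs (optionally averaged over a region's channels in the
time domain — region-level maps are computed on the averaged signal, a
configurable choice) are convolved per frequency; points within 2σ_t of an
epoch edge are flagged invalid, which matters below ~3 Hz where the kernel
outlives the 3-s epoch.

ITPC at each (f, t) is the mean resultant length of the per-trial unit
phasors, `|Σ_k F_k/|F_k||/n`; zero-magnitude coefficients carry no phase
and are dropped from that point's sum with n adjusted. (The magnitude of
the complex mean is taken; without it the quantity would not lie in [0, 1]
or measure phase locking.) Induced (non-phase-locked) power subtracts the
trial-averaged evoked waveform in the time domain, re-transforms, averages
|F|² over trials, and expresses each frequency row as percent change from
its mean over the pre-stimulus baseline ([−0.5, 0) s by default). Maps are
binned to the 100 × 625 analysis matrix by averaging non-overlapping time
blocks (1875 native samples → 3 per bin); frequency needs no binning
because the grid is already the 100 integer frequencies.

## Cluster-based permutation statistics

Two groups of subject matrices are compared pointwise with Welch's t. The
cluster-forming threshold is the two-sided pointwise test at α = 0.05 with
per-pixel Welch degrees of freedom (configurable). Suprathreshold pixels
are clustered under 4-connectivity (8 available), separately per sign, and
each cluster's size (pixel count) and mass (Σ|t|) recorded. The null is
the per-permutation maximum cluster statistic over random relabelings of
subjects that preserve group sizes (1000 by default; exhaustive
enumeration available for small samples). Cluster
p = (1 + #{null ≥ obs})/(1 + n_perm); a cluster is significant at
α = 0.025 per tail, i.e. two-tailed 0.05. Invalid (edge) pixels are
excluded before thresholding.

A property worth knowing: the cluster-**size** statistic is
integer-valued and ties heavily in the null, so its attained family-wise
level sits below nominal (≈1.3% instead of 2.5% on small unsmoothed maps
in our simulations) — valid but conservative. The cluster-**mass**
statistic is effectively continuous and attains the nominal level almost
exactly; the calibration checks therefore use mass, while size remains the
default inferential statistic for compatibility with the conventional
"cluster size" formulation. Both are always computed.

## Band-power group statistics

Per region, band-power ratios are analyzed with a fixed-effects two-way
ANOVA (group × band, type-II sums of squares via OLS), with per-band
two-group post hoc t contrasts Bonferroni-corrected at m = bands ×
pairwise group contrasts. Treating band as a between-cell factor ignores
the repeated-measures structure over bands within animal; a
repeated-measures or mixed formulation would be the stricter choice and is
a known limitation.

## Problem sizes used by the automated checks

The acceptance checks simulate: one default session (30 channels, 300
trials) for the structural constants; three 6-channel, 300-trial sessions
for phase-locking recovery at r ∈ {0.2, 0.5, 0.8} (ridge ITPC read along
the sweep diagonal at 30–50 Hz, the neighborhood the c = 10 wavelet is
tuned for); 12 animals per group at low-gamma gains {1, 1.5, 2} for
band-gain recovery; 200 replicates × 500 permutations on 40 × 60
exchangeable maps (10 + 10 subjects) for null calibration, with the
enumeration oracle at 4 + 4 subjects; and 10 + 10 subjects × 100 trials
with a step phase-locking profile (0.5 inside 30–80 Hz vs 0.1) for
sensitivity. Six channels (one per region) are used wherever the region
structure, not the channel count, is what matters.

## Numerical notes

- κ(r) is solved by bracketed root finding on the exponentially scaled
  Bessel ratio; r < 1e−8 maps to κ = 0, r > 0.999 to the asymptotic
  0.5/(1 − r).
- Circular interpolation of knot phases follows the shortest arc.
- Degenerate inputs are first-class: all-rejected segment sets raise with
  a message pointing at the exclusion rule; an all-evoked epoch set (zero
  residual) raises a degenerate-baseline error for induced power rather
  than dividing rounding noise by rounding noise; zero-variance series
  make Pearson r undefined (reported as NaN), and zero-variance pixels get
  t = 0.
- Wavelet coefficients are stored complex64 (≈450 MB for 300 trials ×
  100 frequencies × 1875 samples); ITPC is scale-invariant, so the reduced
  mantissa is immaterial.
- HDF5 is the on-disk container (`/samples, /fs, /labels, /regions,
  /events`); events can also round-trip through a CSV sidecar. A missing
  events group degrades to an empty table with a logged warning; missing
  required datasets raise naming the field.
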