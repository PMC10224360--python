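# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order data flows through the pipeline.

## Signal model and the synthetic generator

A recording is the potential difference between two electrodes on a plant
stem, in microvolts, uniformly sampled at fs = 62.5 Hz. The study design
the package targets uses two-hour phases (450,000 samples) recorded before
and after a stimulus, with 23 replicate plants per treatment.

The generator emulates the gross statistical features of such recordings:

- **Coloured background.** White Gaussian noise is spectrally shaped by
  multiplying its rFFT coefficients by f^(−β/2) (DC zeroed) and inverting,
  giving an exact 1/f^β power-law density; the realisation is then rescaled
  to a target RMS. Defaults: β = 1, RMS 20 μV.
- **Oscillatory components.** Either pure sinusoids (bandwidth 0, uniform
  random phase, peak = RMS·√2) or Gaussian noise band-passed with a 4th
  order Butterworth filter (forward-backward, so zero phase) to
  [center − bw/2, center + bw/2], rescaled to the target RMS. The default
  cohort carries one component at 0.1–0.4 Hz with 60 μV RMS, placing most
  signal energy below 0.5 Hz, as plant electromes do; total amplitude scale
  (~60–65 μV RMS) sits inside the 5–250 μV range typical of EPG recordings.
- **Step modulation ("host presentation").** From a configurable onset
  (default 1200 s = 20 min) in the after phase only, components whose
  centre frequency lies in a named band are scaled in amplitude by √g, so
  band power scales by the gain g (default scenario: g = 3 on the low
  band). The background is never modulated.
- **Seeding.** Stream seed = base_seed + 10007·replicate + phase offset
  (before 0, after 1), so cohorts are bit-reproducible and replicates
  independent.

Amplitudes are calibrated by RMS, not peak, because published EPG work
reports amplitude ranges rather than waveforms. The generator does not
model acquisition hardware (mains notch, hardware band-pass), ion-channel
kinetics, action/variation potentials, electrode drift or artifacts; it is
already band-limited below Nyquist. Passing tests therefore demonstrate
correctness of the *analysis chain* under a controlled spectral model, not
fidelity to any particular plant's electrome.

## File formats

Recordings travel as CSV (`time_s,voltage_uv`) plus a JSON sidecar with fs
and labels. Authoritative timing is the sidecar fs (the time column is for
human inspection; the reader rejects files whose median time step disagrees
with fs by > 1 %). Voltages are written with 17 significant digits so
write→read round-trips are bit-identical (reading uses round-trip float
parsing). Cohorts are a directory of such pairs plus `manifest.json`.

## Spectral features

- **Segmentation.** Non-overlapping 60 s windows (3750 samples); a trailing
  partial window is dropped. All figures and summaries are minute-indexed.
- **Mean DDP** is the raw window mean — deliberately *not* detrended, since
  the DC level is the quantity of interest.
- **Mean frequency** is the spectral centroid Σ fᵢPᵢ / Σ Pᵢ over positive
  rFFT frequencies of the mean-subtracted window, with Pᵢ the squared
  magnitude. A magnitude-weighted variant (`mode="magnitude_mean"`) is
  provided because the weighting convention is genuinely ambiguous in the
  EPG literature; the power-weighted centroid is the standard reading and
  the default. An all-zero window raises rather than returning 0.
- **Welch PSD.** 4 s segments (250 samples, so Δf = 0.25 Hz, grid up to
  31.25 Hz), periodic Hann taper, 50 % overlap, per-segment constant
  detrend, one-sided density scaling. These are the conventional defaults
  of scipy's implementation, fixed explicitly so results are reproducible
  across languages.
- **Band power.** Composite Simpson integration of the density over the
  in-band grid points, inclusive at both edges. Adjacent bands sharing an
  edge (0.5, 4, 8 Hz) are integrals over contiguous intervals: quadrature
  assigns the shared point half-interval weight on each side, so summing a
  contiguous partition does not double-count area. Bands reaching past
  Nyquist (beta 13–30 only partially, gamma 20–100 substantially) are
  clipped to fs/2 with a logged warning; bands with fewer than three grid
  points fall back to the trapezoidal rule (logged). A band entirely above
  Nyquist is an error.

### Known numerical limitation: unresolved spectral lines

Composite Simpson on a 0.25 Hz grid mis-integrates features narrower than
a few grid bins. The worst case is a sinusoid on a grid frequency: through
the Hann taper it occupies three bins with relative powers (¼, 1, ¼), and
composite Simpson integrates that line to 8/9 (−11 %) or 7/6 (+17 %) of
its true power depending on which Simpson node the peak lands on. This is
a property of the prescribed quadrature at the prescribed resolution, not
an implementation defect: the rectangle (Parseval) sum of the same PSD
recovers a 1 Hz, 10 μV tone's 50 μV² exactly, as a unit test verifies.
Consequences:

- Band-power *ratios* of an unchanged spectral shape (the quantity the
  phase comparison uses) are unaffected — the bias cancels.
- Power-conservation (Parseval) checks are meaningful only for signals the
  estimator resolves. The verification suite therefore uses windows of
  white background plus broad (6 Hz wide) band-limited components, for
  which the partition sum matches window variance to ~1 %.
- Signal energy below the segment resolution (≲ 0.25 Hz) is additionally
  attenuated by the per-segment constant detrend; with the default
  low-frequency-heavy cohort the Welch integral recovers only part of the
  sample variance. This mirrors the estimator's behaviour on real EPG
  recordings and is why absolute low-band ABP values should be compared
  only between conditions analysed identically.

## TDAF and phase comparison

Per minute, across replicates: min, q1, median, q3, max, with quartiles by
linear interpolation between order statistics (the common default across
scientific stacks; fixed so that independent reimplementations agree
exactly). Figures show the median line with min–max shading; interquartile
bounds are emitted alongside.

Phase comparison pools each phase with the median of per-minute medians and
reports after/before. The onset estimate is the first after-phase minute
from which the per-minute median exceeds the before phase's pooled q3 (the
median over minutes of per-minute q3) for at least 5 consecutive minutes
(`min_run`, configurable); it is a pragmatic detector for sustained shifts,
deliberately simple, and not an inferential changepoint method. No
hypothesis tests are performed across treatments.

## Pipeline determinism and problem sizes

A run is fully determined by its manifest and seed; tables are written with
fixed float formatting, so reruns are byte-identical. Warnings (Nyquist
clipping, trapezoid fallback) go to the log and into `run_log.json`
alongside every convention listed above, so published tables are
self-describing.

Default analysis sizes follow the study design (2 h phases, 23 replicates).
The test suite and acceptance script use those full sizes where the check
needs them (step-recovery cohort, background-slope calibration) and smaller
cohorts (minutes-long phases, ≤ 6 replicates) for contract tests where the
size is immaterial.

## Open choices made here

- Component membership for step modulation is decided by the component's
  centre frequency falling inside a named default band; a component matched
  by several overlapping bands receives the product of their gains.
- The generator's amplitude/exponent defaults are plausible for EPG-like
  signals but are not estimates of any published recording's parameters —
  no amplitude or spectral statistics are available to fit them to.
- ABP is computed per minute from minute-long windows; the alternative (one
  Welch estimate of the whole phase, windowed differently) would change
  absolute values slightly but not the per-minute structure the dispersion
  analysis needs.
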