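# electrome

Band-power and temporal-dispersion analysis of plant electrophysiological
recordings (electrophytograms, EPG), with a synthetic electrome generator
for testing the full chain against known ground truth.

## The problem

Plants produce spontaneous micro-voltage electrical activity — their
*electrome* — that changes when the plant perceives a salient stimulus, for
example when a parasitic vine is presented with a suitable host plant.
Recordings are long (hours), noisy, low-frequency-dominated time series of
the potential difference ΔV between two electrodes (the DDP, in μV),
sampled here at fs = 62.5 Hz in two-hour phases before and after a
stimulus, with ~23 replicate plants per treatment.

This package implements the EEG-style analysis used to quantify such
changes:

1. **Per-minute features.** Each recording is cut into consecutive 60 s
   windows. For each window the pipeline computes the mean DDP (raw mean,
   μV), the spectral mean frequency (power-weighted centroid of the rFFT,
   Hz), and the **average band power (ABP)**:

   ABP(band) = ∫_band S(f) df,

   where S(f) is the Welch power spectral density (4 s Hann segments, 50 %
   overlap, one-sided density in μV²/Hz) and the integral is evaluated by
   the composite Simpson rule over the in-band frequency grid.

2. **Seven frequency bands** borrowed from neuroscience practice:
   low 0–0.5 Hz, delta 0.5–4, theta 4–8, mu 9–11, alpha 8–13, beta 13–30,
   gamma 20–100 Hz (beta/gamma are clipped at the 31.25 Hz Nyquist limit,
   with a logged warning).

3. **TDAF — time dispersion analysis of features.** Per-minute features are
   aggregated across replicate plants into order statistics (min, q1,
   median, q3, max) kept in temporal order, and the before/after phases are
   contrasted by pooled medians, an after/before ratio, and a sustained-step
   onset estimate.

Because no raw plant recordings are distributed, the package ships a
**synthetic electrome generator**: 1/f^β coloured-noise background plus
narrow-band oscillatory components at μV amplitudes, with an optional
"host-presentation" step that multiplies low-band power by a known gain g
from a known onset — so every stage can be validated by parameter recovery.

## Worked example

A small stimulus-response cohort: 5 replicate plants, 1 h phases, and a 3×
low-band power step starting 20 min into the after phase.

```python
import dataclasses
import electrome as e

cfg = dataclasses.replace(
    e.host_presentation_config(base_seed=7, gain=3.0, onset_s=1200.0),
    n_replicates=5, duration_s=3600.0,
)
low = [e.DEFAULT_BANDS[0]]                     # the 0-0.5 Hz "low" band
summaries = {}
for phase in ("before", "after"):
    series = [e.abp_series(e.generate_recording(cfg, i, phase), low)["low"]
              for i in range(cfg.n_replicates)]
    summaries[phase] = e.tdaf_aggregate(series)
cmp = e.compare_phases(summaries["before"], summaries["after"])
print(f"low-band ABP pooled median before: {cmp.median_before:8.1f} uV^2")
print(f"low-band ABP pooled median after:  {cmp.median_after:8.1f} uV^2")
print(f"after/before ratio:                {cmp.after_before_ratio:8.2f}")
print(f"estimated step onset:              minute {cmp.onset_minute_estimate}")
```

prints

```
low-band ABP pooled median before:   2881.8 uV^2
low-band ABP pooled median after:    7840.5 uV^2
after/before ratio:                    2.72
estimated step onset:              minute 19
```

The pooled after/before ratio (2.72) underestimates the injected gain 3
because the after-phase median pools the 20 unmodulated pre-onset minutes
and the coloured background dilutes the component's contribution; with the
full 23-replicate, 2 h study conditions the recovered ratio lands within
10 % of the truth (see the acceptance script). The onset estimate (first
minute whose cohort median stays above the before-phase pooled q3 for ≥ 5
consecutive minutes) lands at the injected 20 min boundary ± a minute.

The same analysis is available from a shell:

```sh
electrome simulate --config cohort.json --out cohort/
electrome features --input cohort/manifest.json --out features/
electrome run --manifest run.json --out results/
```

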