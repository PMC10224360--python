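"""Synthetic electrome generator.

Produces cohorts of surrogate electrophytogram (EPG) recordings with known
ground truth, standing in for raw plant recordings that are not distributed.
A recording is the sum of

* a coloured-noise background with power-law spectrum ``S(f) ~ 1/f**beta``,
  realised by spectral shaping of white Gaussian noise and calibrated to a
  target RMS amplitude in microvolts;
* a set of oscillatory components, each either a pure sinusoid (bandwidth 0)
  or Gaussian noise band-pass filtered to a narrow interval, again calibrated
  by RMS;
* an optional step modulation emulating the response to a stimulus such as a
  host-plant presentation: from an onset time onward, components whose centre
  frequency falls in a named band have their amplitude scaled by ``sqrt(g)``
  so that their power scales by the configured gain ``g``.

Default parameters mirror the recording protocol the package targets:
62.5 Hz sampling, two-hour phases (450,000 samples), 23 replicate plants per
treatment, microvolt amplitudes with energy concentrated below 0.5 Hz, and a
sustained low-band power increase starting 20 min into the post-stimulus
phase.

Determinism
-----------
Each (replicate, phase) stream uses its own :class:`numpy.random.Generator`
seeded as ``base_seed + 10007 * replicate_index + phase_offset`` (0 for the
"before" phase, 1 for "after"), so cohorts are bit-reproducible and
replicates are mutually independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .bands import DEFAULT_BANDS, BandDefinition
from .errors import ConfigurationError
from .io import Recording, RecordingSet

__all__ = [
    "OscillatoryComponent",
    "StepModulation",
    "GeneratorConfig",
    "generate_recording",
    "generate_cohort",
    "host_presentation_config",
]

PHASES = ("before", "after")
_REPLICATE_SEED_STRIDE = 10007
_PHASE_OFFSET = {"before": 0, "after": 1}


@dataclass(frozen=True)
class OscillatoryComponent:
    """One narrow-band source in the synthetic electrome.

    ``bandwidth_hz == 0`` degenerates to a pure sinusoid with uniformly
    random phase; otherwise the component is Gaussian noise band-passed to
    ``[center_hz - bandwidth_hz/2, center_hz + bandwidth_hz/2]``.  Amplitude
    is specified as RMS in microvolts (for a sinusoid, peak = RMS * sqrt(2)).
    """

    center_hz: float
    bandwidth_hz: float = 0.0
    rms_uv: float = 1.0


@dataclass(frozen=True)
class StepModulation:
    """Sustained power step applied from ``onset_s`` onward in the after phase.

    ``band_gains`` maps a band name (resolved against the default band set)
    to a multiplicative *power* gain ``g >= 0``; components whose centre
    frequency lies inside that band are scaled in amplitude by ``sqrt(g)``.
    """

    onset_s: float = 1200.0
    band_gains: dict[str, float] = field(default_factory=dict)


def _default_components() -> list[OscillatoryComponent]:
    # Dominant sub-0.5 Hz activity: band-limited noise at 0.1-0.4 Hz, 60 uV RMS.
    return [OscillatoryComponent(center_hz=0.25, bandwidth_hz=0.3, rms_uv=60.0)]


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    fs
        Sampling rate in Hz.
    duration_s
        Length of one phase in seconds (each replicate yields one "before"
        and one "after" recording of this length).
    n_replicates
        Number of replicate plants per treatment.
    background_exponent
        Power-law exponent ``beta`` of the 1/f**beta background.
    background_rms
        Background amplitude in microvolts (RMS); 0 disables the background.
    components
        Oscillatory sources added on top of the background.
    modulation
        Optional step modulation, applied only in the "after" phase.
    base_seed
        Root seed for the cohort.
    treatment
        Label attached to generated recordings.
    """

    fs: float = 62.5
    duration_s: float = 7200.0
    n_replicates: int = 23
    background_exponent: float = 1.0
    background_rms: float = 20.0
    components: tuple[OscillatoryComponent, ...] = field(
        default_factory=lambda: tuple(_default_components())
    )
    modulation: StepModulation | None = None
    base_seed: int = 0
    treatment: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if not self.duration_s > 0:
            raise ConfigurationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if self.background_rms < 0:
            raise ConfigurationError(
                f"background_rms must be >= 0, got {self.background_rms}"
            )
        if self.background_exponent < 0:
            raise ConfigurationError(
                f"background_exponent must be >= 0, got {self.background_exponent}"
            )
        object.__setattr__(self, "components", tuple(self.components))
        nyq = self.fs / 2
        for comp in self.components:
            if not 0 <= comp.center_hz <= nyq:
                raise ConfigurationError(
                    f"components: center_hz {comp.center_hz} outside [0, fs/2]"
                )
            if comp.bandwidth_hz < 0:
                raise ConfigurationError(
                    f"components: bandwidth_hz must be >= 0, got {comp.bandwidth_hz}"
                )
            if comp.rms_uv < 0:
                raise ConfigurationError(
                    f"components: rms_uv must be >= 0, got {comp.rms_uv}"
                )
        if self.modulation is not None:
            mod = self.modulation
            if not 0 <= mod.onset_s <= self.duration_s:
                raise ConfigurationError(
                    f"modulation: onset_s {mod.onset_s} outside [0, duration_s]"
                )
            known = {b.name for b in DEFAULT_BANDS}
            for name, gain in mod.band_gains.items():
                if name not in known:
                    raise ConfigurationError(
                        f"modulation: unknown band name {name!r} "
                        f"(known: {sorted(known)})"
                    )
                if not (math.isfinite(gain) and gain >= 0):
                    raise ConfigurationError(
                        f"modulation: gain for band {name!r} must be finite "
                        f"and >= 0, got {gain}"
                    )

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.duration_s)

    def replicate_seed(self, replicate_index: int, phase: str) -> int:
        """Deterministic per-stream seed (documented, fixture-stable)."""
        return (
            self.base_seed
            + _REPLICATE_SEED_STRIDE * replicate_index
            + _PHASE_OFFSET[phase]
        )


def host_presentation_config(
    base_seed: int = 0,
    gain: float = 3.0,
    onset_s: float = 1200.0,
    treatment: str = "suitable_host",
) -> GeneratorConfig:
    """Config for the stimulus-response scenario: a sustained low-band power
    step of factor *gain* starting *onset_s* seconds into the after phase."""
    return GeneratorConfig(
        modulation=StepModulation(onset_s=onset_s, band_gains={"low": gain}),
        base_seed=base_seed,
        treatment=treatment,
    )


def _power_law_background(
    rng: np.random.Generator, n: int, fs: float, beta: float, rms: float
) -> np.ndarray:
    """White Gaussian noise spectrally shaped to a 1/f**beta density.

    rFFT coefficients are scaled by ``f**(-beta/2)`` (DC zeroed), then the
    series is rescaled so its realised standard deviation equals *rms*.
    """
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    coeff = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(coeff * shape, n)
    std = x.std()
    if std > 0:
        x *= rms / std
    return x


def _component_signal(
    rng: np.random.Generator, comp: OscillatoryComponent, n: int, fs: float
) -> np.ndarray:
    if comp.rms_uv == 0:
        return np.zeros(n)
    if comp.bandwidth_hz == 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / fs
        return comp.rms_uv * np.sqrt(2.0) * np.sin(2 * np.pi * comp.center_hz * t + phase)
    nyq = fs / 2.0
    lo = comp.center_hz - comp.bandwidth_hz / 2.0
    hi = min(comp.center_hz + comp.bandwidth_hz / 2.0, 0.999 * nyq)
    white = rng.standard_normal(n)
    if lo <= 0:
        sos = _sig.butter(4, hi, btype="lowpass", fs=fs, output="sos")
    else:
        sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, white)
    std = x.std()
    if std > 0:
        x *= comp.rms_uv / std
    return x


def _component_gain(comp: OscillatoryComponent, mod: StepModulation) -> float:
    """Product of power gains over all named bands containing the centre."""
    gain = 1.0
    by_name = {b.name: b for b in DEFAULT_BANDS}
    for name, g in mod.band_gains.items():
        band: BandDefinition = by_name[name]
        if band.f_lo_hz <= comp.center_hz <= band.f_hi_hz:
            gain *= g
    return gain


def generate_recording(
    config: GeneratorConfig, replicate_index: int, phase: str
) -> Recording:
    """Synthesise one replicate's recording for one phase.

    Deterministic given ``(config.base_seed, replicate_index, phase)``.  The
    step modulation, if configured, is applied only when ``phase == "after"``.
    """
    if phase not in PHASES:
        raise ConfigurationError(f"phase must be one of {PHASES}, got {phase!r}")
    if not 0 <= replicate_index < config.n_replicates:
        raise ConfigurationError(
            f"replicate_index {replicate_index} outside [0, {config.n_replicates})"
        )
    n = config.n_samples
    rng = np.random.default_rng(config.replicate_seed(replicate_index, phase))
    samples = _power_law_background(
        rng, n, config.fs, config.background_exponent, config.background_rms
    )
    mod = config.modulation if phase == "after" else None
    onset_idx = round(mod.onset_s * config.fs) if mod is not None else n
    for comp in config.components:
        wave = _component_signal(rng, comp, n, config.fs)
        if mod is not None:
            g = _component_gain(comp, mod)
            if g != 1.0:
                wave[onset_idx:] *= np.sqrt(g)
        samples = samples + wave
    return Recording(
        samples=samples,
        fs=config.fs,
        plant_id=f"plant{replicate_index:02d}",
        treatment=config.treatment,
        phase=phase,
    )


def generate_cohort(config: GeneratorConfig) -> RecordingSet:
    """Generate ``n_replicates`` recordings for each of the two phases."""
    recordings = [
        generate_recording(config, i, phase)
        for phase in PHASES
        for i in range(config.n_replicates)
    ]
    return RecordingSet(
        recordings=recordings,
        metadata={
            "treatment": config.treatment,
            "base_seed": config.base_seed,
            "n_replicates": config.n_replicates,
        },
    )


def control_config(config: GeneratorConfig, treatment: str = "control") -> GeneratorConfig:
    """The same cohort conditions with the stimulus modulation removed."""
    return replace(config, modulation=None, treatment=treatment)


def config_from_dict(data: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from its JSON representation."""
    if not isinstance(data, dict):
        raise ConfigurationError("generator config must be a JSON object")
    data = dict(data)
    comps = [
        OscillatoryComponent(
            center_hz=float(c["center_hz"]),
            bandwidth_hz=float(c.get("bandwidth_hz", 0.0)),
            rms_uv=float(c.get("rms_uv", 1.0)),
        )
        for c in data.pop("components", [])
    ] if "components" in data else None
    mod_data = data.pop("modulation", None)
    modulation = (
        StepModulation(
            onset_s=float(mod_data.get("onset_s", 1200.0)),
            band_gains={k: float(v) for k, v in mod_data.get("band_gains", {}).items()},
        )
        if mod_data
        else None
    )
    allowed = {
        "fs",
        "duration_s",
        "n_replicates",
        "background_exponent",
        "background_rms",
        "base_seed",
        "treatment",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown generator config fields: {sorted(unknown)}")
    kwargs = dict(data)
    if comps is not None:
        kwargs["components"] = tuple(comps)
    kwargs["modulation"] = modulation
    return GeneratorConfig(**kwargs)


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serialisable representation (inverse of :func:`config_from_dict`)."""
    out = {
        "fs": config.fs,
        "duration_s": config.duration_s,
        "n_replicates": config.n_replicates,
        "background_exponent": config.background_exponent,
        "background_rms": config.background_rms,
        "base_seed": config.base_seed,
        "treatment": config.treatment,
        "components": [
            {
                "center_hz": c.center_hz,
                "bandwidth_hz": c.bandwidth_hz,
                "rms_uv": c.rms_uv,
            }
            for c in config.components
        ],
    }
    if config.modulation is not None:
        out["modulation"] = {
            "onset_s": config.modulation.onset_s,
            "band_gains": dict(config.modulation.band_gains),
        }
    return out
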