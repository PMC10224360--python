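"""Spectral feature extraction.

The analysis chain for one recording is: split the series into consecutive
one-minute windows, and for each window compute

* the mean potential difference (DDP) of the raw samples, in microvolts;
* the spectral centroid ("mean frequency"), the power-weighted mean of the
  positive rFFT frequencies of the mean-subtracted window, in Hz;
* the Welch power spectral density (PSD; 4 s Hann segments, 50% overlap,
  one-sided density scaling), and from it the average band power (ABP) of
  each named band, obtained by composite Simpson integration of the density
  over the in-band frequency grid, in microvolt^2.

Bands extending past the Nyquist frequency (beta and gamma at 62.5 Hz
sampling) are clipped to fs/2 with a logged warning; a band with fewer than
three in-band grid points falls back to trapezoidal integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as _integrate
from scipy import signal as _sig

from .bands import BandDefinition
from .errors import (
    EmptyBandError,
    ShortRecordingError,
    UndefinedCentroidError,
)
from .io import Recording

__all__ = [
    "PSDEstimate",
    "FeatureSeries",
    "segment_minutes",
    "mean_frequency",
    "mean_ddp",
    "welch_psd",
    "band_power",
    "abp_series",
    "compute_features",
]

logger = logging.getLogger(__name__)

CENTROID_MODES = ("centroid", "magnitude_mean")


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided Welch PSD on a uniform frequency grid.

    ``density`` is in signal-units^2 per Hz (microvolt^2/Hz here); the grid
    runs from 0 to fs/2 with spacing ``1/window_seconds`` so that integrating
    the density over frequency approximates the signal's variance.
    """

    freqs_hz: np.ndarray
    density: np.ndarray
    window_seconds: float
    overlap_fraction: float
    taper_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if self.freqs_hz.shape != self.density.shape:
            raise ValueError("freqs_hz and density must have equal length")
        if np.any(self.density < 0):
            raise ValueError("PSD density must be non-negative")

    @property
    def df(self) -> float:
        return 1.0 / self.window_seconds

    @property
    def nyquist_hz(self) -> float:
        return float(self.freqs_hz[-1])

    def total_power(self) -> float:
        """Trapezoidal integral of the density over the full grid."""
        return float(np.trapezoid(self.density, self.freqs_hz))


@dataclass
class FeatureSeries:
    """Per-minute values of one feature for one recording.

    ``feature_name`` is ``"mean_frequency"``, ``"mean_ddp"`` or
    ``"abp:<band>"``; ``values[i]`` belongs to minute window ``i`` (0-based,
    trailing partial windows dropped).
    """

    feature_name: str
    values: np.ndarray
    units: str
    seg_seconds: float = 60.0
    plant_id: str = "plant00"
    treatment: str = "unknown"
    phase: str = "before"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("FeatureSeries requires a non-empty 1-D value array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.feature_name}: non-finite feature values")

    @property
    def minute_index(self) -> np.ndarray:
        return np.arange(self.values.size)

    def __len__(self) -> int:
        return self.values.size


def segment_minutes(recording: Recording, seg_seconds: float = 60.0) -> list[np.ndarray]:
    """Split a recording into consecutive non-overlapping windows.

    Each window has ``round(seg_seconds * fs)`` samples; a trailing partial
    window is dropped.  Raises if not even one full window fits.
    """
    win = round(seg_seconds * recording.fs)
    if win < 2:
        raise ShortRecordingError(
            f"seg_seconds={seg_seconds} at fs={recording.fs} gives a window of "
            f"{win} samples (need >= 2)"
        )
    n_windows = recording.n_samples // win
    if n_windows == 0:
        raise ShortRecordingError(
            f"recording {recording.plant_id!r} has {recording.n_samples} samples; "
            f"one {seg_seconds} s window needs {win}"
        )
    x = recording.samples
    return [x[i * win : (i + 1) * win] for i in range(n_windows)]


def mean_frequency(window: np.ndarray, fs: float, mode: str = "centroid") -> float:
    """Spectral mean frequency of one window, in Hz.

    The window is mean-subtracted, transformed with the real FFT, and the
    positive frequencies are averaged with weights given by the squared
    magnitude (``mode="centroid"``, the spectral centroid) or the plain
    magnitude (``mode="magnitude_mean"``).  A window with zero total power
    has no defined centroid and raises.
    """
    if mode not in CENTROID_MODES:
        raise ValueError(f"mode must be one of {CENTROID_MODES}, got {mode!r}")
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mag = np.abs(spectrum[1:])
    weights = mag**2 if mode == "centroid" else mag
    total = weights.sum()
    if total == 0:
        raise UndefinedCentroidError("window has zero power; centroid undefined")
    return float((freqs[1:] * weights).sum() / total)


def mean_ddp(window: np.ndarray) -> float:
    """Arithmetic mean of the raw (not detrended) samples, in microvolts."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(x.mean())


def welch_psd(
    samples: np.ndarray,
    fs: float,
    window_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
    taper: str = "hann",
) -> PSDEstimate:
    """Welch PSD with ``window_seconds``-long tapered segments.

    Defaults: 4 s Hann segments, 50% overlap, per-segment constant detrend,
    one-sided density scaling.  At fs = 62.5 Hz this gives 250-sample
    segments and a 0.25 Hz frequency grid up to 31.25 Hz.
    """
    x = np.asarray(samples, dtype=float)
    nperseg = round(window_seconds * fs)
    if x.size < nperseg:
        raise ShortRecordingError(
            f"need at least {nperseg} samples for {window_seconds} s Welch "
            f"segments, got {x.size}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    freqs, density = _sig.welch(
        x,
        fs=fs,
        window=taper,
        nperseg=nperseg,
        noverlap=round(overlap_fraction * nperseg),
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(
        freqs_hz=freqs,
        density=density,
        window_seconds=window_seconds,
        overlap_fraction=overlap_fraction,
        taper_name=taper,
    )


def band_power(psd: PSDEstimate, band: BandDefinition) -> float:
    """Average band power: integral of the PSD over one band, in uV^2.

    Composite Simpson integration over the in-band grid points, inclusive at
    both edges.  Because this is quadrature (not a rectangle sum), summing
    band powers over contiguous bands that share an edge point does not
    double-count area.  A band reaching past Nyquist is clipped to fs/2 with
    a warning; fewer than three in-band points fall back to trapezoidal
    integration.
    """
    nyq = psd.nyquist_hz
    if band.f_lo_hz >= nyq:
        raise EmptyBandError(
            f"band {band.name!r} [{band.f_lo_hz}, {band.f_hi_hz}] Hz lies "
            f"entirely above the Nyquist frequency {nyq} Hz"
        )
    f_hi = band.f_hi_hz
    if f_hi > nyq:
        logger.warning(
            "band %r upper edge %g Hz clipped to Nyquist %g Hz",
            band.name,
            band.f_hi_hz,
            nyq,
        )
        f_hi = nyq
    tol = psd.df * 1e-9
    f = psd.freqs_hz
    mask = (f >= band.f_lo_hz - tol) & (f <= f_hi + tol)
    n_points = int(mask.sum())
    if n_points == 0:
        raise EmptyBandError(
            f"band {band.name!r} contains no grid points (grid spacing {psd.df} Hz)"
        )
    if n_points < 3:
        logger.warning(
            "band %r has only %d in-band grid points; using trapezoidal rule",
            band.name,
            n_points,
        )
        return float(np.trapezoid(psd.density[mask], f[mask]))
    return float(_integrate.simpson(psd.density[mask], x=f[mask]))


def _minute_psds(
    recording: Recording,
    seg_seconds: float,
    window_seconds: float,
    overlap_fraction: float,
    taper: str,
) -> list[PSDEstimate]:
    psds = []
    for window in segment_minutes(recording, seg_seconds):
        detrended = window - window.mean()
        psds.append(
            welch_psd(detrended, recording.fs, window_seconds, overlap_fraction, taper)
        )
    return psds


def abp_series(
    recording: Recording,
    bands: list[BandDefinition],
    seg_seconds: float = 60.0,
    window_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
    taper: str = "hann",
) -> dict[str, FeatureSeries]:
    """Per-minute average band power for every band, keyed by band name.

    Each minute window is mean-subtracted, Welch-transformed, and integrated
    per band; all series share minute indexing.
    """
    psds = _minute_psds(recording, seg_seconds, window_seconds, overlap_fraction, taper)
    out: dict[str, FeatureSeries] = {}
    for band in bands:
        values = np.array([band_power(psd, band) for psd in psds])
        out[band.name] = FeatureSeries(
            feature_name=f"abp:{band.name}",
            values=values,
            units="uV^2",
            seg_seconds=seg_seconds,
            plant_id=recording.plant_id,
            treatment=recording.treatment,
            phase=recording.phase,
        )
    return out


def mean_frequency_series(
    recording: Recording, seg_seconds: float = 60.0, mode: str = "centroid"
) -> FeatureSeries:
    """Per-minute spectral mean frequency."""
    values = np.array(
        [
            mean_frequency(w, recording.fs, mode=mode)
            for w in segment_minutes(recording, seg_seconds)
        ]
    )
    return FeatureSeries(
        feature_name="mean_frequency",
        values=values,
        units="Hz",
        seg_seconds=seg_seconds,
        plant_id=recording.plant_id,
        treatment=recording.treatment,
        phase=recording.phase,
    )


def mean_ddp_series(recording: Recording, seg_seconds: float = 60.0) -> FeatureSeries:
    """Per-minute mean potential difference (raw samples, not detrended)."""
    values = np.array([mean_ddp(w) for w in segment_minutes(recording, seg_seconds)])
    return FeatureSeries(
        feature_name="mean_ddp",
        values=values,
        units="uV",
        seg_seconds=seg_seconds,
        plant_id=recording.plant_id,
        treatment=recording.treatment,
        phase=recording.phase,
    )


def compute_features(
    recording: Recording,
    bands: list[BandDefinition],
    seg_seconds: float = 60.0,
    centroid_mode: str = "centroid",
) -> list[FeatureSeries]:
    """All per-minute features of one recording: mean frequency, mean DDP,
    and one ABP series per band, in that order."""
    series = [
        mean_frequency_series(recording, seg_seconds, mode=centroid_mode),
        mean_ddp_series(recording, seg_seconds),
    ]
    series.extend(abp_series(recording, bands, seg_seconds).values())
    return series
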