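"""Recording containers and file I/O.

A recording travels as a two-column CSV (``time_s,voltage_uv``) plus a JSON
sidecar ``<stem>.meta.json`` carrying the sampling rate and labels.  The time
column exists for human inspection only: authoritative timing comes from the
sidecar ``fs`` (assumed uniform sampling), and the reader cross-checks the
two, rejecting files whose median time step disagrees with ``fs`` by more
than 1%.  Voltages are serialised with 17 significant digits so that a
write/read round trip is bit-identical for float64 data.

A cohort is a directory of such pairs plus a ``manifest.json`` listing the
files with their treatment/phase labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .bands import BandDefinition, load_bands
from .errors import (
    MissingSidecarError,
    NonFiniteValueError,
    NonMonotoneTimeError,
    SamplingRateMismatchError,
    SignalIOError,
)

__all__ = [
    "Recording",
    "RecordingSet",
    "read_recording",
    "write_recording",
    "read_bands",
    "read_manifest",
    "write_cohort",
]

#: Minimum recording length, in seconds, for minute-wise analysis.
MIN_ANALYSIS_SECONDS = 60.0


@dataclass
class Recording:
    """One replicate's micro-voltage time series.

    ``samples`` holds the electrode potential difference (DDP) in microvolts
    at uniform sampling rate ``fs``.  Labels identify the plant, the
    treatment (e.g. which host species was presented) and the phase relative
    to the stimulus (``"before"`` / ``"after"``).
    """

    samples: np.ndarray
    fs: float
    plant_id: str = "plant00"
    treatment: str = "unknown"
    phase: str = "before"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise SignalIOError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise NonFiniteValueError(
                f"recording {self.plant_id!r}: non-finite voltage values"
            )
        if not self.fs > 0:
            raise SignalIOError(f"fs must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def has_full_minute(self) -> bool:
        """Whether the recording spans at least one full analysis minute."""
        return self.duration_s >= MIN_ANALYSIS_SECONDS


@dataclass
class RecordingSet:
    """A cohort of recordings sharing one sampling rate.

    Within each (treatment, phase) group all recordings must have equal
    length so minute indices align across replicates.
    """

    recordings: list[Recording]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.recordings:
            raise SignalIOError("RecordingSet requires at least one recording")
        fs_values = {r.fs for r in self.recordings}
        if len(fs_values) > 1:
            raise SignalIOError(f"recordings disagree on fs: {sorted(fs_values)}")
        for (trt, phase), group in self.by_group().items():
            lengths = {r.n_samples for r in group}
            if len(lengths) > 1:
                raise SignalIOError(
                    f"group ({trt!r}, {phase!r}) has unequal lengths: "
                    f"{sorted(lengths)}"
                )

    @property
    def fs(self) -> float:
        return self.recordings[0].fs

    def by_group(self) -> dict[tuple[str, str], list[Recording]]:
        groups: dict[tuple[str, str], list[Recording]] = {}
        for rec in self.recordings:
            groups.setdefault((rec.treatment, rec.phase), []).append(rec)
        return groups

    def phase(self, phase: str) -> list[Recording]:
        return [r for r in self.recordings if r.phase == phase]


def _meta_path(csv_path: Path) -> Path:
    return csv_path.parent / (csv_path.stem + ".meta.json")


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV and its JSON sidecar.

    Raises a distinct error for each failure mode: missing sidecar,
    non-finite voltages, non-monotone time column, or a sampling rate that
    disagrees with the median time step by more than 1%.
    """
    path = Path(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise MissingSidecarError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    frame = pd.read_csv(path, float_precision="round_trip")
    expected_cols = ["time_s", "voltage_uv"]
    if list(frame.columns) != expected_cols:
        raise SignalIOError(
            f"{path}: expected header {expected_cols}, got {list(frame.columns)}"
        )
    time = frame["time_s"].to_numpy(dtype=float)
    volts = frame["voltage_uv"].to_numpy(dtype=float)
    if not np.all(np.isfinite(volts)):
        raise NonFiniteValueError(f"{path}: non-finite voltage values")
    fs = float(meta["fs"])
    if time.size >= 2:
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise NonMonotoneTimeError(f"{path}: time column not strictly increasing")
        median_step = float(np.median(steps))
        if abs(median_step - 1.0 / fs) > 0.01 / fs:
            raise SamplingRateMismatchError(
                f"{path}: sidecar fs={fs} Hz implies step {1.0 / fs:.6g} s "
                f"but median time step is {median_step:.6g} s"
            )
    return Recording(
        samples=volts,
        fs=fs,
        plant_id=str(meta.get("plant_id", path.stem)),
        treatment=str(meta.get("treatment", "unknown")),
        phase=str(meta.get("phase", "before")),
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV + sidecar; round-trips bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = recording.n_samples
    time = np.arange(n) / recording.fs
    with path.open("w") as fh:
        fh.write("time_s,voltage_uv\n")
        for t, v in zip(time, recording.samples):
            fh.write(f"{t:.6f},{v:.17g}\n")
    meta = {
        "fs": recording.fs,
        "plant_id": recording.plant_id,
        "treatment": recording.treatment,
        "phase": recording.phase,
        "n_samples": n,
        "units": "uV",
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_bands(path: str | Path | None = None) -> list[BandDefinition]:
    """Read band definitions (JSON list); default seven bands when omitted."""
    return load_bands(path)


def write_cohort(cohort: RecordingSet, out_dir: str | Path) -> Path:
    """Write every recording of a cohort plus a ``manifest.json``.

    Returns the manifest path.  File names encode treatment, plant and
    phase, e.g. ``suitable_host_plant03_after.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort.recordings:
        name = f"{rec.treatment}_{rec.plant_id}_{rec.phase}.csv"
        write_recording(rec, out_dir / name)
        entries.append(
            {
                "csv": name,
                "plant_id": rec.plant_id,
                "treatment": rec.treatment,
                "phase": rec.phase,
            }
        )
    manifest = {"fs": cohort.fs, "metadata": cohort.metadata, "recordings": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def read_manifest(manifest_path: str | Path) -> RecordingSet:
    """Load a cohort from a ``manifest.json`` written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    entries: Iterable[dict] = manifest.get("recordings", [])
    entries = list(entries)
    if not entries:
        raise SignalIOError(f"{manifest_path}: manifest lists no recordings")
    recordings = [
        read_recording(manifest_path.parent / entry["csv"]) for entry in entries
    ]
    return RecordingSet(recordings=recordings, metadata=manifest.get("metadata", {}))
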