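"""Named frequency bands.

The band set mirrors the EEG convention carried over to electrophytogram
(EPG) analysis: a "low" band capturing the sub-0.5 Hz activity where plant
electrical signalling concentrates, plus the classical delta through gamma
intervals.  Bands are allowed to overlap (mu is contained in alpha, beta and
gamma share 20-30 Hz) and are always analysed independently, never merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import BandDefinitionError

__all__ = ["BandDefinition", "DEFAULT_BANDS", "default_bands", "load_bands"]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval in Hz.

    Parameters
    ----------
    name
        Label, e.g. ``"low"`` or ``"delta"``.  Case is preserved.
    f_lo_hz, f_hi_hz
        Lower and upper edges in Hz; requires ``0 <= f_lo_hz < f_hi_hz``.
    """

    name: str
    f_lo_hz: float
    f_hi_hz: float

    def __post_init__(self) -> None:
        if not self.name:
            raise BandDefinitionError("band name must be non-empty")
        if self.f_lo_hz < 0:
            raise BandDefinitionError(
                f"band {self.name!r}: f_lo_hz must be >= 0, got {self.f_lo_hz}"
            )
        if not self.f_lo_hz < self.f_hi_hz:
            raise BandDefinitionError(
                f"band {self.name!r}: empty interval "
                f"[{self.f_lo_hz}, {self.f_hi_hz}] (need f_lo_hz < f_hi_hz)"
            )


#: The seven analysis bands, in canonical order.  Overlaps are intentional.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("low", 0.0, 0.5),
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("mu", 9.0, 11.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 20.0, 100.0),
)


def default_bands() -> list[BandDefinition]:
    """Return a fresh list of the seven default bands."""
    return list(DEFAULT_BANDS)


def _validate_band_list(bands: list[BandDefinition]) -> list[BandDefinition]:
    names = [b.name for b in bands]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise BandDefinitionError(f"duplicate band names: {sorted(dupes)}")
    return bands


def load_bands(path: str | Path | None = None) -> list[BandDefinition]:
    """Read band definitions from a JSON file.

    The file holds a JSON list of ``{"name", "f_lo_hz", "f_hi_hz"}`` objects.
    Order and case are preserved; overlapping bands are legal.  When *path*
    is ``None`` the seven default bands are returned.
    """
    if path is None:
        return default_bands()
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise BandDefinitionError("bands file must contain a JSON list")
    bands = []
    for entry in raw:
        try:
            bands.append(
                BandDefinition(
                    name=str(entry["name"]),
                    f_lo_hz=float(entry["f_lo_hz"]),
                    f_hi_hz=float(entry["f_hi_hz"]),
                )
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise BandDefinitionError(f"band entry missing key {exc}") from exc
    return _validate_band_list(bands)


def dump_bands(bands: list[BandDefinition], path: str | Path) -> None:
    """Write band definitions as JSON (inverse of :func:`load_bands`)."""
    _validate_band_list(bands)
    payload = [
        {"name": b.name, "f_lo_hz": b.f_lo_hz, "f_hi_hz": b.f_hi_hz} for b in bands
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
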