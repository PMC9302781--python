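"""Multi-bistatic acquisition geometry.

The scanner records the complex transmission coefficient S21 between a
transmitting antenna on an outer circle and a receiving antenna on an inner
circle, both rotating in the azimuth (coronal) plane.  The receiver visits
``n_receivers`` equispaced azimuths; the transmitter occupies two closely
spaced positions (a *doublet*) inside each of five transmitting sections.
Subtracting the doublet pair cancels any transmit-independent contribution.

Angles are measured in degrees, counterclockwise from the +x axis, in
[0, 360).  Lengths are in metres, frequencies in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["AcquisitionGeometry", "GeometryError", "build_geometry"]


class GeometryError(ValueError):
    """Raised when an acquisition configuration is inconsistent."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Antenna positions, transmitting sections and the frequency grid.

    Defaults reproduce the clinical scanner: 80 receiving points every 4.5
    degrees on a 7 cm circle, 5 transmitting sections (2 doublet positions
    each) on a 30 cm circle, and a 1-9 GHz sweep sampled every 5 MHz.
    """

    receiver_radius: float = 0.07
    tx_radius: float = 0.30
    n_receivers: int = 80
    receiver_step: float = 4.5
    section_centers: tuple[float, ...] = (0.0, 72.0, 144.0, 216.0, 288.0)
    doublet_offset: float = 9.0
    freq_start: float = 1e9
    freq_stop: float = 9e9
    freq_step: float = 5e6

    def __post_init__(self) -> None:
        if self.receiver_radius <= 0 or self.tx_radius <= 0:
            raise GeometryError("antenna radii must be positive")
        if self.receiver_radius >= self.tx_radius:
            raise GeometryError(
                "receiver circle must lie inside the transmitter circle"
            )
        if self.n_receivers < 1:
            raise GeometryError("need at least one receiver position")
        if abs(self.n_receivers * self.receiver_step - 360.0) > 1e-6:
            raise GeometryError(
                f"receiver step {self.receiver_step} deg does not tile 360 deg "
                f"with {self.n_receivers} positions"
            )
        if not self.section_centers:
            raise GeometryError("section list must be non-empty")
        if self.freq_step <= 0 or self.freq_stop <= self.freq_start:
            raise GeometryError("frequency grid must be ascending")
        if self.freq_start <= 0:
            raise GeometryError("frequencies must be positive")

    # -- receivers ---------------------------------------------------------

    @property
    def receiver_azimuths(self) -> np.ndarray:
        """Receiver azimuths in degrees, ``k * step`` for k = 0..N-1."""
        return np.arange(self.n_receivers) * self.receiver_step

    @property
    def receiver_positions(self) -> np.ndarray:
        """(N, 2) Cartesian receiver coordinates in metres."""
        phi = np.deg2rad(self.receiver_azimuths)
        return self.receiver_radius * np.column_stack([np.cos(phi), np.sin(phi)])

    # -- transmitters ------------------------------------------------------

    @property
    def n_sections(self) -> int:
        return len(self.section_centers)

    @property
    def n_transmitters(self) -> int:
        """Sections times the two doublet positions."""
        return 2 * self.n_sections

    def transmitter_angle(self, section: int, doublet: int) -> float:
        """Azimuth (deg) of doublet member ``doublet`` (0 or 1) of a section."""
        if doublet not in (0, 1):
            raise GeometryError("doublet index must be 0 or 1")
        return (self.section_centers[section] + doublet * self.doublet_offset) % 360.0

    def transmitter_position(self, section: int, doublet: int) -> np.ndarray:
        a = np.deg2rad(self.transmitter_angle(section, doublet))
        return self.tx_radius * np.array([np.cos(a), np.sin(a)])

    def section_center_position(self, section: int) -> np.ndarray:
        a = np.deg2rad(self.section_centers[section])
        return self.tx_radius * np.array([np.cos(a), np.sin(a)])

    @property
    def transmitter_pairs(self) -> list[tuple[int, int]]:
        """All (section, doublet) pairs, enumerating transmitter positions."""
        return [(m, p) for m in range(self.n_sections) for p in (0, 1)]

    # -- frequencies -------------------------------------------------------

    @property
    def frequencies(self) -> np.ndarray:
        """Strictly ascending frequency grid in Hz (endpoints inclusive)."""
        n = int(round((self.freq_stop - self.freq_start) / self.freq_step)) + 1
        return self.freq_start + self.freq_step * np.arange(n)

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies)

    def decimated(self, freq_step: float) -> "AcquisitionGeometry":
        """Same geometry on a coarser frequency grid (for fast analysis)."""
        return replace(self, freq_step=freq_step)


_GEOMETRY_KEYS = {f.name for f in AcquisitionGeometry.__dataclass_fields__.values()}


def build_geometry(config: Mapping[str, object] | None = None) -> AcquisitionGeometry:
    """Build an :class:`AcquisitionGeometry` from a parameter mapping.

    ``config`` may override any geometry field.  ``n_receivers`` is derived
    from ``receiver_step`` (or vice versa) when only one is given, keeping
    the invariant ``n_receivers * receiver_step == 360``.

    Raises :class:`GeometryError` for a step that does not divide 360, for
    non-positive radii, or for unknown keys.
    """
    cfg = dict(config or {})
    unknown = set(cfg) - _GEOMETRY_KEYS
    if unknown:
        raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
    if isinstance(cfg.get("section_centers"), Sequence):
        cfg["section_centers"] = tuple(float(a) for a in cfg["section_centers"])
    if "receiver_step" in cfg and "n_receivers" not in cfg:
        step = float(cfg["receiver_step"])
        if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
            raise GeometryError(f"receiver step {step} deg does not divide 360")
        cfg["n_receivers"] = int(round(360.0 / step))
    elif "n_receivers" in cfg and "receiver_step" not in cfg:
        cfg["receiver_step"] = 360.0 / int(cfg["n_receivers"])
    return AcquisitionGeometry(**cfg)  # type: ignore[arg-type]
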