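"""Huygens-principle intensity-map reconstruction.

The internal field is synthesized on a polar grid inside the receiver
circle as a weighted sum of the doublet-differenced S21 records, each
propagated by a zeroth-order cylindrical-wave kernel evaluated at the
complex wavenumber of an assumed homogeneous medium::

    E(rho, phi; m; f)  ∝  sum_n  dS21[n, m, f] * G(k1 |r_n - r|)

Under the e^{+jwt} convention the kernel is the *incoming* cylindrical wave
``H0^(1)(k1 r)``: the recorded boundary values are back-propagated into the
interior.  When the assumed conductivity is non-zero, ``k1`` acquires a
negative imaginary part and ``|H0^(1)(k1 r)|`` grows like
``exp(+|Im k1| r)`` — this growth is the attenuation compensation that
keeps deep scatterers from being penalized, and it can be switched off.

The intensity image sums the squared field magnitude incoherently over all
transmitting sections and frequencies; maps are in arbitrary units.
Varying the assumed conductivity produces the conductivity-weighted image
family (0.01, 0.20, 0.40, 0.60 S/m); 0.40 S/m is the default used by the
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import hankel1

from .geometry import AcquisitionGeometry

__all__ = [
    "C0",
    "EPS0",
    "MU0",
    "CONDUCTIVITY_LEVELS",
    "MediumModel",
    "ReconstructionGrid",
    "IntensityMap",
    "free_space_wavenumber",
    "complex_wavenumber",
    "greens_2d",
    "doublet_difference",
    "huygens_field",
    "intensity_map",
    "polar_to_cartesian",
    "reconstruct",
    "cartesian_axes",
]

C0 = 299792458.0
EPS0 = 8.8541878128e-12
MU0 = 4e-7 * np.pi

#: The four conductivity weightings investigated for each breast, S/m.
CONDUCTIVITY_LEVELS = {
    "sigma1": 0.01,
    "sigma2": 0.20,
    "sigma3": 0.40,
    "sigma4": 0.60,
}

#: Distance floor guarding the kernel singularity at receiver-coincident
#: grid points (metres).
MIN_DISTANCE = 1e-6


class ReconstructionError(ValueError):
    pass


@dataclass(frozen=True)
class MediumModel:
    """Homogeneous medium assumed by the reconstruction kernel.

    The relative permittivity defaults to free space (the antennas operate
    in air); the conductivity is the weighting knob, 0.40 S/m (sigma3) by
    default.
    """

    conductivity: float = CONDUCTIVITY_LEVELS["sigma3"]
    relative_permittivity: float = 1.0

    def __post_init__(self) -> None:
        if self.conductivity < 0:
            raise ReconstructionError("conductivity must be >= 0")
        if self.relative_permittivity < 1:
            raise ReconstructionError("relative permittivity must be >= 1")

    @property
    def label(self) -> str:
        for name, value in CONDUCTIVITY_LEVELS.items():
            if abs(self.conductivity - value) < 1e-12:
                return name
        return f"sigma={self.conductivity:g}"


@dataclass(frozen=True)
class ReconstructionGrid:
    """Polar grid: 1 mm radial and 3 degree azimuthal sampling by default."""

    max_radius: float = 0.07
    radial_step: float = 1e-3
    azimuthal_step: float = 3.0

    def __post_init__(self) -> None:
        if self.max_radius <= 0 or self.radial_step <= 0 or self.azimuthal_step <= 0:
            raise ReconstructionError("grid samplings must be positive")
        if 360.0 % self.azimuthal_step:
            raise ReconstructionError("azimuthal step must divide 360")

    @property
    def rho(self) -> np.ndarray:
        """Radial sample positions in metres (radial_step .. max_radius)."""
        n = int(round(self.max_radius / self.radial_step))
        return self.radial_step * np.arange(1, n + 1)

    @property
    def phi(self) -> np.ndarray:
        """Azimuthal sample positions in degrees, [0, 360)."""
        return np.arange(0.0, 360.0, self.azimuthal_step)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rho), len(self.phi)

    def points(self) -> np.ndarray:
        """(n_rho * n_phi, 2) Cartesian coordinates, rho-major order."""
        p = np.deg2rad(self.phi)
        x = np.outer(self.rho, np.cos(p))
        y = np.outer(self.rho, np.sin(p))
        return np.column_stack([x.ravel(), y.ravel()])


def cartesian_axes(grid_radius: float = 0.07, step: float = 1e-3):
    """x and y axes (metres) of the square Cartesian grid spanning the disc."""
    n = int(round(grid_radius / step))
    ax = step * np.arange(-n, n + 1)
    return ax, ax.copy()


@dataclass
class IntensityMap:
    """Non-negative 2D homogeneity map in arbitrary units.

    Polar maps carry their (rho, phi) axes; Cartesian maps are square
    arrays on a 1 mm grid with pixels outside the disc set to zero.  Row
    index increases downward: row 0 is the top of the coronal image, so
    the "upper zone" is the upper half of the array.
    """

    values: np.ndarray
    kind: Literal["polar", "cartesian"]
    grid_radius: float = 0.07
    rho: np.ndarray | None = None
    phi: np.ndarray | None = None
    conductivity_label: str | None = None
    breast_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ReconstructionError("intensity values must be finite")
        if np.any(self.values < 0):
            raise ReconstructionError("intensity values must be non-negative")
        if self.kind == "polar":
            if self.rho is None or self.phi is None:
                raise ReconstructionError("polar map needs rho and phi axes")
            if self.values.shape != (len(self.rho), len(self.phi)):
                raise ReconstructionError("polar shape does not match axes")
        elif self.kind == "cartesian":
            n = int(round(self.grid_radius / 1e-3)) * 2 + 1
            if self.values.shape != (n, n):
                raise ReconstructionError(
                    f"cartesian map must be {n}x{n} for radius {self.grid_radius}"
                )
        else:
            raise ReconstructionError(f"unknown map kind {self.kind!r}")

    @property
    def disc_mask(self) -> np.ndarray:
        """Boolean in-disc mask (Cartesian maps)."""
        if self.kind != "cartesian":
            raise ReconstructionError("disc_mask is defined for Cartesian maps")
        n = self.values.shape[0]
        c = (n - 1) / 2.0
        rows, cols = np.ogrid[0:n, 0:n]
        return (rows - c) ** 2 + (cols - c) ** 2 <= c**2

    def argmax_polar(self) -> tuple[float, float]:
        """(rho_m, phi_deg) of the global maximum of a polar map."""
        if self.kind != "polar":
            raise ReconstructionError("argmax_polar is defined for polar maps")
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return float(self.rho[i]), float(self.phi[j])


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def free_space_wavenumber(f):
    """Real free-space wavenumber 2*pi*f/c, rad/m."""
    return 2.0 * np.pi * np.asarray(f, dtype=float) / C0


def complex_wavenumber(f: float, medium: MediumModel) -> complex:
    """Complex wavenumber ``k1 = w sqrt(mu0 eps_hat)`` of the lossy medium.

    ``eps_hat = eps0 epsr (1 - j sigma / (w eps0 epsr))``; for sigma=0 this
    reduces to the real free-space wavenumber.  ``Im k1 <= 0``; the field
    attenuation rate is ``|Im k1|`` nepers/m.
    """
    if np.any(np.asarray(f) <= 0):
        raise ReconstructionError("frequency must be positive")
    w = 2.0 * np.pi * f
    epsr = medium.relative_permittivity
    eps_hat = EPS0 * epsr * (1.0 - 1j * medium.conductivity / (w * EPS0 * epsr))
    return w * np.sqrt(MU0 * eps_hat)


def greens_2d(k1: complex, distance, compensate: bool = True):
    """Zeroth-order cylindrical back-propagation kernel ``H0^(1)(k1 r)``.

    All constant prefactors are dropped (the field sum is a
    proportionality; maps are in arbitrary units).  For lossy media
    (``Im k1 < 0``) the kernel magnitude grows like ``exp(+|Im k1| r)``,
    compensating the attenuation a wave suffered travelling distance ``r``
    into the medium; ``compensate=False`` removes that growth factor.  For
    ``sigma = 0`` the kernel is lossless and the flag is a no-op.
    """
    r = np.asarray(distance, dtype=float)
    if np.any(r <= 0):
        raise ReconstructionError("distance must be positive")
    g = hankel1(0, k1 * r)
    alpha = abs(np.imag(k1))
    if not compensate and alpha > 0:
        g = g * np.exp(-alpha * r)
    return g


# ---------------------------------------------------------------------------
# Reconstruction pipeline
# ---------------------------------------------------------------------------


def doublet_difference(dataset) -> np.ndarray:
    """Per-section doublet subtraction, ``(n, m, f) -> S21[p=0] - S21[p=1]``.

    Any contribution identical across a section's doublet (the direct
    antenna coupling, cup reflections, ...) cancels exactly.
    """
    values = dataset.values if hasattr(dataset, "values") else np.asarray(dataset)
    if values.ndim != 4 or values.shape[2] != 2:
        raise ReconstructionError(
            "expected S21 array of shape (receivers, sections, 2, frequencies)"
        )
    return values[:, :, 0, :] - values[:, :, 1, :]


def huygens_field(
    diff: np.ndarray,
    geometry: AcquisitionGeometry,
    medium: MediumModel,
    grid: ReconstructionGrid | None = None,
    compensate: bool = True,
    frequencies: np.ndarray | None = None,
) -> tuple[np.ndarray, ReconstructionGrid]:
    """Back-propagate differenced signals onto the polar grid.

    Returns ``(E, grid)`` with ``E`` complex of shape
    ``(n_rho, n_phi, n_sections, n_freq)``.  Distances from grid points to
    receivers are floored at ``MIN_DISTANCE`` to guard the kernel
    singularity at receiver-coincident points.
    """
    grid = grid or ReconstructionGrid(max_radius=geometry.receiver_radius)
    if grid.max_radius > geometry.receiver_radius + 1e-12:
        raise ReconstructionError("grid extends beyond the receiver circle")
    freqs = geometry.frequencies if frequencies is None else np.asarray(frequencies)
    n_rx, n_sec = geometry.n_receivers, geometry.n_sections
    if diff.shape != (n_rx, n_sec, len(freqs)):
        raise ReconstructionError(
            f"differenced array shape {diff.shape} != "
            f"({n_rx}, {n_sec}, {len(freqs)})"
        )
    pts = grid.points()  # (npix, 2)
    rx = geometry.receiver_positions
    dist = np.sqrt(
        (pts[None, :, 0] - rx[:, 0:1]) ** 2 + (pts[None, :, 1] - rx[:, 1:2]) ** 2
    )
    dist = np.maximum(dist, MIN_DISTANCE)  # (n_rx, npix)

    n_rho, n_phi = grid.shape
    out = np.empty((n_rho, n_phi, n_sec, len(freqs)), dtype=np.complex128)
    for fi, f in enumerate(freqs):
        k1 = complex_wavenumber(float(f), medium)
        g = greens_2d(k1, dist, compensate=compensate)  # (n_rx, npix)
        e = diff[:, :, fi].T @ g  # (n_sec, npix)
        out[:, :, :, fi] = e.T.reshape(n_rho, n_phi, n_sec)
    return out, grid


def intensity_map(
    fields: np.ndarray,
    grid: ReconstructionGrid,
    conductivity_label: str | None = None,
    breast_id: str | None = None,
) -> IntensityMap:
    """Incoherent sum ``I = sum_m sum_f |E|^2`` over sections and frequencies."""
    fields = np.asarray(fields)
    if fields.ndim != 4 or fields.shape[:2] != grid.shape:
        raise ReconstructionError("fields do not match the reconstruction grid")
    values = np.sum(np.abs(fields) ** 2, axis=(2, 3))
    return IntensityMap(
        values=values,
        kind="polar",
        grid_radius=grid.max_radius,
        rho=grid.rho,
        phi=grid.phi,
        conductivity_label=conductivity_label,
        breast_id=breast_id,
    )


def polar_to_cartesian(pmap: IntensityMap) -> IntensityMap:
    """Bilinear (rho, phi) interpolation onto the 1 mm Cartesian grid.

    The azimuth axis is wrapped so interpolation is continuous across 360
    degrees; radii below the first ring are clamped to it.  Pixels outside
    the disc are zero; the output is ``(2R+1) x (2R+1)`` pixels (141x141
    for the default 7 cm radius).
    """
    if pmap.kind != "polar":
        raise ReconstructionError("input must be a polar map")
    rho, phi = pmap.rho, pmap.phi
    vals = np.concatenate([pmap.values, pmap.values[:, :1]], axis=1)
    phi_wrapped = np.concatenate([phi, [phi[0] + 360.0]])
    interp = RegularGridInterpolator(
        (rho, phi_wrapped), vals, method="linear", bounds_error=False, fill_value=None
    )
    x, y = cartesian_axes(pmap.grid_radius)
    # row 0 = top of the image = +y
    yy = y[::-1][:, None]
    xx = x[None, :]
    r = np.hypot(xx, yy)
    a = np.rad2deg(np.arctan2(np.broadcast_to(yy, r.shape), np.broadcast_to(xx, r.shape))) % 360.0
    disc = r <= pmap.grid_radius + 1e-12
    rq = np.clip(r, rho[0], rho[-1])
    out = np.zeros_like(r)
    out[disc] = interp(np.column_stack([rq[disc], a[disc]]))
    out = np.clip(out, 0.0, None)
    return IntensityMap(
        values=out,
        kind="cartesian",
        grid_radius=pmap.grid_radius,
        conductivity_label=pmap.conductivity_label,
        breast_id=pmap.breast_id,
    )


def reconstruct(
    dataset,
    medium: MediumModel | None = None,
    grid: ReconstructionGrid | None = None,
    compensate: bool = True,
    cartesian: bool = False,
) -> IntensityMap:
    """Full chain: doublet difference -> field synthesis -> intensity map."""
    medium = medium or MediumModel()
    diff = doublet_difference(dataset)
    fields, grid = huygens_field(diff, dataset.geometry, medium, grid, compensate)
    pmap = intensity_map(fields, grid, conductivity_label=medium.label)
    return polar_to_cartesian(pmap) if cartesian else pmap
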