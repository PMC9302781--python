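"""Synthetic scattering data and synthetic intensity-map cohorts.

Two generators make the full pipeline testable without clinical recordings:

* :func:`simulate_s21` — a single-scattering (Born-type) forward model for
  the multi-bistatic acquisition.  Each record is a direct-coupling term,
  shared exactly by the two doublet members of a section, plus one
  cylindrical-wave bounce per inclusion, plus optional circular complex
  Gaussian noise.  The shared direct term is a modelling choice, not a
  physics claim: it guarantees that doublet subtraction cancels the
  artefact exactly in the noiseless case, which is the property the
  reconstruction relies on.

* :func:`synth_intensity_map` / :func:`synth_cohort` — Gaussian-blob
  intensity images on the 1 mm Cartesian grid, with controlled contrast
  between malignant-finding (MF) and no-finding/benign (NF+BF) groups, for
  exercising segmentation and classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import hankel2

from .geometry import AcquisitionGeometry
from .recon import IntensityMap, cartesian_axes, free_space_wavenumber

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "S21Dataset",
    "CohortItem",
    "simulate_s21",
    "synth_intensity_map",
    "synth_cohort",
]


class ValidationError(ValueError):
    """Raised when a phantom or generator specification is invalid."""


@dataclass(frozen=True)
class Inclusion:
    """A point/disc scatterer inside the cup.

    ``center_rho`` (m) and ``center_phi`` (deg, ccw from +x) place the
    inclusion in the coronal plane; ``amplitude`` is its complex scattering
    strength in the single-bounce model; ``radius`` is descriptive only.
    """

    center_rho: float
    center_phi: float
    radius: float = 0.005
    amplitude: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("inclusion radius must be positive")
        if not np.isfinite(self.amplitude):
            raise ValidationError("inclusion amplitude must be finite")

    @property
    def position(self) -> np.ndarray:
        a = np.deg2rad(self.center_phi)
        return self.center_rho * np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class PhantomSpec:
    """The breast stand-in: a cup with zero or more inclusions."""

    cup_radius: float = 0.07
    background_conductivity: float = 0.0
    inclusions: tuple[Inclusion, ...] = ()

    def __post_init__(self) -> None:
        if self.cup_radius <= 0:
            raise ValidationError("cup radius must be positive")
        for inc in self.inclusions:
            if inc.center_rho > self.cup_radius:
                raise ValidationError(
                    f"inclusion at rho={inc.center_rho} m lies outside the "
                    f"{self.cup_radius} m cup"
                )


@dataclass
class S21Dataset:
    """Complex S21 records, shape ``(n_receivers, n_sections, 2, n_freq)``."""

    values: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        g = self.geometry
        expected = (g.n_receivers, g.n_sections, 2, g.n_frequencies)
        if self.values.shape != expected:
            raise ValidationError(
                f"S21 array shape {self.values.shape} != geometry shape {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("S21 values must be finite")


def simulate_s21(
    phantom: PhantomSpec,
    geometry: AcquisitionGeometry,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> S21Dataset:
    """Forward-model the multi-bistatic acquisition of ``phantom``.

    For receiver n, section m, doublet member p and frequency f::

        S21[n,m,p,f] = G(k0 |tx_center_m - rx_n|)                      (direct)
                     + sum_inc  a_inc G(k0 |tx_{m,p} - r_inc|)
                                      G(k0 |r_inc - rx_n|)             (scattered)
                     + noise

    with ``G = H0^(2)`` (outgoing cylindrical wave, e^{+jwt} convention) and
    ``k0`` the free-space wavenumber.  The direct term is evaluated at the
    section centre so it is identical for both doublet members; with
    ``noise_sd = 0`` the doublet difference therefore removes it exactly.
    Noise is circular complex Gaussian with total standard deviation
    ``noise_sd`` per sample, seeded for bit-identical reproducibility.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if phantom.cup_radius > geometry.receiver_radius:
        raise ValidationError("cup must fit inside the receiver circle")
    rng = np.random.default_rng(seed)
    rx = geometry.receiver_positions  # (N, 2)
    freqs = geometry.frequencies
    k0 = free_space_wavenumber(freqs)  # (NF,)
    n, nf = geometry.n_receivers, geometry.n_frequencies

    values = np.zeros((n, geometry.n_sections, 2, nf), dtype=np.complex128)
    for m in range(geometry.n_sections):
        d_direct = np.linalg.norm(rx - geometry.section_center_position(m), axis=1)
        direct = hankel2(0, k0[None, :] * d_direct[:, None])  # (N, NF)
        for p in (0, 1):
            tx = geometry.transmitter_position(m, p)
            total = direct.copy()
            for inc in phantom.inclusions:
                d_ti = np.linalg.norm(tx - inc.position)
                d_ir = np.linalg.norm(rx - inc.position, axis=1)  # (N,)
                total += inc.amplitude * hankel2(0, k0 * d_ti)[None, :] * hankel2(
                    0, k0[None, :] * d_ir[:, None]
                )
            values[:, m, p, :] = total
    if noise_sd > 0:
        scale = noise_sd / np.sqrt(2.0)
        values += scale * (
            rng.standard_normal(values.shape) + 1j * rng.standard_normal(values.shape)
        )
    return S21Dataset(values=values, geometry=geometry)


# ---------------------------------------------------------------------------
# Intensity-map generators
# ---------------------------------------------------------------------------


def synth_intensity_map(
    grid_radius: float = 0.07,
    lesions: Sequence[tuple[tuple[float, float], float, float]] = (),
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    breast_id: str | None = None,
) -> IntensityMap:
    """Gaussian-blob intensity image on the 1 mm Cartesian grid.

    ``lesions`` is a sequence of ``((row, col), radius_mm, amplitude)``
    entries; ``(row, col)`` are pixel coordinates (row 0 at the top of the
    coronal map) and the blob profile is ``amplitude *
    exp(-d^2 / (2 radius_mm^2))``.  The result is clipped to be
    non-negative and zeroed outside the ``grid_radius`` disc.
    """
    if background_level < 0 or noise_sd < 0:
        raise ValidationError("background level and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x_mm, y_mm = cartesian_axes(grid_radius)
    npix = len(x_mm)
    center = (npix - 1) / 2.0
    rows, cols = np.mgrid[0:npix, 0:npix].astype(float)
    disc = (rows - center) ** 2 + (cols - center) ** 2 <= center**2

    img = np.full((npix, npix), float(background_level))
    for (crow, ccol), radius_mm, amplitude in lesions:
        if (crow - center) ** 2 + (ccol - center) ** 2 > center**2:
            raise ValidationError(f"lesion centre ({crow}, {ccol}) outside the disc")
        if radius_mm <= 0:
            raise ValidationError("lesion radius must be positive")
        d2 = (rows - crow) ** 2 + (cols - ccol) ** 2
        img += amplitude * np.exp(-d2 / (2.0 * radius_mm**2))
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, None)
    img[~disc] = 0.0
    return IntensityMap(values=img, kind="cartesian", grid_radius=grid_radius,
                        breast_id=breast_id)


class CohortItem(NamedTuple):
    """One synthetic breast: the image plus its gold label and lesion zone."""

    image: IntensityMap
    label: str  # "MF" or "NF+BF"
    zone: str  # "upper" or "lower"


@dataclass(frozen=True)
class CohortParams:
    """Study conditions of the synthetic cohort.

    ``background_mean``/``background_sd`` set the between-breast spread of
    the flat tissue-homogeneity level; every breast carries one focal blob
    (benign or malignant finding, or a dense fibroglandular focus) of
    ``blob_amplitude`` at ``blob_rho_mm`` from the centre, placed in the
    upper zone with probability ``p_upper``.  MF breasts have their level
    shifted by ``effect_size * shift_unit``; 150 a.u. is 2.5x the
    between-breast SD, so ``effect_size`` is a standardized separation dial
    with 0 giving exchangeable groups.
    """

    grid_radius: float = 0.07
    background_mean: float = 1000.0
    background_sd: float = 60.0
    shift_unit: float = 150.0
    blob_amplitude: float = 2500.0
    blob_sigma_mm: float = 8.0
    blob_rho_mm: float = 35.0
    pixel_noise_sd: float = 10.0
    p_upper: float = 0.7
    phi_margin_deg: float = 15.0


def synth_cohort(
    n_nfbf: int,
    n_mf: int,
    effect_size: float = 3.0,
    seed: int = 0,
    params: CohortParams | None = None,
) -> list[CohortItem]:
    """Generate ``n_nfbf`` NF+BF and ``n_mf`` MF synthetic breasts.

    Labels and lesion zones are recorded as ground truth.  The per-item
    random draws are identical for both groups; the only group difference
    is the MF level shift, so at ``effect_size = 0`` the two groups'
    image distributions are exchangeable by construction.
    """
    if n_nfbf <= 0 or n_mf <= 0:
        raise ValidationError("both group sizes must be positive")
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    npix = int(round(p.grid_radius / 1e-3)) * 2 + 1
    center = (npix - 1) / 2.0

    items: list[CohortItem] = []
    for i in range(n_nfbf + n_mf):
        is_mf = i >= n_nfbf
        zone = "upper" if rng.random() < p.p_upper else "lower"
        level = p.background_mean + p.background_sd * rng.standard_normal()
        if is_mf:
            level += effect_size * p.shift_unit
        level = max(level, 0.0)
        lo, hi = (p.phi_margin_deg, 180.0 - p.phi_margin_deg)
        if zone == "lower":
            lo, hi = 180.0 + p.phi_margin_deg, 360.0 - p.phi_margin_deg
        phi = np.deg2rad(rng.uniform(lo, hi))
        # +y (sin) is up; image rows grow downward
        crow = center - p.blob_rho_mm * np.sin(phi)
        ccol = center + p.blob_rho_mm * np.cos(phi)
        img = synth_intensity_map(
            grid_radius=p.grid_radius,
            lesions=[((crow, ccol), p.blob_sigma_mm, p.blob_amplitude)],
            background_level=level,
            noise_sd=p.pixel_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            breast_id=f"synth-{i + 1:03d}",
        )
        items.append(CohortItem(image=img, label="MF" if is_mf else "NF+BF", zone=zone))
    return items
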