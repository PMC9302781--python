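"""Non-parametric quartile thresholding of smoothed intensity maps.

Each breast image is Gaussian-smoothed (sigma = 30 px on the 1 mm grid,
replicate padding) and summarized by the quartiles of its in-disc pixel
intensities.  The cohort decision threshold is the average of the two
groups' mean upper quartiles::

    theta = ( mean_{NF+BF} Q3  +  mean_{MF} Q3 ) / 2

and a breast is called MF when its median lies beyond theta (Q2 > theta;
ties go to NF+BF).  The comparison direction is configurable because the
group statistics of real cohorts can point either way.

Quartiles use the linear-interpolation estimator between order statistics.
For disc-masked images the smoothing is mask-aware (normalized
convolution), so a constant in-disc level stays constant instead of being
dragged down by the zeros outside the disc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "SmoothingParams",
    "BoxplotSummary",
    "CohortThreshold",
    "gaussian_smooth",
    "intensity_quartiles",
    "cohort_threshold",
    "classify_breast",
    "summarize_cohort",
    "classify_cohort",
]

MF = "MF"
NFBF = "NF+BF"


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class SmoothingParams:
    """2D Gaussian kernel: sigma in pixels, replicate padding, 4-sigma cut."""

    sigma: float = 30.0
    padding: str = "nearest"  # scipy name for replicate (edge-value) padding
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ClassifierError("sigma must be positive")
        if self.truncate < 2:
            raise ClassifierError("kernel must extend at least 2 sigma")


@dataclass(frozen=True)
class BoxplotSummary:
    """Per-breast quartiles plus Tukey 1.5*IQR whisker fences (a.u.)."""

    breast_id: str
    q1: float
    q2: float
    q3: float
    whisker_low: float
    whisker_high: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ClassifierError("quartiles must be ordered Q1 <= Q2 <= Q3")


@dataclass(frozen=True)
class CohortThreshold:
    """The Q3-average decision threshold and the group means behind it."""

    theta: float
    mean_q3_nfbf: float
    mean_q3_mf: float
    direction: str = "above"  # "above": Q2 > theta => MF; "below": Q2 < theta => MF


def gaussian_smooth(image, params: SmoothingParams | None = None,
                    mask: np.ndarray | None = None):
    """Separable Gaussian smoothing with replicate padding.

    With ``mask`` given (or an in-disc Cartesian :class:`IntensityMap`),
    normalized (mask-aware) convolution is used: the smoothed value at an
    in-disc pixel averages only in-disc neighbours, so constants inside the
    disc are fixed points and the disc edge introduces no falloff.
    Out-of-mask pixels remain zero.  Non-negativity is preserved.
    """
    params = params or SmoothingParams()
    is_map = hasattr(image, "values")
    if is_map:
        if mask is None and image.kind == "cartesian":
            mask = image.disc_mask
        arr = image.values
    else:
        arr = np.asarray(image, dtype=float)

    if mask is None:
        out = ndimage.gaussian_filter(
            arr, params.sigma, mode=params.padding, truncate=params.truncate
        )
    else:
        m = mask.astype(float)
        num = ndimage.gaussian_filter(
            arr * m, params.sigma, mode=params.padding, truncate=params.truncate
        )
        den = ndimage.gaussian_filter(
            m, params.sigma, mode=params.padding, truncate=params.truncate
        )
        out = np.where(mask, num / np.maximum(den, 1e-300), 0.0)
    out = np.clip(out, 0.0, None)
    if is_map:
        from .recon import IntensityMap

        return IntensityMap(
            values=out,
            kind=image.kind,
            grid_radius=image.grid_radius,
            rho=image.rho,
            phi=image.phi,
            conductivity_label=image.conductivity_label,
            breast_id=image.breast_id,
        )
    return out


def intensity_quartiles(image, mask: np.ndarray | None = None,
                        breast_id: str | None = None) -> BoxplotSummary:
    """Quartiles of the masked pixel intensities (linear interpolation)."""
    if hasattr(image, "values"):
        if mask is None and image.kind == "cartesian":
            mask = image.disc_mask
        if breast_id is None:
            breast_id = image.breast_id
        arr = image.values
    else:
        arr = np.asarray(image, dtype=float)
    vals = arr[mask] if mask is not None else arr.ravel()
    if vals.size == 0:
        raise ClassifierError("empty pixel mask")
    q1, q2, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    return BoxplotSummary(
        breast_id=breast_id or "",
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def cohort_threshold(
    summaries: Sequence[BoxplotSummary],
    labels: Sequence[str],
    direction: str = "above",
) -> CohortThreshold:
    """Average the two groups' mean Q3 values into the decision threshold."""
    if len(summaries) != len(labels):
        raise ClassifierError("summaries and labels must align")
    q3_nfbf = [s.q3 for s, l in zip(summaries, labels) if l == NFBF]
    q3_mf = [s.q3 for s, l in zip(summaries, labels) if l == MF]
    if not q3_nfbf or not q3_mf:
        raise ClassifierError("both groups must be non-empty to fit a threshold")
    m_n, m_m = float(np.mean(q3_nfbf)), float(np.mean(q3_mf))
    return CohortThreshold(
        theta=(m_n + m_m) / 2.0, mean_q3_nfbf=m_n, mean_q3_mf=m_m,
        direction=direction,
    )


def classify_breast(summary: BoxplotSummary, threshold: CohortThreshold) -> str:
    """MF when the median lies beyond theta; the tie goes to NF+BF."""
    if threshold.direction == "above":
        return MF if summary.q2 > threshold.theta else NFBF
    if threshold.direction == "below":
        return MF if summary.q2 < threshold.theta else NFBF
    raise ClassifierError(f"unknown direction {threshold.direction!r}")


def summarize_cohort(
    images: Iterable,
    smoothing: SmoothingParams | None = None,
) -> list[BoxplotSummary]:
    """Smooth each image and summarize its in-disc quartiles."""
    return [intensity_quartiles(gaussian_smooth(img, smoothing)) for img in images]


def classify_cohort(
    images: Sequence,
    gold_labels: Sequence[str],
    smoothing: SmoothingParams | None = None,
    direction: str = "above",
    threshold: CohortThreshold | None = None,
) -> tuple[list[str], CohortThreshold, list[BoxplotSummary]]:
    """Supervised chain: smooth -> quartiles -> fit theta on gold -> classify.

    A pre-fitted ``threshold`` may be supplied instead (held-out
    application); gold labels are then only carried through for scoring.
    """
    summaries = summarize_cohort(images, smoothing)
    if threshold is None:
        threshold = cohort_threshold(summaries, gold_labels, direction)
    predictions = [classify_breast(s, threshold) for s in summaries]
    return predictions, threshold, summaries
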