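"""Simplified pulse-coupled neural network (PCNN) segmentation.

One neuron per pixel.  Each iteration n computes

    F[n] = S                                  (feeding: the stimulus)
    L[n] = sum_kl W[k,l] O[n-1]               (linking: neighbours' pulses)
    U[n] = F[n] (1 + beta L[n])               (internal activity)
    O[n] = 1 where U[n] > T[n-1]              (pulse output)
    T[n] = exp(-alpha_t) T[n-1] + V_T O[n-1]  (decaying, pulse-boosted threshold)

with O[0] = 0 and T[0] = t0 (0 by default, so every positive-stimulus
neuron fires at iteration 1).  The network is run for a fixed budget of 32
iterations — it has no stopping criterion — and the iteration-5 mask is the
one used for lesion localization.  The whole recurrence is deterministic.

The stimulus is the min-max normalized image scaled to the 8-bit range
(``stimulus_scale = 255``); with the default constants (V_T=20, beta=3,
alpha_t=0.2) this places the threshold trajectory inside the activity range
so that by iteration 5 only high-intensity, spatially supported regions
keep firing, and the iteration-5 mask closely resembles late-iteration
masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PCNNParams",
    "PCNNState",
    "SegmentationStack",
    "LesionRegion",
    "default_linking_kernel",
    "normalize_input",
    "linking_field",
    "pcnn_step",
    "run_pcnn",
    "select_mask",
    "extract_regions",
    "assign_zone",
    "segment",
]


class SegmentationError(ValueError):
    pass


class DegenerateInputWarning(UserWarning):
    """Emitted when the stimulus is constant (zero dynamic range)."""


def default_linking_kernel() -> np.ndarray:
    """3x3 inverse-Euclidean-distance weights, centre 0, unnormalized."""
    d = 2.0**-0.5
    return np.array([[d, 1.0, d], [1.0, 0.0, 1.0], [d, 1.0, d]])


@dataclass(frozen=True)
class PCNNParams:
    beta: float = 3.0
    alpha_t: float = 0.2
    v_t: float = 20.0
    weights: np.ndarray = field(default_factory=default_linking_kernel)
    n_iter: int = 32
    t0: float = 0.0
    selected_iteration: int = 5
    stimulus_scale: float = 255.0
    min_area: int = 5

    def __post_init__(self) -> None:
        if self.beta < 0 or self.alpha_t <= 0 or self.v_t <= 0:
            raise SegmentationError("beta >= 0, alpha_t > 0 and v_t > 0 required")
        if not (1 <= self.selected_iteration <= self.n_iter):
            raise SegmentationError("selected iteration must be within n_iter")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise SegmentationError("linking weights must be non-negative")
        object.__setattr__(self, "weights", w)


@dataclass
class PCNNState:
    """All lattices of one iteration; ``n`` is the 1-based iteration index."""

    s: np.ndarray
    f: np.ndarray
    l: np.ndarray
    u: np.ndarray
    t: np.ndarray
    o: np.ndarray
    n: int = 0

    @classmethod
    def initial(cls, s: np.ndarray, params: PCNNParams) -> "PCNNState":
        z = np.zeros_like(s)
        return cls(s=s, f=s.copy(), l=z.copy(), u=z.copy(),
                   t=np.full_like(s, params.t0), o=z.copy(), n=0)


@dataclass
class LesionRegion:
    """An 8-connected component of a fired mask."""

    pixels: np.ndarray  # (area, 2) row/col coordinates
    centroid: tuple[float, float]
    area: int
    zone: str | None = None


@dataclass
class SegmentationStack:
    """Binary masks for every iteration, plus the selected one's regions."""

    masks: list[np.ndarray]
    selected: int  # 1-based iteration index
    regions: list[LesionRegion] = field(default_factory=list)

    @property
    def selected_mask(self) -> np.ndarray:
        return self.masks[self.selected - 1]


# ---------------------------------------------------------------------------


def normalize_input(image, mask: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalize in-disc pixels to [0, 1]; outside pixels are 0.

    ``image`` may be an :class:`~mwbreast.recon.IntensityMap` (Cartesian) or
    a plain array.  A constant image has zero range: the result is all
    zeros and a :class:`DegenerateInputWarning` is emitted.
    """
    if hasattr(image, "values"):
        if mask is None and image.kind == "cartesian":
            mask = image.disc_mask
        arr = image.values
    else:
        arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise SegmentationError("stimulus must be finite")
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    vals = arr[mask]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(arr, dtype=float)
    if hi == lo:
        warnings.warn(
            "constant image: stimulus is identically zero", DegenerateInputWarning
        )
        return out
    out[mask] = (arr[mask] - lo) / (hi - lo)
    return out


def linking_field(o_prev: np.ndarray, params: PCNNParams) -> np.ndarray:
    """Weighted sum of the previous pulses over each neuron's neighbourhood.

    Border neurons see only in-bounds neighbours (zero padding).
    """
    return ndimage.correlate(
        np.asarray(o_prev, dtype=float), params.weights, mode="constant", cval=0.0
    )


def pcnn_step(state: PCNNState, params: PCNNParams) -> PCNNState:
    """Advance the network one iteration.

    The threshold update uses the *previous* iteration's output, so where
    ``O[n-1] = 0`` the threshold decays by exactly ``exp(-alpha_t)``.
    """
    l = linking_field(state.o, params)
    u = state.s * (1.0 + params.beta * l)
    o_new = (u > state.t).astype(float)
    t_new = np.exp(-params.alpha_t) * state.t + params.v_t * state.o
    return PCNNState(s=state.s, f=state.s.copy(), l=l, u=u, t=t_new, o=o_new,
                     n=state.n + 1)


def run_pcnn(image, params: PCNNParams | None = None,
             mask: np.ndarray | None = None) -> SegmentationStack:
    """Run the PCNN for the fixed iteration budget (32 by default).

    Returns one binary mask per iteration.  Deterministic: there is no
    randomness anywhere in the recurrence.
    """
    params = params or PCNNParams()
    s = normalize_input(image, mask) * params.stimulus_scale
    state = PCNNState.initial(s, params)
    masks: list[np.ndarray] = []
    for _ in range(params.n_iter):
        state = pcnn_step(state, params)
        masks.append(state.o.astype(bool))
    return SegmentationStack(masks=masks, selected=params.selected_iteration)


def select_mask(stack: SegmentationStack, k: int | None = None) -> np.ndarray:
    """Mask of iteration ``k`` (1-based; default the stack's selected one)."""
    k = stack.selected if k is None else k
    if not (1 <= k <= len(stack.masks)):
        raise IndexError(f"iteration {k} outside 1..{len(stack.masks)}")
    return stack.masks[k - 1]


_EIGHT = np.ones((3, 3), dtype=int)


def extract_regions(mask: np.ndarray, min_area: int = 5) -> list[LesionRegion]:
    """8-connected components with area >= ``min_area``, largest first."""
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    regions: list[LesionRegion] = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        if len(pix) < min_area:
            continue
        regions.append(
            LesionRegion(
                pixels=pix,
                centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
                area=len(pix),
            )
        )
    regions.sort(key=lambda r: r.area, reverse=True)
    return regions


def assign_zone(region: LesionRegion, image_shape: tuple[int, int]) -> str:
    """Upper/lower half of the coronal image, by centroid row.

    Row 0 is the top of the image; a centroid exactly on the centre row is
    assigned "upper" (documented tie rule).
    """
    center_row = (image_shape[0] - 1) / 2.0
    return "upper" if region.centroid[0] <= center_row else "lower"


def segment(image, params: PCNNParams | None = None,
            mask: np.ndarray | None = None) -> SegmentationStack:
    """Run the PCNN, then label and zone the selected-iteration regions."""
    params = params or PCNNParams()
    stack = run_pcnn(image, params, mask)
    selected = select_mask(stack)
    regions = extract_regions(selected, min_area=params.min_area)
    for r in regions:
        r.zone = assign_zone(r, selected.shape)
    stack.regions = regions
    return stack
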