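"""Dense warp-field estimation and iterative reference-frame selection.

Every frame of a sequence is described by the per-pixel displacement
("warp") field that maps it onto a common reference frame; the warp
field is the *shape* half of the hybrid shape+texture representation,
the image itself the *texture* half.

The default estimator is dense iterative Lucas-Kanade
(:func:`skimage.registration.optical_flow_ilk`), multi-scale and
iteratively refined.  Any callable ``(frame_gray, reference_gray) ->
(dy, dx)`` with the same sign convention can be substituted via the
``estimator`` argument: the pipeline depends only on the field's
semantics, not on a particular flow algorithm.

Sign convention: the field stores, at each reference-grid pixel, the
displacement at which to *sample the current frame* so that the warped
frame aligns with the reference (backward warping) --
``warped(r, c) = frame(r + dy(r, c), c + dx(r, c))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk

__all__ = [
    "WarpField",
    "ReferenceSelection",
    "estimate_warp",
    "warp_image",
    "select_reference",
]

logger = logging.getLogger(__name__)

#: ILK settings: radius/warp counts tuned for ~120x160 articulation imagery
_ILK_KWARGS = dict(radius=7, num_warp=3, gaussian=True)


@dataclass(frozen=True)
class WarpField:
    """Per-pixel (dx, dy) displacement mapping a frame onto a reference."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must share geometry")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("warp field must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "WarpField":
        return cls(np.zeros(shape), np.zeros(shape))


def _as_gray(image: np.ndarray) -> np.ndarray:
    """Mean-over-channels grayscale; pass 2-D images through."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got shape {image.shape}")
    return img


def estimate_warp(
    frame: np.ndarray,
    reference: np.ndarray,
    estimator: Callable[[np.ndarray, np.ndarray], tuple] | None = None,
) -> WarpField:
    """Estimate the dense field warping ``frame`` onto ``reference``.

    Identical inputs produce an exactly zero field; constant (untextured)
    inputs produce a zero field with a logged warning, since no gradient
    information constrains the flow there.
    """
    f = _as_gray(frame)
    r = _as_gray(reference)
    if f.shape != r.shape:
        raise ValueError(
            f"frame geometry {f.shape} != reference geometry {r.shape}"
        )
    if np.array_equal(f, r):
        return WarpField.zero(f.shape)
    if np.ptp(f) == 0 or np.ptp(r) == 0:
        logger.warning(
            "constant (untextured) input to estimate_warp; returning zero field"
        )
        return WarpField.zero(f.shape)
    if estimator is None:
        dy, dx = optical_flow_ilk(r, f, **_ILK_KWARGS)
    else:
        dy, dx = estimator(f, r)
    return WarpField(np.asarray(dx, dtype=np.float64), np.asarray(dy, dtype=np.float64))


def warp_image(image: np.ndarray, fld: WarpField) -> np.ndarray:
    """Backward-warp ``image`` by ``fld`` (bilinear, border-clamped).

    Output pixel (r, c) samples the image at (r + dy, c + dx); samples
    falling outside the image clamp to the nearest border pixel.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape[:2] != fld.shape:
        raise ValueError(
            f"image geometry {img.shape[:2]} != field geometry {fld.shape}"
        )
    h, w = fld.shape
    rr, cc = np.mgrid[0:h, 0:w]
    coords = np.array([rr + fld.dy, cc + fld.dx])
    if img.ndim == 2:
        return ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.map_coordinates(
            img[..., ch], coords, order=1, mode="nearest"
        )
    return out


@dataclass(frozen=True)
class ReferenceSelection:
    """Result of the iterative mean-texture reference procedure."""

    reference: np.ndarray
    iteration_references: list[np.ndarray]  # I_1 ... I_n (initial included)
    fields: list[WarpField]  # final-iteration warp fields, one per frame
    initial_index: int
    n_iterations: int


def select_reference(
    seq: Sequence[np.ndarray] | np.ndarray,
    n_iterations: int = 3,
    seed: int = 0,
    estimator: Callable | None = None,
) -> ReferenceSelection:
    """Choose a sequence reference by iterated mean warped texture.

    Iteration 1 takes a seeded random frame as reference I_1.  Each
    iteration warps every frame onto the current reference and sets the
    next reference I_{N+1} to the mean of the warped textures.  The warp
    fields of the final iteration are returned for use as PCA input.
    The fixed iteration count (default 3) is the convergence criterion;
    in practice successive references stabilise quickly and the final
    reference is nearly independent of the initial random choice.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in seq]
    if len(frames) < 2:
        raise ValueError("sequence must contain at least 2 frames")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame geometry: {sorted(shapes)}")

    rng = np.random.default_rng(seed)
    idx = int(rng.integers(len(frames)))
    reference = frames[idx]
    iteration_refs = [reference]
    fields: list[WarpField] = []
    for _ in range(n_iterations):
        fields = [estimate_warp(f, reference, estimator) for f in frames]
        warped = [warp_image(f, fld) for f, fld in zip(frames, fields)]
        reference = np.mean(warped, axis=0)
        iteration_refs.append(reference)
    # I_N (the reference the final fields map onto) is the penultimate entry
    return ReferenceSelection(
        reference=iteration_refs[-2] if n_iterations >= 1 else reference,
        iteration_references=iteration_refs,
        fields=fields,
        initial_index=idx,
        n_iterations=n_iterations,
    )
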