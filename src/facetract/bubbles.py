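"""Bubbles occlusion mapping: which regions drive cross-modal recovery.

A bubble mask is a set of randomly positioned hard-edged discs; pixels
under a disc stay visible, everything else is zeroed.  On each
iteration the same mask multiplies every frame's pixel channels and
both warp planes of one modality, the other modality is zeroed
entirely, the partial array is projected into the PCA space fitted on
the *unoccluded* hybrid, and reconstruction fidelity is scored as the
loading SSE against the original loadings.  Masks from the
lowest-SSE iterations (best reconstructions) are summed into
CorrectPlane and divided by the sum of all masks (TotalPlane), giving
the per-pixel ProportionPlane: the probability that a pixel's
visibility lands an iteration in the top tier, high where visibility
genuinely helps.

Hard-edged Boolean discs (not Gaussian apertures) are used because warp
values are absolute displacements and must not be scaled; defaults are
46 discs of 12 px diameter.  At an uninformative pixel the expected
plane value is the top fraction itself (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hybrid import HybridArray
from .pca_recon import (
    FidelityMetrics,
    PCAModel,
    loading_correlation,
    loading_sse,
    project,
)

__all__ = [
    "BubbleMask",
    "ProportionPlane",
    "BubblesResult",
    "generate_mask",
    "occlude_and_reconstruct",
    "proportion_plane",
    "run_bubbles",
]


@dataclass(frozen=True)
class BubbleMask:
    """Boolean visibility mask built from randomly positioned discs."""

    mask: np.ndarray  # (H, W) bool, True = visible
    centers: tuple[tuple[int, int], ...]
    diameter: int
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_bubbles(self) -> int:
        return len(self.centers)


def generate_mask(
    height: int,
    width: int,
    n_bubbles: int = 46,
    diameter: int = 12,
    seed: int = 0,
) -> BubbleMask:
    """Draw a seeded mask of ``n_bubbles`` hard-edged discs.

    Centers are uniform over the pixel grid; discs may overlap and may be
    clipped at the borders.  Pixel (r, c) is visible iff its Euclidean
    distance to some center is <= diameter / 2.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    if n_bubbles < 1 or diameter < 1:
        raise ValueError("n_bubbles and diameter must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, height, size=n_bubbles)
    cols = rng.integers(0, width, size=n_bubbles)
    radius = diameter / 2.0
    r_int = int(np.ceil(radius))
    mask = np.zeros((height, width), dtype=bool)
    for r0, c0 in zip(rows, cols):
        r_lo, r_hi = max(0, r0 - r_int), min(height, r0 + r_int + 1)
        c_lo, c_hi = max(0, c0 - r_int), min(width, c0 + r_int + 1)
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        mask[r_lo:r_hi, c_lo:c_hi] |= (
            (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        )
    return BubbleMask(
        mask=mask,
        centers=tuple(zip(rows.tolist(), cols.tolist())),
        diameter=diameter,
        seed=seed,
    )


def _mask_vector(mask: np.ndarray, n_channels: int) -> np.ndarray:
    """Serialized per-observation multiplier for one modality block:
    the mask repeated over each pixel channel and both warp planes."""
    flat = mask.ravel(order="F").astype(np.float64)
    return np.tile(flat, n_channels + 2)


def occlude_and_reconstruct(
    model: PCAModel,
    h: HybridArray,
    mask: BubbleMask | np.ndarray,
    occluded_modality: str,
) -> FidelityMetrics:
    """Score reconstruction from a bubble-occluded single modality.

    The mask multiplies every frame's pixel channels and warp planes of
    ``occluded_modality``; the other modality's blocks are zeroed
    entirely.  The partial columns are projected into ``model`` (fit on
    the unoccluded hybrid) and fidelity is measured against the model's
    original loadings.
    """
    m = mask.mask if isinstance(mask, BubbleMask) else np.asarray(mask, bool)
    lo = h.layout(occluded_modality)
    if m.shape != (lo.height, lo.width):
        raise ValueError(
            f"mask geometry {m.shape} != modality geometry "
            f"{(lo.height, lo.width)}"
        )
    mvec = _mask_vector(m, lo.n_channels)
    # all other modalities are zeroed and the mask is Boolean, so only
    # the visible rows of the occluded block enter the inner products
    nz = np.flatnonzero(mvec)
    recon = np.zeros_like(model.loadings)
    for sl in h.modality_rows(occluded_modality):
        rows = sl.start + nz
        recon += model.components[rows].T @ h.data[rows]
    if np.ptp(recon) == 0:
        corr = float("nan")  # all-false mask: zero loadings, R undefined
    else:
        corr = loading_correlation(model.loadings, recon)
    return FidelityMetrics(
        loading_correlation=corr,
        loading_sse=loading_sse(model.loadings, recon),
        per_frame_sse=loading_sse(model.loadings, recon, per_sample=True),
    )


@dataclass(frozen=True)
class ProportionPlane:
    """Per-pixel importance map CorrectPlane / TotalPlane.

    ``plane`` is NaN where no mask ever covered the pixel; ``scope`` is
    "sequence" or a frame index for the per-frame variant.
    """

    plane: np.ndarray
    correct_plane: np.ndarray
    total_plane: np.ndarray
    top_frac: float
    scope: str | int = "sequence"


def _select_lowest(sses: np.ndarray, k: int) -> np.ndarray:
    # stable sort: ties at the top-k boundary break by iteration index
    return np.argsort(sses, kind="stable")[:k]


def proportion_plane(
    masks: Sequence[BubbleMask | np.ndarray],
    sses: np.ndarray,
    top_frac: float = 0.1,
):
    """ProportionPlane from per-iteration masks and SSE scores.

    With 1-D ``sses`` (one total SSE per iteration) returns a single
    whole-sequence plane.  With 2-D ``sses`` of shape (n_iterations,
    n_frames) the selection is re-ranked independently per frame and a
    list of per-frame planes is returned.
    """
    arrs = [
        m.mask if isinstance(m, BubbleMask) else np.asarray(m, bool)
        for m in masks
    ]
    sses = np.asarray(sses, dtype=np.float64)
    n = len(arrs)
    if sses.shape[0] != n:
        raise ValueError("masks and sses must be aligned")
    if n < 10:
        raise ValueError("need at least 10 iterations")
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    k = max(1, int(np.floor(top_frac * n)))
    stack = np.asarray(arrs)
    total = stack.sum(axis=0).astype(np.int64)

    def build(scores: np.ndarray, scope) -> ProportionPlane:
        correct = stack[_select_lowest(scores, k)].sum(axis=0).astype(np.int64)
        with np.errstate(invalid="ignore"):
            plane = np.where(total > 0, correct / np.maximum(total, 1), np.nan)
        return ProportionPlane(
            plane=plane,
            correct_plane=correct,
            total_plane=total,
            top_frac=top_frac,
            scope=scope,
        )

    if sses.ndim == 1:
        return build(sses, "sequence")
    return [build(sses[:, j], j) for j in range(sses.shape[1])]


@dataclass(frozen=True)
class BubblesResult:
    """Full Bubbles run: masks, per-iteration scores, and planes."""

    masks: list[BubbleMask]
    sses: np.ndarray  # (n_iter,)
    per_frame_sses: np.ndarray  # (n_iter, n_frames)
    plane: ProportionPlane
    per_frame_planes: list[ProportionPlane] | None
    occluded_modality: str
    seed: int


def run_bubbles(
    model: PCAModel,
    h: HybridArray,
    occluded_modality: str,
    n_iter: int = 1000,
    n_bubbles: int = 46,
    diameter: int = 12,
    top_frac: float = 0.1,
    per_frame: bool = False,
    seed: int = 0,
) -> BubblesResult:
    """Repeat occlude-and-reconstruct over ``n_iter`` random masks and
    aggregate the importance planes."""
    lo = h.layout(occluded_modality)
    rng = np.random.default_rng(seed)
    masks, sses, pf = [], [], []
    for _ in range(n_iter):
        mask = generate_mask(
            lo.height,
            lo.width,
            n_bubbles=n_bubbles,
            diameter=diameter,
            seed=int(rng.integers(2**31)),
        )
        metrics = occlude_and_reconstruct(model, h, mask, occluded_modality)
        masks.append(mask)
        sses.append(metrics.loading_sse)
        pf.append(metrics.per_frame_sse)
    sses = np.asarray(sses)
    pf = np.asarray(pf)
    plane = proportion_plane(masks, sses, top_frac)
    per_frame_planes = (
        proportion_plane(masks, pf, top_frac) if per_frame else None
    )
    return BubblesResult(
        masks=masks,
        sses=sses,
        per_frame_sses=pf,
        plane=plane,
        per_frame_planes=per_frame_planes,
        occluded_modality=occluded_modality,
        seed=seed,
    )
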