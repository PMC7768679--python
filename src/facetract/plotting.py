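"""Small visualization helpers: null histograms, importance heat maps,
warp-field quiver overlays."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bubbles import ProportionPlane
from .optic_flow import WarpField
from .permutation import PermutationResult

__all__ = ["save_null_histogram", "save_plane_png", "save_quiver_overlay"]


def save_null_histogram(path: str | Path, result: PermutationResult) -> Path:
    """Null loading-correlation histogram with the observed value marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(result.null_correlations, bins=30, color="0.6")
    ax.axvline(
        result.observed.loading_correlation,
        color="tab:red",
        linestyle="--",
        label=f"observed R={result.observed.loading_correlation:.3f}",
    )
    ax.axvspan(*result.null_ci95, color="0.85", zorder=0)
    ax.set_xlabel("loading correlation")
    ax.set_ylabel("count")
    ax.set_title(f"{result.mode} shuffle, p={result.p_value_correlation:.4g}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_plane_png(
    path: str | Path, plane: ProportionPlane | np.ndarray
) -> Path:
    """ProportionPlane as a 16-bit grayscale PNG (NaN -> 0)."""
    arr = plane.plane if isinstance(plane, ProportionPlane) else np.asarray(plane)
    scaled = np.nan_to_num(arr, nan=0.0)
    out = np.clip(scaled * 65535.0, 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), out)
    return Path(path)


def save_quiver_overlay(
    path: str | Path, image: np.ndarray, fld: WarpField, step: int = 8
) -> Path:
    """Frame with its warp field drawn as a subsampled quiver plot."""
    img = np.asarray(image)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(img.astype(np.uint8) if img.ndim == 3 else img, cmap="gray")
    rr, cc = np.mgrid[0 : fld.shape[0] : step, 0 : fld.shape[1] : step]
    ax.quiver(
        cc,
        rr,
        fld.dx[::step, ::step],
        fld.dy[::step, ::step],
        color="tab:red",
        angles="xy",
        scale_units="xy",
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
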