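"""PCA over hybrid samples and cross-modal reconstruction fidelity.

The hybrid array has far more observations (pixels + warp values) than
samples (frames), so components are obtained economically from the
eigendecomposition of the small sample Gram matrix D'D rather than a
full decomposition in observation space.  All components are retained by
default.

The decomposition is *uncentered* by default (a second-moment rather
than covariance decomposition).  This choice is load-bearing: because
projection is then a plain inner product, splitting any column into its
two modality blocks splits its loadings additively, so the
video-zeroed and MR-zeroed reconstructed loadings sum exactly to the
original loadings.  A centered mode is provided but breaks that
additivity identity.

Reconstruction works as autoassociative recall: zero one modality's
block, project the partial columns onto the components, and rebuild
full observation vectors from the resulting loadings.  Fidelity is
quantified on loadings, not pixels -- pixel correlations are dominated
by the static background -- as the Pearson correlation (R) and the sum
of squared errors (SSE) between original and reconstructed loadings
pooled over all (sample, component) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .hybrid import HybridArray, deserialize_frame

__all__ = [
    "PCAModel",
    "ReconstructionResult",
    "FidelityMetrics",
    "fit_pca",
    "project",
    "reconstruct_modality",
    "loading_correlation",
    "loading_sse",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class PCAModel:
    """Orthonormal components over observation space plus sample loadings.

    ``components``: (n_observations, n_components), columns orthonormal.
    ``loadings``: (n_components, n_samples), loading of sample j on
    component k; with ``centered=False`` these are plain inner products
    and data column j equals components @ loadings[:, j] when all
    components are kept.
    """

    components: np.ndarray
    loadings: np.ndarray
    centered: bool = False
    mean_vector: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_samples(self) -> int:
        return self.loadings.shape[1]

    def __post_init__(self) -> None:
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-6):
            raise ValueError("components are not orthonormal")
        if self.centered and self.mean_vector is None:
            raise ValueError("centered model requires mean_vector")


def fit_pca(h: HybridArray | np.ndarray, centered: bool = False) -> PCAModel:
    """Fit the (by default uncentered) PCA of a hybrid array.

    Components with negligible variance (Gram eigenvalue below
    ``n * eps * max_eigenvalue``) are dropped; the rest span the sample
    set, so projecting the training data back reconstructs it exactly to
    numerical tolerance.  Component signs are fixed so each component's
    largest-magnitude loading is positive, making reports reproducible
    across linear-algebra backends.
    """
    data = h.data if isinstance(h, HybridArray) else np.asarray(h, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D array with at least 2 samples")
    mean_vector = None
    if centered:
        mean_vector = data.mean(axis=1)
        data = data - mean_vector[:, None]

    # economical route: eigendecomposition of the n x n Gram matrix
    gram = data.T @ data
    evals, evecs = linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cutoff = max(data.shape) * np.finfo(float).eps * max(evals.max(), 0.0)
    keep = evals > cutoff
    if not np.any(keep):
        raise ValueError("data matrix has rank zero; nothing to decompose")
    evals, evecs = evals[keep], evecs[:, keep]
    scale = np.sqrt(evals)
    components = (data @ evecs) / scale  # (N, k), orthonormal columns
    loadings = scale[:, None] * evecs.T  # (k, n) == components.T @ data

    # sign convention: largest-|.| loading of each component positive
    flip = np.sign(
        loadings[np.arange(len(scale)), np.abs(loadings).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    components = components * flip
    loadings = loadings * flip[:, None]
    return PCAModel(
        components=components,
        loadings=loadings,
        centered=centered,
        mean_vector=mean_vector,
    )


def project(model: PCAModel, columns: np.ndarray) -> np.ndarray:
    """Loadings of observation-space columns: inner products with the
    components (mean-subtracted first only in centered mode)."""
    cols = np.asarray(columns, dtype=np.float64)
    squeeze = cols.ndim == 1
    if squeeze:
        cols = cols[:, None]
    if cols.shape[0] != model.components.shape[0]:
        raise ValueError(
            f"column length {cols.shape[0]} != observation dimension "
            f"{model.components.shape[0]}"
        )
    if model.centered:
        cols = cols - model.mean_vector[:, None]
    out = model.components.T @ cols
    return out[:, 0] if squeeze else out


@dataclass(frozen=True)
class FidelityMetrics:
    """Loading-space reconstruction fidelity summary."""

    loading_correlation: float
    loading_sse: float
    per_frame_sse: np.ndarray


@dataclass(frozen=True)
class ReconstructionResult:
    """Cross-modal reconstruction with deserialized images and fields."""

    recon_loadings: np.ndarray
    recon_vectors: np.ndarray
    recon_images: dict[str, list[np.ndarray]]
    recon_fields: dict[str, list]
    zeroed_modality: str
    metrics: FidelityMetrics


def reconstruct_modality(
    model: PCAModel,
    h: HybridArray,
    zeroed: str,
    apply_mean_scaling: bool = False,
) -> ReconstructionResult:
    """Reconstruct the whole hybrid from one modality alone.

    Zeroes the named modality's block(s), projects the partial columns
    into the model, and rebuilds full observation vectors from the
    reconstructed loadings.  With ``apply_mean_scaling`` the loadings are
    first multiplied by the mean original/reconstructed ratio (computed
    across all samples and components) to compensate for the halved
    input energy; off by default.
    """
    partial = h.zeroed(zeroed)  # validates the modality name
    recon_loadings = project(model, partial)
    if apply_mean_scaling:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = model.loadings / recon_loadings
        finite = np.isfinite(ratio)
        if finite.any():
            recon_loadings = recon_loadings * ratio[finite].mean()
    recon_vectors = model.components @ recon_loadings
    if model.centered:
        recon_vectors = recon_vectors + model.mean_vector[:, None]

    recon_images: dict[str, list[np.ndarray]] = {}
    recon_fields: dict[str, list] = {}
    for name in h.modalities:
        lo = h.layout(name)
        images, fields = [], []
        for j in range(recon_vectors.shape[1]):
            # for paired arrays this deserializes the frame-t half
            img, fld = deserialize_frame(
                recon_vectors[h.modality_rows(name)[0], j], lo
            )
            images.append(img)
            fields.append(fld)
        recon_images[name] = images
        recon_fields[name] = fields

    metrics = FidelityMetrics(
        loading_correlation=loading_correlation(model.loadings, recon_loadings),
        loading_sse=loading_sse(model.loadings, recon_loadings),
        per_frame_sse=loading_sse(
            model.loadings, recon_loadings, per_sample=True
        ),
    )
    return ReconstructionResult(
        recon_loadings=recon_loadings,
        recon_vectors=recon_vectors,
        recon_images=recon_images,
        recon_fields=recon_fields,
        zeroed_modality=zeroed,
        metrics=metrics,
    )


def loading_correlation(orig: np.ndarray, recon: np.ndarray) -> float:
    """Pearson R between loading sets, pooled over samples and components.

    Scale-invariant: a reconstruction that differs from the original by a
    common positive factor still scores 1.
    """
    o = np.asarray(orig, dtype=np.float64).ravel()
    r = np.asarray(recon, dtype=np.float64).ravel()
    if o.shape != r.shape:
        raise ValueError("loading sets must have the same shape")
    if o.size < 3:
        raise ValueError("need at least 3 loading values")
    if np.ptp(o) == 0 or np.ptp(r) == 0:
        raise ValueError("loading correlation undefined for zero variance")
    return float(np.corrcoef(o, r)[0, 1])


def loading_sse(
    orig: np.ndarray, recon: np.ndarray, per_sample: bool = False
):
    """Sum of squared loading errors; optionally per sample (column)."""
    o = np.asarray(orig, dtype=np.float64)
    r = np.asarray(recon, dtype=np.float64)
    if o.shape != r.shape:
        raise ValueError("loading sets must have the same shape")
    sq = (o - r) ** 2
    if per_sample:
        return sq.sum(axis=0) if sq.ndim == 2 else sq
    return float(sq.sum())
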