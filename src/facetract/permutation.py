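"""Frame-order shuffling nulls for cross-modal reconstruction fidelity.

The question the null answers: does reconstruction fidelity reflect a
common articulatory cause linking the two modalities frame by frame, or
merely the arbitrary association of *some* MR frame with *some* video
frame?  Shuffling the MR frame order while keeping the video order
destroys the frame-wise correspondence but preserves everything else
(the images themselves, their marginal statistics, the PCA machinery),
so fidelity surviving the shuffle measures mere association.

The PCA is refit on every shuffled hybrid -- the null models an analyst
handed misaligned recordings, not a basis mismatch -- and fidelity is
scored against each shuffled fit's own loadings.  Three modes:

- ``single``: shuffle MR frames before building the single-frame hybrid;
- ``paired_keep_pairs``: build MR (t, t+1) frame pairs first, then
  shuffle the pairs as units (within-pair order intact);
- ``paired_shuffle_before``: shuffle MR frames first, then pair,
  destroying within-pair temporal dependency as well.

Identity permutations are rejected and redrawn, and p-values use the
add-one estimator (count + 1) / (n_perm + 1), so a p-value is never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hybrid import FrameMatchPlan, serialize_sequence
from .pca_recon import FidelityMetrics, loading_correlation, loading_sse

__all__ = ["PermutationResult", "permutation_test", "MODES"]

MODES = ("single", "paired_keep_pairs", "paired_shuffle_before")


@dataclass(frozen=True)
class PermutationResult:
    """Observed fidelity against its frame-shuffling null distribution."""

    observed: FidelityMetrics
    null_correlations: np.ndarray
    null_sses: np.ndarray
    p_value_correlation: float
    p_value_sse: float
    null_mean: float
    null_ci95: tuple[float, float]
    mode: str
    n_perm: int
    seed: int


def _score_gram(
    gram_v: np.ndarray, gram_m: np.ndarray, n_rows: int
) -> FidelityMetrics:
    """Refit-and-reconstruct fidelity entirely in sample (Gram) space.

    For uncentered PCA of stacked blocks D = [V; M], the Gram matrix is
    G = V'V + M'M, loadings are sqrt(lam) * W' from G = W diag(lam) W',
    and the MR-zeroed reconstructed loadings are
    C_v' V = lam^{-1/2} W' (V'V) -- no observation-space work at all.
    This is algebraically identical to :func:`facetract.pca_recon.fit_pca`
    followed by zero-block projection (same eigenvalue cutoff, same
    largest-|loading| sign convention), just factored through the small
    n x n matrices; the equivalence is covered by tests.
    """
    gram = gram_v + gram_m
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cutoff = max(n_rows, gram.shape[0]) * np.finfo(float).eps * max(evals.max(), 0.0)
    keep = evals > cutoff
    evals, evecs = evals[keep], evecs[:, keep]
    scale = np.sqrt(evals)
    loadings = scale[:, None] * evecs.T
    recon = (evecs.T @ gram_v) / scale[:, None]
    flip = np.sign(
        loadings[np.arange(len(scale)), np.abs(loadings).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    recon = recon * flip[:, None]
    return FidelityMetrics(
        loading_correlation=loading_correlation(loadings, recon),
        loading_sse=loading_sse(loadings, recon),
        per_frame_sse=loading_sse(loadings, recon, per_sample=True),
    )


def permutation_test(
    video: tuple[Sequence, Sequence],
    mr: tuple[Sequence, Sequence],
    plan: FrameMatchPlan | None = None,
    n_perm: int = 1000,
    mode: str = "single",
    seed: int = 0,
) -> PermutationResult:
    """Frame-order permutation test of cross-modal reconstruction.

    ``video`` and ``mr`` are (frames, warp-fields) tuples; ``video`` is
    decimated by ``plan`` if given.  For each of ``n_perm`` draws the MR
    frame (or frame-pair) order is shuffled, the PCA refit, the MR block
    zeroed, and loading correlation / SSE recorded against the shuffled
    fit's own loadings.  The observed value uses the unshuffled order.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    v_frames, v_fields = video
    m_frames, m_fields = mr
    if plan is not None:
        v_frames = plan.apply(list(v_frames))
        v_fields = plan.apply(list(v_fields))
    n = len(m_frames)
    if len(v_frames) != n:
        raise ValueError("sequences must be matched to equal frame counts")
    if n <= 2:
        raise ValueError("sequence too short to permute (need > 2 frames)")

    v_block = serialize_sequence(list(v_frames), list(v_fields))
    m_block = serialize_sequence(list(m_frames), list(m_fields))
    gram_v = v_block.T @ v_block
    gram_m = m_block.T @ m_block
    n_rows = v_block.shape[0] + m_block.shape[0]

    def pair_gram(g: np.ndarray, p: np.ndarray) -> np.ndarray:
        # Gram of pair-stacked columns: entry (j, k) sums the (t, t) and
        # (t+1, t+1) single-frame inner products of the permuted order
        return g[np.ix_(p[:-1], p[:-1])] + g[np.ix_(p[1:], p[1:])]

    identity_n = np.arange(n)
    gv_pair = pair_gram(gram_v, identity_n)

    if mode == "single":
        observed = _score_gram(gram_v, gram_m, n_rows)
        n_units = n
    else:
        observed = _score_gram(
            gv_pair, pair_gram(gram_m, identity_n), 2 * n_rows
        )
        n_units = n - 1 if mode == "paired_keep_pairs" else n

    rng = np.random.default_rng(seed)
    identity = np.arange(n_units)
    null_r = np.empty(n_perm)
    null_sse = np.empty(n_perm)
    gm_pair = pair_gram(gram_m, identity_n)
    for i in range(n_perm):
        perm = rng.permutation(n_units)
        while np.array_equal(perm, identity):
            perm = rng.permutation(n_units)
        if mode == "single":
            metrics = _score_gram(
                gram_v, gram_m[np.ix_(perm, perm)], n_rows
            )
        elif mode == "paired_keep_pairs":
            metrics = _score_gram(
                gv_pair, gm_pair[np.ix_(perm, perm)], 2 * n_rows
            )
        else:  # paired_shuffle_before
            metrics = _score_gram(
                gv_pair, pair_gram(gram_m, perm), 2 * n_rows
            )
        null_r[i] = metrics.loading_correlation
        null_sse[i] = metrics.loading_sse

    p_r = (np.sum(null_r >= observed.loading_correlation) + 1) / (n_perm + 1)
    p_sse = (np.sum(null_sse <= observed.loading_sse) + 1) / (n_perm + 1)
    lo, hi = np.percentile(null_r, [2.5, 97.5])
    return PermutationResult(
        observed=observed,
        null_correlations=null_r,
        null_sses=null_sse,
        p_value_correlation=float(p_r),
        p_value_sse=float(p_sse),
        null_mean=float(null_r.mean()),
        null_ci95=(float(lo), float(hi)),
        mode=mode,
        n_perm=n_perm,
        seed=seed,
    )
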