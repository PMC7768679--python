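# Methods

## Model and assumptions

The analysis treats two temporally aligned image sequences — a frontal
face video and a midsagittal vocal-tract MR scan of the same utterance —
as joint observations of a single underlying articulatory process. Each
matched frame pair is one *sample*; the *observations* are the
serialized texture (pixel channels, column-major) and shape (per-pixel
warp field onto a sequence reference) of both modalities, stacked into
one hybrid column. PCA over these columns captures whatever variation
the two modalities share; reconstruction of one modality from the other
(zero its block, project, rebuild) then measures how much of each
modality's variation is recoverable from the other alone.

Assumptions worth stating explicitly:

- **Temporal alignment.** Frame j of the decimated video corresponds to
  frame j of the MR sequence. The frame-matching rule retains video
  frame `round(1 + (i−1)·N_vid/N_MR)` for i = 1..N_MR, with halves
  rounded *away from zero* — the worked example (9 video, 6 MR frames →
  retained [1, 3, 4, 6, 7, 9]) pins this convention; round-half-even
  would silently yield [1, 2, 4, 6, 7, 8].
- **Uncentered PCA.** The decomposition is of second moments, not
  covariances. This makes projection a plain inner product, so the
  video-zeroed and MR-zeroed reconstructed loadings sum *exactly* to the
  original loadings (verified to 1e-8 relative). A `centered=True` mode
  exists but is flagged: mean re-subtraction breaks that additivity
  identity.
- **All components retained.** With n samples the model keeps all
  components of non-negligible variance (Gram eigenvalue above
  `max(N, n)·eps·λ_max`); projecting the training data back is then the
  identity to numerical tolerance.
- **Native units.** Pixel intensities stay on 0–255 and warp values in
  pixels, unweighted. `channel_weights` exposes rebalancing per modality
  block but defaults to 1 everywhere.

## Warp fields and reference selection

The shape half of the representation is the dense displacement field
warping each frame onto a common reference (backward sampling:
`warped(r,c) = frame(r+dy, c+dx)`, bilinear, border-clamped). The
estimator is pluggable behind this contract; the default is dense
iterative Lucas–Kanade (`skimage.registration.optical_flow_ilk`,
radius 7, 3 warp refinements), which recovers pure translations of
smooth textures to well under 0.01 px and removes ≳ 90 % of the
residual of smooth non-rigid deformations on synthetic fixtures. The
contract requires only ≤ 0.25 px translation error and ≥ 50 % residual
reduction, leaving room for coarser estimators. Identical frames and
untextured (constant) inputs short-circuit to an exactly zero field,
the latter with a logged warning.

The reference is selected by fixed-count iteration (3, not a tolerance):
a seeded random frame starts iteration 1; each iteration warps every
frame onto the current reference and takes the mean warped texture as
the next reference. The warp fields of the final iteration are the PCA
input. On synthetic sequences successive references correlate
non-decreasingly and final references from different random starts agree
at r ≥ 0.95, so the random initial choice is immaterial in practice.

Interpolation/boundary scheme (bilinear, border-clamp) is a fixed
package choice. The content of the pixel block is raw frame pixels by
default; the pipeline's `use_warped_texture` switch substitutes the
reference-warped texture instead, for workflows that want shape fully
factored out of the texture block.

## Fidelity metrics

Pixel-space correlations are dominated by static background, so
fidelity is scored in loading space: Pearson's R between original and
reconstructed loadings pooled over all (frame, component) pairs, plus
the sum of squared errors (total and per frame). R is invariant to a
common positive rescaling of either loading set; SSE is not, which is
why the null test uses both. The optional mean-scaling augmentation
(multiply reconstructed loadings by the mean original/reconstructed
ratio) is implemented but off by default; with symmetric duplicated
blocks it exactly restores the original loadings.

Component signs are fixed so each component's largest-magnitude
*loading* is positive. Loading-space pooled correlation is not invariant
to joint sign flips of a component's loading rows, so a deterministic,
backend-independent convention matters; a sample-space rule also lets
the permutation engine reproduce the convention without forming
observation-space components.

## Permutation nulls

Shuffling the MR frame order while keeping the video order destroys the
frame-wise correspondence but preserves each modality's content, so the
null distribution of R measures how well *mere association* can
reconstruct. The PCA is refit for every permutation (the null models
misaligned recordings, not a basis mismatch). Identity permutations are
rejected and redrawn; p-values use the add-one estimator
`(count+1)/(n_perm+1)`; the null summary interval is the 2.5–97.5
percentile of the null values. Observed values are computed through the
same code path as the nulls.

Implementation note: for stacked blocks D = [V; M] the whole
refit-and-reconstruct reduces to the n×n sample Gram matrices
(G = VᵀV + MᵀM; reconstructed loadings = Λ^{-1/2}Wᵀ(VᵀV)), which makes
thousands of refits cheap. The equivalence with the explicit
observation-space path is asserted in the test suite at 1e-8.

Paired-frame samples (stack frames t and t+1; sample count n−1; row
count doubled) implicitly encode motion direction. Two shuffle modes
probe what that buys: shuffling intact MR pairs (`paired_keep_pairs`)
versus shuffling MR frames before pairing (`paired_shuffle_before`).
On synthetic data the null-mean inflation from single-frame to
paired mode is reliably smaller when within-pair order is kept,
i.e. the paired representation is more robust to sample-order shuffling.

## Bubbles occlusion mapping

Each iteration draws 46 hard-edged Boolean discs of diameter 12 px
(centers uniform over the pixel grid; overlap and border clipping
allowed; membership is Euclidean distance ≤ diameter/2 on pixel
centers). The mask multiplies every frame's pixel channels and both
warp planes of one modality; the other modality is zeroed entirely; the
partial columns are projected into the PCA fit on the *unoccluded*
hybrid. Masks from the `floor(0.1·n)` lowest-SSE iterations (ties broken
by iteration index, deterministically) are summed into CorrectPlane and
divided by the sum of all masks. Hard discs rather than Gaussian
apertures because warp values are absolute displacements and must not be
scaled. At an uninformative pixel the expected plane value equals the
top fraction (0.1); informative regions rise above it. The per-frame
variant re-ranks iterations independently per frame using per-frame SSE.
Default iteration count is 1,000 (configurable; sampling error of the
plane scales as ~1/√n iterations).

## Synthetic data generator

The generator emulates the *structure* of paired articulation
recordings, not their appearance: k_shared latent channels drive
features in both modalities (the common articulatory cause), k_priv_a /
k_priv_b channels drive one modality only, and Gaussian pixel noise is
added everywhere. Latents are stationary AR(1) walks with unit
innovation variance; the single `smoothness` knob (default 0.9) is the
AR(1) coefficient and equals the lag-1 autocorrelation. Each channel
renders as a soft-edged Gaussian intensity blob whose amplitude and
position are driven by the (tanh-squashed) latent value — intensity and
motion cues both carry signal, so the flow estimator has usable
gradients. Channel regions are disjoint by construction and pixels
outside all regions are constant across frames (the static
background). The default scene places mouth/cheek/brow sites on the
face and jaw/tongue/velum sites in the tract at the study geometry
(120×160 px), with shared channel i driving face site i and tract site
i together.

Defaults used throughout the validation suite: 40 frames, k_shared = 2,
one private channel per modality, noise sd = 2 intensity units. These
sizes keep a full permutation run in seconds while leaving the
shared-cause signal clearly separable from the shuffled null, and the
multi-seed properties (calibration, paired improvement, Bubbles margins)
were chosen as seeded statistical tests rather than single-run
assertions. The Bubbles validation uses a single shared channel and no
private channels so that exactly one ground-truth informative region
exists per modality; its in-region/out-of-region plane margin threshold
(0.02 over a 0.1 baseline) is deliberately conservative relative to the
generator's signal strength.

What the generator does *not* emulate — and hence what passing tests do
not show about real recordings: photorealistic appearance, correlated
(structured) noise, imperfect temporal alignment between modalities,
large or non-smooth motions, occlusions, and latent dimensionality
anywhere near real articulation. Results on synthetic data validate the
machinery and its statistical calibration, not the empirical claims one
could make from real face/MR data.

## Numerical choices and degenerate inputs

- PCA route: eigendecomposition of the sample Gram matrix (observations
  ≫ samples); the test oracle is an independent full SVD, agreement at
  1e-8 up to sign.
- Rank-deficient input: zero-variance directions are dropped; rank-zero
  input raises.
- Loading correlation is undefined (raises) for zero-variance loading
  sets and for fewer than 3 values; an all-false bubble mask yields zero
  loadings and is reported with R = NaN and SSE = Σ L².
- All stochastic stages take explicit seeds; the pipeline derives each
  stage's seed from a master seed and the stage name, so one integer
  reproduces a full run bit-for-bit (reports round floats to 6 decimals
  before serialization).

## Known limitations

- AVI I/O requires an imageio codec backend; PNG frame directories are
  the canonical, always-available interchange format.
- The flow estimator handles the small, smooth displacements of
  articulation-scale imagery; it is not a large-displacement flow and
  does no occlusion reasoning.
- Uncentered PCA means the first component largely encodes the mean
  frame; this is intentional (it preserves the additivity identity) but
  inflates absolute loading correlations, which is why inference is
  always against the shuffled null rather than against zero.
- Exactly two modalities are supported end-to-end; the block layout
  generalizes but is untested beyond two.
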