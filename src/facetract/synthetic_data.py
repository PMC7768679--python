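"""Synthetic paired face/vocal-tract sequence generator.

Stands in for the temporally aligned frontal-face video and midsagittal
MR vocal-tract recordings the analysis assumes.  Frame-to-frame variation
is driven partly by *shared* latent trajectories (a common articulatory
cause moving features in both modalities) and partly by modality-private
latents plus pixel noise.  Ground-truth informative regions are returned
as boolean masks so downstream stages (reconstruction fidelity,
permutation nulls, Bubbles importance maps) can be validated against a
known generative truth.

Latent dynamics are stationary AR(1) walks with unit innovation variance;
the single ``smoothness`` knob is the AR(1) coefficient.  Each latent
channel drives one soft-edged intensity blob per mapped modality: the
latent value modulates both the blob's amplitude and its position (via a
bounded tanh squash), so intensity and motion cues both carry the signal.
Pixels outside every channel region are constant across frames, emulating
the static background (brain, spinal cord, blue screen) of real
recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatentTrajectory",
    "ChannelMap",
    "SceneSpec",
    "PairedSequenceBundle",
    "generate_latents",
    "render_paired_sequences",
    "default_scene_spec",
    "make_bundle",
]

#: default image geometry (rows, cols) for both modalities
DEFAULT_SHAPE = (120, 160)


@dataclass(frozen=True)
class LatentTrajectory:
    """AR(1) latent trajectories: shared plus per-modality private channels.

    Arrays are (n_frames, k) with k possibly zero.  ``smoothness`` is the
    AR(1) coefficient rho: with rho = 0 successive values are independent,
    and the lag-1 autocorrelation of each channel equals rho.
    """

    shared: np.ndarray
    private_a: np.ndarray
    private_b: np.ndarray
    smoothness: float

    @property
    def n_frames(self) -> int:
        return self.shared.shape[0]

    def __post_init__(self) -> None:
        n = self.shared.shape[0]
        if self.private_a.shape[0] != n or self.private_b.shape[0] != n:
            raise ValueError("latent sequences must have identical length")
        for arr in (self.shared, self.private_a, self.private_b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("latent values must be finite")


def generate_latents(
    n_frames: int,
    k_shared: int,
    k_priv_a: int,
    k_priv_b: int,
    smoothness: float = 0.9,
    seed: int = 0,
) -> LatentTrajectory:
    """Draw seeded AR(1) latent trajectories.

    Each channel follows x_t = rho * x_{t-1} + e_t with e_t ~ N(0, 1) and a
    stationary start (x_0 ~ N(0, 1/(1-rho^2)) for rho < 1), so the process
    variance and lag-1 autocorrelation are constant over the sequence.
    Shared and private channels are mutually independent.
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    if min(k_shared, k_priv_a, k_priv_b) < 0:
        raise ValueError("latent dimensions must be non-negative")
    if not 0.0 <= smoothness <= 1.0:
        raise ValueError(f"smoothness must be in [0, 1], got {smoothness}")
    rng = np.random.default_rng(seed)

    def walk(k: int) -> np.ndarray:
        x = np.empty((n_frames, k))
        if k == 0:
            return x
        rho = smoothness
        sd0 = 1.0 / np.sqrt(1.0 - rho**2) if rho < 1.0 else 1.0
        x[0] = rng.normal(0.0, sd0, size=k)
        innov = rng.standard_normal((n_frames - 1, k))
        for t in range(1, n_frames):
            x[t] = rho * x[t - 1] + innov[t - 1]
        return x

    return LatentTrajectory(
        shared=walk(k_shared),
        private_a=walk(k_priv_a),
        private_b=walk(k_priv_b),
        smoothness=smoothness,
    )


@dataclass(frozen=True)
class ChannelMap:
    """Rendering of one latent channel in one modality.

    The channel drives a Gaussian intensity blob: position shifts by
    ``max_shift * tanh(z) * shift_dir`` pixels and amplitude is
    ``amp_base + amp_gain * tanh(z)``, where z is the latent value scaled
    to roughly unit variance.  Rendering is confined to an elliptical
    region around ``center`` large enough to hold the blob at any shift;
    that region is the channel's ground-truth informative mask.
    """

    modality: str  # "a" (face-like) or "b" (tract-like)
    center: tuple[float, float]  # (row, col)
    sigma: float = 5.0
    shift_dir: tuple[float, float] = (1.0, 0.0)
    max_shift: float = 4.0
    amp_base: float = 110.0
    amp_gain: float = 70.0

    def region_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean informative-region mask in the modality geometry."""
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        ar = 3.0 * self.sigma + self.max_shift * abs(self.shift_dir[0])
        ac = 3.0 * self.sigma + self.max_shift * abs(self.shift_dir[1])
        return ((rr - self.center[0]) / ar) ** 2 + (
            (cc - self.center[1]) / ac
        ) ** 2 <= 1.0

    def render(self, shape: tuple[int, int], z: float) -> np.ndarray:
        """Intensity contribution of this channel at squashed latent z."""
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        r0 = self.center[0] + self.max_shift * z * self.shift_dir[0]
        c0 = self.center[1] + self.max_shift * z * self.shift_dir[1]
        amp = self.amp_base + self.amp_gain * z
        blob = amp * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * self.sigma**2)
        )
        return blob * self.region_mask(shape)


@dataclass(frozen=True)
class SceneSpec:
    """Full rendering specification for a paired-sequence bundle.

    ``channel_maps`` assigns each latent channel, keyed by
    ``("shared" | "private_a" | "private_b", index)``, to one or more
    :class:`ChannelMap` renderers.  Regions of distinct channels within a
    modality must be disjoint so that informative-region ground truth is
    unambiguous.
    """

    face_shape: tuple[int, int] = DEFAULT_SHAPE
    tract_shape: tuple[int, int] = DEFAULT_SHAPE
    channel_maps: dict[tuple[str, int], tuple[ChannelMap, ...]] = field(
        default_factory=dict
    )
    noise_sd: float = 2.0
    background: float = 60.0
    seed: int = 0

    def shape_for(self, modality: str) -> tuple[int, int]:
        return self.face_shape if modality == "a" else self.tract_shape

    def validate(self) -> None:
        for modality in ("a", "b"):
            shape = self.shape_for(modality)
            stack = []
            for maps in self.channel_maps.values():
                for m in maps:
                    if m.modality != modality:
                        continue
                    mask = m.region_mask(shape)
                    if not mask.any():
                        raise ValueError("channel region empty in image grid")
                    stack.append(mask)
            if stack and np.sum(stack, axis=0).max() > 1:
                raise ValueError(
                    f"channel regions overlap in modality {modality!r}"
                )


@dataclass(frozen=True)
class PairedSequenceBundle:
    """Synthetic face-like + tract-like sequences with generative truth.

    ``seq_a`` / ``seq_b`` are (n_frames, H, W, 3) float arrays on the
    0-255 intensity scale.  ``region_masks`` maps each latent-channel key
    to its boolean informative region per modality.
    """

    seq_a: np.ndarray
    seq_b: np.ndarray
    latents: LatentTrajectory
    region_masks: dict[tuple[str, int], dict[str, np.ndarray]]
    spec: SceneSpec

    def __post_init__(self) -> None:
        if self.seq_a.shape[0] != self.seq_b.shape[0]:
            raise ValueError("seq_a and seq_b must have equal frame counts")

    def shared_mask(self, modality: str) -> np.ndarray:
        """Union of informative regions of all shared channels."""
        shape = self.spec.shape_for(modality)
        out = np.zeros(shape, dtype=bool)
        for (kind, _idx), masks in self.region_masks.items():
            if kind == "shared" and modality in masks:
                out |= masks[modality]
        return out


def _squash(x: np.ndarray, smoothness: float) -> np.ndarray:
    # scale by the stationary sd so tanh sees ~unit-variance input
    sd = 1.0 / np.sqrt(1.0 - smoothness**2) if smoothness < 1.0 else 1.0
    return np.tanh(x / (1.5 * sd))


def render_paired_sequences(
    spec: SceneSpec, latents: LatentTrajectory
) -> PairedSequenceBundle:
    """Render both modalities' image sequences from latent trajectories.

    Each frame is a deterministic function of that frame's latent values
    plus seeded Gaussian pixel noise.  With ``noise_sd = 0`` pixels
    outside every channel region are constant across frames.
    """
    spec.validate()
    dims = {
        "shared": latents.shared.shape[1],
        "private_a": latents.private_a.shape[1],
        "private_b": latents.private_b.shape[1],
    }
    for (kind, idx) in spec.channel_maps:
        if idx >= dims[kind]:
            raise ValueError(
                f"scene maps channel ({kind}, {idx}) but latents provide "
                f"only {dims[kind]} {kind} channel(s)"
            )

    n = latents.n_frames
    rng = np.random.default_rng(spec.seed)
    seqs = {}
    for modality, shape in (("a", spec.face_shape), ("b", spec.tract_shape)):
        frames = np.full((n, *shape), spec.background, dtype=np.float64)
        for (kind, idx), maps in sorted(spec.channel_maps.items()):
            series = getattr(latents, kind)[:, idx]
            z = _squash(series, latents.smoothness)
            for m in maps:
                if m.modality != modality:
                    continue
                for t in range(n):
                    frames[t] += m.render(shape, z[t])
        if spec.noise_sd > 0:
            frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
        np.clip(frames, 0.0, 255.0, out=frames)
        # equal RGB channels: grayscale-native oracles stay applicable
        seqs[modality] = np.repeat(frames[..., None], 3, axis=-1)

    region_masks: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for key, maps in spec.channel_maps.items():
        region_masks[key] = {
            m.modality: m.region_mask(spec.shape_for(m.modality)) for m in maps
        }
    return PairedSequenceBundle(
        seq_a=seqs["a"],
        seq_b=seqs["b"],
        latents=latents,
        region_masks=region_masks,
        spec=spec,
    )


# canonical feature sites; shared channel i pairs face site i with tract
# site i, private channels consume the remaining sites in order
_FACE_SITES = (
    ChannelMap("a", center=(86.0, 80.0), shift_dir=(1.0, 0.0)),   # mouth
    ChannelMap("a", center=(58.0, 126.0), shift_dir=(0.0, 1.0)),  # cheek
    ChannelMap("a", center=(24.0, 80.0), shift_dir=(-1.0, 0.0)),  # brow
)
_TRACT_SITES = (
    ChannelMap("b", center=(88.0, 48.0), shift_dir=(1.0, 0.0)),   # jaw
    ChannelMap("b", center=(58.0, 92.0), shift_dir=(0.0, 1.0)),   # tongue
    ChannelMap("b", center=(24.0, 130.0), shift_dir=(1.0, 0.0)),  # velum
)


def default_scene_spec(
    k_shared: int = 2,
    k_priv_a: int = 1,
    k_priv_b: int = 1,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> SceneSpec:
    """Default scene: mouth/cheek/brow on the face, jaw/tongue/velum in the
    tract, with shared channels driving paired face+tract sites.

    Supports up to ``k_shared + k_priv_a <= 3`` face channels and
    ``k_shared + k_priv_b <= 3`` tract channels.
    """
    if k_shared + k_priv_a > len(_FACE_SITES):
        raise ValueError("too many face channels for the default scene")
    if k_shared + k_priv_b > len(_TRACT_SITES):
        raise ValueError("too many tract channels for the default scene")
    channel_maps: dict[tuple[str, int], tuple[ChannelMap, ...]] = {}
    for i in range(k_shared):
        channel_maps[("shared", i)] = (_FACE_SITES[i], _TRACT_SITES[i])
    for i in range(k_priv_a):
        channel_maps[("private_a", i)] = (_FACE_SITES[k_shared + i],)
    for i in range(k_priv_b):
        channel_maps[("private_b", i)] = (_TRACT_SITES[k_shared + i],)
    return SceneSpec(channel_maps=channel_maps, noise_sd=noise_sd, seed=seed)


def make_bundle(
    n_frames: int = 40,
    k_shared: int = 2,
    k_priv_a: int = 1,
    k_priv_b: int = 1,
    smoothness: float = 0.9,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> PairedSequenceBundle:
    """Convenience: latents + default scene in one seeded call."""
    latents = generate_latents(
        n_frames, k_shared, k_priv_a, k_priv_b, smoothness, seed=seed
    )
    spec = default_scene_spec(
        k_shared, k_priv_a, k_priv_b, noise_sd=noise_sd, seed=seed + 1
    )
    return render_paired_sequences(spec, latents)


def spec_to_dict(spec: SceneSpec) -> dict:
    """Plain-dict form of a scene spec for YAML sidecars."""
    d = dataclasses.asdict(spec)
    d["channel_maps"] = {
        f"{kind}:{idx}": [dataclasses.asdict(m) for m in maps]
        for (kind, idx), maps in spec.channel_maps.items()
    }
    return d


def spec_from_dict(d: dict) -> SceneSpec:
    maps = {}
    for key, entries in d.get("channel_maps", {}).items():
        kind, idx = key.rsplit(":", 1)
        maps[(kind, int(idx))] = tuple(
            ChannelMap(
                **{
                    **e,
                    "center": tuple(e["center"]),
                    "shift_dir": tuple(e["shift_dir"]),
                }
            )
            for e in entries
        )
    return SceneSpec(
        face_shape=tuple(d.get("face_shape", DEFAULT_SHAPE)),
        tract_shape=tuple(d.get("tract_shape", DEFAULT_SHAPE)),
        channel_maps=maps,
        noise_sd=float(d.get("noise_sd", 2.0)),
        background=float(d.get("background", 60.0)),
        seed=int(d.get("seed", 0)),
    )
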