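"""Temporal frame matching and hybrid observation-array construction.

The two modalities are sampled at different rates (video ~25 fps, MR
~16 fps), so the longer video sequence is decimated to the MR frame
count before analysis: with scale factor s = n_vid / n_mr, the retained
video frames are round(1 + (i - 1) * s) for i = 1..n_mr, rounding halves
away from zero.  Each matched frame is then serialized -- RGB pixel
channels column-major, followed by the x and y warp planes column-major
-- and the two modalities' vectors are stacked into one hybrid
observation-by-sample array.  The paired-frame variant stacks frames t
and t+1 per sample, implicitly encoding motion direction.

Pixel intensities stay on their native 0-255 scale and warp values in
pixels; per-block weights are exposed for rebalancing but default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optic_flow import WarpField

__all__ = [
    "FrameMatchPlan",
    "ModalityLayout",
    "HybridArray",
    "PairedHybridArray",
    "match_frames",
    "serialize_frame",
    "deserialize_frame",
    "build_hybrid",
    "build_paired",
]


@dataclass(frozen=True)
class FrameMatchPlan:
    """Decimation plan matching the video frame count to the MR count.

    ``retained_indices`` are 1-based into the video sequence.
    """

    n_vid: int
    n_mr: int
    retained_indices: tuple[int, ...]

    @property
    def scale_factor(self) -> float:
        return self.n_vid / self.n_mr

    def __post_init__(self) -> None:
        idx = self.retained_indices
        if len(idx) != self.n_mr:
            raise ValueError("plan must retain exactly n_mr indices")
        if idx[0] != 1:
            raise ValueError("first retained index must be 1")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("retained indices must be strictly increasing")
        if idx[-1] > self.n_vid:
            raise ValueError("retained index exceeds n_vid")

    def apply(self, seq: list) -> list:
        """Select the retained items from a video-rate sequence."""
        return [seq[i - 1] for i in self.retained_indices]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is round-half-even and would give e.g. round(2.5) = 2
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def match_frames(n_vid: int, n_mr: int) -> FrameMatchPlan:
    """Build the retained-frame plan for matching video to MR frame count.

    Retained video index i (1-based, i = 1..n_mr) is
    round(1 + (i - 1) * n_vid / n_mr) with halves rounded away from zero;
    e.g. n_vid = 9, n_mr = 6 retains [1, 3, 4, 6, 7, 9].
    """
    if n_vid < 1 or n_mr < 1:
        raise ValueError("frame counts must be positive")
    if n_mr > n_vid:
        raise ValueError(
            f"n_mr ({n_mr}) > n_vid ({n_vid}): the MR sequence must be the "
            "shorter one"
        )
    s = n_vid / n_mr
    raw = 1.0 + np.arange(n_mr) * s
    idx = _round_half_away(raw).astype(int)
    return FrameMatchPlan(n_vid=n_vid, n_mr=n_mr, retained_indices=tuple(idx))


@dataclass(frozen=True)
class ModalityLayout:
    """Row layout of one modality's block within a hybrid column.

    Serialization order: channel 1 column-major, channel 2, ..., then the
    dx plane column-major, then dy.  Total rows = (C + 2) * H * W.
    """

    name: str
    height: int
    width: int
    n_channels: int
    offset: int = 0  # first row of this block within the hybrid column
    weight: float = 1.0

    @property
    def plane_size(self) -> int:
        return self.height * self.width

    @property
    def n_rows(self) -> int:
        return (self.n_channels + 2) * self.plane_size

    @property
    def rows(self) -> slice:
        return slice(self.offset, self.offset + self.n_rows)

    def channel_rows(self, ch: int) -> slice:
        start = self.offset + ch * self.plane_size
        return slice(start, start + self.plane_size)

    @property
    def dx_rows(self) -> slice:
        return self.channel_rows(self.n_channels)

    @property
    def dy_rows(self) -> slice:
        return self.channel_rows(self.n_channels + 1)


def serialize_frame(image: np.ndarray, fld: WarpField) -> np.ndarray:
    """Serialize one frame + warp field into an observation vector.

    Layout: each image channel column-major (Fortran order), then dx
    column-major, then dy; length (C + 2) * H * W (5*H*W for RGB).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if img.shape[:2] != fld.shape:
        raise ValueError(
            f"image geometry {img.shape[:2]} != field geometry {fld.shape}"
        )
    parts = [img[..., ch].ravel(order="F") for ch in range(img.shape[2])]
    parts.append(fld.dx.ravel(order="F"))
    parts.append(fld.dy.ravel(order="F"))
    return np.concatenate(parts)


def deserialize_frame(
    vector: np.ndarray, layout: ModalityLayout, local: bool = True
) -> tuple[np.ndarray, WarpField]:
    """Invert :func:`serialize_frame` given the modality layout.

    With ``local=True`` the vector holds only this modality's block
    (layout offset ignored); otherwise it is a full hybrid column.
    """
    v = np.asarray(vector, dtype=np.float64)
    off = 0 if local else layout.offset
    if local and v.shape[0] != layout.n_rows:
        raise ValueError(
            f"vector length {v.shape[0]} != layout rows {layout.n_rows}"
        )
    h, w, c = layout.height, layout.width, layout.n_channels
    ps = layout.plane_size

    def plane(i: int) -> np.ndarray:
        return v[off + i * ps : off + (i + 1) * ps].reshape((h, w), order="F")

    image = np.stack([plane(ch) for ch in range(c)], axis=-1)
    return image, WarpField(dx=plane(c), dy=plane(c + 1))


@dataclass(frozen=True)
class HybridArray:
    """Observation-by-sample array stacking both modalities' blocks.

    ``data`` has one column per matched frame; ``layouts`` records each
    modality's row ranges and geometry.  Column order is temporal order.
    """

    data: np.ndarray
    layouts: dict[str, ModalityLayout] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(lo.n_rows for lo in self.layouts.values())
        if self.data.shape[0] != total:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layouts describe "
                f"{total}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_observations(self) -> int:
        return self.data.shape[0]

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.layouts)

    def layout(self, modality: str) -> ModalityLayout:
        try:
            return self.layouts[modality]
        except KeyError:
            raise ValueError(
                f"unknown modality {modality!r}; have {list(self.layouts)}"
            ) from None

    def modality_rows(self, modality: str) -> list[slice]:
        """Row slices (one contiguous block here) of a modality."""
        return [self.layout(modality).rows]

    def zeroed(self, modality: str) -> np.ndarray:
        """Copy of ``data`` with one modality's block set to zero."""
        out = self.data.copy()
        for sl in self.modality_rows(modality):
            out[sl] = 0.0
        return out

    def frames(self, modality: str) -> list[tuple[np.ndarray, WarpField]]:
        """Deserialize every sample of one modality back to (image, field)."""
        lo = self.layout(modality)
        return [
            deserialize_frame(self.data[lo.rows, j], lo)
            for j in range(self.n_samples)
        ]


@dataclass(frozen=True)
class PairedHybridArray(HybridArray):
    """Hybrid array whose column j stacks single-frame columns j and j+1."""

    base: HybridArray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.base is None:
            raise ValueError("PairedHybridArray requires its base array")
        if self.data.shape[0] != 2 * self.base.data.shape[0]:
            raise ValueError("paired rows must be twice the base rows")
        if self.data.shape[1] != self.base.data.shape[1] - 1:
            raise ValueError("paired samples must be base samples - 1")

    def modality_rows(self, modality: str) -> list[slice]:
        sl = self.base.layout(modality).rows
        n = self.base.data.shape[0]
        return [sl, slice(sl.start + n, sl.stop + n)]

    def zeroed(self, modality: str) -> np.ndarray:
        out = self.data.copy()
        for sl in self.modality_rows(modality):
            out[sl] = 0.0
        return out

    def unstack(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Columns (t, t+1) of the base array recovered from column j."""
        n = self.base.data.shape[0]
        return self.data[:n, j], self.data[n:, j]


def serialize_sequence(
    frames: list[np.ndarray], fields: list[WarpField]
) -> np.ndarray:
    if len(frames) != len(fields):
        raise ValueError("one warp field per frame required")
    return np.column_stack(
        [serialize_frame(f, w) for f, w in zip(frames, fields)]
    )


def build_hybrid(
    video: tuple[list[np.ndarray], list[WarpField]],
    mr: tuple[list[np.ndarray], list[WarpField]],
    plan: FrameMatchPlan | None = None,
    channel_weights: dict[str, float] | None = None,
    names: tuple[str, str] = ("video", "mr"),
) -> HybridArray:
    """Stack both modalities' serialized sequences into a hybrid array.

    ``video`` is given at video rate and decimated by ``plan`` (pass
    ``plan=None`` if the sequences are already matched); ``mr`` must have
    n_mr frames.  ``channel_weights`` multiplies a whole modality block
    (default 1 -- intensities and warp pixels mix at native scale).
    """
    v_frames, v_fields = video
    m_frames, m_fields = mr
    if plan is not None:
        v_frames = plan.apply(list(v_frames))
        v_fields = plan.apply(list(v_fields))
    if len(v_frames) != len(m_frames):
        raise ValueError(
            f"frame-count mismatch after matching: video {len(v_frames)}, "
            f"mr {len(m_frames)}"
        )
    weights = channel_weights or {}
    blocks, layouts, offset = [], {}, 0
    for name, (frames, fields) in zip(names, ((v_frames, v_fields), (m_frames, m_fields))):
        img0 = np.atleast_3d(np.asarray(frames[0]))
        lo = ModalityLayout(
            name=name,
            height=img0.shape[0],
            width=img0.shape[1],
            n_channels=img0.shape[2],
            offset=offset,
            weight=float(weights.get(name, 1.0)),
        )
        block = serialize_sequence(list(frames), list(fields))
        if lo.weight != 1.0:
            block = block * lo.weight
        blocks.append(block)
        layouts[name] = lo
        offset += lo.n_rows
    return HybridArray(data=np.vstack(blocks), layouts=layouts)


def build_paired(h: HybridArray) -> PairedHybridArray:
    """Stack columns (t, t+1) of a hybrid array into paired-frame samples."""
    if h.n_samples < 2:
        raise ValueError("paired-frame input needs at least 2 samples")
    data = np.vstack([h.data[:, :-1], h.data[:, 1:]])
    return PairedHybridArray(data=data, layouts=dict(h.layouts), base=h)
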