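"""Sequence and container I/O.

Directories of numbered PNG frames are the canonical lossless
interchange format; AVI is supported through imageio when a codec
backend is available, but is flagged as lossy unless an uncompressed
codec is used.  Analysis artifacts (bundles, hybrid arrays, PCA models,
planes) persist in a single portable HDF5 container.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import yaml

from . import synthetic_data as sd
from .hybrid import HybridArray, ModalityLayout
from .pca_recon import PCAModel

__all__ = [
    "read_sequence",
    "write_sequence",
    "save_bundle",
    "load_bundle",
    "save_hybrid",
    "load_hybrid",
    "save_model",
    "load_model",
]

_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path):
    nums = _NUM_RE.findall(p.stem)
    return (int(nums[-1]) if nums else 0, p.name)


def _to_rgb(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=-1)
    elif arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr.astype(np.float64)


def read_sequence(path: str | Path) -> np.ndarray:
    """Read an image sequence from a PNG-frame directory or an AVI file.

    Returns (n_frames, H, W, 3) float64 on the 0-255 scale; grayscale
    frames are promoted to RGB.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() == ".png"),
            key=_numeric_key,
        )
        if not files:
            raise IOError(f"no PNG frames found in {path}")
        frames = [_to_rgb(iio.imread(p)) for p in files]
    elif path.is_file():
        try:
            frames = [_to_rgb(f) for f in iio.imiter(path)]
        except Exception as exc:  # pragma: no cover - backend dependent
            raise IOError(
                f"could not decode {path}; install an ffmpeg backend or use "
                f"a PNG frame directory"
            ) from exc
        if not frames:
            raise IOError(f"no frames decoded from {path}")
    else:
        raise IOError(f"no such file or directory: {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame geometry in {path}: {shapes}")
    return np.stack(frames)


def write_sequence(path: str | Path, frames: np.ndarray) -> list[Path]:
    """Write frames as a directory of numbered PNGs (frame_0001.png ...)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(frames, start=1):
        out = path / f"frame_{i:04d}.png"
        arr = np.clip(np.rint(np.asarray(frame)), 0, 255).astype(np.uint8)
        iio.imwrite(out, arr)
        written.append(out)
    return written


def save_bundle(
    out_dir: str | Path, bundle: sd.PairedSequenceBundle
) -> Path:
    """Write a synthetic bundle as PNG frame directories plus sidecars.

    Layout: ``face/`` and ``tract/`` frame directories, per-channel mask
    PNGs under ``masks/``, and ``bundle.yaml`` recording the scene spec,
    seed, and latent trajectories.
    """
    out_dir = Path(out_dir)
    write_sequence(out_dir / "face", bundle.seq_a)
    write_sequence(out_dir / "tract", bundle.seq_b)
    masks_dir = out_dir / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    for (kind, idx), masks in bundle.region_masks.items():
        for modality, mask in masks.items():
            name = "face" if modality == "a" else "tract"
            iio.imwrite(
                masks_dir / f"{kind}_{idx}_{name}.png",
                (mask.astype(np.uint8) * 255),
            )
    sidecar = {
        "spec": sd.spec_to_dict(bundle.spec),
        "latents": {
            "shared": bundle.latents.shared.tolist(),
            "private_a": bundle.latents.private_a.tolist(),
            "private_b": bundle.latents.private_b.tolist(),
            "smoothness": float(bundle.latents.smoothness),
        },
    }
    sidecar_path = out_dir / "bundle.yaml"
    sidecar_path.write_text(yaml.safe_dump(sidecar))
    return out_dir


def load_bundle(path: str | Path) -> sd.PairedSequenceBundle:
    """Reload a bundle written by :func:`save_bundle`.

    Pixel values come back PNG-quantized (rounded to integers)."""
    path = Path(path)
    sidecar = yaml.safe_load((path / "bundle.yaml").read_text())
    spec = sd.spec_from_dict(sidecar["spec"])
    lat = sidecar["latents"]
    latents = sd.LatentTrajectory(
        shared=np.asarray(lat["shared"], dtype=np.float64),
        private_a=np.asarray(lat["private_a"], dtype=np.float64),
        private_b=np.asarray(lat["private_b"], dtype=np.float64),
        smoothness=float(lat["smoothness"]),
    )
    region_masks = {
        key: {
            m.modality: m.region_mask(spec.shape_for(m.modality))
            for m in maps
        }
        for key, maps in spec.channel_maps.items()
    }
    return sd.PairedSequenceBundle(
        seq_a=read_sequence(path / "face"),
        seq_b=read_sequence(path / "tract"),
        latents=latents,
        region_masks=region_masks,
        spec=spec,
    )


def save_hybrid(path: str | Path, h: HybridArray, group: str = "hybrid"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=h.data)
        for name, lo in h.layouts.items():
            lg = g.create_group(f"layout/{name}")
            for key in ("height", "width", "n_channels", "offset", "weight"):
                lg.attrs[key] = getattr(lo, key)


def load_hybrid(path: str | Path, group: str = "hybrid") -> HybridArray:
    with h5py.File(path, "r") as f:
        g = f[group]
        data = g["data"][()]
        layouts = {}
        for name, lg in g["layout"].items():
            layouts[name] = ModalityLayout(
                name=name,
                height=int(lg.attrs["height"]),
                width=int(lg.attrs["width"]),
                n_channels=int(lg.attrs["n_channels"]),
                offset=int(lg.attrs["offset"]),
                weight=float(lg.attrs["weight"]),
            )
    return HybridArray(data=data, layouts=layouts)


def save_model(path: str | Path, model: PCAModel, group: str = "pca"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("components", data=model.components)
        g.create_dataset("loadings", data=model.loadings)
        g.attrs["centered"] = model.centered
        if model.mean_vector is not None:
            g.create_dataset("mean_vector", data=model.mean_vector)


def load_model(path: str | Path, group: str = "pca") -> PCAModel:
    with h5py.File(path, "r") as f:
        g = f[group]
        mean = g["mean_vector"][()] if "mean_vector" in g else None
        return PCAModel(
            components=g["components"][()],
            loadings=g["loadings"][()],
            centered=bool(g.attrs["centered"]),
            mean_vector=mean,
        )
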