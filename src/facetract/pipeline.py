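"""End-to-end pipeline: simulate/ingest -> reference selection -> warping
-> hybrid -> PCA -> reconstruction -> permutation / Bubbles inference.

Every stochastic stage derives its seed deterministically from the
master seed and the stage name, so one integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as ft_io
from . import synthetic_data as sd
from .bubbles import run_bubbles
from .hybrid import build_hybrid, build_paired, match_frames
from .optic_flow import select_reference
from .pca_recon import fit_pca, reconstruct_modality
from .permutation import permutation_test

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "prepare_sequences"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from master seed + stage name."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run.

    With ``video_path``/``mr_path`` unset, a synthetic bundle is
    generated from the ``sim_*`` parameters; otherwise sequences are read
    from disk (PNG directories or AVI).
    """

    # input: either paths ...
    video_path: str | None = None
    mr_path: str | None = None
    # ... or simulation parameters
    sim_n_frames: int = 40
    sim_k_shared: int = 2
    sim_k_priv_a: int = 1
    sim_k_priv_b: int = 1
    sim_smoothness: float = 0.9
    sim_noise_sd: float = 2.0

    flow_iterations: int = 3
    # pixel block content: raw frame pixels by default; optionally the
    # reference-warped texture (frames resampled onto the reference)
    use_warped_texture: bool = False
    centered: bool = False
    paired: bool = False
    zero_modality: str = "mr"

    permutation_enabled: bool = False
    permutation_n_perm: int = 100
    permutation_mode: str = "single"

    bubbles_enabled: bool = False
    bubbles_target: str = "video"
    bubbles_n_iter: int = 1000
    bubbles_n_bubbles: int = 46
    bubbles_diameter: int = 12
    bubbles_top_frac: float = 0.1
    bubbles_per_frame: bool = False

    seed: int = 0
    out_dir: str = "facetract_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def prepare_sequences(config: PipelineConfig):
    """Stage 1-2: obtain the two sequences and their reference warp fields.

    Returns ((video_frames, video_fields), (mr_frames, mr_fields), plan),
    with the video sequence already decimated to the MR frame count.
    """
    if config.video_path or config.mr_path:
        if not (config.video_path and config.mr_path):
            raise ValueError("both video_path and mr_path are required")
        video = ft_io.read_sequence(config.video_path)
        mr = ft_io.read_sequence(config.mr_path)
    else:
        bundle = sd.make_bundle(
            n_frames=config.sim_n_frames,
            k_shared=config.sim_k_shared,
            k_priv_a=config.sim_k_priv_a,
            k_priv_b=config.sim_k_priv_b,
            smoothness=config.sim_smoothness,
            noise_sd=config.sim_noise_sd,
            seed=stage_seed(config.seed, "simulate"),
        )
        video, mr = bundle.seq_a, bundle.seq_b

    plan = match_frames(len(video), len(mr))
    video = np.asarray(plan.apply(list(video)))
    sel_v = select_reference(
        video, config.flow_iterations, seed=stage_seed(config.seed, "ref_video")
    )
    sel_m = select_reference(
        mr, config.flow_iterations, seed=stage_seed(config.seed, "ref_mr")
    )
    v_frames, m_frames = list(video), list(mr)
    if config.use_warped_texture:
        from .optic_flow import warp_image

        v_frames = [warp_image(f, fld) for f, fld in zip(v_frames, sel_v.fields)]
        m_frames = [warp_image(f, fld) for f, fld in zip(m_frames, sel_m.fields)]
    return (v_frames, sel_v.fields), (m_frames, sel_m.fields), plan


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; write report.yaml and artifacts.

    Returns the report dict (also written to ``<out_dir>/report.yaml``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    logger.info("stage: prepare sequences")
    (v_frames, v_fields), (m_frames, m_fields), plan = prepare_sequences(config)
    report["stages"].append("prepare")
    report["n_frames"] = len(m_frames)
    report["scale_factor"] = round(plan.scale_factor, 6)

    logger.info("stage: hybrid + PCA")
    h = build_hybrid((v_frames, v_fields), (m_frames, m_fields))
    if config.paired:
        h = build_paired(h)
    model = fit_pca(h, centered=config.centered)
    container = out_dir / "results.h5"
    ft_io.save_hybrid(container, h.base if config.paired else h)
    ft_io.save_model(container, model)
    report["stages"] += ["hybrid", "pca"]
    report["n_components"] = model.n_components

    logger.info("stage: cross-modal reconstruction")
    recon = {}
    for zeroed in h.modalities:
        res = reconstruct_modality(model, h, zeroed)
        recon[zeroed] = res
        report[f"loading_correlation_recon_{zeroed}"] = round(
            res.metrics.loading_correlation, 6
        )
        report[f"loading_sse_recon_{zeroed}"] = round(res.metrics.loading_sse, 6)
    report["stages"].append("reconstruct")
    for name, res in recon.items():
        ft_io.write_sequence(out_dir / f"recon_{name}", res.recon_images[name])

    if config.permutation_enabled:
        logger.info("stage: permutation test (%d perms)", config.permutation_n_perm)
        perm = permutation_test(
            (v_frames, v_fields),
            (m_frames, m_fields),
            n_perm=config.permutation_n_perm,
            mode=config.permutation_mode,
            seed=stage_seed(config.seed, "permutation"),
        )
        report["stages"].append("permutation")
        report["permutation"] = {
            "mode": perm.mode,
            "observed_correlation": round(perm.observed.loading_correlation, 6),
            "p_value_correlation": round(perm.p_value_correlation, 6),
            "p_value_sse": round(perm.p_value_sse, 6),
            "null_mean": round(perm.null_mean, 6),
            "null_ci95": [round(v, 6) for v in perm.null_ci95],
            "null_values": [round(float(v), 6) for v in perm.null_correlations],
        }

    if config.bubbles_enabled:
        logger.info("stage: bubbles (%d iterations)", config.bubbles_n_iter)
        target = config.bubbles_target
        occluded = "video" if target == "video" else "mr"
        bub = run_bubbles(
            model,
            h,
            occluded,
            n_iter=config.bubbles_n_iter,
            n_bubbles=config.bubbles_n_bubbles,
            diameter=config.bubbles_diameter,
            top_frac=config.bubbles_top_frac,
            per_frame=config.bubbles_per_frame,
            seed=stage_seed(config.seed, "bubbles"),
        )
        report["stages"].append("bubbles")
        plane = bub.plane.plane
        finite = np.isfinite(plane)
        report["bubbles"] = {
            "occluded_modality": occluded,
            "n_iter": config.bubbles_n_iter,
            "plane_max": round(float(np.nanmax(plane)), 6),
            "plane_mean": round(float(plane[finite].mean()), 6),
            "plane_argmax": [
                int(v) for v in np.unravel_index(np.nanargmax(plane), plane.shape)
            ],
        }
        np_path = out_dir / "proportion_plane.npy"
        np.save(np_path, plane)

    report_path = out_dir / "report.yaml"
    report_path.write_text(yaml.safe_dump(report, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report
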