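"""End-to-end marker-free longitudinal registration.

Stage order: detect features in both frames -> relaxation matching
(gradient-direction SAD) -> strict shape-context matching -> per-side
matching-vector revision of the relaxed tier -> merge + ANMS de-cluster
-> consensus trim against the smoothed deformation field ->
thin-plate-spline warp -> competitive winner-guided (SOM) refinement
of the control points by mutual information -> final warp and metrics.

Each stage logs how many points survived it, so a starved pipeline is
diagnosable from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .evaluation import ssim_index
from .features import detect_features
from .image import Image
from .matching import (
    ControlPointPairs,
    MatchSet,
    UnderdeterminedPairsError,
    merge_control_pairs,
    relaxation_match,
    revise_relaxed,
    shape_context,
    strict_match,
    train_matching_vectors,
    trim_control_pairs,
)
from .som import SOMParams, mutual_information, refine
from .tps import TPSModel, fit_tps, warp_image

__all__ = ["RegistrationResult", "PipelineError", "run_registration"]

log = logging.getLogger("thermoreg")


class PipelineError(RuntimeError):
    """Registration failed; the message names the stage that starved it."""


@dataclass
class RegistrationResult:
    """Everything :func:`run_registration` produces.

    ``tps_forward`` maps source coordinates to target coordinates (the
    reported correspondence); ``tps_backward`` maps target pixels to
    source pixels and is what resamples the image.
    """

    warped_source: Image
    control_pairs: ControlPointPairs
    tps_forward: TPSModel
    tps_backward: TPSModel
    metrics: dict[str, float]
    som_trace: list[float] = field(default_factory=list)
    som_converged: bool = True
    strict_pairs: MatchSet | None = None
    relaxed_pairs: MatchSet | None = None


def _preprocess(img: Image, config: PipelineConfig) -> Image:
    if img.height < 32 or img.width < 32:
        raise PipelineError("input image smaller than 32 px per side")
    out = img.normalized()
    if config.clahe_enabled:
        from skimage.exposure import equalize_adapthist

        out = Image(equalize_adapthist(out.pixels, clip_limit=config.clahe_clip))
    return out


def run_registration(
    source: Image, target: Image, config: PipelineConfig | None = None
) -> RegistrationResult:
    """Register ``source`` (earlier visit) onto ``target`` (later visit).

    Deterministic given ``config.seed``.  Raises :class:`PipelineError`
    naming the starving stage when any tier leaves fewer than 4 control
    pairs, or when a frame yields no features at all.
    """
    config = config or PipelineConfig()
    src = _preprocess(source, config)
    tgt = _preprocess(target, config)

    # ---- stage 1: features ------------------------------------------------
    det_kwargs = dict(
        harris_sigma=config.harris_sigma,
        harris_k=config.harris_k,
        harris_rel_threshold=config.harris_rel_threshold,
        anms_n=config.anms_n,
        anms_c_robust=config.anms_c_robust,
        vessel_sigma=config.vessel_sigma,
        junction_merge_radius=config.junction_merge_radius,
    )
    src_feats, src_skel, src_heat = detect_features(src, **det_kwargs)
    tgt_feats, tgt_skel, tgt_heat = detect_features(tgt, **det_kwargs)
    log.info("features: %d source, %d target", len(src_feats), len(tgt_feats))
    if not src_feats:
        raise PipelineError("no features detected in the source image")
    if not tgt_feats:
        raise PipelineError("no features detected in the target image")

    # ---- stage 2: relaxation matching ------------------------------------
    relaxed = relaxation_match(
        src_feats, src, tgt, W=config.relax_window, search_radius=config.relax_search_radius
    )
    log.info("relaxation matching: %d pairs", len(relaxed))

    # ---- stage 3: strict shape-context matching --------------------------
    sc_kwargs = dict(R=config.sc_radius, n_angle=config.sc_n_angle, n_rad=config.sc_n_rad)
    src_desc = [shape_context(p, src_skel, src_heat, **sc_kwargs) for p in src_feats]
    tgt_desc = [shape_context(p, tgt_skel, tgt_heat, **sc_kwargs) for p in tgt_feats]
    radii = np.array([p.suppression_radius for p in src_feats])
    radii = radii[np.isfinite(radii)]
    r_s = float(np.median(radii)) if radii.size else config.sc_radius / 2
    T = float(np.clip((config.sc_radius - r_s) / config.sc_radius, 1e-3, 1 - 1e-3))
    strict = strict_match(src_desc, tgt_desc, src_feats, tgt_feats, T=T)
    log.info("strict matching: %d pairs (T=%.3f)", len(strict), T)
    if not strict:
        raise PipelineError("strict shape-context matching kept no pairs")

    # ---- stage 4: matching-vector revision -------------------------------
    midline = src.width / 2
    vectors = train_matching_vectors(strict, midline_x=midline)
    revised = revise_relaxed(relaxed, vectors, midline_x=midline, tol_px=config.vector_tol_px)
    log.info("matching-vector revision: %d of %d relaxed pairs kept", len(revised), len(relaxed))

    # ---- stage 5: merge + ANMS -------------------------------------------
    try:
        pairs = merge_control_pairs(
            strict, revised, anms_n=config.merge_anms_n, anms_c_robust=config.anms_c_robust
        )
    except UnderdeterminedPairsError as exc:
        raise PipelineError(f"control-pair merging starved the pipeline: {exc}") from exc
    log.info("control pairs after ANMS: %d", len(pairs))

    # ---- stage 5b: consensus trim -----------------------------------------
    if config.trim_enabled:
        n_before = len(pairs)
        pairs = trim_control_pairs(
            pairs, lam=config.trim_lambda, threshold_px=config.trim_threshold_px
        )
        log.info("consensus trim: %d of %d pairs kept", len(pairs), n_before)

    # ---- metrics before ---------------------------------------------------
    ssim_before = ssim_index(src, tgt)
    mi_before = mutual_information(src, tgt, bins=config.mi_bins)

    # ---- stage 6: SOM refinement ------------------------------------------
    som_trace: list[float] = []
    som_converged = True
    if config.som_enabled and config.som_i_max > 0:
        params = SOMParams(
            grid_size=config.som_grid_size,
            grid_spacing=config.som_grid_spacing,
            eta0=config.som_eta0,
            sig0=config.som_sig0,
            i_max=config.som_i_max,
            mi_bins=config.mi_bins,
            mi_stride=config.som_mi_stride,
            seed=config.seed,
        )
        pairs, state = refine(pairs, src, tgt, params)
        som_trace = state.mi_trace
        som_converged = state.converged
        log.info(
            "SOM refinement: %d iterations, converged=%s, MI %.4f -> %.4f",
            state.iteration, state.converged, som_trace[0], som_trace[-1],
        )

    # ---- stage 7: final TPS warp ------------------------------------------
    try:
        backward = fit_tps(pairs.target_xy(), pairs.source_xy(), reg_lambda=config.tps_reg_lambda)
        forward = fit_tps(pairs.source_xy(), pairs.target_xy(), reg_lambda=config.tps_reg_lambda)
    except Exception as exc:
        raise PipelineError(f"TPS fit failed on final control pairs: {exc}") from exc
    warped = warp_image(backward, src, tgt.shape)

    metrics = {
        "ssim_before": ssim_before,
        "ssim_after": ssim_index(warped, tgt),
        "mi_before": mi_before,
        "mi_after": mutual_information(warped, tgt, bins=config.mi_bins),
    }
    log.info("SSIM %.4f -> %.4f; MI %.4f -> %.4f",
             metrics["ssim_before"], metrics["ssim_after"],
             metrics["mi_before"], metrics["mi_after"])
    return RegistrationResult(
        warped_source=warped,
        control_pairs=pairs,
        tps_forward=forward,
        tps_backward=backward,
        metrics=metrics,
        som_trace=som_trace,
        som_converged=som_converged,
        strict_pairs=strict,
        relaxed_pairs=relaxed,
    )
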