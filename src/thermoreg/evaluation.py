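"""Registration quality assessment.

Covers the quantitative metrics (SSIM, mutual information, coincidence
rate of delineated curves, marker position error) and the visual
Canny-edge overlay used to judge longitudinal alignment by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.metrics import structural_similarity
from skimage.morphology import dilation, disk

from .image import Image

__all__ = ["LineMask", "ErrorReport", "ssim_index", "coincidence_rate", "canny_overlay", "marker_error"]


@dataclass(frozen=True)
class LineMask:
    """Binary mask of a delineated curve (e.g. an expert-drawn vessel line)."""

    mask: np.ndarray
    provenance: str = "source"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class ErrorReport:
    """Min / max / mean of per-marker Euclidean position differences (px)."""

    min: float
    max: float
    mean: float


def ssim_index(a: Image, b: Image) -> float:
    """Mean structural similarity with a Gaussian window on [0, 1] intensities."""
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    return float(
        structural_similarity(
            a.pixels, b.pixels, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
    )


def coincidence_rate(m1: LineMask, m2: LineMask, tol_px: int = 1) -> float:
    """Percent tolerant overlap between two delineated curves.

    A pixel of either mask counts as overlapping when it lies within
    ``tol_px`` of the other mask (morphological dilation by a disk);
    the rate is 100 * |overlap| / |union|.  ``tol_px = 0`` is the exact
    Jaccard index. Symmetric, and non-decreasing in ``tol_px``.
    """
    if m1.shape != m2.shape:
        raise ValueError("masks must share a shape")
    a, b = m1.mask, m2.mask
    if not a.any() or not b.any():
        raise ValueError("both masks must be non-empty")
    if tol_px < 0:
        raise ValueError("tol_px must be >= 0")
    if tol_px == 0:
        da, db = a, b
    else:
        selem = disk(tol_px)
        da = dilation(a, selem)
        db = dilation(b, selem)
    overlap = (a & db) | (b & da)
    union = a | b
    return float(100.0 * overlap.sum() / union.sum())


def canny_overlay(
    warped_source: Image, target: Image, low: float = 0.1, high: float = 0.2
) -> np.ndarray:
    """RGB edge overlay: white = source-only, red = target-only, green = both.

    Edges are Canny edges with hysteresis thresholds ``(low, high)`` on the
    normalized range; "both" means the edges agree to within 1 px.
    """
    if warped_source.shape != target.shape:
        raise ValueError("images must share a shape")
    es = canny(warped_source.pixels, low_threshold=low, high_threshold=high)
    et = canny(target.pixels, low_threshold=low, high_threshold=high)
    near_t = dilation(et, disk(1))
    near_s = dilation(es, disk(1))
    both = (es & near_t) | (et & near_s)
    s_only = es & ~both
    t_only = et & ~both
    out = np.zeros((*target.shape, 3))
    out[s_only] = (1.0, 1.0, 1.0)
    out[t_only] = (1.0, 0.0, 0.0)
    out[both] = (0.0, 1.0, 0.0)
    return out


def marker_error(pred: np.ndarray, truth: np.ndarray) -> ErrorReport:
    """Per-marker Euclidean distance summary between two matched point sets.

    ``pred`` and ``truth`` are (n, 2) arrays matched by row order (id).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape or pred.shape[1] != 2:
        raise ValueError("point sets must be matched (n, 2) arrays")
    d = np.hypot(*(pred - truth).T)
    return ErrorReport(min=float(d.min()), max=float(d.max()), mean=float(d.mean()))
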