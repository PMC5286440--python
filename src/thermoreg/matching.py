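"""Two-tier feature correspondence.

Tier 1, *relaxation matching*, is deliberately permissive: every source
feature is matched to the location in the target whose window of gradient
directions is most similar (minimum sum of absolute circular angle
differences, SAD).  It produces many pairs, some wrong.

Tier 2, *strict matching*, compares shape-context descriptors — log-polar
histograms of the vascular skeleton and of the binarized heat pattern
around each feature — and keeps only pairs that are the mutual optimum of
the assignment AND clearly better than their second-best alternatives.
It produces few pairs, essentially all right.

The strict pairs train one representative displacement ("matching
vector") per body side (left/right of a midline, since the two breasts
deform differently between visits); relaxed matches whose displacement
strays from their side's vector are discarded.  The surviving union is
thinned by adaptive non-maximal suppression into the control-point pairs
that anchor the thin-plate-spline warp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .features import FeaturePoint, SkeletonMap, anms
from .image import Image

__all__ = [
    "GradientDescriptor",
    "ShapeContextDescriptor",
    "Match",
    "MatchSet",
    "MatchingVector",
    "gradient_descriptor",
    "sad_score",
    "relaxation_match",
    "shape_context",
    "sc_cost",
    "strict_match",
    "train_matching_vectors",
    "revise_relaxed",
    "merge_control_pairs",
    "trim_control_pairs",
]

Provenance = Literal["strict", "relaxed", "relaxed_revised"]


# ---------------------------------------------------------------------------
# gradient-direction descriptor and relaxation matching


@dataclass(frozen=True)
class GradientDescriptor:
    """Window of per-pixel gradient directions around a feature point.

    ``angles`` are radians in [0, 2pi); ``valid`` flags pixels with nonzero
    gradient magnitude (zero-gradient pixels carry angle 0 and are excluded
    from SAD comparisons).
    """

    angles: np.ndarray
    valid: np.ndarray
    center: tuple[float, float]

    @property
    def window(self) -> int:
        return self.angles.shape[0]


def _angle_maps(img: Image) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient angle in [0, 2pi) and validity mask."""
    gy, gx = np.gradient(img.pixels)
    mag = np.hypot(gx, gy)
    valid = mag > 1e-12
    angles = np.where(valid, np.mod(np.arctan2(gy, gx), 2 * np.pi), 0.0)
    return angles, valid


def gradient_descriptor(img: Image, p: FeaturePoint | tuple[float, float], W: int = 21) -> GradientDescriptor:
    """Descriptor for the W x W window centered at ``p`` (W odd).

    Raises ``ValueError`` when the window does not fit inside the image;
    such border points are simply not describable.
    """
    if W % 2 == 0 or W < 1:
        raise ValueError("W must be odd and >= 1")
    x, y = (p.x, p.y) if isinstance(p, FeaturePoint) else p
    cx, cy = int(round(x)), int(round(y))
    h = W // 2
    if cx - h < 0 or cy - h < 0 or cx + h >= img.width or cy + h >= img.height:
        raise ValueError(f"window of side {W} at ({x}, {y}) exceeds image bounds")
    angles, valid = _angle_maps(img)
    sl = np.s_[cy - h : cy + h + 1, cx - h : cx + h + 1]
    return GradientDescriptor(angles[sl].copy(), valid[sl].copy(), center=(float(x), float(y)))


def _circular_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, 2 * np.pi - d)


def sad_score(d_s: GradientDescriptor, d_t: GradientDescriptor) -> float:
    """Sum of absolute circular angle differences over mutually valid pixels.

    Returns +inf when no pixel is valid in both windows.
    """
    if d_s.angles.shape != d_t.angles.shape:
        raise ValueError("descriptor window sizes differ")
    both = d_s.valid & d_t.valid
    if not both.any():
        return float("inf")
    return float(_circular_diff(d_s.angles[both], d_t.angles[both]).sum())


@dataclass(frozen=True)
class Match:
    source: FeaturePoint
    target: FeaturePoint
    cost: float
    provenance: Provenance

    @property
    def displacement(self) -> tuple[float, float]:
        return (self.target.x - self.source.x, self.target.y - self.source.y)


@dataclass
class MatchSet:
    """Ordered correspondences between source and target points."""

    pairs: list[Match] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def source_xy(self) -> np.ndarray:
        return np.array([[m.source.x, m.source.y] for m in self.pairs]).reshape(-1, 2)

    def target_xy(self) -> np.ndarray:
        return np.array([[m.target.x, m.target.y] for m in self.pairs]).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": range(len(self.pairs)),
                "x_source": [m.source.x for m in self.pairs],
                "y_source": [m.source.y for m in self.pairs],
                "x_target": [m.target.x for m in self.pairs],
                "y_target": [m.target.y for m in self.pairs],
                "cost": [m.cost for m in self.pairs],
                "provenance": [m.provenance for m in self.pairs],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MatchSet":
        df = pd.read_csv(path)
        pairs = [
            Match(
                source=FeaturePoint(x=r.x_source, y=r.y_source, response=0.0),
                target=FeaturePoint(x=r.x_target, y=r.y_target, response=0.0),
                cost=float(r.cost),
                provenance=str(r.provenance),
            )
            for r in df.itertuples()
        ]
        return cls(pairs)


# alias: the merged, ANMS-thinned set that anchors the TPS warp
ControlPointPairs = MatchSet


def _subpixel_offset(surface: np.ndarray, iy: int, ix: int, axis: int) -> float:
    """Offset of the parabola through the minimum and its two axis neighbours.

    Returns 0 at surface borders, for non-finite neighbours, and for a flat
    triple (an exact integer minimum stays exactly integer).
    """
    if axis == 0:
        if iy == 0 or iy == surface.shape[0] - 1:
            return 0.0
        a, b, c = surface[iy - 1, ix], surface[iy, ix], surface[iy + 1, ix]
    else:
        if ix == 0 or ix == surface.shape[1] - 1:
            return 0.0
        a, b, c = surface[iy, ix - 1], surface[iy, ix], surface[iy, ix + 1]
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(c)):
        return 0.0
    if b <= 1e-12:
        return 0.0  # an exact match is exactly here
    denom = a - 2 * b + c
    if denom <= 1e-12:
        return 0.0
    off = 0.5 * (a - c) / denom
    return float(np.clip(off, -0.5, 0.5))


def relaxation_match(
    src_pts: Sequence[FeaturePoint],
    src_img: Image,
    tgt_img: Image,
    W: int = 21,
    search_radius: int = 30,
) -> MatchSet:
    """Template matching of gradient-direction windows (provenance "relaxed").

    For each describable source point, every pixel of the target within
    ``search_radius`` of the same coordinates is scored by SAD and the
    minimum wins.  Matches need not be mutually consistent — mismatches are
    tolerated here and culled later by the matching vectors.
    """
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    h = W // 2
    s_ang, s_val = _angle_maps(src_img)
    t_ang, t_val = _angle_maps(tgt_img)
    H, Wd = tgt_img.height, tgt_img.width
    out = MatchSet()
    for p in src_pts:
        cx, cy = int(round(p.x)), int(round(p.y))
        if cx - h < 0 or cy - h < 0 or cx + h >= src_img.width or cy + h >= src_img.height:
            continue  # not describable
        sw_a = s_ang[cy - h : cy + h + 1, cx - h : cx + h + 1]
        sw_v = s_val[cy - h : cy + h + 1, cx - h : cx + h + 1]
        # candidate centers: window must also fit in the target
        x_lo = max(h, cx - search_radius)
        x_hi = min(Wd - h - 1, cx + search_radius)
        y_lo = max(h, cy - search_radius)
        y_hi = min(H - h - 1, cy + search_radius)
        if x_lo > x_hi or y_lo > y_hi:
            continue
        # region holding every candidate window, viewed as sliding windows
        reg_a = t_ang[y_lo - h : y_hi + h + 1, x_lo - h : x_hi + h + 1]
        reg_v = t_val[y_lo - h : y_hi + h + 1, x_lo - h : x_hi + h + 1]
        win_a = np.lib.stride_tricks.sliding_window_view(reg_a, (W, W))
        win_v = np.lib.stride_tricks.sliding_window_view(reg_v, (W, W))
        both = win_v & sw_v[None, None]
        diff = _circular_diff(win_a, sw_a[None, None])
        sad = np.where(both, diff, 0.0).sum(axis=(2, 3))
        sad = np.where(both.any(axis=(2, 3)), sad, np.inf)
        iy, ix = np.unravel_index(np.argmin(sad), sad.shape)
        best = float(sad[iy, ix])
        if not np.isfinite(best):
            continue
        # integer displacement applied to the original sub-pixel point, so
        # a zero-displacement match maps the point exactly onto itself
        tx = p.x + (x_lo + ix - cx)
        ty = p.y + (y_lo + iy - cy)
        # parabolic sub-pixel refinement of the SAD minimum along each axis
        tx += _subpixel_offset(sad, iy, ix, axis=1)
        ty += _subpixel_offset(sad, iy, ix, axis=0)
        out.pairs.append(
            Match(
                source=p,
                target=FeaturePoint(x=tx, y=ty, response=p.response, kind=p.kind),
                cost=best,
                provenance="relaxed",
            )
        )
    return out


# ---------------------------------------------------------------------------
# shape-context descriptor and strict matching


@dataclass(frozen=True)
class ShapeContextDescriptor:
    """Dual-map log-polar histogram: 12 angles x 5 radii per map, 120 bins.

    The first 60 bins count vascular-skeleton pixels around the point, the
    last 60 count set pixels of the binary heat-pattern map.  Each 60-bin
    half is normalized to sum 1 (an all-zero half stays zero).
    """

    bins: np.ndarray
    radius: float
    n_angle: int = 12
    n_rad: int = 5


def _log_polar_hist(
    points_xy: np.ndarray, center: tuple[float, float], R: float, n_angle: int, n_rad: int
) -> np.ndarray:
    """Counts of points in log-polar bins around ``center``.

    Radial edges are log-uniform from R/16 to R; points closer than R/16
    or farther than R (or at the center itself) are not counted.  Angular
    bin 0 starts at the +x axis, width 2pi/n_angle.
    """
    hist = np.zeros((n_angle, n_rad))
    if points_xy.size == 0:
        return hist
    d = points_xy - np.asarray(center, dtype=float)
    r = np.hypot(d[:, 0], d[:, 1])
    edges = np.geomspace(R / 16, R, n_rad + 1)
    ok = (r >= edges[0]) & (r <= edges[-1])
    if not ok.any():
        return hist
    r = r[ok]
    theta = np.mod(np.arctan2(d[ok, 1], d[ok, 0]), 2 * np.pi)
    a_idx = np.minimum((theta / (2 * np.pi / n_angle)).astype(int), n_angle - 1)
    r_idx = np.minimum(np.searchsorted(edges, r, side="right") - 1, n_rad - 1)
    np.add.at(hist, (a_idx, r_idx), 1.0)
    return hist


def shape_context(
    p: FeaturePoint | tuple[float, float],
    skel: SkeletonMap,
    heat_mask: np.ndarray,
    R: float = 100.0,
    n_angle: int = 12,
    n_rad: int = 5,
) -> ShapeContextDescriptor:
    """Dual-map shape-context descriptor centered at ``p``."""
    if R <= 0:
        raise ValueError("R must be > 0")
    center = (p.x, p.y) if isinstance(p, FeaturePoint) else (float(p[0]), float(p[1]))
    halves = []
    for mask in (skel.mask, np.asarray(heat_mask, dtype=bool)):
        rr, cc = np.nonzero(mask)
        pts = np.column_stack([cc, rr]).astype(float)
        h = _log_polar_hist(pts, center, R, n_angle, n_rad).ravel()
        s = h.sum()
        halves.append(h / s if s > 0 else h)
    return ShapeContextDescriptor(np.concatenate(halves), radius=R, n_angle=n_angle, n_rad=n_rad)


def sc_cost(g: ShapeContextDescriptor, h: ShapeContextDescriptor) -> float:
    """Chi-squared matching cost C_s = 1/2 sum_k (g_k - h_k)^2 / (g_k + h_k).

    Empty bins on both sides contribute 0; with two unit-normalized halves
    the cost lies in [0, 2].
    """
    if g.bins.shape != h.bins.shape:
        raise ValueError("descriptor bin counts differ")
    num = (g.bins - h.bins) ** 2
    den = g.bins + h.bins
    nz = den > 0
    return float(0.5 * (num[nz] / den[nz]).sum())


def strict_match(
    src_desc: Sequence[ShapeContextDescriptor],
    tgt_desc: Sequence[ShapeContextDescriptor],
    src_pts: Sequence[FeaturePoint],
    tgt_pts: Sequence[FeaturePoint],
    T: float,
) -> MatchSet:
    """Optimal one-to-one assignment filtered down to unambiguous pairs.

    The full cost matrix ``C[i, j] = sc_cost(src[i], tgt[j])`` is solved by
    minimum-total-cost assignment; pair (i, j) is kept only if it is both
    its row and column minimum and beats its second-best alternatives in
    both directions: ``C[i,j]/C[i_sec,j] <= T`` and ``C[i,j]/C[i,j_sec] <= T``.
    The result is few pairs, but stable ones.
    """
    if not src_desc or not tgt_desc:
        raise ValueError("descriptor lists must be non-empty")
    if not 0 < T < 1:
        raise ValueError("T must be in (0, 1)")
    C = np.array([[sc_cost(g, h) for h in tgt_desc] for g in src_desc])
    rows, cols = linear_sum_assignment(C)
    out = MatchSet()
    for i, j in zip(rows, cols):
        c = C[i, j]
        if c != C[i, :].min() or c != C[:, j].min():
            continue
        col = np.delete(C[:, j], i)
        row = np.delete(C[i, :], j)
        sec_col = col.min() if col.size else np.inf
        sec_row = row.min() if row.size else np.inf
        r1 = 0.0 if c == 0 else (c / sec_col if sec_col > 0 else np.inf)
        r2 = 0.0 if c == 0 else (c / sec_row if sec_row > 0 else np.inf)
        if r1 <= T and r2 <= T:
            out.pairs.append(Match(src_pts[i], tgt_pts[j], float(c), "strict"))
    return out


# ---------------------------------------------------------------------------
# matching vectors and revision


@dataclass(frozen=True)
class MatchingVector:
    """Representative displacement of one body side, learned from strict pairs."""

    side: Literal["left", "right"]
    dx: float
    dy: float
    support: int

    @property
    def vec(self) -> np.ndarray:
        return np.array([self.dx, self.dy])


def train_matching_vectors(
    strict: MatchSet, midline_x: float
) -> tuple[MatchingVector | None, MatchingVector | None]:
    """Component-wise median displacement per side (source x < midline = left).

    A side with no strict support yields ``None``; revision then keeps no
    relaxed match on that side.
    """
    left = [m for m in strict if m.source.x < midline_x]
    right = [m for m in strict if m.source.x >= midline_x]

    def _vec(ms: list[Match], side: str) -> MatchingVector | None:
        if not ms:
            return None
        d = np.array([m.displacement for m in ms])
        dx, dy = np.median(d, axis=0)
        return MatchingVector(side=side, dx=float(dx), dy=float(dy), support=len(ms))

    return _vec(left, "left"), _vec(right, "right")


def revise_relaxed(
    relaxed: MatchSet,
    vectors: tuple[MatchingVector | None, MatchingVector | None],
    midline_x: float,
    tol_px: float = 10.0,
) -> MatchSet:
    """Keep relaxed matches whose displacement agrees with their side's vector.

    A match survives iff its side's matching vector exists and the Euclidean
    deviation of its displacement from that vector is <= ``tol_px``.
    Survivors are relabelled "relaxed_revised".
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be > 0")
    left, right = vectors
    out = MatchSet()
    for m in relaxed:
        v = left if m.source.x < midline_x else right
        if v is None:
            continue
        if np.hypot(m.displacement[0] - v.dx, m.displacement[1] - v.dy) <= tol_px:
            out.pairs.append(Match(m.source, m.target, m.cost, "relaxed_revised"))
    return out


class UnderdeterminedPairsError(RuntimeError):
    """Fewer control pairs survive than a TPS fit requires."""


def trim_control_pairs(
    pairs: "ControlPointPairs",
    lam: float = 2000.0,
    threshold_px: float = 3.0,
    max_iter: int = 3,
) -> "ControlPointPairs":
    """Drop pairs inconsistent with the smoothed deformation field.

    A heavily regularized TPS (``lam``) fitted to all pairs estimates the
    smooth component of the deformation; pairs whose target deviates from
    it by more than ``threshold_px`` are discarded and the fit repeated.
    Wrong correspondences that happen to agree with the smooth field are
    left alone — they cannot damage the warp.  Trimming never goes below
    4 pairs (it stops instead).
    """
    from .tps import fit_tps, tps_apply

    all_s, all_t = pairs.source_xy(), pairs.target_xy()
    inliers = np.ones(len(pairs), dtype=bool)
    for _ in range(max_iter):
        model = fit_tps(all_s[inliers], all_t[inliers], reg_lambda=lam)
        # re-score every pair against the current smooth field, so a pair
        # trimmed by an outlier-contaminated early fit can re-enter
        resid = np.hypot(*(tps_apply(model, all_s) - all_t).T)
        new_inliers = resid <= threshold_px
        if new_inliers.sum() < 4 or (new_inliers == inliers).all():
            break
        inliers = new_inliers
    return ControlPointPairs([m for m, k in zip(pairs, inliers) if k])


def merge_control_pairs(
    strict: MatchSet, relaxed_revised: MatchSet, anms_n: int = 40, anms_c_robust: float = 0.9
) -> ControlPointPairs:
    """Union of both tiers, thinned by ANMS over the source points.

    On a duplicate source point the strict pair wins.  ANMS uses the
    negative cost as response so cheap (reliable) pairs dominate; at most
    ``anms_n`` spatially spread pairs are returned.  Fewer than 4 survivors
    raise :class:`UnderdeterminedPairsError` (a TPS needs >= 4 anchors).
    """
    by_src: dict[tuple[float, float], Match] = {}
    for m in relaxed_revised:
        by_src[(m.source.x, m.source.y)] = m
    for m in strict:
        by_src[(m.source.x, m.source.y)] = m  # strict precedence
    merged = list(by_src.values())
    if len(merged) < 4:
        raise UnderdeterminedPairsError(
            f"only {len(merged)} control pairs after merging; >= 4 needed for TPS"
        )
    proxies = [
        FeaturePoint(x=m.source.x, y=m.source.y, response=-m.cost, kind=m.source.kind)
        for m in merged
    ]
    kept = anms(proxies, n_target=anms_n, c_robust=anms_c_robust)
    index = {(p.x, p.y): p.suppression_radius for p in kept}
    out = ControlPointPairs(
        [m for m in merged if (m.source.x, m.source.y) in index]
    )
    if len(out) < 4:
        raise UnderdeterminedPairsError(
            f"only {len(out)} control pairs after ANMS; >= 4 needed for TPS"
        )
    return out
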