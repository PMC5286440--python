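"""Thin-plate-spline (TPS) warps anchored on control-point pairs.

A TPS is the minimal-bending-energy interpolant of a 2-D displacement
field.  Each output coordinate is an affine part plus a radial-kernel sum

    x' = a1 + ax*x + ay*y + sum_j w_j U(r_j),      U(r) = r^2 log(r^2)

with ``r_j`` the distance from the evaluated point to the j-th anchor and
``U(0) = 0``.  The coefficients come from the linear system
``L [w; a] = [targets; 0]`` where

    L = [[K + lam*I, P],
         [P^T,       0]],   K_ij = U(|anchor_i - anchor_j|),  P_i = (1, x_i, y_i).

The zero block enforces the side conditions sum w_j = sum w_j x_j =
sum w_j y_j = 0, which make the kernel part square-integrable; with
``lam = 0`` the model interpolates its anchors exactly, ``lam > 0`` trades
exactness for smoothness on noisy pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist

from .image import Image

__all__ = ["TPSModel", "fit_tps", "tps_apply", "warp_image", "tps_kernel"]


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log(r^2), with the removable singularity U(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz] ** 2)
    return out


@dataclass(frozen=True)
class TPSModel:
    """Fitted thin-plate-spline map R^2 -> R^2.

    ``affine`` is a (2, 3) array of rows (a1, ax, ay) for x' and y';
    ``weights`` is (n, 2) non-affine coefficients, one column per output
    coordinate; ``anchors`` the (n, 2) control points of the input side.
    """

    anchors: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    reg_lambda: float = 0.0

    @property
    def n_anchors(self) -> int:
        return self.anchors.shape[0]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_apply(self, points)

    def bending_energy(self) -> float:
        """w^T K w summed over the two output coordinates (>= 0)."""
        K = tps_kernel(cdist(self.anchors, self.anchors))
        return float(sum(self.weights[:, d] @ K @ self.weights[:, d] for d in range(2)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "anchors": self.anchors.tolist(),
                    "affine": self.affine.tolist(),
                    "weights": self.weights.tolist(),
                    "reg_lambda": self.reg_lambda,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TPSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            anchors=np.asarray(d["anchors"], dtype=float),
            affine=np.asarray(d["affine"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            reg_lambda=float(d["reg_lambda"]),
        )


class TPSFitError(ValueError):
    """Raised when the TPS system is degenerate (collinear or conflicting anchors)."""


def fit_tps(anchors: np.ndarray, targets: np.ndarray, reg_lambda: float = 0.0) -> TPSModel:
    """Fit a TPS mapping ``anchors`` onto ``targets``.

    Exact duplicate anchors with identical targets are collapsed; duplicates
    with conflicting targets are rejected.  Requires >= 4 distinct,
    non-collinear anchors and ``reg_lambda >= 0``.
    """
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if anchors.shape != targets.shape or anchors.shape[1] != 2:
        raise ValueError("anchors and targets must both be (n, 2)")
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")

    # collapse exact duplicates, rejecting contradictory ones
    uniq, inv = np.unique(anchors, axis=0, return_inverse=True)
    if uniq.shape[0] != anchors.shape[0]:
        kept_t = np.empty((uniq.shape[0], 2))
        for u in range(uniq.shape[0]):
            tt = targets[inv == u]
            if not np.allclose(tt, tt[0]):
                raise TPSFitError(f"duplicate anchor {uniq[u]} with conflicting targets")
            kept_t[u] = tt[0]
        anchors, targets = uniq, kept_t

    n = anchors.shape[0]
    if n < 4:
        raise TPSFitError(f"need >= 4 distinct control points, got {n}")

    K = tps_kernel(cdist(anchors, anchors)) + reg_lambda * np.eye(n)
    P = np.column_stack([np.ones(n), anchors])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    Y = np.zeros((n + 3, 2))
    Y[:n] = targets
    # collinear anchors make P rank-deficient and the system singular
    if np.linalg.matrix_rank(P, tol=1e-8 * max(np.abs(anchors).max(), 1.0)) < 3:
        raise TPSFitError("degenerate TPS system: anchors are collinear")
    try:
        sol = np.linalg.solve(L, Y)
    except np.linalg.LinAlgError as exc:
        raise TPSFitError(f"degenerate TPS system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise TPSFitError("degenerate TPS system produced non-finite coefficients")
    return TPSModel(
        anchors=anchors,
        affine=sol[n:].T.copy(),  # (2, 3): rows (a1, ax, ay)
        weights=sol[:n].copy(),
        reg_lambda=reg_lambda,
    )


def tps_apply(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map at ``points`` ((m, 2) or a single (2,) point)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    U = tps_kernel(cdist(pts, model.anchors))
    ones = np.column_stack([np.ones(len(pts)), pts])
    out = ones @ model.affine.T + U @ model.weights
    return out[0] if single else out


def warp_image(model: TPSModel, source: Image, out_shape: tuple[int, int]) -> Image:
    """Resample ``source`` through a *backward* TPS map.

    ``model`` must map output (target) pixel coordinates to source
    coordinates; each output pixel is bilinearly sampled from the source
    at ``model((x, y))``, with out-of-bounds samples set to 0.  Fitting the
    map backward (on swapped point pairs) avoids inverting the spline.
    """
    h, w = out_shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src_xy = tps_apply(model, pts)
    # snap coordinates that are within rounding error of a pixel center, so
    # a numerically-identity model does not leak border pixels out of bounds
    near = np.rint(src_xy)
    src_xy = np.where(np.abs(src_xy - near) < 1e-9, near, src_xy)
    # map_coordinates takes (row, col) = (y, x)
    coords = np.stack([src_xy[:, 1].reshape(h, w), src_xy[:, 0].reshape(h, w)])
    warped = map_coordinates(source.pixels, coords, order=1, mode="constant", cval=0.0)
    return Image(warped, source.bit_depth_in)
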