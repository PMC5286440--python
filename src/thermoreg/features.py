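"""Feature detection for infrared thermograms.

Two complementary landmark families are extracted:

* **Corners** — Harris response maxima with adaptive non-maximal
  suppression (ANMS), which keeps spatially spread, locally dominant
  corners instead of dense clusters on the brightest heat pattern.
* **Vascular intersections** — branch points of the thinned skeleton of
  vessel-like bright ridges.  Ridges are enhanced by analysing the two
  Hessian eigenvalues per pixel (a bright ridge has one strongly negative
  eigenvalue across the vessel and a near-zero one along it), thresholded
  with Otsu's rule, thinned to a 1-pixel skeleton, and skeleton pixels
  with >= 3 skeleton neighbours are clustered into junctions whose
  barycenters become the landmarks.

Coordinates follow the package convention: x = column, y = row, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist, squareform
from skimage.feature import corner_harris, hessian_matrix, hessian_matrix_eigvals, peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .image import Image

__all__ = [
    "FeaturePoint",
    "SkeletonMap",
    "harris_corners",
    "anms",
    "vessel_map",
    "skeletonize",
    "skeleton_intersections",
    "junction_barycenters",
    "detect_features",
]


@dataclass(frozen=True)
class FeaturePoint:
    """A located landmark with detector response.

    ``suppression_radius`` is set by :func:`anms` (NaN until then): the
    distance to the nearest point that is decisively stronger.
    """

    x: float
    y: float
    response: float
    kind: Literal["corner", "vessel_intersection"] = "corner"
    suppression_radius: float = float("nan")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class SkeletonMap:
    """1-pixel-thin binary skeleton, same shape as the image it came from."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def harris_corners(
    img: Image, sigma: float = 2.0, k: float = 0.04, rel_threshold: float = 0.01
) -> list[FeaturePoint]:
    """Harris corner maxima above ``rel_threshold * max(R)``.

    The response is ``R = det(M) - k * trace(M)^2`` with M the
    Gaussian-windowed gradient autocorrelation matrix at scale ``sigma``.
    A constant image yields no corners.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0.04 <= k <= 0.06:
        raise ValueError("k outside the customary [0.04, 0.06] range")
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    if img.pixels.max() - img.pixels.min() < 1e-12:
        return []  # zero gradients everywhere
    R = corner_harris(img.pixels, method="k", k=k, sigma=sigma)
    if R.max() <= 0:
        return []
    # the response is padded with zeros, so the border rim carries phantom
    # corners on any non-dark image; exclude it
    border = max(1, int(round(2 * sigma)))
    peaks = peak_local_max(
        R, min_distance=1, threshold_abs=rel_threshold * R.max(), exclude_border=border
    )
    return [
        FeaturePoint(x=float(c), y=float(r), response=float(R[r, c]), kind="corner")
        for r, c in peaks
    ]


def anms(points: list[FeaturePoint], n_target: int, c_robust: float = 0.9) -> list[FeaturePoint]:
    """Adaptive non-maximal suppression.

    Each point's suppression radius is its distance to the nearest point
    whose response, damped by ``c_robust``, still exceeds its own; the
    global maximum gets an infinite radius.  The ``n_target`` points of
    largest radius are returned (all points, radii set, when fewer exist),
    ordered by decreasing radius.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if not 0 < c_robust <= 1:
        raise ValueError("c_robust must be in (0, 1]")
    if not points:
        return []
    xy = np.array([[p.x, p.y] for p in points])
    resp = np.array([p.response for p in points])
    n = len(points)
    radii = np.full(n, np.inf)
    if n > 1:
        D = squareform(pdist(xy))
        # stronger[i, j]: j suppresses i
        stronger = (c_robust * resp)[None, :] > resp[:, None]
        D_masked = np.where(stronger, D, np.inf)
        radii = D_masked.min(axis=1)
    order = np.lexsort((np.arange(n), -resp, -radii))  # radius desc, response desc, index
    keep = order[: min(n_target, n)]
    return [replace(points[i], suppression_radius=float(radii[i])) for i in keep]


def vessel_map(img: Image, sigma_v: float = 2.0) -> tuple[Image, np.ndarray]:
    """Bright-ridge (vessel) likelihood from per-pixel Hessian eigenvalues.

    At scale ``sigma_v`` the eigenvalues are ordered |l1| <= |l2|.  A bright
    curvilinear vessel has l2 << 0 across its axis and l1 ~ 0 along it, so
    the likelihood is ``|l2| * exp(-(l1/l2)^2 / (2 beta^2))`` where l2 < 0
    (beta = 0.5), which suppresses isotropic blobs (|l1| ~ |l2|).  The
    binary mask applies Otsu's threshold to the nonzero likelihoods.

    Returns ``(likelihood image, mask)``.
    """
    if sigma_v <= 0:
        raise ValueError("sigma_v must be > 0")
    H = hessian_matrix(img.pixels, sigma=sigma_v, mode="reflect", use_gaussian_derivatives=True)
    ev = hessian_matrix_eigvals(H)  # sorted descending: ev[0] >= ev[1]
    # order by magnitude: l1 small, l2 large
    mags = np.abs(ev)
    swap = mags[0] > mags[1]
    l1 = np.where(swap, ev[1], ev[0])
    l2 = np.where(swap, ev[0], ev[1])
    beta = 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
    like = np.where(l2 < 0, np.abs(l2) * np.exp(-ratio2 / (2 * beta**2)), 0.0)
    nz = like[like > 1e-12]
    if nz.size == 0 or nz.min() == nz.max():
        mask = np.zeros_like(like, dtype=bool)
    else:
        mask = like >= threshold_otsu(nz)
    return Image(like), mask


def skeletonize(mask: np.ndarray) -> SkeletonMap:
    """Thin a binary mask to a 1-pixel skeleton preserving 8-connectivity."""
    return SkeletonMap(_sk_skeletonize(np.asarray(mask, dtype=bool)))


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_intersections(skel: SkeletonMap) -> list[np.ndarray]:
    """Raw junction pixel clusters of a thin skeleton.

    A skeleton pixel is a raw junction iff it has >= 3 skeleton neighbours
    in its 8-neighbourhood.  Junction pixels are grouped into 8-connected
    clusters; each cluster is returned as an (m, 2) array of (x, y) pixels.
    """
    m = skel.mask
    nb = ndimage.convolve(m.astype(int), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    junction = m & (nb >= 3)
    labels, n_lab = ndimage.label(junction, structure=np.ones((3, 3), dtype=int))
    clusters = []
    for lab in range(1, n_lab + 1):
        rr, cc = np.nonzero(labels == lab)
        clusters.append(np.column_stack([cc, rr]).astype(float))
    return clusters


def junction_barycenters(raw: list[np.ndarray], merge_radius: float = 8.0) -> list[FeaturePoint]:
    """Merge nearby junction clusters and return their barycenters.

    Clusters whose centroids lie within ``merge_radius`` of each other
    (transitively) are merged; each output landmark is the centroid of the
    merged pixels with the pixel count as its response.
    """
    if merge_radius < 1:
        raise ValueError("merge_radius must be >= 1")
    if not raw:
        return []
    centroids = np.array([c.mean(axis=0) for c in raw])
    # single-linkage merge: connected components of the within-radius graph
    adj = cdist(centroids, centroids) <= merge_radius
    n_comp, comp = connected_components(adj, directed=False)
    out = []
    for g in range(n_comp):
        pix = np.vstack([raw[i] for i in np.nonzero(comp == g)[0]])
        cx, cy = pix.mean(axis=0)
        out.append(
            FeaturePoint(
                x=float(cx), y=float(cy), response=float(len(pix)), kind="vessel_intersection"
            )
        )
    out.sort(key=lambda p: (-p.response, p.x, p.y))
    return out


def detect_features(
    img: Image,
    harris_sigma: float = 2.0,
    harris_k: float = 0.04,
    harris_rel_threshold: float = 0.01,
    anms_n: int = 100,
    anms_c_robust: float = 0.9,
    vessel_sigma: float = 2.0,
    junction_merge_radius: float = 8.0,
) -> tuple[list[FeaturePoint], SkeletonMap, np.ndarray]:
    """Run both detectors on one image.

    Returns ``(features, skeleton, vessel_mask)`` where ``features`` is the
    ANMS-thinned corner set followed by the vascular-junction barycenters.
    """
    corners = anms(
        harris_corners(img, sigma=harris_sigma, k=harris_k, rel_threshold=harris_rel_threshold),
        n_target=anms_n,
        c_robust=anms_c_robust,
    )
    _, mask = vessel_map(img, sigma_v=vessel_sigma)
    skel = skeletonize(mask)
    junctions = junction_barycenters(skeleton_intersections(skel), merge_radius=junction_merge_radius)
    return corners + junctions, skel, mask
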