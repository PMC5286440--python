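"""Competitive winner-guided refinement of control-point positions.

Matched control points land slightly off their true anatomic positions
(different basal temperature shifts the apparent heat pattern between
visits).  This module polishes them with a self-organizing-map style
competition: candidate replacement positions ("competition units") are
laid out on a small lattice around each target-side control point, each
candidate registration is scored by the mutual information between the
re-warped source and the target, and the best candidate (the "winning
unit") pulls the control point toward it.  Other control points follow
the winner with a strength that decays with their distance from it and
with the iteration count, per the classic Kohonen update

    K(i) = EtaN(i) * exp(-d(N, N_p)^2 / (2 SigN(i)^2)),
    EtaN(i) = eta0 * (1 - i/i_max),   SigN(i) = Sig0 * (1 - i/i_max).

The competition lattices stay centered on the original control-point
positions, so the total adjustment of any point is bounded by the lattice
reach.  Each point's update (its own move plus the neighborhood drag) is
accepted only if the masked mutual information does not drop, and a sweep
is committed only when the full-grid objective did not decrease — the
refinement can never degrade a registration it was given.  Convergence is
declared when the winner set is unchanged for three consecutive sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image import Image
from .matching import ControlPointPairs, Match
from .features import FeaturePoint
from .tps import TPSFitError, fit_tps, tps_kernel
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist

__all__ = [
    "SOMParams",
    "SOMState",
    "mutual_information",
    "competition_units",
    "find_winner",
    "som_step",
    "refine",
]


@dataclass(frozen=True)
class SOMParams:
    """Schedules and sizes of the competitive refinement.

    grid_size
        Units per lattice side (odd, >= 1); ``grid_size = 1`` disables motion.
    grid_spacing
        Lattice pitch in pixels.
    eta0
        Initial learning rate, in (0, 1].
    sig0
        Initial neighborhood radius in pixels; controls how far the
        winner's pull reaches across the control-point set.
    i_max
        Iteration budget for the linearly decaying schedules.
    mi_bins
        Joint-histogram bins for mutual information.
    accept_epsilon
        Minimum MI gain (nats) for a per-point update to be accepted;
        rejects noise-level fluctuations of the objective.
    mi_stride
        Subsampling stride of the pixel grid used for MI *during the
        winner search* (the commit decision always uses the full grid).
    stability_window
        Consecutive sweeps with an unchanged winner set required to
        declare convergence.
    """

    grid_size: int = 9
    grid_spacing: float = 1.0
    eta0: float = 0.9
    sig0: float = 1.0
    i_max: int = 30
    mi_bins: int = 32
    mi_stride: int = 1
    stability_window: int = 3
    accept_epsilon: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 1 or self.grid_size % 2 == 0:
            raise ValueError("grid_size must be odd and >= 1")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1 px")
        if not 0 < self.eta0 <= 1:
            raise ValueError("eta0 must be in (0, 1]")
        if self.i_max < self.stability_window:
            raise ValueError("i_max must be >= stability_window")


@dataclass
class SOMState:
    """Mutable optimizer state: current pairs, MI trace and bookkeeping."""

    pairs: ControlPointPairs
    iteration: int = 0
    mi_trace: list[float] = field(default_factory=list)
    committed_mi: float = -np.inf
    best_pairs: ControlPointPairs | None = None
    stable_count: int = 0
    converged: bool = False
    last_sweep_null: bool = False
    # lattice centers: the original target-side positions; the competition
    # units stay distributed around these, bounding total drift
    initial_targets: np.ndarray | None = None
    # winner positions of the previous sweep, for the stability test
    last_winners: np.ndarray | None = None


def mutual_information(a: Image, b: Image, bins: int = 32) -> float:
    """Mutual information (nats) of the joint intensity histogram.

    Both images must share a shape; only pixels finite in both enter the
    joint histogram.  MI(a, a) equals the histogram entropy of a.
    """
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    return _mi_arrays(a.pixels.ravel(), b.pixels.ravel(), bins)


def _mi_arrays(av: np.ndarray, bv: np.ndarray, bins: int) -> float:
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    if av.size == 0:
        raise ValueError("empty overlap between images")
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def competition_units(
    p: np.ndarray | tuple[float, float],
    G: int,
    s: float,
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """G x G lattice of candidate positions centered at ``p`` (spacing s).

    Units falling outside ``image_shape`` (height, width) are clipped away;
    the center unit (p itself, offset (0, 0)) is always retained.  Units
    are ordered row-major by (dy, dx) offset, so the order is deterministic.
    """
    if G < 1 or G % 2 == 0:
        raise ValueError("G must be odd and >= 1")
    x0, y0 = float(p[0]), float(p[1])
    half = G // 2
    offs = s * np.arange(-half, half + 1)
    units = np.array([[x0 + dx, y0 + dy] for dy in offs for dx in offs])
    if image_shape is not None:
        h, w = image_shape
        keep = (
            (units[:, 0] >= 0)
            & (units[:, 0] <= w - 1)
            & (units[:, 1] >= 0)
            & (units[:, 1] <= h - 1)
        ) | np.all(np.isclose(units, [x0, y0]), axis=1)
        units = units[keep]
    return units


def structure_mask(img: Image, dilate_px: int = 2) -> np.ndarray:
    """Scoring mask for the competitive MI objective: dilated vessel ridges.

    Over the full frame the featureless warm background dominates the
    joint histogram, and a warp can "improve" MI by reshaping it without
    improving the geometric alignment.  The vessel-like ridges are the
    high-information anatomy, so the objective is evaluated on the
    vesselness mask dilated by ``dilate_px``; an image without detectable
    vessels falls back to the full frame.
    """
    from skimage.morphology import dilation, disk

    from .features import vessel_map

    _, m = vessel_map(img)
    if not m.any():
        return np.ones(img.shape, dtype=bool)
    if dilate_px > 0:
        m = dilation(m, disk(dilate_px))
    return m


class _WarpScorer:
    """Scores candidate target-side anchor moves by mutual information.

    The backward TPS maps target coordinates to source coordinates, so its
    anchors are the target-side control points.  Moving one anchor changes
    one column of the grid kernel matrix and one row/column of the fit
    system; the grid kernel columns for the unmoved anchors are cached,
    which makes a winner search over many candidates cheap.

    ``mask`` (target-shaped, bool) optionally restricts the pixels entering
    the joint histogram (see :func:`structure_mask`).
    """

    def __init__(self, source: Image, target: Image, pairs_src: np.ndarray,
                 pairs_tgt: np.ndarray, mi_bins: int, stride: int = 1,
                 mask: np.ndarray | None = None):
        self.source = source
        self.target = target
        self.src = pairs_src
        self.tgt = pairs_tgt
        self.mi_bins = mi_bins
        h, w = target.shape
        ys, xs = np.mgrid[0:h:stride, 0:w:stride]
        grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        tvals = target.pixels[::stride, ::stride].ravel()
        if mask is not None:
            keep = mask[::stride, ::stride].ravel()
            grid, tvals = grid[keep], tvals[keep]
        self.grid = grid
        self.tvals = tvals
        self.U = tps_kernel(cdist(self.grid, self.tgt))

    def score(self, idx: int | None, candidate: np.ndarray | None) -> float:
        """MI of the registration with anchor ``idx`` moved to ``candidate``.

        ``idx=None`` scores the current configuration.  Returns -inf when
        the TPS fit for the candidate is degenerate.
        """
        tgt = self.tgt
        U = self.U
        if idx is not None:
            tgt = tgt.copy()
            tgt[idx] = candidate
            col = tps_kernel(
                np.hypot(self.grid[:, 0] - candidate[0], self.grid[:, 1] - candidate[1])
            )
            U = U.copy()
            U[:, idx] = col
        try:
            model = fit_tps(tgt, self.src, reg_lambda=0.0)
        except TPSFitError:
            return -np.inf
        # evaluate the backward map on the cached grid kernel
        if model.anchors.shape[0] != tgt.shape[0]:
            # duplicate anchors were collapsed inside fit_tps; fall back
            src_xy = model(self.grid)
        else:
            ones = np.column_stack([np.ones(len(self.grid)), self.grid])
            src_xy = ones @ model.affine.T + U @ model.weights
        # cval=0 keeps every pixel in the joint histogram: pushing content
        # out of bounds cannot shrink the overlap and fake an MI gain
        vals = map_coordinates(
            self.source.pixels,
            np.stack([src_xy[:, 1], src_xy[:, 0]]),
            order=1,
            mode="constant",
            cval=0.0,
        )
        return _mi_arrays(vals, self.tvals, self.mi_bins)


def find_winner(
    pairs: ControlPointPairs,
    idx: int,
    units: np.ndarray,
    source: Image,
    target: Image,
    mi_bins: int = 32,
    _scorer: _WarpScorer | None = None,
) -> tuple[np.ndarray, float]:
    """Winning competition unit for control point ``idx``.

    Each unit replaces the target-side point, the backward TPS is refit,
    the source re-warped and scored by MI against the target; the argmax
    wins.  Ties break toward the unit nearest the current position, then
    the lowest lattice index.  All units failing the TPS fit is an error.
    """
    if not 0 <= idx < len(pairs):
        raise IndexError("control point index out of range")
    scorer = _scorer or _WarpScorer(
        source, target, pairs.source_xy(), pairs.target_xy(), mi_bins
    )
    cur = pairs.target_xy()[idx]
    scores = np.array([scorer.score(idx, u) for u in units])
    if not np.isfinite(scores).any():
        raise RuntimeError("no viable competition unit (all TPS fits failed)")
    best = scores.max()
    cand = np.nonzero(scores >= best - 1e-12)[0]
    d = np.hypot(units[cand, 0] - cur[0], units[cand, 1] - cur[1])
    win = cand[np.lexsort((cand, d))][0]
    return units[win].copy(), float(scores[win])


def _with_targets(pairs: ControlPointPairs, tgt: np.ndarray) -> ControlPointPairs:
    new = [
        Match(
            m.source,
            FeaturePoint(
                x=float(tgt[i, 0]), y=float(tgt[i, 1]),
                response=m.target.response, kind=m.target.kind,
            ),
            m.cost,
            m.provenance,
        )
        for i, m in enumerate(pairs)
    ]
    return ControlPointPairs(new)


def som_step(
    state: SOMState,
    params: SOMParams,
    source: Image,
    target: Image,
    order: np.ndarray | None = None,
) -> SOMState:
    """One full sweep of winner-guided updates over all control points.

    For each control point in ``order``: find its winner, move it toward
    the winner by ``EtaN(i)``, and move every other control point by the
    same offset damped by the Kohonen kernel ``K(i)``.  After the sweep
    the full-resolution MI is recomputed; the sweep is committed only if
    it did not decrease, otherwise reverted (a "null move").
    """
    if state.converged or state.iteration >= params.i_max:
        raise RuntimeError("optimizer already finished")
    i = state.iteration
    decay = 1.0 - i / params.i_max
    eta = params.eta0 * decay
    sig = max(params.sig0 * decay, 1e-6)

    src_xy = state.pairs.source_xy()
    tgt_xy = state.pairs.target_xy()
    n = len(state.pairs)
    order = np.arange(n) if order is None else order
    shape = target.shape
    centers = state.initial_targets if state.initial_targets is not None else tgt_xy.copy()
    reach = params.grid_spacing * (params.grid_size // 2)
    mask = structure_mask(target)

    scorer = _WarpScorer(source, target, src_xy, tgt_xy, params.mi_bins,
                         stride=params.mi_stride, mask=mask)
    mi_cur = scorer.score(None, None)
    all_center = True
    winners = np.empty_like(tgt_xy)
    for k in order:
        units = competition_units(centers[k], params.grid_size, params.grid_spacing, shape)
        cur_pairs = _with_targets(state.pairs, tgt_xy)
        winner, _ = find_winner(cur_pairs, int(k), units, source, target,
                                params.mi_bins, _scorer=scorer)
        winners[k] = winner
        offset = winner - tgt_xy[k]
        if np.hypot(*offset) > 1e-9:
            all_center = False
            dists = np.hypot(*(tgt_xy - tgt_xy[k]).T)
            K = eta * np.exp(-(dists**2) / (2 * sig**2))
            K[k] = eta  # the winner's own point moves by the full learning rate
            proposed = tgt_xy + K[:, None] * offset[None, :]
            # the neighborhood restricts the adjustment range: no point may
            # leave its own competition lattice
            proposed = np.clip(proposed, centers - reach, centers + reach)
            prop_U = tps_kernel(cdist(scorer.grid, proposed))
            old_tgt, old_U = scorer.tgt, scorer.U
            scorer.tgt, scorer.U = proposed, prop_U
            # vet each point's update: the partial (EtaN-scaled) move plus the
            # neighborhood drag is not the configuration the winner search
            # scored, so accept it only if it does not lower the objective
            if scorer.score(None, None) >= mi_cur + params.accept_epsilon:
                tgt_xy = proposed
                mi_cur = scorer.score(None, None)
            else:
                scorer.tgt, scorer.U = old_tgt, old_U

    # commit decision at full resolution
    full = _WarpScorer(source, target, src_xy, tgt_xy, params.mi_bins, stride=1,
                       mask=mask)
    mi_new = full.score(None, None)
    new_state = replace_state(state)
    if mi_new >= state.committed_mi:
        new_state.pairs = _with_targets(state.pairs, tgt_xy)
        new_state.committed_mi = mi_new
        new_state.best_pairs = new_state.pairs
        new_state.last_sweep_null = False
    else:
        new_state.last_sweep_null = True
    new_state.mi_trace = state.mi_trace + [new_state.committed_mi]
    new_state.iteration = i + 1
    # stability: no point moved, or every winner unchanged since last sweep
    stable = all_center or (
        state.last_winners is not None and np.allclose(winners, state.last_winners)
    )
    new_state.last_winners = winners
    new_state.stable_count = state.stable_count + 1 if stable else 0
    if new_state.stable_count >= params.stability_window:
        new_state.converged = True
    return new_state


def replace_state(s: SOMState) -> SOMState:
    return SOMState(
        pairs=s.pairs,
        iteration=s.iteration,
        mi_trace=list(s.mi_trace),
        committed_mi=s.committed_mi,
        best_pairs=s.best_pairs,
        stable_count=s.stable_count,
        converged=s.converged,
        last_sweep_null=s.last_sweep_null,
        initial_targets=s.initial_targets,
        last_winners=s.last_winners,
    )


def refine(
    pairs: ControlPointPairs,
    source: Image,
    target: Image,
    params: SOMParams | None = None,
) -> tuple[ControlPointPairs, SOMState]:
    """Iterate :func:`som_step` to convergence or the iteration budget.

    Returns the best-MI committed configuration and the final state
    (``state.converged`` is False when the budget ran out first).  Sweep
    order is a seeded permutation per iteration, so the whole refinement
    is deterministic given ``params.seed``.
    """
    params = params or SOMParams()
    if len(pairs) < 4:
        raise ValueError("refinement needs >= 4 control pairs")
    rng = np.random.default_rng(params.seed)
    mask = structure_mask(target)
    full = _WarpScorer(source, target, pairs.source_xy(), pairs.target_xy(),
                       params.mi_bins, stride=1, mask=mask)
    state = SOMState(pairs=pairs, committed_mi=full.score(None, None), best_pairs=pairs,
                     initial_targets=pairs.target_xy())
    state.mi_trace.append(state.committed_mi)
    while not state.converged and state.iteration < params.i_max:
        order = rng.permutation(len(state.pairs))
        state = som_step(state, params, source, target, order=order)
    return state.best_pairs or pairs, state
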