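# Methods

`thermoreg` registers longitudinal single-channel infrared (IR) images of
the same subject — an earlier "source" frame onto a later "target" frame —
without skin markers. The anatomy it relies on is the heat pattern:
subject-specific bright regions and vessel-like ridges whose geometry is
stable across visits even when the basal temperature is not. This note
records the model, the parameters that matter, the numerical choices, and
what the synthetic validation does and does not show.

## Pipeline

1. **Feature detection.** Two landmark families per frame:
   * *Corners*: Harris response `R = det(M) − k·trace(M)²` (Gaussian-window
     scale `harris_sigma = 2 px`, `k = 0.04`), local maxima above
     `0.01·max(R)`, thinned by adaptive non-maximal suppression (ANMS).
     ANMS assigns each point the distance to its nearest decisively
     stronger neighbour (`c_robust = 0.9` damping; the global maximum gets
     ∞) and keeps the `anms_n = 100` largest-radius points — spatially
     spread rather than merely strongest.
   * *Vascular intersections*: per-pixel Hessian eigenvalues at scale
     `vessel_sigma = 2 px` (order by magnitude, |λ1| ≤ |λ2|); bright-ridge
     likelihood `|λ2|·exp(−(λ1/λ2)²/(2·0.5²))` where λ2 < 0, zero
     elsewhere; Otsu threshold on the nonzero likelihoods; morphological
     thinning to a 1-px skeleton; skeleton pixels with ≥ 3 skeleton
     neighbours form junction clusters; clusters whose centroids lie
     within `junction_merge_radius = 8 px` merge, and their barycenters
     are the landmarks. The ≥ 3-neighbour rule is our concrete reading of
     junction-finding by connected-area labeling; the merge radius absorbs
     the multi-pixel clusters a thinned crossing leaves behind.

2. **Relaxation matching** (permissive tier). Each source feature carries a
   `relax_window = 21 px` window of gradient directions (central
   differences; zero-magnitude pixels flagged and excluded). Every target
   position within `relax_search_radius = 30 px` is scored by the sum of
   absolute circular angle differences (SAD); the discrete minimum is
   refined to sub-pixel precision by an axis-wise three-point parabola
   (clipped to half a pixel; an exact-zero match stays exactly integer),
   and the resulting displacement is applied to the original sub-pixel
   source point. Many pairs, mismatches tolerated by design.

3. **Strict matching** (reliable tier). Each feature gets a dual-map shape
   context: 12 angular × 5 radial log-polar bins (radial edges log-uniform
   from `R/16` to `R`, `sc_radius R = 100 px`) counted over the vascular
   skeleton, concatenated with the same 60 bins over the binarized
   (Otsu) heat pattern; each half normalized to unit sum. Costs are
   χ²/2 distances in [0, 2]. A minimum-total-cost one-to-one assignment
   (Hungarian) is filtered to pairs that are their row *and* column
   minimum and beat the second-best alternative in both directions:
   `C(i,j)/C(i_sec,j) ≤ T` and `C(i,j)/C(i,j_sec) ≤ T`, with
   `T = (R − r_s)/R` and `r_s` the median ANMS suppression radius of the
   source features. Few pairs, essentially all correct.

4. **Matching vectors.** Because the two body sides deform differently,
   strict-pair displacements train one representative vector per side of
   the vertical midline — the component-wise *median*, robust to a
   residual bad pair. Relaxed matches deviating more than
   `vector_tol_px = 10 px` from their side's vector are discarded; a side
   without strict support keeps nothing.

5. **Merge, de-cluster, trim.** Union of strict and revised-relaxed pairs
   (strict wins a duplicated source point); ANMS over source points with
   −cost as response keeps ≤ `merge_anms_n = 40` spread pairs. A
   *consensus trim* then fits a heavily regularized TPS
   (`trim_lambda = 2000`) to all pairs and iteratively drops pairs whose
   target deviates > `trim_threshold_px = 3 px` from that smooth field
   (re-scoring all pairs each round so early casualties can re-enter).
   Rationale: a wrong strict pair whose displacement happens to match the
   per-side median evades step 4 but, if it disagrees with the local
   deformation, visibly tears the interpolating spline; conversely a
   wrong pair consistent with the smooth field cannot damage the warp and
   is deliberately left alone. Fewer than 4 surviving pairs abort the
   pipeline with the starving stage named.

6. **Thin-plate spline.** `U(r) = r² log r²` with `U(0) = 0`; affine part
   plus kernel weights solved from `L·[w; a] = [targets; 0]` with the side
   conditions `Σw = Σw·x = Σw·y = 0`; `reg_lambda = 0` interpolates the
   control pairs exactly. Images are resampled through the *backward*
   model (fit on swapped pairs, target → source) with bilinear
   interpolation and zero fill, so no spline inversion is needed; the
   forward model is fitted alongside for reporting correspondences and
   transforming point sets. Collinear anchors are rejected by a rank test
   on the affine design matrix (the raw system is reported singular only
   unreliably in floating point).

7. **Competitive winner-guided refinement (SOM).** Candidate replacement
   positions for each target-side control point lie on a `grid_size` ×
   `grid_size` lattice with `grid_spacing = 1 px` centered on the point's
   *original* position, which bounds total drift to the lattice reach.
   Standalone refinement defaults to a 9 × 9 lattice (±4 px reach); the
   pipeline uses 5 × 5 (±2 px), since post-trim control pairs are already
   within ~1.5 px and a short leash caps the harm a noisy objective can
   do. Each candidate is scored by refitting the backward TPS and
   measuring the mutual information (MI, 32-bin joint histogram) between
   the re-warped source and the target, evaluated over the dilated
   vesselness mask of the target (`som.structure_mask`): over the full
   frame the featureless warm background dominates the histogram and MI
   gains decouple from geometric alignment. The winner pulls its point by
   `EtaN(i) = eta0·(1 − i/i_max)` (`eta0 = 0.9`) and drags every other
   point by `K(i) = EtaN(i)·exp(−d²/(2·SigN(i)²))`,
   `SigN(i) = sig0·(1 − i/i_max)` with `sig0 = 1 px` — effectively only
   immediate neighbours. Each point's update is accepted only if the
   masked MI rises by at least `accept_epsilon = 1e-3` nats (noise-level
   fluctuations rejected); a whole sweep is committed only if the
   full-grid objective did not decrease, so the committed MI trace is
   non-decreasing and the refinement cannot un-register a pair it was
   given. Convergence: the winner set unchanged for 3 consecutive sweeps,
   or the `i_max = 30` budget. The per-candidate refit is exact — one
   kernel column is recomputed per candidate, which keeps the search
   affordable.

   Wide neighbourhoods (tens of pixels) were tried and discarded: with
   ~20 control points on a 128-px frame they couple the whole point set
   nearly rigidly, so any single-point correction drags the rest off and
   is rejected. Winner-search MI runs at full grid resolution
   (`mi_stride = 1`); subsampling measurably blurred the argmax.

8. **Evaluation.** SSIM (Gaussian window, σ = 1.5, data range 1);
   full-frame MI; coincidence rate of delineated curves = 100·|overlap|/
   |union| where a pixel overlaps if it lies within `tol_px` (dilation, 1
   px default) of the other curve — symmetric and monotone in the
   tolerance, exact Jaccard at tolerance 0; Canny-edge overlays (white =
   source-only, red = target-only, green = agreeing within 1 px); and
   min/max/mean Euclidean marker errors.

## Coordinates, intensities, determinism

0-based, `x` = column, `y` = row, pixel centers at integers; point files
store `(x, y)`. Files are scaled to [0, 1] by the *format* maximum at
read time (so absolute levels compare across a series); the pipeline
additionally min–max normalizes each frame, which removes the global
intensity offset between visits before any threshold is applied. The
only stochastic element is the SOM sweep order, drawn from
`PipelineConfig.seed`; two runs with identical inputs and seed are
bit-identical. Every stage logs its survivor count so a starved pipeline
is diagnosable from the log.

## Synthetic scenes

Clinical IR series are not deposited, so validation uses generated
scenes: an anisotropic Gaussian warm blob (peak 0.5), a wavy vessel trunk
with 5 side branches rendered as Gaussian-profile ridges (width 3 px,
brightness 0.35) whose sprout points are recorded as true junctions,
additive Gaussian noise (σ = 0.01), a global intensity offset (0.05)
for the second visit, and a smooth ground-truth warp (identity,
translation, or a 9-anchor TPS rescaled so its *grid-wide* maximum
displacement equals the stated bound, redrawn if the sampled Jacobian
ever turns negative). Landmark pairs are exact under the warp; rendering
is a pure function of (scene, warp, seeds).

What this emulates: bright curvilinear structure on a smooth warm
background, inter-visit offsets, sensor noise, smooth non-rigid motion.
What it does not: real vascular branching density and tortuosity,
spatially varying emissivity, pose changes out of plane, devices or
dressings occluding the field, and the richer texture of true
thermograms. Passing here shows the machinery is correct and the
pipeline recovers known smooth warps on IR-like structure; it does not
certify clinical accuracy.

## Problem sizes and observed behaviour

Default scenes are 128 × 128 px with ~15–25 control pairs surviving to
the spline; an end-to-end run takes ~10–30 s on one CPU. On ten
generator seeds with a 15-px ground-truth TPS warp, the full pipeline
brings mean landmark error to ≤ 2 px on 9/10 seeds (typically ~1.2 px)
with SSIM improved on 10/10; the consensus trim is what removes the rare
field-inconsistent strict pair, and the SOM stage shifts the error by a
few tenths of a pixel either way on these low-texture scenes (one seed
in ten gains ~0.5 px while its masked MI rises — a known limit of an
intensity-only objective where structure is sparse). A deliberately
misplaced control point (4 px) is pulled back within 2 px on 8/10
scenes; on a perfectly registered pair the refinement is exactly
stationary.

## Degenerate inputs and tie-breaks

Constant images yield no features (explicit early exits; the Hessian
uses reflect boundaries and the Harris peak search excludes a 2σ border
rim where zero-padding manufactures phantom corners). Descriptor windows
must fit inside the frame; border points are simply not describable.
`sc_cost` treats 0/0 bins as 0. Winner ties break toward the unit
nearest the current position, then the lowest lattice index. ANMS orders
by radius, then response, then input index. An all-zero shape-context
half stays all-zero rather than being normalized.

## Known limitations

* The MI objective is only as geometric as the image structure allows;
  on nearly blank regions the refinement is intentionally conservative
  (epsilon-gated) rather than accurate.
* Matching vectors assume the per-side deformation has a meaningful
  median; pathological fields (e.g. strong rotation) would need more
  sides or a local model.
* The relaxation tier's sub-pixel refinement assumes a locally quadratic
  SAD valley; registration accuracy below ~1/4 px still comes from the
  spline averaging over many pairs, not from any single correspondence.
* Frames are treated as already roughly comparable in scale and
  orientation, as consecutive-visit imaging of the same subject warrants;
  there is no global pre-alignment stage.
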