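"""Two-depth-plane figure-ground loop (model V2 <-> V4).

Completed 2D boundaries are projected identically onto a near (D1) and far
(D2) plane — in 2D-picture mode every boundary is initially depth-ambiguous.
Three near-to-far asymmetries then sculpt the stack:

* boundary pruning: surface contours from a successfully contained fill at a
  depth strengthen the same-depth boundaries and suppress boundaries at the
  same positions on *farther* planes, never the reverse;
* surface pruning: feature-contour sources captured at the near plane are
  deleted from the far plane;
* boundary enrichment: near-plane boundaries are added to the far plane
  before visible-surface (V4) filling-in.

The disparity filter makes boundaries at the two depths compete at each
(position, orientation) in proportion to their relative strength, and
top-down attention (ART matching: modulatory on-center, subtractive
off-surround) lets V4's filled surfaces strengthen their generative V2
boundaries.  The readout assigns the farther plane to the side of the
completed contour that carries end-gap remnants: the central region's depth
margin is the normalized difference in near-plane surface capture between
the central region and its surround.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from fgseg._convolve import KernelBank, gaussian_kernel
from fgseg.config import (DepthParams, FillingParams, GroupingParams,
                          PipelineConfig, DEFAULT_CONFIG)
from fgseg.early_vision import (FeatureContourField, complex_cells,
                                discount_illuminant, simple_cells)
from fgseg.errors import ConvergenceError, ShapeError
from fgseg.filling import (SurfaceContourField, SurfaceField, fill_in,
                           region_labels, surface_contours)
from fgseg.grouping import (BoundaryField, GapAnalysis, bipole_step,
                            detect_end_gaps, normalize_driving,
                            settle_boundaries)
from fgseg.stimuli import LuminanceImage

NEAR, FAR = "D1", "D2"


@dataclass
class DepthBoundaryStack:
    """Boundary activity per depth plane (near D1, far D2)."""

    d1: BoundaryField
    d2: BoundaryField

    def __post_init__(self):
        if self.d1.activity.shape != self.d2.activity.shape:
            raise ShapeError("depth planes must share geometry")

    def copy(self) -> "DepthBoundaryStack":
        return DepthBoundaryStack(
            BoundaryField(self.d1.activity.copy(), self.d1.saturation),
            BoundaryField(self.d2.activity.copy(), self.d2.saturation))

    @property
    def saturation(self) -> float:
        return self.d1.saturation


@dataclass
class DepthSurfaceStack:
    """Filled surfaces per depth: V2 (monocular FIDO) and V4 (visible) copies."""

    v2: dict[str, SurfaceField]
    v4: dict[str, SurfaceField] = dc_field(default_factory=dict)


@dataclass(frozen=True)
class FigureGroundReport:
    """Figure-ground readout for one display."""

    central_depth: str                      # in_front | behind | same_plane
    margin: float                           # in [-1, 1]; positive = center nearer
    decision_probabilities: tuple[float, float, float]
    ownership_map: np.ndarray               # (H, W, 2) unit normals, 0 off-contour
    diagnostics: dict

    def __post_init__(self):
        p = np.asarray(self.decision_probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("decision probabilities must lie on the simplex")
        if not np.isfinite(self.margin) or not -1 <= self.margin <= 1:
            raise ValueError("margin must be finite and in [-1, 1]")
        if self.central_depth not in ("in_front", "behind", "same_plane"):
            raise ValueError(f"bad depth label {self.central_depth!r}")


def project_to_depths(boundary: BoundaryField) -> DepthBoundaryStack:
    """Copy a depth-ambiguous 2D boundary onto both depth planes.

    The copies are independent: mutating one plane leaves the other intact.
    """
    return DepthBoundaryStack(
        BoundaryField(boundary.activity.copy(), boundary.saturation),
        BoundaryField(boundary.activity.copy(), boundary.saturation))


def _norm_sc(sc: SurfaceContourField) -> np.ndarray:
    """Saturating normalization of surface-contour activity into [0, 1)."""
    a = sc.activity
    m = float(a.max())
    if m <= 0:
        return np.zeros_like(a)
    return a / (a + 0.2 * m)


def pruning_off_surround(sc_near: SurfaceContourField,
                         params: DepthParams | None = None) -> np.ndarray:
    """Normalized near-depth surface-contour signal with spatial extent.

    Surface contours are thin ridges along the fill step; the off-surround
    that prunes farther-depth boundaries must cover the few-pixel-wide
    boundary band around them, so the ridge is dilated by a small disc.
    """
    params = params or DepthParams()
    return ndimage.maximum_filter(
        _norm_sc(sc_near),
        footprint=_disc_mask(params.pruning_surround_radius))


@lru_cache(maxsize=8)
def _disc_mask(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= radius * radius


def pruning_inhibition(near_boundary: BoundaryField,
                       sc_near: SurfaceContourField,
                       params: DepthParams | None = None) -> np.ndarray:
    """Per-orientation near-to-far pruning inhibition, (K, H, W).

    The off-surround removes the *redundant copies* of the near plane's
    successful boundaries, so it is weighted by the near plane's orientation
    profile: a vertical contour's surface feedback prunes far vertical
    boundaries at those positions without cutting an unrelated horizontal
    contour passing close by.
    """
    params = params or DepthParams()
    off = pruning_off_surround(sc_near, params)
    act = near_boundary.activity
    share = act / np.maximum(act.max(axis=0, keepdims=True), 1e-12)
    return (params.pruning_off_gain * near_boundary.saturation
            * off[None, :, :] * share)


def boundary_pruning(stack: DepthBoundaryStack,
                     contours_by_depth: dict[str, SurfaceContourField],
                     params: DepthParams | None = None) -> DepthBoundaryStack:
    """On-center strengthening at the same depth, off-surround suppression of
    the same positions at farther depths (near-to-far only)."""
    params = params or DepthParams()
    sat = stack.saturation
    sc1 = _norm_sc(contours_by_depth[NEAR])
    sc2 = _norm_sc(contours_by_depth[FAR])
    off1 = pruning_inhibition(stack.d1, contours_by_depth[NEAR], params)
    d1 = np.minimum(sat, stack.d1.activity * (1 + params.pruning_on_gain * sc1))
    d2 = stack.d2.activity * (1 + params.pruning_on_gain * sc2)
    d2 = np.maximum(d2 - off1, 0.0)
    d2 = np.minimum(sat, d2)
    return DepthBoundaryStack(BoundaryField(d1, sat), BoundaryField(d2, sat))


def disparity_filter(stack: DepthBoundaryStack,
                     params: DepthParams | None = None) -> DepthBoundaryStack:
    """Across-depth, same-(position, orientation) competition.

    Each plane is suppressed in proportion to the other plane's share of the
    total: b_d <- relu(b_d - k * b_other^2 / (b_1 + b_2)).  Strong boundaries
    eliminate weak same-position ones; exact ties attenuate both equally and
    eliminate neither; single-depth content is untouched.
    """
    params = params or DepthParams()
    b1 = stack.d1.activity
    b2 = stack.d2.activity
    total = b1 + b2
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = np.where(total > 0, b2 * b2 / total, 0.0)
        s2 = np.where(total > 0, b1 * b1 / total, 0.0)
    k = params.disparity_gain
    sat = stack.saturation
    return DepthBoundaryStack(
        BoundaryField(np.maximum(b1 - k * s1, 0.0), sat),
        BoundaryField(np.maximum(b2 - k * s2, 0.0), sat))


def boundary_enrichment(stack: DepthBoundaryStack,
                        params: DepthParams | None = None
                        ) -> DepthBoundaryStack:
    """V4 copy: near boundaries added topographically to the far plane."""
    sat = stack.saturation
    e1 = BoundaryField(stack.d1.activity.copy(), sat)
    e2 = BoundaryField(
        np.minimum(sat, stack.d1.activity + stack.d2.activity), sat)
    return DepthBoundaryStack(e1, e2)


def surface_pruning(features: FeatureContourField,
                    capture_by_depth: dict[str, np.ndarray]
                    ) -> dict[str, FeatureContourField]:
    """Delete near-captured feature-contour sources from the far plane.

    ``capture_by_depth[NEAR]`` flags pixels whose sources were captured by the
    near plane; those sources are removed from the far plane's input.  Far
    capture never deletes near sources.
    """
    near_cap = capture_by_depth.get(NEAR)
    if near_cap is None:
        near_cap = np.zeros_like(features.on_activity, dtype=bool)
    keep_far = ~near_cap.astype(bool)
    return {
        NEAR: features,
        FAR: FeatureContourField(features.on_activity * keep_far,
                                 features.off_activity * keep_far),
    }


def _surround_bank(sigma: float) -> KernelBank:
    return KernelBank([gaussian_kernel(sigma)])


def top_down_attention(v4_surfaces: DepthSurfaceStack,
                       v2_stack: DepthBoundaryStack,
                       enriched: DepthBoundaryStack | None = None,
                       params: DepthParams | None = None,
                       filling_params: FillingParams | None = None
                       ) -> DepthBoundaryStack:
    """ART matching: V4 surface contours modulate their V2 boundaries.

    Multiplicative on-center gain (>= 1) at positions/depths with matched V4
    surface-contour support, subtractive suppression in a spatial off-surround
    at the same depth.  Purely modulatory: where bottom-up V2 activity is
    zero, it stays zero.
    """
    params = params or DepthParams()
    filling_params = filling_params or FillingParams()
    enriched = enriched or boundary_enrichment(v2_stack, params)
    sat = v2_stack.saturation
    surround = _surround_bank(params.attention_surround_sigma)
    out = {}
    for depth, bnd in ((NEAR, v2_stack.d1), (FAR, v2_stack.d2)):
        surf = v4_surfaces.v4.get(depth)
        if surf is None:
            out[depth] = BoundaryField(bnd.activity.copy(), sat)
            continue
        eb = enriched.d1 if depth == NEAR else enriched.d2
        sc = _norm_sc(surface_contours(surf, eb, filling_params))
        off = surround.convolve(sc)[0]
        off = np.maximum(off - sc, 0.0)  # center excluded from the surround
        a = bnd.activity * (1 + params.attention_gain * sc)
        a = np.maximum(a - params.attention_surround_gain * sat * off, 0.0)
        out[depth] = BoundaryField(np.minimum(a, sat), sat)
    return DepthBoundaryStack(out[NEAR], out[FAR])


# ---------------------------------------------------------------------------
# Full-model orchestration


def _resettle(drive: np.ndarray, inhibition: np.ndarray,
              init: BoundaryField, gp: GroupingParams,
              n_iters: int) -> BoundaryField:
    """A few bipole steps on inhibited driving input, warm-started."""
    from fgseg.early_vision import OrientedActivityField

    from fgseg.grouping import sharpen_orientations

    eff = OrientedActivityField(
        sharpen_orientations(drive, gp.orientation_sharpness))
    b = init
    for _ in range(n_iters):
        stepped = bipole_step(b, eff, gp, inhibition=inhibition)
        nxt = BoundaryField(
            b.activity + gp.relaxation * (stepped.activity - b.activity),
            saturation=gp.saturation)
        if float(np.max(np.abs(nxt.activity - b.activity))) < gp.tol:
            return nxt
        b = nxt
    return b


def _central_seed(labels: np.ndarray) -> tuple[int, int] | None:
    """A seed pixel at/near the image center lying off the boundary."""
    H, W = labels.shape
    cy, cx = H // 2, W // 2
    for r in range(0, 12):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if max(abs(dy), abs(dx)) != r:
                    continue
                y, x = cy + dy, cx + dx
                if 0 <= y < H and 0 <= x < W and labels[y, x] > 0:
                    return x, y
    return None


def _boundary_of(mask: np.ndarray) -> np.ndarray:
    """Pixels just outside ``mask`` (its bounding contour)."""
    return ndimage.binary_dilation(mask) & ~mask


def _gap_votes(gaps: GapAnalysis, center_mask: np.ndarray,
               probe: float = 6.0, min_shift: float = 1.5
               ) -> tuple[int, int]:
    """Count end-gap pixels lying on the central side vs the surround side.

    Each gap's side vector points from the head contour into the gap-bearing
    side.  Stepping a few pixels along it clears the boundary web; the vote
    is then whether the probe point falls inside the central compartment's
    bounding box (the inside of the completed contour) or beyond it.  The
    bounding-box criterion is insensitive to how the space between inducers
    fragments into sub-compartments.
    """
    if not center_mask.any():
        return 0, 0
    # strictly interior box: probes that merely graze the contour band at the
    # compartment's rim do not count as inside
    ys_c, xs_c = np.nonzero(center_mask)
    y0, y1 = ys_c.min() + 2, ys_c.max() - 2
    x0, x1 = xs_c.min() + 2, xs_c.max() - 2
    H, W = center_mask.shape
    ys, xs = np.nonzero(gaps.mask)
    n_center = n_surround = 0
    for y, x in zip(ys, xs):
        vx, vy = gaps.side_vectors[y, x]
        if vx == 0 and vy == 0:
            continue
        px = int(round(x + vx * probe))
        py = int(round(y + vy * probe))
        if not (0 <= px < W and 0 <= py < H):
            continue
        if y0 <= py <= y1 and x0 <= px <= x1:
            n_center += 1
        else:
            n_surround += 1
    return n_center, n_surround


def _support_fraction(region_mask: np.ndarray, sc: SurfaceContourField,
                      reach: int = 2) -> float:
    """Fraction of a region's bounding contour with surface-contour support."""
    contour = _boundary_of(region_mask)
    if not contour.any():
        return 0.0
    near_sc = ndimage.binary_dilation(sc.activity > 0, iterations=reach)
    return float(np.count_nonzero(contour & near_sc)) / float(
        np.count_nonzero(contour))


def ownership_labels(boundary_mask: np.ndarray, near_mask: np.ndarray
                     ) -> np.ndarray:
    """Unit normals on contour pixels pointing into the nearer region."""
    H, W = boundary_mask.shape
    ind = ndimage.gaussian_filter(near_mask.astype(float), 2.0)
    gy, gx = np.gradient(ind)
    normals = np.zeros((H, W, 2))
    ys, xs = np.nonzero(boundary_mask)
    for y, x in zip(ys, xs):
        v = np.array([gx[y, x], gy[y, x]])
        n = np.linalg.norm(v)
        if n > 1e-12:
            normals[y, x] = v / n
    return normals


@dataclass
class ModelState:
    """Converged internal state of the full model (for readout and tests)."""

    boundary: BoundaryField            # V2 monocular converged boundary
    gaps: GapAnalysis                  # end-gap analysis of that boundary
    stack: DepthBoundaryStack          # V2 depth stack after the loop
    enriched: DepthBoundaryStack       # V4 boundary copies
    surfaces: DepthSurfaceStack        # V2 and V4 fills per depth
    sc_by_depth: dict
    gap_masks_final: dict
    features: FeatureContourField
    diagnostics: dict


def run_depth_loop(image: LuminanceImage,
                   config: PipelineConfig | None = None) -> ModelState | None:
    """Settle boundaries, then iterate the V2 <-> V4 depth loop to a fixed point.

    Returns ``None`` for a featureless display (nothing to group).
    """
    config = config or DEFAULT_CONFIG
    ev, gp, fp, dp = (config.early_vision, config.grouping,
                      config.filling, config.depth)
    fc = discount_illuminant(image, ev)
    cx = complex_cells(simple_cells(image, ev))
    drive = normalize_driving(cx, ev)
    diagnostics: dict = {}
    if float(drive.activity.max()) < 1e-6:
        return None

    boundary, n_settle = settle_boundaries(drive, gp)
    diagnostics["settle_iters"] = n_settle
    gaps = detect_end_gaps(boundary, gp)
    stack = project_to_depths(boundary)
    inhib = {NEAR: np.zeros_like(stack.d1.activity),
             FAR: np.zeros_like(stack.d2.activity)}
    feats = {NEAR: fc, FAR: fc}
    outer_residual = np.inf
    sc_by_depth = {NEAR: SurfaceContourField(np.zeros(image.shape)),
                   FAR: SurfaceContourField(np.zeros(image.shape))}
    gap_masks = {}
    n_outer = 0
    enriched = boundary_enrichment(stack, dp)
    v4 = DepthSurfaceStack(v2={})
    for n_outer in range(1, dp.max_outer_iters + 1):
        prev = np.concatenate([stack.d1.activity.ravel(),
                               stack.d2.activity.ravel()])
        # V2 monocular fills and surface contours per depth
        surf = {d: fill_in(feats[d], bnd, fp, depth_label=d)
                for d, bnd in ((NEAR, stack.d1), (FAR, stack.d2))}
        sc_by_depth = {d: surface_contours(surf[d],
                                           stack.d1 if d == NEAR else stack.d2,
                                           fp)
                       for d in (NEAR, FAR)}
        stack = boundary_pruning(stack, sc_by_depth, dp)
        # pruning inhibition persists into the re-grouping passes
        inhib[FAR] = np.maximum(
            inhib[FAR], pruning_inhibition(stack.d1, sc_by_depth[NEAR], dp))
        # a clearly dominated boundary at one depth is persistently
        # suppressed by its counterpart (the disparity filter's lasting
        # effect); exact ties are exempt, so depth-ambiguous boundaries
        # survive on both planes
        b1, b2 = stack.d1.activity, stack.d2.activity
        tot = b1 + b2
        with np.errstate(invalid="ignore", divide="ignore"):
            s1 = np.where((tot > 0) & (b2 >= dp.depth_dominance_ratio * b1),
                          dp.depth_suppression_gain
                          * b2 * b2 / np.maximum(tot, 1e-12), 0.0)
            s2 = np.where((tot > 0) & (b1 >= dp.depth_dominance_ratio * b2),
                          dp.depth_suppression_gain
                          * b1 * b1 / np.maximum(tot, 1e-12), 0.0)
        inhib[NEAR] = np.maximum(inhib[NEAR], s1)
        inhib[FAR] = np.maximum(inhib[FAR], s2)
        stack = disparity_filter(stack, dp)
        enriched = boundary_enrichment(stack, dp)
        # near-depth capture: the V4 near plane fills only near-captured
        # sources (depth-selective surface capture); far-plane sources lose
        # the near-captured positions via surface pruning
        capture = _near_capture(boundary, sc_by_depth, gaps, fp, dp)
        feats_v4 = surface_pruning(fc, capture)
        if capture[NEAR].any():
            near_cap = capture[NEAR]
            feats_v4[NEAR] = FeatureContourField(
                fc.on_activity * near_cap, fc.off_activity * near_cap)
        v4 = DepthSurfaceStack(v2=surf)
        v4.v4 = {d: fill_in(feats_v4[d],
                            enriched.d1 if d == NEAR else enriched.d2,
                            fp, depth_label=d)
                 for d in (NEAR, FAR)}
        stack = top_down_attention(v4, stack, enriched, dp, fp)
        # re-group each depth on inhibited bottom-up drive
        stack = DepthBoundaryStack(
            _resettle(drive.activity, inhib[NEAR], stack.d1, gp,
                      dp.inner_bipole_iters),
            _resettle(drive.activity, inhib[FAR], stack.d2, gp,
                      dp.inner_bipole_iters))
        gap_masks = {d: detect_end_gaps(b, gp).mask
                     for d, b in ((NEAR, stack.d1), (FAR, stack.d2))}
        cur = np.concatenate([stack.d1.activity.ravel(),
                              stack.d2.activity.ravel()])
        outer_residual = float(np.max(np.abs(cur - prev)))
        if outer_residual < dp.outer_tol:
            break
    else:
        raise ConvergenceError(
            f"figure-ground loop did not converge in {dp.max_outer_iters} "
            f"outer iterations (residual {outer_residual:.3g})",
            residual=outer_residual, stage="run_full_model")
    diagnostics["outer_iters"] = n_outer
    diagnostics["outer_residual"] = outer_residual

    # Consolidation: express the surface-capture outcome at the boundary
    # level.  The near plane retains the boundaries of its captured
    # compartments (so end-gap remnants of far content vanish from the near
    # plane); the far plane regroups with the near-captured contour
    # suppressed, letting the occluded content complete behind it.
    cap = capture[NEAR]
    if cap.any() and not cap.all():
        # only the outer contour of the captured compartment counts: spurious
        # boundary web crossing the region's interior is first closed over,
        # leaving one clean bounding ring
        solid = ndimage.binary_closing(cap, structure=_disc_mask(8.0))
        rim = _boundary_of(solid)
        # wide enough to cover the full driven boundary band around the rim
        contour_zone = ndimage.binary_dilation(rim, iterations=9)
        # orientation gate: along the rim only channels aligned with the
        # rim's local tangent belong to the near contour.  The near plane
        # keeps exactly those; the far plane loses exactly those, so a
        # differently oriented occluded contour can complete behind the
        # captured surface while its redundant copy cannot re-form.
        sm = ndimage.gaussian_filter(solid.astype(float), 3.0)
        gy, gx = np.gradient(sm)
        tangent = np.arctan2(gy, gx) + np.pi / 2
        K = stack.d1.activity.shape[0]
        angles = np.arange(K) * np.pi / K
        delta = np.abs((angles[:, None, None] - tangent[None]) % np.pi)
        delta = np.minimum(delta, np.pi - delta)
        # +-45 deg (inclusive) so that at the rim's corners, where the tangent
        # estimate is diagonal, both cardinal channels still count as the
        # contour; truly perpendicular content stays free
        aligned = (delta <= np.pi / 4 + 1e-9) & contour_zone[None, :, :]
        big = 10.0 * stack.saturation
        inh1 = np.where(aligned, 0.0, big)
        inh2 = np.where(aligned, big, 0.0)
        d1_final = _resettle(drive.activity, inh1, stack.d1, gp,
                             2 * dp.inner_bipole_iters)
        d2_final = _resettle(drive.activity, inh2, stack.d2, gp,
                             2 * dp.inner_bipole_iters)
        stack = DepthBoundaryStack(d1_final, d2_final)
        gap_masks = {d: detect_end_gaps(b, gp).mask
                     for d, b in ((NEAR, stack.d1), (FAR, stack.d2))}
    diagnostics["gap_pixels_initial"] = gaps.count
    diagnostics["gap_pixels_final"] = {d: int(m.sum())
                                       for d, m in gap_masks.items()}
    return ModelState(boundary=boundary, gaps=gaps, stack=stack,
                      enriched=enriched, surfaces=v4,
                      sc_by_depth=sc_by_depth, gap_masks_final=gap_masks,
                      features=fc, diagnostics=diagnostics)


def run_full_model(image: LuminanceImage,
                   config: PipelineConfig | None = None) -> FigureGroundReport:
    """Run the complete boundary-surface pipeline on one display.

    Stages: illuminant discounting and oriented filtering -> bipole boundary
    settling -> end-gap analysis -> projection to two depth planes -> an
    outer loop of {per-depth filling-in, surface contours, boundary pruning,
    disparity filter, boundary enrichment, surface pruning, V4 filling,
    top-down attention, per-depth re-grouping} to a fixed point -> readout.
    """
    config = config or DEFAULT_CONFIG
    fp, dp = config.filling, config.depth
    from fgseg.psychophysics import choice_probabilities

    state = run_depth_loop(image, config)
    if state is None:  # featureless display
        H, W = image.shape
        probs = choice_probabilities(0.0, params=config.choice)
        return FigureGroundReport(
            central_depth="same_plane", margin=0.0,
            decision_probabilities=probs,
            ownership_map=np.zeros((H, W, 2)),
            diagnostics={"blank": True})
    diagnostics = dict(state.diagnostics)

    margin, readout = _readout(state.boundary, state.stack, state.sc_by_depth,
                               state.gaps, fp, dp)
    diagnostics.update(readout)
    if margin > dp.tau_same:
        decision = "in_front"
    elif margin < -dp.tau_same:
        decision = "behind"
    else:
        decision = "same_plane"
    probs = choice_probabilities(margin, params=config.choice)
    center_mask = readout["center_mask"]
    bmask = _boundary_of(center_mask)
    near_mask = center_mask if margin >= 0 else ~(center_mask | bmask)
    normals = ownership_labels(bmask, near_mask)
    diagnostics.pop("center_mask", None)
    return FigureGroundReport(central_depth=decision, margin=float(margin),
                              decision_probabilities=probs,
                              ownership_map=normals,
                              diagnostics=diagnostics)


def _near_capture(boundary: BoundaryField,
                  sc_by_depth: dict[str, SurfaceContourField],
                  gaps: GapAnalysis, fp: FillingParams,
                  dp: DepthParams) -> dict[str, np.ndarray]:
    """Pixels captured by the near plane: closed, gap-free compartments win.

    Scored on the initial (depth-ambiguous) compartment structure: the
    central compartment and its surround each get a capture score
    q = closure / (1 + gap_weight * gap_share); the higher-scoring side is
    captured near, the other far (ties capture both — a featureless or
    symmetric display stays depth-ambiguous).
    """
    labels = region_labels(boundary, fp)
    seed = _central_seed(labels)
    if seed is None:
        return {NEAR: np.zeros(labels.shape, dtype=bool)}
    center_label = labels[seed[1], seed[0]]
    center = labels == center_label
    surround = (labels > 0) & ~center
    q_c, q_s, _ = _capture_scores(center, surround, sc_by_depth[NEAR],
                                  gaps, dp)
    cap = np.zeros(labels.shape, dtype=bool)
    if q_c >= q_s:
        cap |= center
    if q_s >= q_c:
        cap |= surround
    return {NEAR: cap}


def _capture_scores(center, surround, sc1, gaps, dp):
    """Near-plane capture score per region.

    A region is captured by the near plane to the degree that it is a closed
    compartment whose side of the completed contour is free of end-gap
    remnants: q = closure / (1 + gap_weight * gap_share), where gap_share is
    the region's share of the end-gap votes.  Surface-contour support along
    each region's bounding contour is reported as a diagnostic.
    """
    n_c, n_s = _gap_votes(gaps, center)
    total = n_c + n_s
    f_c = n_c / total if total else 0.0
    f_s = n_s / total if total else 0.0
    q_c = 1.0 / (1.0 + dp.gap_weight * f_c)
    q_s = 1.0 / (1.0 + dp.gap_weight * f_s)
    s_c = _support_fraction(center, sc1)
    s_s = _support_fraction(surround, sc1)
    return q_c, q_s, {"gap_votes": (n_c, n_s),
                      "support": (s_c, s_s)}


def _readout(boundary: BoundaryField, stack: DepthBoundaryStack,
             sc_by_depth: dict[str, SurfaceContourField], gaps: GapAnalysis,
             fp: FillingParams, dp: DepthParams):
    """Margin = normalized difference of near-plane capture scores."""
    labels = region_labels(boundary, fp)
    seed = _central_seed(labels)
    if seed is None:
        return 0.0, {"center_mask": np.zeros(labels.shape, dtype=bool)}
    center_label = labels[seed[1], seed[0]]
    center = labels == center_label
    surround = (labels > 0) & ~center
    if not surround.any():
        return 0.0, {"center_mask": center}
    q_c, q_s, extra = _capture_scores(center, surround, sc_by_depth[NEAR],
                                      gaps, dp)
    denom = q_c + q_s
    margin = 0.0 if denom <= 0 else (q_c - q_s) / denom
    margin = float(np.clip(margin, -1.0, 1.0))
    info = {"center_mask": center, "capture_scores": (q_c, q_s)}
    info.update(extra)
    return margin, info
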