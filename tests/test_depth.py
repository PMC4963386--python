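"""Depth-plane machinery and the full figure-ground model."""

import numpy as np
import pytest

from fgseg.config import PipelineConfig
from fgseg.depth import (DepthBoundaryStack, DepthSurfaceStack, NEAR, FAR,
                         boundary_enrichment, boundary_pruning,
                         disparity_filter, project_to_depths, run_full_model,
                         surface_pruning, top_down_attention)
from fgseg.early_vision import FeatureContourField
from fgseg.filling import SurfaceContourField, SurfaceField, region_closure
from fgseg.grouping import BoundaryField
from fgseg.stimuli import BACKGROUND, LuminanceImage


def rand_boundary(seed=0, shape=(8, 24, 24), sat=1.0):
    rng = np.random.default_rng(seed)
    return BoundaryField(rng.uniform(0, sat, size=shape), saturation=sat)


def zero_sc(shape=(24, 24)):
    return SurfaceContourField(np.zeros(shape))


def test_projection_copies_both_planes():
    b = rand_boundary()
    stack = project_to_depths(b)
    np.testing.assert_array_equal(stack.d1.activity, b.activity)
    np.testing.assert_array_equal(stack.d2.activity, b.activity)
    stack.d1.activity[0, 0, 0] = 99.0  # planes are independently mutable
    assert stack.d2.activity[0, 0, 0] != 99.0
    z = project_to_depths(BoundaryField(np.zeros((8, 4, 4))))
    assert z.d1.activity.max() == 0 and z.d2.activity.max() == 0


def test_pruning_with_no_contours_is_identity():
    stack = project_to_depths(rand_boundary())
    out = boundary_pruning(stack, {NEAR: zero_sc(), FAR: zero_sc()})
    np.testing.assert_array_equal(out.d1.activity, stack.d1.activity)
    np.testing.assert_array_equal(out.d2.activity, stack.d2.activity)


def test_pruning_is_near_to_far_only():
    stack = project_to_depths(rand_boundary())
    sc = np.zeros((24, 24))
    sc[10:14, 10:14] = 1.0
    # far contours may strengthen the far plane but never reduce the near one
    out = boundary_pruning(stack, {NEAR: zero_sc(),
                                   FAR: SurfaceContourField(sc)})
    assert (out.d1.activity >= stack.d1.activity - 1e-12).all()
    np.testing.assert_array_equal(out.d1.activity, stack.d1.activity)
    # near contours do suppress the far plane
    out2 = boundary_pruning(stack, {NEAR: SurfaceContourField(sc),
                                    FAR: zero_sc()})
    assert (out2.d2.activity <= stack.d2.activity + 1e-12).all()
    assert out2.d2.activity[:, 11, 11].max() < stack.d2.activity[:, 11, 11].max()


def test_disparity_filter_properties():
    b = rand_boundary()
    # single-depth content is untouched
    stack = DepthBoundaryStack(b, BoundaryField(np.zeros_like(b.activity)))
    out = disparity_filter(stack)
    np.testing.assert_array_equal(out.d1.activity, b.activity)
    # exact ties attenuate both planes equally and eliminate neither
    tie = project_to_depths(b)
    out_tie = disparity_filter(tie)
    np.testing.assert_allclose(out_tie.d1.activity, out_tie.d2.activity)
    assert (out_tie.d1.activity[b.activity > 0.1] > 0).all()
    # a strong plane eliminates a weak same-position one
    strong = BoundaryField(np.full((8, 8, 8), 1.0))
    weak = BoundaryField(np.full((8, 8, 8), 0.2))
    out_sw = disparity_filter(DepthBoundaryStack(strong, weak))
    assert out_sw.d2.activity.max() < 0.01
    assert out_sw.d1.activity.min() > 0.9


def test_enrichment_adds_near_to_far_only():
    stack = DepthBoundaryStack(rand_boundary(1), rand_boundary(2))
    enr = boundary_enrichment(stack)
    np.testing.assert_array_equal(enr.d1.activity, stack.d1.activity)
    assert (enr.d2.activity >= stack.d2.activity - 1e-12).all()
    assert enr.d2.activity.max() <= stack.saturation + 1e-12


def test_surface_pruning_deletes_near_captured_sources_from_far():
    rng = np.random.default_rng(5)
    feats = FeatureContourField(rng.uniform(0, 1, (16, 16)),
                                rng.uniform(0, 1, (16, 16)))
    none = surface_pruning(feats, {NEAR: np.zeros((16, 16), bool)})
    np.testing.assert_array_equal(none[FAR].on_activity, feats.on_activity)
    cap = np.zeros((16, 16), bool)
    cap[4:10, 4:10] = True
    pruned = surface_pruning(feats, {NEAR: cap})
    assert pruned[FAR].on_activity[4:10, 4:10].max() == 0.0
    np.testing.assert_array_equal(pruned[NEAR].on_activity, feats.on_activity)


def test_attention_is_modulatory():
    """ART matching: feedback cannot create boundary activity where the
    bottom-up signal is zero."""
    b = np.zeros((8, 24, 24))
    b[0, 12, 4:20] = 0.8
    stack = DepthBoundaryStack(BoundaryField(b.copy()),
                               BoundaryField(b.copy()))
    surf = SurfaceField(np.pad(np.ones((12, 12)), 6) * 0.9)
    v4 = DepthSurfaceStack(v2={}, v4={NEAR: surf, FAR: surf})
    out = top_down_attention(v4, stack)
    assert (out.d1.activity[b == 0] == 0).all()
    assert (out.d2.activity[b == 0] == 0).all()


def test_attention_is_idempotent_at_saturation():
    b = np.zeros((8, 24, 24))
    b[0, 12, 4:20] = 1.0  # already at saturation
    stack = DepthBoundaryStack(BoundaryField(b.copy()),
                               BoundaryField(b.copy()))
    surf = SurfaceField(np.pad(np.ones((12, 12)), 6))
    v4 = DepthSurfaceStack(v2={}, v4={NEAR: surf, FAR: surf})
    once = top_down_attention(v4, stack)
    twice = top_down_attention(v4, once)
    assert np.abs(once.d1.activity - twice.d1.activity).max() <= 1e-6


def test_blank_image_reports_same_plane(config):
    rep = run_full_model(LuminanceImage(np.full((64, 64), BACKGROUND)), config)
    assert rep.central_depth == "same_plane"
    assert rep.margin == 0.0
    p = rep.decision_probabilities
    assert abs(p[0] - p[1]) < 1e-12


def test_direction_determines_figure_ground(reports):
    for scheme in ("all_negative", "all_positive", "mixed"):
        assert reports[("inward", scheme)].central_depth == "in_front"
        assert reports[("outward", scheme)].central_depth == "behind"


def test_margins_are_polarity_invariant(reports):
    for direction in ("inward", "outward"):
        ms = [reports[(direction, s)].margin
              for s in ("all_negative", "all_positive", "mixed")]
        assert max(ms) - min(ms) < 0.01


def test_direction_antisymmetry_of_margins(reports):
    m_in = reports[("inward", "all_negative")].margin
    m_out = reports[("outward", "all_negative")].margin
    assert m_in > 0 > m_out
    assert abs(m_in + m_out) <= 0.2 * max(m_in, -m_out)


def test_ownership_normals_point_to_the_nearer_side(reports):
    inw = reports[("inward", "all_negative")].ownership_map
    out = reports[("outward", "all_negative")].ownership_map
    # along the top contour, inward normals point down (into the rectangle),
    # outward normals point up (into the surround)
    def top_mean(nm):
        mags = np.linalg.norm(nm, axis=-1)
        ys, xs = np.nonzero(mags > 0)
        sel = [(y, x) for y, x in zip(ys, xs) if 37 <= y <= 43 and 60 <= x <= 130]
        return np.mean([nm[y, x] for y, x in sel], axis=0)

    assert top_mean(inw)[1] > 0.8
    assert top_mean(out)[1] < -0.8


def test_full_loop_converges_within_budget(reports, config):
    for rep in reports.values():
        assert rep.diagnostics["outer_iters"] <= config.depth.max_outer_iters
        assert rep.diagnostics["outer_residual"] < config.depth.outer_tol


def test_occlusion_far_plane_completes_behind(occlusion3_state, config):
    """Three abutting rectangles: the far plane holds one closed horizontal
    rectangle completed behind the occluder."""
    closed, mask = region_closure(occlusion3_state.stack.d2, (136, 80),
                                  config.filling)
    assert closed
    ys, xs = np.nonzero(mask)
    assert xs.min() < 40 and xs.max() > 150   # spans both flanks
    assert mask.sum() < 8000                  # and is its own compartment
    # the occluder's redundant far copy is pruned
    assert occlusion3_state.stack.d2.activity[4][45:115, 76:87].max() < \
        config.grouping.theta_gap


def test_occlusion_near_plane_is_clean(occlusion3_state, config):
    p1 = occlusion3_state.stack.d1.pooled
    # occluder contour survives at the near plane...
    assert p1[50:110, 78:83].max(axis=1).min() > config.grouping.theta_c
    # ...while the flanks' end-gap boundaries are gone
    assert p1[62:67, 118:155].max() < config.grouping.theta_gap
    assert occlusion3_state.diagnostics["gap_pixels_final"][NEAR] == 0


def test_enrichment_closes_the_unclosable_far_flank(occlusion2_state, config):
    """Two abutting rectangles: the far flank cannot close at the grouping
    stage, but borrowing the near plane's boundary closes it for visible
    filling-in."""
    _, raw = region_closure(occlusion2_state.stack.d2, (136, 80),
                            config.filling)
    assert raw.sum() > 15000  # leaks into the background at the far plane
    enriched = boundary_enrichment(occlusion2_state.stack, config.depth)
    closed, mask = region_closure(enriched.d2, (136, 80), config.filling)
    assert closed and mask.sum() < 8000
    # attention + disparity loop has removed the near end-gap remnants
    assert occlusion2_state.diagnostics["gap_pixels_final"][NEAR] == 0
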