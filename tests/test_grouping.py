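"""Bipole completion, competition, and end-gap emergence."""

import numpy as np
import pytest

from fgseg.config import GroupingParams
from fgseg.early_vision import OrientedActivityField
from fgseg.errors import ConvergenceError, ShapeError
from fgseg.grouping import (BoundaryField, bipole_kernels, bipole_step,
                            detect_end_gaps, settle_boundaries)
from fgseg.stimuli import LuminanceImage, StimulusSpec, \
    generate_experimental_display

from conftest import drive_of


def test_bipole_kernel_invariants(config):
    for k in bipole_kernels(config.grouping, 8):
        assert (k.left >= 0).all() and (k.right >= 0).all()
        assert abs(k.left.sum() - 1.0) < 1e-12
        assert abs(k.right.sum() - 1.0) < 1e-12
        assert not np.any((k.left > 0) & (k.right > 0))  # disjoint lobes
        np.testing.assert_allclose(k.left, k.right[::-1, ::-1])  # mirror


def test_zero_input_settles_immediately(config):
    d = OrientedActivityField(np.zeros((8, 32, 32)))
    b, n = settle_boundaries(d, config.grouping)
    assert n == 1
    assert b.activity.max() == 0.0


def test_shape_mismatch_rejected(config):
    b = BoundaryField(np.zeros((8, 32, 32)))
    d = OrientedActivityField(np.zeros((8, 16, 16)))
    with pytest.raises(ShapeError):
        bipole_step(b, d, config.grouping)


def test_convergence_error_carries_residual(config):
    img = generate_experimental_display(StimulusSpec())
    with pytest.raises(ConvergenceError) as err:
        settle_boundaries(drive_of(img, config), config.grouping, max_iters=2)
    assert err.value.residual is not None and err.value.residual > 0


def test_single_inducer_does_not_extend(config):
    """The AND property: no boundary beyond one lobe length past a lone bar."""
    v = np.full((96, 160), 50.5)
    v[44:52, 60:100] = 1.5
    b, _ = settle_boundaries(drive_of(LuminanceImage(v), config),
                             config.grouping)
    lobe = int(config.grouping.lobe_length)
    row = b.pooled[40:50, :].max(axis=0)
    assert row[:60 - lobe - 2].max() < config.grouping.theta_gap
    assert row[100 + lobe + 2:].max() < config.grouping.theta_gap


def test_collinear_gap_is_bridged(config):
    v = np.full((96, 160), 50.5)
    v[44:52, 20:68] = 1.5
    v[44:52, 92:140] = 1.5  # gap of 24 px <= lobe length
    b, _ = settle_boundaries(drive_of(LuminanceImage(v), config),
                             config.grouping)
    row = b.pooled[42:47, :].max(axis=0)
    bridge = row[68:92].min()
    inducer = row[25:60].mean()
    assert bridge >= 0.5 * inducer
    assert bridge > config.grouping.theta_c


def test_opposite_polarity_bridge_matches_same_polarity(config):
    same = np.full((96, 160), 50.5)
    same[44:52, 20:68] = 1.5
    same[44:52, 92:140] = 1.5
    opp = same.copy()
    opp[44:52, 92:140] = 99.5
    b1, _ = settle_boundaries(drive_of(LuminanceImage(same), config),
                              config.grouping)
    b2, _ = settle_boundaries(drive_of(LuminanceImage(opp), config),
                              config.grouping)
    bridge1 = b1.pooled[42:47, 68:92]
    bridge2 = b2.pooled[42:47, 68:92]
    assert np.abs(bridge1 - bridge2).max() <= 1e-6


def test_residuals_decay_after_burn_in(config):
    """After the completion front has settled, the residual envelope decays
    monotonically (small single-step bumps are numerical, not growth)."""
    img = generate_experimental_display(StimulusSpec())
    _, _, res = settle_boundaries(drive_of(img, config), config.grouping,
                                  record_residuals=True)
    res = np.asarray(res)
    burn, block = 15, 5
    blocks = [res[i:i + block].max()
              for i in range(burn, len(res) - block + 1, block)]
    assert all(a >= b for a, b in zip(blocks, blocks[1:]))
    assert res[-1] < 0.01 * res[burn:].max()


def test_converged_display_contour_is_closed(settled_boundaries, config):
    """The rectangle contour's minimum activity clears the completion
    threshold all the way around, bridges included."""
    b = settled_boundaries[("inward", "all_negative")]
    p = b.pooled
    mins = [p[37:44, 48:144].max(axis=0).min(),
            p[116:123, 48:144].max(axis=0).min(),
            p[40:120, 45:52].max(axis=1).min(),
            p[40:120, 140:147].max(axis=1).min()]
    assert min(mins) > config.grouping.theta_c


def test_no_outward_spreading_on_displays(settled_boundaries, config):
    """Boundary support far outside the inducer/bridge zone stays silent."""
    b = settled_boundaries[("inward", "all_negative")]
    p = b.pooled
    frame = np.zeros_like(p, dtype=bool)
    frame[:18, :] = frame[-18:, :] = True
    frame[:, :18] = frame[:, -18:] = True
    assert p[frame].max() < config.grouping.theta_gap


def test_boundaries_are_polarity_invariant(settled_boundaries):
    for direction in ("inward", "outward"):
        ref = settled_boundaries[(direction, "all_negative")].activity
        for scheme in ("all_positive", "mixed"):
            other = settled_boundaries[(direction, scheme)].activity
            assert np.abs(ref - other).max() <= 1e-6


def test_t_junction_carves_an_end_gap(t_junction_boundary, config):
    b = t_junction_boundary
    gp = config.grouping
    stem_channel = b.activity[4]  # vertical stem orientation
    near_head = stem_channel[49:54, 56:72].max()
    distal = stem_channel[60:90, 56:72].max()
    assert near_head < gp.theta_gap
    assert distal > gp.theta_c
    gaps = detect_end_gaps(b, gp)
    assert gaps.count > 0
    # the gap side vector points from the head into the stem side (downward)
    mean_side = gaps.side_vectors[gaps.mask].mean(axis=0)
    assert mean_side[1] > 0.8


def test_removing_the_head_abolishes_the_gap(headless_stem_boundary, config):
    gaps = detect_end_gaps(headless_stem_boundary, config.grouping)
    assert gaps.count == 0


def test_display_gaps_lie_on_the_inducer_side(settled_boundaries, config):
    """Outward displays carry their end gaps inside the completed rectangle,
    inward displays outside."""
    for direction, inside_expected in (("inward", False), ("outward", True)):
        b = settled_boundaries[(direction, "all_negative")]
        gaps = detect_end_gaps(b, config.grouping)
        assert gaps.count > 0
        ys, xs = np.nonzero(gaps.mask)
        inside = (ys >= 40) & (ys < 120) & (xs >= 48) & (xs < 144)
        frac_inside = inside.mean()
        if inside_expected:
            assert frac_inside > 0.8
        else:
            assert frac_inside < 0.2
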