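"""Shared fixtures: expensive model runs are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from fgseg.config import PipelineConfig
from fgseg.depth import run_depth_loop, run_full_model
from fgseg.early_vision import complex_cells, simple_cells
from fgseg.grouping import normalize_driving, settle_boundaries
from fgseg.stimuli import (LuminanceImage, StimulusSpec,
                           generate_experimental_display, generate_fixture)

DIRECTIONS = ("inward", "outward")
SCHEMES = ("all_negative", "all_positive", "mixed")
CONDITIONS = tuple((d, s) for d in DIRECTIONS for s in SCHEMES)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def displays():
    """The six experimental displays."""
    return {c: generate_experimental_display(
        StimulusSpec(edge_direction=c[0], polarity_scheme=c[1]))
        for c in CONDITIONS}


def drive_of(image: LuminanceImage, config: PipelineConfig):
    return normalize_driving(
        complex_cells(simple_cells(image, config.early_vision)),
        config.early_vision)


@pytest.fixture(scope="session")
def settled_boundaries(displays, config):
    """Converged V2 boundary field per display condition."""
    out = {}
    for cond, img in displays.items():
        b, _ = settle_boundaries(drive_of(img, config), config.grouping)
        out[cond] = b
    return out


@pytest.fixture(scope="session")
def reports(displays, config):
    """Full-model figure-ground reports for all six displays."""
    return {c: run_full_model(img, config) for c, img in displays.items()}


@pytest.fixture(scope="session")
def occlusion3_state(config):
    """Converged model state for the three-abutting-rectangles figure."""
    return run_depth_loop(generate_fixture("abutting_rectangles_3"), config)


@pytest.fixture(scope="session")
def occlusion2_state(config):
    """Converged model state for the two-abutting-rectangles figure."""
    return run_depth_loop(generate_fixture("abutting_rectangles_2"), config)


@pytest.fixture(scope="session")
def t_junction_boundary(config):
    """Converged boundary for a synthetic T (head bar + abutting stem)."""
    v = np.full((128, 128), 50.5)
    v[40:48, 24:104] = 1.5   # head
    v[48:100, 60:68] = 1.5   # stem
    b, _ = settle_boundaries(drive_of(LuminanceImage(v), config),
                             config.grouping)
    return b


@pytest.fixture(scope="session")
def headless_stem_boundary(config):
    """Same stem bar with the head removed."""
    v = np.full((128, 128), 50.5)
    v[48:100, 60:68] = 1.5
    b, _ = settle_boundaries(drive_of(LuminanceImage(v), config),
                             config.grouping)
    return b
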