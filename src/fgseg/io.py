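"""Report serialization (JSON) and ownership-map overlays."""

from __future__ import annotations

import json
import math

import numpy as np

from fgseg.config import SCHEMA_VERSION
from fgseg.depth import FigureGroundReport


def report_to_dict(report: FigureGroundReport) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return clean(obj.tolist())
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    return {
        "schema_version": SCHEMA_VERSION,
        "central_depth": report.central_depth,
        "margin": float(report.margin),
        "decision_probabilities": [float(p)
                                   for p in report.decision_probabilities],
        "diagnostics": clean(report.diagnostics),
    }


def write_report(report: FigureGroundReport, path) -> None:
    """Write a report as schema-versioned JSON (full float precision).

    Reports with non-finite margins or probabilities are rejected before
    anything is written.
    """
    if not math.isfinite(report.margin):
        raise ValueError("refusing to serialize a non-finite margin")
    if not all(math.isfinite(p) for p in report.decision_probabilities):
        raise ValueError("refusing to serialize non-finite probabilities")
    payload = report_to_dict(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)


def read_report(path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if "schema_version" not in data:
        raise ValueError("report file lacks a schema version")
    return data


def ownership_overlay_png(report: FigureGroundReport, image_values: np.ndarray,
                          path) -> None:
    """Overlay ownership normals on the stimulus as an RGB PNG.

    Contour pixels are tinted by the direction of the owning side (red = x
    component, green = y component).
    """
    from PIL import Image

    from fgseg.stimuli import luminance_to_gray

    gray = luminance_to_gray(image_values)
    rgb = np.stack([gray] * 3, axis=-1).astype(np.int16)
    normals = report.ownership_map
    on = np.linalg.norm(normals, axis=-1) > 0
    rgb[on, 0] = np.clip(148 + 107 * normals[on, 0], 0, 255)
    rgb[on, 1] = np.clip(148 + 107 * normals[on, 1], 0, 255)
    rgb[on, 2] = 64
    Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(str(path))
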