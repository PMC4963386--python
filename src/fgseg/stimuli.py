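"""Synthesis of fragmented-inducer displays and classic contour-illusion fixtures.

All displays are luminance images (cd/m^2) on a uniform mid-gray background.
The experimental displays consist of a nominal central rectangle (12:10 aspect)
whose contour is only partially carried by physical luminance edges: thin
inducer bars lie flush against the contour, on the outside of the rectangle
for *inward*-directed contrast edges and on the inside for *outward*-directed
ones.  Exactly half of the contour perimeter coincides with a luminance step;
the remainder must be completed perceptually.

Coordinates are 0-based, half-open pixel intervals, y increasing downward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image

from fgseg.errors import ConfigurationError, FormatError

# Printed luminances and their 8-bit gray anchors (display calibration):
# dark 1.5 cd/m^2 <-> 0, background 50.5 <-> 148, light 99.5 <-> 255.
DARK = 1.5
BACKGROUND = 50.5
LIGHT = 99.5
_GRAY_ANCHORS = np.array([0.0, 148.0, 255.0])
_LUM_ANCHORS = np.array([DARK, BACKGROUND, LIGHT])


class EdgeDirection(str, enum.Enum):
    INWARD = "inward"
    OUTWARD = "outward"


class PolarityScheme(str, enum.Enum):
    ALL_NEGATIVE = "all_negative"
    ALL_POSITIVE = "all_positive"
    MIXED = "mixed"


@dataclass(frozen=True)
class LuminanceImage:
    """A 2D grid of luminance samples in cd/m^2 (row-major, y-down)."""

    values: np.ndarray
    pixel_pitch_mm: float = 1.25  # metadata only: 96 px central width = 12 cm

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("luminance grid must be 2D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("luminances must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one experimental display.

    ``central_rect`` is (width, height) in pixels and must keep the printed
    12:10 aspect ratio.  ``fragment_length`` of ``None`` means each fragment
    covers ``contour_coverage_fraction / fragment_count_per_side`` of its
    side's length.
    """

    edge_direction: EdgeDirection = EdgeDirection.INWARD
    polarity_scheme: PolarityScheme = PolarityScheme.ALL_NEGATIVE
    background_luminance: float = BACKGROUND
    dark_luminance: float = DARK
    light_luminance: float = LIGHT
    image_size: tuple[int, int] = (192, 160)  # (width, height)
    central_rect: tuple[int, int] = (96, 80)  # (width, height), 12:10
    fragment_count_per_side: int = 2
    fragment_length: int | None = None
    fragment_thickness: int = 8
    # Alternate fragment thickness by +-this amount around the contour so the
    # inducers' outer edges are never mutually collinear: only the nominal
    # rectangle contour itself can then be completed by collinear grouping.
    thickness_alternation: int = 2
    contour_coverage_fraction: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "edge_direction",
                           EdgeDirection(self.edge_direction))
        object.__setattr__(self, "polarity_scheme",
                           PolarityScheme(self.polarity_scheme))
        for lum in (self.background_luminance, self.dark_luminance,
                    self.light_luminance):
            if not np.isfinite(lum) or lum < 0:
                raise ConfigurationError("luminances must be finite and >= 0")
        w, h = self.central_rect
        if w * 10 != h * 12:
            raise ConfigurationError(
                f"central rectangle {w}x{h} violates the 12:10 aspect ratio")
        if not 0 < self.contour_coverage_fraction <= 1:
            raise ConfigurationError("coverage fraction must be in (0, 1]")
        if self.fragment_count_per_side < 1:
            raise ConfigurationError("need at least one fragment per side")
        if self.thickness_alternation >= self.fragment_thickness:
            raise ConfigurationError(
                "thickness alternation must be smaller than the thickness")

    @property
    def rect_origin(self) -> tuple[int, int]:
        """Top-left pixel (x0, y0) of the nominal central rectangle."""
        W, H = self.image_size
        w, h = self.central_rect
        return (W - w) // 2, (H - h) // 2


def weber_contrast(feature_luminance: float, background_luminance: float) -> float:
    """Weber contrast (L_feature - L_background) / L_background."""
    if background_luminance <= 0:
        raise ValueError("background luminance must be positive")
    return (feature_luminance - background_luminance) / background_luminance


def _side_arcs(side_length: int, n_frag: int, coverage: float,
               frag_length: int | None) -> list[tuple[int, int]]:
    """Half-open arcs [a, b) of fragment support along one side.

    Fragments are anchored at the two ends of the side so that physical edges
    reach every rectangle corner; with more than two fragments the remainder
    are spaced evenly in between.
    """
    if frag_length is None:
        total = coverage * side_length
        per = total / n_frag
        if abs(per - round(per)) > 1e-9:
            raise ConfigurationError(
                f"coverage {coverage} of a {side_length}-px side cannot be "
                f"honored exactly by {n_frag} equal integer-length fragments")
        per = int(round(per))
    else:
        per = int(frag_length)
        if per * n_frag != int(round(coverage * side_length)):
            raise ConfigurationError(
                "fragment_length inconsistent with coverage fraction")
    if n_frag == 1:
        return [(0, per)]
    gap_total = side_length - per * n_frag
    if gap_total < 0:
        raise ConfigurationError("fragments overlap: coverage too high")
    # n_frag fragments, n_frag - 1 interior gaps, end-anchored.
    gap, rem = divmod(gap_total, n_frag - 1)
    arcs, pos = [], 0
    for i in range(n_frag):
        arcs.append((pos, pos + per))
        pos += per + gap + (1 if i < rem else 0)
    if arcs[-1][1] != side_length:
        raise ConfigurationError("fragment layout does not tile the side")
    return arcs


def _fragments_clockwise(spec: StimulusSpec):
    """Yield (side, arc) for every fragment, ordered clockwise from top-left.

    ``side`` is one of 'top', 'right', 'bottom', 'left'.  Clockwise ordering
    defines the alternation sequence for the mixed polarity scheme.
    """
    w, h = spec.central_rect
    top = _side_arcs(w, spec.fragment_count_per_side,
                     spec.contour_coverage_fraction, spec.fragment_length)
    side = _side_arcs(h, spec.fragment_count_per_side,
                      spec.contour_coverage_fraction, spec.fragment_length)
    out = [("top", a) for a in top]
    out += [("right", a) for a in side]
    out += [("bottom", a) for a in reversed(top)]
    out += [("left", a) for a in reversed(side)]
    return out


def _fragment_box(spec: StimulusSpec, side: str, arc: tuple[int, int],
                  thickness: int | None = None):
    """Pixel box (x0, x1, y0, y1) occupied by one inducer bar."""
    x0, y0 = spec.rect_origin
    w, h = spec.central_rect
    t = spec.fragment_thickness if thickness is None else thickness
    a, b = arc
    outside = spec.edge_direction is EdgeDirection.INWARD
    if side == "top":
        ys = (y0 - t, y0) if outside else (y0, y0 + t)
        return (x0 + a, x0 + b, *ys)
    if side == "bottom":
        ys = (y0 + h, y0 + h + t) if outside else (y0 + h - t, y0 + h)
        return (x0 + a, x0 + b, *ys)
    if side == "left":
        xs = (x0 - t, x0) if outside else (x0, x0 + t)
        return (*xs, y0 + a, y0 + b)
    if side == "right":
        xs = (x0 + w, x0 + w + t) if outside else (x0 + w - t, x0 + w)
        return (*xs, y0 + a, y0 + b)
    raise ValueError(side)


def _fill_corner_blocks(spec: StimulusSpec, img: np.ndarray) -> None:
    """Join the two bars meeting at each rectangle corner into one L-shaped
    inducer element (inward displays only).

    Without the corner block, each bar's thickness edge would extend the
    rectangle's contour lines past the corner, creating spurious T-junctions
    whose end gaps lie on the wrong side of the completed contour.  With it,
    each corner carries a single homogeneous L-shaped shape whose two inner
    edges are the contour edges.
    """
    x0, y0 = spec.rect_origin
    w, h = spec.central_rect
    x1, y1 = x0 + w, y0 + h
    base, alt = spec.fragment_thickness, spec.thickness_alternation
    thick = [base - alt if i % 2 == 0 else base + alt for i in range(8)]
    # corner blocks keyed by (x-slice, y-slice, luminance source pixel)
    blocks = [
        (slice(x0 - thick[7], x0), slice(y0 - thick[0], y0), (y0 - 1, x0)),
        (slice(x1, x1 + thick[2]), slice(y0 - thick[1], y0), (y0 - 1, x1 - 1)),
        (slice(x1, x1 + thick[3]), slice(y1, y1 + thick[4]), (y1, x1 - 1)),
        (slice(x0 - thick[6], x0), slice(y1, y1 + thick[5]), (y1, x0)),
    ]
    for xs, ysl, (sy, sx) in blocks:
        img[ysl, xs] = img[sy, sx]


def generate_experimental_display(spec: StimulusSpec) -> LuminanceImage:
    """Render one of the six fragmented-inducer displays.

    Deterministic: equal specs give identical grids.  Exactly
    ``contour_coverage_fraction`` of the nominal rectangle perimeter carries a
    luminance step; inducer bars are spatially disjoint.
    """
    W, H = spec.image_size
    x0, y0 = spec.rect_origin
    w, h = spec.central_rect
    t_max = spec.fragment_thickness + spec.thickness_alternation
    margin = 24  # >= one bipole lobe length
    if not (x0 - t_max >= margin and y0 - t_max >= margin
            and x0 + w + t_max + margin <= W
            and y0 + h + t_max + margin <= H):
        raise ConfigurationError(
            "central rectangle too close to the image frame")
    img = np.full((H, W), spec.background_luminance)
    frags = _fragments_clockwise(spec)
    n = len(frags)
    for i, (side, arc) in enumerate(frags):
        if spec.polarity_scheme is PolarityScheme.ALL_NEGATIVE:
            lum = spec.dark_luminance
        elif spec.polarity_scheme is PolarityScheme.ALL_POSITIVE:
            lum = spec.light_luminance
        else:
            # The two bars meeting at a corner merge into one L-shaped
            # inducer element whose contrast must stay homogeneous (a
            # polarity flip on their shared collinear edge lines would
            # cancel in any oriented filter straddling the corner), so
            # polarity alternates element-by-element around the contour:
            # element j pairs the bar entering corner j with the bar
            # leaving it.
            element = ((i + 1) % n) // 2
            lum = (spec.dark_luminance if element % 2 == 0
                   else spec.light_luminance)
        t = spec.fragment_thickness + (spec.thickness_alternation if i % 2
                                       else -spec.thickness_alternation)
        fx0, fx1, fy0, fy1 = _fragment_box(spec, side, arc, thickness=t)
        img[fy0:fy1, fx0:fx1] = lum
    if spec.edge_direction is EdgeDirection.INWARD:
        _fill_corner_blocks(spec, img)
    out = LuminanceImage(img)
    measured = measure_perimeter_coverage(out, spec)
    if abs(measured - spec.contour_coverage_fraction) > 1e-12:
        raise ConfigurationError(
            f"generated coverage {measured} != requested "
            f"{spec.contour_coverage_fraction}")
    return out


def perimeter_edge_flags(image: LuminanceImage, spec: StimulusSpec) -> np.ndarray:
    """Boolean flag per perimeter position: does a luminance step cross here?

    The perimeter is traversed as the four open contour lines of the nominal
    rectangle (length 2*(w+h) positions); each position compares the two
    pixels facing each other across the contour line.
    """
    v = image.values
    x0, y0 = spec.rect_origin
    w, h = spec.central_rect
    flags = []
    flags.append(v[y0 - 1, x0:x0 + w] != v[y0, x0:x0 + w])          # top
    flags.append(v[y0:y0 + h, x0 + w - 1] != v[y0:y0 + h, x0 + w])  # right
    flags.append(v[y0 + h - 1, x0:x0 + w] != v[y0 + h, x0:x0 + w])  # bottom
    flags.append(v[y0:y0 + h, x0 - 1] != v[y0:y0 + h, x0])          # left
    return np.concatenate(flags)


def measure_perimeter_coverage(image: LuminanceImage, spec: StimulusSpec) -> float:
    """Fraction of the nominal rectangle perimeter carrying a luminance step."""
    flags = perimeter_edge_flags(image, spec)
    return float(np.count_nonzero(flags)) / flags.size


# ---------------------------------------------------------------------------
# Fixture displays

FIXTURE_NAMES = ("kanizsa", "reverse_contrast_kanizsa", "ehrenstein",
                 "fragmented_ehrenstein_mixed", "abutting_rectangles_3",
                 "abutting_rectangles_2")


def _pacman(img: np.ndarray, cx: int, cy: int, r: int,
            quadrant: tuple[int, int], lum: float) -> None:
    """Disc of radius r centered at (cx, cy) with one quadrant removed.

    ``quadrant`` is (sx, sy) with entries +-1 selecting the removed quarter
    (pixels with sx*(x-cx) >= 0 and sy*(y-cy) >= 0), which leaves two straight
    mouth edges along the lines x = cx and y = cy.
    """
    H, W = img.shape
    yy, xx = np.mgrid[0:H, 0:W]
    # Sample at pixel centers relative to the (integer) corner position so the
    # mouth edges land exactly on pixel boundaries.
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    disc = dx * dx + dy * dy <= r * r
    sx, sy = quadrant
    mouth = (sx * dx >= 0) & (sy * dy >= 0)
    img[disc & ~mouth] = lum


def _kanizsa(reverse: bool) -> LuminanceImage:
    img = np.full((160, 192), BACKGROUND)
    # Illusory square x in [56, 136), y in [40, 120); pac-men at its corners.
    corners = [(56, 40, (1, 1)), (136, 40, (-1, 1)),
               (136, 120, (-1, -1)), (56, 120, (1, -1))]
    for i, (cx, cy, quad) in enumerate(corners):
        if reverse:
            lum = LIGHT if i % 2 == 0 else DARK  # two lighter, two darker
        else:
            lum = DARK
        _pacman(img, cx, cy, 20, quad, lum)
    return LuminanceImage(img)


def _ehrenstein(mixed_fragments: bool) -> LuminanceImage:
    """Radial lines converging on a central circular gap.

    With ``mixed_fragments`` each radial line is split into two collinear
    fragments of opposite contrast polarity.
    """
    img = np.full((160, 192), BACKGROUND)
    cx, cy = 96.0, 80.0
    r_in, r_mid, r_out, halfw = 16.0, 34.0, 52.0, 1.0
    yy, xx = np.mgrid[0:160, 0:192]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    rr = np.hypot(dx, dy)
    for k in range(8):
        ang = k * np.pi / 4
        ux, uy = np.cos(ang), np.sin(ang)
        axial = dx * ux + dy * uy
        lateral = np.abs(-dx * uy + dy * ux)
        on_line = (lateral <= halfw) & (axial > 0)
        if mixed_fragments:
            inner = on_line & (rr >= r_in) & (rr < r_mid - 1)
            outer = on_line & (rr >= r_mid + 1) & (rr < r_out)
            img[inner] = DARK
            img[outer] = LIGHT
        else:
            img[on_line & (rr >= r_in) & (rr < r_out)] = DARK
    return LuminanceImage(img)


def _abutting_rectangles(n: int) -> LuminanceImage:
    """Occlusion figures: a vertical rectangle abutting flanking horizontals."""
    img = np.full((160, 192), BACKGROUND)
    img[40:120, 80:112] = DARK              # vertical rectangle
    img[64:96, 112:160] = LIGHT             # right horizontal rectangle
    if n == 3:
        img[64:96, 32:80] = LIGHT           # left horizontal rectangle
    return LuminanceImage(img)


def generate_fixture(name: str) -> LuminanceImage:
    """Return one of the named classic displays at default geometry."""
    if name == "kanizsa":
        return _kanizsa(reverse=False)
    if name == "reverse_contrast_kanizsa":
        return _kanizsa(reverse=True)
    if name == "ehrenstein":
        return _ehrenstein(mixed_fragments=False)
    if name == "fragmented_ehrenstein_mixed":
        return _ehrenstein(mixed_fragments=True)
    if name == "abutting_rectangles_3":
        return _abutting_rectangles(3)
    if name == "abutting_rectangles_2":
        return _abutting_rectangles(2)
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# Image file I/O (8-bit grayscale PNG / PGM)

def luminance_to_gray(lum: np.ndarray) -> np.ndarray:
    """Map luminance to 8-bit gray via the three calibration anchors."""
    g = np.interp(lum, _LUM_ANCHORS, _GRAY_ANCHORS)
    return np.rint(g).astype(np.uint8)


def gray_to_luminance(gray: np.ndarray) -> np.ndarray:
    """Inverse of :func:`luminance_to_gray` (linear between anchors)."""
    return np.interp(gray.astype(float), _GRAY_ANCHORS, _LUM_ANCHORS)


def write_image(image: LuminanceImage, path) -> None:
    """Write an 8-bit grayscale PNG or PGM under the fixed gray mapping."""
    gray = luminance_to_gray(image.values)
    fmt = "PPM" if str(path).lower().endswith((".pgm", ".ppm")) else "PNG"
    Image.fromarray(gray, mode="L").save(str(path), format=fmt)


def read_image(path) -> LuminanceImage:
    """Read an 8-bit grayscale PNG or PGM back into luminance units."""
    with Image.open(str(path)) as im:
        if im.mode not in ("L", "P", "1", "I;16"):
            raise FormatError(f"cannot map pixel mode {im.mode!r} to luminance")
        if im.mode != "L":
            try:
                im = im.convert("L")
            except Exception as exc:  # pragma: no cover
                raise FormatError(str(exc)) from exc
        gray = np.asarray(im, dtype=np.uint8)
    return LuminanceImage(gray_to_luminance(gray))


def image_io(image: LuminanceImage | None, path, direction: str):
    """Unified read/write entry point (``direction`` in {'read', 'write'})."""
    if direction == "write":
        if image is None:
            raise ValueError("write requires an image")
        write_image(image, path)
        return None
    if direction == "read":
        return read_image(path)
    raise ValueError("direction must be 'read' or 'write'")


def polarity_flipped(spec: StimulusSpec) -> StimulusSpec:
    """The spec with dark and light schemes exchanged (mirror luminances)."""
    flip = {PolarityScheme.ALL_NEGATIVE: PolarityScheme.ALL_POSITIVE,
            PolarityScheme.ALL_POSITIVE: PolarityScheme.ALL_NEGATIVE}
    return replace(spec, polarity_scheme=flip.get(spec.polarity_scheme,
                                                  spec.polarity_scheme))
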