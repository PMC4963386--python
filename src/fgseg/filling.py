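"""Boundary-gated surface filling-in and surface-contour feedback (model V2 thin stripes).

Brightness signals diffuse on the pixel lattice; each lattice edge's
conductance is gated by the boundary strength across it, g = 1/(1 + lambda*B),
so strong boundaries act as near-impermeable walls.  Feature-contour signals
(the illuminant-discounted on/off activity) act as clamped sources.  A closed
boundary contains its filled-in surface and thereby produces steep filled-in
steps along the contour, which the contrast-sensitive surface-contour operator
converts into feedback signals; a boundary with a hole lets the fill equalize
and emits none.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from fgseg._convolve import KernelBank, gaussian_kernel
from fgseg.config import FillingParams
from fgseg.early_vision import FeatureContourField
from fgseg.errors import InvalidSeedError, NumericalError, ShapeError
from fgseg.grouping import BoundaryField


@dataclass(frozen=True)
class SurfaceField:
    """Filled-in surface activity (signed: on minus off) at one depth."""

    filled_activity: np.ndarray
    depth_label: str | None = None


@dataclass(frozen=True)
class SurfaceContourField:
    """Contrast-sensitive output signals along contained surface boundaries."""

    activity: np.ndarray


def _edge_conductances(boundary: BoundaryField, params: FillingParams):
    """Horizontal and vertical lattice-edge conductances gated by boundaries.

    g = 1 / (1 + lambda * B) for sub-threshold boundary strength B; edges
    crossing a supra-threshold boundary are fully impermeable (g = 0), so a
    closed boundary truly contains its fill at steady state while any
    supra-threshold hole lets the two sides equalize.
    """
    b = boundary.pooled / boundary.saturation
    bx = np.maximum(b[:, :-1], b[:, 1:])
    by = np.maximum(b[:-1, :], b[1:, :])
    gx = np.where(bx >= params.permeability_threshold, 0.0,
                  1.0 / (1.0 + params.boundary_gate * bx))
    gy = np.where(by >= params.permeability_threshold, 0.0,
                  1.0 / (1.0 + params.boundary_gate * by))
    return gx, gy


def _assemble_system(source: np.ndarray, source_mask: np.ndarray,
                     gx: np.ndarray, gy: np.ndarray, params: FillingParams):
    """Sparse SPD system for the diffusion steady state (soft-clamped sources)."""
    H, W = source.shape
    n = H * W
    idx = np.arange(n).reshape(H, W)
    alpha = np.where(source_mask, params.clamp_strength, 0.0).ravel()
    diag = np.full(n, params.leak) + alpha
    rows, cols, vals = [], [], []
    # horizontal edges
    a, b = idx[:, :-1].ravel(), idx[:, 1:].ravel()
    g = gx.ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)
    # vertical edges
    a, b = idx[:-1, :].ravel(), idx[1:, :].ravel()
    g = gy.ravel()
    rows += [a, b]
    cols += [b, a]
    vals += [-g, -g]
    np.add.at(diag, a, g)
    np.add.at(diag, b, g)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
    rhs = (alpha * source.ravel())
    return A, rhs


def fill_in(features: FeatureContourField, boundary: BoundaryField,
            params: FillingParams | None = None,
            depth_label: str | None = None,
            method: str = "direct",
            max_iters: int = 200_000) -> SurfaceField:
    """Steady state of boundary-gated lattice diffusion with clamped sources.

    ``method`` 'direct' solves the sparse linear system; 'jacobi' iterates the
    diffusion relaxation to the same fixed point (used as an independent
    cross-check of the solver).
    """
    params = params or FillingParams()
    src = features.signed
    if src.shape != boundary.pooled.shape:
        raise ShapeError("features and boundary must share geometry")
    mask = features.magnitude >= params.source_threshold
    if not mask.any():
        return SurfaceField(np.zeros_like(src), depth_label)
    gx, gy = _edge_conductances(boundary, params)
    if method == "direct":
        A, rhs = _assemble_system(src, mask, gx, gy, params)
        u = spsolve(A.tocsc(), rhs)
        resid = float(np.max(np.abs(A @ u - rhs)))
        scale = max(1.0, float(np.max(np.abs(rhs))))
        if not np.all(np.isfinite(u)) or resid > params.solver_tol * scale:
            raise NumericalError("diffusion solve failed", residual=resid)
        return SurfaceField(u.reshape(src.shape), depth_label)
    if method == "jacobi":
        return _fill_in_jacobi(src, mask, gx, gy, params, depth_label,
                               max_iters)
    raise ValueError(f"unknown method {method!r}")


def _fill_in_jacobi(src, mask, gx, gy, params, depth_label, max_iters):
    """Plain Jacobi relaxation of the same linear system (oracle path)."""
    H, W = src.shape
    alpha = np.where(mask, params.clamp_strength, 0.0)
    u = np.zeros_like(src)
    gxp = np.zeros((H, W))  # conductance to the right neighbor
    gxp[:, :-1] = gx
    gxm = np.zeros((H, W))
    gxm[:, 1:] = gx
    gyp = np.zeros((H, W))
    gyp[:-1, :] = gy
    gym = np.zeros((H, W))
    gym[1:, :] = gy
    denom = params.leak + alpha + gxp + gxm + gyp + gym
    b = alpha * src
    tol = params.solver_tol
    for _ in range(max_iters):
        nb = np.zeros_like(u)
        nb[:, :-1] += gxp[:, :-1] * u[:, 1:]
        nb[:, 1:] += gxm[:, 1:] * u[:, :-1]
        nb[:-1, :] += gyp[:-1, :] * u[1:, :]
        nb[1:, :] += gym[1:, :] * u[:-1, :]
        new = (b + nb) / denom
        delta = float(np.max(np.abs(new - u)))
        u = new
        if delta < tol * 1e-2:
            return SurfaceField(u, depth_label)
    raise NumericalError("Jacobi relaxation did not converge", residual=delta)


@lru_cache(maxsize=8)
def _disc_mask_cached(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= radius * radius


@lru_cache(maxsize=8)
def _contour_dog_bank(params: FillingParams) -> KernelBank:
    return KernelBank([gaussian_kernel(params.contour_center_sigma),
                       gaussian_kernel(params.contour_surround_sigma)])


@lru_cache(maxsize=8)
def _dog_step_peak(params: FillingParams) -> float:
    """Peak |DoG| response to a contained unit step (threshold reference)."""
    v = np.zeros((48, 48))
    v[:, 24:] = 1.0
    c, s = _contour_dog_bank(params).convolve(v)
    return float(np.max(np.abs(c - s)))


def surface_contours(surface: SurfaceField, boundary: BoundaryField,
                     params: FillingParams | None = None
                     ) -> SurfaceContourField:
    """Rectified on-center off-surround output of the filled-in surface.

    Emits signals only where the filled-in activity has a large, steep step
    (at least ``contour_threshold_frac`` of the response a fully contained
    unit-amplitude step would produce, relative to the surface's own range),
    and only within a 2-px dilation of supra-threshold boundary positions.
    """
    params = params or FillingParams()
    u = surface.filled_activity
    if u.shape != boundary.pooled.shape:
        raise ShapeError("surface and boundary must share geometry")
    c, s = _contour_dog_bank(params).convolve(u)
    resp = np.abs(c - s)
    amplitude = max(float(np.max(np.abs(u))), 1e-12)
    thresh = params.contour_threshold_frac * _dog_step_peak(params) * amplitude
    act = np.where(resp >= thresh, resp, 0.0)
    bmask = (boundary.pooled / boundary.saturation
             >= params.permeability_threshold)
    support = ndimage.binary_dilation(bmask, iterations=2)
    # containment gating: a boundary emits surface contours only where it
    # actually separates two distinct filling-in compartments.  A region that
    # leaks through end gaps merges with its neighbor, so the boundary
    # between them no longer separates anything and stays silent -- the
    # operational form of "signals only at positions surrounded by closed
    # boundaries".
    labels = region_labels(boundary, params)
    big = labels.max() + 1
    fp = _disc_mask_cached(3.0)
    lmax = ndimage.maximum_filter(labels, footprint=fp)
    lmin = ndimage.minimum_filter(np.where(labels > 0, labels, big),
                                  footprint=fp)
    separates = (lmax > 0) & (lmin < big) & (lmax != lmin)
    return SurfaceContourField(np.where(support & separates, act, 0.0))


def _blocked_mask(boundary: BoundaryField, params: FillingParams) -> np.ndarray:
    """Supra-threshold boundary pixels, with hairline chinks sealed.

    Where two boundary bands meet at a corner their supra-threshold cores can
    be separated by a one-to-two-pixel diagonal sliver; flow through such a
    constriction between strong boundaries is negligible, so a single
    morphological closing treats the junction as sealed.  Genuine end gaps
    are several pixels wide and stay open.
    """
    blocked = (boundary.pooled / boundary.saturation
               >= params.permeability_threshold)
    return ndimage.binary_closing(blocked, structure=np.ones((3, 3), bool))


def region_closure(boundary: BoundaryField, seed_position: tuple[int, int],
                   params: FillingParams | None = None,
                   frame_is_boundary: bool = True
                   ) -> tuple[bool, np.ndarray]:
    """Flood fill over permeable lattice edges from ``seed_position`` (x, y).

    Returns (closed, region mask).  With ``frame_is_boundary`` the outermost
    pixel ring acts as a permanent closed boundary (so e.g. the region between
    a closed figure and the image frame is itself a closed compartment);
    without it, a region whose flood reaches the frame counts as open.
    """
    params = params or FillingParams()
    blocked = _blocked_mask(boundary, params)
    H, W = blocked.shape
    x, y = seed_position
    if not (0 <= x < W and 0 <= y < H):
        raise ValueError("seed outside the image")
    if frame_is_boundary:
        blocked[0, :] = blocked[-1, :] = True
        blocked[:, 0] = blocked[:, -1] = True
    if blocked[y, x]:
        raise InvalidSeedError(
            f"seed {seed_position} lies on a supra-threshold boundary pixel")
    labels, _ = ndimage.label(~blocked)
    mask = labels == labels[y, x]
    ring = np.zeros_like(mask)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    closed = not bool(np.any(mask & ring))
    return closed, mask


def region_labels(boundary: BoundaryField,
                  params: FillingParams | None = None,
                  frame_is_boundary: bool = True) -> np.ndarray:
    """Connected-component labels of unblocked space (0 on boundary pixels)."""
    params = params or FillingParams()
    blocked = _blocked_mask(boundary, params)
    if frame_is_boundary:
        blocked[0, :] = blocked[-1, :] = True
        blocked[:, 0] = blocked[:, -1] = True
    labels, _ = ndimage.label(~blocked)
    return labels
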