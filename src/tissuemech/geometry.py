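"""Initial cross-section geometry: loop construction and polygon helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np


class GeometryError(ValueError):
    """Raised when an initial layout violates geometric constraints."""


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (CCW positive).

    ``points`` is an (N, 2) array of vertices; the closing edge from the
    last vertex back to the first is implied.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon requires an (N>=3, 2) vertex array")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the polygon with counterclockwise orientation."""
    if polygon_area(points) < 0:
        return points[::-1].copy()
    return points


def is_simple(points: np.ndarray) -> bool:
    """True if no two non-adjacent edges of the closed polygon intersect.

    O(N^2) segment test; loops here have ~50 vertices so this is cheap.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    a = pts
    b = np.roll(pts, -1, axis=0)

    def cross2(u, v) -> float:
        return u[0] * v[1] - u[1] * v[0]

    def seg_intersect(p1, p2, p3, p4) -> bool:
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if seg_intersect(a[i], b[i], a[j], b[j]):
                return False
    return True


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points at uniform arclength."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate outline: zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def circle(center: Tuple[float, float], radius: float, n: int,
           phase: float = 0.0) -> np.ndarray:
    """CCW circle sampled at ``n`` points."""
    t = phase + np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def superellipse(center: Tuple[float, float], half_w: float, half_h: float,
                 exponent: float, n: int) -> np.ndarray:
    """CCW superellipse |x/a|^p + |y/b|^p = 1 resampled to uniform arclength.

    ``exponent`` = 2 gives an ellipse; larger values give rounded rectangles.
    """
    t = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = center[0] + half_w * np.sign(ct) * np.abs(ct) ** (2.0 / exponent)
    y = center[1] + half_h * np.sign(st) * np.abs(st) ** (2.0 / exponent)
    return resample_closed(np.column_stack([x, y]), n)


def perimeter(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def mirror_x(points: np.ndarray) -> np.ndarray:
    """Mirror a CCW loop about the vertical midline, preserving CCW order."""
    out = points.copy()
    out[:, 0] = -out[:, 0]
    return out[::-1].copy()


@dataclass(frozen=True)
class CanonicalLayout:
    """Free dimensions of the canonical four-tissue initial arrangement.

    The two presomitic-mesoderm loops and the neural tube start as
    circles with perimeter ``N * l0`` (unstretched springs): PSM_L/PSM_R
    rest on the yolk line at ``x = +-psm_center_x`` and the NT is wedged
    into the groove between them (or stacked above if the groove is too
    narrow).  The notochord starts as a vertical ellipse filling the
    cavity between yolk, PSMs and NT; it inflates toward rest perimeter
    during relaxation.  ``gap`` is the initial clearance between
    adjacent loops and between loops and the yolk; it lies inside the
    adhesion range so every intended interface is engaged at t=0.

    These dimensions were tuned once against the wild-type shape anchors
    and are frozen for all conditions.
    """

    gap: float = 0.135
    psm_center_x: float = 1.1
    nt_lift: float = 0.35         # extra initial elevation of the NT
    nt_aspect: float = 1.0        # initial NT height/width ratio (1 = circle)
    nc_half_height: float | None = None  # cap on the initial NC half-height
    yolk_halfwidth: float = 4.5
    yolk_spacing: float = 0.05
    jitter: float = 0.0           # optional symmetry-breaking noise (model units)


TISSUE_NAMES = ("NT", "PSM_L", "PSM_R", "NC")


def _vertical_ellipse(center, half_w, half_h, n, phase=None) -> np.ndarray:
    """Ellipse resampled to uniform arclength, exactly mirror-symmetric
    about its vertical axis (sampling starts at the bottom axis point)."""
    t = -np.pi / 2 + np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    pts = np.column_stack([center[0] + half_w * np.cos(t),
                           center[1] + half_h * np.sin(t)])
    out = resample_closed(pts, n)
    # enforce exact reflection symmetry: partner of point k is point n-k
    partner = out[np.r_[0, n - 1:0:-1]] * [-1.0, 1.0] + [2.0 * center[0], 0.0]
    return 0.5 * (out + partner)


def _ellipse_perimeter(a: float, b: float) -> float:
    t = np.linspace(0.0, 2 * np.pi, 2000)
    return float(np.sum(np.hypot(np.diff(a * np.cos(t)), np.diff(b * np.sin(t)))))


def _ellipse_half_height(a: float, target_perimeter: float) -> float:
    lo, hi = 1e-3, target_perimeter
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _ellipse_perimeter(a, mid) < target_perimeter:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ellipse_half_width(aspect: float, target_perimeter: float) -> float:
    lo, hi = 1e-3, target_perimeter
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _ellipse_perimeter(mid, aspect * mid) < target_perimeter:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def canonical_positions(layout: CanonicalLayout, params) -> dict:
    """Initial loop positions for the canonical layout, keyed by tissue name.

    Loops are exactly mirror-symmetric about x = 0 (PSM_R is the reflected
    PSM_L; NT and NC are sampled symmetrically).
    """
    r0 = params.N * params.l0 / (2 * np.pi)
    rest_perimeter = params.N * params.l0
    g = layout.gap
    px = layout.psm_center_x
    psm_cy = g + r0
    phase = np.pi / params.N
    psm_r = circle((px, psm_cy), r0, params.N)
    psm_l = mirror_x(psm_r)

    if layout.nt_aspect > 1.0:
        # tall NT ellipse wedged between the PSMs, small NC underneath
        nt_a = _ellipse_half_width(layout.nt_aspect, rest_perimeter)
        nt_a = min(nt_a, px - r0 - g)
        nt_b = _ellipse_half_height(nt_a, rest_perimeter)
        nc_a = nt_a
        nc_b = layout.nc_half_height if layout.nc_half_height is not None else 0.4
        nc_c = (0.0, g + nc_b)
        nt_cy = 2 * g + 2 * nc_b + nt_b + layout.nt_lift
        nt = _vertical_ellipse((0.0, nt_cy), nt_a, nt_b, params.N, phase)
        nc = _vertical_ellipse(nc_c, nc_a, nc_b, params.N, phase)
        for _ in range(60):
            dmin = min(
                np.min(np.linalg.norm(nc[:, None, :] - other[None, :, :], axis=2))
                for other in (nt, psm_r, psm_l))
            if dmin >= g:
                break
            nc_a *= 0.97
            nc_b *= 0.97
            nc_c = (0.0, g + nc_b)
            nc = _vertical_ellipse(nc_c, nc_a, nc_b, params.N, phase)
        return {"NT": nt, "PSM_L": psm_l, "PSM_R": psm_r, "NC": nc}

    # NT circle: clearance `gap` from both PSM circles if the groove is
    # wide enough to wedge into, else stacked at groove width.
    reach = 2 * r0 + g
    dy = np.sqrt(max(reach * reach - px * px, 0.0))
    nt_cy = psm_cy + dy + layout.nt_lift
    nt = circle((0.0, nt_cy), r0, params.N, phase=phase)

    # NC: vertical ellipse in the cavity between yolk, PSMs and NT.
    nc_a = max(px - r0 - g, 0.3 * r0)
    nc_b = max((nt_cy - r0) - 2 * g, nc_a)
    nc_c = (0.0, g + nc_b)

    # shrink the NC until it clears every neighbour by `gap`
    for _ in range(60):
        nc = _vertical_ellipse(nc_c, nc_a, nc_b, params.N, phase)
        dmin = min(
            np.min(np.linalg.norm(nc[:, None, :] - other[None, :, :], axis=2))
            for other in (nt, psm_r, psm_l))
        if dmin >= g and nc_c[1] - nc_b >= g - 1e-9:
            break
        nc_a *= 0.97
        nc_b *= 0.97
        nc_c = (0.0, g + nc_b)
    return {"NT": nt, "PSM_L": psm_l, "PSM_R": psm_r, "NC": nc}


def yolk_points(layout: CanonicalLayout) -> np.ndarray:
    """Fixed points of the rigid yolk wall along y = 0."""
    n = int(round(2 * layout.yolk_halfwidth / layout.yolk_spacing)) + 1
    x = np.linspace(-layout.yolk_halfwidth, layout.yolk_halfwidth, n)
    return np.column_stack([x, np.zeros_like(x)])
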