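"""Shape metrics of simulated cross-sections and polygonal tissue outlines.

All operations work on a steady :class:`~tissuemech.model.SimState` (or on
plain polygons), mirroring measurements made on transverse-section images:
interfacial length and angle, bounding extents, areas and left/right
asymmetry, circle-fit radii of curvature, and medial-lateral tension
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import is_simple, polygon_area as signed_area
from .model import SimState, TensionField
from .params import ModelParams


class MeasurementError(ValueError):
    pass


@dataclass
class InterfaceRecord:
    """Surface points of one tissue participating in a contact interface.

    ``indices`` are consecutive along the source loop (cyclic order);
    ``gap_segments`` are runs of loop indices inside the interface arc
    whose nearest partner point exceeds the contact range.
    """

    tissue: str
    partner: str
    indices: np.ndarray
    points: np.ndarray
    gap_segments: List[np.ndarray] = field(default_factory=list)
    full_detachment: bool = False

    @property
    def n_points(self) -> int:
        return len(self.indices)

    @property
    def n_gaps(self) -> int:
        return len(self.gap_segments)


@dataclass
class MorphometricsResult:
    L_psm_nt: Dict[str, float]
    angle_theta: Dict[str, float]
    nt_ml_width: float
    nt_dv_length: float
    areas: Dict[str, float]
    lr_area_diff: float
    radius_psm_nt: Dict[str, float]
    radius_psm_e: Dict[str, float]
    n_gaps: Dict[str, int]

    def as_dict(self) -> dict:
        out = {"nt_ml_width": self.nt_ml_width,
               "nt_dv_length": self.nt_dv_length,
               "lr_area_diff": self.lr_area_diff}
        for side in ("L", "R"):
            out[f"L_psm_nt_{side}"] = self.L_psm_nt.get(side, np.nan)
            out[f"theta_{side}"] = self.angle_theta.get(side, np.nan)
            out[f"radius_psm_nt_{side}"] = self.radius_psm_nt.get(side, np.nan)
            out[f"radius_psm_e_{side}"] = self.radius_psm_e.get(side, np.nan)
            out[f"n_gaps_{side}"] = self.n_gaps.get(side, 0)
        for name, a in self.areas.items():
            out[f"area_{name}"] = a
        return out


def _cyclic_runs(mask: np.ndarray) -> List[np.ndarray]:
    """Runs of consecutive True indices on a cyclic boolean array."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then find contiguous runs
    start = int(np.argmin(mask))
    rot = np.roll(mask, -start)
    runs = []
    i = 0
    while i < n:
        if rot[i]:
            j = i
            while j < n and rot[j]:
                j += 1
            runs.append((np.arange(i, j) + start) % n)
            i = j
        else:
            i += 1
    return runs


def extract_interface(state: SimState, tissueA: str, tissueB: str,
                      contact_range: Optional[float] = None,
                      params: Optional[ModelParams] = None) -> InterfaceRecord:
    """Surface points of ``tissueA`` within ``contact_range`` of ``tissueB``.

    The interface is the contact arc of the loop: all in-range runs plus
    the out-of-range runs between them (recorded as gaps).  The arc is
    the cyclic span of in-range points that excludes the longest
    detached stretch of the loop.
    """
    if contact_range is None:
        contact_range = (params or ModelParams()).R_adh
    a = state.cross_section.tissue(tissueA).positions
    if tissueB == "yolk":
        b = state.cross_section.yolk
    else:
        b = state.cross_section.tissue(tissueB).positions
    near = cdist(a, b).min(axis=1) <= contact_range
    if not near.any():
        return InterfaceRecord(tissueA, tissueB, np.array([], dtype=int),
                               np.empty((0, 2)), full_detachment=True)
    runs = _cyclic_runs(near)
    if len(runs) == 1:
        idx = runs[0]
        gaps: List[np.ndarray] = []
    else:
        # choose the arc excluding the longest detached stretch
        false_runs = _cyclic_runs(~near)
        longest_gap = max(false_runs, key=len)
        n = len(near)
        start = (longest_gap[-1] + 1) % n
        order = (np.arange(n) + start) % n
        arc = order[near[order].cumsum() > 0]
        last_true = np.max(np.where(near[arc])[0])
        arc = arc[: last_true + 1]
        idx = arc[near[arc]]
        gaps = [g for g in _cyclic_runs(~near) if np.isin(g, arc).all()]
    return InterfaceRecord(tissueA, tissueB, idx, a[idx], gap_segments=gaps)


def extract_free_surface(state: SimState, tissue: str,
                         contact_range: Optional[float] = None,
                         params: Optional[ModelParams] = None) -> InterfaceRecord:
    """Longest run of ``tissue`` points away from every other tissue and yolk."""
    if contact_range is None:
        contact_range = (params or ModelParams()).R_adh
    cs = state.cross_section
    a = cs.tissue(tissue).positions
    dmin = np.full(len(a), np.inf)
    for other in cs.tissues:
        if other.name == tissue:
            continue
        dmin = np.minimum(dmin, cdist(a, other.positions).min(axis=1))
    dmin = np.minimum(dmin, cdist(a, cs.yolk).min(axis=1))
    free = dmin > contact_range
    runs = _cyclic_runs(free)
    if not runs:
        return InterfaceRecord(tissue, "free", np.array([], dtype=int),
                               np.empty((0, 2)), full_detachment=True)
    idx = max(runs, key=len)
    return InterfaceRecord(tissue, "free", idx, a[idx])


def interfacial_length(rec: InterfaceRecord) -> float:
    """Polyline length through the interface points, in loop order."""
    if rec.n_points < 2:
        raise MeasurementError("interfacial length requires at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(rec.points, axis=0), axis=1)))


def _side_name(side: str) -> str:
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    return f"PSM_{side}"


def interfacial_angle(state: SimState, side: str, k: int = 3,
                      params: Optional[ModelParams] = None) -> float:
    """Angle (degrees) at the lateral end of the PSM|NT interface.

    Measured between the chord through the last ``k`` interface points
    and the chord through the next ``k`` PSM surface points continuing
    past the lateral end of the interface.
    """
    psm = _side_name(side)
    rec = extract_interface(state, psm, "NT", params=params)
    if rec.n_points <= k:
        raise MeasurementError(f"interface shorter than k={k} points")
    loop = state.cross_section.tissue(psm).positions
    n = len(loop)
    first, last = rec.indices[0], rec.indices[-1]
    # lateral end: the endpoint farther from the midline
    if abs(loop[last, 0]) >= abs(loop[first, 0]):
        end = last
        inward = rec.points[-1 - k: -1][::-1]      # k points toward interface
        cont = loop[(end + 1 + np.arange(k)) % n]  # continue along the loop
    else:
        end = first
        inward = rec.points[1: 1 + k]
        cont = loop[(end - 1 - np.arange(k)) % n]
    p0 = loop[end]
    v1 = inward[-1] - p0
    v2 = cont[-1] - p0
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def bounding_extents(outline: np.ndarray) -> Tuple[float, float]:
    """Axis-aligned bounding-box (ML width, DV height) of a closed polygon."""
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise MeasurementError("bounding extents require >= 3 vertices")
    return (float(pts[:, 0].max() - pts[:, 0].min()),
            float(pts[:, 1].max() - pts[:, 1].min()))


def polygon_area(outline: np.ndarray) -> float:
    """Unsigned shoelace area of a simple closed polygon."""
    pts = np.asarray(outline, dtype=float)
    if not is_simple(pts):
        raise MeasurementError("polygon is self-intersecting")
    return abs(signed_area(pts))


def lr_asymmetry(area_left: float, area_right: float) -> float:
    return abs(area_left - area_right)


def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Largest sub-pixel contour (at level 0.5) of a binary mask, as (x, y)."""
    from skimage import measure
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise MeasurementError("mask has no foreground contour")
    c = max(contours, key=len)
    if np.allclose(c[0], c[-1]):
        c = c[:-1]          # drop the repeated closing vertex
    return np.column_stack([c[:, 1], c[:, 0]])


def tension_profile(rec: InterfaceRecord, tfield: TensionField, side_of: str,
                    midline_x: float = 0.0,
                    reach: float = 1.0, margin: float = 0.1,
                    params: Optional[ModelParams] = None):
    """Medial->lateral tension profile of one tissue along an interface.

    Selects springs of ``side_of`` (e.g. "NT") whose midpoints project
    onto the medial-lateral span of the interface (from the midline out
    to the lateral end, plus ``margin``) and lie within ``reach`` of the
    interface polyline (which excludes the far side of the loop).
    Returns ``(positions, tensions, slope)`` ordered medial->lateral,
    where ``slope`` is the least-squares slope of tension versus
    medial-lateral position.
    """
    if rec.n_points == 0:
        raise MeasurementError("empty interface")
    mids = tfield.midpoints[side_of]
    tens = tfield.tensions[side_of]
    proj = np.abs(mids[:, 0] - midline_x)
    lateral_end = np.abs(rec.points[:, 0] - midline_x).max() + margin
    d = cdist(mids, rec.points).min(axis=1)
    sel = (d <= reach) & (proj <= lateral_end)
    if not sel.any():
        raise MeasurementError("no springs project onto the interface span")
    pos = proj[sel]
    t = tens[sel]
    order = np.argsort(pos)
    pos, t = pos[order], t[order]
    slope = float(np.polyfit(pos, t, 1)[0]) if len(pos) > 1 else 0.0
    return pos, t, slope


def radius_of_curvature(rec: InterfaceRecord) -> float:
    """Pratt circle-fit radius through the interface points."""
    from .imquant import pratt_circle_fit
    if rec.n_points < 3:
        raise MeasurementError("radius of curvature requires >= 3 points")
    _, radius = pratt_circle_fit(rec.points)
    return radius


def measure_state(state: SimState, params: Optional[ModelParams] = None,
                  angle_k: int = 3) -> MorphometricsResult:
    """All shape metrics of a steady state."""
    params = params or ModelParams()
    cs = state.cross_section
    L, theta, r_nt, r_e, gaps = {}, {}, {}, {}, {}
    for side in ("L", "R"):
        psm = _side_name(side)
        rec = extract_interface(state, psm, "NT", params=params)
        gaps[side] = rec.n_gaps
        if rec.n_points >= 2:
            L[side] = interfacial_length(rec)
        # curvature of the contact line is read off the NT-side trace,
        # which hugs the shared interface without the PSM corner points
        nt_rec = extract_interface(state, "NT", psm, params=params)
        if nt_rec.n_points >= 3:
            r_nt[side] = radius_of_curvature(nt_rec)
        free = extract_free_surface(state, psm, params=params)
        if free.n_points >= 3:
            r_e[side] = radius_of_curvature(free)
        try:
            theta[side] = interfacial_angle(state, side, k=angle_k, params=params)
        except MeasurementError:
            pass
    nt = cs.tissue("NT").positions
    width, height = bounding_extents(nt)
    areas = {t.name: t.area() for t in cs.tissues}
    return MorphometricsResult(
        L_psm_nt=L, angle_theta=theta, nt_ml_width=width, nt_dv_length=height,
        areas=areas, lr_area_diff=lr_asymmetry(areas["PSM_L"], areas["PSM_R"]),
        radius_psm_nt=r_nt, radius_psm_e=r_e, n_gaps=gaps)
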