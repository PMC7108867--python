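"""Pressurized mass-spring tissue loops with overdamped explicit-Euler dynamics.

Four closed loops (neural tube NT, left/right presomitic mesoderm PSM_L /
PSM_R, notochord NC) interact with each other and with a fixed yolk wall
through a piecewise spring law: stiff repulsion below ``R_rep``, linear
adhesion between ``R_rep`` and ``R_adh``, nothing beyond.  Each loop
carries surface springs of stiffness ``K_S`` and a constant internal
pressure ``P`` acting outward on every surface segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import _kernels
from .geometry import (CanonicalLayout, GeometryError, canonical_positions,
                       ensure_ccw, is_simple, polygon_area, yolk_points)
from .params import ModelParams

YOLK_ID = 4


class SimulationError(RuntimeError):
    """Raised when the dynamics produce non-finite forces or diverge."""


@dataclass
class TissueLoop:
    """A closed loop of mass points with optional per-tissue overrides.

    ``ks_scale`` optionally scales the stiffness of individual surface
    springs (spring i connects point i to point i+1 mod N); it is used
    for half-surface perturbations.
    """

    name: str
    positions: np.ndarray
    K_S: Optional[float] = None
    K_adh: Optional[float] = None
    ks_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        if self.ks_scale is not None:
            self.ks_scale = np.asarray(self.ks_scale, dtype=float)
            if self.ks_scale.shape != (len(self.positions),):
                raise ValueError("ks_scale must have one entry per spring")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def spring_lengths(self) -> np.ndarray:
        nxt = np.roll(self.positions, -1, axis=0)
        return np.linalg.norm(nxt - self.positions, axis=1)

    def area(self) -> float:
        return abs(polygon_area(self.positions))


@dataclass
class CrossSection:
    """Four tissue loops plus the immobile yolk wall."""

    tissues: List[TissueLoop]
    yolk: np.ndarray

    def __post_init__(self) -> None:
        self.yolk = np.asarray(self.yolk, dtype=float)

    def tissue(self, name: str) -> TissueLoop:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def copy(self) -> "CrossSection":
        return CrossSection(
            tissues=[TissueLoop(t.name, t.positions.copy(), t.K_S, t.K_adh,
                                None if t.ks_scale is None else t.ks_scale.copy())
                     for t in self.tissues],
            yolk=self.yolk.copy(),
        )


@dataclass
class SimState:
    """Simulation snapshot: geometry plus dynamics bookkeeping."""

    cross_section: CrossSection
    velocities: np.ndarray
    step_count: int = 0
    converged: bool = False
    max_residual_force: float = np.inf
    drift_per_step: float = np.inf
    layout: Optional[CanonicalLayout] = None


@dataclass
class TensionField:
    """Per-spring signed tension ``K_S (l_i - l0)`` and spring midpoints."""

    tissue_names: List[str]
    midpoints: Dict[str, np.ndarray]
    tensions: Dict[str, np.ndarray]


def build_cross_section(layout: CanonicalLayout | str | None = None,
                        params: ModelParams | None = None,
                        seed: Optional[int] = None) -> CrossSection:
    """Construct the canonical four-loop initial condition.

    Raises :class:`GeometryError` if any loop self-intersects or two
    loops start closer than ``R_rep``.
    """
    params = params or ModelParams()
    if layout is None or layout == "canonical":
        layout = CanonicalLayout()
    if not isinstance(layout, CanonicalLayout):
        raise TypeError("layout must be a CanonicalLayout or 'canonical'")
    pos = canonical_positions(layout, params)
    if layout.jitter > 0:
        rng = np.random.default_rng(seed)
        for name in pos:
            pos[name] = pos[name] + rng.normal(0.0, layout.jitter, pos[name].shape)
    tissues = []
    for name, pts in pos.items():
        pts = ensure_ccw(pts)
        if not is_simple(pts):
            raise GeometryError(f"initial loop {name} is self-intersecting")
        tissues.append(TissueLoop(name, pts))
    cs = CrossSection(tissues=tissues, yolk=yolk_points(layout))
    flat = _flatten(cs, params)
    dmin = _kernels.min_cross_tissue_distance(flat["pos"], flat["tissue_id"])
    if dmin < params.R_rep:
        raise GeometryError(
            f"initial loops overlap: min cross-tissue distance {dmin:.4f} < R_rep")
    return cs


def _flatten(cs: CrossSection, params: ModelParams) -> dict:
    """Pack a cross-section into flat arrays for the kernels."""
    pos_list, tid_list, mobile_list = [], [], []
    spring_a, spring_b, ks_spring, kadh_pt = [], [], [], []
    offsets = {}
    offset = 0
    for idx, t in enumerate(cs.tissues):
        n = t.n_points
        offsets[t.name] = (offset, n)
        pos_list.append(t.positions)
        tid_list.append(np.full(n, idx, dtype=np.int64))
        mobile_list.append(np.ones(n, dtype=np.bool_))
        ks = t.K_S if t.K_S is not None else params.K_S
        scale = t.ks_scale if t.ks_scale is not None else np.ones(n)
        ka = t.K_adh if t.K_adh is not None else params.K_adh
        i = np.arange(n)
        spring_a.append(offset + i)
        spring_b.append(offset + (i + 1) % n)
        ks_spring.append(ks * scale)
        kadh_pt.append(np.full(n, ka))
        offset += n
    ny = len(cs.yolk)
    pos_list.append(cs.yolk)
    tid_list.append(np.full(ny, YOLK_ID, dtype=np.int64))
    mobile_list.append(np.zeros(ny, dtype=np.bool_))
    kadh_pt.append(np.full(ny, params.K_adh))
    return {
        "pos": np.ascontiguousarray(np.vstack(pos_list), dtype=np.float64),
        "tissue_id": np.concatenate(tid_list),
        "mobile": np.concatenate(mobile_list),
        "spring_a": np.concatenate(spring_a).astype(np.int64),
        "spring_b": np.concatenate(spring_b).astype(np.int64),
        "ks_spring": np.concatenate(ks_spring).astype(np.float64),
        "kadh_point": np.concatenate(kadh_pt).astype(np.float64),
        "offsets": offsets,
    }


def _unflatten(cs: CrossSection, pos: np.ndarray, offsets: dict) -> CrossSection:
    out = cs.copy()
    for t in out.tissues:
        start, n = offsets[t.name]
        t.positions = pos[start:start + n].copy()
    return out


def tissue_forces(loop: TissueLoop, params: ModelParams) -> np.ndarray:
    """Net surface-spring tension + pressure force on each point of a loop.

    Force on point i is ``T_i - T_{i+1} + (P l0 / 2)(n_i + n_{i+1})`` where
    spring i+1 joins points i and i+1, tensions act along the springs and
    ``n`` are outward edge normals of the CCW loop.
    """
    pts = loop.positions
    n = len(pts)
    ks = loop.K_S if loop.K_S is not None else params.K_S
    scale = loop.ks_scale if loop.ks_scale is not None else np.ones(n)
    edge = np.roll(pts, -1, axis=0) - pts          # edge i: point i -> i+1
    length = np.linalg.norm(edge, axis=1)
    if np.any(length < 1e-12):
        bad = int(np.argmin(length))
        raise SimulationError(f"degenerate spring at point {bad} of {loop.name}")
    unit = edge / length[:, None]
    tension = (ks * scale * (length - params.l0))[:, None] * unit
    normals = np.column_stack([unit[:, 1], -unit[:, 0]])  # outward for CCW
    pressure = 0.5 * params.P * params.l0 * (normals + np.roll(normals, 1, axis=0))
    # point i: pulled along edge i (toward i+1) and along -edge i-1 (toward i-1)
    forces = tension - np.roll(tension, 1, axis=0) + pressure
    return forces


def interaction_force(r_vec: Sequence[float], params: ModelParams,
                      K_adh: Optional[float] = None) -> np.ndarray:
    """Piecewise inter-tissue force on point i given ``r_vec = r_i - r_j``.

    Repulsive ``K_rep (R_rep - r)`` below ``R_rep``, adhesive
    ``-K_adh (r - R_rep)`` up to ``R_adh``, zero beyond.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        raise SimulationError("coincident points: interaction direction undefined")
    ka = params.K_adh if K_adh is None else K_adh
    if r < params.R_rep:
        mag = params.K_rep * (params.R_rep - r)
    elif r <= params.R_adh:
        mag = -ka * (r - params.R_rep)
    else:
        return np.zeros(2)
    return mag * r_vec / r


def _raise_kernel_error(status: int, pos: np.ndarray, forces: np.ndarray) -> None:
    if status == _kernels.ERR_DEGENERATE_SPRING:
        raise SimulationError("degenerate spring (zero length) encountered")
    if status == _kernels.ERR_COINCIDENT:
        raise SimulationError("coincident cross-tissue points encountered")
    if status == _kernels.ERR_NONFINITE:
        bad = np.where(~np.isfinite(forces).all(axis=1))[0]
        where = f" at point index {bad[0]}" if len(bad) else ""
        raise SimulationError(f"non-finite force{where}")
    raise SimulationError(f"kernel error {status}")


def _run(flat: dict, params: ModelParams, n_steps: int, skin: float = 0.1):
    n = len(flat["pos"])
    cap = n * n // 2 + 1
    pair_i = np.empty(cap, dtype=np.int64)
    pair_j = np.empty(cap, dtype=np.int64)
    forces = np.zeros_like(flat["pos"])
    ref = np.zeros_like(flat["pos"])
    mean = np.zeros_like(flat["pos"])
    status, max_force, _ = _kernels.run_chunk(
        flat["pos"], flat["mobile"], flat["tissue_id"],
        flat["spring_a"], flat["spring_b"], flat["ks_spring"],
        flat["kadh_point"], params.l0, params.P, params.K_rep,
        params.R_rep, params.R_adh, params.c, params.dt,
        n_steps, skin, pair_i, pair_j, forces, ref, mean)
    if status != _kernels.OK:
        _raise_kernel_error(status, flat["pos"], forces)
    return max_force, forces, mean


def step(state: SimState, params: ModelParams) -> SimState:
    """Advance the state by a single explicit-Euler step."""
    flat = _flatten(state.cross_section, params)
    max_force, forces, _ = _run(flat, params, 1)
    cs = _unflatten(state.cross_section, flat["pos"], flat["offsets"])
    vel = np.where(flat["mobile"][:, None], forces / params.c, 0.0)
    return SimState(cross_section=cs, velocities=vel,
                    step_count=state.step_count + 1,
                    converged=False, max_residual_force=max_force,
                    layout=state.layout)


def run_to_steady_state(cross_section: CrossSection, params: ModelParams,
                        tol: float = 1e-4, max_steps: int = 4_000_000,
                        chunk: int = 5000, drift_tol: float = 5e-5,
                        min_steps: int = 50_000) -> SimState:
    """Iterate the dynamics until the configuration stops moving.

    Convergence is declared when either the maximum per-point net force
    falls below ``tol`` or the chunk-averaged positions drift by less
    than ``drift_tol`` between consecutive chunks of ``chunk`` steps.
    The averaged criterion is needed because sustained repulsion
    contacts carry a bounded micro-oscillation (the explicit-Euler gain
    ``K_rep dt / c`` exceeds the stability limit) whose instantaneous
    residual force never vanishes even though the shape is stationary.

    Raises :class:`SimulationError` on divergence (chunk residual growing
    more than tenfold above its running minimum).
    """
    flat = _flatten(cross_section, params)
    prev_mean = None
    best_residual = np.inf
    steps_done = 0
    converged = False
    max_force = np.inf
    drift = np.inf
    forces = None
    while steps_done < max_steps:
        n_steps = min(chunk, max_steps - steps_done)
        max_force, forces, mean = _run(flat, params, n_steps)
        steps_done += n_steps
        if prev_mean is not None:
            drift = float(np.max(np.linalg.norm(mean - prev_mean, axis=1)))
        prev_mean = mean.copy()
        best_residual = min(best_residual, max_force)
        if steps_done >= min_steps and max_force > 10.0 * best_residual \
                and max_force > 1e4:
            raise SimulationError(
                f"divergence: residual {max_force:.3g} grew >10x above "
                f"{best_residual:.3g} after {steps_done} steps")
        if max_force < tol or (steps_done >= min_steps and drift < drift_tol):
            converged = True
            break
    cs = _unflatten(cross_section, flat["pos"], flat["offsets"])
    vel = np.where(flat["mobile"][:, None], forces / params.c, 0.0)
    return SimState(cross_section=cs, velocities=vel, step_count=steps_done,
                    converged=converged, max_residual_force=max_force,
                    drift_per_step=drift / chunk if np.isfinite(drift) else drift)


def tension_field(state: SimState, params: ModelParams) -> TensionField:
    """Signed spring tensions ``K_S (l_i - l0)`` with midpoints, per tissue."""
    midpoints: Dict[str, np.ndarray] = {}
    tensions: Dict[str, np.ndarray] = {}
    names = []
    for t in state.cross_section.tissues:
        ks = t.K_S if t.K_S is not None else params.K_S
        scale = t.ks_scale if t.ks_scale is not None else np.ones(t.n_points)
        nxt = np.roll(t.positions, -1, axis=0)
        lengths = np.linalg.norm(nxt - t.positions, axis=1)
        if np.any(lengths < 1e-12):
            raise SimulationError(f"degenerate spring in {t.name}")
        midpoints[t.name] = 0.5 * (t.positions + nxt)
        tensions[t.name] = ks * scale * (lengths - params.l0)
        names.append(t.name)
    return TensionField(tissue_names=names, midpoints=midpoints, tensions=tensions)


def simulate_steady_state(K_S: float, K_adh: float,
                          params: ModelParams | None = None,
                          layout: CanonicalLayout | None = None,
                          overrides: Optional[Dict[str, dict]] = None,
                          seed: Optional[int] = None,
                          **run_kwargs) -> SimState:
    """Convenience wrapper: canonical layout -> steady state at (K_S, K_adh).

    ``overrides`` maps tissue names to ``TissueLoop`` field overrides,
    e.g. ``{"PSM_L": {"K_adh": 5.0}}`` or ``{"NT": {"ks_scale": arr}}``.
    ``seed`` controls the layout's optional symmetry-breaking jitter.
    """
    base = params or ModelParams()
    p = base.with_stiffness(K_S=K_S, K_adh=K_adh)
    cs = build_cross_section(layout or CanonicalLayout(), p, seed=seed)
    if overrides:
        for name, fields in overrides.items():
            t = cs.tissue(name)
            for key, value in fields.items():
                setattr(t, key, value)
            t.__post_init__()
    state = run_to_steady_state(cs, p, **run_kwargs)
    state.layout = layout or CanonicalLayout()
    return state
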