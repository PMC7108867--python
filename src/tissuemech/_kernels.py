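"""Numba kernels for the mass-spring dynamics.

The inner loop (spring forces, piecewise inter-tissue forces, explicit
Euler update) runs entirely inside :func:`run_chunk` with an internal
Verlet-style neighbor list, so Python overhead is paid once per chunk of
steps rather than per step.

Error codes returned by the kernels (negative values):
  -1  degenerate spring (zero length)
  -2  coincident points of different tissues (interaction direction undefined)
  -3  non-finite force encountered
"""

from __future__ import annotations

import numpy as np
from numba import njit

OK = 0
ERR_DEGENERATE_SPRING = -1
ERR_COINCIDENT = -2
ERR_NONFINITE = -3


@njit(cache=True)
def build_pairs(pos, tissue_id, cutoff, pair_i, pair_j):
    """Fill pair arrays with all cross-tissue pairs within ``cutoff``."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if tissue_id[i] == tissue_id[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            if dx * dx + dy * dy < c2:
                pair_i[m] = i
                pair_j[m] = j
                m += 1
    return m


@njit(cache=True)
def compute_forces(pos, forces, spring_a, spring_b, ks_spring, l0, P,
                   pair_i, pair_j, n_pairs, kadh_point,
                   K_rep, R_rep, R_adh):
    """Accumulate tissue + interaction forces into ``forces`` (zeroed here)."""
    forces[:] = 0.0
    n_springs = spring_a.shape[0]
    half_pl0 = 0.5 * P * l0
    for s in range(n_springs):
        a = spring_a[s]
        b = spring_b[s]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        length = np.sqrt(dx * dx + dy * dy)
        if length < 1e-12:
            return ERR_DEGENERATE_SPRING
        ux = dx / length
        uy = dy / length
        t = ks_spring[s] * (length - l0)
        forces[a, 0] += t * ux
        forces[a, 1] += t * uy
        forces[b, 0] -= t * ux
        forces[b, 1] -= t * uy
        # outward normal of a CCW loop edge is the direction rotated -90 deg
        nx = uy
        ny = -ux
        forces[a, 0] += half_pl0 * nx
        forces[a, 1] += half_pl0 * ny
        forces[b, 0] += half_pl0 * nx
        forces[b, 1] += half_pl0 * ny
    for k in range(n_pairs):
        i = pair_i[k]
        j = pair_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = np.sqrt(dx * dx + dy * dy)
        if r > R_adh:
            continue
        if r < 1e-12:
            return ERR_COINCIDENT
        if r < R_rep:
            f = K_rep * (R_rep - r) / r
        else:
            ka = min(kadh_point[i], kadh_point[j])
            f = -ka * (r - R_rep) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
    return OK


@njit(cache=True)
def run_chunk(pos, mobile, tissue_id, spring_a, spring_b, ks_spring,
              kadh_point, l0, P, K_rep, R_rep, R_adh, c, dt,
              n_steps, skin, pair_i, pair_j, forces, ref_pos, mean_pos):
    """Advance ``n_steps`` explicit-Euler steps in place.

    Returns (status, max_force, n_rebuilds).  ``mean_pos`` receives the
    position average over the chunk (for convergence monitoring that is
    insensitive to the fast micro-oscillation at repulsion contacts).
    """
    n = pos.shape[0]
    cutoff = R_adh + skin
    half_skin2 = (0.5 * skin) * (0.5 * skin)
    ref_pos[:] = pos
    n_pairs = build_pairs(pos, tissue_id, cutoff, pair_i, pair_j)
    rebuilds = 1
    mean_pos[:] = 0.0
    inv_c = dt / c
    max_force = 0.0
    for step in range(n_steps):
        status = compute_forces(pos, forces, spring_a, spring_b, ks_spring,
                                l0, P, pair_i, pair_j, n_pairs, kadh_point,
                                K_rep, R_rep, R_adh)
        if status != OK:
            return status, 0.0, rebuilds
        max_force = 0.0
        max_disp2 = 0.0
        for i in range(n):
            if not mobile[i]:
                continue
            fx = forces[i, 0]
            fy = forces[i, 1]
            if not (np.isfinite(fx) and np.isfinite(fy)):
                return ERR_NONFINITE, 0.0, rebuilds
            f2 = fx * fx + fy * fy
            if f2 > max_force:
                max_force = f2
            pos[i, 0] += inv_c * fx
            pos[i, 1] += inv_c * fy
            ddx = pos[i, 0] - ref_pos[i, 0]
            ddy = pos[i, 1] - ref_pos[i, 1]
            d2 = ddx * ddx + ddy * ddy
            if d2 > max_disp2:
                max_disp2 = d2
        for i in range(n):
            mean_pos[i, 0] += pos[i, 0]
            mean_pos[i, 1] += pos[i, 1]
        if max_disp2 > half_skin2:
            ref_pos[:] = pos
            n_pairs = build_pairs(pos, tissue_id, cutoff, pair_i, pair_j)
            rebuilds += 1
    for i in range(n):
        mean_pos[i, 0] /= n_steps
        mean_pos[i, 1] /= n_steps
    return OK, np.sqrt(max_force), rebuilds


@njit(cache=True)
def min_cross_tissue_distance(pos, tissue_id):
    """Minimum distance between points of different tissues (O(n^2))."""
    n = pos.shape[0]
    best = 1e300
    for i in range(n):
        for j in range(i + 1, n):
            if tissue_id[i] == tissue_id[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d2 = dx * dx + dy * dy
            if d2 < best:
                best = d2
    return np.sqrt(best)
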