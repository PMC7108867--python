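"""In-silico campaigns: parameter sweeps, the genotype panel, and
unilateral (contralateral-effect) perturbations.

All campaigns run the canonical cross-section to steady state and emit
tidy :class:`pandas.DataFrame` tables.  Steady states are memoized per
process since several campaigns share parameter points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import CanonicalLayout, canonical_positions
from .model import SimState, SimulationError, simulate_steady_state, tension_field
from .morphometrics import (extract_interface, measure_state, tension_profile)
from .params import GENOTYPES, GenotypePreset, ModelParams


class SweepError(RuntimeError):
    pass


@dataclass
class SweepResult:
    """Tidy sweep table plus the sweep-level normalization."""

    table: pd.DataFrame
    metric: str
    swept: str

    @property
    def normalized(self) -> pd.Series:
        return self.table[f"{self.metric}_norm"]


# -- steady-state memo -------------------------------------------------------

_STATE_CACHE: Dict[tuple, SimState] = {}


def _override_key(overrides: Optional[dict]) -> tuple:
    if not overrides:
        return ()
    items = []
    for name in sorted(overrides):
        for k in sorted(overrides[name]):
            v = overrides[name][k]
            if isinstance(v, np.ndarray):
                v = tuple(np.round(v, 12))
            items.append((name, k, v))
    return tuple(items)


def steady_state(K_S: float, K_adh: float,
                 layout: Optional[CanonicalLayout] = None,
                 params: Optional[ModelParams] = None,
                 overrides: Optional[dict] = None, **run_kwargs) -> SimState:
    """Memoized steady state of the canonical cross-section."""
    layout = layout or CanonicalLayout()
    params = params or ModelParams()
    key = (float(K_S), float(K_adh), layout, params,
           _override_key(overrides), tuple(sorted(run_kwargs.items())))
    if key not in _STATE_CACHE:
        _STATE_CACHE[key] = simulate_steady_state(
            K_S, K_adh, params=params, layout=layout, overrides=overrides,
            **run_kwargs)
    return _STATE_CACHE[key]


def clear_cache() -> None:
    _STATE_CACHE.clear()


# -- sweeps ------------------------------------------------------------------

def _mean_or_nan(d: dict) -> float:
    return float(np.mean(list(d.values()))) if d else np.nan


def _run_grid(points: Sequence[Tuple[float, float]],
              layout: Optional[CanonicalLayout],
              params: Optional[ModelParams]) -> pd.DataFrame:
    rows = []
    for ks, ka in points:
        row = {"K_S": ks, "K_adh": ka}
        try:
            st = steady_state(ks, ka, layout=layout, params=params)
            p = (params or ModelParams()).with_stiffness(ks, ka)
            m = measure_state(st, p)
            row.update(m.as_dict())
            row["L_psm_nt"] = _mean_or_nan(m.L_psm_nt)
            row["theta"] = _mean_or_nan(m.angle_theta)
            row["width_over_L"] = row["nt_ml_width"] / row["L_psm_nt"]
            row["detached"] = any(v > 0 for v in m.n_gaps.values())
            row["converged"] = bool(st.converged)
        except SimulationError as exc:
            row["converged"] = False
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _check_failures(df: pd.DataFrame) -> None:
    frac_failed = 1.0 - df["converged"].mean()
    if frac_failed > 0.2:
        raise SweepError(
            f"{frac_failed:.0%} of sweep runs failed to converge; aborting")


def sweep_surface_stiffness(ks_grid: Sequence[float], K_adh: float = 10.0,
                            layout: Optional[CanonicalLayout] = None,
                            params: Optional[ModelParams] = None) -> SweepResult:
    """Steady states along a surface-stiffness grid at fixed adhesion.

    The interfacial length is normalized to its maximum over the
    converged runs of the sweep.
    """
    ks_grid = list(ks_grid)
    if sorted(ks_grid) != ks_grid:
        raise ValueError("K_S grid must be sorted ascending")
    df = _run_grid([(ks, K_adh) for ks in ks_grid], layout, params)
    _check_failures(df)
    ok = df["converged"]
    df["L_psm_nt_norm"] = np.where(ok, df["L_psm_nt"] / df.loc[ok, "L_psm_nt"].max(),
                                   np.nan)
    return SweepResult(table=df, metric="L_psm_nt", swept="K_S")


def sweep_adhesion_stiffness(ka_grid: Sequence[float], K_S: float = 100.0,
                             layout: Optional[CanonicalLayout] = None,
                             params: Optional[ModelParams] = None) -> SweepResult:
    """Steady states along an adhesion-stiffness grid at fixed K_S.

    The headline metric is the neural-tube ML width over the interfacial
    length; its saturation value is the mean over grid points with
    K_adh in [8, 12].
    """
    ka_grid = list(ka_grid)
    if sorted(ka_grid) != ka_grid:
        raise ValueError("K_adh grid must be sorted ascending")
    df = _run_grid([(K_S, ka) for ka in ka_grid], layout, params)
    _check_failures(df)
    ok = df["converged"]
    df["width_over_L_norm"] = np.where(
        ok, df["width_over_L"] / df.loc[ok, "width_over_L"].max(), np.nan)
    return SweepResult(table=df, metric="width_over_L", swept="K_adh")


def saturation_value(result: SweepResult, lo: float = 8.0,
                     hi: float = 12.0) -> float:
    """Mean of the sweep metric over grid points with K_adh in [lo, hi]."""
    df = result.table
    sel = (df["K_adh"] >= lo) & (df["K_adh"] <= hi) & df["converged"]
    if not sel.any():
        raise SweepError("no converged grid points in the saturation window")
    return float(df.loc[sel, result.metric].mean())


# -- genotype panel ----------------------------------------------------------

def genotype_panel(presets: Optional[Iterable[GenotypePreset]] = None,
                   layout: Optional[CanonicalLayout] = None,
                   params: Optional[ModelParams] = None) -> pd.DataFrame:
    """Interfacial length and angle for each preset, relative to WT."""
    if presets is None:
        presets = [GENOTYPES[k] for k in ("WT", "cdh2", "itga5", "cdh2_itga5")]
    presets = list(presets)
    if not any(g.name == "WT" for g in presets):
        raise ValueError("genotype panel requires a WT preset")
    rows = []
    for g in presets:
        st = steady_state(g.K_S, g.K_adh, layout=layout, params=params)
        p = (params or ModelParams()).with_stiffness(g.K_S, g.K_adh)
        m = measure_state(st, p)
        rows.append({"genotype": g.name, "K_S": g.K_S, "K_adh": g.K_adh,
                     "L_psm_nt": _mean_or_nan(m.L_psm_nt),
                     "theta": _mean_or_nan(m.angle_theta),
                     "converged": bool(st.converged)})
    df = pd.DataFrame(rows).set_index("genotype")
    wt = df.loc["WT"]
    df["L_rel"] = df["L_psm_nt"] / wt["L_psm_nt"]
    df["theta_rel"] = df["theta"] / wt["theta"]
    return df.reset_index()


# -- asymmetric perturbations ------------------------------------------------

@dataclass
class PerturbationResult:
    mode: str
    factor: float
    symmetric: SimState
    perturbed: SimState
    slope_right_symmetric: float
    slope_right_perturbed: float
    asymmetry_symmetric: float
    asymmetry_perturbed: float


def _right_nt_slope(state: SimState, params: ModelParams) -> float:
    """Medial->lateral tension slope on the NT side of the right interface."""
    rec = extract_interface(state, "PSM_R", "NT", params=params)
    fld = tension_field(state, params)
    nc = state.cross_section.tissue("NC").positions
    midline = float(nc[:, 0].mean())
    mids = fld.midpoints["NT"]
    right = mids[:, 0] >= midline
    sub = type(fld)(tissue_names=["NT"],
                    midpoints={"NT": mids[right]},
                    tensions={"NT": fld.tensions["NT"][right]})
    _, _, slope = tension_profile(rec, sub, "NT", midline_x=midline,
                                  params=params)
    return slope


def _nt_half_scale(layout: CanonicalLayout, params: ModelParams,
                   factor: float) -> np.ndarray:
    """Per-spring K_S multipliers reducing the NT's left-half surface."""
    pos = canonical_positions(layout, params)["NT"]
    mid_x = 0.5 * (pos[:, 0] + np.roll(pos[:, 0], -1))
    return np.where(mid_x < 0.0, factor, 1.0)


def asymmetric_perturbation(mode: str, factor: float,
                            K_S: float = 200.0, K_adh: float = 10.0,
                            layout: Optional[CanonicalLayout] = None,
                            params: Optional[ModelParams] = None
                            ) -> PerturbationResult:
    """Left-sided perturbation versus the matched symmetric run.

    ``mode='left_adhesion'`` scales the left PSM's adhesion stiffness by
    ``factor``; ``mode='left_NT_halfsurface'`` scales the surface
    stiffness of the NT's left-half springs.  Reported are the tension
    gradient on the (unperturbed) right side of the NT and the PSM area
    asymmetry, for both runs.
    """
    if not 0 < factor <= 1:
        raise ValueError("reduction factor must lie in (0, 1]")
    layout = layout or CanonicalLayout()
    base = (params or ModelParams()).with_stiffness(K_S, K_adh)
    if mode == "left_adhesion":
        overrides = {"PSM_L": {"K_adh": factor * K_adh}}
    elif mode == "left_NT_halfsurface":
        overrides = {"NT": {"ks_scale": _nt_half_scale(layout, base, factor)}}
    else:
        raise ValueError("mode must be 'left_adhesion' or 'left_NT_halfsurface'")
    sym = steady_state(K_S, K_adh, layout=layout, params=params)
    pert = steady_state(K_S, K_adh, layout=layout, params=params,
                        overrides=overrides)
    m_sym = measure_state(sym, base)
    m_pert = measure_state(pert, base)
    return PerturbationResult(
        mode=mode, factor=factor, symmetric=sym, perturbed=pert,
        slope_right_symmetric=_right_nt_slope(sym, base),
        slope_right_perturbed=_right_nt_slope(pert, base),
        asymmetry_symmetric=m_sym.lr_area_diff,
        asymmetry_perturbed=m_pert.lr_area_diff)
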