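"""Deterministic run manifests and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .geometry import CanonicalLayout
from .params import GENOTYPES, ModelParams


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: Dict[str, dict] = field(default_factory=dict)
    completed: bool = False

    def record(self, stage: str, outputs: Dict[str, Path]) -> None:
        self.stages[stage] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "sha256": {k: sha256_of(p) for k, p in outputs.items()},
        }

    def fail(self, stage: str, error: Exception) -> None:
        self.stages[stage] = {"error": f"{type(error).__name__}: {error}"}

    def write(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def write_state_csv(state, path: Path) -> None:
    rows = []
    for t in state.cross_section.tissues:
        for i, (x, y) in enumerate(t.positions):
            rows.append({"tissue": t.name, "index": i, "x": x, "y": y})
    for i, (x, y) in enumerate(state.cross_section.yolk):
        rows.append({"tissue": "yolk", "index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_state_csv(path: Path, layout: Optional[CanonicalLayout] = None):
    from .model import CrossSection, SimState, TissueLoop
    df = pd.read_csv(path)
    tissues = []
    for name, grp in df[df.tissue != "yolk"].groupby("tissue", sort=False):
        grp = grp.sort_values("index")
        tissues.append(TissueLoop(str(name), grp[["x", "y"]].to_numpy()))
    yolk_df = df[df.tissue == "yolk"].sort_values("index")
    if len(yolk_df):
        yolk = yolk_df[["x", "y"]].to_numpy()
    else:
        from .geometry import yolk_points
        yolk = yolk_points(layout or CanonicalLayout())
    cs = CrossSection(tissues=tissues, yolk=yolk)
    n = sum(t.n_points for t in tissues) + len(yolk)
    return SimState(cross_section=cs, velocities=np.zeros((n, 2)))


def write_tension_csv(tfield, path: Path) -> None:
    rows = []
    for name in tfield.tissue_names:
        mids = tfield.midpoints[name]
        for i, t in enumerate(tfield.tensions[name]):
            rows.append({"tissue": name, "spring": i, "x": mids[i, 0],
                         "y": mids[i, 1], "tension": t})
    pd.DataFrame(rows).to_csv(path, index=False)


def run_all(config: dict, out_dir: Path, seed: int = 0) -> RunManifest:
    """simulate -> measure -> sweeps -> genotypes -> perturbations ->
    synthetic images -> quantification.  Every stage writes under
    ``out_dir``; failures are recorded and later stages still run."""
    from . import experiments, imquant, model, morphometrics, synth, tension_field
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed)
    layout = CanonicalLayout(**config.get("layout", {}))
    params = ModelParams(**config.get("model", {}))

    def stage(name, fn):
        try:
            manifest.record(name, fn())
        except Exception as exc:                          # noqa: BLE001
            manifest.fail(name, exc)

    def _simulate():
        wt = GENOTYPES["WT"]
        st = experiments.steady_state(wt.K_S, wt.K_adh, layout=layout,
                                      params=params)
        p = params.with_stiffness(wt.K_S, wt.K_adh)
        state_path = out_dir / "wt_state.csv"
        write_state_csv(st, state_path)
        tension_path = out_dir / "wt_tension.csv"
        write_tension_csv(tension_field(st, p), tension_path)
        conv_path = out_dir / "wt_convergence.json"
        with open(conv_path, "w") as fh:
            json.dump({"steps": st.step_count, "converged": st.converged,
                       "max_residual_force": st.max_residual_force}, fh)
        return {"state": state_path, "tension": tension_path,
                "convergence": conv_path}

    def _measure():
        wt = GENOTYPES["WT"]
        st = experiments.steady_state(wt.K_S, wt.K_adh, layout=layout,
                                      params=params)
        p = params.with_stiffness(wt.K_S, wt.K_adh)
        m = morphometrics.measure_state(st, p)
        path = out_dir / "wt_morphometrics.csv"
        pd.DataFrame([m.as_dict()]).to_csv(path, index=False)
        return {"morphometrics": path}

    def _sweeps():
        ks = experiments.sweep_surface_stiffness(
            config.get("ks_grid", [35, 50, 75, 100, 150, 200]),
            layout=layout, params=params)
        ka = experiments.sweep_adhesion_stiffness(
            config.get("ka_grid", [5, 6.5, 8, 10, 12]),
            layout=layout, params=params)
        p1 = out_dir / "sweep_ks.csv"
        p2 = out_dir / "sweep_kadh.csv"
        ks.table.to_csv(p1, index=False)
        ka.table.to_csv(p2, index=False)
        return {"sweep_ks": p1, "sweep_kadh": p2}

    def _genotypes():
        df = experiments.genotype_panel(layout=layout, params=params)
        path = out_dir / "genotypes.csv"
        df.to_csv(path, index=False)
        return {"genotypes": path}

    def _perturb():
        rows = []
        for mode in ("left_adhesion", "left_NT_halfsurface"):
            res = experiments.asymmetric_perturbation(
                mode, config.get("perturbation_factor", 0.8),
                layout=layout, params=params)
            rows.append({"mode": mode, "factor": res.factor,
                         "slope_right_symmetric": res.slope_right_symmetric,
                         "slope_right_perturbed": res.slope_right_perturbed,
                         "asymmetry_symmetric": res.asymmetry_symmetric,
                         "asymmetry_perturbed": res.asymmetry_perturbed})
        path = out_dir / "perturbations.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return {"perturbations": path}

    def _synth():
        img, truth = synth.gen_matrix_image(
            width_um=150, height_um=50, n_small=20, n_large=2,
            ml_gradient_slope=0.8, seed=seed, small_range_um=(4, 25),
            large_range_um=(40, 70))
        m_path = out_dir / "synthetic_matrix.tif"
        tifffile.imwrite(m_path, img.data)
        series = synth.gen_spot_series(ml_shrink_fraction=0.4, n_frames=5,
                                       seed=seed)
        s_path = out_dir / "synthetic_spots.tif"
        tifffile.imwrite(s_path, np.stack([f.data for f in series.frames]))
        truth_path = out_dir / "synthetic_truth.json"
        with open(truth_path, "w") as fh:
            json.dump({"matrix_slope": truth.ml_gradient_slope,
                       "n_elements": len(truth.size_classes),
                       "spot_ml_extents_px": series.ml_extents_px.tolist()},
                      fh)
        return {"matrix": m_path, "spots": s_path, "truth": truth_path}

    def _quantify():
        import tifffile as tf
        img = tf.imread(out_dir / "synthetic_matrix.tif")
        mask = imquant.local_threshold_phansalkar(img)
        classes = imquant.size_sort(mask)
        tissue = imquant.BinaryMask(np.ones_like(mask.data), mask.pixels_per_um)
        profile = imquant.ml_distribution(classes.small, tissue)
        p1 = out_dir / "ml_distribution.csv"
        pd.DataFrame({"position": profile.positions,
                      "fraction": profile.values}).to_csv(p1, index=False)
        frames = tf.imread(out_dir / "synthetic_spots.tif")
        masks = [imquant.otsu_mask(f) for f in frames]
        sm = imquant.spot_metrics(masks)
        p2 = out_dir / "spot_metrics.csv"
        pd.DataFrame({"width_px": sm.widths, "height_px": sm.heights,
                      "width_norm": sm.widths_norm,
                      "height_norm": sm.heights_norm}).to_csv(p2, index=False)
        return {"ml_distribution": p1, "spot_metrics": p2}

    stage("simulate", _simulate)
    stage("measure", _measure)
    stage("sweeps", _sweeps)
    stage("genotypes", _genotypes)
    stage("perturbations", _perturb)
    stage("synth", _synth)
    stage("quantify", _quantify)
    manifest.completed = all("error" not in s for s in manifest.stages.values())
    manifest.write(out_dir / "manifest.json")
    return manifest
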