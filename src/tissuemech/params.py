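"""Model parameters and named parameter presets.

All quantities are in dimensionless model units.  The fixed constants
(``l0``, ``K_rep``, ``c``, ``R_rep``, ``R_adh``, ``P``, ``dt``) are never
varied between runs; only the surface stiffness ``K_S`` and the adhesion
stiffness ``K_adh`` differ between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict


@dataclass(frozen=True)
class ModelParams:
    """Constants of the mass-spring cross-section model.

    Attributes
    ----------
    K_S : float
        Surface-spring stiffness (tissue surface tension proxy).
    K_adh : float
        Inter-tissue adhesive-spring stiffness.
    K_rep : float
        Volume-exclusion repulsion stiffness.
    P : float
        Internal pressure acting outward at the tissue surface.
    l0 : float
        Rest length of the surface springs.
    R_rep : float
        Range below which point pairs of different tissues repel.
    R_adh : float
        Range up to which point pairs of different tissues adhere.
    c : float
        Viscous drag coefficient of the overdamped dynamics.
    dt : float
        Explicit-Euler time step.
    N : int
        Number of mass points per tissue loop.
    """

    K_S: float = 100.0
    K_adh: float = 10.0
    K_rep: float = 30000.0
    P: float = 5.0
    l0: float = 0.1
    R_rep: float = 0.1
    R_adh: float = 0.2
    c: float = 10.0
    dt: float = 0.001
    N: int = 50

    def __post_init__(self) -> None:
        for name in ("K_S", "K_adh", "K_rep", "P", "l0", "R_rep", "R_adh", "c", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.N < 3:
            raise ValueError("N must be at least 3")
        if not self.R_rep < self.R_adh:
            raise ValueError("R_rep must be smaller than R_adh")

    def with_stiffness(self, K_S: float | None = None, K_adh: float | None = None) -> "ModelParams":
        kw = {}
        if K_S is not None:
            kw["K_S"] = K_S
        if K_adh is not None:
            kw["K_adh"] = K_adh
        return replace(self, **kw)


@dataclass(frozen=True)
class GenotypePreset:
    """A named (K_S, K_adh) pair."""

    name: str
    K_S: float
    K_adh: float


#: The four genotype presets used throughout, plus the high-stiffness
#: preset used for tension maps.
GENOTYPES: Dict[str, GenotypePreset] = {
    "WT": GenotypePreset("WT", 100.0, 10.0),
    "cdh2": GenotypePreset("cdh2", 55.0, 12.0),
    "itga5": GenotypePreset("itga5", 100.0, 6.5),
    "cdh2_itga5": GenotypePreset("cdh2_itga5", 55.0, 6.5),
    "tension_map": GenotypePreset("tension_map", 200.0, 10.0),
}

#: Exploration points: K_adh varied at fixed K_S=50, K_S varied at fixed K_adh=8.
EXPLORATION_POINTS = (
    GenotypePreset("lowadh", 50.0, 4.0),
    GenotypePreset("highadh", 50.0, 12.0),
    GenotypePreset("lowstiff", 35.0, 8.0),
    GenotypePreset("highstiff", 100.0, 8.0),
)
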