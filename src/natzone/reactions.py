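"""Nitrogen-cycle reaction network: stoichiometry and Monod kinetics.

Four volumetric reactions drive the porewater nitrogen cycle in this model:

* aerobic organic-carbon mineralization (consumes O2, releases NH4+),
* denitrifying mineralization (consumes NO3−, releases NH4+),
* nitrification (NH4+ + 2 O2 → NO3−),
* anammox, lumped on nitrate with electron-balanced stoichiometry
  5 NH4+ + 3 NO3− → 4 N2, i.e. per mol NH4+ oxidized: 0.6 mol NO3−
  consumed and 1.6 mol N released as N2. Nitrite is not carried as an
  explicit state because it is not measured in the profiles this model is
  fitted to; the lumped form keeps the anammox niche (the depth interval
  where nitrate and ammonium co-occur) intact.

Organic-carbon mineralization follows a prescribed exponentially
attenuating profile R_C(z) = R0·exp(−z/z_att); the aerobic and
denitrifying pathways split it by substrate availability, and any
remainder is implicitly routed to deeper electron acceptors (sulfate
reduction and beyond), which are out of scope and leave no tracked
products. N2 is carried as a produced-nitrogen diagnostic pool only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "KineticParams",
    "RateVector",
    "monod",
    "inhibition",
    "volumetric_rates",
    "species_sources",
]

#: mol NO3− consumed per mol C mineralized by denitrification (5 CH2O : 4 NO3−)
NO3_PER_C_DENIT = 0.8
#: mol O2 consumed per mol NH4+ nitrified
O2_PER_NH4_NIT = 2.0
#: anammox, per mol NH4+: NO3− demand and N2-N yield (5 NH4+ + 3 NO3− → 4 N2)
NO3_PER_NH4_AMX = 0.6
N2N_PER_NH4_AMX = 1.6
#: mol N2-N produced per mol C denitrified (4 NO3− → 2 N2 per 5 C)
N2N_PER_C_DENIT = 0.8


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the nitrogen network.

    Parameters
    ----------
    R0 : float
        Organic-carbon mineralization rate at the sediment surface,
        µM-C·yr⁻¹.
    z_att : float
        e-folding attenuation depth of mineralization, m.
    r_NC : float
        N:C mole ratio of mineralized organic matter; Redfield 16/106 by
        default.
    k_nit : float
        Nitrification rate constant, yr⁻¹ (first order in NH4+).
    k_amx : float
        Anammox bimolecular rate constant, µM⁻¹·yr⁻¹.
    K_O2, K_O2nit, K_NO3 : float
        Monod half-saturations (µM) for O2 in aerobic mineralization, O2 in
        nitrification, and NO3− in denitrification.
    Ki_O2 : float
        O2 inhibition constant (µM) applied to the anaerobic pathways
        (denitrification and anammox).
    """

    R0: float = 2460.0
    z_att: float = 0.05
    r_NC: float = 16.0 / 106.0
    k_nit: float = 500.0
    k_amx: float = 0.02
    K_O2: float = 1.0
    K_O2nit: float = 2.0
    K_NO3: float = 1.0
    Ki_O2: float = 2.0

    def __post_init__(self) -> None:
        for name in ("R0", "z_att", "r_NC", "k_nit", "k_amx", "K_O2", "K_O2nit", "K_NO3", "Ki_O2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"kinetic parameter {name} must be > 0")
        if not self.r_NC < 1:
            raise ValueError(f"r_NC must be in (0, 1), got {self.r_NC}")

    def replace(self, **updates) -> "KineticParams":
        from dataclasses import replace as _replace

        return _replace(self, **updates)


@dataclass(frozen=True)
class RateVector:
    """Per-cell volumetric reaction rates, µM·yr⁻¹.

    ``R_O2C``/``R_denC`` are carbon-based mineralization rates; ``R_nit``
    and ``R_amx`` are per mol NH4+.
    """

    R_O2C: np.ndarray
    R_denC: np.ndarray
    R_nit: np.ndarray
    R_amx: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "R_O2C": self.R_O2C,
            "R_denC": self.R_denC,
            "R_nit": self.R_nit,
            "R_amx": self.R_amx,
        }


def monod(c, K):
    """Saturation factor c/(c+K) ∈ [0, 1)."""
    c = np.asarray(c, dtype=float)
    if not K > 0:
        raise ValueError(f"half-saturation K must be > 0, got {K}")
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = c / (c + K)
    return out if out.ndim else float(out)


def inhibition(c, Ki):
    """Inhibition factor Ki/(Ki+c) ∈ (0, 1]; 1 at full anoxia."""
    c = np.asarray(c, dtype=float)
    if not Ki > 0:
        raise ValueError(f"inhibition constant Ki must be > 0, got {Ki}")
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = Ki / (Ki + c)
    return out if out.ndim else float(out)


def volumetric_rates(concs: dict[str, np.ndarray], grid: Grid, kp: KineticParams) -> RateVector:
    """Evaluate the four reaction rates at every cell.

    ``concs`` maps ``"O2"``, ``"NO3"``, ``"NH4"`` to per-cell µM arrays.
    """
    o2 = np.asarray(concs["O2"], dtype=float)
    no3 = np.asarray(concs["NO3"], dtype=float)
    nh4 = np.asarray(concs["NH4"], dtype=float)
    if np.any(o2 < 0) or np.any(no3 < 0) or np.any(nh4 < 0):
        raise ValueError("concentrations must be >= 0")
    z = grid.cell_centers
    R_C = kp.R0 * np.exp(-z / kp.z_att)
    f_o2 = monod(o2, kp.K_O2)
    inhib = inhibition(o2, kp.Ki_O2)
    R_O2C = R_C * f_o2
    R_denC = R_C * (1.0 - f_o2) * monod(no3, kp.K_NO3) * inhib
    R_nit = kp.k_nit * nh4 * monod(o2, kp.K_O2nit)
    R_amx = kp.k_amx * nh4 * no3 * inhib
    return RateVector(R_O2C=R_O2C, R_denC=R_denC, R_nit=R_nit, R_amx=R_amx)


def species_sources(rates: RateVector, kp: KineticParams) -> dict[str, np.ndarray]:
    """Net volumetric source terms (µM·yr⁻¹) per species from a RateVector.

    ``N2N`` is the diagnostic produced-nitrogen pool (mol N in N2); the
    fixed-nitrogen bookkeeping S_N2N = −S_NO3 − S_NH4 + r_NC·(R_O2C+R_denC)
    holds identically.
    """
    S_O2 = -rates.R_O2C - O2_PER_NH4_NIT * rates.R_nit
    S_NO3 = rates.R_nit - NO3_PER_C_DENIT * rates.R_denC - NO3_PER_NH4_AMX * rates.R_amx
    S_NH4 = kp.r_NC * (rates.R_O2C + rates.R_denC) - rates.R_nit - rates.R_amx
    S_N2N = N2N_PER_C_DENIT * rates.R_denC + N2N_PER_NH4_AMX * rates.R_amx
    return {"O2": S_O2, "NO3": S_NO3, "NH4": S_NH4, "N2N": S_N2N}
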