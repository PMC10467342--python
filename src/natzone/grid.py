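"""Spatial discretization and porosity-corrected transport coefficients.

The depth axis is meters below the sediment-water interface, positive
downward, with z = 0 at the interface. Concentrations are in µM
(mmol per m³ of porewater) and time is in years throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "PorosityModel",
    "TransportParams",
    "build_grid",
    "porosity_on_grid",
    "effective_diffusivity",
    "SPECIES",
]

#: Dissolved species carried by the nitrogen-cycle model, in state order.
SPECIES = ("O2", "NO3", "NH4")


@dataclass(frozen=True)
class Grid:
    """Cell-centered 1-D grid over the sediment column.

    Attributes
    ----------
    cell_centers : ndarray
        Depths of cell centers (m), strictly increasing.
    cell_widths : ndarray
        Cell widths Δz (m); they sum to the domain extent.
    interfaces : ndarray
        The ``n_cells + 1`` interface depths (m), from 0 to the extent.
    """

    cell_centers: np.ndarray
    cell_widths: np.ndarray
    interfaces: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cell_centers, dtype=float)
        w = np.asarray(self.cell_widths, dtype=float)
        f = np.asarray(self.interfaces, dtype=float)
        object.__setattr__(self, "cell_centers", c)
        object.__setattr__(self, "cell_widths", w)
        object.__setattr__(self, "interfaces", f)
        if c.ndim != 1 or c.size < 1 or c.size != w.size or f.size != c.size + 1:
            raise ValueError("inconsistent grid arrays")
        if np.any(np.diff(f) <= 0) or (c.size > 1 and np.any(np.diff(c) <= 0)):
            raise ValueError("grid depths must be strictly increasing")
        if np.any(c <= f[:-1]) or np.any(c >= f[1:]):
            raise ValueError("cell centers must lie strictly inside their cells")

    @property
    def n_cells(self) -> int:
        return self.cell_centers.size

    @property
    def extent(self) -> float:
        """Total depth extent L (m)."""
        return float(self.interfaces[-1] - self.interfaces[0])


@dataclass(frozen=True)
class PorosityModel:
    """Exponential porosity-depth law φ(z) = φ_inf + (φ0 − φ_inf)·exp(−z/λ).

    With ``lam=inf`` (the default) porosity is constant at ``phi0``; this is
    the package default because site-specific compaction data are rarely
    available at the scales modelled here.
    """

    phi0: float = 0.8
    phi_inf: float | None = None
    lam: float = math.inf

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0 <= 1.0:
            raise ValueError(f"phi0 must be in (0, 1], got {self.phi0}")
        if self.phi_inf is not None and not 0.0 < self.phi_inf <= 1.0:
            raise ValueError(f"phi_inf must be in (0, 1], got {self.phi_inf}")
        if not self.lam > 0:
            raise ValueError(f"attenuation length lam must be > 0, got {self.lam}")

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        if self.phi_inf is None or not math.isfinite(self.lam):
            out = np.full_like(z, self.phi0)
        else:
            out = self.phi_inf + (self.phi0 - self.phi_inf) * np.exp(-z / self.lam)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class TransportParams:
    """Free-solution diffusivities (m²·yr⁻¹) per species and burial velocity.

    ``w`` is the (constant) porewater burial velocity in m·yr⁻¹, positive
    downward. Defaults are representative of cold (≈ 0–4 °C) bottom water.
    """

    D0: dict[str, float] = field(
        default_factory=lambda: {"O2": 0.0365, "NO3": 0.0345, "NH4": 0.0350}
    )
    w: float = 5.0e-5

    def __post_init__(self) -> None:
        for sp, d in self.D0.items():
            if not d > 0:
                raise ValueError(f"D0[{sp!r}] must be > 0, got {d}")
        if self.w < 0:
            raise ValueError(f"burial velocity w must be >= 0, got {self.w}")


def build_grid(L: float, n_cells: int, spacing: str = "uniform", ratio: float = 1.0) -> Grid:
    """Build a cell-centered grid over ``[0, L]``.

    Parameters
    ----------
    L : float
        Domain extent in meters (> 0).
    n_cells : int
        Number of cells (>= 1).
    spacing : {"uniform", "geometric"}
        ``geometric`` makes successive cell widths grow by ``ratio``.
    ratio : float
        Width growth factor for geometric spacing (> 0).
    """
    if not L > 0:
        raise ValueError(f"domain extent L must be > 0, got {L}")
    if not isinstance(n_cells, (int, np.integer)) or n_cells < 1:
        raise ValueError(f"n_cells must be a positive integer, got {n_cells}")
    if spacing == "uniform":
        widths = np.full(n_cells, L / n_cells)
    elif spacing == "geometric":
        if not ratio > 0:
            raise ValueError(f"geometric ratio must be > 0, got {ratio}")
        weights = ratio ** np.arange(n_cells, dtype=float)
        widths = L * weights / weights.sum()
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    interfaces = np.concatenate([[0.0], np.cumsum(widths)])
    interfaces[-1] = L  # absorb cumulative-sum round-off
    centers = 0.5 * (interfaces[:-1] + interfaces[1:])
    return Grid(cell_centers=centers, cell_widths=widths, interfaces=interfaces)


def porosity_on_grid(grid: Grid, pm: PorosityModel) -> np.ndarray:
    """Evaluate porosity at cell centers, validating the (0, 1] range."""
    phi = np.asarray(pm(grid.cell_centers), dtype=float)
    if np.any(phi <= 0) or np.any(phi > 1):
        raise ValueError("porosity model yields values outside (0, 1] on the grid")
    return phi


def effective_diffusivity(D0, phi):
    """Tortuosity-corrected porewater diffusivity Ds = D0 / (1 − ln φ²).

    This is Boudreau's empirical relation between tortuosity and porosity,
    the standard correction in marine diagenetic modelling. Ds ≤ D0 with
    equality only at φ = 1, and Ds increases monotonically with φ.
    """
    D0 = np.asarray(D0, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi > 1):
        raise ValueError("porosity must be in (0, 1]")
    if np.any(D0 <= 0):
        raise ValueError("free-solution diffusivity D0 must be > 0")
    out = D0 / (1.0 - np.log(phi**2))
    return out if out.ndim else float(out)
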