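"""Model/Results front end for the sediment nitrogen-cycle pipeline.

``SedimentNitrogenModel`` bundles a scenario (grid, porosity, transport,
kinetics, boundary conditions) the way a statsmodels model bundles data
and design: ``solve()`` returns a :class:`SteadyStateResults` carrying the
steady-state profiles, reaction rates and diagnostics, and
``fit()`` calibrates free parameters against an observed profile set,
returning :class:`CalibrationResults` with estimates and a summary table.

Example
-------
>>> from natzone import SedimentNitrogenModel
>>> model = SedimentNitrogenModel.from_reference()
>>> res = model.solve()
>>> zone = res.nat_zone()
>>> round(zone.midpoint, 2)
2.25
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate as _calibrate
from . import config as _config
from .calibrate import CalibrationResult, ForwardSetup, ObservedProfileSet
from .niche import ConcentrationProfile, NATZone, detect_nat_zone, rate_maximum_depth
from .solver import (
    SolutionState,
    depth_integrated_rate,
    mass_balance_report,
    solve_steady_state,
)

__all__ = ["SedimentNitrogenModel", "SteadyStateResults", "CalibrationResults"]


class SedimentNitrogenModel:
    """Steady-state reaction-transport model of porewater O2/NO3−/NH4+.

    Parameters
    ----------
    scenario : natzone.config.Scenario
        A resolved configuration; use :meth:`from_config` /
        :meth:`from_reference` for the common constructions.
    """

    def __init__(self, scenario: _config.Scenario):
        self.scenario = scenario

    @classmethod
    def from_config(cls, path: str | Path | None = None) -> "SedimentNitrogenModel":
        """Build from a YAML configuration file (defaults if None)."""
        return cls(_config.load_config(path))

    @classmethod
    def from_reference(cls) -> "SedimentNitrogenModel":
        """The packaged GS13-CC2-like reference scenario."""
        return cls(_config.load_config(_config.reference_config_path()))

    # -- convenience accessors -------------------------------------------
    @property
    def grid(self):
        return self.scenario.grid

    @property
    def setup(self) -> ForwardSetup:
        return self.scenario.setup

    def with_params(self, **params) -> "SedimentNitrogenModel":
        """A copy with named free parameters (e.g. ``k_amx=0.1``) applied."""
        setup = self.setup.with_params(params)
        scenario = replace(self.scenario, kinetics=setup.kinetics,
                           transport=setup.transport, bc=setup.bc)
        return SedimentNitrogenModel(scenario)

    # -- solving and fitting ---------------------------------------------
    def solve(self, **options) -> "SteadyStateResults":
        """Solve for the steady state; ``options`` override solver options."""
        s = self.scenario
        opts = replace(s.solver_options, **options) if options else s.solver_options
        sol = solve_steady_state(s.grid, s.porosity, s.transport, s.kinetics, s.bc,
                                 options=opts)
        return SteadyStateResults(self, sol)

    def fit(self, observed: ObservedProfileSet, free: list[str] | None = None,
            bounds: dict | None = None, start: dict | None = None,
            seed: int | None = None, **opts) -> "CalibrationResults":
        """Calibrate free parameters to observed profiles.

        Defaults for ``free``/``bounds``/``start``/``seed`` come from the
        scenario's ``fit`` block.
        """
        fit_cfg = self.scenario.raw["fit"]
        free = list(fit_cfg["free"]) if free is None else free
        bounds = {k: tuple(v) for k, v in fit_cfg["bounds"].items()} if bounds is None else bounds
        start = dict(fit_cfg["start"]) if start is None else start
        seed = fit_cfg["seed"] if seed is None else seed
        result = _calibrate.fit_parameters(observed, free, bounds, start, self.setup,
                                           seed=seed, **opts)
        return CalibrationResults(self, result, observed)


class SteadyStateResults:
    """Steady-state solution with diagnostics and niche-mapping helpers."""

    def __init__(self, model: SedimentNitrogenModel, solution: SolutionState):
        self.model = model
        self.solution = solution

    @property
    def converged(self) -> bool:
        return self.solution.converged

    @property
    def concentrations(self) -> pd.DataFrame:
        """Per-cell concentrations (µM) indexed by depth (m)."""
        return pd.DataFrame(self.solution.concentrations,
                            index=pd.Index(self.model.grid.cell_centers, name="depth_m"))

    @property
    def rates(self) -> pd.DataFrame:
        """Per-cell volumetric reaction rates (µM·yr⁻¹) indexed by depth."""
        return pd.DataFrame(self.solution.rates.as_dict(),
                            index=pd.Index(self.model.grid.cell_centers, name="depth_m"))

    def profile(self, species: str) -> ConcentrationProfile:
        return ConcentrationProfile(self.model.grid.cell_centers,
                                    self.solution.concentrations[species], species)

    def nat_zone(self, eps_no3: float | None = None, eps_nh4: float | None = None) -> NATZone:
        """Detect the nitrate-ammonium transition zone of this solution."""
        e1, e2 = self.model.scenario.nat_thresholds
        return detect_nat_zone(self.profile("NO3"), self.profile("NH4"),
                               e1 if eps_no3 is None else eps_no3,
                               e2 if eps_nh4 is None else eps_nh4)

    def anammox_peak_depth(self) -> float:
        return rate_maximum_depth(self.solution.rates.R_amx, self.model.grid)

    def depth_integrated_rate(self, which: str = "anammox") -> float:
        s = self.model.scenario
        return depth_integrated_rate(self.solution, s.grid, s.porosity, which)

    def mass_balance(self) -> dict:
        s = self.model.scenario
        return mass_balance_report(self.solution, s.grid, s.porosity, s.transport, s.bc)

    def summary(self) -> str:
        """Plain-text summary of the solve and its headline diagnostics."""
        s = self.model.scenario
        lines = [
            "Steady-state sediment nitrogen model",
            "=" * 52,
            f"grid: {s.grid.n_cells} cells over {s.grid.extent:g} m",
            f"converged: {self.converged}   relative residual: {self.solution.residual_norm:.3e}"
            f"   iterations: {self.solution.iterations}",
        ]
        for name in ("anammox", "denitrification", "nitrification"):
            lines.append(f"depth-integrated {name}: "
                         f"{self.depth_integrated_rate(name):.4f} mmol m^-2 yr^-1")
        try:
            zone = self.nat_zone()
            lines.append(f"NAT zone: [{zone.z_top:.3f}, {zone.z_bottom:.3f}] m "
                         f"(midpoint {zone.midpoint:.3f} m, mode {zone.mode})")
            lines.append(f"anammox rate peak: {self.anammox_peak_depth():.3f} m")
        except ValueError as exc:
            lines.append(f"NAT zone: {exc}")
        return "\n".join(lines)

    def plot_profiles(self, ax=None):
        """Concentration profiles and the anammox rate versus depth."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 6))
        z = self.model.grid.cell_centers
        for sp, scale in (("O2", 1.0), ("NO3", 1.0), ("NH4", 1.0)):
            ax.plot(self.solution.concentrations[sp] * scale, z, label=sp)
        ax2 = ax.twiny()
        ax2.plot(self.solution.rates.R_amx, z, "k--", label="anammox rate")
        ax2.set_xlabel("anammox rate (µM yr$^{-1}$)")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("depth (m)")
        ax.invert_yaxis()
        ax.legend(loc="lower right")
        return ax


class CalibrationResults:
    """Calibration estimates with residual diagnostics."""

    def __init__(self, model: SedimentNitrogenModel, result: CalibrationResult,
                 observed: ObservedProfileSet):
        self.model = model
        self.result = result
        self.observed = observed

    @property
    def params(self) -> dict[str, float]:
        return self.result.params

    @property
    def objective(self) -> float:
        return self.result.objective

    @property
    def converged(self) -> bool:
        return self.result.converged

    def fitted_model(self) -> SedimentNitrogenModel:
        return self.model.with_params(**self.params)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Calibration of sediment nitrogen model",
            "=" * 52,
            f"objective (weighted SSE): {r.objective:.6g}",
            f"forward evaluations: {r.n_forward_evaluations}   seed: {r.seed}",
            f"forward model converged at optimum: {r.converged}",
            "",
            f"{'parameter':<16}{'estimate':>14}",
            "-" * 30,
        ]
        for name, value in r.params.items():
            lines.append(f"{name:<16}{value:>14.6g}")
        rms = {sp: float(np.sqrt(np.mean(res**2))) for sp, res in r.residuals.items()}
        lines.append("")
        lines.append("weighted RMS residual per species: "
                     + ", ".join(f"{sp}={v:.3g}" for sp, v in rms.items()))
        return "\n".join(lines)
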