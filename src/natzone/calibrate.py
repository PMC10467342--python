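"""Weighted least-squares calibration of the forward model to profiles.

The paper-grade workflow is: measure porewater profiles, then adjust a
small set of kinetic/transport parameters until the forward steady-state
model reproduces them. Here that is formalized as bounded, derivative-free
minimization (Nelder–Mead on log10-transformed parameters, with seeded
restarts) of a weighted sum of squared residuals between the model —
linearly interpolated from cell centers to observation depths — and the
observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .grid import SPECIES, Grid, TransportParams
from .reactions import KineticParams
from .solver import BoundaryConditions, BottomBC, SolverOptions, solve_steady_state

__all__ = [
    "ObservedProfileSet",
    "CalibrationResult",
    "FREE_PARAMETER_NAMES",
    "objective",
    "fit_parameters",
]

log = logging.getLogger(__name__)

#: objective value substituted for non-convergent forward runs
NONCONVERGED_PENALTY = 1e12

KINETIC_NAMES = ("R0", "z_att", "r_NC", "k_nit", "k_amx", "K_O2", "K_O2nit", "K_NO3", "Ki_O2")
#: calibratable parameter names: kinetics, burial velocity, per-species
#: diffusivity scale factors, and boundary concentrations
FREE_PARAMETER_NAMES = (
    KINETIC_NAMES
    + ("w",)
    + tuple(f"D0_scale_{sp}" for sp in SPECIES)
    + tuple(f"top_{sp}" for sp in SPECIES)
    + tuple(f"bottom_{sp}" for sp in SPECIES)
)


@dataclass(frozen=True)
class ObservedProfileSet:
    """Depth-sampled observed concentrations per species.

    ``data`` maps species name to ``(depths, concentrations, sigmas)``
    arrays; sigmas default to 1 µM so the unweighted SSE is recovered.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for sp, triple in self.data.items():
            d, c, *rest = triple
            d = np.asarray(d, dtype=float)
            c = np.asarray(c, dtype=float)
            s = np.asarray(rest[0], dtype=float) if rest else np.ones_like(d)
            if not (d.size == c.size == s.size):
                raise ValueError(f"{sp}: depths/concentrations/sigmas differ in length")
            if np.any(s <= 0):
                raise ValueError(f"{sp}: sigmas must be > 0")
            if np.any(c < 0):
                raise ValueError(f"{sp}: concentrations must be >= 0")
            order = np.argsort(d, kind="stable")
            clean[sp] = (d[order], c[order], s[order])
        object.__setattr__(self, "data", clean)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data)

    def n_observations(self) -> int:
        return sum(d.size for d, _, _ in self.data.values())


@dataclass(frozen=True)
class CalibrationResult:
    """Best-found parameters and fit diagnostics."""

    params: dict[str, float]
    objective: float
    converged: bool
    n_forward_evaluations: int
    residuals: dict[str, np.ndarray]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


@dataclass(frozen=True)
class ForwardSetup:
    """Everything but the free parameters: grid + fixed model structure."""

    grid: Grid
    porosity: object
    transport: TransportParams
    kinetics: KineticParams
    bc: BoundaryConditions
    solver_options: SolverOptions = field(default_factory=SolverOptions)

    def with_params(self, params: dict[str, float]) -> "ForwardSetup":
        """Return a copy with the named free parameters applied."""
        kin_updates = {k: v for k, v in params.items() if k in KINETIC_NAMES}
        kinetics = self.kinetics.replace(**kin_updates) if kin_updates else self.kinetics
        transport = self.transport
        bc = self.bc
        w = params.get("w")
        d0 = dict(transport.D0)
        d0_changed = False
        top = dict(bc.top)
        bottom = dict(bc.bottom)
        bc_changed = False
        for name, value in params.items():
            if name in KINETIC_NAMES or name == "w":
                continue
            elif name.startswith("D0_scale_"):
                sp = name.removeprefix("D0_scale_")
                d0[sp] = self.transport.D0[sp] * value
                d0_changed = True
            elif name.startswith("top_"):
                top[name.removeprefix("top_")] = value
                bc_changed = True
            elif name.startswith("bottom_"):
                sp = name.removeprefix("bottom_")
                if bottom[sp].kind != "dirichlet":
                    raise ValueError(f"cannot calibrate bottom_{sp}: bottom BC is not dirichlet")
                bottom[sp] = BottomBC("dirichlet", value)
                bc_changed = True
            else:
                raise ValueError(f"unknown free parameter {name!r}")
        if w is not None or d0_changed:
            transport = TransportParams(D0=d0, w=self.transport.w if w is None else w)
        if bc_changed:
            bc = BoundaryConditions(top=top, bottom=bottom)
        return replace(self, kinetics=kinetics, transport=transport, bc=bc)


def _interp_to_obs(solution, grid: Grid, depths: np.ndarray, species: str) -> np.ndarray:
    return np.interp(depths, grid.cell_centers, solution.concentrations[species])


def objective(params: dict[str, float], observed: ObservedProfileSet,
              setup: ForwardSetup, _state_cache: dict | None = None) -> float:
    """Weighted SSE between the forward model and the observations.

    Σ_species Σ_i ((C_model(z_i) − C_obs,i)/σ_i)². Non-convergent forward
    runs return a large finite penalty so the optimizer can retreat.
    """
    trial = setup.with_params(params)
    L = trial.grid.interfaces[-1]
    for sp, (d, _, _) in observed.data.items():
        if np.any(d < 0) or np.any(d > L):
            raise ValueError(f"{sp}: observation depth outside the model extent [0, {L}]")
    x0 = _state_cache.get("x0") if _state_cache is not None else None
    sol = solve_steady_state(trial.grid, trial.porosity, trial.transport,
                             trial.kinetics, trial.bc, options=trial.solver_options, x0=x0)
    if not sol.converged:
        return NONCONVERGED_PENALTY
    if _state_cache is not None:
        _state_cache["x0"] = np.column_stack(
            [sol.concentrations[sp] for sp in SPECIES]).ravel()
    sse = 0.0
    for sp, (d, c, s) in observed.data.items():
        model = _interp_to_obs(sol, trial.grid, d, sp)
        sse += float(np.sum(((model - c) / s) ** 2))
    return sse


def fit_parameters(observed: ObservedProfileSet, free: list[str],
                   bounds: dict[str, tuple[float, float]],
                   start: dict[str, float], setup: ForwardSetup,
                   seed: int = 0, n_restarts: int = 3,
                   maxfev: int | None = None, xatol: float = 1e-4,
                   fatol: float = 1e-10) -> CalibrationResult:
    """Fit the named free parameters by bounded Nelder–Mead in log10 space.

    Three additional restarts from seeded perturbations of the start guard
    against simplex collapse on the noisy forward map. Deterministic given
    ``seed`` and inputs. At most 6 free parameters are accepted and more
    than 3 triggers an identifiability warning.
    """
    if not free:
        raise ValueError("no free parameters given")
    if len(free) > 6:
        raise ValueError("at most 6 free parameters are supported")
    if len(free) > 3:
        warnings.warn("more than 3 free parameters: identifiability is unlikely "
                      "from three porewater profiles", stacklevel=2)
    for name in free:
        if name not in FREE_PARAMETER_NAMES:
            raise ValueError(f"unknown free parameter {name!r}")
        lo, hi = bounds[name]
        if not (0 < lo < hi and np.isfinite(hi)):
            raise ValueError(f"bounds for {name} must be finite and positive (log-space search)")
        if not (lo <= start[name] <= hi):
            raise ValueError(f"start value for {name} outside its bounds")

    lo10 = np.log10([bounds[n][0] for n in free])
    hi10 = np.log10([bounds[n][1] for n in free])
    x_start = np.log10([start[n] for n in free])
    n_eval = 0
    cache: dict = {}

    def f(x10: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = {n: 10.0 ** v for n, v in zip(free, x10)}
        return objective(params, observed, setup, _state_cache=cache)

    rng = np.random.default_rng(seed)
    starts = [x_start]
    for _ in range(n_restarts):
        pert = x_start + rng.uniform(-0.15, 0.15, size=len(free))
        starts.append(np.clip(pert, lo10, hi10))

    best = None
    maxfev = maxfev or 250 * len(free)
    for s0 in starts:
        res = minimize(f, s0, method="Nelder-Mead",
                       bounds=list(zip(lo10, hi10)),
                       options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun <= fatol:
            break

    if best is None or not np.isfinite(best.fun) or best.fun >= NONCONVERGED_PENALTY:
        raise RuntimeError("calibration failed: every forward run diverged")

    fitted = {n: 10.0 ** v for n, v in zip(free, best.x)}
    trial = setup.with_params(fitted)
    sol = solve_steady_state(trial.grid, trial.porosity, trial.transport,
                             trial.kinetics, trial.bc, options=trial.solver_options)
    residuals = {}
    for sp, (d, c, s) in observed.data.items():
        residuals[sp] = (_interp_to_obs(sol, trial.grid, d, sp) - c) / s
    return CalibrationResult(params=fitted, objective=float(best.fun),
                             converged=bool(sol.converged), n_forward_evaluations=n_eval,
                             residuals=residuals, seed=seed)
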