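"""Steady-state solver versus closed-form oracles, plus conservation checks."""

import numpy as np
import pytest

from natzone import (
    BottomBC,
    BoundaryConditions,
    KineticParams,
    PorosityModel,
    TransportParams,
    assemble_residual,
    build_grid,
    depth_integrated_rate,
    effective_diffusivity,
    mass_balance_report,
    solve_steady_state,
    solve_transport_reaction,
)

PHI = 0.8
D0 = 0.03
DS = effective_diffusivity(D0, PHI)
L = 2.0


def _zero_sources(concs, grid):
    return {sp: np.zeros(grid.n_cells) for sp in concs}


def _solve_single(n, w=0.0, top=10.0, bottom=BottomBC("dirichlet", 2.0), sources=_zero_sources,
                  D=D0):
    g = build_grid(L, n)
    phi = np.full(n, PHI)
    C, info = solve_transport_reaction(g, phi, ["c"], {"c": D}, w, {"c": top},
                                       {"c": bottom}, sources)
    return g, C[:, 0], info


class TestClosedFormOracles:
    def test_pure_diffusion_linear_profile_is_exact(self):
        g, c, info = _solve_single(50)
        exact = 10.0 + (2.0 - 10.0) * g.cell_centers / L
        assert info["converged"]
        np.testing.assert_allclose(c, exact, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("pe", [1.0, 5.0])
    def test_advection_diffusion_exponential(self, pe):
        w = pe * DS / L
        g, c, info = _solve_single(200, w=w)
        z = g.cell_centers
        exact = 10.0 + (2.0 - 10.0) * np.expm1(pe * z / L) / np.expm1(pe)
        assert info["converged"]
        err = np.max(np.abs(c - exact) / np.abs(exact))
        assert err < 0.005

    def test_reaction_diffusion_cosh_profile(self):
        # alpha*L = 2: the decay scale is well inside the domain, so the
        # pointwise relative error is meaningful everywhere
        k = (2.0 / L) ** 2 * DS
        g, c, info = _solve_single(200, sources=lambda concs, grid: {"c": -k * concs["c"]},
                                   bottom=BottomBC("neumann"))
        alpha = np.sqrt(k / DS)
        exact = 10.0 * np.cosh(alpha * (L - g.cell_centers)) / np.cosh(alpha * L)
        assert info["converged"]
        err = np.max(np.abs(c - exact) / exact)
        assert err < 0.005

    def test_reaction_diffusion_grid_convergence_second_order(self):
        k = (2.0 / L) ** 2 * DS
        alpha = np.sqrt(k / DS)
        errs = []
        for n in (50, 100, 200):
            g, c, _ = _solve_single(n, sources=lambda concs, grid: {"c": -k * concs["c"]},
                                    bottom=BottomBC("neumann"))
            exact = 10.0 * np.cosh(alpha * (L - g.cell_centers)) / np.cosh(alpha * L)
            errs.append(np.max(np.abs(c - exact) / exact))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        for p in orders:
            assert 1.7 <= p <= 2.3

    def test_one_cell_decay_balance_solved_by_hand(self):
        # single cell: phi*Ds*(C0 - C)/(dz/2)/dz = phi*k*C
        k = 3.0
        g, c, info = _solve_single(1, sources=lambda concs, grid: {"c": -k * concs["c"]},
                                   bottom=BottomBC("neumann"))
        dz = L
        a = 2.0 * DS / dz**2
        expected = 10.0 * a / (a + k)
        assert info["converged"]
        assert c[0] == pytest.approx(expected, rel=1e-10)


class TestAssembleResidual:
    def test_linear_profile_no_reaction_zero_residual(self):
        n = 30
        g = build_grid(L, n)
        kp = KineticParams(k_nit=1.0, k_amx=1.0, R0=1e-300)
        tp = TransportParams(w=0.0)
        bc = BoundaryConditions(
            top={"O2": 10.0, "NO3": 5.0, "NH4": 1.0},
            bottom={sp: BottomBC("dirichlet", v) for sp, v in
                    (("O2", 4.0), ("NO3", 2.0), ("NH4", 7.0))},
        )
        # linear interpolation between the Dirichlet values is the exact
        # steady state when sources vanish; rates are ~0 with R0 -> 0 and
        # concentrations chosen zero where the remaining rate laws bite
        z = g.cell_centers
        concs = {sp: bc.top[sp] + (bc.bottom[sp].value - bc.top[sp]) * z / L
                 for sp in ("O2", "NO3", "NH4")}
        concs["NH4"] = np.zeros(n)  # kill nitrification/anammox exactly
        bc = BoundaryConditions(top={**bc.top, "NH4": 0.0},
                                bottom={**bc.bottom, "NH4": BottomBC("dirichlet", 0.0)})
        res = assemble_residual(concs, g, PorosityModel(phi0=PHI), tp, kp, bc)
        assert np.max(np.abs(res)) < 1e-8

    def test_constant_field_zero_sources_zero_residual(self):
        n = 10
        g = build_grid(L, n)
        kp = KineticParams(R0=1e-300, k_nit=1.0, k_amx=1.0)
        tp = TransportParams(w=0.0)
        bc = BoundaryConditions(
            top={"O2": 25.0, "NO3": 25.0, "NH4": 0.0},
            bottom={"O2": BottomBC("dirichlet", 25.0), "NO3": BottomBC("dirichlet", 25.0),
                    "NH4": BottomBC("dirichlet", 0.0)},
        )
        concs = {"O2": np.full(n, 25.0), "NO3": np.full(n, 25.0), "NH4": np.zeros(n)}
        res = assemble_residual(concs, g, PorosityModel(phi0=PHI), tp, kp, bc)
        assert np.max(np.abs(res)) < 1e-9

    def test_dimension_mismatch_rejected(self):
        g = build_grid(L, 10)
        concs = {"O2": np.zeros(5), "NO3": np.zeros(5), "NH4": np.zeros(5)}
        with pytest.raises(ValueError):
            assemble_residual(concs, g, PorosityModel(phi0=PHI), TransportParams(),
                              KineticParams(), BoundaryConditions())


class TestDepthIntegratedRate:
    def test_uniform_rate(self, ref_results):
        sol = ref_results.solution
        g = ref_results.model.grid
        rates = sol.rates
        uniform = type(rates)(R_O2C=np.ones(g.n_cells), R_denC=rates.R_denC,
                              R_nit=rates.R_nit, R_amx=rates.R_amx)
        sol2 = type(sol)(concentrations=sol.concentrations, rates=uniform, sources=sol.sources,
                         converged=True, residual_norm=0.0, iterations=0, kinetics=sol.kinetics)
        val = depth_integrated_rate(sol2, g, 0.8, "aerobic_mineralization")
        assert val == pytest.approx(1.0 * 0.8 * 4.0, rel=1e-12)

    def test_single_cell_rate(self, ref_results):
        sol = ref_results.solution
        g = ref_results.model.grid
        r = np.zeros(g.n_cells)
        r[7] = 5.0
        rates = type(sol.rates)(R_O2C=r, R_denC=r, R_nit=r, R_amx=r)
        sol2 = type(sol)(concentrations=sol.concentrations, rates=rates, sources=sol.sources,
                         converged=True, residual_norm=0.0, iterations=0, kinetics=sol.kinetics)
        val = depth_integrated_rate(sol2, g, 0.8, "anammox")
        assert val == pytest.approx(5.0 * 0.8 * g.cell_widths[7], rel=1e-12)

    def test_exponential_rate_matches_analytic_integral(self, ref_results):
        # R_C-like profile: R0 e^{-z/za} integrates to R0 za (1 - e^{-L/za})
        g = ref_results.model.grid
        sol = ref_results.solution
        R0, za = 100.0, 0.3
        r = R0 * np.exp(-g.cell_centers / za)
        rates = type(sol.rates)(R_O2C=r, R_denC=r, R_nit=r, R_amx=r)
        sol2 = type(sol)(concentrations=sol.concentrations, rates=rates, sources=sol.sources,
                         converged=True, residual_norm=0.0, iterations=0, kinetics=sol.kinetics)
        val = depth_integrated_rate(sol2, g, 0.8, "nitrification")
        exact = 0.8 * R0 * za * (1 - np.exp(-4.0 / za))
        assert val == pytest.approx(exact, rel=5e-3)

    def test_unknown_reaction_rejected(self, ref_results):
        with pytest.raises(ValueError, match="unknown reaction"):
            ref_results.depth_integrated_rate("sulfate_reduction")


class TestMassBalance:
    def test_no_reaction_linear_case_flux_through(self):
        n = 60
        g = build_grid(L, n)
        kp = KineticParams(R0=1e-300)
        tp = TransportParams(w=0.0)
        bc = BoundaryConditions(
            top={"O2": 10.0, "NO3": 5.0, "NH4": 0.0},
            bottom={"O2": BottomBC("dirichlet", 2.0), "NO3": BottomBC("dirichlet", 1.0),
                    "NH4": BottomBC("dirichlet", 0.0)},
        )
        sol = solve_steady_state(g, PorosityModel(phi0=PHI), tp, kp, bc)
        assert sol.converged
        rep = mass_balance_report(sol, g, PorosityModel(phi0=PHI), tp, bc)
        for sp in ("O2", "NO3"):
            assert rep[sp]["flux_top"] == pytest.approx(rep[sp]["flux_bottom"], rel=1e-10)
            assert rep[sp]["closure_rel"] < 1e-10

    def test_full_network_closure(self, ref_results):
        rep = ref_results.mass_balance()
        for sp in ("O2", "NO3", "NH4"):
            assert rep[sp]["closure_rel"] <= 1e-6

    def test_fixed_nitrogen_budget(self, ref_results):
        rep = ref_results.mass_balance()
        assert rep["fixed_N"]["closure_rel"] <= 1e-6


class TestFullNetworkSolution:
    def test_non_negative_concentrations(self, ref_results):
        for c in ref_results.solution.concentrations.values():
            assert np.all(c >= 0)

    def test_anammox_colocated_with_substrates(self, ref_results):
        """Anammox can only run where both NO3- and NH4+ are present, so its
        maximum sits inside the substrate co-occurrence interval."""
        sol = ref_results.solution
        g = ref_results.model.grid
        active = sol.rates.R_amx > 1e-12
        both = (sol.concentrations["NO3"] > 0) & (sol.concentrations["NH4"] > 0)
        assert np.all(both[active])
        peak = g.cell_centers[np.argmax(sol.rates.R_amx)]
        co = g.cell_centers[both]
        assert co.min() <= peak <= co.max()

    def test_budget_exhaustion_returns_diagnostics_not_exception(self):
        from natzone import SolverOptions

        g = build_grid(4.0, 50)
        sol = solve_steady_state(g, PorosityModel(), TransportParams(), KineticParams(),
                                 BoundaryConditions(),
                                 options=SolverOptions(max_newton=1, max_outer=1,
                                                       max_ptc_steps=1))
        assert not sol.converged
        assert sol.residual_norm > 0
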