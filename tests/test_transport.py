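"""Finite-volume operator, implicit stepping and the steady-state driver."""

import numpy as np
import pytest

from thromboflow.errors import ConfigurationError, ModelCollapseError
from thromboflow.fields import (FlowField, SpeciesState, StructuredGrid2D,
                                uniform_state)
from thromboflow.kinetics import reaction_sources
from thromboflow.stress import scalar_stress_field
from thromboflow.synthetic import axial_bands, closed_recirculation, make_poiseuille
from thromboflow.transport import (CLOSED_BOUNDARIES, DEFAULT_BOUNDARIES,
                                   assemble_transport_operator, build_operators,
                                   run_to_steady, step_species)


def _zero_flow(grid):
    return FlowField(u=np.zeros(grid.shape), v=np.zeros(grid.shape),
                     mu=np.full(grid.shape, 3.5e-3))


class TestOperatorAssembly:
    def test_uniform_field_is_equilibrium_on_closed_domain(self, grid):
        op = assemble_transport_operator(grid, _zero_flow(grid), 1e-11,
                                         CLOSED_BOUNDARIES)
        rate = op.A @ np.full(grid.n_cells, 3.7) + op.b
        np.testing.assert_allclose(rate, 0.0, atol=1e-18)

    def test_closed_diffusion_rows_and_columns_sum_to_zero(self, grid):
        op = assemble_transport_operator(grid, _zero_flow(grid), 1e-9,
                                         CLOSED_BOUNDARIES)
        scale = np.abs(op.A.data).max()
        np.testing.assert_allclose(np.asarray(op.A.sum(axis=1)).ravel(), 0.0,
                                   atol=1e-14 * scale)
        np.testing.assert_allclose(np.asarray(op.A.sum(axis=0)).ravel(), 0.0,
                                   atol=1e-14 * scale)

    def test_upwind_step_matches_hand_computation(self):
        """One explicit step of uniform advection reproduces the textbook
        update phi_i <- phi_i - (u dt / dx)(phi_i - phi_{i-1}) on a 5-cell
        line (checked on the interior row of a 5x3 grid)."""
        g = StructuredGrid2D(nx=5, ny=3, dx=0.1, dy=0.1)
        flow = FlowField(u=np.full(g.shape, 2.0), v=np.zeros(g.shape),
                         mu=np.full(g.shape, 1.0))
        inlet_value = 4.0
        op = assemble_transport_operator(g, flow, 1e-30, DEFAULT_BOUNDARIES,
                                         inlet_value=inlet_value)
        profile = np.array([4.0, 4.0, 1.0, 1.0, 1.0])
        phi = np.tile(profile, (3, 1)).ravel()
        dt = 0.01
        stepped = (phi + dt * (op.A @ phi + op.b)).reshape(3, 5)
        c = 2.0 * dt / 0.1
        expected = profile - c * (profile - np.array([inlet_value, *profile[:-1]]))
        np.testing.assert_allclose(stepped[1], expected, rtol=1e-12)

    def test_unknown_boundary_label_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            assemble_transport_operator(grid, _zero_flow(grid), 1e-11,
                                        {"left": "inflow", "right": "outlet",
                                         "bottom": "wall", "top": "wall"})

    def test_nonpositive_diffusivity_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            assemble_transport_operator(grid, _zero_flow(grid), 0.0)


class TestStepSpecies:
    def test_equilibrium_state_unchanged(self, grid, params):
        ops = build_operators(grid, _zero_flow(grid), params, CLOSED_BOUNDARIES)
        state = uniform_state(grid, params)
        tau = np.zeros(grid.shape)
        new, am, ac, nf = step_species(state, ops, tau, params)
        np.testing.assert_allclose(new.phi_a, state.phi_a, rtol=1e-12)
        np.testing.assert_allclose(new.phi_n, state.phi_n, rtol=1e-12)
        assert am.sum() == 0.0 and ac.sum() == 0.0 and nf == 0

    def test_closed_domain_conserves_total_platelets(self, params):
        grid, flow, _ = closed_recirculation(24, 12)
        ops = build_operators(grid, flow, params, CLOSED_BOUNDARIES)
        tau = np.full(grid.shape, 20.0)
        state = uniform_state(grid, params)
        total0 = (state.phi_a + state.phi_n).sum()
        for _ in range(20):
            prev_total = (state.phi_a + state.phi_n).sum()
            state, *_ = step_species(state, ops, tau, params)
            total = (state.phi_a + state.phi_n).sum()
            assert total == pytest.approx(prev_total, rel=1e-8)
        assert state.phi_a.mean() > params.phi_a0  # activation happened
        assert (state.phi_a + state.phi_n).sum() == pytest.approx(total0, rel=1e-8)

    def test_implicit_diffusion_of_spike_is_monotone_and_conservative(self, params):
        grid = StructuredGrid2D(nx=11, ny=11, dx=1e-3, dy=1e-3)
        flow = _zero_flow(grid)
        big_d = params.with_(D_a=1e-7, dt=0.5)  # diffusion visible per step
        ops = build_operators(grid, flow, big_d, CLOSED_BOUNDARIES)
        state = SpeciesState(np.zeros(grid.shape), np.full(grid.shape, 1.0),
                             np.zeros(grid.shape))
        state.phi_a[5, 5] = 1e6
        tau = np.zeros(grid.shape)
        mass = state.phi_a.sum()
        peak = state.phi_a.max()
        for _ in range(10):
            state, *_ = step_species(state, ops, tau, big_d)
            assert state.phi_a.sum() == pytest.approx(mass, rel=1e-10)
            assert state.phi_a.max() <= peak * (1 + 1e-12)
            assert state.phi_a.min() >= 0.0
            peak = state.phi_a.max()
        assert peak < 1e6 / 2  # the spike actually spread


class TestRunToSteady:
    def test_equilibrium_converges_in_minimum_steps(self, grid, params):
        regions = axial_bands(grid, 2)
        state = uniform_state(grid, params)
        result = run_to_steady(state, grid, _zero_flow(grid), params, regions,
                               boundary_spec=CLOSED_BOUNDARIES,
                               tau_field=np.zeros(grid.shape))
        assert result.converged
        # first comparison happens at step 2: minimum is consecutive_steps + 1
        assert result.steps_taken == params.consecutive_steps + 1
        assert len(result.history) == result.steps_taken

    def test_activation_accumulates_downstream(self, params):
        grid = StructuredGrid2D(nx=24, ny=12, dx=0.05 / 24, dy=0.01 / 12)
        flow = make_poiseuille(grid, 0.5)
        regions = axial_bands(grid, 4)
        result = run_to_steady(uniform_state(grid, params), grid, flow, params,
                               regions)
        avgs = result.region_averages()
        assert result.converged
        assert avgs["Region4"] > avgs["Region1"]

    def test_faster_carrier_flow_reduces_steady_ap(self, params):
        """Doubling the velocities at an identical imposed stress field
        shortens residence times and lowers the steady AP level."""
        grid = StructuredGrid2D(nx=24, ny=12, dx=0.05 / 24, dy=0.01 / 12)
        flow = make_poiseuille(grid, 0.5)
        fast = flow.copy()
        fast.u *= 2.0
        fast.v *= 2.0
        tau = scalar_stress_field(grid, flow)
        regions = axial_bands(grid, 4)
        state = uniform_state(grid, params)
        slow_res = run_to_steady(state, grid, flow, params, regions, tau_field=tau)
        fast_res = run_to_steady(state, grid, fast, params, regions, tau_field=tau)
        for name in slow_res.region_averages():
            assert fast_res.region_averages()[name] < slow_res.region_averages()[name]

    def test_scaling_stress_up_never_decreases_ap(self, desk_demo, params):
        grid, flow, regions = desk_demo
        tau = scalar_stress_field(grid, flow)
        state = uniform_state(grid, params)
        previous = None
        for scale in (0.5, 1.0, 2.0):
            result = run_to_steady(state, grid, flow, params, regions,
                                   tau_field=scale * tau)
            avgs = result.region_averages()
            if previous is not None:
                for name in avgs:
                    assert avgs[name] >= previous[name]
            previous = avgs

    def test_activated_fraction_bounded_in_converged_run(self, desk_demo, params):
        grid, flow, regions = desk_demo
        result = run_to_steady(uniform_state(grid, params), grid, flow, params,
                               regions)
        assert result.converged
        phi_f = result.state.phi_f()
        assert phi_f.min() >= 0.0 and phi_f.max() <= 1.0

    def test_collapse_attaches_partial_history(self, params):
        grid, flow, regions = closed_recirculation(24, 12)
        stiff = params.with_(ADP_t=1e-4, t_ADP=1.0, max_steps=80)
        tau = np.full(grid.shape, 50.0)
        with pytest.raises(ModelCollapseError) as excinfo:
            run_to_steady(uniform_state(grid, stiff), grid, flow, stiff, regions,
                          boundary_spec=CLOSED_BOUNDARIES, tau_field=tau)
        partial = excinfo.value.partial_result
        assert partial is not None
        assert len(partial.history) >= 1
        assert not partial.converged


class TestOracleEquivalence:
    def test_steady_state_independent_of_time_step(self, params):
        """The 1 s implicit steady state matches an explicit dt = 1e-3 s
        integration of the same semi-discrete system."""
        from thromboflow.synthetic import demo_channel
        grid, flow, regions = demo_channel(24, 12)
        p = params.with_(stabilization_tol=1e-9)
        tau = scalar_stress_field(grid, flow)
        state0 = uniform_state(grid, p)
        implicit = run_to_steady(state0, grid, flow, p, regions, tau_field=tau)
        assert implicit.converged

        ops = build_operators(grid, flow, p)
        mats = {n: getattr(ops, n).A for n in ("phi_a", "phi_n", "adp")}
        rhs = {n: getattr(ops, n).b for n in ("phi_a", "phi_n", "adp")}
        dt = 1e-3
        pa = state0.phi_a.ravel().copy()
        pn = state0.phi_n.ravel().copy()
        ad = state0.adp.ravel().copy()
        for _ in range(40000):  # 40 s, several residence times past steady
            src = reaction_sources(
                SpeciesState(pa.reshape(grid.shape), pn.reshape(grid.shape),
                             ad.reshape(grid.shape)), tau, p)
            pa = pa + dt * (mats["phi_a"] @ pa + rhs["phi_a"] + src.S_a.ravel())
            pn = pn + dt * (mats["phi_n"] @ pn + rhs["phi_n"] + src.S_n.ravel())
            ad = ad + dt * (mats["adp"] @ ad + rhs["adp"] + src.S_adp.ravel())
        explicit = pa.reshape(grid.shape)
        for rid in regions.region_ids:
            name = regions.names[rid]
            ref = float(explicit[regions.mask(rid)].mean())
            assert implicit.region_averages()[name] == pytest.approx(ref, rel=1e-3)

    def test_upwind_advection_first_order_convergence(self):
        """Error against the analytically translated profile shrinks at
        first order across three grid refinements."""
        errors = []
        for nx in (64, 128, 256):
            g = StructuredGrid2D(nx=nx, ny=3, dx=1.0 / nx, dy=1.0 / 3)
            X, _ = g.meshgrid()
            flow = FlowField(u=np.ones(g.shape), v=np.zeros(g.shape),
                             mu=np.full(g.shape, 3.5e-3))
            op = assemble_transport_operator(g, flow, 1e-12, DEFAULT_BOUNDARIES,
                                             inlet_value=0.0)
            phi = np.exp(-(((X - 0.25) / 0.08) ** 2)).ravel()
            dt = 0.4 * g.dx
            n_steps = int(round(0.4 / dt))
            for _ in range(n_steps):
                phi = phi + dt * (op.A @ phi + op.b)
            exact = np.exp(-(((X - 0.25 - n_steps * dt) / 0.08) ** 2)).ravel()
            errors.append(np.abs(phi - exact).mean())
        orders = [np.log2(errors[i] / errors[i + 1]) for i in range(2)]
        assert all(o > 0.6 for o in orders)
        assert errors[-1] < errors[0] / 2
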