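"""Unit and property tests of the four-field reaction-diffusion core."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from branchrd.model_core import (
    FieldState,
    InitialConditionSpec,
    ModelParameters,
    NonFiniteFieldError,
    SimulationDomain,
    StepperConfig,
    default_baselines,
    initialize,
    laplacian,
    reaction_rates,
    run,
    stability_dt_limit,
    step,
)


class TestModelParameters:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            ModelParameters(mu=-0.1)

    def test_slow_inhibitor_diffusion_warns(self):
        with pytest.warns(UserWarning, match="faster"):
            ModelParameters(D_A=0.3, D_H=0.2)

    def test_defaults_satisfy_activator_inhibitor_ordering(self, params):
        assert params.D_A < params.D_H


class TestReactionRates:
    def test_hand_computed_activator_rate(self):
        # dA = c*A^2*S/H - mu*A + rho_A*Y at A=H=S=1, Y=0
        p = ModelParameters()
        dA, dH, dS, dY = reaction_rates(1.0, 1.0, 1.0, 0.0, p)
        assert dA == pytest.approx(p.c - p.mu)  # 0.04 - 0.3 = -0.26
        assert dA == pytest.approx(-0.26)

    def test_zero_activator_substrate_balance_is_fixed_point(self, params):
        S_eq = params.c0 / params.gamma
        rates = reaction_rates(0.0, 0.0, S_eq, 0.0, params)
        assert all(abs(r) < 1e-15 for r in rates)

    def test_upper_commitment_root_is_stationary(self, params):
        # nonzero roots of -e*Y + Y^2/(1+f*Y^2) solve f*e*Y^2 - Y + e = 0
        e, f = params.e, params.f
        disc = np.sqrt(1.0 - 4.0 * f * e * e)
        y_up = (1.0 + disc) / (2.0 * f * e)
        assert y_up == pytest.approx((1 + np.sqrt(0.6)) / 2)
        _, _, _, dY = reaction_rates(0.0, 1.0, 1.0, y_up, params)
        assert abs(dY) < 1e-12

    def test_elementwise_over_fields(self, params, rng):
        A, H, S, Y = (rng.random((4, 5, 6)) + 0.1 for _ in range(4))
        dA, dH, dS, dY = reaction_rates(A, H, S, Y, params)
        i = (1, 2, 3)
        scalar = reaction_rates(A[i], H[i], S[i], Y[i], params)
        assert dA[i] == pytest.approx(scalar[0])
        assert dY[i] == pytest.approx(scalar[3])

    def test_denominator_clamp_prevents_division_blowup(self, params):
        dA, *_ = reaction_rates(1.0, 0.0, 1.0, 0.0, params, H_floor=1e-8)
        assert np.isfinite(dA)


class TestLaplacian:
    def test_uniform_field_has_zero_laplacian(self, small_domain):
        f = np.full(small_domain.shape, 3.2)
        assert np.allclose(laplacian(f, small_domain), 0.0)

    def test_unit_impulse_stencil(self):
        dom = SimulationDomain(5, 5, 5)
        f = np.zeros(dom.shape)
        f[2, 2, 2] = 1.0
        lap = laplacian(f, dom)
        assert lap[2, 2, 2] == -6.0
        for off in [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]:
            assert lap[off] == 1.0
        assert lap.sum() == pytest.approx(0.0)

    def test_linear_ramp_zero_flux(self):
        dom = SimulationDomain(8, 5, 5)
        x = np.arange(8, dtype=float)
        f = np.broadcast_to(x[:, None, None], dom.shape).copy()
        lap = laplacian(f, dom)
        assert np.allclose(lap[1:-1], 0.0)  # affine interior
        # mirror ghosts make boundary planes nonzero
        assert np.allclose(lap[0], 1.0) and np.allclose(lap[-1], -1.0)

    def test_periodic_wraps(self):
        dom = SimulationDomain(6, 5, 5, boundary="periodic")
        f = np.zeros(dom.shape)
        f[0, 2, 2] = 1.0
        lap = laplacian(f, dom)
        assert lap[5, 2, 2] == 1.0  # wrapped neighbor

    def test_shape_mismatch_rejected(self, small_domain):
        with pytest.raises(ValueError, match="shape"):
            laplacian(np.zeros((3, 3, 3)), small_domain)


class TestStep:
    def test_full_fixed_point_state_is_preserved(self, params):
        from branchrd.stability import steady_state_full

        ss = steady_state_full(params)
        dom = SimulationDomain(8, 8, 8)
        state = FieldState(
            A=np.full(dom.shape, ss.A_star), H=np.full(dom.shape, ss.H_star),
            S=np.full(dom.shape, ss.S_star), Y=np.full(dom.shape, ss.Y_star),
        )
        before = {k: v.copy() for k, v in state.fields().items()}
        step(state, params, StepperConfig(dt=0.5), dom)
        for name in ("A", "H", "S", "Y"):
            rel = np.abs(state.fields()[name] - before[name]) / before[name].max()
            assert rel.max() < 1e-10

    def test_zero_diffusion_matches_ode_oracle(self):
        # single voxel, no diffusion: explicit Euler vs high-accuracy ODE
        p = ModelParameters(D_A=0.0, D_H=0.0, D_S=0.0)
        dom = SimulationDomain(3, 3, 3)
        y0 = [0.2, 0.05, 1.0, 0.6]
        state = FieldState(*(np.full(dom.shape, v) for v in y0))
        stepper = StepperConfig(dt=0.5, n_steps=1000)
        for _ in range(stepper.n_steps):
            step(state, p, stepper, dom)

        sol = solve_ivp(
            lambda t, y: reaction_rates(*y, p),
            (0.0, stepper.dt * stepper.n_steps), y0,
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        final = sol.y[:, -1]
        euler = [state.A[1, 1, 1], state.H[1, 1, 1], state.S[1, 1, 1], state.Y[1, 1, 1]]
        for e, o in zip(euler, final):
            assert abs(e - o) / max(abs(o), 1e-12) < 0.01

    def test_pure_diffusion_conserves_mass_with_zero_flux(self, rng):
        p = ModelParameters(c=0, mu=0, nu=0, rho_A=0, rho_H=0, c0=0,
                            gamma=0, epsilon=0, d=0, e=0, f=0)
        dom = SimulationDomain(10, 9, 8)
        # Y starts at zero: its quadratic self-activation has no off switch
        state = FieldState(*(rng.random(dom.shape) for _ in range(3)),
                           Y=np.zeros(dom.shape))
        sums0 = {k: v.sum() for k, v in state.fields().items()}
        stepper = StepperConfig(dt=0.5, n_steps=1000)
        for _ in range(stepper.n_steps):
            step(state, p, stepper, dom)
        for name in ("A", "H", "S"):
            arr = state.fields()[name]
            assert abs(arr.sum() - sums0[name]) / abs(sums0[name]) < 1e-10
        assert state.Y.sum() == 0.0

    def test_dt_stability_bound_enforced_and_overridable(self, params, small_domain):
        limit = stability_dt_limit(params, small_domain.h)
        assert limit == pytest.approx(1.0 / (6 * 0.26))
        with pytest.raises(ValueError, match="stability"):
            StepperConfig(dt=2 * limit).validate_against(params, small_domain)
        StepperConfig(dt=2 * limit, allow_unstable_dt=True).validate_against(
            params, small_domain)

    def test_nonfinite_field_aborts_with_diagnostic(self, params):
        dom = SimulationDomain(6, 6, 6)
        state = FieldState(*(np.full(dom.shape, 1.0) for _ in range(4)))
        state.H[2, 2, 2] = 1e-12  # division spike -> overflow within a few steps
        stepper = StepperConfig(dt=50.0, allow_unstable_dt=True)
        with pytest.raises((NonFiniteFieldError, FloatingPointError)):
            for _ in range(50):
                step(state, params, stepper, dom)


class TestInitialize:
    def test_fluctuation_bounds_respected(self, params):
        dom = SimulationDomain(20, 20, 10)
        ic = InitialConditionSpec(A0=0.5, H0=0.2, fluctuation=0.05, rng_seed=7)
        state = initialize(dom, ic, params)
        rel = np.abs(state.A - 0.5) / 0.5
        assert rel.max() <= 0.05 + 1e-12
        assert rel.max() > 0.03  # fluctuation actually applied

    def test_seed_sphere_geometry(self, params):
        dom = SimulationDomain(21, 21, 21)
        ic = InitialConditionSpec(seed_radius=3.0, rng_seed=0)
        state = initialize(dom, ic, params)
        assert state.Y[10, 10, 10] == 1.0
        assert state.Y[10, 10, 14] == 0.0
        assert state.Y.sum() == pytest.approx(((np.indices(dom.shape) - 10) ** 2)
                                              .sum(axis=0).__le__(9).sum())

    def test_gradient_mode_has_no_differentiated_cells(self, params):
        dom = SimulationDomain(8, 8, 16)
        ic = InitialConditionSpec(mode="gradient", fluctuation=0.0, rng_seed=0)
        state = initialize(dom, ic, params)
        assert np.all(state.Y == 0)
        ramp = state.A[0, 0, :]
        assert ramp[0] == pytest.approx(ic.gradient_low)
        assert ramp[-1] == pytest.approx(ic.gradient_high)
        diffs = np.diff(ramp)
        assert np.allclose(diffs, diffs[0])  # affine

    def test_equilibrium_inhibitor_tracks_activator(self, params):
        dom = SimulationDomain(8, 8, 16)
        ic = InitialConditionSpec(mode="gradient", fluctuation=0.0,
                                  H_mode="equilibrium", rng_seed=0)
        state = initialize(dom, ic, params)
        S0 = params.c0 / params.gamma
        expected = np.maximum(params.c * state.A ** 2 * S0 / params.nu, 1e-3)
        assert np.allclose(state.H, expected)

    def test_same_seed_bitwise_identical(self, params):
        dom = SimulationDomain(12, 12, 12)
        ic = InitialConditionSpec(rng_seed=99)
        s1 = initialize(dom, ic, params)
        s2 = initialize(dom, ic, params)
        for name in ("A", "H", "S", "Y"):
            assert np.array_equal(s1.fields()[name], s2.fields()[name])

    def test_seed_outside_domain_rejected(self, params):
        dom = SimulationDomain(8, 8, 8)
        with pytest.raises(ValueError, match="outside"):
            initialize(dom, InitialConditionSpec(seed_radius=6.0), params)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            InitialConditionSpec(fluctuation=1.5)
        with pytest.raises(ValueError):
            InitialConditionSpec(mode="bogus")
        with pytest.raises(ValueError):
            InitialConditionSpec(gradient_low=2.0, gradient_high=1.0)


class TestRun:
    def test_zero_steps_is_identity(self, params, small_domain, seeded_ic):
        res = run(params, small_domain, seeded_ic, StepperConfig(n_steps=0))
        ref = initialize(small_domain, seeded_ic, params)
        for name in ("A", "H", "S", "Y"):
            assert np.array_equal(res.final.fields()[name], ref.fields()[name])

    def test_identical_configs_reproduce_bitwise(self, params, small_domain, seeded_ic):
        st = StepperConfig(dt=0.5, n_steps=100)
        r1 = run(params, small_domain, seeded_ic, st)
        r2 = run(params, small_domain, seeded_ic, st)
        for name in ("A", "H", "S", "Y"):
            assert np.array_equal(r1.final.fields()[name], r2.final.fields()[name])

    def test_commitment_marker_has_no_diffusion(self, params):
        # a voxel's Y evolves exactly as the local ODE of its own history
        dom = SimulationDomain(8, 8, 8)
        ic = InitialConditionSpec(rng_seed=3, seed_radius=2.0)
        st = StepperConfig(dt=0.5, n_steps=40)
        state = initialize(dom, ic, params)
        probe = (1, 1, 1)  # far from the seed
        y_hist = [state.Y[probe]]
        a_hist = [state.A[probe]]
        for _ in range(st.n_steps):
            step(state, params, st, dom)
            y_hist.append(state.Y[probe])
            a_hist.append(state.A[probe])
        # replay the local Y update from the recorded A history
        y = y_hist[0]
        for k in range(st.n_steps):
            a = a_hist[k]
            y = y + st.dt * (params.d * a - params.e * y
                             + y * y / (1 + params.f * y * y))
        assert y == pytest.approx(y_hist[-1], rel=1e-12, abs=1e-15)

    def test_mirror_symmetry_with_zero_fluctuation(self, params):
        dom = SimulationDomain(17, 17, 17)
        ic = InitialConditionSpec(fluctuation=0.0, seed_radius=3.0, rng_seed=0)
        res = run(params, dom, ic, StepperConfig(dt=0.5, n_steps=400))
        for name, arr in res.final.fields().items():
            for axis in range(3):
                assert np.abs(arr - np.flip(arr, axis=axis)).max() < 1e-8, (
                    f"{name} asymmetric along axis {axis}")

    def test_run_log_tracks_field_ranges_and_positivity(self, params, small_domain,
                                                        seeded_ic):
        st = StepperConfig(dt=0.5, n_steps=200, snapshot_every=50)
        res = run(params, small_domain, seeded_ic, st)
        assert len(res.log.snapshots) >= 4
        for entry in res.log.snapshots:
            for f in ("A", "H", "S", "Y"):
                assert entry[f"{f}_min"] > -1e-9  # positivity monitoring
                assert entry[f"{f}_max"] >= entry[f"{f}_min"]
        assert res.trajectory[-1][0] == 200

    def test_snapshots_are_deep_copies(self, params, small_domain, seeded_ic):
        st = StepperConfig(dt=0.5, n_steps=20, snapshot_every=10)
        res = run(params, small_domain, seeded_ic, st)
        (s1_step, s1), (s2_step, s2) = res.trajectory[0], res.trajectory[-1]
        assert s1_step < s2_step
        assert not np.array_equal(s1.A, s2.A)


class TestYBistability:
    """With A clamped to 0 the local Y dynamics is bistable: attractors at 0
    and (1+sqrt(1-4 f e^2))/(2 f e), repeller between them."""

    @pytest.mark.parametrize("e,f", [(0.1, 10.0), (0.08, 12.0), (0.12, 8.0)])
    def test_trajectories_sort_across_the_repeller(self, e, f):
        p = ModelParameters(e=e, f=f)
        disc = np.sqrt(1.0 - 4.0 * f * e * e)
        y_rep = (1.0 - disc) / (2.0 * f * e)
        y_up = (1.0 + disc) / (2.0 * f * e)

        def integrate(y0, t_end=2000.0, dt=0.25):
            y = y0
            for _ in range(int(t_end / dt)):
                y += dt * (-p.e * y + y * y / (1 + p.f * y * y))
            return y

        assert integrate(0.99 * y_rep) == pytest.approx(0.0, abs=1e-6)
        assert integrate(1.01 * y_rep) == pytest.approx(y_up, rel=1e-6)
        assert integrate(1.5 * y_up) == pytest.approx(y_up, rel=1e-6)

    def test_default_parameters_give_printed_attractors(self):
        # e=0.1, f=10 -> attractor (1+sqrt(0.6))/2, repeller (1-sqrt(0.6))/2
        disc = np.sqrt(0.6)
        assert (1 + disc) / 2 == pytest.approx(0.8873, abs=5e-5)
        assert (1 - disc) / 2 == pytest.approx(0.1127, abs=5e-5)
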