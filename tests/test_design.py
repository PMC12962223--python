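"""Pulse-design optimizer: exact toy solutions, brute-force oracle,
gradient certification, L-curve and Pareto behavior, scenario assembly."""

import numpy as np
import pytest

import ptxmux as px
from ptxmux.design import (
    DesignProblem,
    SCENARIO_DT_S,
    TradeoffCurve,
    build_scenario,
    design_pulse,
    evaluate_converted,
    gradient_check,
    lcurve,
    make_problem,
    pareto,
    passive_split_coupling,
    random_init,
)


def uniform_problem(beta=1000.0, nvox=1, nc=1, lsar=None, vops=None):
    grid = px.VoxelGrid((nvox, 1, 1), (0.01,) * 3, (0.0,) * 3, np.ones((nvox, 1, 1), bool))
    sens = np.full((nc, nvox, 1, 1), beta, dtype=complex)
    labels = [px.CoilLabel("top", i + 1, 45.0 * i) for i in range(nc)]
    fields = px.ChannelFieldSet(grid, sens, labels)
    return DesignProblem(
        fields=fields,
        db0=px.OffResonanceMap.zero(grid),
        schedule=px.ChannelSchedule.static(nc, 1),
        timing=px.PulseTiming(1e-4, 10e-3),
        target_deg=5.0,
        vops=vops,
        lsar_max=lsar,
        optimize_k=False,
    )


class TestDesignPulse:
    def test_single_channel_uniform_exact(self):
        # static shim, uniform field: exactly solvable, |p| = b/(dt*beta)
        prob = uniform_problem()
        sol = design_pulse(prob, (np.full((1, 1), 0.1 + 0.1j), None))
        assert sol.nrmse == pytest.approx(0.0, abs=1e-8)
        expect = np.deg2rad(5.0) / (1e-4 * 1000.0)
        assert abs(sol.pulse.amplitudes[0, 0]) == pytest.approx(expect, rel=1e-6)

    def test_matches_dense_grid_search_two_voxels(self):
        # 2 voxels, 2 channels, static shim: brute-force oracle over
        # (amplitude, phase) of channel 2 relative to channel 1
        grid = px.VoxelGrid((2, 1, 1), (0.01,) * 3, (0.0,) * 3, np.ones((2, 1, 1), bool))
        sens = np.array([[[[200.0]], [[400.0]]],
                         [[[350.0]], [[150.0]]]], dtype=complex)
        fields = px.ChannelFieldSet(grid, sens, [px.CoilLabel("top", 1, 0.0),
                                                 px.CoilLabel("top", 2, 45.0)])
        prob = DesignProblem(
            fields=fields, db0=px.OffResonanceMap.zero(grid),
            schedule=px.ChannelSchedule.static(2, 1),
            timing=px.PulseTiming(1e-4, 10e-3), target_deg=5.0, optimize_k=False,
        )
        sol = design_pulse(prob, (np.full((1, 2), 0.2 + 0.1j), None))

        # oracle: dense grid over both amplitudes and the relative phase
        b = np.deg2rad(5.0)
        beta = fields.masked() * 1e-4  # rad/V per voxel
        best = np.inf
        for a1 in np.arange(0.0, 1.5, 0.01):
            for a2 in np.arange(0.0, 1.5, 0.01):
                for ph in np.deg2rad(np.arange(0, 360, 1.0)):
                    p = np.array([a1, a2 * np.exp(1j * ph)])
                    fa = np.abs(beta.T @ p)
                    err = np.sqrt(np.mean((fa - b) ** 2)) / b
                    best = min(best, err)
        assert sol.nrmse <= best + 1e-3

    def test_halving_binding_limit_never_improves(self, dataset, vops):
        sc = build_scenario("full16", dataset.fields, vops)
        prob_free = make_problem(sc, dataset.db0, 2)
        sol_free = design_pulse(prob_free, random_init(prob_free, np.random.default_rng(0)),
                                maxiter=800)
        binding = sol_free.psar / 4
        k_groups = sol_free.pulse.k_locations[: prob_free.n_k_groups]
        nrmses = []
        for lim in (binding, binding / 2):
            prob = DesignProblem(**{**prob_free.__dict__, "lsar_max": lim,
                                    "optimize_k": False, "k_groups_init": k_groups})
            sol = design_pulse(prob, (sol_free.pulse.amplitudes, None))
            assert sol.psar <= lim * (1 + 1e-6)
            nrmses.append(sol.nrmse)
        assert nrmses[1] >= nrmses[0] - 1e-6

    def test_smoothed_magnitude_gradient_finite_at_zero(self):
        from ptxmux.design import _MLSObjective

        prob = uniform_problem()
        obj = _MLSObjective(prob)
        v0 = obj.pack(np.zeros((1, 1), dtype=complex))
        f, g = obj.value_and_grad(v0)
        assert np.all(np.isfinite(g))


class TestGradientCheck:
    def test_objective_and_constraints_match_fd(self, dataset, vops):
        sc = build_scenario("full16", dataset.fields, vops)
        prob = make_problem(sc, dataset.db0, 2, lsar_max=1.0)
        rep = gradient_check(prob)
        assert rep["max_rel_err"] < 1e-5

    def test_multiplexed_paired_k_gradients(self, dataset, vops):
        sc = build_scenario("multi8_opt", dataset.fields, vops)
        prob = make_problem(sc, dataset.db0, 2, lsar_max=1.0)
        rep = gradient_check(prob)
        assert rep["max_rel_err"] < 1e-5

    def test_sar_constraint_gradient_is_quadratic_form_derivative(self, dataset, vops):
        # d(sar_n)/dp_j = 2 (dt/TR) V_n p_j, checked via the jacobian rows
        from ptxmux.design import _MLSObjective, _SARConstraints

        sc = build_scenario("full16", dataset.fields, vops)
        prob = make_problem(sc, dataset.db0, 1, lsar_max=1.0)
        obj = _MLSObjective(prob)
        rng = np.random.default_rng(0)
        P = rng.standard_normal((1, 16)) + 1j * rng.standard_normal((1, 16))
        v = obj.pack(P)
        cons = _SARConstraints(obj, prob.vops, 1.0)
        jac = cons.jac(v)
        coef = prob.timing.sub_pulse_duration / prob.timing.tr
        vp = 2 * coef * (prob.vops.matrices[0] @ P[0])
        np.testing.assert_allclose(-jac[0][:16], vp.real, rtol=1e-10)
        np.testing.assert_allclose(-jac[0][16:32], vp.imag, rtol=1e-10)


class TestLcurve:
    @pytest.fixture(scope="class")
    @staticmethod
    def sweep(dataset, vops):
        sc = build_scenario("full16", dataset.fields, vops)
        prob = make_problem(sc, dataset.db0, 2)
        return lcurve(prob, seed=11, levels=8)

    def test_levels_linear_grid(self, sweep):
        spacing = np.diff(sweep.lsar_max)
        assert np.allclose(spacing, spacing[0], atol=1e-12 * abs(spacing[0]))
        assert sweep.lsar_max[-1] == pytest.approx(0.1)

    def test_default_level_count_is_64(self):
        import inspect
        assert inspect.signature(lcurve).parameters["levels"].default == 64

    def test_first_point_is_unconstrained_optimum(self, sweep, dataset, vops):
        # first level is the unconstrained solution's own pSAR, so its
        # solution is feasible there and no other point beats it
        assert sweep.psar[0] <= sweep.lsar_max[0] * (1 + 1e-6)
        assert sweep.nrmse[0] <= sweep.nrmse.min() + 1e-9

    def test_nrmse_monotone_in_limit(self, sweep):
        assert np.all(np.diff(sweep.nrmse) >= -1e-6)

    def test_constrained_points_feasible(self, sweep):
        assert np.all(sweep.psar <= sweep.lsar_max * (1 + 1e-6))

    def test_deterministic_under_seed(self, dataset, vops):
        sc = build_scenario("full16", dataset.fields, vops)
        prob = make_problem(sc, dataset.db0, 1)
        c1 = lcurve(prob, seed=3, levels=4)
        c2 = lcurve(prob, seed=3, levels=4)
        np.testing.assert_array_equal(c1.nrmse, c2.nrmse)
        np.testing.assert_array_equal(c1.psar, c2.psar)


class TestPareto:
    def test_single_monotone_curve_is_its_own_front(self):
        lsar = np.array([5.0, 3.0, 1.0])
        nr = np.array([0.1, 0.2, 0.3])
        c = TradeoffCurve(lsar, nr, lsar.copy(), [None] * 3)
        front = pareto([c])
        np.testing.assert_array_equal(front.psar, lsar)
        np.testing.assert_array_equal(front.nrmse, nr)

    def test_dominating_curve_wins(self):
        a = TradeoffCurve(np.array([5.0, 1.0]), np.array([0.1, 0.3]),
                          np.array([5.0, 1.0]), [None] * 2)
        b = TradeoffCurve(np.array([5.0, 1.0]), np.array([0.2, 0.4]),
                          np.array([5.0, 1.0]), [None] * 2)
        front = pareto([a, b])
        # psar decreasing along the front, nrmse increasing; only curve a
        np.testing.assert_array_equal(front.psar, [5.0, 1.0])
        np.testing.assert_array_equal(front.nrmse, [0.1, 0.3])

    def test_matches_quadratic_domination_oracle(self):
        rng = np.random.default_rng(0)
        psar = rng.uniform(0, 10, 1000)
        nr = rng.uniform(0, 1, 1000)
        c = TradeoffCurve(psar, nr, psar, [None] * 1000, kind="pareto")
        front = pareto([c])
        # O(n^2) oracle
        keep = []
        for i in range(1000):
            dominated = any(
                (psar[j] <= psar[i] and nr[j] <= nr[i])
                and (psar[j] < psar[i] or nr[j] < nr[i])
                for j in range(1000)
            )
            if not dominated:
                keep.append((psar[i], nr[i]))
        expect = sorted(keep)[::-1]
        got = sorted(zip(front.psar, front.nrmse))[::-1]
        assert got == expect

    def test_empty_input_empty_front(self):
        front = pareto([])
        assert len(front) == 0


class TestScenarios:
    def test_dt_table(self):
        assert SCENARIO_DT_S["full16"] == pytest.approx(0.2e-3)
        assert SCENARIO_DT_S["multi8_opt"] == pytest.approx(0.1e-3)
        assert SCENARIO_DT_S["multi8_2T_opt"] == pytest.approx(0.2e-3)

    def test_passive_split_coupling_structure(self, dataset):
        C = passive_split_coupling(dataset.fields)
        assert C.shape == (8, 16)
        for m in range(8):
            nz = np.flatnonzero(np.abs(C[m]) > 0)
            assert nz.size == 2
            phase = np.angle(C[m, nz[1]] / C[m, nz[0]], deg=True)
            assert phase == pytest.approx(-22.5, abs=1e-10)
            np.testing.assert_allclose(np.abs(C[m, nz]), 1.0)

    def test_multi8_conv_reproduces_full16_flip_angle(self, dataset, vops):
        # conversion keeps the excitation (dB0=0) but changes the pSAR seen
        # by the joint VOPs
        db0 = px.OffResonanceMap.zero(dataset.fields.grid)
        sc = build_scenario("full16", dataset.fields, vops)
        prob = make_problem(sc, db0, 2)
        sol = design_pulse(prob, random_init(prob, np.random.default_rng(1)),
                           maxiter=500)
        conv = evaluate_converted(sol, dataset.fields, db0, vops["combined_vop"])
        assert conv.nrmse == pytest.approx(sol.nrmse, abs=1e-9)
        psar_full = sol.psar
        assert conv.psar != pytest.approx(psar_full, rel=1e-3)

    def test_single_row_scenario_missing_row_errors(self, dataset, vops):
        bottom_only = dataset.fields.subset(dataset.fields.row_indices("bottom"))
        with pytest.raises(ValueError, match="top"):
            build_scenario("top", bottom_only, vops)

    def test_unknown_scenario_rejected(self, dataset, vops):
        with pytest.raises(ValueError, match="unknown"):
            build_scenario("multi4_opt", dataset.fields, vops)
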