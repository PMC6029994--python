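import numpy as np
import pytest

from simekit.aif_models import constrained_parent_aif, hill_fraction
from simekit.exceptions import InvalidParameterError
from simekit.kinetics import KineticParams, RegionTAC, model_tac, volume_of_distribution
from simekit.sime import (
    FitConfig,
    SimeProblem,
    _JointModel,
    fit_sime,
    reconstruct_aif,
    refit_individual,
    sime_cost,
)
from simekit.synthetic import REGIONS

from helpers import truth_theta


class TestProblemValidation:
    def test_constrained_requires_wb(self, noiseless_study):
        with pytest.raises(InvalidParameterError):
            SimeProblem(tacs=noiseless_study.tacs, mode="constrained", wb=None)

    def test_minimum_regions(self, noiseless_study):
        with pytest.raises(InvalidParameterError):
            SimeProblem(tacs=noiseless_study.tacs[:1], mode="original")

    def test_parameter_count(self, noiseless_study):
        assert noiseless_study.problem("constrained").n_params == 4 * 4 + 5
        assert noiseless_study.problem("original").n_params == 4 * 4 + 6


class TestCost:
    def test_truth_is_machine_level(self, default_truth, noiseless_study):
        problem = noiseless_study.problem("constrained")
        theta = truth_theta(default_truth, "constrained")
        total = sum(float(np.sum(tac.values**2)) for tac in noiseless_study.tacs)
        assert sime_cost(problem, theta) < 1e-10 * total

    def test_zero_kinetics_closed_form(self, default_truth, noiseless_study):
        problem = noiseless_study.problem("constrained")
        theta = truth_theta(default_truth, "constrained")
        theta[5:] = 0.0  # all kinetic parameters zero -> only the V_b term remains
        vb = 0.05
        expected = 0.0
        # K1=0 kills the convolution term; V_b * C_WB survives frame averaging
        wb_frames = model_tac(
            noiseless_study.wb, noiseless_study.wb,
            KineticParams(0.0, 0.0, 0.0, 0.0, vb), problem.schedule,
        ).values
        for tac in noiseless_study.tacs:
            expected += float(np.sum((wb_frames - tac.values) ** 2))
        assert sime_cost(problem, theta) == pytest.approx(expected, rel=1e-10)

    def test_independent_summation_oracle(self, default_truth, noiseless_study, rng):
        problem = noiseless_study.problem("constrained")
        theta = truth_theta(default_truth, "constrained")
        theta *= rng.uniform(0.8, 1.2, size=theta.size)  # fixed arbitrary point
        theta[0] = min(theta[0], 1.0)
        got = sime_cost(problem, theta)
        # straight-line re-implementation: forward-model each region, sum squares
        from simekit.aif_models import HillParams, RatioParams
        from simekit.kinetics import KineticParams

        h, r = HillParams(*theta[:3]), RatioParams(*theta[3:5])
        parent = lambda t: constrained_parent_aif(noiseless_study.wb, h, r, t)
        expected = 0.0
        for i, tac in enumerate(noiseless_study.tacs):
            kp = KineticParams(*theta[5 + 4 * i : 9 + 4 * i])
            modeled = model_tac(parent, noiseless_study.wb, kp, tac.schedule).values
            expected += float(np.sum((modeled - tac.values) ** 2))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_region_order_invariance(self, default_truth, noiseless_study):
        problem = noiseless_study.problem("constrained")
        theta = truth_theta(default_truth, "constrained")
        rev_tacs = list(reversed(noiseless_study.tacs))
        rev_problem = SimeProblem(tacs=rev_tacs, mode="constrained", wb=noiseless_study.wb)
        rev_theta = np.concatenate([theta[:5]] + [theta[5 + 4 * i : 9 + 4 * i] for i in (3, 2, 1, 0)])
        assert sime_cost(problem, theta) == pytest.approx(
            sime_cost(rev_problem, rev_theta), rel=1e-12
        )

    def test_wrong_length_rejected(self, noiseless_study):
        with pytest.raises(InvalidParameterError):
            sime_cost(noiseless_study.problem("constrained"), np.ones(7))


class TestAnalyticJacobian:
    @pytest.mark.parametrize("mode", ["original", "constrained"])
    def test_matches_finite_differences(self, default_truth, noiseless_study, mode):
        problem = noiseless_study.problem(mode)
        model = _JointModel(problem, FitConfig(fine_step=0.05))
        theta = truth_theta(default_truth, mode)
        jac = model.jacobian(theta)
        for j in range(theta.size):
            delta = 1e-6 * max(abs(theta[j]), 1e-4)
            tp, tm = theta.copy(), theta.copy()
            tp[j] += delta
            tm[j] -= delta
            col = (model.residuals(tp) - model.residuals(tm)) / (2 * delta)
            scale = np.abs(col).max() + 1e-9
            np.testing.assert_allclose(jac[:, j], col, atol=5e-4 * scale)


class TestFitNoiseless:
    def test_init_at_truth_recovers_everything(self, default_truth, noiseless_study):
        """Started at the optimum, the fit must stay there (cost already ~0)."""
        init = {"a": 0.25, "b": 1.6, "c": 25.0, "d": 0.0015, "e": 1.08}
        for region, kp in default_truth.kinetics.items():
            for name, v in zip(("k1", "k2", "k3", "k4"), kp.as_array()):
                init[f"{region}.{name}"] = float(v)
        cfg = FitConfig(multistarts=1, seed=0, init=init, grid_init=False)
        result = fit_sime(noiseless_study.problem("constrained"), cfg)
        assert result.success
        assert result.cost < 1e-8
        assert result.aif_params["a"] == pytest.approx(0.25, rel=1e-3)
        assert result.aif_params["b"] == pytest.approx(1.6, rel=1e-3)
        assert result.aif_params["c"] == pytest.approx(25.0, rel=1e-3)
        assert result.aif_params["d"] == pytest.approx(0.0015, rel=1e-3)
        assert result.aif_params["e"] == pytest.approx(1.08, rel=1e-3)
        for region in REGIONS:
            assert result.v_t[region] == pytest.approx(default_truth.v_t(region), rel=1e-3)

    def test_parent_fraction_and_bp_recovery_from_default_init(
        self, default_truth, noiseless_study
    ):
        """From generic inits: Hill fraction and BP_ND are identified exactly;
        V_T carries a common scale shared by every region (gauge freedom of the
        ratio line against K1)."""
        cfg = FitConfig(multistarts=1, seed=0)
        result = fit_sime(noiseless_study.problem("constrained"), cfg)
        assert result.cost < 1e-8
        tsample = np.array([3.5, 10.0, 17.5, 32.5, 55.0, 85.0])
        pf_err = np.abs(
            hill_fraction(result.hill, tsample) - hill_fraction(default_truth.hill, tsample)
        )
        assert pf_err.max() < 0.01
        for region in ("parietal", "hippocampus", "striatum"):
            assert result.bp_nd[region] == pytest.approx(
                default_truth.bp_nd(region), rel=1e-3
            )
        scales = [result.v_t[r] / default_truth.v_t(r) for r in REGIONS]
        np.testing.assert_allclose(scales, scales[0], rtol=1e-3)

    def test_scale_invariance_constrained(self, default_truth, noiseless_study):
        """Scaling TACs and wb jointly by s leaves (a, b, c, d, e) unchanged."""
        cfg = FitConfig(multistarts=1, seed=0)
        base = fit_sime(noiseless_study.problem("constrained"), cfg)
        s = 2.0
        scaled_tacs = [
            RegionTAC(t.region, t.schedule, t.values * s) for t in noiseless_study.tacs
        ]
        scaled = fit_sime(
            SimeProblem(tacs=scaled_tacs, mode="constrained", wb=noiseless_study.wb.scaled(s)),
            cfg,
        )
        for name in ("a", "b", "c", "d", "e"):
            assert scaled.aif_params[name] == pytest.approx(base.aif_params[name], rel=1e-3)

    def test_scale_invariance_original_cost(self, default_truth, noiseless_study):
        """Original-mode cost scales by s^2 when data and AIF amplitudes scale by s."""
        theta = truth_theta(default_truth, "original")
        problem = noiseless_study.problem("original")
        base = sime_cost(problem, theta)
        s = 3.0
        scaled_tacs = [
            RegionTAC(t.region, t.schedule, t.values * s) for t in noiseless_study.tacs
        ]
        scaled_problem = SimeProblem(tacs=scaled_tacs, mode="original")
        theta_s = theta.copy()
        theta_s[:3] *= s  # amplitudes scale, decay rates don't
        assert sime_cost(scaled_problem, theta_s) == pytest.approx(s**2 * base, rel=1e-9)


class TestRefit:
    def test_noiseless_self_consistency(self, default_truth, noiseless_study):
        parent = lambda t: constrained_parent_aif(
            noiseless_study.wb, default_truth.hill, default_truth.ratio, t
        )
        cfg = FitConfig()
        for tac_clean, region in zip(noiseless_study.noiseless, REGIONS):
            rf = refit_individual(tac_clean, parent, noiseless_study.wb, cfg)
            truth_kp = default_truth.kinetics[region]
            for got, want in zip(rf.params.as_array(), truth_kp.as_array()):
                assert got == pytest.approx(want, rel=1e-3)
            assert volume_of_distribution(rf.params) == pytest.approx(
                default_truth.v_t(region), rel=1e-4
            )

    def test_zero_tac_hits_lower_bound(self, noiseless_study):
        sched = noiseless_study.schedule
        zero_tac = RegionTAC("null", sched, np.zeros(sched.n_frames))
        parent = noiseless_study.wb
        rf = refit_individual(zero_tac, parent, noiseless_study.wb, FitConfig())
        assert rf.params.k1 == pytest.approx(1e-4, rel=1e-3)  # K1 at its lower bound
        assert "k1" in rf.at_lower_bound


class TestReconstruct:
    def test_constrained_identity_components(self, noiseless_study, fast_config):
        result = fit_sime(noiseless_study.problem("constrained"), fast_config)
        result.aif_params.update({"a": 1.0, "d": 0.0, "e": 1.0})
        t = np.linspace(0.0, 90.0, 50)
        np.testing.assert_allclose(reconstruct_aif(result, t), noiseless_study.wb(t), rtol=1e-12)

    def test_matches_factorwise_oracle(self, noiseless_study, fast_config):
        result = fit_sime(noiseless_study.problem("constrained"), fast_config)
        t = noiseless_study.schedule.mid_times
        expected = constrained_parent_aif(noiseless_study.wb, result.hill, result.ratio, t)
        np.testing.assert_allclose(reconstruct_aif(result, t), expected, rtol=1e-12)

    def test_unconverged_rejected(self, noiseless_study, fast_config):
        result = fit_sime(noiseless_study.problem("constrained"), fast_config)
        result.success = False
        from simekit.exceptions import SimekitError

        with pytest.raises(SimekitError):
            reconstruct_aif(result, np.array([0.0, 1.0]))
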