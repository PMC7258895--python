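import numpy as np
import pytest

import dcmnet as d
from dcmnet.forward import HemodynamicConstants


class TestDesign:
    def test_make_design_volume_counts(self):
        assert d.make_design(4, 400, 40).n_volumes == 100
        assert d.make_design(2, 400, 40).n_volumes == 200
        with pytest.raises(ValueError, match="divisible"):
            d.make_design(3, 400, 40)

    def test_microtime_must_divide_tr(self):
        with pytest.raises(ValueError, match="divide"):
            d.StimulusDesign(TR=4.0, n_volumes=10, microtime_dt=0.3)

    def test_block_schedule(self, design):
        assert d.input_function(design, 10.0) == 0.0
        assert d.input_function(design, 50.0) == 1.0  # first active block spans 40-80 s
        t = np.arange(0, design.duration, 0.25)
        u = d.input_function(design, t)
        # alternating 40 s blocks from rest: 5 active blocks = 200 s
        assert u.sum() * 0.25 == pytest.approx(200.0)
        with pytest.raises(ValueError, match="outside"):
            d.input_function(design, -1.0)


class TestNeuralLayer:
    def test_fixed_point_and_input(self, model11):
        p = d.DCMParameters.from_prior_means(model11, c_gain=0.5)
        assert np.allclose(d.neural_derivative(np.zeros(8), 0.0, p), 0.0)
        dx = d.neural_derivative(np.zeros(8), 1.0, p)
        assert np.allclose(dx, p.C)

    def test_known_coupling_propagates(self, model11):
        A = np.zeros((8, 8))
        A[0, 2] = 0.0886  # cSMA -> cM1
        p = d.DCMParameters(
            A=A, self_log_scale=np.zeros(8), C=np.zeros(8), hemo=d.HemodynamicParams.priors(8)
        )
        x = np.zeros(8)
        x[2] = 1.0
        dx = d.neural_derivative(x, 0.0, p)
        assert dx[0] == pytest.approx(0.0886)

    def test_linearity_in_state_and_input_gain(self, model11):
        rng = np.random.default_rng(3)
        A = np.where(model11.a_mask, rng.normal(0, 0.1, (8, 8)), 0.0)
        p = d.DCMParameters(
            A=A,
            self_log_scale=np.zeros(8),
            C=np.where(model11.c_mask, 0.5, 0.0),
            hemo=d.HemodynamicParams.priors(8),
        )
        p2 = d.DCMParameters(
            A=A, self_log_scale=p.self_log_scale, C=2 * p.C, hemo=p.hemo
        )
        x = rng.normal(size=8)
        assert np.allclose(
            d.neural_derivative(2 * x, 1.0, p2), 2 * d.neural_derivative(x, 1.0, p)
        )

    def test_mask_violation_rejected(self, model11):
        A = np.zeros((8, 8))
        A[3, 0] = 0.1  # an edge into S1 never exists
        p = d.DCMParameters(
            A=A, self_log_scale=np.zeros(8), C=np.zeros(8), hemo=d.HemodynamicParams.priors(8)
        )
        with pytest.raises(ValueError, match="a_mask"):
            d.neural_derivative(np.zeros(8), 0.0, p, spec=model11)


class TestHemodynamics:
    def test_resting_fixed_point(self):
        dh = d.hemodynamic_derivative((0.0, 1.0, 1.0, 1.0), 0.0)
        assert np.allclose(dh, 0.0)

    def test_activity_enters_signal_only(self):
        dh = d.hemodynamic_derivative((0.0, 1.0, 1.0, 1.0), 1.0)
        assert dh[0] == pytest.approx(1.0)
        assert np.allclose(dh[1:], 0.0)

    def test_flow_feedback_term(self):
        dh = d.hemodynamic_derivative((0.0, 1.2, 1.0, 1.0), 0.0)
        assert dh[0] == pytest.approx(-0.32 * 0.2)  # -gamma (f - 1)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            d.hemodynamic_derivative((0.0, 1.0, -0.1, 1.0), 0.0)

    def test_bold_signal(self):
        c = HemodynamicConstants()
        assert d.bold_signal(1.0, 1.0, c) == 0.0
        expected = c.V0 * (c.k1 * 0.1 + c.k2(1.0) * 0.1)
        assert d.bold_signal(1.0, 0.9, c, epsilon=1.0) == pytest.approx(expected)
        # decreasing q at fixed v raises the signal
        assert d.bold_signal(1.0, 0.8, c) > d.bold_signal(1.0, 0.9, c)

    def test_bold_coefficients(self):
        c = HemodynamicConstants()
        assert c.k1 == pytest.approx(4.3 * 40.3 * 0.4 * 0.042)
        assert c.k2(1.0) == pytest.approx(25.0 * 0.4 * 0.042)
        assert c.k3(1.0) == 0.0


class TestIntegration:
    def test_no_input_stays_at_rest(self, model11, design):
        p = d.DCMParameters.from_prior_means(model11, c_gain=0.0)
        sess = d.integrate_dcm(model11, p, design)
        assert np.all(sess.values == 0.0)

    def test_bold_layer_is_nonlinear(self, reduced_model, reduced_truth, design):
        sess1 = d.integrate_dcm(reduced_model, reduced_truth, design)
        p2 = d.DCMParameters(
            A=reduced_truth.A,
            self_log_scale=reduced_truth.self_log_scale,
            C=2 * reduced_truth.C,
            hemo=reduced_truth.hemo,
        )
        sess2 = d.integrate_dcm(reduced_model, p2, design)
        ratio = sess2.values.max() / sess1.values.max()
        assert ratio < 1.95  # saturating observation, despite a linear neural layer

    def test_step_halving_convergence(self, reduced_model, reduced_truth):
        coarse = d.make_design()
        fine = d.StimulusDesign(TR=4.0, n_volumes=100, microtime_dt=coarse.microtime_dt / 2)
        y1 = d.integrate_dcm(reduced_model, reduced_truth, coarse).values
        y2 = d.integrate_dcm(reduced_model, reduced_truth, fine).values
        assert np.max(np.abs(y1 - y2)) < 1e-4 * np.ptp(y1)

    def test_seeded_reproducibility(self, reduced_model, reduced_truth, design):
        kw = dict(noise=d.NoiseSpec(state_sd=0.01, obs_snr=5.0), seed=11)
        a = d.integrate_dcm(reduced_model, reduced_truth, design, **kw)
        b = d.integrate_dcm(reduced_model, reduced_truth, design, **kw)
        assert np.array_equal(a.values, b.values)
        c = d.integrate_dcm(reduced_model, reduced_truth, design, noise=d.NoiseSpec(0.01, 5.0), seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_unstable_dynamics_flagged_with_index(self, design):
        model = d.ReducedModel(
            a_mask=np.ones((2, 2), dtype=bool),
            c_mask=np.array([True, False]),
            region_labels=("r1", "r2"),
        )
        A = np.array([[0.0, 2.0], [2.0, 0.0]])  # coupling overwhelms self-decay
        p = d.DCMParameters(
            A=A,
            self_log_scale=np.zeros(2),
            C=np.array([1.0, 0.0]),
            hemo=d.HemodynamicParams.priors(2),
        )
        with pytest.raises(FloatingPointError, match="volume index"):
            d.integrate_dcm(model, p, design)

    def test_bounded_for_stable_couplings(self, reduced_model, reduced_truth, design):
        assert d.is_stable(reduced_truth.a_eff)
        y = d.integrate_dcm(reduced_model, reduced_truth, design).values
        assert np.all(np.isfinite(y)) and np.abs(y).max() < 1.0
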