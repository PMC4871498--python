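"""Model container, simulation, residuals and the zoo."""

import numpy as np
import pytest

from mbam import (
    InputProtocol,
    ParameterVector,
    QoISpec,
    residuals,
    simulate,
    zoo,
    zoo_names,
)
from mbam.models import simulate_stacked
from mbam.zoo import SamplingError, sample_adaptive_params


@pytest.fixture()
def mm(mm_full):
    return mm_full


class TestInputProtocol:
    def test_step_is_zero_at_onset(self):
        u = InputProtocol("step", 2.0, onset=1.0)
        assert u(0.5) == 0.0
        assert u(1.0) == 0.0  # Heaviside convention Theta(0) = 0
        assert u(1.0 + 1e-12) == 2.0

    def test_constant(self):
        u = InputProtocol("constant", 0.7)
        assert u(-5.0) == u(100.0) == 0.7

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            InputProtocol("step", -1.0)


class TestSimulate:
    def test_conservation_laws_hold(self, mm):
        """E0 = [E]+[C] and S0 = [S]+[C]+[P] along the whole trajectory."""
        model, theta0, _ = mm
        traj = simulate(model, theta0, np.linspace(0.1, 15, 40))
        e_tot = traj["E"] + traj["C"]
        s_tot = traj["S"] + traj["C"] + traj["P"]
        assert np.abs(e_tot - 0.25).max() <= 1e-8
        assert np.abs(s_tot - 1.0).max() <= 1e-8

    @pytest.mark.parametrize("name", zoo_names())
    def test_output_starts_at_its_initial_value(self, name):
        """Every bundled model's product/output state starts at zero."""
        model, ref, qoi = zoo(name)
        if ref is None:
            ref = ParameterVector(model.parameter_names, np.zeros(model.n_params))
        traj = simulate(model, ref, np.array([0.0, 0.5]), qoi.protocol)
        out_state = "P" if "P" in model.state_names else (
            qoi.observable if qoi.observable in model.state_names else model.state_names[0]
        )
        assert traj[out_state][0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(
            traj.states[0], model.initial_state(ref.as_dict(linear=True)), atol=1e-12
        )

    def test_cross_solver_agreement(self, mm):
        """Two independent integrator families agree on the predictions."""
        model, theta0, qoi = mm
        t = np.array([5.0, 10.0, 15.0])
        lsoda = simulate(model, theta0, t, method="LSODA", rtol=1e-10, atol=1e-12)
        radau = simulate(model, theta0, t, method="Radau", rtol=1e-10, atol=1e-12)
        assert np.abs(lsoda["P"] - radau["P"]).max() <= 1e-6

    @pytest.mark.parametrize("name", ["NFB_2", "IFFLP_2", "NFB_4", "IFFLP_4"])
    def test_cross_solver_agreement_gated(self, name):
        model, _, qoi = zoo(name)
        pv = ParameterVector(model.parameter_names, np.zeros(model.n_params))
        t = np.linspace(0.5, 8.0, 8)
        a = simulate(model, pv, t, qoi.protocol, method="LSODA", rtol=1e-10, atol=1e-12)
        b = simulate(model, pv, t, qoi.protocol, method="Radau", rtol=1e-10, atol=1e-12)
        assert np.abs(a.states - b.states).max() <= 1e-6

    def test_saturation_bound_respected(self):
        """Heaviside-gated states never exceed their cap."""
        model, _, qoi = zoo("NFB_4")
        pv = ParameterVector.from_linear(
            {"kIA": 5.0, "kCB*kBC/(KCB*KBC)": 0.5, "kFB/KFB": 0.5, "kAC": 3.0}
        )
        traj = simulate(model, pv, np.linspace(0.1, 30, 120), qoi.protocol)
        assert traj["A"].max() <= 1.0 + 1e-9
        assert traj["C"].max() <= 1.0 + 1e-9
        # the input node does saturate at these parameters
        assert traj["A"].max() == pytest.approx(1.0, abs=1e-9)

    def test_parameter_name_mismatch(self, mm):
        model, _, _ = mm
        bad = ParameterVector(("a", "b", "c"), np.zeros(3))
        with pytest.raises(ValueError, match="do not match"):
            simulate(model, bad, [1.0])

    def test_stacked_matches_loop(self, mm):
        model, theta0, _ = mm
        thetas = [theta0.values + d for d in (0.0, 0.05, -0.05)]
        ks = [dict(zip(model.parameter_names, np.exp(th))) for th in thetas]
        t = np.array([2.0, 5.0, 9.0])
        stacked = simulate_stacked(model, ks, t)
        for b, th in enumerate(thetas):
            solo = simulate(model, theta0.with_values(th), t)
            assert np.abs(stacked[b] - solo.states).max() < 1e-8


class TestResiduals:
    def test_unit_sigma_returns_raw_predictions(self, mm):
        model, theta0, qoi = mm
        r = residuals(model, theta0, qoi)
        traj = simulate(model, theta0, qoi.times)
        assert np.allclose(r, traj["P"] / 1.0, atol=1e-9)
        assert r.shape == (3,)

    def test_linear_in_inverse_sigma(self, mm):
        model, theta0, qoi = mm
        r1 = residuals(model, theta0, qoi)
        r2 = residuals(model, theta0, qoi.with_sigmas(2.0 * qoi.sigmas))
        assert np.allclose(r2, r1 / 2.0, atol=1e-12)

    def test_unknown_observable(self, mm):
        model, theta0, qoi = mm
        with pytest.raises(ValueError, match="observable"):
            residuals(model, theta0, QoISpec("nope", qoi.times, 1.0))


class TestZoo:
    def test_mm_full_shape(self, mm):
        model, theta0, qoi = mm
        assert model.parameter_names == ("kf", "kr", "kc")
        assert model.n_states == 4
        assert len(model.conservation) == 2
        assert np.allclose(theta0.values, [1.0, 0.5, 1.5])
        assert list(qoi.times) == [5.0, 10.0, 15.0]

    def test_nfb4_parameter_combinations(self):
        model, _, _ = zoo("NFB_4")
        assert set(model.parameter_names) == {
            "kIA", "kCB*kBC/(KCB*KBC)", "kFB/KFB", "kAC"
        }

    def test_egfr2_shape(self):
        model, ref, _ = zoo("EGFR_2")
        assert model.parameter_names == ("theta1", "theta2")
        assert model.n_states == 2
        assert np.allclose(ref.k, [1.558, 0.977])

    def test_unknown_name_lists_models(self):
        with pytest.raises(KeyError, match="MM_FULL"):
            zoo("NOT_A_MODEL")


class TestAdaptiveSampler:
    def test_seeded_determinism(self):
        model, _, _ = zoo("NFB_12")
        a = sample_adaptive_params(model, seed=3)
        b = sample_adaptive_params(model, seed=3)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_returned_set_is_adaptive(self, nfb12_fixture):
        from mbam.adaptation import extract_phenotype

        model, params, _ = nfb12_fixture
        traj = simulate(
            model, params, np.geomspace(1e-3, 1e3, 400), InputProtocol("step", 0.5)
        )
        ph = extract_phenotype(traj, "C")
        assert ph.adaptive
        assert ph.sensitivity >= 0.1 * 0.5
        assert ph.precision_offset <= 0.2 * ph.sensitivity + 1e-12

    def test_impossible_criteria_exhaust(self):
        model, _, _ = zoo("NFB_12")
        with pytest.raises(SamplingError) as err:
            sample_adaptive_params(
                model, sensitivity_min=1e6, seed=0, max_draws=40
            )
        assert err.value.draws == 40

    def test_wrong_model_rejected(self):
        model, _, _ = zoo("NFB_4")
        with pytest.raises(ValueError):
            sample_adaptive_params(model, seed=0)
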