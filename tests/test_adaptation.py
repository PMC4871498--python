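"""Adaptation phenotypes, the dimensionless ratio tau, and closed forms."""

import numpy as np
import pytest

from mbam import InputProtocol, ParameterVector, Trajectory, simulate, zoo
from mbam.adaptation import (
    NonAdaptiveResponse,
    UnsettledTailError,
    canonical_params,
    extract_phenotype,
    ifflp_early_time,
    nfb_steady_states,
    tau_of,
    tau_sweep,
)


def _traj(t, y, name="C"):
    return Trajectory(
        t, y[:, None], (name,), np.zeros_like(t), {"success": True}
    )


class TestExtractPhenotype:
    def test_analytic_peak(self):
        """C(t) = t e^{1-t} peaks at t = 1 with height 1 and decays to 0."""
        t = np.linspace(0.0, 60.0, 6000)
        ph = extract_phenotype(_traj(t, t * np.exp(1.0 - t)))
        assert ph.adaptive
        assert ph.response_time == pytest.approx(1.0, rel=0.01)
        assert ph.sensitivity == pytest.approx(1.0, rel=0.01)
        assert ph.precision_offset == pytest.approx(0.0, abs=0.01)
        # FWHM of t e^{1-t} is about 2.45 time units
        assert ph.peak_width == pytest.approx(2.45, rel=0.05)

    def test_zero_output_is_non_adaptive(self):
        t = np.linspace(0.0, 10.0, 200)
        with pytest.raises(NonAdaptiveResponse) as err:
            extract_phenotype(_traj(t, np.zeros_like(t)))
        assert err.value.phenotype.sensitivity == 0.0
        assert not err.value.phenotype.adaptive

    def test_monotone_rise_is_non_adaptive(self):
        t = np.linspace(0.0, 10.0, 200)
        with pytest.raises(NonAdaptiveResponse):
            extract_phenotype(_traj(t, 1.0 - np.exp(-t)))

    def test_unsettled_tail_names_horizon(self):
        t = np.linspace(0.0, 3.0, 300)  # cut off mid-decay
        with pytest.raises(UnsettledTailError, match="horizon"):
            extract_phenotype(_traj(t, t * np.exp(1.0 - t)))


class TestTau:
    def test_egfr_value(self):
        """theta1/sqrt(theta2) at the reported reduced-parameter values."""
        _, ref, _ = zoo("EGFR_2")
        tv = tau_of("EGFR_2", ref)
        assert tv.tau == pytest.approx(1.576, abs=0.001)
        assert round(tv.tau, 1) == 1.6
        assert tv.mechanism == "EGFR"

    def test_time_rescaling_invariance(self):
        """Dividing every rate by alpha leaves tau unchanged."""
        alpha = 7.0
        pv = ParameterVector.from_linear(
            {"kAC": 1.3, "kCB*kBC/(KCB*KBC)": 0.6}
        )
        tau0 = tau_of("NFB_2", pv, I=0.5).tau
        # kAC scales by 1/alpha; the lumped kCB*kBC combination by 1/alpha^2
        scaled = ParameterVector.from_linear(
            {"kAC": 1.3 / alpha, "kCB*kBC/(KCB*KBC)": 0.6 / alpha**2}
        )
        tau1 = tau_of("NFB_2", scaled, I=0.5).tau
        assert abs(tau1 - tau0) <= 1e-12

    def test_unknown_model(self):
        pv = ParameterVector.from_linear({"kAC": 1.0})
        with pytest.raises(KeyError):
            tau_of("NFB_4", pv)

    def test_canonical_params_round_trip(self):
        for mid in ("NFB_2", "IFFLP_2", "EGFR_2"):
            for tau in (0.3, 1.0, 2.7):
                pv = canonical_params(mid, tau)
                assert tau_of(mid, pv).tau == pytest.approx(tau, rel=1e-12)

    def test_equal_tau_curves_collapse_after_time_rescaling(self):
        """Two parameter sets with equal tau superimpose once time is
        rescaled by the ratio of their kAC values."""
        model, _, _ = zoo("NFB_2")
        tau = 0.8
        a = canonical_params("NFB_2", tau)  # kAC = 1
        alpha = 3.0
        b = ParameterVector.from_linear(
            {
                "kAC": 1.0 / alpha,
                "kCB*kBC/(KCB*KBC)": tau_of("NFB_2", a).tau ** -2 / alpha**2,
            }
        )
        assert tau_of("NFB_2", b).tau == pytest.approx(tau, rel=1e-12)
        t = np.linspace(0.05, 40.0, 300)
        u = InputProtocol("step", 1.0)
        ya = simulate(model, a, t, u)["C"]
        yb = simulate(model, b, t * alpha, u)["C"]
        assert np.abs(ya - yb).max() <= 1e-4


class TestClosedForms:
    def test_nfb_steady_state_matches_long_integration(self):
        model, _, _ = zoo("NFB_4")
        pv = ParameterVector.from_linear(
            {"kIA": 1.2, "kCB*kBC/(KCB*KBC)": 2.0, "kFB/KFB": 0.8, "kAC": 0.4}
        )
        A, B, C = nfb_steady_states(pv, I=0.5)
        assert A == 1.0
        traj = simulate(model, pv, np.array([1e4]), InputProtocol("step", 0.5))
        assert np.abs(traj.states[-1] - [A, B, C]).max() <= 1e-6

    def test_precision_improves_with_KFB(self):
        """Raising K_FB (lowering the lumped decay rate kFB/KFB) lowers the
        final steady state of the output node."""
        base = {"kIA": 1.2, "kCB*kBC/(KCB*KBC)": 2.0, "kFB/KFB": 0.8, "kAC": 0.4}
        offsets = []
        for scale in (1.0, 2.0, 4.0):  # increasing K_FB
            p = dict(base, **{"kFB/KFB": base["kFB/KFB"] / scale})
            _, _, c_star = nfb_steady_states(ParameterVector.from_linear(p))
            offsets.append(c_star)
        assert offsets[0] > offsets[1] > offsets[2]

    def test_phenotype_offset_agrees_with_steady_state(self):
        model, _, _ = zoo("NFB_4")
        pv = ParameterVector.from_linear(
            {"kIA": 1.2, "kCB*kBC/(KCB*KBC)": 2.0, "kFB/KFB": 0.8, "kAC": 0.4}
        )
        _, _, c_star = nfb_steady_states(pv, I=0.5)
        t = np.linspace(0.1, 2000.0, 2000)
        traj = simulate(model, pv, t, InputProtocol("step", 0.5))
        ph = extract_phenotype(traj, "C")
        assert abs(ph.precision_offset - c_star) <= 1e-3

    def test_ifflp_early_time_exact(self):
        model, _, _ = zoo("IFFLP_4")
        pv = ParameterVector.from_linear(
            {"kIA": 0.7, "kAB": 0.9, "kAC": 0.5, "kBC/KBC": 1.1}
        )
        for t in (0.0, 0.2, 0.4):
            A, B = ifflp_early_time(pv, t, I=0.5)
            if t == 0.0:
                assert A == B == 0.0
                continue
            traj = simulate(model, pv, np.array([t]), InputProtocol("step", 0.5))
            assert abs(traj["A"][-1] - A) <= 1e-8
            assert abs(traj["B"][-1] - B) <= 1e-8
            # B / (t A) = kAB / 2 exactly in the pre-saturation window
            assert B / (t * A) == pytest.approx(0.9 / 2.0, rel=1e-12)

    def test_ifflp_early_time_rejects_post_saturation(self):
        pv = ParameterVector.from_linear(
            {"kIA": 5.0, "kAB": 0.9, "kAC": 0.5, "kBC/KBC": 1.1}
        )
        with pytest.raises(ValueError, match="saturation"):
            ifflp_early_time(pv, 5.0, I=0.5)


@pytest.fixture(scope="module")
def sweeps():
    grid = [0.25, 0.5, 1.0, 2.0, 4.0]
    return {mid: tau_sweep(mid, grid) for mid in ("NFB_2", "IFFLP_2")}, grid


class TestTauSweep:

    def test_response_time_increases_with_tau(self, sweeps):
        tables, _ = sweeps
        nfb = tables["NFB_2"]
        assert nfb["peak_time"].is_monotonic_increasing
        assert nfb["peak_time"].nunique() == len(nfb)

    def test_peak_height_monotone_until_cap(self, sweeps):
        """Sensitivity rises with tau and saturates at the output cap."""
        tables, _ = sweeps
        for mid, table in tables.items():
            h = table["peak_height"].to_numpy()
            assert np.all(np.diff(h) >= -1e-9)
            below = h < 1.0 - 1e-9
            assert np.all(np.diff(h[below]) > 0)
            assert h[-1] == pytest.approx(1.0, abs=1e-6)  # cap reached

    def test_feedback_beats_feedforward_on_sensitivity(self, sweeps):
        tables, _ = sweeps
        nfb, ifflp = tables["NFB_2"], tables["IFFLP_2"]
        assert np.all(
            nfb["peak_height"].to_numpy() >= ifflp["peak_height"].to_numpy() - 1e-9
        )

    def test_feedforward_beats_feedback_on_precision(self, sweeps):
        tables, _ = sweeps
        nfb, ifflp = tables["NFB_2"], tables["IFFLP_2"]
        assert np.all(
            ifflp["final_offset"].to_numpy() <= nfb["final_offset"].to_numpy() + 1e-9
        )

    def test_deterministic(self, sweeps):
        tables, grid = sweeps
        again = tau_sweep("NFB_2", grid)
        assert np.allclose(
            again.to_numpy(dtype=float), tables["NFB_2"].to_numpy(dtype=float)
        )
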