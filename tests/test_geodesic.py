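"""Geodesics, curvature stencils, and boundary classification."""

from dataclasses import replace

import numpy as np
import pytest

from mbam import FDOptions, ParameterVector, QoISpec, jacobian
from mbam.geodesic import (
    GeodesicOptions,
    classify_limit,
    integrate_geodesic,
    second_directional_derivative,
)
from mbam.models import ODEModel
from mbam.zoo import MM_BOUNDARY_QOI


def _theta_model(fn, pnames):
    """Trivial-dynamics model whose observable is an explicit map of theta.

    dx/dt = 0 keeps the solver out of the way; the observable closure
    computes y_m(theta) directly, so curvature properties are exact.
    """
    def rhs(t, x, k, u, gates):
        return np.zeros(1) if np.ndim(x[0]) == 0 else np.zeros((1, len(x[0])))

    def obs(states, k):
        theta = np.log([k[p] for p in pnames])
        T = states.shape[0]
        return np.array([fn(theta, m) for m in range(T)])

    return ODEModel(
        name="direct", state_names=("x",), parameter_names=pnames,
        rhs=rhs, initial_state=lambda k: np.zeros(1),
        observables={"y": obs},
    )


class TestSecondDirectionalDerivative:
    def test_linear_map_has_zero_curvature(self):
        model = _theta_model(lambda th, m: 2.0 * th[0] - th[1] * (m + 1), ("a", "b"))
        pv = ParameterVector(("a", "b"), np.array([0.2, -0.1]))
        qoi = QoISpec("y", np.array([1.0, 2.0, 3.0]), 1.0)
        for v in (np.array([1.0, 0.0]), np.array([0.6, -0.8])):
            A = second_directional_derivative(model, pv, v, qoi, h=1e-3)
            assert np.abs(A).max() <= 1e-8

    def test_quadratic_map_exact(self):
        model = _theta_model(lambda th, m: th[0] ** 2, ("a",))
        pv = ParameterVector(("a",), np.zeros(1))
        qoi = QoISpec("y", np.array([1.0]), 1.0)
        A = second_directional_derivative(model, pv, np.array([1.0]), qoi, h=1e-3)
        assert A[0] == pytest.approx(2.0, abs=1e-6)

    def test_scales_quadratically_with_velocity(self):
        model = _theta_model(lambda th, m: th[0] ** 2 + th[0] * th[1], ("a", "b"))
        pv = ParameterVector(("a", "b"), np.array([0.1, 0.3]))
        qoi = QoISpec("y", np.array([1.0]), 1.0)
        v = np.array([0.3, -0.4])
        A1 = second_directional_derivative(model, pv, v, qoi)
        A3 = second_directional_derivative(model, pv, 3.0 * v, qoi)
        assert A3[0] == pytest.approx(9.0 * A1[0], rel=1e-6)

    def test_step_halving_stable_on_enzyme_model(self, mm_full, mm_spectrum):
        model, theta0, qoi = mm_full
        v = mm_spectrum.sloppiest
        a1 = second_directional_derivative(model, theta0, v, qoi, h=2e-2)
        a2 = second_directional_derivative(model, theta0, v, qoi, h=1e-2)
        assert np.abs(a1 - a2).max() <= 1e-4


class TestGeodesic:
    def test_equilibrium_boundary(self, equilibrium_path):
        """The + direction finds the rapid-equilibrium face: kf, kr -> inf."""
        p = equilibrium_path
        assert p.termination == "boundary"
        d = classify_limit(p)
        assert d.verdicts == {"kf": "inf", "kr": "inf", "kc": "finite"}
        # the surviving combination log Kd = log kr - log kf stays finite
        # and moves from its starting value (-0.5) toward the calibrated
        # equilibrium-face value (0.396)
        kd_end = p.final_theta[1] - p.final_theta[0]
        assert -0.5 < kd_end < 0.45

    def test_irreversibility_boundary(self, irreversibility_path):
        """The - direction finds the irreversible-binding face: kr -> 0."""
        p = irreversibility_path
        assert p.termination == "boundary"
        d = classify_limit(p)
        assert d.verdicts == {"kf": "finite", "kr": "zero", "kc": "finite"}

    def test_two_signs_reach_distinct_boundaries(
        self, equilibrium_path, irreversibility_path
    ):
        va = classify_limit(equilibrium_path).nonfinite
        vb = classify_limit(irreversibility_path).nonfinite
        assert va != vb

    def test_fisher_speed_conserved(self, mm_full, equilibrium_path):
        """Unit Fisher speed is a first integral of the geodesic equation."""
        model, theta0, _ = mm_full
        p = equilibrium_path
        cut = p.taus[-1] * 0.95
        fd = FDOptions(h=1e-3, rtol=1e-9, atol=1e-11)
        drifts = []
        idx = [i for i in range(len(p.taus)) if p.taus[i] <= cut]
        for i in idx[:: max(1, len(idx) // 10)]:
            J = jacobian(
                model, theta0.with_values(p.thetas[i]), MM_BOUNDARY_QOI, fd
            )
            v = p.velocities[i]
            drifts.append(abs(np.sqrt(v @ (J.T @ J) @ v) - 1.0))
        assert max(drifts) <= 1e-3

    def test_path_monotone_tau_and_start(self, mm_full, equilibrium_path):
        model, theta0, _ = mm_full
        p = equilibrium_path
        assert p.taus[0] == 0.0
        assert np.all(np.diff(p.taus) > 0)
        assert np.allclose(p.thetas[0], theta0.values)

    def test_tolerance_robustness(self, mm_full, equilibrium_path):
        """10x tighter inner tolerances move the terminal tau by <= 2%."""
        model, theta0, _ = mm_full
        opts = GeodesicOptions(
            direction=+1,
            fd=FDOptions(h=1e-3, rtol=1e-10, atol=1e-12),
        )
        p2 = integrate_geodesic(model, theta0, MM_BOUNDARY_QOI, opts)
        t1, t2 = equilibrium_path.taus[-1], p2.taus[-1]
        assert abs(t2 - t1) / t1 <= 0.02

    def test_singular_start_raises(self, mm_full):
        model, theta0, qoi3 = mm_full
        with pytest.raises(ValueError, match="singular"):
            integrate_geodesic(model, theta0, qoi3, GeodesicOptions())

    def test_flat_manifold_runs_to_max_tau(self):
        model = _theta_model(
            lambda th, m: th[0] * (m + 1) + 0.5 * th[1] * (m + 1) ** 2, ("a", "b")
        )
        pv = ParameterVector(("a", "b"), np.array([0.3, -0.2]))
        qoi = QoISpec("y", np.array([1.0, 2.0, 3.0]), 1.0)
        opts = GeodesicOptions(max_tau=1.0, direction=+1)
        p = integrate_geodesic(model, pv, qoi, opts)
        assert p.termination == "max-tau"
        # straight line: velocity constant, eigenvalue traces flat
        assert np.allclose(p.velocities, p.velocities[0], atol=1e-6)
        assert np.allclose(p.lambda_min, p.lambda_min[0], rtol=1e-6)


class TestClassifyLimit:
    def test_component_threshold(self, equilibrium_path):
        tight = classify_limit(equilibrium_path, component_threshold=0.9)
        assert tight.nonfinite == {}

    def test_rejects_failed_paths(self, equilibrium_path):
        import copy

        p = copy.copy(equilibrium_path)
        p.termination = "solver-failure"
        with pytest.raises(ValueError):
            classify_limit(p)
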