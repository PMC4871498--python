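"""Limit rules, calibration, identifiability and the MBAM loop."""

import numpy as np
import pytest

from mbam import ParameterVector, QoISpec, residuals, zoo
from mbam.geodesic import LimitDescriptor
from mbam.reduction import (
    PAPER_CHAINS,
    UnmatchedLimitError,
    apply_limit,
    calibrate,
    default_registry,
    descriptor_from_verdicts,
    identifiability_check,
    mbam_run,
    replay_chain,
)


def _descriptor(model, nonfinite):
    return descriptor_from_verdicts(model, nonfinite)


class TestApplyLimit:
    def test_equilibrium_limit(self, mm_full):
        """kf, kr -> inf yields the (Kd, kc) model with Kd guessed as kr/kf."""
        model, theta0, _ = mm_full
        reduced, phi = apply_limit(
            model, theta0, _descriptor(model, {"kf": "inf", "kr": "inf"})
        )
        assert reduced.name == "MM_EQUILIBRIUM"
        assert phi.names == ("Kd", "kc")
        assert phi["Kd"] == pytest.approx(theta0["kr"] - theta0["kf"])
        assert phi["kc"] == pytest.approx(theta0["kc"])

    def test_irreversibility_limit(self, mm_full):
        model, theta0, _ = mm_full
        reduced, phi = apply_limit(
            model, theta0, _descriptor(model, {"kr": "zero"})
        )
        assert reduced.name == "MM_IRREVERSIBLE"
        assert phi.names == ("kf", "kc")

    def test_qssa_limit_combinations(self):
        """kf, kc -> inf with E0 -> 0 leaves Vmax = kc E0 and KM = kc/kf."""
        model, theta0, _ = zoo("MM_IRREVERSIBLE_P")
        theta0 = ParameterVector(
            ("kf", "kc", "E0", "S0"), np.array([1.0, 1.5, np.log(0.25), 0.0])
        )
        reduced, phi = apply_limit(
            model, theta0,
            _descriptor(model, {"kf": "inf", "kc": "inf", "E0": "zero"}),
        )
        assert reduced.name == "MM_QSSA"
        assert phi["Vmax"] == pytest.approx(theta0["kc"] + theta0["E0"])
        assert phi["KM"] == pytest.approx(theta0["kc"] - theta0["kf"])

    def test_unmatched_limit_carries_descriptor(self, mm_full):
        model, theta0, _ = mm_full
        d = _descriptor(model, {"kc": "inf"})
        with pytest.raises(UnmatchedLimitError) as err:
            apply_limit(model, theta0, d)
        assert err.value.descriptor.nonfinite == {"kc": "inf"}

    def test_registry_is_extensible(self, mm_full):
        from mbam.reduction import LimitRule, Registry

        model, theta0, _ = mm_full
        sentinel = object()
        reg = Registry([LimitRule(
            "user rule",
            matches=lambda m, d: d.nonfinite == {"kc": "inf"},
            apply=lambda m, p, d: (sentinel, p),
        )])
        out, _ = apply_limit(
            model, theta0, _descriptor(model, {"kc": "inf"}), reg
        )
        assert out is sentinel


class TestCalibrate:
    def test_self_fit_is_exact(self, mm_full):
        model, theta0, qoi = mm_full
        y = residuals(model, theta0, qoi) * qoi.sigmas
        res = calibrate(model, y, qoi, theta0)
        assert res.cost <= 1e-12
        assert res.converged

    def test_cost_never_worse_than_guess(self, mm_full):
        model, theta0, qoi = mm_full
        y = residuals(model, theta0, qoi) * qoi.sigmas
        bad_guess = theta0.with_values(theta0.values + 0.5)
        res = calibrate(model, y, qoi, bad_guess)
        y0 = residuals(model, bad_guess, qoi) * qoi.sigmas
        cost_guess = float(np.sum(((y - y0) / qoi.sigmas) ** 2))
        assert res.cost <= cost_guess + 1e-12

    def test_equilibrium_fits_full_model_within_band(self, mm_full):
        """The boundary model reproduces the interior predictions: cost << M."""
        model, theta0, qoi = mm_full
        y = residuals(model, theta0, qoi) * qoi.sigmas
        reduced, phi = apply_limit(
            model, theta0, _descriptor(model, {"kf": "inf", "kr": "inf"})
        )
        res = calibrate(reduced, y, qoi, phi)
        assert res.cost <= qoi.m


class TestIdentifiability:
    def test_threshold_semantics(self):
        model, theta0, qoi = zoo("MM_FULL")
        ok, w = identifiability_check(model, theta0, qoi, lambda_star=1.0)
        assert not ok  # the enzyme model at theta0 warrants reduction
        assert w.shape == (3,)
        ok_loose, _ = identifiability_check(
            model, theta0, qoi, lambda_star=w[-1] / 2
        )
        assert ok_loose


class TestMBAMRun:
    def test_mm_chain_reaches_equilibrium_model(self, mm_chain_report):
        rep = mm_chain_report
        assert rep.steps, "at least one reduction step expected"
        first = rep.steps[0]
        assert first.descriptor.nonfinite == {"kf": "inf", "kr": "inf"}
        assert first.reduced_name == "MM_EQUILIBRIUM"
        assert rep.final_model.name == "MM_EQUILIBRIUM"
        assert rep.final_params.names == ("Kd", "kc")

    def test_promoted_chain_reproduces_qssa_sequence(self, promoted_chain_report):
        """kr -> 0 first, then {kf, kc -> inf, E0 -> 0}, ending at
        d[P]/dt = Vmax [S] / (KM + [S])."""
        rep = promoted_chain_report
        limits = [s.descriptor.nonfinite for s in rep.steps[:2]]
        assert limits[0] == {"kr": "zero"}
        assert limits[1] == {"kf": "inf", "kc": "inf", "E0": "zero"}
        assert rep.steps[1].reduced_name == "MM_QSSA"

    def test_every_step_cost_within_sigma_band(
        self, mm_chain_report, promoted_chain_report
    ):
        for rep in (mm_chain_report, promoted_chain_report):
            for step in rep.steps:
                assert step.calibration.cost <= 15.0  # M = 15 QoIs

    def test_parameter_count_strictly_decreases(
        self, mm_chain_report, promoted_chain_report
    ):
        for rep in (mm_chain_report, promoted_chain_report):
            counts = [len(rep.steps[0].spectrum_before.eigenvalues)]
            counts += [len(s.spectrum_after.eigenvalues) for s in rep.steps]
            assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_surviving_eigenvalues_stable_across_steps(self, promoted_chain_report):
        """After each step the surviving eigenvalues move by less than a
        decade."""
        for step in promoted_chain_report.steps:
            before = step.spectrum_before.eigenvalues
            after = step.spectrum_after.eigenvalues
            n_after = len(after)
            for wb, wa in zip(before[:n_after], after):
                assert abs(np.log10(wa / wb)) < 1.0

    def test_report_serializes(self, mm_chain_report):
        import json

        blob = json.dumps(mm_chain_report.to_dict())
        assert "MM_EQUILIBRIUM" in blob


class TestLimitConvergence:
    def test_equilibrium_error_decreases_with_rate_scale(self, mm_full):
        """Pushing kf, kr up at fixed Kd drives the full model onto the
        equilibrium face monotonically."""
        model, theta0, qoi = mm_full
        reduced, phi = apply_limit(
            model, theta0, _descriptor(model, {"kf": "inf", "kr": "inf"})
        )
        y_eq = residuals(reduced, phi, qoi) * qoi.sigmas
        errs = []
        for c in (10.0, 100.0, 1000.0):
            pushed = theta0.with_values(
                theta0.values + np.log(np.array([c, c, 1.0]))
            )
            y_full = residuals(model, pushed, qoi) * qoi.sigmas
            errs.append(np.abs(y_full - y_eq).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3


class TestReplayChains:
    """The bundled reduction sequences reproduce the reduced motif forms."""

    @pytest.mark.parametrize(
        "source,target,chain,combos",
        [
            (
                "NFB_12", "NFB_4", "NFB_12->NFB_4",
                {
                    frozenset({("kIA", 1)}),
                    frozenset({("kCB", 1), ("kBC", 1), ("KCB", -1), ("KBC", -1)}),
                    frozenset({("kFB", 1), ("KFB", -1)}),
                    frozenset({("kAC", 1)}),
                },
            ),
            (
                "IFFLP_12", "IFFLP_4", "IFFLP_12->IFFLP_4",
                {
                    frozenset({("kIA", 1)}),
                    frozenset({("kAB", 1)}),
                    frozenset({("kAC", 1)}),
                    frozenset({("kBC", 1), ("KBC", -1)}),
                },
            ),
        ],
    )
    def test_twelve_to_four(self, source, target, chain, combos, request):
        fixture = request.getfixturevalue(
            "nfb12_fixture" if source == "NFB_12" else "ifflp12_fixture"
        )
        model, params, qoi = fixture
        steps = replay_chain(model, params, qoi, chain)
        final, calib = steps[-1]
        sm = final.meta["structured"]
        target_sm = zoo(target)[0].meta["structured"]
        assert sm.same_structure(target_sm)
        got = {frozenset(sm.provenance[p].powers) for p in sm.params}
        assert got == combos
        assert all(c.cost <= qoi.m for _, c in steps)

    @pytest.mark.parametrize(
        "source,target",
        [("NFB_4", "NFB_2"), ("IFFLP_4", "IFFLP_2")],
    )
    def test_four_to_two(self, source, target, nfb12_fixture, ifflp12_fixture):
        fixture = nfb12_fixture if "NFB" in source else ifflp12_fixture
        model12, params12, qoi = fixture
        chain12 = f"{source.replace('_4', '_12')}->{source}"
        steps = replay_chain(model12, params12, qoi, chain12)
        model4, calib4 = steps[-1]
        steps2 = replay_chain(
            model4, calib4.phi, qoi, f"{source}->{target}"
        )
        final, _ = steps2[-1]
        sm = final.meta["structured"]
        assert sm.same_structure(zoo(target)[0].meta["structured"])
        assert len(sm.params) == 2


class TestParameterRecovery:
    def test_nfb4_recovers_from_noisy_self_data(self):
        """Fitting the 4-parameter feedback model to noisy data generated
        from itself recovers each log-parameter within three standard
        errors, across seeded replicates."""
        from mbam import FDOptions, fim, jacobian
        from mbam.models import InputProtocol

        model, _, _ = zoo("NFB_4")
        truth = ParameterVector.from_linear(
            {"kIA": 1.2, "kCB*kBC/(KCB*KBC)": 2.0, "kFB/KFB": 0.8, "kAC": 0.4}
        )
        qoi = QoISpec(
            "C", np.linspace(0.5, 20.0, 20), 0.02, InputProtocol("step", 0.5)
        )
        y_true = residuals(model, truth, qoi) * qoi.sigmas
        J = jacobian(model, truth, qoi, FDOptions(h=1e-3))
        cov = np.linalg.inv(fim(J, truth.names, qoi).matrix)
        se = np.sqrt(np.diag(cov))
        rng = np.random.default_rng(0)
        failures = 0
        for _ in range(20):
            y_noisy = y_true + qoi.sigmas * rng.standard_normal(qoi.m)
            fit = calibrate(model, y_noisy, qoi, truth, n_restarts=0)
            if np.any(np.abs(fit.phi.values - truth.values) > 3.0 * se):
                failures += 1
        assert failures == 0
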