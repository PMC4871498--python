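"""Geodesics on the model manifold and manifold-boundary detection.

The geodesic equation in log-parameter space,

    d^2 theta / d tau^2 = - g^{-1} J^T A(v),      A_m(v) = v^T (d^2 r_m) v,

is integrated from a starting point along the sloppiest eigendirection of
the Fisher Information Matrix.  A boundary of the model manifold announces
itself as a singularity: the smallest FIM eigenvalue collapses relative to
the next one while the parameter-space velocity diverges.  The final unit
velocity identifies the limiting approximation (which log-parameters run to
+inf or -inf).

The directional second derivative A_m(v) is estimated with the symmetric
second-difference stencil (r(theta + h v) + r(theta - h v) - 2 r(theta)) /
h^2, evaluated on the unit vector and rescaled by |v|^2 so the stencil
stays well conditioned as the velocity grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import RK45

from .infogeo import FDOptions, fim, jacobian, spectrum
from .models import IntegrationError, ODEModel, QoISpec, residuals
from .params import ParameterVector

__all__ = [
    "GeodesicOptions",
    "GeodesicPath",
    "LimitDescriptor",
    "second_directional_derivative",
    "integrate_geodesic",
    "classify_limit",
]

# Below this eigenvalue ratio the metric is treated as numerically singular.
_SINGULAR_RATIO = 1e-10


@dataclass(frozen=True)
class GeodesicOptions:
    """Settings for geodesic integration and boundary detection.

    ``normalization``: "fisher" scales the initial velocity to unit
    Fisher-metric speed so tau measures information distance; "parameter"
    scales to unit Euclidean norm in log-parameter space.
    ``direction``: "auto" integrates a short trial segment both ways and
    keeps the sign along which the parameter-space velocity norm grows;
    +1/-1 force the orientation of the sloppiest eigenvector.
    """

    normalization: str = "fisher"
    direction: str | int = "auto"
    eig_ratio: float = 1e-3  # collapse: lambda_min < eig_ratio * lambda_next
    vel_growth: float = 25.0  # boundary: |v| grows by this factor
    max_tau: float = 10.0
    rtol: float = 1e-8
    atol: float = 1e-10
    h_avv: float = 2e-2
    trial_tau: float = 0.02
    pinv_rcond: float = 1e-12
    component_threshold: float = 0.2
    max_steps: int = 3000
    fd: FDOptions = field(
        default_factory=lambda: FDOptions(h=1e-3, rtol=1e-9, atol=1e-11)
    )

    def __post_init__(self) -> None:
        if not (0 < self.eig_ratio < 1):
            raise ValueError("eig_ratio must lie in (0, 1)")
        if self.vel_growth <= 1 or self.max_tau <= 0 or self.h_avv <= 0:
            raise ValueError("boundary thresholds must be positive")
        if self.normalization not in ("fisher", "parameter"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class GeodesicPath:
    """A geodesic trace: tau grid, parameters, velocities, eigenvalue traces."""

    taus: np.ndarray
    thetas: np.ndarray  # (T, N)
    velocities: np.ndarray  # (T, N)
    lambda_min: np.ndarray
    lambda_next: np.ndarray
    termination: str  # boundary | max-tau | solver-failure | curvature-lost
    parameter_names: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)

    @property
    def final_theta(self) -> np.ndarray:
        return self.thetas[-1]

    @property
    def final_unit_velocity(self) -> np.ndarray:
        v = self.velocities[-1]
        return v / np.linalg.norm(v)

    def to_frame(self):
        import pandas as pd

        cols = {"tau": self.taus}
        for i, n in enumerate(self.parameter_names):
            cols[f"theta_{n}"] = self.thetas[:, i]
        for i, n in enumerate(self.parameter_names):
            cols[f"v_{n}"] = self.velocities[:, i]
        cols["lambda_min"] = self.lambda_min
        cols["lambda_next"] = self.lambda_next
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class LimitDescriptor:
    """Per-parameter verdicts read off the final unit geodesic velocity."""

    verdicts: dict[str, str]  # "inf" | "zero" | "finite"
    final_unit_velocity: np.ndarray
    parameter_names: tuple[str, ...]
    grouping: str = ""

    @property
    def to_infinity(self) -> tuple[str, ...]:
        return tuple(p for p, v in self.verdicts.items() if v == "inf")

    @property
    def to_zero(self) -> tuple[str, ...]:
        return tuple(p for p, v in self.verdicts.items() if v == "zero")

    @property
    def nonfinite(self) -> dict[str, str]:
        return {p: v for p, v in self.verdicts.items() if v != "finite"}

    def to_dict(self) -> dict:
        return {
            "verdicts": dict(self.verdicts),
            "final_unit_velocity": self.final_unit_velocity.tolist(),
            "parameter_names": list(self.parameter_names),
            "grouping": self.grouping,
        }


def second_directional_derivative(
    model: ODEModel,
    params: ParameterVector,
    direction: np.ndarray,
    qoi: QoISpec,
    h: float = 5e-2,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> np.ndarray:
    """Stencil estimate of A_m(v); exact for quadratic residual maps."""
    v = np.asarray(direction, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        return np.zeros(qoi.m)
    vh = v / nv

    def r(th):
        try:
            return residuals(model, params.with_values(th), qoi, rtol=rtol, atol=atol)
        except IntegrationError as err:
            raise IntegrationError(
                f"simulation failed in curvature stencil at theta={th}", err.partial
            ) from err

    th0 = params.values
    return nv**2 * (r(th0 + h * vh) + r(th0 - h * vh) - 2.0 * r(th0)) / h**2


def _geodesic_rhs(model, params, qoi, opts, cache):
    """Geodesic acceleration; one stacked residual batch per evaluation."""
    from .infogeo import residuals_batch

    n = len(params)
    h = opts.fd.h
    eye = np.eye(n) * h

    def cached_jacobian(th):
        key = th.tobytes()
        if key not in cache:
            if len(cache) > 512:
                cache.clear()
            cache[key] = jacobian(model, params.with_values(th), qoi, opts.fd)
        return cache[key]

    def rhs(tau, y):
        th, v = y[:n], y[n:]
        nv = np.linalg.norm(v)
        vh = v / nv if nv > 0 else v
        ha = opts.h_avv
        pts = (
            [th + eye[mu] for mu in range(n)]
            + [th - eye[mu] for mu in range(n)]
            + [th + ha * vh, th - ha * vh, th]
        )
        R = residuals_batch(
            model, pts, qoi, rtol=opts.fd.rtol, atol=opts.fd.atol
        )
        J = (R[:n] - R[n : 2 * n]).T / (2 * h)
        key = th.tobytes()
        if len(cache) > 512:
            cache.clear()
        cache[key] = J
        A = nv**2 * (R[2 * n] + R[2 * n + 1] - 2 * R[2 * n + 2]) / ha**2
        g = J.T @ J
        a = -np.linalg.pinv(g, rcond=opts.pinv_rcond, hermitian=True) @ (J.T @ A)
        return np.concatenate([v, a])

    return rhs, cached_jacobian


def _trial_growth(rhs, theta0, v0, trial_tau, max_steps=60):
    """Euclidean velocity norm after a short trial segment.

    The step budget keeps the trial cheap even when the trial segment runs
    into a boundary singularity (where the velocity diverges -- which is
    itself growth, so the truncated norm still ranks the two signs).
    """
    solver = RK45(
        rhs, 0.0, np.concatenate([theta0, v0]), trial_tau, rtol=1e-6, atol=1e-8
    )
    n = theta0.size
    try:
        for _ in range(max_steps):
            if solver.status != "running":
                break
            solver.step()
            if np.linalg.norm(solver.y[n:]) > 25.0 * np.linalg.norm(v0):
                break
    except Exception:
        return -np.inf
    return float(np.linalg.norm(solver.y[n:]))


def integrate_geodesic(
    model: ODEModel,
    start: ParameterVector,
    qoi: QoISpec,
    opts: GeodesicOptions = GeodesicOptions(),
) -> GeodesicPath:
    """Follow the sloppiest direction from ``start`` to a manifold boundary.

    Terminates when the smallest FIM eigenvalue collapses below
    ``eig_ratio`` times the next eigenvalue, when the parameter-space
    velocity norm grows by ``vel_growth`` over its initial value, or at
    ``max_tau``.  Raises ValueError if the FIM at the start is numerically
    singular (the QoI grid then carries no information about the sloppiest
    combination and the initial direction is undefined).
    """
    n = len(start)
    J0 = jacobian(model, start, qoi, opts.fd)
    g0 = fim(J0, start.names, qoi)
    spec0 = spectrum(g0)
    lam = spec0.eigenvalues
    if lam[0] <= 0 or (
        opts.normalization == "fisher" and lam[-1] / lam[0] < _SINGULAR_RATIO
    ):
        raise ValueError(
            "FIM at the starting point is numerically singular "
            f"(eigenvalues {lam}); unit Fisher speed is undefined there -- "
            "use a more informative QoI grid or parameter-unit normalization"
        )
    v0 = spec0.sloppiest.copy()
    if opts.normalization == "fisher":
        v0 = v0 / np.sqrt(v0 @ g0.matrix @ v0)
    cache: dict = {}
    rhs, cached_jacobian = _geodesic_rhs(model, start, qoi, opts, cache)

    if opts.direction in ("+", +1):
        sign = +1.0
    elif opts.direction in ("-", -1):
        sign = -1.0
    else:
        g_plus = _trial_growth(rhs, start.values, v0, opts.trial_tau)
        g_minus = _trial_growth(rhs, start.values, -v0, opts.trial_tau)
        sign = +1.0 if g_plus >= g_minus else -1.0
    v0 = sign * v0
    nv0 = np.linalg.norm(v0)

    taus = [0.0]
    thetas = [start.values.copy()]
    vels = [v0.copy()]
    lmins = [lam[-1]]
    lnexts = [lam[-2]]
    termination = "max-tau"
    diag: dict = {"sign": sign, "normalization": opts.normalization}
    ratio0 = lam[-1] / lam[-2]
    # Absolute collapse threshold when the spectrum starts healthy; when the
    # start is already degenerate, a boundary is declared on a *further*
    # collapse by the same factor.
    ratio_armed = ratio0 > opts.eig_ratio
    collapse_at = opts.eig_ratio * (1.0 if ratio_armed else ratio0)
    min_ratio = ratio0
    regrow_count = 0

    solver = RK45(
        rhs,
        0.0,
        np.concatenate([start.values, v0]),
        opts.max_tau,
        rtol=opts.rtol,
        atol=opts.atol,
    )
    max_steps = opts.max_steps
    n_steps = 0
    while solver.status == "running":
        n_steps += 1
        if n_steps > max_steps:
            termination = "solver-failure"
            diag["error"] = f"step budget ({max_steps}) exhausted"
            break
        try:
            solver.step()
        except (IntegrationError, ValueError, FloatingPointError) as err:
            termination = "solver-failure"
            diag["error"] = str(err)
            break
        th, v = solver.y[:n], solver.y[n:]
        try:
            Jc = cached_jacobian(th)
        except IntegrationError as err:
            termination = "solver-failure"
            diag["error"] = f"spectrum monitoring failed: {err}"
            break
        w = np.linalg.eigvalsh(Jc.T @ Jc)
        taus.append(solver.t)
        thetas.append(th.copy())
        vels.append(v.copy())
        lmins.append(w[0])
        lnexts.append(w[1])
        ratio = w[0] / w[1]
        if ratio > opts.eig_ratio and not ratio_armed:
            ratio_armed = True
            collapse_at = opts.eig_ratio
        if ratio < min_ratio:
            min_ratio = ratio
            regrow_count = 0
        # "gravitational slingshot" guard: sustained re-growth of the
        # smallest eigenvalue after a deep minimum means the geodesic bent
        # away from the boundary.  Only meaningful if the spectrum was ever
        # healthy (otherwise the tiny starting ratio wobbles harmlessly).
        elif ratio_armed and min_ratio < 1e-2 and ratio > 50.0 * min_ratio:
            regrow_count += 1
            if regrow_count >= 10:
                termination = "curvature-lost"
                diag["hint"] = (
                    "restart from a nearby point or along another direction "
                    "in the sloppiest subspace"
                )
                break
        if ratio < collapse_at:
            termination = "boundary"
            diag["reason"] = "eigenvalue-collapse"
            break
        if np.linalg.norm(v) > opts.vel_growth * nv0:
            termination = "boundary"
            diag["reason"] = "velocity-growth"
            break
    else:
        termination = "max-tau"

    path = GeodesicPath(
        np.array(taus),
        np.array(thetas),
        np.array(vels),
        np.array(lmins),
        np.array(lnexts),
        termination,
        start.names,
        diag,
    )
    return path


def classify_limit(
    path: GeodesicPath, component_threshold: float = 0.2
) -> LimitDescriptor:
    """Read the limiting approximation off the final unit velocity.

    Components above the threshold in magnitude are classified as running
    to +inf (positive) or to 0 (negative, in log space); the rest stay
    finite.
    """
    if path.termination not in ("boundary", "max-tau"):
        raise ValueError(
            f"cannot classify a path terminated by {path.termination!r}"
        )
    vhat = path.final_unit_velocity
    verdicts = {}
    for p, c in zip(path.parameter_names, vhat):
        if c >= component_threshold:
            verdicts[p] = "inf"
        elif c <= -component_threshold:
            verdicts[p] = "zero"
        else:
            verdicts[p] = "finite"
    moving = [p for p, v in verdicts.items() if v != "finite"]
    grouping = (
        "parameters moving together: " + ", ".join(moving) if moving else "none"
    )
    return LimitDescriptor(verdicts, vhat, path.parameter_names, grouping)
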