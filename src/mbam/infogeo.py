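"""Residual Jacobians, the Fisher Information Matrix, and its spectrum.

The FIM g = J^T J of the scaled residual vector r_m = y_m(theta)/sigma_m,
with derivatives taken in log-parameter space, is the Riemannian metric on
the model manifold.  Its eigen-decomposition orders the stiff-to-sloppy
parameter combinations; the eigenvector of the smallest eigenvalue seeds
the geodesic search for the nearest manifold boundary.

Jacobians default to central finite differences with a single absolute step
in log-parameter units (the log transform makes one step size meaningful
across parameters).  A forward-sensitivity-ODE mode, which augments the
state with d(state)/d(theta) and integrates jointly, serves as an
independent cross-check for smooth models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    IntegrationError,
    ODEModel,
    QoISpec,
    residuals,
    simulate_stacked,
)
from .params import ParameterVector

__all__ = [
    "FDOptions",
    "FIM",
    "Spectrum",
    "jacobian",
    "fim",
    "spectrum",
    "residuals_batch",
]


def residuals_batch(
    model: ODEModel,
    thetas: list[np.ndarray],
    qoi: QoISpec,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> np.ndarray:
    """Residual vectors r = y/sigma for several log-parameter points, (B, M).

    Smooth models are integrated as one stacked ODE system (one integrator
    call for the whole batch); gated models fall back to per-point runs.
    """
    names = model.parameter_names
    if model.caps:
        # If the gated states stay safely below their caps at the first
        # (reference) point, the Heaviside gates are inert across the whole
        # batch of nearby points and the copies can be stacked smoothly.
        pv0 = ParameterVector(names, np.asarray(thetas[0], dtype=float))
        base = residuals  # keep the slow path importable below
        traj0 = None
        from .models import simulate as _simulate

        try:
            traj0 = _simulate(
                model, pv0, qoi.times, qoi.protocol, rtol=rtol, atol=atol
            )
        except IntegrationError:
            traj0 = None
        safe = traj0 is not None and all(
            traj0[s].max() <= cap * 0.97 for s, cap in model.caps.items()
        )
        if not safe:
            rows = []
            for th in thetas:
                pv = ParameterVector(names, np.asarray(th, dtype=float))
                rows.append(base(model, pv, qoi, rtol=rtol, atol=atol))
            return np.array(rows)
    k_list = [dict(zip(names, np.exp(np.asarray(th, dtype=float)))) for th in thetas]
    states = simulate_stacked(
        model, k_list, qoi.times, qoi.protocol, rtol=rtol, atol=atol,
        ignore_caps=bool(model.caps),
    )
    obs = model.observables[qoi.observable]
    out = np.empty((len(thetas), qoi.m))
    for b, k in enumerate(k_list):
        out[b] = np.asarray(obs(states[b], k), dtype=float) / qoi.sigmas
    return out


@dataclass(frozen=True)
class FDOptions:
    """Finite-difference settings for residual Jacobians."""

    h: float = 1e-4  # log-parameter units
    scheme: str = "central"
    mode: str = "fd"  # "fd" or "sensitivity"
    rtol: float = 1e-9
    atol: float = 1e-11

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("finite-difference step h must be positive")
        if self.scheme not in ("central", "forward"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.mode not in ("fd", "sensitivity"):
            raise ValueError(f"unknown sensitivity mode {self.mode!r}")


@dataclass(frozen=True)
class FIM:
    matrix: np.ndarray
    parameter_names: tuple[str, ...]
    qoi: QoISpec | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError("FIM entries must be finite")
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("FIM must be square")
        scale = np.abs(g).max() or 1.0
        if np.abs(g - g.T).max() > 1e-12 * scale:
            raise ValueError("FIM must be symmetric")
        object.__setattr__(self, "matrix", g)


@dataclass(frozen=True)
class Spectrum:
    """Descending eigenvalues with sign-conventioned orthonormal eigenvectors.

    Each eigenvector (column) is oriented so that its largest-magnitude
    component is positive, ties broken by lowest parameter index; this makes
    repeated calls (and degenerate spectra) deterministic.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns aligned to eigenvalues
    parameter_names: tuple[str, ...]
    sign_convention: str = "largest-component-positive"

    @property
    def sloppiest(self) -> np.ndarray:
        return self.eigenvectors[:, -1]

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "parameter_names": list(self.parameter_names),
        }


def jacobian(
    model: ODEModel,
    params: ParameterVector,
    qoi: QoISpec,
    opts: FDOptions = FDOptions(),
) -> np.ndarray:
    """M x N matrix of d r_m / d theta_mu in log-parameter space."""
    if opts.mode == "sensitivity":
        return _jacobian_sensitivity(model, params, qoi, opts)
    theta = params.values
    n = len(theta)
    eye = np.eye(n) * opts.h
    if opts.scheme == "central":
        points = [theta + eye[mu] for mu in range(n)]
        points += [theta - eye[mu] for mu in range(n)]
    else:
        points = [theta + eye[mu] for mu in range(n)] + [theta]
    try:
        R = residuals_batch(model, points, qoi, rtol=opts.rtol, atol=opts.atol)
    except IntegrationError:
        # rerun point by point to name the offending perturbation
        R = np.empty((len(points), qoi.m))
        for i, th in enumerate(points):
            mu = i % n
            try:
                R[i] = residuals(
                    model, params.with_values(th), qoi,
                    rtol=opts.rtol, atol=opts.atol,
                )
            except IntegrationError as err:
                sign = "+" if i < n or opts.scheme == "forward" else "-"
                raise IntegrationError(
                    f"simulation failed while perturbing "
                    f"{params.names[mu]!r} ({sign}{opts.h:g}): {err}",
                    err.partial,
                ) from err
    if opts.scheme == "central":
        return (R[:n] - R[n:]).T / (2 * opts.h)
    return (R[:n] - R[n]).T / opts.h


def _num_grad(f, x, scale=1e-6):
    """Central-difference gradient of vector function f at x (per column)."""
    n = x.size
    out = []
    for i in range(n):
        h = scale * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        out.append((np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * h))
    return np.column_stack(out)


def _jacobian_sensitivity(
    model: ODEModel,
    params: ParameterVector,
    qoi: QoISpec,
    opts: FDOptions,
) -> np.ndarray:
    """Forward-sensitivity Jacobian: integrate dS/dt = f_x S + f_theta."""
    if model.caps:
        raise ValueError(
            "forward sensitivities are defined for smooth models only "
            f"(model {model.name!r} has Heaviside-gated states)"
        )
    k_names = model.parameter_names
    theta0 = params.values
    n_p = len(theta0)
    k0 = dict(zip(k_names, np.exp(theta0)))
    n_s = model.n_states
    gates = np.ones(n_s)
    u_of = qoi.protocol

    def f(t, x, theta):
        k = dict(zip(k_names, np.exp(theta)))
        return np.asarray(model.rhs(t, x, k, u_of(t), gates), dtype=float)

    def aug_rhs(t, z):
        x = z[:n_s]
        S = z[n_s:].reshape(n_s, n_p)
        fx = _num_grad(lambda xv: f(t, xv, theta0), x)
        fth = _num_grad(lambda th: f(t, x, th), theta0)
        dS = fx @ S + fth
        return np.concatenate([f(t, x, theta0), dS.ravel()])

    x0 = np.asarray(model.initial_state(k0), dtype=float)
    S0 = _num_grad(
        lambda th: np.asarray(
            model.initial_state(dict(zip(k_names, np.exp(th)))), dtype=float
        ),
        theta0,
    )
    z0 = np.concatenate([x0, S0.ravel()])
    sol = solve_ivp(
        aug_rhs, (0.0, float(qoi.times[-1])), z0,
        t_eval=qoi.times, method="LSODA", rtol=opts.rtol, atol=opts.atol,
    )
    if not sol.success:
        raise IntegrationError(f"sensitivity integration failed: {sol.message}")
    obs = model.observables[qoi.observable]
    J = np.empty((qoi.m, n_p))
    for m, (t, z) in enumerate(zip(sol.t, sol.y.T)):
        x = z[:n_s]
        S = z[n_s:].reshape(n_s, n_p)
        gx = _num_grad(lambda xv: np.atleast_1d(obs(xv[None, :], k0)), x)[0]
        gth = _num_grad(
            lambda th: np.atleast_1d(
                obs(x[None, :], dict(zip(k_names, np.exp(th))))
            ),
            theta0,
        )[0]
        J[m] = (gx @ S + gth) / qoi.sigmas[m]
    return J


def fim(J: np.ndarray, parameter_names=None, qoi: QoISpec | None = None) -> FIM:
    """Gram matrix g = J^T J, symmetrized to kill round-off."""
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    g = J.T @ J
    g = 0.5 * (g + g.T)
    names = tuple(parameter_names) if parameter_names else tuple(
        f"p{i}" for i in range(g.shape[0])
    )
    return FIM(g, names, qoi)


def spectrum(g: FIM | np.ndarray, parameter_names=None) -> Spectrum:
    """Descending eigen-decomposition with a deterministic sign convention."""
    if isinstance(g, FIM):
        mat, names = g.matrix, g.parameter_names
    else:
        mat = np.asarray(g, dtype=float)
        names = tuple(parameter_names) if parameter_names else tuple(
            f"p{i}" for i in range(mat.shape[0])
        )
        mat = 0.5 * (mat + mat.T)
    w, V = np.linalg.eigh(mat)
    w, V = w[::-1].copy(), V[:, ::-1].copy()
    for j in range(V.shape[1]):
        i_star = int(np.argmax(np.abs(V[:, j])))  # first max = lowest index
        if V[i_star, j] < 0:
            V[:, j] = -V[:, j]
    return Spectrum(w, V, names)
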