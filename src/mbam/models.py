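"""ODE model container, step-input protocols and trajectory simulation.

Models are systems of biochemical-kinetics ODEs with log-transformed
positive parameters.  Production terms of the form ``rate * Theta(cap - x)``
(a Heaviside gate with the convention ``Theta(0) = 0``) are integrated with
event-detection clamping: when a gated state reaches its cap while its net
production is positive, the state slides along the cap (derivative pinned to
zero) until the ungated right-hand side turns negative again.  This is the
Filippov solution of the discontinuous system and avoids discontinuity
chatter in stiff solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParameterVector

__all__ = [
    "InputProtocol",
    "ODEModel",
    "QoISpec",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "residuals",
]

_MAX_SEGMENTS = 400


@dataclass(frozen=True)
class InputProtocol:
    """A constant or step stimulus u(t).

    For ``kind="step"`` the input is 0 for t <= onset and ``magnitude`` for
    t > onset (Heaviside convention Theta(0) = 0).
    """

    kind: str = "step"
    magnitude: float = 1.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("input magnitude must be nonnegative")

    def __call__(self, t: float) -> float:
        if self.kind == "constant":
            return self.magnitude
        return self.magnitude if t > self.onset else 0.0


NO_INPUT = InputProtocol("constant", 0.0)


@dataclass
class ODEModel:
    """A log-parameterized kinetic model.

    Attributes
    ----------
    rhs
        ``rhs(t, x, k, u, gates) -> dx/dt`` with ``k`` a dict of natural
        (linear-scale) parameter values, ``u`` the scalar input and
        ``gates`` an array (one entry per state, default 1.0) by which any
        Heaviside-gated production term for state i must be multiplied.
    initial_state
        ``initial_state(k) -> x0``.
    observables
        Named functions ``f(states, k) -> array`` mapping a (T, n_state)
        state matrix to a prediction per time point.
    conservation
        Named linear combinations expected constant along trajectories.
    caps
        Per-state saturation bound for Heaviside-gated states.
    """

    name: str
    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    rhs: Callable[..., np.ndarray]
    initial_state: Callable[[dict], np.ndarray]
    observables: dict[str, Callable] = field(default_factory=dict)
    conservation: dict[str, Callable] = field(default_factory=dict)
    caps: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def check_params(self, params: ParameterVector) -> dict[str, float]:
        if tuple(params.names) != tuple(self.parameter_names):
            raise ValueError(
                f"parameter names {params.names} do not match model "
                f"{self.name!r} parameters {self.parameter_names}"
            )
        return params.as_dict(linear=True)


@dataclass(frozen=True)
class QoISpec:
    """Quantities of interest: an observable at a set of times with tolerances.

    Each (observable, time) pair behaves like a pseudo data point y_m with
    tolerance sigma_m; the residual vector is r_m = y_m(theta) / sigma_m.
    """

    observable: str
    times: np.ndarray
    sigmas: np.ndarray
    protocol: InputProtocol = NO_INPUT

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        sig = np.asarray(self.sigmas, dtype=float)
        if sig.ndim == 0:
            sig = np.full(times.shape, float(sig))
        if np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("QoI times must be positive and strictly increasing")
        if sig.shape != times.shape or np.any(sig <= 0):
            raise ValueError("QoI tolerances must be positive, one per time")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sigmas", sig)

    @property
    def m(self) -> int:
        return self.times.size

    def with_sigmas(self, sigmas) -> "QoISpec":
        return QoISpec(self.observable, self.times, sigmas, self.protocol)


@dataclass
class Trajectory:
    """Simulated states at requested times plus solver diagnostics."""

    times: np.ndarray
    states: np.ndarray  # (T, n_states)
    state_names: tuple[str, ...]
    inputs: np.ndarray
    diagnostics: dict

    def __getitem__(self, state: str) -> np.ndarray:
        return self.states[:, self.state_names.index(state)]

    @property
    def success(self) -> bool:
        return bool(self.diagnostics.get("success", False))

    def to_csv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.states, columns=list(self.state_names))
        frame.insert(0, "time", self.times)
        frame["input"] = self.inputs
        frame.to_csv(path, index=False)


class IntegrationError(RuntimeError):
    """Stiff blow-up or solver failure; carries the partial trajectory."""

    def __init__(self, message: str, partial: Trajectory | None = None):
        super().__init__(message)
        self.partial = partial


def _segment_breaks(t0: float, t1: float, protocol: InputProtocol) -> list[float]:
    breaks = [t0, t1]
    if protocol.kind == "step" and t0 < protocol.onset < t1:
        breaks.insert(1, protocol.onset)
    return breaks


def simulate(
    model: ODEModel,
    params: ParameterVector,
    times,
    protocol: InputProtocol | None = None,
    *,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate ``model`` from t = 0 and report states at ``times``.

    ``times`` must be nonempty and strictly increasing with times[0] >= 0.
    Raises :class:`IntegrationError` (carrying the partial trajectory) if the
    inner solver fails.
    """
    k = model.check_params(params)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be nonempty, nonnegative, increasing")
    protocol = protocol or NO_INPUT

    x0 = np.asarray(model.initial_state(k), dtype=float)
    if not np.all(np.isfinite(model.rhs(0.0, x0, k, protocol(0.0), np.ones(x0.size)))):
        raise IntegrationError(f"RHS of {model.name!r} not finite at the initial state")

    n = x0.size
    cap_idx = np.array(
        [model.state_index(s) for s in model.caps], dtype=int
    )
    cap_val = np.array([model.caps[s] for s in model.caps], dtype=float)
    pinned = np.zeros(len(cap_idx), dtype=bool)

    out_t: list[float] = []
    out_x: list[np.ndarray] = []
    nfev = 0

    if times[0] == 0.0:
        out_t.append(0.0)
        out_x.append(x0.copy())
        remaining = times[1:]
    else:
        remaining = times
    t_end = float(times[-1]) if times[-1] > 0 else 0.0

    def gated_rhs(t, x, u, force_on=None):
        # Free gated states keep their production on: the hit events stop
        # the integration exactly at the cap, so between events the RHS
        # stays smooth (implicit solvers need this).  Pinned states slide
        # along the cap with zero derivative until released.
        gates = np.ones(n)
        for j, i in enumerate(cap_idx):
            if pinned[j] and j != force_on:
                gates[i] = 0.0
        dx = np.asarray(model.rhs(t, x, k, u, gates), dtype=float)
        for j, i in enumerate(cap_idx):
            if pinned[j] and j != force_on:
                dx[i] = 0.0
        return dx

    def finish(success: bool, message: str) -> Trajectory:
        t_arr = np.array(out_t)
        x_arr = np.array(out_x) if out_x else np.empty((0, n))
        diag = {
            "success": success,
            "message": message,
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "nfev": nfev,
        }
        return Trajectory(
            t_arr, x_arr, model.state_names, np.array([protocol(t) for t in t_arr]), diag
        )

    x = x0.copy()
    for a, b in zip(*(lambda s: (s[:-1], s[1:]))(_segment_breaks(0.0, t_end, protocol))):
        u = protocol(0.5 * (a + b))
        t_cur = a
        guard = 0
        while t_cur < b:
            guard += 1
            if guard > _MAX_SEGMENTS:
                raise IntegrationError(
                    f"event clamping did not settle within {_MAX_SEGMENTS} restarts",
                    finish(False, "chatter"),
                )
            events = []
            event_kind: list[tuple[str, int]] = []
            for j, i in enumerate(cap_idx):
                if pinned[j]:
                    def release(t, x, j=j, i=i):
                        return gated_rhs(t, x, u, force_on=j)[i]

                    release.terminal = True
                    release.direction = -1.0
                    events.append(release)
                    event_kind.append(("release", j))
                else:
                    def hit(t, x, j=j, i=i):
                        return x[i] - cap_val[j]

                    hit.terminal = True
                    hit.direction = 1.0
                    events.append(hit)
                    event_kind.append(("hit", j))

            t_eval = remaining[(remaining > t_cur) & (remaining <= b)]
            sol = solve_ivp(
                lambda t, x: gated_rhs(t, x, u),
                (t_cur, b),
                x,
                method=method,
                t_eval=t_eval if t_eval.size else None,
                events=events or None,
                rtol=rtol,
                atol=atol,
                dense_output=True,
            )
            nfev += sol.nfev
            if not sol.success:
                if t_eval.size and len(sol.t):
                    for tt, xx in zip(sol.t, np.asarray(sol.y).T):
                        out_t.append(tt)
                        out_x.append(xx)
                raise IntegrationError(
                    f"solver {method} failed for {model.name!r}: {sol.message}",
                    finish(False, sol.message),
                )
            stop_t = b
            triggered = None
            if sol.status == 1:  # event hit
                for idx_ev, te in enumerate(sol.t_events):
                    if te.size:
                        if triggered is None or te[0] < stop_t:
                            stop_t = te[0]
                            triggered = idx_ev
            # record requested outputs inside this stretch
            if t_eval.size and len(sol.t):
                for tt, xx in zip(sol.t, np.asarray(sol.y).T):
                    if tt <= stop_t + 1e-14:
                        out_t.append(tt)
                        out_x.append(xx)
            if triggered is None:
                x = np.asarray(sol.sol(b), dtype=float)
                t_cur = b
                continue
            kind, j = event_kind[triggered]
            x = np.asarray(sol.sol(stop_t), dtype=float)
            i = cap_idx[j]
            # re-entering the free region exactly on the cap would leave the
            # solver on the gate discontinuity; restart a hair inside it
            inside = cap_val[j] * (1.0 - 1e-12) - 1e-13
            if kind == "hit":
                f_on = gated_rhs(stop_t, x, u, force_on=j)[i]
                if f_on > 0:
                    pinned[j] = True
                    x[i] = cap_val[j]
                else:
                    x[i] = inside
            else:  # release: net production just turned negative
                pinned[j] = False
                x[i] = inside
            t_cur = stop_t

    traj = finish(True, "ok")
    if traj.states.size and not np.all(np.isfinite(traj.states)):
        raise IntegrationError(f"non-finite states in {model.name!r}", traj)
    return traj


def simulate_stacked(
    model: ODEModel,
    k_list: list[dict],
    times,
    protocol: InputProtocol | None = None,
    *,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: float = 1e-11,
    ignore_caps: bool = False,
) -> np.ndarray:
    """Integrate several parameter copies of a smooth model jointly.

    Returns an array of shape (B, T, n_states).  Requires a model without
    Heaviside-gated states whose RHS is elementwise in the state and
    parameter values (true for all bundled smooth models); the copies are
    stacked into one ODE system so the integrator overhead is paid once.
    ``ignore_caps`` permits stacking a gated model whose gated states are
    known (by the caller) to stay strictly below their caps, where the
    gates are inert.
    """
    if model.caps and not ignore_caps:
        raise ValueError("stacked integration requires a model without caps")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    protocol = protocol or NO_INPUT
    B = len(k_list)
    kvec = {
        p: np.array([k[p] for k in k_list]) for p in model.parameter_names
    }
    x0 = np.stack([np.asarray(model.initial_state(k), dtype=float) for k in k_list])
    S = x0.shape[1]
    gates = np.ones(S)

    def rhs(t, z):
        X = z.reshape(B, S)
        dX = model.rhs(t, X.T, kvec, protocol(t), gates)
        return np.asarray(dX).T.reshape(-1)

    t0 = 0.0
    out = np.empty((B, times.size, S))
    start = 0
    if times[0] == t0:
        out[:, 0, :] = x0
        start = 1
    if start < times.size:
        sol = solve_ivp(
            rhs,
            (t0, float(times[-1])),
            x0.reshape(-1),
            method=method,
            t_eval=times[start:],
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"stacked integration failed for {model.name!r}: {sol.message}"
            )
        out[:, start:, :] = sol.y.reshape(B, S, -1).transpose(0, 2, 1)
    return out


def residuals(
    model: ODEModel,
    params: ParameterVector,
    qoi: QoISpec,
    *,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> np.ndarray:
    """QoI residual vector r_m = y_m(theta) / sigma_m in fixed QoI order."""
    if qoi.observable not in model.observables:
        raise ValueError(
            f"model {model.name!r} has no observable {qoi.observable!r}; "
            f"available: {list(model.observables)}"
        )
    k = params.as_dict(linear=True)
    traj = simulate(
        model, params, qoi.times, qoi.protocol, method=method, rtol=rtol, atol=atol
    )
    y = np.asarray(model.observables[qoi.observable](traj.states, k), dtype=float)
    return y / qoi.sigmas
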