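"""Bundled model zoo: enzyme kinetics and minimal adaptation motifs.

Every entry returns a fully wired :class:`~mbam.models.ODEModel`, a
reference log-parameter vector where one exists, and a default QoI
specification.  The enzyme family covers the mass-action reaction
E + S <-> C -> E + P and its classical limits (rapid equilibrium,
irreversible binding, quasi-steady state); the adaptation family covers the
twelve-parameter negative-feedback and incoherent-feed-forward motifs, their
four- and two-parameter reductions, and the two-parameter ERK/P90 system.
"""

from __future__ import annotations

import math

import numpy as np

from .models import (
    NO_INPUT,
    InputProtocol,
    IntegrationError,
    ODEModel,
    ParameterVector,
    QoISpec,
    simulate,
)
from .terms import Mono, StructuredModel, Term

__all__ = [
    "zoo",
    "zoo_names",
    "adaptation_qoi",
    "sample_adaptive_params",
    "SamplingError",
]

# External inhibition levels and stimulus magnitude used by the bundled
# adaptation motifs (held fixed, not fitted).
F_A = 0.5
F_B = 0.5
ADAPT_INPUT = InputProtocol("step", 0.5)

# Fixed initial concentrations for the 3-parameter enzyme demonstration.
E0_FIXED = 0.25
S0_FIXED = 1.0


# ---------------------------------------------------------------------------
# Enzyme-kinetics family (hand-written right-hand sides)
# ---------------------------------------------------------------------------

def _mm_full(promoted: bool) -> ODEModel:
    pnames = ("kf", "kr", "kc") + (("E0", "S0") if promoted else ())

    def rhs(t, x, k, u, gates):
        E, S, C, P = x
        bind = k["kf"] * E * S - k["kr"] * C
        cat = k["kc"] * C
        return np.array([-bind + cat, -bind, bind - cat, cat])

    def ic(k):
        e0 = k["E0"] if promoted else E0_FIXED
        s0 = k["S0"] if promoted else S0_FIXED
        return np.array([e0, s0, 0.0, 0.0])

    def p_frac(states, k):
        s0 = k["S0"] if promoted else S0_FIXED
        return states[:, 3] / s0

    # With S0 promoted to a parameter the fractional observable [P]/S0 has
    # an exact scale invariance (E0, S0 -> c E0, c S0; kf -> kf/c), so the
    # promoted chain observes the absolute product concentration instead.
    observables = {
        "P_frac": p_frac,
        "P_abs": lambda states, k: states[:, 3],
    }
    conservation = {
        "enzyme_total": lambda states, k: states[:, 0] + states[:, 2],
        "substrate_total": lambda states, k: states[:, 1] + states[:, 2] + states[:, 3],
    }
    return ODEModel(
        name="MM_FULL_P" if promoted else "MM_FULL",
        state_names=("E", "S", "C", "P"),
        parameter_names=pnames,
        rhs=rhs,
        initial_state=ic,
        observables=observables,
        conservation=conservation,
    )


def _mm_irreversible(promoted: bool) -> ODEModel:
    pnames = ("kf", "kc") + (("E0", "S0") if promoted else ())

    def rhs(t, x, k, u, gates):
        E, S, C, P = x
        bind = k["kf"] * E * S
        cat = k["kc"] * C
        return np.array([-bind + cat, -bind, bind - cat, cat])

    def ic(k):
        e0 = k["E0"] if promoted else E0_FIXED
        s0 = k["S0"] if promoted else S0_FIXED
        return np.array([e0, s0, 0.0, 0.0])

    def p_frac(states, k):
        s0 = k["S0"] if promoted else S0_FIXED
        return states[:, 3] / s0

    return ODEModel(
        name="MM_IRREVERSIBLE_P" if promoted else "MM_IRREVERSIBLE",
        state_names=("E", "S", "C", "P"),
        parameter_names=pnames,
        rhs=rhs,
        initial_state=ic,
        observables={"P_frac": p_frac, "P_abs": lambda states, k: states[:, 3]},
        conservation={
            "enzyme_total": lambda states, k: states[:, 0] + states[:, 2],
        },
    )


def _mm_equilibrium() -> ODEModel:
    """Rapid-equilibrium (Michaelis-Menten) limit: parameters (Kd, kc).

    The intermediate complex is slaved to C = [E][S]/Kd; after eliminating
    it the free substrate, free enzyme and product evolve as a closed system.
    The initial condition places the bound fraction on the equilibrium
    manifold: s0 solves s^2 + (Kd + E0 - S0) s - Kd S0 = 0.
    """

    def ic(k):
        kd = k["Kd"]
        b = kd + E0_FIXED - S0_FIXED
        s = 0.5 * (-b + math.sqrt(b * b + 4.0 * kd * S0_FIXED))
        c = E0_FIXED * s / (kd + s)
        return np.array([s, E0_FIXED - c, 0.0])

    def rhs(t, x, k, u, gates):
        S, E, P = x
        kd = k["Kd"]
        flux = k["kc"] * E0_FIXED * S / (kd + S)
        dS = -flux / (1.0 + E / (kd + S))
        dE = flux * E / (kd + S + E)
        return np.array([dS, dE, flux])

    return ODEModel(
        name="MM_EQUILIBRIUM",
        state_names=("S", "E", "P"),
        parameter_names=("Kd", "kc"),
        rhs=rhs,
        initial_state=ic,
        observables={"P_frac": lambda states, k: states[:, 2] / S0_FIXED, "P_abs": lambda states, k: states[:, 2]},
    )


def _mm_qssa() -> ODEModel:
    """Quasi-steady-state limit: d[P]/dt = Vmax [S] / (KM + [S])."""

    def rhs(t, x, k, u, gates):
        S, P = x
        flux = k["Vmax"] * S / (k["KM"] + S)
        return np.array([-flux, flux])

    return ODEModel(
        name="MM_QSSA",
        state_names=("S", "P"),
        parameter_names=("Vmax", "KM", "S0"),
        rhs=rhs,
        initial_state=lambda k: np.array([k["S0"], 0.0]),
        observables={"P_frac": lambda states, k: states[:, 1] / k["S0"], "P_abs": lambda states, k: states[:, 1]},
    )


# ---------------------------------------------------------------------------
# Adaptation family (structured term language)
# ---------------------------------------------------------------------------

def _motif_12(name: str, b_driver: str, b_rate: str, b_K: str) -> StructuredModel:
    """Twelve-parameter three-node motif with Michaelis-Menten kinetics.

    ``b_driver`` is the node activating the buffer/proportioner B: node C for
    the negative feedback loop, node A for the incoherent feed-forward loop.
    """
    params = (
        "kIA", "KIA", "kFA", "KFA",
        b_rate, b_K, "kFB", "KFB",
        "kAC", "KAC", "kBC", "KBC",
    )
    eqs = {
        "A": (
            Term(+1, Mono.of("kIA"), ("I",), "mm_act", Mono.of("KIA")),
            Term(-1, Mono.of("kFA", const=F_A), (), "mm_inh", Mono.of("KFA")),
        ),
        "B": (
            Term(+1, Mono.of(b_rate), (b_driver,), "mm_act", Mono.of(b_K)),
            Term(-1, Mono.of("kFB", const=F_B), (), "mm_inh", Mono.of("KFB")),
        ),
        "C": (
            Term(+1, Mono.of("kAC"), ("A",), "mm_act", Mono.of("KAC")),
            Term(-1, Mono.of("kBC"), ("B",), "mm_inh", Mono.of("KBC")),
        ),
    }
    return StructuredModel(name, ("A", "B", "C"), params, eqs, "C")


def _nfb_4() -> StructuredModel:
    params = ("kIA", "kCB*kBC/(KCB*KBC)", "kFB/KFB", "kAC")
    w = Mono.of("kCB*kBC/(KCB*KBC)")
    q = Mono.of("kFB/KFB", const=F_B)
    eqs = {
        "A": (Term(+1, Mono.of("kIA"), ("I",), "gate_act"),),
        "Bt": (
            Term(+1, w, ("C",), "bare"),
            Term(-1, q, (), "lin_inh"),
        ),
        "C": (
            Term(+1, Mono.of("kAC"), ("A",), "gate_act"),
            Term(-1, Mono((), 1.0), ("Bt",), "lin_inh"),
        ),
    }
    prov = {
        "kIA": Mono.of("kIA"),
        "kCB*kBC/(KCB*KBC)": Mono.of(kCB=1, kBC=1, KCB=-1, KBC=-1),
        "kFB/KFB": Mono.of(kFB=1, KFB=-1),
        "kAC": Mono.of("kAC"),
    }
    return StructuredModel("NFB_4", ("A", "Bt", "C"), params, eqs, "C", prov)


def _ifflp_4() -> StructuredModel:
    params = ("kIA", "kAB", "kAC", "kBC/KBC")
    eqs = {
        "A": (Term(+1, Mono.of("kIA"), ("I",), "gate_act"),),
        "B": (Term(+1, Mono.of("kAB"), ("A",), "gate_act"),),
        "C": (
            Term(+1, Mono.of("kAC"), ("A",), "gate_act"),
            Term(-1, Mono.of("kBC/KBC"), ("B",), "lin_inh"),
        ),
    }
    prov = {
        "kIA": Mono.of("kIA"),
        "kAB": Mono.of("kAB"),
        "kAC": Mono.of("kAC"),
        "kBC/KBC": Mono.of(kBC=1, KBC=-1),
    }
    return StructuredModel("IFFLP_4", ("A", "B", "C"), params, eqs, "C", prov)


def _nfb_2() -> StructuredModel:
    params = ("kAC", "kCB*kBC/(KCB*KBC)")
    eqs = {
        "C": (
            Term(+1, Mono.of("kAC"), ("I",), "gate_act"),
            Term(-1, Mono((), 1.0), ("Bt",), "lin_inh"),
        ),
        "Bt": (Term(+1, Mono.of("kCB*kBC/(KCB*KBC)"), ("C",), "bare"),),
    }
    prov = {
        "kAC": Mono.of("kAC"),
        "kCB*kBC/(KCB*KBC)": Mono.of(kCB=1, kBC=1, KCB=-1, KBC=-1),
    }
    return StructuredModel("NFB_2", ("C", "Bt"), params, eqs, "C", prov)


def _ifflp_2() -> StructuredModel:
    params = ("kAC", "kAB*kBC/KBC")
    eqs = {
        "C": (
            Term(+1, Mono.of("kAC"), ("I",), "gate_act"),
            Term(-1, Mono((), 1.0), ("Bt",), "lin_inh"),
        ),
        "Bt": (Term(+1, Mono.of("kAB*kBC/KBC"), ("I",), "bare"),),
    }
    prov = {
        "kAC": Mono.of("kAC"),
        "kAB*kBC/KBC": Mono.of(kAB=1, kBC=1, KBC=-1),
    }
    return StructuredModel("IFFLP_2", ("C", "Bt"), params, eqs, "C", prov)


def _egfr_2() -> ODEModel:
    """Reduced ERK adaptation model: dErk/dt = th1*EGF - P90~*Erk,
    dP90~/dt = th2*Erk."""

    def rhs(t, x, k, u, gates):
        erk, p90 = x
        return np.array([k["theta1"] * u - p90 * erk, k["theta2"] * erk])

    return ODEModel(
        name="EGFR_2",
        state_names=("Erk", "P90"),
        parameter_names=("theta1", "theta2"),
        rhs=rhs,
        initial_state=lambda k: np.zeros(2),
        observables={"Erk": lambda states, k: states[:, 0]},
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_MM_QOI = QoISpec("P_frac", np.array([5.0, 10.0, 15.0]), 1.0, NO_INPUT)
# Boundary (geodesic) runs need a QoI grid informative enough that the FIM
# is numerically nondegenerate at the reference point; the 3-point spectrum
# demo grid is not (the predictions there are nearly saturated).  Same
# observable, unit tolerances, fifteen evenly spaced times.
MM_BOUNDARY_QOI = QoISpec("P_frac", np.arange(1.0, 16.0), 1.0, NO_INPUT)
# The promoted five-parameter chain needs at least as many predictions as
# parameters for the Fisher metric to be nondegenerate; same observable and
# window, six evenly spaced times.
_MM_QOI_P = QoISpec("P_abs", np.arange(1.0, 16.0), 1.0, NO_INPUT)
_ADAPT_QOI = QoISpec("C", np.linspace(0.5, 10.0, 20), 0.1, ADAPT_INPUT)

_THETA0 = np.array([1.0, 0.5, 1.5])
_THETA0_P = np.array([1.0, 0.5, 1.5, math.log(E0_FIXED), math.log(S0_FIXED)])


def _registry() -> dict:
    return {
        "MM_FULL": lambda: (
            _mm_full(False),
            ParameterVector(("kf", "kr", "kc"), _THETA0),
            _MM_QOI,
        ),
        "MM_FULL_P": lambda: (
            _mm_full(True),
            ParameterVector(("kf", "kr", "kc", "E0", "S0"), _THETA0_P),
            _MM_QOI_P,
        ),
        "MM_IRREVERSIBLE": lambda: (_mm_irreversible(False), None, _MM_QOI),
        "MM_IRREVERSIBLE_P": lambda: (_mm_irreversible(True), None, _MM_QOI_P),
        "MM_EQUILIBRIUM": lambda: (_mm_equilibrium(), None, _MM_QOI),
        "MM_QSSA": lambda: (_mm_qssa(), None, _MM_QOI_P),
        "NFB_12": lambda: (
            _motif_12("NFB_12", "C", "kCB", "KCB").to_ode(),
            None,
            _ADAPT_QOI,
        ),
        "IFFLP_12": lambda: (
            _motif_12("IFFLP_12", "A", "kAB", "KAB").to_ode(),
            None,
            _ADAPT_QOI,
        ),
        "NFB_4": lambda: (_nfb_4().to_ode(), None, _ADAPT_QOI),
        "IFFLP_4": lambda: (_ifflp_4().to_ode(), None, _ADAPT_QOI),
        "NFB_2": lambda: (_nfb_2().to_ode(), None, _ADAPT_QOI),
        "IFFLP_2": lambda: (_ifflp_2().to_ode(), None, _ADAPT_QOI),
        "EGFR_2": lambda: (
            _egfr_2(),
            ParameterVector(
                ("theta1", "theta2"), np.log(np.array([1.558, 0.977]))
            ),
            QoISpec("Erk", np.linspace(0.5, 10.0, 20), 0.1, InputProtocol("step", 1.0)),
        ),
    }


def zoo_names() -> list[str]:
    return sorted(_registry())


def zoo(name: str) -> tuple[ODEModel, ParameterVector | None, QoISpec]:
    """Look up a bundled model by name.

    Returns ``(model, reference_parameters_or_None, default_qoi)``.
    """
    reg = _registry()
    try:
        factory = reg[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(reg)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# Adaptation QoIs and fixture sampling
# ---------------------------------------------------------------------------

_SCAN_TIMES = np.geomspace(1e-3, 1e3, 400)


def adaptation_qoi(
    model: ODEModel,
    params: ParameterVector,
    protocol: InputProtocol = ADAPT_INPUT,
    *,
    n_times: int = 20,
    sigma_frac: float = 0.1,
) -> QoISpec:
    """Step-response QoI grid for an adaptation model at given parameters.

    Twenty evenly spaced times spanning ten times the time-to-peak of a
    reference simulation, with tolerance sigma = ``sigma_frac`` times the
    peak response.
    """
    traj = simulate(model, params, _SCAN_TIMES, protocol, rtol=1e-8, atol=1e-10)
    y = traj[model.meta["structured"].observable if "structured" in model.meta else model.state_names[0]]
    i_pk = int(np.argmax(y))
    t_pk, peak = traj.times[i_pk], float(y[i_pk])
    if peak <= 0:
        raise ValueError("reference response has no positive peak")
    horizon = 10.0 * t_pk
    times = np.linspace(horizon / n_times, horizon, n_times)
    return QoISpec(
        observable=model.meta["structured"].observable
        if "structured" in model.meta
        else model.state_names[0],
        times=times,
        sigmas=sigma_frac * peak,
        protocol=protocol,
    )


class SamplingError(RuntimeError):
    """Fixture sampling exhausted its draw budget."""

    def __init__(self, message: str, draws: int):
        super().__init__(message)
        self.draws = draws


def sample_adaptive_params(
    model: ODEModel,
    *,
    sensitivity_min: float = 0.1,
    precision_frac: float = 0.2,
    seed: int = 0,
    max_draws: int = 5000,
    log_bounds: tuple[float, float] = (math.log(1e-2), math.log(1e2)),
) -> ParameterVector:
    """Draw log-uniform parameters until the step response is adaptive.

    A draw is accepted when the step response (input magnitude I) shows a
    transient interior peak of height >= ``sensitivity_min * I`` followed by
    a settled return with final offset <= ``precision_frac`` of the peak.
    Deterministic for a given seed.
    """
    if model.name not in ("NFB_12", "IFFLP_12"):
        raise ValueError("fixture sampling is defined for NFB_12/IFFLP_12 only")
    if sensitivity_min <= 0 or precision_frac <= 0:
        raise ValueError("adaptation criteria must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = log_bounds
    I = ADAPT_INPUT.magnitude
    for draw in range(1, max_draws + 1):
        theta = rng.uniform(lo, hi, size=model.n_params)
        pv = ParameterVector(model.parameter_names, theta)
        try:
            traj = simulate(
                model, pv, _SCAN_TIMES, ADAPT_INPUT, rtol=1e-7, atol=1e-9
            )
        except IntegrationError:
            continue
        c = traj["C"]
        i_pk = int(np.argmax(c))
        peak = float(c[i_pk])
        if peak < sensitivity_min * I or i_pk >= len(c) - 1:
            continue
        tail = c[int(0.9 * len(c)):]
        if np.ptp(tail) > 0.01 * peak:  # not settled within the horizon
            continue
        offset = abs(float(np.mean(tail)))
        if offset <= precision_frac * peak:
            return pv
    raise SamplingError(
        f"no adaptive parameter set found in {max_draws} draws "
        f"(sensitivity >= {sensitivity_min} * I, offset <= {precision_frac} * peak)",
        max_draws,
    )
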