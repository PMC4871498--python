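"""Minimal SBML import for user-supplied kinetic models.

Reads the core subset of SBML Level 2/3 sufficient for mass-action and
Michaelis-Menten reaction networks: compartments, species, global and
reaction-local parameters, reactions with content-MathML kinetic laws, and
assignment rules.  Events, rate/algebraic rules, function definitions and
piecewise kinetics are rejected with a clear message -- the importer aims
at deterministic ODE kinetics only.

On ingestion every strictly positive parameter is log-transformed and
becomes a fittable model parameter; non-positive parameters and
compartment sizes are kept as fixed constants.  Species concentrations are
the state variables; boundary/constant species are held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lxml import etree

from .models import ODEModel
from .params import ParameterVector

__all__ = ["SBMLImportError", "load_sbml"]


class SBMLImportError(ValueError):
    """The document uses SBML features outside the supported subset."""


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _children(node, name):
    return [c for c in node if isinstance(c.tag, str) and _local(c.tag) == name]


def _first(node, name):
    found = _children(node, name)
    return found[0] if found else None


# -- content MathML -> evaluator closures -----------------------------------

_BINARY = {
    "plus": lambda args: lambda env: sum(a(env) for a in args),
    "times": lambda args: lambda env: _prod(args, env),
    "divide": lambda args: lambda env: args[0](env) / args[1](env),
    "power": lambda args: lambda env: args[0](env) ** args[1](env),
}

_UNARY = {
    "exp": np.exp,
    "ln": np.log,
    "log": np.log10,
    "abs": np.abs,
    "floor": np.floor,
    "ceiling": np.ceil,
}


def _prod(args, env):
    v = 1.0
    for a in args:
        v = v * a(env)
    return v


def _compile_math(node):
    tag = _local(node.tag)
    if tag == "math":
        kids = [c for c in node if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise SBMLImportError("expected a single expression under <math>")
        return _compile_math(kids[0])
    if tag == "cn":
        sep = _first(node, "sep")
        if sep is not None or node.get("type") == "e-notation":
            mant = float(node.text)
            exp = float(sep.tail) if sep is not None else 0.0
            val = mant * 10.0**exp
        elif node.get("type") == "rational":
            sep_kids = _children(node, "sep")
            num = float(node.text)
            den = float(sep_kids[0].tail) if sep_kids else 1.0
            val = num / den
        else:
            val = float(node.text)
        return lambda env, val=val: val
    if tag == "ci":
        name = node.text.strip()
        return lambda env, name=name: env[name]
    if tag == "csymbol":
        url = node.get("definitionURL", "")
        if url.endswith("/time"):
            return lambda env: env["__time__"]
        raise SBMLImportError(f"unsupported csymbol {url!r}")
    if tag == "apply":
        kids = [c for c in node if isinstance(c.tag, str)]
        op = _local(kids[0].tag)
        args = [_compile_math(c) for c in kids[1:]]
        if op == "minus":
            if len(args) == 1:
                return lambda env: -args[0](env)
            return lambda env: args[0](env) - args[1](env)
        if op in _BINARY:
            return _BINARY[op](args)
        if op in _UNARY and len(args) == 1:
            f = _UNARY[op]
            return lambda env: f(args[0](env))
        if op == "root" and len(args) == 1:
            return lambda env: np.sqrt(args[0](env))
        raise SBMLImportError(f"unsupported MathML operator <{op}>")
    if tag == "piecewise":
        raise SBMLImportError(
            "piecewise kinetics are not supported (discontinuous rate laws "
            "should be expressed through the package's gated-term models)"
        )
    raise SBMLImportError(f"unsupported MathML element <{tag}>")


@dataclass
class _Species:
    sid: str
    initial: float
    compartment: str
    constant: bool


def load_sbml(path) -> tuple[ODEModel, ParameterVector]:
    """Parse an SBML file into an :class:`ODEModel` plus log parameters.

    Returns ``(model, reference_parameters)`` where the reference values are
    the log-transformed parameter values from the document.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLImportError(f"{path}: root element is not <sbml>")
    model_node = _first(root, "model")
    if model_node is None:
        raise SBMLImportError(f"{path}: no <model> element")

    for banned, msg in (
        ("listOfEvents", "events are not supported"),
        ("listOfConstraints", "constraints are not supported"),
        ("listOfFunctionDefinitions", "function definitions are not supported"),
    ):
        if _first(model_node, banned) is not None:
            raise SBMLImportError(f"{path}: {msg}")
    rules_node = _first(model_node, "listOfRules")
    assignments = []
    if rules_node is not None:
        for rule in rules_node:
            if not isinstance(rule.tag, str):
                continue
            kind = _local(rule.tag)
            if kind != "assignmentRule":
                raise SBMLImportError(
                    f"{path}: only assignment rules are supported, found {kind}"
                )
            var = rule.get("variable")
            math = _first(rule, "math")
            assignments.append((var, _compile_math(math)))

    compartments: dict[str, float] = {}
    node = _first(model_node, "listOfCompartments")
    if node is not None:
        for comp in _children(node, "compartment"):
            size = comp.get("size") or comp.get("volume") or "1"
            compartments[comp.get("id")] = float(size)

    species: list[_Species] = []
    node = _first(model_node, "listOfSpecies")
    if node is not None:
        for sp in _children(node, "species"):
            conc = sp.get("initialConcentration")
            if conc is None:
                amount = sp.get("initialAmount")
                size = compartments.get(sp.get("compartment"), 1.0)
                conc = float(amount) / size if amount is not None else 0.0
            fixed = sp.get("boundaryCondition") == "true" or sp.get("constant") == "true"
            species.append(
                _Species(sp.get("id"), float(conc), sp.get("compartment"), fixed)
            )
    if not species:
        raise SBMLImportError(f"{path}: model declares no species")

    constants: dict[str, float] = dict(compartments)
    fit_params: dict[str, float] = {}
    node = _first(model_node, "listOfParameters")
    if node is not None:
        for par in _children(node, "parameter"):
            pid, val = par.get("id"), float(par.get("value", "nan"))
            if np.isfinite(val) and val > 0:
                fit_params[pid] = val
            else:
                constants[pid] = val

    reactions = []
    node = _first(model_node, "listOfReactions")
    if node is not None:
        for rxn in _children(node, "reaction"):
            rid = rxn.get("id")
            stoich: dict[str, float] = {}
            for side, sign in (("listOfReactants", -1.0), ("listOfProducts", +1.0)):
                side_node = _first(rxn, side)
                if side_node is None:
                    continue
                for ref in _children(side_node, "speciesReference"):
                    s = float(ref.get("stoichiometry", "1"))
                    sid = ref.get("species")
                    stoich[sid] = stoich.get(sid, 0.0) + sign * s
            kl = _first(rxn, "kineticLaw")
            if kl is None:
                raise SBMLImportError(f"{path}: reaction {rid!r} has no kinetic law")
            for lp_list in ("listOfParameters", "listOfLocalParameters"):
                lp_node = _first(kl, lp_list)
                if lp_node is None:
                    continue
                for par in lp_node:
                    if not isinstance(par.tag, str):
                        continue
                    pid, val = par.get("id"), float(par.get("value", "nan"))
                    # local parameters are namespaced by reaction id on clash
                    if pid in fit_params or pid in constants:
                        pid = f"{rid}.{pid}"
                    if np.isfinite(val) and val > 0:
                        fit_params[pid] = val
                    else:
                        constants[pid] = val
            math = _first(kl, "math")
            if math is None:
                raise SBMLImportError(f"{path}: reaction {rid!r} kinetic law has no math")
            reactions.append((rid, stoich, _compile_math(math)))
    if not reactions:
        raise SBMLImportError(f"{path}: model declares no reactions")

    state_species = [s for s in species if not s.constant]
    state_names = tuple(s.sid for s in state_species)
    fixed_species = {s.sid: s.initial for s in species if s.constant}
    sizes = np.array(
        [compartments.get(s.compartment, 1.0) for s in state_species]
    )
    pnames = tuple(fit_params)

    def build_env(t, x, k, u):
        env = dict(constants)
        env.update(fixed_species)
        env["__time__"] = t
        for i, name in enumerate(state_names):
            env[name] = x[i]
        for p in pnames:
            env[p] = k[p]
        for var, expr in assignments:
            env[var] = expr(env)
        return env

    def rhs(t, x, k, u, gates):
        env = build_env(t, x, k, u)
        dx = [0.0 * x[i] for i in range(len(state_names))]
        for rid, stoich, flux in reactions:
            v = flux(env)
            for sid, coeff in stoich.items():
                if sid in fixed_species:
                    continue
                i = state_names.index(sid)
                dx[i] = dx[i] + coeff * v
        return np.array(dx) / sizes[:, None] if np.ndim(x[0]) else np.array(dx) / sizes

    def initial_state(k):
        return np.array([s.initial for s in state_species])

    model = ODEModel(
        name=model_node.get("id") or model_node.get("name") or "sbml_model",
        state_names=state_names,
        parameter_names=pnames,
        rhs=rhs,
        initial_state=initial_state,
        observables={
            s: (lambda states, k, i=i: states[:, i]) for i, s in enumerate(state_names)
        },
        meta={"source": str(path), "constants": constants},
    )
    ref = ParameterVector.from_linear(fit_params) if fit_params else ParameterVector((), np.array([]))
    return model, ref
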