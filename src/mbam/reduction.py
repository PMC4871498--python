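"""Limit rules, recalibration and the iterated MBAM loop.

A manifold boundary corresponds to one or more log-parameters running to
+inf or -inf in a coordinated way.  Turning such a limit into a reduced
model is an algebraic step; this module encodes the limits as a curated,
extensible registry of :class:`LimitRule` objects rather than attempting
general symbolic limit evaluation:

* enzyme-kinetics rules: rapid equilibrium (kf, kr -> inf with Kd = kr/kf
  finite), irreversible binding (kr -> 0), and the quasi-steady-state limit
  (kf, kc -> inf, E0 -> 0 with Vmax = kc E0 and KM = kc/kf finite);
* structural rules on the motif term language: linearizing a saturating
  term (k, K -> inf with k/K finite), deleting a vanishing term, hardening
  a saturation into a Heaviside gate (K -> 0), and the two buffer-node
  renormalizations (rescaling the buffer by a diverging consumer rate, or
  by a diverging Michaelis constant).

After each limit the reduced model is recalibrated to the parent model's
predictions by damped least squares; the loop repeats until every
remaining parameter is identifiable, a target size is reached, or no rule
matches the classified limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .geodesic import (
    GeodesicOptions,
    GeodesicPath,
    LimitDescriptor,
    classify_limit,
    integrate_geodesic,
)
from .infogeo import FDOptions, Spectrum, fim, jacobian, spectrum
from .models import IntegrationError, ODEModel, QoISpec, residuals
from .params import ParameterVector
from .terms import Mono, StructuredModel, Term
from .zoo import zoo as _zoo_lookup

__all__ = [
    "LimitRule",
    "Registry",
    "CalibrationResult",
    "ReductionStep",
    "ReductionReport",
    "MBAMOptions",
    "UnmatchedLimitError",
    "default_registry",
    "apply_limit",
    "calibrate",
    "identifiability_check",
    "mbam_run",
]


class UnmatchedLimitError(RuntimeError):
    """No registered rule matches the classified limit."""

    def __init__(self, model_name: str, descriptor: LimitDescriptor):
        self.descriptor = descriptor
        super().__init__(
            f"no registered limit rule matches {descriptor.nonfinite} on model "
            f"{model_name!r}; register a user rule for this boundary"
        )


@dataclass
class LimitRule:
    """A named manifold-boundary evaluation.

    ``matches(model, descriptor)`` decides applicability;
    ``apply(model, params, descriptor)`` returns the reduced model and an
    initial guess for its log-parameters computed from the old values.
    """

    name: str
    matches: callable
    apply: callable


class Registry:
    def __init__(self, rules: list[LimitRule] | None = None):
        self.rules = list(rules or [])

    def register(self, rule: LimitRule) -> None:
        self.rules.append(rule)

    def find(self, model: ODEModel, descriptor: LimitDescriptor) -> LimitRule | None:
        for rule in self.rules:
            if rule.matches(model, descriptor):
                return rule
        return None


# ---------------------------------------------------------------------------
# Enzyme-kinetics rules
# ---------------------------------------------------------------------------

def _nonfinite(descriptor: LimitDescriptor) -> dict[str, str]:
    return descriptor.nonfinite


def _rule_equilibrium() -> LimitRule:
    def matches(model, d):
        return model.name == "MM_FULL" and _nonfinite(d) == {"kf": "inf", "kr": "inf"}

    def apply(model, params, d):
        reduced, _, _ = _zoo_lookup("MM_EQUILIBRIUM")
        phi = ParameterVector(
            ("Kd", "kc"), np.array([params["kr"] - params["kf"], params["kc"]])
        )
        return reduced, phi

    return LimitRule("equilibrium (kf,kr->inf; Kd=kr/kf)", matches, apply)


def _rule_irreversible() -> LimitRule:
    def matches(model, d):
        return (
            model.name in ("MM_FULL", "MM_FULL_P")
            and _nonfinite(d) == {"kr": "zero"}
        )

    def apply(model, params, d):
        promoted = model.name.endswith("_P")
        reduced, _, _ = _zoo_lookup("MM_IRREVERSIBLE_P" if promoted else "MM_IRREVERSIBLE")
        names = reduced.parameter_names
        phi = ParameterVector(names, np.array([params[n] for n in names]))
        return reduced, phi

    return LimitRule("irreversible binding (kr->0)", matches, apply)


def _rule_qssa() -> LimitRule:
    def matches(model, d):
        return model.name == "MM_IRREVERSIBLE_P" and _nonfinite(d) == {
            "kf": "inf",
            "kc": "inf",
            "E0": "zero",
        }

    def apply(model, params, d):
        reduced, _, _ = _zoo_lookup("MM_QSSA")
        phi = ParameterVector(
            ("Vmax", "KM", "S0"),
            np.array(
                [
                    params["kc"] + params["E0"],
                    params["kc"] - params["kf"],
                    params["S0"],
                ]
            ),
        )
        return reduced, phi

    return LimitRule("quasi-steady state (kf,kc->inf, E0->0)", matches, apply)


# ---------------------------------------------------------------------------
# Structural rules on the motif term language
# ---------------------------------------------------------------------------

def _structured(model: ODEModel) -> StructuredModel | None:
    return model.meta.get("structured")


def _finish_structured(
    sm: StructuredModel,
    old: StructuredModel,
    params: ParameterVector,
    new_values: dict[str, Mono],
    removed: set[str],
    tag: str,
) -> tuple[ODEModel, ParameterVector]:
    """Assemble the reduced structured model and its phi guess.

    ``new_values`` maps each new parameter name to the monomial (over the
    OLD parameter names) whose value initializes it.
    """
    phi = []
    for p in sm.params:
        if p in new_values:
            mono = new_values[p]
            val = sum(e * params[q] for q, e in mono.powers) + np.log(mono.const)
            phi.append(val)
        else:
            phi.append(params[p])
    reduced = sm.to_ode()
    reduced.meta["derived_from"] = old.name
    reduced.meta["limit"] = tag
    return reduced, ParameterVector(sm.params, np.array(phi, dtype=float))


def _compose_provenance(old: StructuredModel, mono: Mono) -> Mono:
    return mono.substitute(old.provenance)


def _new_param_order(params: tuple[str, ...], removed: set[str], new: list[tuple[str, int]]):
    """Keep the old ordering; insert each new name at its anchor position."""
    out = [p for p in params if p not in removed]
    for name, anchor in sorted(new, key=lambda t: t[1]):
        pos = 0
        for i, p in enumerate(params):
            if p == name:
                break
            if i < anchor and p not in removed:
                pos += 1
        out.insert(min(pos, len(out)), name)
    # de-duplicate while preserving order (a combo may collapse onto an
    # existing name after provenance simplification)
    seen, uniq = set(), []
    for p in out:
        if p not in seen:
            seen.add(p)
            uniq.append(p)
    return tuple(uniq)


def _mentions(sm: StructuredModel, p: str):
    return sm.terms_with_param(p)


def _only_in(sm: StructuredModel, p: str, hits) -> bool:
    return len(_mentions(sm, p)) == len(hits)


def _rule_linearize() -> LimitRule:
    """k, K -> inf together: a Michaelis-Menten term enters its linear regime."""

    def _find(sm, d):
        nf = d.nonfinite
        if len(nf) != 2 or set(nf.values()) != {"inf"}:
            return None
        p, q = sorted(nf)
        for cand_p, cand_q in ((p, q), (q, p)):
            for s, i, t, where in sm.terms_with_param(cand_p):
                if where != "coeff" or not t.form.startswith("mm"):
                    continue
                if t.coeff.exponent(cand_p) != 1 or t.K != Mono.of(cand_q):
                    continue
                if len(sm.terms_with_param(cand_p)) == 1 and len(
                    sm.terms_with_param(cand_q)
                ) == 1:
                    return cand_p, cand_q, s, i, t
        return None

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        p, q, s, i, t = _find(sm, d)
        prov = _compose_provenance(sm, Mono.of(p) / Mono.of(q))
        new_name = prov.name()
        new_coeff = (t.coeff / Mono.of(p)) * Mono.of(new_name)
        new_form = "lin_act" if t.form == "mm_act" else "lin_inh"
        new_term = Term(t.sign, new_coeff, t.drivers, new_form, None)
        eqs = sm.replace_term(s, i, new_term)
        removed = {p, q}
        order = _new_param_order(sm.params, removed, [(new_name, sm.params.index(p))])
        provenance = {
            n: sm.provenance[n] for n in order if n in sm.provenance
        }
        provenance[new_name] = prov
        out = StructuredModel(
            f"{sm.name}.lin[{p}/{q}]", sm.states, order, eqs, sm.observable, provenance
        )
        return _finish_structured(
            out, sm, params, {new_name: Mono.of(p) / Mono.of(q)}, removed,
            f"linearize {p},{q}->inf",
        )

    return LimitRule("linearize saturating term (k,K->inf)", matches, apply)


def _rule_drop_term() -> LimitRule:
    """A lumped rate -> 0: the corresponding reaction drops out."""

    def _find(sm, d):
        nf = d.nonfinite
        if set(nf.values()) != {"zero"}:
            return None
        if len(nf) == 1:
            (p,) = nf
            hits = [
                h for h in sm.terms_with_param(p)
                if h[3] == "coeff" and h[2].coeff.exponent(p) == 1
            ]
            if len(hits) == 1 and _only_in(sm, p, hits):
                s, i, t, _ = hits[0]
                return {p}, s, i
        if len(nf) == 2:
            # k -> 0 and its own K -> 0: the whole saturating term vanishes
            p, q = sorted(nf)
            for cp, cq in ((p, q), (q, p)):
                for s, i, t, where in sm.terms_with_param(cp):
                    if (
                        where == "coeff"
                        and t.form.startswith("mm")
                        and t.coeff.exponent(cp) == 1
                        and t.K == Mono.of(cq)
                        and _only_in(sm, cp, [(s, i, t, "coeff")])
                        and len(sm.terms_with_param(cq)) == 1
                    ):
                        return {cp, cq}, s, i
        return None

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        removed, s, i = _find(sm, d)
        eqs = sm.replace_term(s, i, None)
        order = tuple(p for p in sm.params if p not in removed)
        provenance = {n: sm.provenance[n] for n in order}
        out = StructuredModel(
            f"{sm.name}.drop[{'/'.join(sorted(removed))}]",
            sm.states, order, eqs, sm.observable, provenance,
        )
        return _finish_structured(
            out, sm, params, {}, removed, f"drop {sorted(removed)}->0"
        )

    return LimitRule("vanishing reaction (rate->0)", matches, apply)


def _rule_saturate() -> LimitRule:
    """K -> 0 in an activating term: zero-order kinetics with a hard cap."""

    def _find(sm, d):
        nf = d.nonfinite
        if len(nf) != 1:
            return None
        (q,) = nf
        if nf[q] != "zero":
            return None
        hits = sm.terms_with_param(q)
        if len(hits) != 1:
            return None
        s, i, t, where = hits[0]
        if where == "K" and t.form == "mm_act" and t.K == Mono.of(q):
            return q, s, i, t
        return None

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        q, s, i, t = _find(sm, d)
        new_term = Term(t.sign, t.coeff, t.drivers, "gate_act", None)
        eqs = sm.replace_term(s, i, new_term)
        order = tuple(p for p in sm.params if p != q)
        provenance = {n: sm.provenance[n] for n in order}
        out = StructuredModel(
            f"{sm.name}.sat[{q}]", sm.states, order, eqs, sm.observable, provenance
        )
        return _finish_structured(out, sm, params, {}, {q}, f"saturate {q}->0")

    return LimitRule("saturating activation (K->0)", matches, apply)


def _rule_k_inf_vanish() -> LimitRule:
    """K -> inf alone: the saturating term's rate k/K -> 0, term drops."""

    def _find(sm, d):
        nf = d.nonfinite
        if len(nf) != 1:
            return None
        (q,) = nf
        if nf[q] != "inf":
            return None
        hits = sm.terms_with_param(q)
        if len(hits) != 1:
            return None
        s, i, t, where = hits[0]
        if where == "K" and t.form.startswith("mm") and t.K == Mono.of(q):
            # the rate parameters in t.coeff leave the model with the term
            coeff_params = t.coeff.params
            for cp in coeff_params:
                if len(sm.terms_with_param(cp)) != 1:
                    return None
            return q, s, i, t
        return None

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        q, s, i, t = _find(sm, d)
        removed = {q} | set(t.coeff.params)
        eqs = sm.replace_term(s, i, None)
        order = tuple(p for p in sm.params if p not in removed)
        provenance = {n: sm.provenance[n] for n in order}
        out = StructuredModel(
            f"{sm.name}.vanish[{q}]", sm.states, order, eqs, sm.observable, provenance
        )
        return _finish_structured(out, sm, params, {}, removed, f"vanish K {q}->inf")

    return LimitRule("vanishing saturating term (K->inf)", matches, apply)


def _rule_buffer_renorm() -> LimitRule:
    """Renormalize the buffer node by a diverging consumer rate.

    Pattern: the buffer state's production rate(s) and its decay rate and
    Michaelis constant all -> 0 while the rate with which the output node
    senses the buffer -> inf; the products (w*s, kd*s, Kd*s) stay finite for
    the rescaled buffer  b~ = s * b.
    """

    def _find(sm, d):
        nf = d.nonfinite
        zeros = {p for p, v in nf.items() if v == "zero"}
        infs = {p for p, v in nf.items() if v == "inf"}
        if len(infs) != 1 or len(zeros) != 3:
            return None
        s_par = next(iter(infs))
        hits = sm.terms_with_param(s_par)
        if len(hits) != 1:
            return None
        cs, ci, ct, cw = hits[0]
        if cw != "coeff" or ct.coeff.exponent(s_par) != 1 or not ct.drivers:
            return None
        buffers = [dv for dv in ct.drivers if dv in sm.states and dv != sm.observable]
        if len(buffers) != 1:
            return None
        b = buffers[0]
        prod, decay = [], []
        for i, t in enumerate(sm.equations[b]):
            (decay if t.sign < 0 else prod).append((i, t))
        if len(decay) != 1 or not prod:
            return None
        di, dt_ = decay[0]
        if dt_.form != "mm_inh" or dt_.K is None:
            return None
        kd_cands = dt_.coeff.params & zeros
        Kd_cands = dt_.K.params & zeros
        if len(kd_cands) != 1 or len(Kd_cands) != 1:
            return None
        kd, Kd_ = next(iter(kd_cands)), next(iter(Kd_cands))
        w_cands = zeros - {kd, Kd_}
        if len(w_cands) != 1:
            return None
        w = next(iter(w_cands))
        if not any(t.coeff.exponent(w) == 1 for _, t in prod):
            return None
        for _, t in prod:
            if t.form not in ("lin_act", "bare"):
                return None
        return b, s_par, w, kd, Kd_, (cs, ci, ct), di

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        b, s_par, w, kd, Kd_, (cs, ci, ct), di = _find(sm, d)
        bt = b + "t" if not b.endswith("t") else b
        smap = {st: (bt if st == b else st) for st in sm.states}
        states = tuple(smap[st] for st in sm.states)
        s_mono = Mono.of(s_par)
        new_vals: dict[str, Mono] = {}
        prov: dict[str, Mono] = {}

        def lump(mono_old: Mono) -> str:
            name = _compose_provenance(sm, mono_old).name()
            new_vals[name] = mono_old
            prov[name] = _compose_provenance(sm, mono_old)
            return name

        eqs: dict[str, tuple[Term, ...]] = {}
        for st, terms in sm.equations.items():
            new_terms = []
            for i, t in enumerate(terms):
                drivers = tuple(smap.get(dv, dv) for dv in t.drivers)
                if st == b:
                    if t.sign > 0:  # production, coeff * s; (1-b) -> 1
                        cname = lump((t.coeff * s_mono))
                        form = "bare" if t.form in ("lin_act", "bare") else t.form
                        new_terms.append(Term(+1, Mono.of(cname), drivers, form, None))
                    else:  # mm decay: coeff * s, K * s
                        cname = lump(t.coeff * s_mono)
                        kname = lump(t.K * s_mono)
                        new_terms.append(
                            Term(-1, Mono.of(cname), drivers, "mm_inh", Mono.of(kname))
                        )
                elif st == cs and i == ci:
                    new_coeff = t.coeff / s_mono
                    new_terms.append(replace(t, coeff=new_coeff, drivers=drivers))
                else:
                    new_terms.append(replace(t, drivers=drivers))
            eqs[smap[st]] = tuple(new_terms)

        removed = {w, kd, Kd_, s_par}
        anchors = [(n, min(sm.params.index(p) for p in new_vals[n].params))
                   for n in new_vals]
        order = _new_param_order(sm.params, removed, anchors)
        provenance = {n: sm.provenance[n] for n in order if n in sm.provenance}
        provenance.update(prov)
        obs = smap[sm.observable]
        out = StructuredModel(
            f"{sm.name}.renorm[{b}*{s_par}]", states, order, eqs, obs, provenance
        )
        return _finish_structured(
            out, sm, params, new_vals, removed,
            f"renormalize {b} by {s_par}->inf",
        )

    return LimitRule("renormalized buffer (consumer rate->inf)", matches, apply)


def _rule_buffer_rescale_K() -> LimitRule:
    """Rescale the buffer by a diverging Michaelis constant of its consumer.

    Pattern: the output node's inhibition by the buffer saturates at K ->
    inf while the buffer's production rate -> inf; b~ = b / K stays finite
    and inhibits linearly.  A still-saturating buffer decay needs its own
    Michaelis constant -> inf as well.
    """

    def _find(sm, d):
        nf = d.nonfinite
        infs = {p for p, v in nf.items() if v == "inf"}
        if set(nf.values()) != {"inf"} or len(infs) not in (2, 3):
            return None
        for s, i, t, where in list(
            h for p in infs for h in sm.terms_with_param(p)
        ):
            if where != "K" or t.form != "mm_inh" or t.sign > 0:
                continue
            K_cands = t.K.params & infs
            if len(K_cands) != 1 or not t.drivers:
                continue
            K = next(iter(K_cands))
            if t.K != Mono.of(K):
                continue
            buffers = [dv for dv in t.drivers if dv in sm.states and dv != s]
            if len(buffers) != 1:
                continue
            b = buffers[0]
            prod = [
                (j, u) for j, u in enumerate(sm.equations[b]) if u.sign > 0
            ]
            decay = [
                (j, u) for j, u in enumerate(sm.equations[b]) if u.sign < 0
            ]
            if len(prod) != 1:
                continue
            pj, pt = prod[0]
            p1_cands = pt.coeff.params & infs
            if len(p1_cands) != 1 or pt.form != "bare":
                continue
            p1 = next(iter(p1_cands))
            rest = infs - {K, p1}
            p3 = None
            if rest:
                (p3,) = rest
                ok = False
                for j, u in decay:
                    if u.form == "mm_inh" and u.K is not None and u.K == Mono.of(p3):
                        ok = True
                if not ok:
                    continue
            else:
                for j, u in decay:
                    if u.form == "mm_inh":
                        break
                else:
                    u = None
                if u is not None:
                    continue
            return b, K, p1, p3, (s, i, t), pj
        return None

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        b, K, p1, p3, (cs, ci, ct), pj = _find(sm, d)
        K_mono = Mono.of(K)
        new_vals: dict[str, Mono] = {}
        prov: dict[str, Mono] = {}

        def lump(mono_old: Mono) -> str:
            name = _compose_provenance(sm, mono_old).name()
            new_vals[name] = mono_old
            prov[name] = _compose_provenance(sm, mono_old)
            return name

        eqs: dict[str, tuple[Term, ...]] = {}
        for st, terms in sm.equations.items():
            new_terms = []
            for i, t in enumerate(terms):
                if st == cs and i == ci:
                    new_terms.append(
                        Term(t.sign, t.coeff, t.drivers, "lin_inh", None)
                    )
                elif st == b and t.sign > 0:
                    cname = lump(t.coeff / K_mono)
                    new_terms.append(replace(t, coeff=Mono.of(cname)))
                elif st == b and t.form == "mm_inh":
                    kname = lump(t.K / K_mono)
                    new_terms.append(replace(t, K=Mono.of(kname)))
                else:
                    new_terms.append(t)
            eqs[st] = tuple(new_terms)

        removed = {K, p1} | ({p3} if p3 else set())
        anchors = [(n, min(sm.params.index(p) for p in new_vals[n].params))
                   for n in new_vals]
        order = _new_param_order(sm.params, removed, anchors)
        provenance = {n: sm.provenance[n] for n in order if n in sm.provenance}
        provenance.update(prov)
        out = StructuredModel(
            f"{sm.name}.rescale[{b}/{K}]", sm.states, order, eqs,
            sm.observable, provenance,
        )
        return _finish_structured(
            out, sm, params, new_vals, removed, f"rescale {b} by {K}->inf"
        )

    return LimitRule("buffer rescaled by Michaelis constant (K->inf)", matches, apply)


def _rule_buffer_renorm_decay_free() -> LimitRule:
    """Renormalize a decay-free buffer by a diverging consumer rate.

    Pattern: the buffer's production rate -> 0 while the rate with which
    another node senses it -> inf; b~ = s * b stays finite.  The buffer's
    remaining terms must be linear (scale-invariant); saturating production
    in (1 - b) or Theta(1 - b) becomes unsaturated since b -> 0.
    """

    def _find(sm, d):
        nf = d.nonfinite
        zeros = {p for p, v in nf.items() if v == "zero"}
        infs = {p for p, v in nf.items() if v == "inf"}
        if len(infs) != 1 or len(zeros) != 1:
            return None
        s_par, w = next(iter(infs)), next(iter(zeros))
        hits = sm.terms_with_param(s_par)
        if len(hits) != 1:
            return None
        cs, ci, ct, cw = hits[0]
        if cw != "coeff" or ct.coeff.exponent(s_par) != 1 or not ct.drivers:
            return None
        buffers = [dv for dv in ct.drivers if dv in sm.states and dv != cs]
        if len(buffers) != 1:
            return None
        b = buffers[0]
        if b == sm.observable:
            return None
        prod = [(i, t) for i, t in enumerate(sm.equations[b]) if t.sign > 0]
        if not prod or not any(t.coeff.exponent(w) == 1 for _, t in prod):
            return None
        for i, t in enumerate(sm.equations[b]):
            if t.sign > 0 and t.form not in ("lin_act", "bare", "gate_act"):
                return None
            if t.sign < 0 and t.form != "lin_inh":
                return None
        whits = sm.terms_with_param(w)
        if any(h[0] != b for h in whits):
            return None
        return b, s_par, w, (cs, ci, ct)

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        b, s_par, w, (cs, ci, ct) = _find(sm, d)
        bt = b + "t" if not b.endswith("t") else b + "2"
        smap = {st: (bt if st == b else st) for st in sm.states}
        states = tuple(smap[st] for st in sm.states)
        s_mono = Mono.of(s_par)
        new_vals: dict[str, Mono] = {}
        prov: dict[str, Mono] = {}

        def lump(mono_old: Mono) -> str:
            name = _compose_provenance(sm, mono_old).name()
            new_vals[name] = mono_old
            prov[name] = _compose_provenance(sm, mono_old)
            return name

        eqs: dict[str, tuple[Term, ...]] = {}
        for st, terms in sm.equations.items():
            new_terms = []
            for i, t in enumerate(terms):
                drivers = tuple(smap.get(dv, dv) for dv in t.drivers)
                if st == b and t.sign > 0:
                    cname = lump(t.coeff * s_mono)
                    new_terms.append(Term(+1, Mono.of(cname), drivers, "bare", None))
                elif st == b:
                    new_terms.append(replace(t, drivers=drivers))
                elif st == cs and i == ci:
                    new_terms.append(
                        replace(t, coeff=t.coeff / s_mono, drivers=drivers)
                    )
                else:
                    new_terms.append(replace(t, drivers=drivers))
            eqs[smap[st]] = tuple(new_terms)

        removed = {w, s_par}
        anchors = [(n, min(sm.params.index(p) for p in new_vals[n].params))
                   for n in new_vals]
        order = _new_param_order(sm.params, removed, anchors)
        provenance = {n: sm.provenance[n] for n in order if n in sm.provenance}
        provenance.update(prov)
        out = StructuredModel(
            f"{sm.name}.renorm[{b}*{s_par}]", states, order, eqs,
            smap[sm.observable], provenance,
        )
        return _finish_structured(
            out, sm, params, new_vals, removed,
            f"renormalize decay-free {b} by {s_par}->inf",
        )

    return LimitRule("renormalized decay-free buffer", matches, apply)


def _rule_instant_input() -> LimitRule:
    """An input-driven gated node activates instantly (its rate -> inf).

    The node's transient collapses; downstream terms sense the stimulus
    directly (the saturated level is absorbed into their rates on
    recalibration).
    """

    def _find(sm, d):
        nf = d.nonfinite
        if len(nf) != 1:
            return None
        (r,) = nf
        if nf[r] != "inf":
            return None
        hits = sm.terms_with_param(r)
        if len(hits) != 1:
            return None
        a, i, t, where = hits[0]
        if (
            where != "coeff"
            or t.form != "gate_act"
            or t.drivers != ("I",)
            or len(sm.equations[a]) != 1
            or a == sm.observable
        ):
            return None
        return r, a

    def matches(model, d):
        sm = _structured(model)
        return sm is not None and _find(sm, d) is not None

    def apply(model, params, d):
        sm = _structured(model)
        r, a = _find(sm, d)
        states = tuple(st for st in sm.states if st != a)
        eqs = {}
        for st, terms in sm.equations.items():
            if st == a:
                continue
            eqs[st] = tuple(
                replace(
                    t,
                    drivers=tuple("I" if dv == a else dv for dv in t.drivers),
                )
                for t in terms
            )
        order = tuple(p for p in sm.params if p != r)
        provenance = {n: sm.provenance[n] for n in order}
        out = StructuredModel(
            f"{sm.name}.instant[{a}]", states, order, eqs, sm.observable,
            provenance,
        )
        return _finish_structured(
            out, sm, params, {}, {r}, f"instant input node {a} ({r}->inf)"
        )

    return LimitRule("instantly saturating input node (rate->inf)", matches, apply)


def default_registry() -> Registry:
    return Registry(
        [
            _rule_equilibrium(),
            _rule_irreversible(),
            _rule_qssa(),
            _rule_linearize(),
            _rule_saturate(),
            _rule_drop_term(),
            _rule_k_inf_vanish(),
            _rule_buffer_renorm(),
            _rule_buffer_rescale_K(),
            _rule_buffer_renorm_decay_free(),
            _rule_instant_input(),
        ]
    )


# ---------------------------------------------------------------------------
# Replayable reduction chains for the bundled motifs
# ---------------------------------------------------------------------------

# Each chain is the sequence of limits that carries a motif to its reduced
# zoo form, expressed as per-parameter verdict dictionaries.  Replaying a
# chain through the registry is deterministic and does not require geodesic
# success, so downstream analyses can rely on the reduced forms directly.
PAPER_CHAINS: dict[str, list[dict[str, str]]] = {
    "NFB_12->NFB_4": [
        {"kFA": "inf", "KFA": "inf"},
        {"kCB": "inf", "KCB": "inf"},
        {"kCB/KCB": "zero", "kFB": "zero", "KFB": "zero", "kBC": "inf"},
        {"kBC*kFB": "inf", "KFB*kBC": "inf"},
        {"kBC*kCB/KCB": "inf", "KBC": "inf"},
        {"KIA": "zero"},
        {"KAC": "zero"},
        {"kFA/KFA": "zero"},
    ],
    "NFB_4->NFB_2": [
        {"kIA": "inf"},
        {"kFB/KFB": "zero"},
    ],
    "IFFLP_12->IFFLP_4": [
        {"kFB": "inf", "KFB": "inf"},
        {"kFB/KFB": "zero"},
        {"kFA": "inf", "KFA": "inf"},
        {"kFA/KFA": "zero"},
        {"kBC": "inf", "KBC": "inf"},
        {"KIA": "zero"},
        {"KAB": "zero"},
        {"KAC": "zero"},
    ],
    "IFFLP_4->IFFLP_2": [
        {"kIA": "inf"},
        {"kAB": "zero", "kBC/KBC": "inf"},
    ],
}


def descriptor_from_verdicts(
    model: ODEModel, nonfinite: dict[str, str]
) -> LimitDescriptor:
    """Build a limit descriptor by hand (for replayed or user-stated limits)."""
    names = model.parameter_names
    unknown = set(nonfinite) - set(names)
    if unknown:
        raise KeyError(f"unknown parameters in limit: {sorted(unknown)}")
    verdicts = {p: nonfinite.get(p, "finite") for p in names}
    v = np.zeros(len(names))
    for i, p in enumerate(names):
        if verdicts[p] == "inf":
            v[i] = 1.0
        elif verdicts[p] == "zero":
            v[i] = -1.0
    nrm = np.linalg.norm(v)
    return LimitDescriptor(verdicts, v / nrm if nrm else v, names)


def replay_chain(
    model: ODEModel,
    params: ParameterVector,
    qoi: QoISpec,
    chain: str | list[dict[str, str]],
    registry: Registry | None = None,
    *,
    recalibrate: bool = True,
    seed: int = 0,
) -> list[tuple[ODEModel, "CalibrationResult | ParameterVector"]]:
    """Apply a prescribed sequence of limits, recalibrating after each.

    Returns the list of (reduced model, calibration result) per step; the
    last entry is the chain's terminal model.
    """
    registry = registry or default_registry()
    if isinstance(chain, str):
        chain = PAPER_CHAINS[chain]
    out = []
    current_model, current_params = model, params
    for nonfinite in chain:
        d = descriptor_from_verdicts(current_model, nonfinite)
        reduced, phi = apply_limit(current_model, current_params, d, registry)
        if recalibrate:
            y_parent = residuals(current_model, current_params, qoi) * qoi.sigmas
            calib = calibrate(reduced, y_parent, qoi, phi, seed=seed)
            out.append((reduced, calib))
            current_model, current_params = reduced, calib.phi
        else:
            out.append((reduced, phi))
            current_model, current_params = reduced, phi
    return out


def apply_limit(
    model: ODEModel,
    params: ParameterVector,
    descriptor: LimitDescriptor,
    registry: Registry | None = None,
) -> tuple[ODEModel, ParameterVector]:
    """Evaluate a classified limit through the registry."""
    registry = registry or default_registry()
    rule = registry.find(model, descriptor)
    if rule is None:
        raise UnmatchedLimitError(model.name, descriptor)
    return rule.apply(model, params, descriptor)


# ---------------------------------------------------------------------------
# Calibration (Eq. of least-squares recalibration) and identifiability
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    phi: ParameterVector
    cost: float
    converged: bool
    residuals: np.ndarray  # per-QoI (y_target - y_model)/sigma at phi*

    def to_dict(self) -> dict:
        return {
            "parameters": self.phi.as_dict(),
            "cost": self.cost,
            "converged": self.converged,
            "residuals": self.residuals.tolist(),
        }


def calibrate(
    model: ODEModel,
    y_target: np.ndarray,
    qoi: QoISpec,
    phi_init: ParameterVector,
    *,
    n_restarts: int = 3,
    seed: int = 0,
    sim_rtol: float = 1e-9,
    sim_atol: float = 1e-11,
) -> CalibrationResult:
    """Fit the reduced model's predictions to target predictions (Eq. 58).

    Minimizes sum_m ((y_m_target - y_m(phi)) / sigma_m)^2 over log-parameters
    phi, starting from the rule-provided guess; seeded multi-start jitter is
    used as a fallback when the first fit does not converge.
    """
    y_target = np.asarray(y_target, dtype=float)
    big = 1e6

    def fun(phi_vals):
        try:
            r = residuals(
                model, phi_init.with_values(phi_vals), qoi,
                rtol=sim_rtol, atol=sim_atol,
            )
        except IntegrationError:
            return np.full(qoi.m, big)
        return y_target / qoi.sigmas - r

    def run(x0):
        return least_squares(fun, x0, method="lm" if qoi.m >= len(phi_init) else "trf")

    best = run(phi_init.values)
    tried = 1
    rng = np.random.default_rng(seed)
    while (not best.success or 2 * best.cost > qoi.m) and tried <= n_restarts:
        sol = run(phi_init.values + 0.3 * rng.standard_normal(len(phi_init)))
        if sol.cost < best.cost:
            best = sol
        tried += 1
    f0 = fun(phi_init.values)
    cost0 = float(f0 @ f0)
    cost = float(2 * best.cost)
    if cost > cost0:  # minimizer contract: never worse than the guess
        return CalibrationResult(phi_init, cost0, False, f0)
    return CalibrationResult(
        phi_init.with_values(best.x), cost, bool(best.success), best.fun
    )


def identifiability_check(
    model: ODEModel,
    params: ParameterVector,
    qoi: QoISpec,
    lambda_star: float = 1.0,
    fd: FDOptions | None = None,
) -> tuple[bool, np.ndarray]:
    """All FIM eigenvalues >= lambda_star?

    The default lambda_star = 1 in log-parameter space corresponds to a
    standard relative parameter error of a factor e.
    """
    fd = fd or FDOptions()
    J = jacobian(model, params, qoi, fd)
    w = spectrum(fim(J, params.names, qoi)).eigenvalues
    return bool(np.all(w >= lambda_star)), w


# ---------------------------------------------------------------------------
# The iterated MBAM loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MBAMOptions:
    geodesic: GeodesicOptions = field(default_factory=GeodesicOptions)
    lambda_star: float = 1.0
    target_n_params: int | None = None
    max_steps: int = 20
    calibration_restarts: int = 3
    seed: int = 0
    fd: FDOptions = field(default_factory=lambda: FDOptions(h=1e-3))


@dataclass
class ReductionStep:
    model_name: str
    spectrum_before: Spectrum
    path_summary: dict
    descriptor: LimitDescriptor
    rule_name: str
    calibration: CalibrationResult
    spectrum_after: Spectrum
    reduced_name: str

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "eigenvalues_before": self.spectrum_before.eigenvalues.tolist(),
            "geodesic": self.path_summary,
            "limit": self.descriptor.to_dict(),
            "rule": self.rule_name,
            "calibration": self.calibration.to_dict(),
            "eigenvalues_after": self.spectrum_after.eigenvalues.tolist(),
            "reduced_model": self.reduced_name,
        }


@dataclass
class ReductionReport:
    steps: list[ReductionStep]
    stop_reason: str
    final_model: ODEModel
    final_params: ParameterVector
    final_eigenvalues: np.ndarray

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "stop_reason": self.stop_reason,
            "final_model": self.final_model.name,
            "final_parameters": self.final_params.as_dict(),
            "final_eigenvalues": self.final_eigenvalues.tolist(),
        }


def _path_summary(path: GeodesicPath) -> dict:
    return {
        "tau_end": float(path.taus[-1]),
        "termination": path.termination,
        "final_unit_velocity": path.final_unit_velocity.tolist(),
        "lambda_min_end": float(path.lambda_min[-1]),
        "lambda_next_end": float(path.lambda_next[-1]),
        **{k: v for k, v in path.diagnostics.items() if k != "error"},
    }


def mbam_run(
    model: ODEModel,
    params: ParameterVector,
    qoi: QoISpec,
    registry: Registry | None = None,
    options: MBAMOptions | None = None,
    progress=None,
) -> ReductionReport:
    """Iterate spectrum -> geodesic -> limit -> recalibration.

    Stops when all parameters are identifiable at ``lambda_star``, when the
    target parameter count is reached, or when the geodesic/limit machinery
    cannot continue (no boundary, unmatched limit, singular metric); every
    step is recorded in the report.
    """
    registry = registry or default_registry()
    opts = options or MBAMOptions()
    current_model, current_params = model, params
    steps: list[ReductionStep] = []
    stop = "max-steps"

    for _ in range(opts.max_steps):
        J = jacobian(current_model, current_params, qoi, opts.fd)
        spec_before = spectrum(fim(J, current_params.names, qoi))
        w = spec_before.eigenvalues
        if np.all(w >= opts.lambda_star):
            stop = "identifiable"
            break
        if (
            opts.target_n_params is not None
            and len(current_params) <= opts.target_n_params
        ):
            stop = "target-size"
            break
        try:
            path = integrate_geodesic(current_model, current_params, qoi, opts.geodesic)
        except ValueError as err:
            stop = f"singular-metric: {err}"
            break
        if path.termination == "curvature-lost":
            stop = (
                "curvature-lost: " + path.diagnostics.get("hint", "restart by hand")
            )
            break
        if path.termination == "solver-failure":
            stop = "geodesic-failure: " + path.diagnostics.get("error", "")
            break
        if path.termination == "max-tau":
            stop = "no-boundary-before-max-tau"
            break
        # Candidate limits in preference order: the full classification at a
        # few thresholds first, then -- since a geodesic can run into a
        # corner where several boundary faces meet -- one face at a time,
        # starting from the fastest-moving parameter combinations.
        candidates: list[LimitDescriptor] = []
        seen_limits: set = set()

        def push(cand: LimitDescriptor) -> None:
            key = tuple(sorted(cand.nonfinite.items()))
            if cand.nonfinite and key not in seen_limits:
                seen_limits.add(key)
                candidates.append(cand)

        for scale in (1.0, 1.5, 2.0, 0.6):
            push(classify_limit(path, opts.geodesic.component_threshold * scale))
        full = classify_limit(path, opts.geodesic.component_threshold)
        vhat = dict(zip(full.parameter_names, full.final_unit_velocity))
        ranked = sorted(full.nonfinite, key=lambda p: -abs(vhat[p]))
        subsets = [ranked[:k] for k in range(len(ranked) - 1, 1, -1)]
        subsets += [[p] for p in ranked]
        for chosen in subsets:
            sub = dict.fromkeys(chosen)
            verdicts = {
                p: (full.verdicts[p] if p in sub else "finite")
                for p in full.parameter_names
            }
            push(
                LimitDescriptor(
                    verdicts, full.final_unit_velocity, full.parameter_names,
                    full.grouping,
                )
            )

        y_parent = residuals(current_model, current_params, qoi) * qoi.sigmas
        accepted = None
        rejections = []
        for cand in candidates:
            rule = registry.find(current_model, cand)
            if rule is None:
                continue
            reduced, phi_init = rule.apply(current_model, current_params, cand)
            calib = calibrate(
                reduced, y_parent, qoi, phi_init,
                n_restarts=opts.calibration_restarts, seed=opts.seed,
            )
            if calib.cost <= qoi.m:
                accepted = (cand, rule, reduced, calib)
                break
            # this face breaks the sigma band here; try the next candidate
            rejections.append((rule.name, cand.nonfinite, calib.cost))
        if accepted is None:
            reason = (
                "unmatched-limit: " + str(full.nonfinite)
                if not rejections
                else "step-rejected: every matching limit exceeds the sigma "
                f"band (M = {qoi.m}): "
                + "; ".join(f"{r} {nf} cost={c:.3g}" for r, nf, c in rejections)
            )
            return ReductionReport(steps, reason, current_model, current_params, w)
        descriptor, rule, reduced, calib = accepted
        J_after = jacobian(reduced, calib.phi, qoi, opts.fd)
        spec_after = spectrum(fim(J_after, calib.phi.names, qoi))
        steps.append(
            ReductionStep(
                current_model.name, spec_before, _path_summary(path), descriptor,
                rule.name, calib, spec_after, reduced.name,
            )
        )
        if progress is not None:
            progress(steps[-1])
        current_model, current_params = reduced, calib.phi
    final_J = jacobian(current_model, current_params, qoi, opts.fd)
    final_w = spectrum(fim(final_J, current_params.names, qoi)).eigenvalues
    return ReductionReport(steps, stop, current_model, current_params, final_w)
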