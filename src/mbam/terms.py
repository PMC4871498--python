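"""A small structured term language for three-node regulatory motifs.

The adaptation models (negative feedback loop with buffer node, incoherent
feed-forward loop with proportioner node, and the reduced ERK/P90 system)
are all sums of terms of the shape

    sign * coeff * (product of drivers) * f(x)

where ``x`` is the equation's own state, ``coeff`` is a monomial in the
positive parameters (times a fixed constant such as an external inhibition
F_A), and ``f`` is one of a handful of kinetic forms:

    mm_act   (1 - x) / ((1 - x) + K)     saturating activation
    mm_inh   x / (x + K)                 saturating inhibition/decay
    lin_act  (1 - x)                     linearized activation
    lin_inh  x                           linearized decay
    gate_act Theta(1 - x)                zero-order activation, hard cap at 1
    bare     1                           driver-only production

Representing models structurally (rather than as opaque callables) is what
lets the reduction registry *evaluate parameter limits mechanically*:
linearizing a Michaelis-Menten term, deleting a vanishing term, hardening a
saturation into a Heaviside gate, or renormalizing a buffer node are all
local rewrites of this term list.  Each rewrite records the provenance of
any new lumped parameter as a monomial in the root model's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import ODEModel

__all__ = ["Mono", "Term", "StructuredModel"]

FORMS = ("mm_act", "mm_inh", "lin_act", "lin_inh", "gate_act", "bare")


@dataclass(frozen=True)
class Mono:
    """A monomial const * prod(param ** exponent) over named parameters."""

    powers: tuple[tuple[str, int], ...] = ()
    const: float = 1.0

    @staticmethod
    def of(*params: str, const: float = 1.0, **expo: int) -> "Mono":
        d: dict[str, int] = {}
        for p in params:
            d[p] = d.get(p, 0) + 1
        for p, e in expo.items():
            d[p] = d.get(p, 0) + e
        return Mono(tuple(sorted((p, e) for p, e in d.items() if e != 0)), const)

    def value(self, k: dict) -> float:
        v = self.const
        for p, e in self.powers:
            v *= k[p] ** e
        return v

    @property
    def params(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.powers)

    def exponent(self, p: str) -> int:
        return dict(self.powers).get(p, 0)

    def __mul__(self, other: "Mono") -> "Mono":
        d = dict(self.powers)
        for p, e in other.powers:
            d[p] = d.get(p, 0) + e
        return Mono(
            tuple(sorted((p, e) for p, e in d.items() if e != 0)),
            self.const * other.const,
        )

    def __truediv__(self, other: "Mono") -> "Mono":
        inv = Mono(tuple((p, -e) for p, e in other.powers), 1.0 / other.const)
        return self * inv

    def substitute(self, table: dict[str, "Mono"]) -> "Mono":
        """Rewrite every parameter through ``table`` (identity if absent)."""
        out = Mono((), self.const)
        for p, e in self.powers:
            base = table.get(p, Mono.of(p))
            expanded = Mono(tuple((q, f * e) for q, f in base.powers), base.const**e)
            out = out * expanded
        return out

    def name(self) -> str:
        """Canonical readable name, e.g. ``kCB*kBC/(KCB*KBC)``."""
        num = [p if e == 1 else f"{p}^{e}" for p, e in self.powers if e > 0]
        den = [p if e == -1 else f"{p}^{-e}" for p, e in self.powers if e < 0]
        top = "*".join(num) if num else "1"
        if not den:
            return top
        bot = "*".join(den)
        return f"{top}/({bot})" if len(den) > 1 else f"{top}/{bot}"


@dataclass(frozen=True)
class Term:
    sign: int
    coeff: Mono
    drivers: tuple[str, ...] = ()  # state names and/or "I" (the input)
    form: str = "bare"
    K: Mono | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown kinetic form {self.form!r}")
        if self.form.startswith("mm") and self.K is None:
            raise ValueError("Michaelis-Menten forms require a constant K")

    def signature(self) -> tuple:
        return (self.sign, self.form, tuple(sorted(self.drivers)))


@dataclass
class StructuredModel:
    """A motif model as an ordered set of per-state term lists."""

    name: str
    states: tuple[str, ...]
    params: tuple[str, ...]
    equations: dict[str, tuple[Term, ...]]
    observable: str
    provenance: dict[str, Mono] = field(default_factory=dict)

    def __post_init__(self) -> None:
        used = set()
        for terms in self.equations.values():
            for t in terms:
                used |= t.coeff.params
                if t.K is not None:
                    used |= t.K.params
        missing = used - set(self.params)
        if missing:
            raise ValueError(f"terms reference undeclared parameters {missing}")
        for p in self.params:
            self.provenance.setdefault(p, Mono.of(p))

    # -- compile to a simulatable ODEModel --------------------------------
    def to_ode(self) -> ODEModel:
        states = self.states
        idx = {s: i for i, s in enumerate(states)}
        eqs = [(idx[s], self.equations[s]) for s in states]
        caps = {
            s: 1.0
            for s in states
            if any(t.form == "gate_act" for t in self.equations[s])
        }

        def rhs(t, x, k, u, gates):
            # x rows may be scalars or arrays (stacked parameter copies)
            out = []
            for si, terms in eqs:
                xv = x[si]
                acc = 0.0 * xv
                for term in terms:
                    v = term.coeff.value(k)
                    for d in term.drivers:
                        v = v * (u if d == "I" else x[idx[d]])
                    f = term.form
                    if f == "mm_act":
                        one_m = 1.0 - xv
                        v = v * one_m / (one_m + term.K.value(k))
                    elif f == "mm_inh":
                        # tiny floor guards the 0/0 at (x, K) = (0, 0)
                        v = v * xv / (xv + term.K.value(k) + 1e-300)
                    elif f == "lin_act":
                        v = v * (1.0 - xv)
                    elif f == "lin_inh":
                        v = v * xv
                    elif f == "gate_act":
                        v = v * gates[si]
                    acc = acc + term.sign * v
                out.append(acc)
            return np.array(out)

        observables = {
            s: (lambda states_mat, k, i=idx[s]: states_mat[:, i]) for s in states
        }

        model = ODEModel(
            name=self.name,
            state_names=states,
            parameter_names=self.params,
            rhs=rhs,
            initial_state=lambda k: np.zeros(len(states)),
            observables=observables,
            caps=caps,
            meta={"structured": self},
        )
        return model

    # -- structural comparison -------------------------------------------
    def signature(self) -> dict[str, tuple]:
        return {
            s: tuple(sorted(t.signature() for t in terms))
            for s, terms in self.equations.items()
        }

    def same_structure(self, other: "StructuredModel") -> bool:
        return (
            set(self.states) == set(other.states)
            and self.signature() == other.signature()
        )

    def rename(self, name: str) -> "StructuredModel":
        return StructuredModel(
            name, self.states, self.params, dict(self.equations), self.observable,
            dict(self.provenance),
        )

    def terms_with_param(self, p: str) -> list[tuple[str, int, Term, str]]:
        """All (state, position, term, where) mentions of parameter ``p``.

        ``where`` is ``"coeff"`` or ``"K"``.
        """
        hits = []
        for s, terms in self.equations.items():
            for i, t in enumerate(terms):
                if p in t.coeff.params:
                    hits.append((s, i, t, "coeff"))
                if t.K is not None and p in t.K.params:
                    hits.append((s, i, t, "K"))
        return hits

    def replace_term(self, state: str, pos: int, new: Term | None) -> dict[str, tuple[Term, ...]]:
        eqs = dict(self.equations)
        terms = list(eqs[state])
        if new is None:
            terms.pop(pos)
        else:
            terms[pos] = new
        eqs[state] = tuple(terms)
        return eqs
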