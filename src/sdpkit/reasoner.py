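"""Completion-rule saturation, classification, and derivation traces.

The calculus is the standard EL⊥ rule set over the normal forms produced by
:mod:`sdpkit.normalize`:

* init  ``A ∈ S(A)`` and ``⊤ ∈ S(A)`` for every class name ``A``
* R1    ``A' ∈ S(A)``, ``A' ⊑ B``             ⇒ ``B ∈ S(A)``
* R2    ``A1, A2 ∈ S(A)``, ``A1 ⊓ A2 ⊑ B``    ⇒ ``B ∈ S(A)``
* R3    ``A' ∈ S(A)``, ``A' ⊑ ∃r.B``          ⇒ ``(A,B) ∈ R(r)``
* R4    ``(A,B) ∈ R(r)``, ``B' ∈ S(B)``, ``∃r.B' ⊑ C`` ⇒ ``C ∈ S(A)``
* R5    ``(A,B) ∈ R(r)``, ``⊥ ∈ S(B)``        ⇒ ``⊥ ∈ S(A)``
* R6    ``(A,B) ∈ R(r)``, ``r ⊑ s``           ⇒ ``(A,B) ∈ R(s)``
* R7    ``(A,B), (B,C) ∈ R(r)``, r transitive ⇒ ``(A,C) ∈ R(r)``

Role domains participate through their ``∃r.⊤ ⊑ D`` normal form and R4.
The role hierarchy is closed reflexively–transitively up front, so R6 fires
through chains of declared inclusions in one step.  Transitivity applies to
the declared role only, never to its sub-roles.

Saturation runs a FIFO worklist over indexed axioms; the resulting fixpoint
is independent of processing order (a tested property, not an assumption).
Every derived fact records its first derivation, which :func:`explain` turns
into a replayable :class:`DerivationTrace`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import NotEntailedError, UnknownNameError
from .model import BOT, FRESH_PREFIX, TOP, EntityName, Ontology
from .normalize import NormalizedAxiomSet, normalize

# Facts are tuples: ("sub", A, B) for B ∈ S(A); ("rel", r, A, B) for
# (A,B) ∈ R(r).  Axiom premises: ("ax_atomic", A, B), ("ax_conj", A1, A2, B),
# ("ax_ei", A, r, B), ("ax_ee", r, A, B), ("ax_ri", r, s), ("ax_tr", r).
Fact = tuple


def role_closure(norm: NormalizedAxiomSet) -> dict[EntityName, tuple[EntityName, ...]]:
    """Reflexive–transitive closure of the declared role inclusions."""
    roles = norm.role_names()
    g = nx.DiGraph()
    g.add_nodes_from(roles)
    g.add_edges_from(norm.role_inclusions)
    return {
        r: tuple(sorted(nx.descendants(g, r) | {r})) for r in roles
    }


@dataclass
class SaturationState:
    """Derived subsumer sets S and role-successor sets R, with provenance."""

    S: dict[EntityName, set[EntityName]]
    R: dict[EntityName, set[tuple[EntityName, EntityName]]]
    provenance: dict[Fact, tuple[str, tuple[Fact, ...]]]
    closure: dict[EntityName, tuple[EntityName, ...]]

    def subsumers(self, a: EntityName) -> set[EntityName]:
        return self.S.get(a, {a, TOP})

    def successors(self, role: EntityName, a: EntityName) -> set[EntityName]:
        return {b for (x, b) in self.R.get(role, set()) if x == a}


def saturate(norm: NormalizedAxiomSet) -> SaturationState:
    """Run the completion rules to their least fixpoint."""
    closure = role_closure(norm)

    # indexes over the normalized axioms
    atomic_by_lhs: dict[EntityName, list[EntityName]] = {}
    for a, b in norm.atomic:
        atomic_by_lhs.setdefault(a, []).append(b)
    conj_by_operand: dict[EntityName, list[tuple[EntityName, EntityName, EntityName]]] = {}
    for a1, a2, b in norm.conjunctive:
        conj_by_operand.setdefault(a1, []).append((a1, a2, b))
        if a2 != a1:
            conj_by_operand.setdefault(a2, []).append((a1, a2, b))
    ei_by_lhs: dict[EntityName, list[tuple[EntityName, EntityName]]] = {}
    for a, r, b in norm.exist_intro:
        ei_by_lhs.setdefault(a, []).append((r, b))
    ee_by_role_filler: dict[tuple[EntityName, EntityName], list[EntityName]] = {}
    for r, a, b in norm.exist_elim:
        ee_by_role_filler.setdefault((r, a), []).append(b)

    S: dict[EntityName, set[EntityName]] = {}
    R: dict[EntityName, set[tuple[EntityName, EntityName]]] = {
        r: set() for r in norm.role_names()
    }
    rpred: dict[EntityName, set[tuple[EntityName, EntityName]]] = {}  # B -> {(r, A)}
    rsucc: dict[tuple[EntityName, EntityName], set[EntityName]] = {}  # (r, A) -> {B}
    provenance: dict[Fact, tuple[str, tuple[Fact, ...]]] = {}
    queue: deque[Fact] = deque()

    def add_sub(a: EntityName, b: EntityName, rule: str, premises: tuple[Fact, ...]) -> None:
        bucket = S.setdefault(a, set())
        if b not in bucket:
            bucket.add(b)
            fact = ("sub", a, b)
            provenance[fact] = (rule, premises)
            queue.append(fact)

    def add_rel(r: EntityName, a: EntityName, b: EntityName, rule: str,
                premises: tuple[Fact, ...]) -> None:
        base = ("rel", r, a, b)
        for s in closure[r]:
            pairs = R.setdefault(s, set())
            if (a, b) in pairs:
                continue
            pairs.add((a, b))
            rpred.setdefault(b, set()).add((s, a))
            rsucc.setdefault((s, a), set()).add(b)
            fact = ("rel", s, a, b)
            if s == r:
                provenance[fact] = (rule, premises)
            else:
                provenance[fact] = ("R6", (base, ("ax_ri", r, s)))
            queue.append(fact)

    for a in sorted(norm.class_names()):
        add_sub(a, a, "init", ())
        if a != TOP:
            add_sub(a, TOP, "init", ())

    while queue:
        fact = queue.popleft()
        if fact[0] == "sub":
            _, a, bp = fact
            for b2 in atomic_by_lhs.get(bp, ()):  # R1
                add_sub(a, b2, "R1", (fact, ("ax_atomic", bp, b2)))
            for a1, a2, b2 in conj_by_operand.get(bp, ()):  # R2
                other = a2 if bp == a1 else a1
                if other in S.get(a, ()):
                    add_sub(a, b2, "R2",
                            (("sub", a, a1), ("sub", a, a2), ("ax_conj", a1, a2, b2)))
            for r, b2 in ei_by_lhs.get(bp, ()):  # R3
                add_rel(r, a, b2, "R3", (fact, ("ax_ei", bp, r, b2)))
            # the class `a` just gained subsumer bp; as a role *target* this
            # can fire R4/R5 for its predecessors
            for r, a0 in rpred.get(a, set()).copy():
                for c in ee_by_role_filler.get((r, bp), ()):  # R4
                    add_sub(a0, c, "R4",
                            (("rel", r, a0, a), fact, ("ax_ee", r, bp, c)))
                if bp == BOT:  # R5
                    add_sub(a0, BOT, "R5", (("rel", r, a0, a), fact))
        else:
            _, r, a, b = fact
            for bp in S.get(b, set()).copy():  # R4
                for c in ee_by_role_filler.get((r, bp), ()):
                    add_sub(a, c, "R4", (fact, ("sub", b, bp), ("ax_ee", r, bp, c)))
            if BOT in S.get(b, ()):  # R5
                add_sub(a, BOT, "R5", (fact, ("sub", b, BOT)))
            if r in norm.transitive_roles:  # R7, both join directions
                for c in rsucc.get((r, b), set()).copy():
                    add_rel(r, a, c, "R7", (fact, ("rel", r, b, c), ("ax_tr", r)))
                for z, x in rpred.get(a, set()).copy():
                    if z == r:
                        add_rel(r, x, b, "R7",
                                (("rel", r, x, a), fact, ("ax_tr", r)))

    return SaturationState(S=S, R=R, provenance=provenance, closure=closure)


# ---------------------------------------------------------------------------
# Reasoner facade
# ---------------------------------------------------------------------------


class Reasoner:
    """Normalizes and saturates an ontology once; answers queries off the
    fixpoint."""

    def __init__(self, ont: Ontology):
        ont.validate()
        self.ontology = ont
        self.norm = normalize(ont)
        self.state = saturate(self.norm)

    # -- queries -------------------------------------------------------------

    def _require(self, n: EntityName) -> None:
        if not (n in self.ontology.classes or n in (TOP, BOT)):
            raise UnknownNameError(f"unknown class name: {n}")

    def is_subsumed(self, sub: EntityName, sup: EntityName) -> bool:
        self._require(sub)
        self._require(sup)
        subsumers = self.state.subsumers(sub)
        return sup in subsumers or BOT in subsumers

    def is_unsatisfiable(self, cls: EntityName) -> bool:
        self._require(cls)
        return BOT in self.state.subsumers(cls)

    def unsatisfiable_classes(self) -> set[EntityName]:
        return {a for a in self.ontology.classes if BOT in self.state.subsumers(a)}

    def equivalent(self, a: EntityName, b: EntityName) -> bool:
        return self.is_subsumed(a, b) and self.is_subsumed(b, a)

    def entailed_pairs(self) -> set[tuple[EntityName, EntityName]]:
        """All derived pairs (A, B) with B ∈ S(A), restricted to declared
        names plus owl:Thing/owl:Nothing (fresh names filtered out)."""
        declared = self.ontology.classes | {TOP, BOT}
        out: set[tuple[EntityName, EntityName]] = set()
        for a in self.ontology.classes:
            for b in self.state.subsumers(a):
                if b in declared:
                    out.add((a, b))
        return out


def is_subsumed(ont: Ontology, sub: EntityName, sup: EntityName) -> bool:
    """True iff ``sub ⊑ sup`` is entailed (an unsatisfiable ``sub`` is below
    everything)."""
    return Reasoner(ont).is_subsumed(sub, sup)


def unsatisfiable_classes(ont: Ontology) -> set[EntityName]:
    """Declared class names with ``owl:Nothing`` among their subsumers."""
    return Reasoner(ont).unsatisfiable_classes()


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """Equivalence-collapsed, transitively reduced subsumption DAG."""

    groups: dict[EntityName, tuple[EntityName, ...]]  # representative -> members
    direct_sup: dict[EntityName, tuple[EntityName, ...]]  # on representatives
    unsatisfiable: frozenset[EntityName]

    def representative(self, cls: EntityName) -> EntityName:
        for rep, members in self.groups.items():
            if cls in members:
                return rep
        raise UnknownNameError(f"unknown class name: {cls}")

    def to_tsv(self) -> str:
        lines = ["sub\tdirect_sup"]
        for rep in sorted(self.groups):
            sups = self.direct_sup[rep] or (TOP,)
            for member in self.groups[rep]:
                for sup in sups:
                    lines.append(f"{member}\t{sup}")
        for cls in sorted(self.unsatisfiable):
            lines.append(f"{cls}\t{BOT}")
        return "\n".join(lines) + "\n"


def classify(ont: Ontology) -> Taxonomy:
    """Group mutually subsuming classes, reduce transitively, flag
    unsatisfiable names.  Fresh normalization names never appear."""
    r = Reasoner(ont)
    declared = sorted(n for n in ont.classes if n.prefix != FRESH_PREFIX)
    unsat = frozenset(n for n in declared if BOT in r.state.subsumers(n))
    sat = [n for n in declared if n not in unsat]

    g = nx.DiGraph()
    g.add_nodes_from(sat)
    for a in sat:
        for b in r.state.subsumers(a):
            if b != a and b in g:
                g.add_edge(a, b)
    groups: dict[EntityName, tuple[EntityName, ...]] = {}
    rep_of: dict[EntityName, EntityName] = {}
    for comp in nx.strongly_connected_components(g):
        members = tuple(sorted(comp))
        rep = members[0]
        groups[rep] = members
        for m in members:
            rep_of[m] = rep
    dag = nx.DiGraph()
    dag.add_nodes_from(groups)
    for a, b in g.edges:
        ra, rb = rep_of[a], rep_of[b]
        if ra != rb:
            dag.add_edge(ra, rb)
    reduced = nx.transitive_reduction(dag)
    direct = {rep: tuple(sorted(reduced.successors(rep))) for rep in groups}
    return Taxonomy(groups=groups, direct_sup=direct, unsatisfiable=unsat)


# ---------------------------------------------------------------------------
# Derivation traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceStep:
    rule: str
    premises: tuple[Fact, ...]
    conclusion: Fact


@dataclass
class DerivationTrace:
    """Ordered rule applications ending in the queried subsumption."""

    steps: list[TraceStep] = field(default_factory=list)

    @property
    def conclusion(self) -> Fact:
        return self.steps[-1].conclusion

    def to_json_obj(self) -> list[dict]:
        return [
            {
                "rule": s.rule,
                "premises": [render_fact(p) for p in s.premises],
                "conclusion": render_fact(s.conclusion),
            }
            for s in self.steps
        ]


def render_fact(fact: Fact) -> str:
    kind = fact[0]
    if kind == "sub":
        return f"{fact[1]} ⊑ {fact[2]}"
    if kind == "rel":
        return f"({fact[2]}, {fact[3]}) ∈ R({fact[1]})"
    if kind == "ax_atomic":
        return f"axiom: {fact[1]} ⊑ {fact[2]}"
    if kind == "ax_conj":
        return f"axiom: {fact[1]} ⊓ {fact[2]} ⊑ {fact[3]}"
    if kind == "ax_ei":
        return f"axiom: {fact[1]} ⊑ ∃{fact[2]}.{fact[3]}"
    if kind == "ax_ee":
        return f"axiom: ∃{fact[1]}.{fact[2]} ⊑ {fact[3]}"
    if kind == "ax_ri":
        return f"role axiom: {fact[1]} ⊑ {fact[2]}"
    if kind == "ax_tr":
        return f"role axiom: transitive({fact[1]})"
    return repr(fact)


def _collect_steps(state: SaturationState, goal: Fact) -> list[TraceStep]:
    """Back-chain through provenance, emitting steps in dependency order."""
    steps: list[TraceStep] = []
    emitted: set[Fact] = set()

    def visit(fact: Fact) -> None:
        if fact in emitted:
            return
        rule, premises = state.provenance[fact]
        for p in premises:
            if p[0] in ("sub", "rel"):
                visit(p)
        emitted.add(fact)
        steps.append(TraceStep(rule=rule, premises=premises, conclusion=fact))

    visit(goal)
    return steps


def explain(ont: Ontology, sub: EntityName, sup: EntityName) -> DerivationTrace:
    """A replayable derivation of ``sub ⊑ sup``.

    Raises :class:`NotEntailedError` when the subsumption does not hold.
    """
    r = Reasoner(ont)
    if not r.is_subsumed(sub, sup):
        raise NotEntailedError(f"{sub} ⊑ {sup} is not entailed")
    subsumers = r.state.subsumers(sub)
    if sup in subsumers:
        steps = _collect_steps(r.state, ("sub", sub, sup))
    else:  # entailed only through unsatisfiability of sub
        steps = _collect_steps(r.state, ("sub", sub, BOT))
        steps.append(
            TraceStep(rule="bottom", premises=(("sub", sub, BOT),),
                      conclusion=("sub", sub, sup))
        )
    return DerivationTrace(steps=steps)


def replay_trace(norm: NormalizedAxiomSet, trace: DerivationTrace, goal: Fact) -> bool:
    """Independently validate a trace: every premise must be a normalized
    axiom or a prior conclusion, every step a correct rule application, and
    the final conclusion the goal."""
    axioms: set[Fact] = set()
    axioms.update(("ax_atomic", a, b) for a, b in norm.atomic)
    axioms.update(("ax_conj", a1, a2, b) for a1, a2, b in norm.conjunctive)
    axioms.update(("ax_ei", a, r, b) for a, r, b in norm.exist_intro)
    axioms.update(("ax_tr", r) for r in norm.transitive_roles)
    axioms.update(("ax_ee", r, a, b) for r, a, b in norm.exist_elim)
    closure = role_closure(norm)
    derived: set[Fact] = set()

    def have(fact: Fact) -> bool:
        if fact[0] in ("sub", "rel"):
            return fact in derived
        if fact[0] == "ax_ri":  # accepted through the precomputed closure
            return fact[2] in closure.get(fact[1], ())
        return fact in axioms

    for step in trace.steps:
        if not all(have(p) for p in step.premises):
            return False
        if not _valid_application(step):
            return False
        derived.add(step.conclusion)
    return trace.steps[-1].conclusion == goal if trace.steps else False


def _valid_application(step: TraceStep) -> bool:
    r, p, c = step.rule, step.premises, step.conclusion
    if r == "init":
        return c[0] == "sub" and (c[2] == c[1] or c[2] == TOP)
    if r == "R1":
        return (len(p) == 2 and p[0][0] == "sub" and p[1][0] == "ax_atomic"
                and p[0][2] == p[1][1] and c == ("sub", p[0][1], p[1][2]))
    if r == "R2":
        return (len(p) == 3 and p[0][0] == p[1][0] == "sub"
                and p[0][1] == p[1][1] and p[2][0] == "ax_conj"
                and {p[0][2], p[1][2]} >= {p[2][1], p[2][2]}
                and c == ("sub", p[0][1], p[2][3]))
    if r == "R3":
        return (len(p) == 2 and p[0][0] == "sub" and p[1][0] == "ax_ei"
                and p[0][2] == p[1][1]
                and c == ("rel", p[1][2], p[0][1], p[1][3]))
    if r == "R4":
        return (len(p) == 3 and p[0][0] == "rel" and p[1][0] == "sub"
                and p[2][0] == "ax_ee" and p[0][1] == p[2][1]
                and p[0][3] == p[1][1] and p[1][2] == p[2][2]
                and c == ("sub", p[0][2], p[2][3]))
    if r == "R5":
        return (len(p) == 2 and p[0][0] == "rel" and p[1] == ("sub", p[0][3], BOT)
                and c == ("sub", p[0][2], BOT))
    if r == "R6":
        return (len(p) == 2 and p[0][0] == "rel" and p[1][0] == "ax_ri"
                and p[0][1] == p[1][1]
                and c == ("rel", p[1][2], p[0][2], p[0][3]))
    if r == "R7":
        return (len(p) == 3 and p[0][0] == p[1][0] == "rel"
                and p[2][0] == "ax_tr" and p[0][1] == p[1][1] == p[2][1]
                and p[0][3] == p[1][2]
                and c == ("rel", p[0][1], p[0][2], p[1][3]))
    if r == "bottom":
        return (len(p) == 1 and p[0][0] == "sub" and p[0][2] == BOT
                and c[0] == "sub" and c[1] == p[0][1])
    return False
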