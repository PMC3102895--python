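"""Structural normalization of an ontology into EL normal forms.

Every class axiom is decomposed, with fresh names where needed, into the
four normal forms the completion calculus consumes:

* atomic inclusion         ``A ⊑ B``
* conjunctive inclusion    ``A1 ⊓ A2 ⊑ B``
* existential introduction ``A ⊑ ∃r.B``
* existential elimination  ``∃r.A ⊑ B``

where every slot holds a named class, ``owl:Thing`` or ``owl:Nothing``.
Role inclusions and transitivity marks pass through; a role domain becomes
``∃r.⊤ ⊑ D``; ``DisjointClasses`` becomes pairwise ``A ⊓ B ⊑ ⊥``;
``EquivalentClasses`` splits into two inclusions (pairwise against the first
operand when more than two are given).  Guard and covering declarations are
not part of the calculus and are ignored here.

The transformation is a conservative extension: entailments over the
original signature are unchanged, and normalizing an already-normal ontology
introduces no fresh names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    BOT,
    FRESH_PREFIX,
    TOP,
    Bottom,
    ClassExpression,
    Conjunction,
    DisjointClasses,
    EntityName,
    EquivalentClasses,
    Existential,
    Named,
    Ontology,
    RoleDomain,
    SubClassOf,
    Top,
    TransitiveRole,
)


@dataclass
class NormalizedAxiomSet:
    """The four class-axiom normal forms plus the role box."""

    atomic: list[tuple[EntityName, EntityName]] = field(default_factory=list)
    conjunctive: list[tuple[EntityName, EntityName, EntityName]] = field(default_factory=list)
    exist_intro: list[tuple[EntityName, EntityName, EntityName]] = field(default_factory=list)
    exist_elim: list[tuple[EntityName, EntityName, EntityName]] = field(default_factory=list)
    role_inclusions: list[tuple[EntityName, EntityName]] = field(default_factory=list)
    transitive_roles: set[EntityName] = field(default_factory=set)
    fresh_names: list[EntityName] = field(default_factory=list)
    declared_classes: set[EntityName] = field(default_factory=set)
    declared_roles: set[EntityName] = field(default_factory=set)

    def class_names(self) -> set[EntityName]:
        """All class names occurring anywhere, fresh ones included."""
        out = set(self.declared_classes) | set(self.fresh_names) | {TOP, BOT}
        for a, b in self.atomic:
            out.update((a, b))
        for a1, a2, b in self.conjunctive:
            out.update((a1, a2, b))
        for a, _, b in self.exist_intro:
            out.update((a, b))
        for _, a, b in self.exist_elim:
            out.update((a, b))
        return out

    def role_names(self) -> set[EntityName]:
        out = set(self.declared_roles)
        for _, r, _ in self.exist_intro:
            out.add(r)
        for r, _, _ in self.exist_elim:
            out.add(r)
        for r, s in self.role_inclusions:
            out.update((r, s))
        out |= self.transitive_roles
        return out

    def size(self) -> int:
        return (
            len(self.atomic)
            + len(self.conjunctive)
            + len(self.exist_intro)
            + len(self.exist_elim)
            + len(self.role_inclusions)
            + len(self.transitive_roles)
        )


class _Normalizer:
    def __init__(self) -> None:
        self.out = NormalizedAxiomSet()
        self._counter = 0
        self._seen: set[tuple] = set()

    def fresh(self) -> EntityName:
        self._counter += 1
        n = EntityName(FRESH_PREFIX, f"X{self._counter}")
        self.out.fresh_names.append(n)
        return n

    # -- emission (deduplicated, order-preserving) ---------------------------

    def _emit(self, bucket: list, key: tuple) -> None:
        tagged = (id(bucket), key)
        if tagged not in self._seen:
            self._seen.add(tagged)
            bucket.append(key)

    def emit_atomic(self, a: EntityName, b: EntityName) -> None:
        if b == TOP or a == BOT or a == b:
            return  # tautology
        self._emit(self.out.atomic, (a, b))

    def emit_conj(self, a1: EntityName, a2: EntityName, b: EntityName) -> None:
        if b == TOP:
            return
        self._emit(self.out.conjunctive, (a1, a2, b))

    def emit_ei(self, a: EntityName, r: EntityName, b: EntityName) -> None:
        if a == BOT:
            return
        self._emit(self.out.exist_intro, (a, r, b))

    def emit_ee(self, r: EntityName, a: EntityName, b: EntityName) -> None:
        if b == TOP:
            return
        self._emit(self.out.exist_elim, (r, a, b))

    # -- decomposition -------------------------------------------------------

    @staticmethod
    def _atom(expr: ClassExpression) -> EntityName | None:
        if isinstance(expr, Named):
            return expr.name
        if isinstance(expr, Top):
            return TOP
        if isinstance(expr, Bottom):
            return BOT
        return None

    def gci(self, sub: ClassExpression, sup: ClassExpression) -> None:
        """Normalize one general inclusion ``sub ⊑ sup``."""
        # split a conjunctive superclass first
        if isinstance(sup, Conjunction):
            for op in sup.operands:
                self.gci(sub, op)
            return

        left = self._atom(sub)
        right = self._atom(sup)

        if left is None and isinstance(sub, Existential):
            inner = self._atom(sub.filler)
            if inner is None:
                # ∃r.Ĉ ⊑ D  →  Ĉ ⊑ A, ∃r.A ⊑ D
                a = self.fresh()
                self.gci(sub.filler, Named(a))
                self.gci(Existential(sub.role, Named(a)), sup)
                return
            if right is not None:
                self.emit_ee(sub.role, inner, right)
                return
            # ∃r.A ⊑ Ê  →  ∃r.A ⊑ F, F ⊑ Ê
            f = self.fresh()
            self.emit_ee(sub.role, inner, f)
            self.gci(Named(f), sup)
            return

        if left is None and isinstance(sub, Conjunction):
            operands: list[EntityName] = []
            for op in self._flatten(sub):
                at = self._atom(op)
                if at == BOT:
                    return  # vacuous: ⊥ on the left
                if at == TOP:
                    continue
                if at is None:
                    a = self.fresh()
                    self.gci(op, Named(a))
                    at = a
                operands.append(at)
            if not operands:
                self.gci(Top(), sup)
                return
            if len(operands) == 1:
                self.gci(Named(operands[0]), sup)
                return
            # binarize left-associatively
            while len(operands) > 2:
                f = self.fresh()
                self.emit_conj(operands[0], operands[1], f)
                operands = [f] + operands[2:]
            a1, a2 = operands
            if right is not None:
                self.emit_conj(a1, a2, right)
                return
            f = self.fresh()
            self.emit_conj(a1, a2, f)
            self.gci(Named(f), sup)
            return

        # left side is now an atom
        assert left is not None
        if right is not None:
            self.emit_atomic(left, right)
            return
        assert isinstance(sup, Existential)
        inner = self._atom(sup.filler)
        if inner is None:
            a = self.fresh()
            self.emit_ei(left, sup.role, a)
            self.gci(Named(a), sup.filler)
            return
        self.emit_ei(left, sup.role, inner)

    @staticmethod
    def _flatten(c: Conjunction) -> list[ClassExpression]:
        out: list[ClassExpression] = []
        for op in c.operands:
            if isinstance(op, Conjunction):
                out.extend(_Normalizer._flatten(op))
            else:
                out.append(op)
        return out


def normalize(ont: Ontology) -> NormalizedAxiomSet:
    """Normalize an ontology's class and role axioms.

    Guard and covering declarations are out of the calculus and skipped.
    Deterministic: the same ontology always yields the same set, with fresh
    names numbered in encounter order.
    """
    nz = _Normalizer()
    nz.out.declared_classes = set(ont.classes)
    nz.out.declared_roles = set(ont.roles)
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            nz.gci(ax.sub, ax.sup)
        elif isinstance(ax, EquivalentClasses):
            head = ax.exprs[0]
            for other in ax.exprs[1:]:
                nz.gci(head, other)
                nz.gci(other, head)
        elif isinstance(ax, DisjointClasses):
            for i, a in enumerate(ax.names):
                for b in ax.names[i + 1 :]:
                    nz.gci(Conjunction((a, b)), Bottom())
        elif isinstance(ax, RoleDomain):
            nz.emit_ee(ax.role, TOP, ax.domain.name)
        elif isinstance(ax, TransitiveRole):
            nz.out.transitive_roles.add(ax.role)
        else:  # SubRoleOf
            if (ax.sub, ax.sup) not in nz._seen:
                nz._seen.add((ax.sub, ax.sup))
                nz.out.role_inclusions.append((ax.sub, ax.sup))
    return nz.out
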