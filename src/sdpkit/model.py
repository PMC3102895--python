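"""Ontology data model for the restricted OWL 2 EL dialect.

The model mirrors what the dialect can say and nothing more: named classes,
``owl:Thing``/``owl:Nothing``, conjunction and existential restriction in
axiom positions, plus two constructs that are *not* fed to the EL calculus
and therefore live outside the axiom list:

* guard declarations ``subject SubClassOf role only filler`` (value
  restrictions, used by the pattern-conformance checker), and
* covering declarations ``covered EquivalentTo d1 or d2 or ...``
  (disjunctive classes, used for deferred ontological commitment).

All expression and axiom types are frozen dataclasses, so structural
equality and hashing come for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from .errors import UndeclaredNameError

# ---------------------------------------------------------------------------
# Names
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class EntityName:
    """A prefixed name such as ``bt:PathologicalStructure``."""

    prefix: str
    local: str

    def __post_init__(self) -> None:
        if not self.local:
            raise ValueError("entity local name must be non-empty")

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"


def name(curie: str) -> EntityName:
    """Build an :class:`EntityName` from a ``prefix:Local`` string."""
    prefix, _, local = curie.partition(":")
    return EntityName(prefix, local)


#: owl:Thing — member of every subsumer set.
TOP = EntityName("owl", "Thing")
#: owl:Nothing — membership of BOT in S(A) marks A unsatisfiable.
BOT = EntityName("owl", "Nothing")

#: Reserved prefix for fresh names introduced by normalization.
FRESH_PREFIX = "nf"

#: Default prefix→IRI bindings for the namespaces the toolkit itself uses.
DEFAULT_PREFIXES = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "bt": "http://purl.org/biotop/biotop.owl#",
    "bfo": "http://purl.org/biotop/bfo.owl#",
    "sct": "http://snomed.info/id/",
    "nf": "urn:sdpkit:normalform#",
    "ex": "http://example.org/onto#",
    "rnd": "urn:sdpkit:random#",
}


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Named:
    name: EntityName

    def __str__(self) -> str:
        return str(self.name)


@dataclass(frozen=True)
class Top:
    def __str__(self) -> str:
        return "owl:Thing"


@dataclass(frozen=True)
class Bottom:
    def __str__(self) -> str:
        return "owl:Nothing"


@dataclass(frozen=True)
class Conjunction:
    operands: tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if len(self.operands) < 2:
            raise ValueError("conjunction needs at least two operands")

    def __str__(self) -> str:
        return "(" + " and ".join(str(o) for o in self.operands) + ")"


@dataclass(frozen=True)
class Existential:
    role: EntityName
    filler: "ClassExpression"

    def __str__(self) -> str:
        return f"({self.role} some {self.filler})"


ClassExpression = Union[Named, Top, Bottom, Conjunction, Existential]


def conj(*operands: ClassExpression) -> Conjunction:
    return Conjunction(tuple(operands))


def some(role: EntityName, filler: ClassExpression) -> Existential:
    return Existential(role, filler)


def expression_signature(expr: ClassExpression) -> Iterator[tuple[str, EntityName]]:
    """Yield ('class'|'role', name) pairs for every name in the expression."""
    if isinstance(expr, Named):
        yield ("class", expr.name)
    elif isinstance(expr, Conjunction):
        for op in expr.operands:
            yield from expression_signature(op)
    elif isinstance(expr, Existential):
        yield ("role", expr.role)
        yield from expression_signature(expr.filler)
    # Top/Bottom carry no names


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression

    def __str__(self) -> str:
        return f"{self.sub} subClassOf {self.sup}"


@dataclass(frozen=True)
class EquivalentClasses:
    exprs: tuple[ClassExpression, ...]

    def __post_init__(self) -> None:
        if len(self.exprs) < 2:
            raise ValueError("equivalence needs at least two expressions")

    def __str__(self) -> str:
        return " equivalentTo ".join(str(e) for e in self.exprs)


@dataclass(frozen=True)
class DisjointClasses:
    names: tuple[Named, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2 or len(set(self.names)) != len(self.names):
            raise ValueError("disjointness needs >=2 distinct named classes")

    def __str__(self) -> str:
        return "DisjointClasses(" + " ".join(str(n) for n in self.names) + ")"


@dataclass(frozen=True)
class SubRoleOf:
    sub: EntityName
    sup: EntityName

    def __str__(self) -> str:
        return f"{self.sub} subRoleOf {self.sup}"


@dataclass(frozen=True)
class TransitiveRole:
    role: EntityName

    def __str__(self) -> str:
        return f"transitive({self.role})"


@dataclass(frozen=True)
class RoleDomain:
    role: EntityName
    domain: Named

    def __str__(self) -> str:
        return f"domain({self.role}) = {self.domain}"


Axiom = Union[
    SubClassOf, EquivalentClasses, DisjointClasses, SubRoleOf, TransitiveRole, RoleDomain
]


@dataclass(frozen=True)
class GuardDeclaration:
    """``subject SubClassOf role only filler`` — checked, never saturated."""

    subject: Named
    role: EntityName
    filler: Named

    def __str__(self) -> str:
        return f"{self.subject} subClassOf {self.role} only {self.filler}"


@dataclass(frozen=True)
class CoveringDeclaration:
    """``covered EquivalentTo d1 or d2 or ...`` — a disjunctive class."""

    covered: Named
    disjuncts: tuple[Named, ...]

    def __str__(self) -> str:
        return f"{self.covered} equivalentTo " + " or ".join(str(d) for d in self.disjuncts)


def axiom_signature(axiom: Axiom) -> Iterator[tuple[str, EntityName]]:
    if isinstance(axiom, SubClassOf):
        yield from expression_signature(axiom.sub)
        yield from expression_signature(axiom.sup)
    elif isinstance(axiom, EquivalentClasses):
        for e in axiom.exprs:
            yield from expression_signature(e)
    elif isinstance(axiom, DisjointClasses):
        for n in axiom.names:
            yield ("class", n.name)
    elif isinstance(axiom, SubRoleOf):
        yield ("role", axiom.sub)
        yield ("role", axiom.sup)
    elif isinstance(axiom, TransitiveRole):
        yield ("role", axiom.role)
    elif isinstance(axiom, RoleDomain):
        yield ("role", axiom.role)
        yield ("class", axiom.domain.name)


# ---------------------------------------------------------------------------
# Ontology container
# ---------------------------------------------------------------------------


@dataclass
class Ontology:
    """Declarations, axioms, and the out-of-calculus guard/covering lists.

    The axiom list preserves insertion (= document) order; serialization is
    deterministic, so a parsed-and-reserialized ontology is byte-stable.
    """

    iri: str = "http://example.org/onto"
    prefixes: dict[str, str] = field(default_factory=dict)
    classes: set[EntityName] = field(default_factory=set)
    roles: set[EntityName] = field(default_factory=set)
    axioms: list[Axiom] = field(default_factory=list)
    covering: list[CoveringDeclaration] = field(default_factory=list)
    guards: list[GuardDeclaration] = field(default_factory=list)

    # -- construction helpers ------------------------------------------------

    def declare_class(self, *names: EntityName) -> None:
        for n in names:
            self.classes.add(n)
            self._bind_default_prefix(n.prefix)

    def declare_role(self, *names: EntityName) -> None:
        for n in names:
            self.roles.add(n)
            self._bind_default_prefix(n.prefix)

    def _bind_default_prefix(self, prefix: str) -> None:
        if prefix not in self.prefixes:
            self.prefixes[prefix] = DEFAULT_PREFIXES.get(
                prefix, f"urn:sdpkit:prefix:{prefix}#"
            )

    def add(self, *axioms: Axiom) -> None:
        self.axioms.extend(axioms)

    def add_guard(self, subject: EntityName, role: EntityName, filler: EntityName) -> None:
        self.guards.append(GuardDeclaration(Named(subject), role, Named(filler)))

    def add_covering(self, covered: EntityName, disjuncts: Iterable[EntityName]) -> None:
        self.covering.append(
            CoveringDeclaration(Named(covered), tuple(Named(d) for d in disjuncts))
        )

    # -- queries -------------------------------------------------------------

    def is_declared(self, n: EntityName) -> bool:
        return n in self.classes or n in self.roles or n in (TOP, BOT)

    def signature(self) -> set[EntityName]:
        return set(self.classes) | set(self.roles)

    def validate(self) -> None:
        """Check that every name used anywhere is declared.

        Raises :class:`UndeclaredNameError` naming the first offender.
        """
        for ax in self.axioms:
            for kind, n in axiom_signature(ax):
                self._check(kind, n)
        for g in self.guards:
            self._check("class", g.subject.name)
            self._check("role", g.role)
            self._check("class", g.filler.name)
        for c in self.covering:
            self._check("class", c.covered.name)
            for d in c.disjuncts:
                self._check("class", d.name)

    def _check(self, kind: str, n: EntityName) -> None:
        if n in (TOP, BOT):
            return
        pool = self.classes if kind == "class" else self.roles
        if n not in pool:
            raise UndeclaredNameError(f"undeclared {kind} name: {n}")

    # -- combination ---------------------------------------------------------

    def copy(self) -> "Ontology":
        return Ontology(
            iri=self.iri,
            prefixes=dict(self.prefixes),
            classes=set(self.classes),
            roles=set(self.roles),
            axioms=list(self.axioms),
            covering=list(self.covering),
            guards=list(self.guards),
        )

    def merged_with(self, other: "Ontology") -> "Ontology":
        """Union of two ontologies; duplicate axioms are kept once."""
        out = self.copy()
        for tag, iri in other.prefixes.items():
            out.prefixes.setdefault(tag, iri)
        out.classes |= other.classes
        out.roles |= other.roles
        seen = set(out.axioms)
        for ax in other.axioms:
            if ax not in seen:
                out.axioms.append(ax)
                seen.add(ax)
        for cov in other.covering:
            if cov not in out.covering:
                out.covering.append(cov)
        for g in other.guards:
            if g not in out.guards:
                out.guards.append(g)
        return out

    def structurally_equal(self, other: "Ontology") -> bool:
        return (
            self.prefixes == other.prefixes
            and self.classes == other.classes
            and self.roles == other.roles
            and self.axioms == other.axioms
            and self.covering == other.covering
            and self.guards == other.guards
        )
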