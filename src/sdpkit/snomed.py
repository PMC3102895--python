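"""SNOMED-style relation mapping, ambiguity audit, and disambiguation.

SNOMED CT's finding/disease hierarchy mixes processes and dispositions
under single codes.  This module maps the SNOMED attribute
``sct:FindingSite`` onto the pattern's ``bt:hasLocus`` (so finding sites
join location propagation), flags classes that sit under the disjunctive
condition class without committing to any of its disjuncts, and generates
committed subclasses such as ``ManifestAllergicRhinitis ≡ AllergicRhinitis
⊓ PathologicalProcess``.  ``sct:AssociatedMorphology`` is deliberately left
unmapped: it links findings to abnormal-structure categories, not to
locations, which is exactly why a finding like FibrosisOfPleura is not a
subclass of Fibrosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NameCollisionError, NotAmbiguousError, UnknownNameError, UnknownRoleError
from .model import (
    BOT,
    Axiom,
    ClassExpression,
    Conjunction,
    DisjointClasses,
    EntityName,
    EquivalentClasses,
    Existential,
    GuardDeclaration,
    Named,
    Ontology,
    RoleDomain,
    SubClassOf,
    SubRoleOf,
    TransitiveRole,
    conj,
    name,
)
from .pattern import CATEGORY_CLASSES, PATTERN_PREFIXES, probe_excluded_disjuncts
from .reasoner import Reasoner

FINDING_SITE = name("sct:FindingSite")
ASSOCIATED_MORPHOLOGY = name("sct:AssociatedMorphology")


@dataclass(frozen=True)
class RelationMapping:
    """Injective source→target role rewriting table."""

    pairs: tuple[tuple[EntityName, EntityName], ...]

    def as_dict(self) -> dict[EntityName, EntityName]:
        return dict(self.pairs)


def default_mapping() -> RelationMapping:
    """FindingSite→hasLocus; AssociatedMorphology is kept as its own role."""
    return RelationMapping(pairs=((FINDING_SITE, name("bt:hasLocus")),))


def _rewrite_expr(expr: ClassExpression, table: dict[EntityName, EntityName]) -> ClassExpression:
    if isinstance(expr, Conjunction):
        return Conjunction(tuple(_rewrite_expr(o, table) for o in expr.operands))
    if isinstance(expr, Existential):
        return Existential(table.get(expr.role, expr.role),
                           _rewrite_expr(expr.filler, table))
    return expr


def _rewrite_axiom(ax: Axiom, table: dict[EntityName, EntityName]) -> Axiom:
    if isinstance(ax, SubClassOf):
        return SubClassOf(_rewrite_expr(ax.sub, table), _rewrite_expr(ax.sup, table))
    if isinstance(ax, EquivalentClasses):
        return EquivalentClasses(tuple(_rewrite_expr(e, table) for e in ax.exprs))
    if isinstance(ax, SubRoleOf):
        return SubRoleOf(table.get(ax.sub, ax.sub), table.get(ax.sup, ax.sup))
    if isinstance(ax, TransitiveRole):
        return TransitiveRole(table.get(ax.role, ax.role))
    if isinstance(ax, RoleDomain):
        return RoleDomain(table.get(ax.role, ax.role), ax.domain)
    return ax  # DisjointClasses carries no roles


def map_to_biotop(ont: Ontology, mapping: RelationMapping | None = None) -> Ontology:
    """Rewrite SNOMED-style roles to their pattern counterparts.

    With the built-in default mapping, source roles absent from the
    ontology are skipped, so an ontology without them comes back unchanged.
    An explicitly supplied mapping is strict: an undeclared source role
    raises :class:`UnknownRoleError`.
    """
    strict = mapping is not None
    mapping = mapping or default_mapping()
    table: dict[EntityName, EntityName] = {}
    for src, dst in mapping.pairs:
        if src not in ont.roles:
            if strict:
                raise UnknownRoleError(f"source role not declared: {src}")
            continue
        table[src] = dst
    out = ont.copy()
    if not table:
        return out
    out.axioms = [_rewrite_axiom(ax, table) for ax in out.axioms]
    out.guards = [
        GuardDeclaration(g.subject, table.get(g.role, g.role), g.filler)
        for g in out.guards
    ]
    for src, dst in table.items():
        out.roles.discard(src)
        out.declare_role(dst)
    return out


# ---------------------------------------------------------------------------
# Ambiguity audit
# ---------------------------------------------------------------------------


def detect_ambiguous(ont: Ontology, reasoner: Reasoner | None = None) -> list[EntityName]:
    """Satisfiable classes under a covering class but under none of its
    disjuncts, lexicographically sorted.

    These are the classes for which the ontology has deferred the
    structure/disposition/process commitment — candidates for
    disambiguation.  A class that the covering's case elimination already
    commits to a single disjunct (e.g. a participant-refined process) is
    not ambiguous; neither are classes equivalent to the covering class
    itself (such as a condition alias) or pattern vocabulary.
    """
    r = reasoner or Reasoner(ont)
    flagged: set[EntityName] = set()
    for cov in ont.covering:
        covered = cov.covered.name
        disjuncts = tuple(d.name for d in cov.disjuncts)
        for cls in sorted(ont.classes):
            if cls.prefix in PATTERN_PREFIXES:
                continue
            subsumers = r.state.subsumers(cls)
            if BOT in subsumers or covered not in subsumers:
                continue
            if cls in r.state.subsumers(covered):  # equivalent to the covered class
                continue
            if any(d in subsumers for d in disjuncts):
                continue
            excluded = probe_excluded_disjuncts(ont, cls, disjuncts)
            if len(disjuncts) - len(excluded) <= 1:
                continue  # committed (or unsatisfiable) by case elimination
            flagged.add(cls)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# Disambiguation
# ---------------------------------------------------------------------------

_NAMING = {
    "Process": lambda local: f"Manifest{local}",
    "Disposition": lambda local: f"{local}Disposition",
    "Structure": lambda local: f"{local}Structure",
}


@dataclass
class DisambiguationPlan:
    parent: EntityName
    entries: list[tuple[str, EntityName, EquivalentClasses]] = field(default_factory=list)

    def to_json_obj(self) -> dict:
        return {
            "parent": str(self.parent),
            "entries": [
                {"category": cat, "new_class": str(n), "axiom": str(ax)}
                for cat, n, ax in self.entries
            ],
        }


def _resolve_category_class(ont: Ontology, r: Reasoner, category: str) -> EntityName:
    """Prefer a declared alias equivalent to the bt: category (e.g.
    ``sct:PathologicalProcess``); fall back to the bt: class."""
    bt_cls = CATEGORY_CLASSES[category]
    aliases = sorted(
        cls
        for cls in ont.classes
        if cls.prefix not in PATTERN_PREFIXES
        and bt_cls in r.state.subsumers(cls)
        and cls in r.state.subsumers(bt_cls)
    )
    return aliases[0] if aliases else bt_cls


def disambiguate(
    ont: Ontology, cls: EntityName, categories: list[str]
) -> tuple[Ontology, DisambiguationPlan]:
    """Create committed subclasses of an ambiguous class.

    For each requested category a new class ``New ≡ cls ⊓ Category`` is
    added, named after the printed convention (Process → ``Manifest`` +
    local, Disposition → local + ``Disposition``, Structure → local +
    ``Structure``).  The plan's invariants — each child satisfiable, under
    both parent and category, siblings disjoint — are re-verified by
    classification before the merged ontology is returned.
    """
    if cls not in ont.classes:
        raise UnknownNameError(f"unknown class name: {cls}")
    if not categories:
        raise NotAmbiguousError("no categories requested")
    bad = [c for c in categories if c not in _NAMING]
    if bad:
        raise NotAmbiguousError(f"unknown categories: {bad}")
    r = Reasoner(ont)
    if cls not in detect_ambiguous(ont, reasoner=r):
        raise NotAmbiguousError(f"{cls} is already committed or unsatisfiable")

    out = ont.copy()
    plan = DisambiguationPlan(parent=cls)
    for cat in categories:
        new = EntityName(cls.prefix, _NAMING[cat](cls.local))
        if new in out.classes or new in out.roles:
            raise NameCollisionError(f"generated name already declared: {new}")
        cat_cls = _resolve_category_class(ont, r, cat)
        axiom = EquivalentClasses((Named(new), conj(Named(cls), Named(cat_cls))))
        out.declare_class(new)
        out.add(axiom)
        plan.entries.append((cat, new, axiom))

    _verify_plan(out, plan)
    return out, plan


def _verify_plan(merged: Ontology, plan: DisambiguationPlan) -> None:
    r = Reasoner(merged)
    for cat, new, _ in plan.entries:
        if BOT in r.state.subsumers(new):
            raise NotAmbiguousError(f"generated class {new} is unsatisfiable")
        assert r.is_subsumed(new, plan.parent)
    # sibling disjointness via probe classes
    if len(plan.entries) > 1:
        probe_ont = merged.copy()
        probes = []
        for i, (_, n1, _) in enumerate(plan.entries):
            for j in range(i + 1, len(plan.entries)):
                n2 = plan.entries[j][1]
                p = EntityName("nf", f"Pair{i}_{j}")
                probe_ont.declare_class(p)
                probe_ont.add(SubClassOf(Named(p), Named(n1)),
                              SubClassOf(Named(p), Named(n2)))
                probes.append(p)
        pr = Reasoner(probe_ont)
        for p in probes:
            if BOT not in pr.state.subsumers(p):
                raise NotAmbiguousError(
                    "generated siblings are not entailed disjoint"
                )
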