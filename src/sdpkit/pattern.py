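"""The structure–disposition–process (SDP) design pattern and its checks.

The pattern conflates pathological structures (material bearers),
dispositions (inhering potentials), and processes (their realizations)
under one disjunctive class, ``bt:PathologicalEntity``, so an ontology can
defer the commitment to one of the three categories until an axiom forces
it.  Location and inherence are folded into one transitive relation,
``bt:hasLocus``, so that "located in a part" propagates to the whole for
structures, dispositions, and processes alike — while participation
deliberately does not propagate.

Two constructs stay outside the EL calculus:

* the covering direction of ``PathologicalEntity ≡ S ⊔ D ⊔ P`` is recorded
  as a covering declaration and consumed by :func:`infer_category` (and the
  ambiguity audit) through sound case elimination, because disjunction is
  not in the fragment and the class's purpose is deferred commitment;
* the value restriction ``PathologicalDisposition ⊑ ∀hasRealization.
  PathologicalProcess`` is a guard declaration checked against asserted
  realization fillers by :func:`check_realization_guard`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .errors import UnknownNameError
from .model import (
    BOT,
    DisjointClasses,
    EntityName,
    EquivalentClasses,
    Existential,
    Conjunction,
    Named,
    Ontology,
    RoleDomain,
    SubClassOf,
    SubRoleOf,
    TransitiveRole,
    axiom_signature,
    conj,
    name,
    some,
)
from .reasoner import Reasoner

# -- pattern vocabulary ------------------------------------------------------

PATHOLOGICAL_STRUCTURE = name("bt:PathologicalStructure")
PATHOLOGICAL_DISPOSITION = name("bt:PathologicalDisposition")
PATHOLOGICAL_PROCESS = name("bt:PathologicalProcess")
PATHOLOGICAL_ENTITY = name("bt:PathologicalEntity")
MATERIAL_ENTITY = name("bt:MaterialEntity")
PROCESSUAL_ENTITY = name("bt:ProcessualEntity")
BODY_STRUCTURE = name("bt:BodyStructure")
NON_PROCESSUAL_BEARER_SIDE = name("bt:NonProcessualBearerSide")
INDEPENDENT_CONTINUANT = name("bfo:IndependentContinuant")
DEPENDENT_CONTINUANT = name("bfo:DependentContinuant")
DISPOSITION = name("bfo:Disposition")
OCCURRENT = name("bfo:Occurrent")

HAS_LOCUS = name("bt:hasLocus")
PHYSICALLY_LOCATED_IN = name("bt:physicallyLocatedIn")
PHYSICAL_PART_OF = name("bt:physicalPartOf")
INHERES_IN = name("bt:inheresIn")
BEARER_OF = name("bt:bearerOf")
HAS_PARTICIPANT = name("bt:hasParticipant")
HAS_REALIZATION = name("bt:hasRealization")
REALIZATION_OF = name("bt:realizationOf")
PARTICIPATES_IN = name("bt:participatesIn")
LOCUS_OF = name("bt:locusOf")

#: Prefixes owned by the pattern/toolkit, filtered from user-facing outputs.
PATTERN_PREFIXES = frozenset({"bt", "bfo", "nf", "owl"})

CATEGORY_CLASSES = {
    "Structure": PATHOLOGICAL_STRUCTURE,
    "Disposition": PATHOLOGICAL_DISPOSITION,
    "Process": PATHOLOGICAL_PROCESS,
}


def sdp_axioms() -> Ontology:
    """The SDP axiom module.

    Upper-level placements, pairwise disjointness of the three categories
    (and of the upper categories they sit under, which is what lets a
    participant refinement commit a class to the process branch),
    the inherence and participation dependencies, the hasLocus role box,
    the two role-domain constraints, the realization guard, and the
    covering declaration for ``bt:PathologicalEntity``.

    The converse-dependency axiom ``PathologicalProcess ⊑
    ∃realizationOf.PathologicalDisposition`` is deliberately absent: not
    every pathological process realizes a pathological disposition (a
    traumatic fracture event realizes none).
    """
    ont = Ontology(iri="urn:sdpkit:pattern:sdp")
    ont.declare_class(
        PATHOLOGICAL_STRUCTURE,
        PATHOLOGICAL_DISPOSITION,
        PATHOLOGICAL_PROCESS,
        PATHOLOGICAL_ENTITY,
        MATERIAL_ENTITY,
        PROCESSUAL_ENTITY,
        BODY_STRUCTURE,
        NON_PROCESSUAL_BEARER_SIDE,
        INDEPENDENT_CONTINUANT,
        DEPENDENT_CONTINUANT,
        DISPOSITION,
        OCCURRENT,
    )
    ont.declare_role(
        HAS_LOCUS,
        PHYSICALLY_LOCATED_IN,
        PHYSICAL_PART_OF,
        INHERES_IN,
        BEARER_OF,
        HAS_PARTICIPANT,
        HAS_REALIZATION,
        REALIZATION_OF,
        PARTICIPATES_IN,
        LOCUS_OF,
    )
    ont.add(
        # category placements
        SubClassOf(Named(PATHOLOGICAL_STRUCTURE), Named(MATERIAL_ENTITY)),
        SubClassOf(Named(MATERIAL_ENTITY), Named(INDEPENDENT_CONTINUANT)),
        SubClassOf(Named(PATHOLOGICAL_DISPOSITION), Named(DISPOSITION)),
        SubClassOf(Named(DISPOSITION), Named(DEPENDENT_CONTINUANT)),
        SubClassOf(Named(PATHOLOGICAL_PROCESS), Named(PROCESSUAL_ENTITY)),
        SubClassOf(Named(PROCESSUAL_ENTITY), Named(OCCURRENT)),
        SubClassOf(Named(BODY_STRUCTURE), Named(MATERIAL_ENTITY)),
        # the three categories are mutually disjoint
        DisjointClasses((Named(PATHOLOGICAL_STRUCTURE), Named(PATHOLOGICAL_DISPOSITION))),
        DisjointClasses((Named(PATHOLOGICAL_STRUCTURE), Named(PATHOLOGICAL_PROCESS))),
        DisjointClasses((Named(PATHOLOGICAL_PROCESS), Named(PATHOLOGICAL_DISPOSITION))),
        # upper-level disjointness (material / dispositional / processual)
        DisjointClasses((Named(MATERIAL_ENTITY), Named(PROCESSUAL_ENTITY))),
        DisjointClasses((Named(DISPOSITION), Named(PROCESSUAL_ENTITY))),
        DisjointClasses((Named(MATERIAL_ENTITY), Named(DISPOSITION))),
        # existential dependencies
        SubClassOf(
            Named(PATHOLOGICAL_DISPOSITION),
            some(INHERES_IN, Named(PATHOLOGICAL_STRUCTURE)),
        ),
        SubClassOf(
            Named(PATHOLOGICAL_PROCESS),
            some(HAS_PARTICIPANT, Named(BODY_STRUCTURE)),
        ),
        # role box: partonomy and inherence both specialize hasLocus
        SubRoleOf(PHYSICAL_PART_OF, PHYSICALLY_LOCATED_IN),
        SubRoleOf(PHYSICALLY_LOCATED_IN, HAS_LOCUS),
        SubRoleOf(INHERES_IN, HAS_LOCUS),
        TransitiveRole(HAS_LOCUS),
        # domain constraints: only processual entities have participants;
        # only non-processual entities are bearers (inherence side)
        RoleDomain(HAS_PARTICIPANT, Named(PROCESSUAL_ENTITY)),
        RoleDomain(INHERES_IN, Named(NON_PROCESSUAL_BEARER_SIDE)),
        DisjointClasses((Named(NON_PROCESSUAL_BEARER_SIDE), Named(PROCESSUAL_ENTITY))),
        # the three inclusions into the covering class
        SubClassOf(Named(PATHOLOGICAL_STRUCTURE), Named(PATHOLOGICAL_ENTITY)),
        SubClassOf(Named(PATHOLOGICAL_DISPOSITION), Named(PATHOLOGICAL_ENTITY)),
        SubClassOf(Named(PATHOLOGICAL_PROCESS), Named(PATHOLOGICAL_ENTITY)),
    )
    ont.add_guard(PATHOLOGICAL_DISPOSITION, HAS_REALIZATION, PATHOLOGICAL_PROCESS)
    ont.add_covering(
        PATHOLOGICAL_ENTITY,
        (PATHOLOGICAL_STRUCTURE, PATHOLOGICAL_DISPOSITION, PATHOLOGICAL_PROCESS),
    )
    return ont


def merge_pattern(ont: Ontology) -> Ontology:
    """Merge the SDP module into a copy of ``ont``."""
    return ont.merged_with(sdp_axioms())


# ---------------------------------------------------------------------------
# Category inference
# ---------------------------------------------------------------------------


class Category(str, Enum):
    STRUCTURE = "Structure"
    DISPOSITION = "Disposition"
    PROCESS = "Process"
    UNCOMMITTED = "Uncommitted"
    CONFLICT = "Conflict"


@dataclass
class CategoryVerdict:
    verdict: Category
    evidence: list[str] = field(default_factory=list)


def _category_of_disjunct(d: EntityName) -> str | None:
    for label, cls in CATEGORY_CLASSES.items():
        if d == cls:
            return label
    return None


def probe_excluded_disjuncts(ont: Ontology, cls: EntityName,
                             disjuncts: tuple[EntityName, ...]) -> set[EntityName]:
    """Disjuncts d with ``cls ⊓ d`` unsatisfiable, found with probe classes."""
    probe_ont = ont.copy()
    probes: dict[EntityName, EntityName] = {}
    for i, d in enumerate(disjuncts):
        p = EntityName("nf", f"Probe{i}")
        probes[d] = p
        probe_ont.declare_class(p)
        probe_ont.add(SubClassOf(Named(p), Named(cls)), SubClassOf(Named(p), Named(d)))
    r = Reasoner(probe_ont)
    return {d for d, p in probes.items() if BOT in r.state.subsumers(p)}


def infer_category(ont: Ontology, cls: EntityName,
                   reasoner: Reasoner | None = None) -> CategoryVerdict:
    """Decide which SDP category an ontology commits ``cls`` to.

    ``ont`` must already contain the pattern module.  A directly entailed
    category wins; otherwise the covering declaration licenses case
    elimination: a disjunct whose conjunction with ``cls`` is unsatisfiable
    is ruled out, and a single survivor is the entailed category.
    """
    r = reasoner or Reasoner(ont)
    if cls not in ont.classes:
        raise UnknownNameError(f"unknown class name: {cls}")
    subsumers = r.state.subsumers(cls)
    if BOT in subsumers:
        return CategoryVerdict(
            Category.CONFLICT, [f"{cls} ⊑ owl:Nothing (unsatisfiable)"]
        )
    for label, cat_cls in CATEGORY_CLASSES.items():
        if cat_cls in subsumers:
            return CategoryVerdict(Category(label), [f"{cls} ⊑ {cat_cls}"])

    for cov in ont.covering:
        covered = cov.covered.name
        if covered not in subsumers:
            continue
        disjuncts = tuple(d.name for d in cov.disjuncts)
        excluded = probe_excluded_disjuncts(ont, cls, disjuncts)
        survivors = [d for d in disjuncts if d not in excluded]
        evidence = [f"{cls} ⊑ {covered}"] + [
            f"{cls} ⊓ {d} ⊑ owl:Nothing" for d in sorted(excluded)
        ]
        if len(survivors) == 1:
            label = _category_of_disjunct(survivors[0])
            if label is not None:
                evidence.append(f"hence {cls} ⊑ {survivors[0]}")
                return CategoryVerdict(Category(label), evidence)
        return CategoryVerdict(Category.UNCOMMITTED, evidence)

    return CategoryVerdict(
        Category.UNCOMMITTED, [f"{cls} is not entailed under {PATHOLOGICAL_ENTITY}"]
    )


# ---------------------------------------------------------------------------
# Location closure
# ---------------------------------------------------------------------------


def located_in_closure(ont: Ontology, cls: EntityName,
                       reasoner: Reasoner | None = None) -> set[EntityName]:
    """All named classes A with ``cls ⊑ ∃hasLocus.A`` entailed, read off the
    saturated successor structure; pattern vocabulary and fresh names are
    filtered out."""
    r = reasoner or Reasoner(ont)
    if cls not in ont.classes:
        raise UnknownNameError(f"unknown class name: {cls}")
    return {
        b
        for b in r.state.successors(HAS_LOCUS, cls)
        if b in ont.classes and b.prefix not in PATTERN_PREFIXES
    }


# ---------------------------------------------------------------------------
# Conformance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    kind: str  # realization-guard | missing-pattern-axiom | conflict
    cls: EntityName
    detail: str


@dataclass
class ConformanceReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json_obj(self) -> list[dict]:
        return [
            {"kind": v.kind, "class": str(v.cls), "detail": v.detail}
            for v in self.violations
        ]

    def to_json(self) -> str:
        return json.dumps(self.to_json_obj(), indent=2, ensure_ascii=False)


def _asserted_existentials(ont: Ontology, role: EntityName):
    """Yield (subject, filler) for every asserted ``subject ⊑ ... ∃role.F``."""
    def scan(subject: EntityName, expr) -> list[tuple[EntityName, EntityName]]:
        found = []
        if isinstance(expr, Existential) and expr.role == role:
            if isinstance(expr.filler, Named):
                found.append((subject, expr.filler.name))
        elif isinstance(expr, Conjunction):
            for op in expr.operands:
                found.extend(scan(subject, op))
        return found

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
            yield from scan(ax.sub.name, ax.sup)
        elif isinstance(ax, EquivalentClasses):
            named = [e for e in ax.exprs if isinstance(e, Named)]
            for n in named:
                for e in ax.exprs:
                    if e is not n:
                        yield from scan(n.name, e)


def check_realization_guard(ont: Ontology,
                            reasoner: Reasoner | None = None) -> ConformanceReport:
    """Check every guard declaration against asserted realization fillers.

    For a guard ``subject ⊑ ∀role.filler``: any class entailed under
    ``subject`` that asserts ``∃role.F`` must have ``F ⊑ filler`` entailed.
    The module-level guard on ``bt:PathologicalDisposition`` and any
    per-disposition guards are treated alike.
    """
    r = reasoner or Reasoner(ont)
    report = ConformanceReport()
    for g in ont.guards:
        for subject, filler in _asserted_existentials(ont, g.role):
            if not r.is_subsumed(subject, g.subject.name):
                continue
            if not r.is_subsumed(filler, g.filler.name):
                report.violations.append(
                    Violation(
                        kind="realization-guard",
                        cls=subject,
                        detail=(
                            f"{subject} ⊑ ∃{g.role}.{filler} but {filler} ⋢ "
                            f"{g.filler.name} (guard on {g.subject.name})"
                        ),
                    )
                )
    return report


def _axiom_key(ax):
    if isinstance(ax, DisjointClasses):
        return ("disjoint", frozenset(n.name for n in ax.names))
    return ax


def conformance_report(ont: Ontology) -> ConformanceReport:
    """Aggregate pattern conformance: realization-guard violations,
    unsatisfiable (conflict) classes, and pattern axioms missing from the
    merged ontology."""
    r = Reasoner(ont)
    report = check_realization_guard(ont, reasoner=r)
    for cls in sorted(r.unsatisfiable_classes()):
        if cls.prefix == "nf":
            continue
        report.violations.append(
            Violation(kind="conflict", cls=cls, detail=f"{cls} is unsatisfiable")
        )
    pattern = sdp_axioms()
    present = {_axiom_key(ax) for ax in ont.axioms}
    for ax in pattern.axioms:
        if _axiom_key(ax) not in present:
            first_cls = next(
                (n for kind, n in axiom_signature(ax) if kind == "class"),
                PATHOLOGICAL_ENTITY,
            )
            report.violations.append(
                Violation(
                    kind="missing-pattern-axiom",
                    cls=first_cls,
                    detail=f"pattern axiom absent: {ax}",
                )
            )
    for g in pattern.guards:
        if g not in ont.guards:
            report.violations.append(
                Violation(
                    kind="missing-pattern-axiom",
                    cls=g.subject.name,
                    detail=f"pattern guard absent: {g}",
                )
            )
    for c in pattern.covering:
        if c not in ont.covering:
            report.violations.append(
                Violation(
                    kind="missing-pattern-axiom",
                    cls=c.covered.name,
                    detail=f"pattern covering absent: {c}",
                )
            )
    return report
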