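"""Built-in worked-example ontologies and a seeded random-ontology generator.

Each fixture encodes one clinical vignette — tumor partonomy, the
disposition location chain, gangrene participation vs location, the
participant/inherence conflict, allergy, the Huntington cascade, traumatic
vs pathological fracture, pleural fibrosis, and a small SNOMED-style
terminology — together with the entailments, non-entailments,
unsatisfiable classes, and ambiguity flags expected once the SDP pattern
module is merged in.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .errors import InvalidParamsError, UnknownFixtureError
from .model import (
    Conjunction,
    DisjointClasses,
    EntityName,
    EquivalentClasses,
    Existential,
    Named,
    Ontology,
    SubClassOf,
    SubRoleOf,
    TransitiveRole,
    conj,
    name,
    some,
)
from . import pattern as pt


@dataclass
class FixtureSpec:
    name: str
    ontology: Ontology
    expect_entailed: list[tuple[EntityName, EntityName]] = field(default_factory=list)
    expect_not_entailed: list[tuple[EntityName, EntityName]] = field(default_factory=list)
    expect_unsatisfiable: list[EntityName] = field(default_factory=list)
    expect_ambiguous: list[EntityName] = field(default_factory=list)
    #: expected located_in_closure per class (extra, used by the tests)
    expect_located: dict[EntityName, set[EntityName]] = field(default_factory=dict)

    def manifest_entry(self) -> dict:
        return {
            "name": self.name,
            "expect_entailed": [[str(a), str(b)] for a, b in self.expect_entailed],
            "expect_not_entailed": [
                [str(a), str(b)] for a, b in self.expect_not_entailed
            ],
            "expect_unsatisfiable": [str(a) for a in self.expect_unsatisfiable],
            "expect_ambiguous": [str(a) for a in self.expect_ambiguous],
            "expect_located": {
                str(c): sorted(str(a) for a in locs)
                for c, locs in self.expect_located.items()
            },
        }


def _base(prefix: str, iri_tail: str, classes: list[str],
          bt_classes: list[EntityName] = (), bt_roles: list[EntityName] = ()) -> Ontology:
    ont = Ontology(iri=f"urn:sdpkit:fixture:{iri_tail}")
    ont.declare_class(*(EntityName(prefix, c) for c in classes))
    ont.declare_class(*bt_classes)
    ont.declare_role(*bt_roles)
    return ont


def _tumor() -> FixtureSpec:
    n = lambda local: EntityName("tm", local)
    ont = _base(
        "tm", "tumor",
        ["Tumor", "TumorOfSigmoid", "TumorOfColon", "TumorOfIntestine",
         "SigmoidColon", "Colon", "Intestine"],
        bt_roles=[pt.HAS_LOCUS, pt.PHYSICALLY_LOCATED_IN, pt.PHYSICAL_PART_OF],
    )
    ont.add(
        # the relevant slice of the role box, so the fixture classifies
        # correctly even without the full pattern module
        SubRoleOf(pt.PHYSICAL_PART_OF, pt.PHYSICALLY_LOCATED_IN),
        SubRoleOf(pt.PHYSICALLY_LOCATED_IN, pt.HAS_LOCUS),
        TransitiveRole(pt.HAS_LOCUS),
        EquivalentClasses((Named(n("TumorOfSigmoid")),
                           conj(Named(n("Tumor")), some(pt.HAS_LOCUS, Named(n("SigmoidColon")))))),
        EquivalentClasses((Named(n("TumorOfColon")),
                           conj(Named(n("Tumor")), some(pt.HAS_LOCUS, Named(n("Colon")))))),
        EquivalentClasses((Named(n("TumorOfIntestine")),
                           conj(Named(n("Tumor")), some(pt.HAS_LOCUS, Named(n("Intestine")))))),
        SubClassOf(Named(n("SigmoidColon")), some(pt.PHYSICAL_PART_OF, Named(n("Colon")))),
        SubClassOf(Named(n("Colon")), some(pt.PHYSICAL_PART_OF, Named(n("Intestine")))),
    )
    return FixtureSpec(
        name="tumor",
        ontology=ont,
        expect_entailed=[
            (n("TumorOfSigmoid"), n("TumorOfColon")),
            (n("TumorOfSigmoid"), n("TumorOfIntestine")),
            (n("TumorOfColon"), n("TumorOfIntestine")),
        ],
        expect_not_entailed=[
            (n("TumorOfColon"), n("TumorOfSigmoid")),
            (n("Tumor"), n("TumorOfColon")),
        ],
        expect_located={
            n("TumorOfSigmoid"): {n("SigmoidColon"), n("Colon"), n("Intestine")},
            n("TumorOfColon"): {n("Colon"), n("Intestine")},
        },
    )


def _disposition_chain() -> FixtureSpec:
    n = lambda local: EntityName("dc", local)
    ont = _base(
        "dc", "disposition_chain",
        ["D", "S", "S2", "LocatedInS", "LocatedInS2"],
        bt_classes=[pt.PATHOLOGICAL_DISPOSITION],
        bt_roles=[pt.HAS_LOCUS, pt.PHYSICAL_PART_OF, pt.INHERES_IN],
    )
    ont.add(
        SubClassOf(Named(n("D")), Named(pt.PATHOLOGICAL_DISPOSITION)),
        SubClassOf(Named(n("D")), some(pt.INHERES_IN, Named(n("S")))),
        SubClassOf(Named(n("S")), some(pt.PHYSICAL_PART_OF, Named(n("S2")))),
        EquivalentClasses((Named(n("LocatedInS")), some(pt.HAS_LOCUS, Named(n("S"))))),
        EquivalentClasses((Named(n("LocatedInS2")), some(pt.HAS_LOCUS, Named(n("S2"))))),
    )
    return FixtureSpec(
        name="disposition_chain",
        ontology=ont,
        expect_entailed=[
            (n("D"), n("LocatedInS")),
            (n("D"), n("LocatedInS2")),
            (n("D"), pt.PATHOLOGICAL_DISPOSITION),
        ],
        expect_not_entailed=[(n("S"), n("LocatedInS"))],
        expect_located={n("D"): {n("S"), n("S2")}},
    )


def _gangrene() -> FixtureSpec:
    n = lambda local: EntityName("gg", local)
    ont = _base(
        "gg", "gangrene",
        ["Gangrene", "GangreneOfToe", "GangreneInToe", "Toe", "Foot",
         "ParticipantFoot", "LocatedInFoot"],
        bt_classes=[pt.PATHOLOGICAL_ENTITY],
        bt_roles=[pt.HAS_LOCUS, pt.PHYSICAL_PART_OF, pt.HAS_PARTICIPANT],
    )
    ont.add(
        SubClassOf(Named(n("Gangrene")), Named(pt.PATHOLOGICAL_ENTITY)),
        SubClassOf(Named(n("Toe")), some(pt.PHYSICAL_PART_OF, Named(n("Foot")))),
        SubClassOf(Named(n("GangreneOfToe")), Named(n("Gangrene"))),
        SubClassOf(Named(n("GangreneOfToe")), some(pt.HAS_PARTICIPANT, Named(n("Toe")))),
        SubClassOf(Named(n("GangreneInToe")), Named(n("Gangrene"))),
        SubClassOf(Named(n("GangreneInToe")), some(pt.HAS_LOCUS, Named(n("Toe")))),
        EquivalentClasses((Named(n("ParticipantFoot")),
                           some(pt.HAS_PARTICIPANT, Named(n("Foot"))))),
        EquivalentClasses((Named(n("LocatedInFoot")),
                           some(pt.HAS_LOCUS, Named(n("Foot"))))),
    )
    return FixtureSpec(
        name="gangrene",
        ontology=ont,
        expect_entailed=[(n("GangreneInToe"), n("LocatedInFoot"))],
        expect_not_entailed=[(n("GangreneOfToe"), n("ParticipantFoot"))],
        expect_ambiguous=[n("Gangrene"), n("GangreneInToe")],
        expect_located={
            n("GangreneInToe"): {n("Toe"), n("Foot")},
            n("GangreneOfToe"): set(),
        },
    )


def _conflict() -> FixtureSpec:
    n = lambda local: EntityName("cf", local)
    ont = _base(
        "cf", "conflict",
        ["BadClass", "BearerThing", "ParticipantThing"],
        bt_classes=[pt.PATHOLOGICAL_ENTITY],
        bt_roles=[pt.HAS_PARTICIPANT, pt.INHERES_IN],
    )
    ont.add(
        SubClassOf(Named(n("BadClass")), Named(pt.PATHOLOGICAL_ENTITY)),
        SubClassOf(Named(n("BadClass")), some(pt.HAS_PARTICIPANT, Named(n("ParticipantThing")))),
        SubClassOf(Named(n("BadClass")), some(pt.INHERES_IN, Named(n("BearerThing")))),
    )
    return FixtureSpec(
        name="conflict",
        ontology=ont,
        expect_unsatisfiable=[n("BadClass")],
    )


def _allergy() -> FixtureSpec:
    n = lambda local: EntityName("al", local)
    ont = _base(
        "al", "allergy",
        ["Allergy", "AllergicReaction", "Allergen", "ImmuneSystemComponent",
         "AllergicRhinitis", "RhinitisDisposition", "RhinitisProcess",
         "InflamedNasalMucosa", "NasalMucosa"],
        bt_classes=[pt.PATHOLOGICAL_DISPOSITION, pt.PATHOLOGICAL_PROCESS,
                    pt.PATHOLOGICAL_STRUCTURE, pt.PATHOLOGICAL_ENTITY],
        bt_roles=[pt.INHERES_IN, pt.HAS_PARTICIPANT, pt.HAS_REALIZATION,
                  pt.REALIZATION_OF, pt.PARTICIPATES_IN, pt.PHYSICAL_PART_OF],
    )
    ont.add(
        SubClassOf(Named(n("Allergy")), Named(pt.PATHOLOGICAL_DISPOSITION)),
        SubClassOf(Named(n("Allergy")), some(pt.INHERES_IN, Named(n("ImmuneSystemComponent")))),
        SubClassOf(Named(n("Allergy")), some(pt.HAS_REALIZATION, Named(n("AllergicReaction")))),
        SubClassOf(Named(n("AllergicReaction")), Named(pt.PATHOLOGICAL_PROCESS)),
        SubClassOf(Named(n("AllergicReaction")), some(pt.REALIZATION_OF, Named(n("Allergy")))),
        SubClassOf(Named(n("AllergicReaction")), some(pt.HAS_PARTICIPANT, Named(n("Allergen")))),
        # the bare name is deliberately uncommitted; its three readings are
        # separate, committed classes
        SubClassOf(Named(n("AllergicRhinitis")), Named(pt.PATHOLOGICAL_ENTITY)),
        SubClassOf(Named(n("RhinitisDisposition")), Named(pt.PATHOLOGICAL_DISPOSITION)),
        SubClassOf(Named(n("RhinitisProcess")), Named(pt.PATHOLOGICAL_PROCESS)),
        SubClassOf(Named(n("RhinitisProcess")), some(pt.REALIZATION_OF, Named(n("RhinitisDisposition")))),
        SubClassOf(Named(n("InflamedNasalMucosa")), Named(pt.PATHOLOGICAL_STRUCTURE)),
        SubClassOf(Named(n("InflamedNasalMucosa")), some(pt.PARTICIPATES_IN, Named(n("RhinitisProcess")))),
        SubClassOf(Named(n("InflamedNasalMucosa")), some(pt.PHYSICAL_PART_OF, Named(n("NasalMucosa")))),
    )
    ont.add_guard(n("Allergy"), pt.HAS_REALIZATION, n("AllergicReaction"))
    return FixtureSpec(
        name="allergy",
        ontology=ont,
        expect_entailed=[
            (n("Allergy"), pt.PATHOLOGICAL_DISPOSITION),
            (n("AllergicReaction"), pt.PATHOLOGICAL_PROCESS),
        ],
        expect_not_entailed=[(n("AllergicRhinitis"), pt.PATHOLOGICAL_PROCESS)],
        expect_ambiguous=[n("AllergicRhinitis")],
        expect_located={n("Allergy"): {n("ImmuneSystemComponent")}},
    )


def _huntington() -> FixtureSpec:
    n = lambda local: EntityName("hd", local)
    ont = _base(
        "hd", "huntington",
        ["HttRepeatExpansion", "TranslationDisposition", "TranslationProcess",
         "MutantHuntingtin", "AggregationDisposition", "AggregationProcess"],
        bt_classes=[pt.PATHOLOGICAL_STRUCTURE, pt.PATHOLOGICAL_DISPOSITION,
                    pt.PATHOLOGICAL_PROCESS, pt.DISPOSITION, pt.PROCESSUAL_ENTITY],
        bt_roles=[pt.INHERES_IN, pt.REALIZATION_OF, pt.HAS_REALIZATION],
    )
    ont.add(
        # stage 1: the repeat expansion bears a *non*-pathological
        # transcription/translation disposition realized by ordinary
        # translation
        SubClassOf(Named(n("HttRepeatExpansion")), Named(pt.PATHOLOGICAL_STRUCTURE)),
        SubClassOf(Named(n("TranslationDisposition")), Named(pt.DISPOSITION)),
        SubClassOf(Named(n("TranslationDisposition")),
                   some(pt.INHERES_IN, Named(n("HttRepeatExpansion")))),
        SubClassOf(Named(n("TranslationProcess")), Named(pt.PROCESSUAL_ENTITY)),
        SubClassOf(Named(n("TranslationProcess")),
                   some(pt.REALIZATION_OF, Named(n("TranslationDisposition")))),
        # stage 2: the mutant protein bears a pathological aggregation
        # disposition realized by a pathological process
        SubClassOf(Named(n("MutantHuntingtin")), Named(pt.PATHOLOGICAL_STRUCTURE)),
        SubClassOf(Named(n("AggregationDisposition")), Named(pt.PATHOLOGICAL_DISPOSITION)),
        SubClassOf(Named(n("AggregationDisposition")),
                   some(pt.INHERES_IN, Named(n("MutantHuntingtin")))),
        SubClassOf(Named(n("AggregationProcess")), Named(pt.PATHOLOGICAL_PROCESS)),
        SubClassOf(Named(n("AggregationProcess")),
                   some(pt.REALIZATION_OF, Named(n("AggregationDisposition")))),
    )
    ont.add_guard(n("AggregationDisposition"), pt.HAS_REALIZATION, n("AggregationProcess"))
    return FixtureSpec(
        name="huntington",
        ontology=ont,
        expect_entailed=[
            (n("AggregationDisposition"), pt.PATHOLOGICAL_DISPOSITION),
            (n("AggregationProcess"), pt.PATHOLOGICAL_PROCESS),
        ],
        expect_not_entailed=[
            (n("TranslationDisposition"), pt.PATHOLOGICAL_DISPOSITION),
            (n("TranslationProcess"), pt.PATHOLOGICAL_PROCESS),
        ],
        expect_located={n("AggregationDisposition"): {n("MutantHuntingtin")}},
    )


def _fracture() -> FixtureSpec:
    n = lambda local: EntityName("fr", local)
    ont = _base(
        "fr", "fracture",
        ["Bone", "FragileBone", "BoneBreakingDisposition", "FractureEvent",
         "PathologicFractureEvent", "FragileBoneDisposition", "FracturedBone",
         "HealingDisposition", "HealingProcess", "RealizationOfPathologicalDisposition"],
        bt_classes=[pt.PATHOLOGICAL_STRUCTURE, pt.PATHOLOGICAL_DISPOSITION,
                    pt.PATHOLOGICAL_PROCESS, pt.DISPOSITION, pt.PROCESSUAL_ENTITY,
                    pt.BODY_STRUCTURE],
        bt_roles=[pt.INHERES_IN, pt.REALIZATION_OF, pt.HAS_REALIZATION,
                  pt.HAS_PARTICIPANT],
    )
    ont.add(
        SubClassOf(Named(n("Bone")), Named(pt.BODY_STRUCTURE)),
        # a traumatic fracture realizes only the normal breaking disposition
        SubClassOf(Named(n("BoneBreakingDisposition")), Named(pt.DISPOSITION)),
        SubClassOf(Named(n("BoneBreakingDisposition")), some(pt.INHERES_IN, Named(n("Bone")))),
        SubClassOf(Named(n("FractureEvent")), Named(pt.PROCESSUAL_ENTITY)),
        SubClassOf(Named(n("FractureEvent")), some(pt.HAS_PARTICIPANT, Named(n("Bone")))),
        SubClassOf(Named(n("FractureEvent")),
                   some(pt.REALIZATION_OF, Named(n("BoneBreakingDisposition")))),
        # the pathological fracture realizes a pathological fragility
        SubClassOf(Named(n("FragileBone")), Named(pt.PATHOLOGICAL_STRUCTURE)),
        SubClassOf(Named(n("FragileBoneDisposition")), Named(pt.PATHOLOGICAL_DISPOSITION)),
        SubClassOf(Named(n("FragileBoneDisposition")), some(pt.INHERES_IN, Named(n("FragileBone")))),
        SubClassOf(Named(n("FragileBoneDisposition")),
                   some(pt.HAS_REALIZATION, Named(n("PathologicFractureEvent")))),
        SubClassOf(Named(n("PathologicFractureEvent")), Named(pt.PATHOLOGICAL_PROCESS)),
        SubClassOf(Named(n("PathologicFractureEvent")),
                   some(pt.REALIZATION_OF, Named(n("FragileBoneDisposition")))),
        # the broken bone bears a non-pathological healing disposition
        SubClassOf(Named(n("FracturedBone")), Named(pt.PATHOLOGICAL_STRUCTURE)),
        SubClassOf(Named(n("HealingDisposition")), Named(pt.DISPOSITION)),
        SubClassOf(Named(n("HealingDisposition")), some(pt.INHERES_IN, Named(n("FracturedBone")))),
        SubClassOf(Named(n("HealingProcess")), Named(pt.PROCESSUAL_ENTITY)),
        SubClassOf(Named(n("HealingProcess")),
                   some(pt.REALIZATION_OF, Named(n("HealingDisposition")))),
        EquivalentClasses((Named(n("RealizationOfPathologicalDisposition")),
                           some(pt.REALIZATION_OF, Named(pt.PATHOLOGICAL_DISPOSITION)))),
    )
    ont.add_guard(n("FragileBoneDisposition"), pt.HAS_REALIZATION, n("PathologicFractureEvent"))
    return FixtureSpec(
        name="fracture",
        ontology=ont,
        expect_entailed=[
            (n("PathologicFractureEvent"), n("RealizationOfPathologicalDisposition")),
        ],
        expect_not_entailed=[
            (n("FractureEvent"), n("RealizationOfPathologicalDisposition")),
            (n("FractureEvent"), pt.PATHOLOGICAL_PROCESS),
            (n("HealingProcess"), pt.PATHOLOGICAL_PROCESS),
        ],
    )


def _pleura() -> FixtureSpec:
    n = lambda local: EntityName("pl", local)
    ont = _base(
        "pl", "pleura",
        ["FibrosisOfPleura", "Fibrosis", "MorphologicAbnormality",
         "PleuralMembraneStructure"],
        bt_classes=[pt.PATHOLOGICAL_ENTITY, pt.MATERIAL_ENTITY],
    )
    ont.declare_role(name("sct:AssociatedMorphology"), name("sct:FindingSite"))
    ont.add(
        SubClassOf(Named(n("FibrosisOfPleura")), Named(pt.PATHOLOGICAL_ENTITY)),
        EquivalentClasses((
            Named(n("FibrosisOfPleura")),
            conj(
                some(name("sct:AssociatedMorphology"), Named(n("Fibrosis"))),
                some(name("sct:FindingSite"), Named(n("PleuralMembraneStructure"))),
            ),
        )),
        SubClassOf(Named(n("Fibrosis")), Named(n("MorphologicAbnormality"))),
        SubClassOf(Named(n("MorphologicAbnormality")), Named(pt.MATERIAL_ENTITY)),
    )
    return FixtureSpec(
        name="pleura",
        ontology=ont,
        expect_not_entailed=[(n("FibrosisOfPleura"), n("Fibrosis"))],
        expect_ambiguous=[n("FibrosisOfPleura")],
    )


def _snomed_toy() -> FixtureSpec:
    n = lambda local: EntityName("sct", local)
    ont = _base(
        "sct", "snomed_toy",
        ["Condition", "PathologicalDisposition", "PathologicalProcess",
         "AllergicRhinitis", "FibrosisOfPleura", "Fibrosis",
         "MorphologicAbnormality", "BodyStructure", "PleuralMembraneStructure",
         "Event", "Asphyxiation"],
        bt_classes=[pt.PATHOLOGICAL_ENTITY, pt.PATHOLOGICAL_DISPOSITION,
                    pt.PATHOLOGICAL_PROCESS, pt.MATERIAL_ENTITY, pt.PROCESSUAL_ENTITY],
    )
    ont.declare_role(name("sct:AssociatedMorphology"), name("sct:FindingSite"))
    ont.add(
        # the disjunctive Condition node and the two new top-level classes
        # are aliases of their pattern counterparts
        EquivalentClasses((Named(n("Condition")), Named(pt.PATHOLOGICAL_ENTITY))),
        EquivalentClasses((Named(n("PathologicalDisposition")), Named(pt.PATHOLOGICAL_DISPOSITION))),
        EquivalentClasses((Named(n("PathologicalProcess")), Named(pt.PATHOLOGICAL_PROCESS))),
        SubClassOf(Named(n("AllergicRhinitis")), Named(n("Condition"))),
        SubClassOf(Named(n("FibrosisOfPleura")), Named(n("Condition"))),
        EquivalentClasses((
            Named(n("FibrosisOfPleura")),
            conj(
                some(name("sct:AssociatedMorphology"), Named(n("Fibrosis"))),
                some(name("sct:FindingSite"), Named(n("PleuralMembraneStructure"))),
            ),
        )),
        SubClassOf(Named(n("Fibrosis")), Named(n("MorphologicAbnormality"))),
        SubClassOf(Named(n("MorphologicAbnormality")), Named(n("BodyStructure"))),
        SubClassOf(Named(n("PleuralMembraneStructure")), Named(n("BodyStructure"))),
        SubClassOf(Named(n("BodyStructure")), Named(pt.MATERIAL_ENTITY)),
        # events are processes
        SubClassOf(Named(n("Event")), Named(pt.PROCESSUAL_ENTITY)),
        SubClassOf(Named(n("Asphyxiation")), Named(n("Event"))),
    )
    return FixtureSpec(
        name="snomed_toy",
        ontology=ont,
        expect_entailed=[
            (n("Condition"), pt.PATHOLOGICAL_ENTITY),
            (n("Asphyxiation"), pt.PROCESSUAL_ENTITY),
        ],
        expect_not_entailed=[(n("FibrosisOfPleura"), n("Fibrosis"))],
        expect_ambiguous=[n("AllergicRhinitis"), n("FibrosisOfPleura")],
    )


_BUILDERS = {
    "tumor": _tumor,
    "disposition_chain": _disposition_chain,
    "gangrene": _gangrene,
    "conflict": _conflict,
    "allergy": _allergy,
    "huntington": _huntington,
    "fracture": _fracture,
    "pleura": _pleura,
    "snomed_toy": _snomed_toy,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def build_fixture(fixture_name: str) -> FixtureSpec:
    """Build one of the catalogued fixtures (deterministically)."""
    try:
        builder = _BUILDERS[fixture_name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {fixture_name!r}; choose from {sorted(_BUILDERS)}"
        ) from None
    return builder()


def fixture_manifest() -> str:
    """JSON manifest of every fixture's expectations."""
    return json.dumps(
        [build_fixture(fname).manifest_entry() for fname in FIXTURE_NAMES],
        indent=2,
        ensure_ascii=False,
    )


# ---------------------------------------------------------------------------
# Random ontology generator
# ---------------------------------------------------------------------------

AXIOM_KINDS = (
    "atomic",
    "conjunctive",
    "existential-intro",
    "existential-elim",
    "subrole",
    "transitivity",
    "disjointness",
)

DEFAULT_MIX = {
    "atomic": 0.28,
    "conjunctive": 0.14,
    "existential-intro": 0.20,
    "existential-elim": 0.16,
    "subrole": 0.08,
    "transitivity": 0.06,
    "disjointness": 0.08,
}


@dataclass(frozen=True)
class RandomOntologyParams:
    seed: int
    n_classes: int = 15
    n_roles: int = 3
    n_axioms: int = 25
    mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_MIX.items())

    def validate(self) -> None:
        if self.n_classes < 2 or self.n_roles < 1 or self.n_axioms < 0:
            raise InvalidParamsError(
                "need n_classes >= 2, n_roles >= 1, n_axioms >= 0"
            )
        weights = dict(self.mix)
        if set(weights) - set(AXIOM_KINDS):
            raise InvalidParamsError(f"unknown axiom kinds in mix: {weights}")
        if sum(weights.values()) <= 0 or any(w < 0 for w in weights.values()):
            raise InvalidParamsError("mix weights must be nonnegative, sum > 0")


def random_ontology(params: RandomOntologyParams) -> Ontology:
    """A seeded random ontology over the calculus-supported constructs.

    Never emits guard or covering declarations.  The same params yield a
    byte-identical serialization; the axiom count matches ``n_axioms``
    exactly.
    """
    params.validate()
    rng = random.Random(params.seed)
    classes = [EntityName("rnd", f"C{i:02d}") for i in range(params.n_classes)]
    roles = [EntityName("rnd", f"r{i}") for i in range(params.n_roles)]
    ont = Ontology(iri=f"urn:sdpkit:random:{params.seed}")
    ont.declare_class(*classes)
    ont.declare_role(*roles)

    kinds = [k for k, _ in params.mix]
    weights = [w for _, w in params.mix]
    for _ in range(params.n_axioms):
        kind = rng.choices(kinds, weights=weights, k=1)[0]
        if kind == "atomic":
            ont.add(SubClassOf(Named(rng.choice(classes)), Named(rng.choice(classes))))
        elif kind == "conjunctive":
            a1, a2 = rng.choice(classes), rng.choice(classes)
            ont.add(SubClassOf(Conjunction((Named(a1), Named(a2))),
                               Named(rng.choice(classes))))
        elif kind == "existential-intro":
            ont.add(SubClassOf(Named(rng.choice(classes)),
                               Existential(rng.choice(roles), Named(rng.choice(classes)))))
        elif kind == "existential-elim":
            ont.add(SubClassOf(Existential(rng.choice(roles), Named(rng.choice(classes))),
                               Named(rng.choice(classes))))
        elif kind == "subrole":
            ont.add(SubRoleOf(rng.choice(roles), rng.choice(roles)))
        elif kind == "transitivity":
            ont.add(TransitiveRole(rng.choice(roles)))
        else:  # disjointness
            a, b = rng.sample(classes, 2)
            ont.add(DisjointClasses((Named(a), Named(b))))
    return ont
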