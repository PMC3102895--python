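"""The SDP pattern module: category inference, location closure, guards."""

import pytest

from sdpkit import (
    Category,
    Reasoner,
    build_fixture,
    check_realization_guard,
    conformance_report,
    infer_category,
    is_subsumed,
    located_in_closure,
    merge_pattern,
    name,
    sdp_axioms,
)
from sdpkit.errors import UnknownNameError
from sdpkit.model import (
    DisjointClasses,
    EquivalentClasses,
    Named,
    SubClassOf,
    some,
)
from sdpkit import pattern as pt


# ---------------------------------------------------------------------------
# the axiom module itself
# ---------------------------------------------------------------------------


def test_pattern_module_is_consistent(pattern_ontology):
    assert Reasoner(pattern_ontology).unsatisfiable_classes() == set()


def test_pathological_entity_covers_exactly_the_three_categories(pattern_ontology):
    (cov,) = pattern_ontology.covering
    assert cov.covered.name == pt.PATHOLOGICAL_ENTITY
    assert tuple(d.name for d in cov.disjuncts) == (
        pt.PATHOLOGICAL_STRUCTURE,
        pt.PATHOLOGICAL_DISPOSITION,
        pt.PATHOLOGICAL_PROCESS,
    )
    r = Reasoner(pattern_ontology)
    for d in cov.disjuncts:
        assert r.is_subsumed(d.name, pt.PATHOLOGICAL_ENTITY)


def test_processes_are_not_forced_to_realize_a_disposition(pattern_ontology):
    """The converse-dependency axiom is deliberately absent: a pathological
    process need not be the realization of a pathological disposition."""
    ont = pattern_ontology.copy()
    wrapper = name("ex:RealizesPathologicalDisposition")
    ont.declare_class(wrapper)
    ont.add(
        EquivalentClasses((
            Named(wrapper),
            some(pt.REALIZATION_OF, Named(pt.PATHOLOGICAL_DISPOSITION)),
        ))
    )
    assert not is_subsumed(ont, pt.PATHOLOGICAL_PROCESS, wrapper)


def test_categories_are_pairwise_disjoint(pattern_ontology):
    ont = pattern_ontology.copy()
    probe = name("ex:Both")
    ont.declare_class(probe)
    ont.add(
        SubClassOf(Named(probe), Named(pt.PATHOLOGICAL_STRUCTURE)),
        SubClassOf(Named(probe), Named(pt.PATHOLOGICAL_PROCESS)),
    )
    assert probe in Reasoner(ont).unsatisfiable_classes()


# ---------------------------------------------------------------------------
# category inference
# ---------------------------------------------------------------------------


def test_participant_refinement_commits_to_process(merged_reasoners):
    _, merged, r = merged_reasoners["gangrene"]
    verdict = infer_category(merged, name("gg:GangreneOfToe"), reasoner=r)
    assert verdict.verdict == Category.PROCESS
    assert any("PathologicalProcess" in e for e in verdict.evidence)


def test_mixed_participation_and_inherence_is_a_conflict(merged_reasoners):
    _, merged, r = merged_reasoners["conflict"]
    assert infer_category(merged, name("cf:BadClass"), reasoner=r).verdict == Category.CONFLICT


def test_bare_condition_class_stays_uncommitted(merged_reasoners):
    _, merged, r = merged_reasoners["snomed_toy"]
    verdict = infer_category(merged, name("sct:AllergicRhinitis"), reasoner=r)
    assert verdict.verdict == Category.UNCOMMITTED


def test_direct_assertion_wins(merged_reasoners):
    _, merged, r = merged_reasoners["allergy"]
    assert infer_category(merged, name("al:Allergy"), reasoner=r).verdict == Category.DISPOSITION
    assert (
        infer_category(merged, name("al:InflamedNasalMucosa"), reasoner=r).verdict
        == Category.STRUCTURE
    )


def test_infer_category_unknown_name(merged_reasoners):
    _, merged, r = merged_reasoners["allergy"]
    with pytest.raises(UnknownNameError):
        infer_category(merged, name("al:Nope"), reasoner=r)


def test_category_exclusivity_across_all_fixtures(merged_reasoners):
    """No satisfiable class is entailed under two of the three categories."""
    from sdpkit import BOT

    cats = (pt.PATHOLOGICAL_STRUCTURE, pt.PATHOLOGICAL_DISPOSITION, pt.PATHOLOGICAL_PROCESS)
    for fname, (_, merged, r) in merged_reasoners.items():
        for cls in merged.classes:
            subsumers = r.state.subsumers(cls)
            if BOT in subsumers:
                continue
            hits = [c for c in cats if c in subsumers]
            assert len(hits) <= 1, (fname, str(cls), [str(h) for h in hits])


# ---------------------------------------------------------------------------
# location closure
# ---------------------------------------------------------------------------


def test_tumor_location_closure(merged_reasoners):
    _, merged, r = merged_reasoners["tumor"]
    assert located_in_closure(merged, name("tm:TumorOfSigmoid"), reasoner=r) == {
        name("tm:SigmoidColon"), name("tm:Colon"), name("tm:Intestine")
    }


def test_disposition_chain_location_closure(merged_reasoners):
    _, merged, r = merged_reasoners["disposition_chain"]
    assert located_in_closure(merged, name("dc:D"), reasoner=r) == {
        name("dc:S"), name("dc:S2")
    }


def test_class_without_location_axioms_has_empty_closure(merged_reasoners):
    _, merged, r = merged_reasoners["gangrene"]
    assert located_in_closure(merged, name("gg:Foot"), reasoner=r) == set()


def test_participation_does_not_propagate_but_location_does(merged_reasoners):
    """A gangrene *of* the toe is not a gangrene of the foot; a gangrene
    *located in* a toe is located in the foot."""
    _, merged, r = merged_reasoners["gangrene"]
    assert r.is_subsumed(name("gg:GangreneInToe"), name("gg:LocatedInFoot"))
    assert not r.is_subsumed(name("gg:GangreneOfToe"), name("gg:ParticipantFoot"))


def test_closure_monotone_under_partonomy_additions(merged_reasoners):
    _, merged, _ = merged_reasoners["tumor"]
    extended = merged.copy()
    abdomen = name("tm:Abdomen")
    extended.declare_class(abdomen)
    extended.add(SubClassOf(Named(name("tm:Intestine")),
                            some(pt.PHYSICAL_PART_OF, Named(abdomen))))
    before = located_in_closure(merged, name("tm:TumorOfSigmoid"))
    after = located_in_closure(extended, name("tm:TumorOfSigmoid"))
    assert before < after and abdomen in after


# ---------------------------------------------------------------------------
# guards and conformance
# ---------------------------------------------------------------------------


def test_allergy_realization_guard_is_satisfied(merged_reasoners):
    _, merged, r = merged_reasoners["allergy"]
    assert check_realization_guard(merged, reasoner=r).ok


def test_guard_violation_when_disposition_realized_by_non_process():
    ont = merge_pattern(build_fixture("allergy").ontology)
    bad = name("al:NotAProcess")
    ont.declare_class(bad)
    ont.add(
        SubClassOf(Named(bad), Named(pt.MATERIAL_ENTITY)),
        SubClassOf(Named(name("al:Allergy")), some(pt.HAS_REALIZATION, Named(bad))),
    )
    report = check_realization_guard(ont)
    kinds = {v.kind for v in report.violations}
    assert kinds == {"realization-guard"}
    assert any(v.cls == name("al:Allergy") for v in report.violations)


def test_no_realization_assertions_means_empty_guard_report(merged_reasoners):
    _, merged, r = merged_reasoners["tumor"]
    assert check_realization_guard(merged, reasoner=r).ok


def test_guards_are_stable_under_location_additions(merged_reasoners):
    """Adding partonomy axioms cannot create realization-guard violations."""
    _, merged, _ = merged_reasoners["allergy"]
    extended = merged.copy()
    extended.add(
        SubClassOf(Named(name("al:ImmuneSystemComponent")),
                   some(pt.PHYSICAL_PART_OF, Named(name("al:NasalMucosa")))),
    )
    assert check_realization_guard(extended).ok


@pytest.mark.parametrize("fixture_name", ["tumor", "allergy", "huntington", "fracture"])
def test_conformant_fixtures_have_empty_reports(merged_reasoners, fixture_name):
    _, merged, _ = merged_reasoners[fixture_name]
    assert conformance_report(merged).ok


def test_conflict_fixture_reports_one_conflict(merged_reasoners):
    _, merged, _ = merged_reasoners["conflict"]
    report = conformance_report(merged)
    assert [(v.kind, v.cls) for v in report.violations] == [
        ("conflict", name("cf:BadClass"))
    ]


def test_missing_disjointness_axioms_are_flagged():
    stripped = sdp_axioms()
    stripped.axioms = [
        ax for ax in stripped.axioms if not isinstance(ax, DisjointClasses)
    ]
    report = conformance_report(stripped)
    missing = [v for v in report.violations if v.kind == "missing-pattern-axiom"]
    assert len(missing) == sum(
        isinstance(ax, DisjointClasses) for ax in sdp_axioms().axioms
    )


def test_pattern_never_forces_commitment():
    """Merging the pattern into an ontology of uncommitted disease classes
    adds no subsumptions among those classes."""
    from sdpkit import Ontology, Reasoner

    o = Ontology(iri="urn:test")
    a, b = name("ex:DiseaseA"), name("ex:DiseaseB")
    o.declare_class(a, b, pt.PATHOLOGICAL_ENTITY)
    o.add(SubClassOf(Named(a), Named(pt.PATHOLOGICAL_ENTITY)),
          SubClassOf(Named(b), Named(pt.PATHOLOGICAL_ENTITY)))
    own = {a, b}
    before = {(x, y) for x, y in Reasoner(o).entailed_pairs() if x in own and y in own}
    merged = merge_pattern(o)
    after = {(x, y) for x, y in Reasoner(merged).entailed_pairs() if x in own and y in own}
    assert before == after
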