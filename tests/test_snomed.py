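"""SNOMED-style relation mapping, ambiguity audit, and disambiguation."""

import pytest

from sdpkit import (
    BOT,
    Ontology,
    Reasoner,
    RelationMapping,
    TOP,
    build_fixture,
    detect_ambiguous,
    disambiguate,
    located_in_closure,
    map_to_biotop,
    merge_pattern,
    name,
    oracle_subsumptions,
)
from sdpkit.errors import NameCollisionError, NotAmbiguousError, UnknownRoleError
from sdpkit.model import Named, SubClassOf
from sdpkit import pattern as pt


# ---------------------------------------------------------------------------
# relation mapping
# ---------------------------------------------------------------------------


def test_finding_site_mapping_enables_location_propagation():
    """After FindingSite→hasLocus, the pleural fibrosis finding gains a
    location closure through the pattern's role box."""
    spec = build_fixture("pleura")
    merged = merge_pattern(map_to_biotop(spec.ontology))
    closure = located_in_closure(merged, name("pl:FibrosisOfPleura"))
    assert name("pl:PleuralMembraneStructure") in closure
    # AssociatedMorphology stays its own role: Fibrosis is not a location
    assert name("pl:Fibrosis") not in closure


def test_mapping_without_source_roles_is_identity():
    ont = build_fixture("tumor").ontology
    assert map_to_biotop(ont).structurally_equal(ont)


def test_explicit_mapping_with_undeclared_source_role_fails():
    ont = build_fixture("tumor").ontology
    mapping = RelationMapping(pairs=((name("sct:FindingSite"), name("bt:hasLocus")),))
    with pytest.raises(UnknownRoleError):
        map_to_biotop(ont, mapping)


# ---------------------------------------------------------------------------
# ambiguity audit
# ---------------------------------------------------------------------------


def test_snomed_toy_flags_the_two_uncommitted_condition_classes(merged_reasoners):
    _, merged, r = merged_reasoners["snomed_toy"]
    assert detect_ambiguous(merged, reasoner=r) == [
        name("sct:AllergicRhinitis"),
        name("sct:FibrosisOfPleura"),
    ]


def test_generated_children_are_not_flagged(merged_reasoners):
    _, merged, _ = merged_reasoners["snomed_toy"]
    out, plan = disambiguate(merged, name("sct:AllergicRhinitis"),
                             ["Process", "Disposition"])
    flagged = set(detect_ambiguous(out))
    for _, new, _ in plan.entries:
        assert new not in flagged


def test_fully_committed_ontology_has_no_ambiguity():
    o = Ontology(iri="urn:test")
    d = name("ex:SomeDisposition")
    o.declare_class(d, pt.PATHOLOGICAL_DISPOSITION)
    o.add(SubClassOf(Named(d), Named(pt.PATHOLOGICAL_DISPOSITION)))
    assert detect_ambiguous(merge_pattern(o)) == []


# ---------------------------------------------------------------------------
# disambiguation
# ---------------------------------------------------------------------------


def test_allergic_rhinitis_disambiguation_follows_the_naming_convention(
    merged_reasoners,
):
    _, merged, _ = merged_reasoners["snomed_toy"]
    out, plan = disambiguate(merged, name("sct:AllergicRhinitis"),
                             ["Process", "Disposition"])
    assert [str(n) for _, n, _ in plan.entries] == [
        "sct:ManifestAllergicRhinitis",
        "sct:AllergicRhinitisDisposition",
    ]
    r = Reasoner(out)
    for _, new, _ in plan.entries:
        assert r.is_subsumed(new, name("sct:AllergicRhinitis"))
        assert not r.is_unsatisfiable(new)
    assert r.is_subsumed(name("sct:ManifestAllergicRhinitis"),
                         name("sct:PathologicalProcess"))
    assert r.is_subsumed(name("sct:AllergicRhinitisDisposition"),
                         name("sct:PathologicalDisposition"))


def test_generated_siblings_are_entailed_disjoint(merged_reasoners):
    _, merged, _ = merged_reasoners["snomed_toy"]
    out, plan = disambiguate(merged, name("sct:AllergicRhinitis"),
                             ["Process", "Disposition"])
    probe = out.copy()
    p = name("ex:BothChildren")
    probe.declare_class(p)
    for _, new, _ in plan.entries:
        probe.add(SubClassOf(Named(p), Named(new)))
    assert p in Reasoner(probe).unsatisfiable_classes()


def test_pleural_structure_child_is_still_not_a_fibrosis(merged_reasoners):
    """The morphology/finding split survives disambiguation: the structure
    reading of pleural fibrosis is not subsumed by Fibrosis."""
    _, merged, _ = merged_reasoners["snomed_toy"]
    out, plan = disambiguate(merged, name("sct:FibrosisOfPleura"),
                             ["Process", "Structure"])
    r = Reasoner(out)
    for _, new, _ in plan.entries:
        assert not r.is_subsumed(new, name("sct:Fibrosis"))


def test_disambiguating_a_committed_class_fails(merged_reasoners):
    _, merged, _ = merged_reasoners["snomed_toy"]
    with pytest.raises(NotAmbiguousError):
        disambiguate(merged, name("sct:Fibrosis"), ["Process"])


def test_name_collision_aborts(merged_reasoners):
    _, merged, _ = merged_reasoners["snomed_toy"]
    colliding = merged.copy()
    colliding.declare_class(name("sct:ManifestAllergicRhinitis"))
    with pytest.raises(NameCollisionError):
        disambiguate(colliding, name("sct:AllergicRhinitis"), ["Process"])


@pytest.mark.parametrize(
    "cls,categories",
    [
        ("sct:AllergicRhinitis", ["Process", "Disposition"]),
        ("sct:FibrosisOfPleura", ["Process", "Structure"]),
    ],
)
def test_disambiguation_is_conservative(merged_reasoners, cls, categories):
    """No subsumption among pre-existing names changes after a plan."""
    _, merged, _ = merged_reasoners["snomed_toy"]
    before = oracle_subsumptions(merged)
    out, _ = disambiguate(merged, name(cls), categories)
    keep = merged.classes | {TOP, BOT}
    after = {
        (a, b) for a, b in oracle_subsumptions(out)
        if a in merged.classes and b in keep
    }
    assert before == after
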