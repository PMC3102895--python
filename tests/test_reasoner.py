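"""Saturation, classification, unsatisfiability, and derivation traces."""

import random

import pytest

from sdpkit import (
    BOT,
    TOP,
    Ontology,
    RandomOntologyParams,
    Reasoner,
    build_fixture,
    classify,
    explain,
    is_subsumed,
    merge_pattern,
    name,
    normalize,
    random_ontology,
    replay_trace,
    saturate,
    unsatisfiable_classes,
)
from sdpkit.errors import NotEntailedError, UnknownNameError
from sdpkit.model import DisjointClasses, Named, SubClassOf
from sdpkit.normalize import NormalizedAxiomSet
from sdpkit.pattern import (
    PATHOLOGICAL_DISPOSITION,
    PATHOLOGICAL_ENTITY,
    PATHOLOGICAL_PROCESS,
    PATHOLOGICAL_STRUCTURE,
)


def test_empty_ontology_saturates_to_reflexive_and_top_only():
    o = Ontology(iri="urn:test")
    o.declare_class(name("ex:A"), name("ex:B"))
    state = saturate(normalize(o))
    assert state.subsumers(name("ex:A")) == {name("ex:A"), TOP}
    assert state.subsumers(name("ex:B")) == {name("ex:B"), TOP}
    assert all(not pairs for pairs in state.R.values())


def test_reflexivity_and_top_hold_for_any_declared_class():
    o = build_fixture("tumor").ontology
    a = name("tm:Tumor")
    assert is_subsumed(o, a, a)
    assert is_subsumed(o, a, TOP)


def test_unknown_name_raises():
    o = build_fixture("tumor").ontology
    with pytest.raises(UnknownNameError):
        is_subsumed(o, name("tm:Tumor"), name("tm:NoSuchClass"))


def test_tumor_partonomy_subsumptions(merged_reasoners):
    _, _, r = merged_reasoners["tumor"]
    assert r.is_subsumed(name("tm:TumorOfSigmoid"), name("tm:TumorOfColon"))
    assert r.is_subsumed(name("tm:TumorOfSigmoid"), name("tm:TumorOfIntestine"))
    assert not r.is_subsumed(name("tm:TumorOfColon"), name("tm:TumorOfSigmoid"))


def test_pleural_fibrosis_is_not_a_fibrosis(merged_reasoners):
    _, _, r = merged_reasoners["pleura"]
    assert not r.is_subsumed(name("pl:FibrosisOfPleura"), name("pl:Fibrosis"))


def test_classify_places_the_three_categories_under_pathological_entity(
    pattern_ontology,
):
    tax = classify(pattern_ontology)
    for cat in (PATHOLOGICAL_STRUCTURE, PATHOLOGICAL_DISPOSITION, PATHOLOGICAL_PROCESS):
        rep = tax.representative(cat)
        assert rep not in tax.unsatisfiable
        assert PATHOLOGICAL_ENTITY in tax.direct_sup[rep]
    assert not tax.unsatisfiable


def test_classify_is_stable_across_repeated_calls(merged_reasoners):
    _, merged, _ = merged_reasoners["tumor"]
    t1, t2 = classify(merged), classify(merged)
    assert t1.groups == t2.groups
    assert t1.direct_sup == t2.direct_sup
    assert t1.to_tsv() == t2.to_tsv()


def test_conflicting_participation_and_inherence_is_unsatisfiable(merged_reasoners):
    _, merged, r = merged_reasoners["conflict"]
    assert r.unsatisfiable_classes() == {name("cf:BadClass")}
    tax = classify(merged)
    assert name("cf:BadClass") in tax.unsatisfiable
    assert f"cf:BadClass\t{BOT}" in tax.to_tsv()


def test_disjointness_makes_a_common_subclass_unsatisfiable():
    o = Ontology(iri="urn:test")
    s, d, c = name("ex:S"), name("ex:D"), name("ex:C")
    o.declare_class(s, d, c)
    o.add(
        DisjointClasses((Named(s), Named(d))),
        SubClassOf(Named(c), Named(s)),
        SubClassOf(Named(c), Named(d)),
    )
    assert unsatisfiable_classes(o) == {c}


def test_pattern_alone_has_no_unsatisfiable_classes(pattern_ontology):
    assert unsatisfiable_classes(pattern_ontology) == set()


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def test_explain_reflexive_subsumption_is_a_single_initialization_step():
    o = build_fixture("tumor").ontology
    trace = explain(o, name("tm:Tumor"), name("tm:Tumor"))
    assert len(trace.steps) == 1 and trace.steps[0].rule == "init"


def test_explain_rejects_non_entailed_subsumption():
    o = build_fixture("tumor").ontology
    with pytest.raises(NotEntailedError):
        explain(o, name("tm:Colon"), name("tm:Tumor"))


def test_disposition_chain_trace_cites_role_inclusion_and_transitivity(
    merged_reasoners,
):
    """The derivation of D ⊑ ∃hasLocus.S′ must pass through the
    inheresIn⊑hasLocus role inclusion, the partonomy step, and hasLocus
    transitivity."""
    _, merged, _ = merged_reasoners["disposition_chain"]
    trace = explain(merged, name("dc:D"), name("dc:LocatedInS2"))
    rules = {s.rule for s in trace.steps}
    assert {"R6", "R7"} <= rules  # role-hierarchy lift + transitivity
    assert replay_trace(normalize(merged), trace,
                        ("sub", name("dc:D"), name("dc:LocatedInS2")))


def test_explain_through_unsatisfiability(merged_reasoners):
    _, merged, _ = merged_reasoners["conflict"]
    trace = explain(merged, name("cf:BadClass"), name("cf:BearerThing"))
    assert trace.steps[-1].rule == "bottom"
    assert replay_trace(normalize(merged), trace,
                        ("sub", name("cf:BadClass"), name("cf:BearerThing")))


@pytest.mark.parametrize("seed", range(30))
def test_every_reported_trace_replays_on_random_ontologies(seed):
    ont = random_ontology(RandomOntologyParams(seed=seed))
    r = Reasoner(ont)
    pairs = sorted(
        (a, b) for a, b in r.entailed_pairs() if a != b and b not in (TOP, BOT)
    )
    rng = random.Random(seed)
    for a, b in rng.sample(pairs, min(5, len(pairs))):
        trace = explain(ont, a, b)
        assert replay_trace(r.norm, trace, ("sub", a, b)), (seed, str(a), str(b))


# ---------------------------------------------------------------------------
# order independence and monotonicity
# ---------------------------------------------------------------------------


def _shuffled(norm: NormalizedAxiomSet, seed: int) -> NormalizedAxiomSet:
    rng = random.Random(seed)
    out = NormalizedAxiomSet(
        atomic=list(norm.atomic),
        conjunctive=list(norm.conjunctive),
        exist_intro=list(norm.exist_intro),
        exist_elim=list(norm.exist_elim),
        role_inclusions=list(norm.role_inclusions),
        transitive_roles=set(norm.transitive_roles),
        fresh_names=list(norm.fresh_names),
        declared_classes=set(norm.declared_classes),
        declared_roles=set(norm.declared_roles),
    )
    for bucket in (out.atomic, out.conjunctive, out.exist_intro,
                   out.exist_elim, out.role_inclusions):
        rng.shuffle(bucket)
    return out


@pytest.mark.parametrize("fixture_name", ["tumor", "disposition_chain", "conflict"])
def test_saturation_is_independent_of_axiom_order(merged_reasoners, fixture_name):
    _, merged, r = merged_reasoners[fixture_name]
    for k in range(10):
        state = saturate(_shuffled(r.norm, seed=k))
        assert state.S == r.state.S
        assert state.R == r.state.R


def test_adding_axioms_never_removes_entailments():
    """Monotonicity: 50 random axiom additions to the gangrene fixture only
    grow the entailed subsumption set."""
    base = merge_pattern(build_fixture("gangrene").ontology)
    base_pairs = Reasoner(base).entailed_pairs()
    rng = random.Random(0)
    classes = sorted(c for c in base.classes if c.prefix == "gg")
    for _ in range(50):
        extended = base.copy()
        extended.add(SubClassOf(Named(rng.choice(classes)), Named(rng.choice(classes))))
        assert base_pairs <= Reasoner(extended).entailed_pairs()
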