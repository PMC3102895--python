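# sdpkit

Biomedical ontologies disagree about what a "disease" is: a damaged body
part, a risk it carries, or the process in which that risk unfolds.  The
structure–disposition–process (SDP) design pattern resolves this by
modeling all three — a pathological **structure** (e.g. an expanded CAG
repeat, a fragile bone) bears a pathological **disposition** (the potential
to aggregate, to break), which may be realized by a pathological
**process** (aggregation, a pathological fracture) — while still letting an
ontology *defer* the choice: a disjunctive class `PathologicalEntity`
(`Condition` in SNOMED CT terms) covers all three disjoint categories, so a
disease class can stay uncommitted until an axiom forces its category.

`sdpkit` is an executable toolkit for this pattern, aimed at ontology
engineers and terminologists:

* a reader/writer for a restricted OWL 2 functional-style dialect
  (EL-profile constructs only, plus guard and covering declarations);
* an EL⊥ completion-rule reasoner: structural normalization with fresh
  names, worklist saturation of the rules

  ```
  A′ ∈ S(A),  A′ ⊑ B           ⇒  B ∈ S(A)
  A1,A2 ∈ S(A),  A1 ⊓ A2 ⊑ B   ⇒  B ∈ S(A)
  A′ ∈ S(A),  A′ ⊑ ∃r.B        ⇒  (A,B) ∈ R(r)
  (A,B) ∈ R(r),  B′ ∈ S(B),  ∃r.B′ ⊑ C  ⇒  C ∈ S(A)
  (A,B) ∈ R(r),  ⊥ ∈ S(B)      ⇒  ⊥ ∈ S(A)
  (A,B) ∈ R(r),  r ⊑ s         ⇒  (A,B) ∈ R(s)
  (A,B),(B,C) ∈ R(r),  r transitive  ⇒  (A,C) ∈ R(r)
  ```

  plus classification into an equivalence-collapsed, transitively reduced
  taxonomy, replayable derivation traces, and an independent naive oracle
  for cross-checking;
* the SDP axiom module itself (category placements and disjointness, the
  `inheresIn`/`hasParticipant` dependencies and domain constraints, the
  `physicalPartOf ⊑ physicallyLocatedIn ⊑ hasLocus` / `inheresIn ⊑
  hasLocus` role box with transitive `hasLocus`), with category inference,
  location closure, realization-guard checking, and conformance reports;
* a SNOMED-style adapter: `FindingSite → hasLocus` mapping, detection of
  condition classes that are ambiguous between process and disposition,
  and generation of committed subclasses such as
  `ManifestAllergicRhinitis ≡ AllergicRhinitis ⊓ PathologicalProcess`;
* nine built-in clinical fixtures (tumor partonomy, gangrene, allergy,
  Huntington cascade, fracture, pleural fibrosis, ...) and a seeded
  random-ontology generator.

## Worked example

```python
from sdpkit import (build_fixture, merge_pattern, detect_ambiguous,
                    disambiguate, located_in_closure, is_subsumed, name)

ont = merge_pattern(build_fixture("snomed_toy").ontology)
print([str(c) for c in detect_ambiguous(ont)])
# ['sct:AllergicRhinitis', 'sct:FibrosisOfPleura']

rewritten, plan = disambiguate(ont, name("sct:AllergicRhinitis"),
                               ["Process", "Disposition"])
for cat, new, ax in plan.entries:
    print(f"{cat}: {ax}")
# Process: sct:ManifestAllergicRhinitis equivalentTo (sct:AllergicRhinitis and sct:PathologicalProcess)
# Disposition: sct:AllergicRhinitisDisposition equivalentTo (sct:AllergicRhinitis and sct:PathologicalDisposition)

tm = merge_pattern(build_fixture("tumor").ontology)
print(sorted(str(c) for c in located_in_closure(tm, name("tm:TumorOfSigmoid"))))
# ['tm:Colon', 'tm:Intestine', 'tm:SigmoidColon']
print(is_subsumed(tm, name("tm:TumorOfSigmoid"), name("tm:TumorOfIntestine")))
# True
```

The audit finds exactly the two condition classes that commit to neither
category; disambiguation adds equivalence-defined children committed to
one category each (provably disjoint siblings, and conservative over all
pre-existing subsumptions).  The tumor example shows location propagation:
because `physicalPartOf` and `inheresIn` both specialize the transitive
`hasLocus`, a tumor of the sigmoid colon is located in — and classifies
under tumors of — the colon and the intestine, whether "tumor" is read as
structure or process.  Participation deliberately does not propagate: a
gangrene *of* the toe is not a gangrene *of* the foot.

The same operations are available on the command line:

```sh
sdpkit fixture --name snomed_toy --out toy.ofn
sdpkit audit toy.ofn --report audit.json
sdpkit disambiguate toy.ofn --class sct:AllergicRhinitis \
    --into process,disposition --out toy_fixed.ofn
sdpkit classify toy_fixed.ofn --with-pattern --out taxonomy.tsv
sdpkit explain toy.ofn --sub sct:FibrosisOfPleura --sup bt:PathologicalEntity \
    --out trace.json
```

`check` exits 3 when conformance violations are found, 1 on parse errors,
2 on usage errors.

## Dialect notes

The input syntax is a strict subset of OWL 2 functional-style syntax.  The
correspondence with the Manchester keywords common in the modeling
literature: `subClassOf` → `SubClassOf`, `equivalentTo` →
`EquivalentClasses`, `and` → `ObjectIntersectionOf`, `some` →
`ObjectSomeValuesFrom`, `only` → `ObjectAllValuesFrom` (allowed only as a
guard, i.e. the entire superclass of a named class), `or` →
`ObjectUnionOf` (allowed only as a covering, i.e. the definition of a
disjunctive class).  Inverse roles are outside the EL calculus; paired
roles such as `bearerOf`/`inheresIn` are declared independently and carry
no inverse semantics (a documented limitation, see `docs/methods.md`).

A known SNOMED CT wrinkle that the toolkit documents but does not try to
repair: the structure/finding split produces disconnected duplicates such
as `BlastCell` (body structure) vs `BlastCellsPresent` (finding); lexical
duplicate detection is out of scope here.

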