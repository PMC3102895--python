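# Methods

## The model

`sdpkit` implements the SDP (structure–disposition–process) account of
pathological entities as a computable artifact.  Its ontological
commitments are:

* **Three disjoint categories.**  `bt:PathologicalStructure` (a material
  entity), `bt:PathologicalDisposition` (a dependent continuant inhering
  in a bearer), `bt:PathologicalProcess` (an occurrent).  Disease
  cascades iterate the triad: the outcome of one pathological process is
  a structure bearing the next disposition.
* **Deferred commitment.**  `bt:PathologicalEntity` is the disjunctive
  covering of the three categories.  An ontology may place a disease
  class under it without choosing a category; the toolkit reports such
  classes as *uncommitted* rather than forcing a reading.
* **One location relation.**  `physicalPartOf ⊑ physicallyLocatedIn ⊑
  hasLocus` and `inheresIn ⊑ hasLocus`, with `hasLocus` transitive.
  Location therefore propagates along partonomy for structures,
  dispositions, and processes alike, while `hasParticipant` — not a
  sub-role of `hasLocus` — does not propagate: participation names a
  causal involvement, not a place.
* **Directional realization.**  A disposition constrains what may realize
  it (`hasRealization only PathologicalProcess`, plus per-disposition
  guards), but a pathological process is *not* required to realize any
  pathological disposition — a traumatic fracture event realizes only the
  normal breaking disposition of bone.  The converse axiom is therefore
  deliberately absent from the module, and a regression test keeps it
  non-entailed.
* **Category signals.**  Only processual entities have participants
  (`∃hasParticipant.⊤ ⊑ ProcessualEntity`) and only non-processual
  entities bear inherence (`∃inheresIn.⊤ ⊑ NonProcessualBearerSide`,
  disjoint from `ProcessualEntity`).  A class asserting both is
  unsatisfiable — the toolkit's cue that a disposition and its
  realization need separate classes.

The module also asserts pairwise disjointness of the upper categories
(`MaterialEntity`, `bfo:Disposition`, `ProcessualEntity`).  This is the
standard continuant/occurrent partition of upper-level ontologies, and it
is load-bearing here: committing a participant-refined class to the
process category works by *eliminating* the structure and disposition
cases, which requires that a material or dispositional reading actually
contradict processuality.

## The calculus

Reasoning is completion-rule saturation for EL⊥ (conjunction, existential
restriction, ⊥, role hierarchies, transitive roles, role domains).
Axioms are first normalized to `A ⊑ B`, `A1 ⊓ A2 ⊑ B`, `A ⊑ ∃r.B`, and
`∃r.A ⊑ B` with fresh names (`nf:` prefix, excluded from every
user-facing output); the transformation is a conservative extension, and
a property test checks that entailments over the original signature are
unchanged.  Saturation runs the seven rules listed in the README over a
FIFO worklist with per-axiom indexes; the role hierarchy is closed
reflexively–transitively up front, and transitivity applies only to roles
declared transitive (not to their sub-roles).  The fixpoint is
order-independent; this is tested by shuffling the normalized axiom
order, not assumed.

Completeness is stated *relative to this rule set*: the toolkit's second
reasoning path, a deliberately naive fixpoint that re-scans every rule
over every class pair (no worklist, no indexes, size-guarded at 60
declared names), must agree with the indexed saturation on 200 seeded
random ontologies and on every fixture.  No claim is made about full
OWL-DL semantics.

Two constructs intentionally stay outside the calculus:

* **Coverings.**  `PathologicalEntity ≡ S ⊔ D ⊔ P` would need
  disjunction.  The three inclusions into the covering class are asserted
  as axioms; the covering direction is recorded as a declaration and
  consumed by category inference as *sound case elimination*: a disjunct
  `d` is ruled out when a probe class under `cls ⊓ d` saturates to ⊥, and
  a single survivor is the entailed category.  This is sound (each
  elimination is a genuine entailment) but incomplete relative to full
  disjunction reasoning; for the pattern's three disjuncts plus the
  upper-level disjointness it decides exactly the cases the pattern is
  meant to decide.
* **Guards.**  `hasRealization only PathologicalProcess` would need
  universal restrictions.  Guards are checked against *asserted*
  existential realization fillers: for every class under the guard's
  subject asserting `∃hasRealization.F`, the checker requires `F ⊑
  filler` to be entailed.  This catches exactly the modeling error the
  guard exists for, at the price of not constraining fillers that are
  never asserted.  Guard checks are independent of partonomy, so adding
  location axioms can never create a guard violation (tested).

## Interfaces and conventions

* Dialect: one concrete syntax (a functional-style subset) rather than
  Manchester notation, because it is unambiguous to parse; the keyword
  correspondence is in the README.  Parsing and serialization are
  inverse on the structural level and serialization is byte-deterministic
  (prefixes and declarations sorted, axioms in insertion order).
* Taxonomy: mutually subsuming classes are grouped; the group
  representative is the lexicographically smallest member; direct edges
  are the transitive reduction on representatives (networkx);
  unsatisfiable classes are listed under `owl:Nothing` in the TSV export.
* Location closure: read directly off the saturated `R(hasLocus)`
  successors of the queried class, restricted to declared non-pattern
  names.  Transitive partonomy is already complete inside `R`; superclass
  closure of the successors is deliberately not taken, since it would
  also return every `∃hasLocus` wrapper class as a "location".
* Relation mapping: the built-in default (`sct:FindingSite →
  bt:hasLocus`) skips source roles the ontology does not declare, so
  mapping an ontology without SNOMED-style roles is the identity; an
  explicitly supplied mapping is strict and raises on undeclared
  sources.  `sct:AssociatedMorphology` is never mapped: it relates a
  finding to an abnormal-structure *category*, not a location, which is
  precisely why `FibrosisOfPleura ⋢ Fibrosis` must survive every
  transformation (tested before and after disambiguation).
* Disambiguation naming follows the printed convention — Process →
  `Manifest` + local name, Disposition → local + `Disposition`,
  Structure → local + `Structure`; name collisions abort rather than
  auto-rename.  Plans are verified by re-classification (children
  satisfiable, under parent and category, siblings disjoint) and are
  conservative over pre-existing names (tested by oracle diff).

## Fixtures and the random generator

The nine fixtures encode the clinical vignettes with minimal anatomies
(3–6 anatomical classes each): tumor partonomy, the disposition location
chain, gangrene (participation vs location), the participant+inherence
conflict, allergy (with the bare *allergic rhinitis* name left
uncommitted among its disposition/process/structure readings), the
Huntington cascade (whose first translation step is deliberately
non-pathological), traumatic vs pathological fracture, pleural fibrosis,
and a SNOMED-style toy terminology with a `Condition` alias, `sct:`
category aliases, and events placed under processual entities.  The
thalidomide, VSD, and pneumonia narratives instantiate the same S→D→P
chain shapes as the Huntington and fracture fixtures and are not
separately axiomatized — the narratives supply no additional axiom forms.
Each fixture carries its expected entailments, non-entailments,
unsatisfiable classes, ambiguity flags, and location closures; the suite
checks them exactly, also under pairwise fixture merges (namespace
separation prevents cross-talk).

Fixtures are toy ontologies by construction.  Passing them shows that the
calculus and the pattern produce the intended inferences on the published
examples; it says nothing about coverage of a real SNOMED CT release
(licensed, ~300k concepts), about lexical duplications such as
`BlastCell`/`BlastCellsPresent`, or about where the normal/pathological
threshold lies — all out of scope.

The random generator emits only calculus-supported axiom forms (atomic,
conjunctive, existential introduction/elimination, sub-role,
transitivity, disjointness) over a configurable signature, never guards
or coverings (those are pattern-level and hand-written).  Defaults — 15
classes, 3–4 roles, 25–30 axioms with a mix weighted toward class axioms
— are chosen to keep the naive oracle fast while exercising every rule,
including ⊥ propagation through disjointness; the oracle-agreement suite
runs 200 seeds.  Determinism: identical seed and parameters give a
byte-identical serialization.

## Known limitations

* No inverse-role semantics: `bearerOf`/`inheresIn` are independent
  declarations; fixtures assert whichever direction an entailment needs.
* Guard checking sees asserted fillers only (see above).
* Category inference via covering elimination is sound but not complete
  for arbitrary user-defined coverings.
* `explain` returns one derivation (the first found during saturation),
  not all justifications.
* The dialect has no annotations, data properties, individuals, or
  imports.
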