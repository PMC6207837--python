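# Methods

## Problem statement

A morphological description is a sequence of statements, each a token
sequence with annotated entity mentions (organ names and candidate
structures). Some mentions are **non-specific structure (NSS) terms** —
*apex*, *base*, *margin*, *edge*, *side*, *surface*, and similar — that name
a part without naming the organ it belongs to. The task is, for every NSS
occurrence, to select its **anchor**: the entity (or chain of entities) whose
part it is, and to emit the anchored name (e.g. *leaflet lower surface*,
*abdomen upper margin*). This is associative (bridging) anaphora where the
bridging relation is mereological: the NSS term refers to a part of its
antecedent, not to the antecedent itself.

The default NSS lexicon ships in `nssresolve/data/nss_terms.txt` (39 terms,
including both *center* and *centre* spellings). Lexicon matching and all
name comparisons go through a canonical form: lowercase, whitespace-collapsed,
with the last word singularised (irregulars such as *axes → axis* and
*leaves → leaf* handled explicitly; words ending in *-ss*, *-is*, *-us* are
never stripped). Compound mentions (*lower surface*, *long axes*) match the
lexicon by head word.

## Part-of ontology as a soft constraint

The ontology stores `part_of` and `subclass_of` edges over canonical names.
The single query used everywhere is `may_be_part_of(part, whole)`: could a
structure named *part* plausibly be a part of *whole*? It is deliberately a
*soft* constraint — it answers "is this pairing consistent with the
ontology?", not the formal all-some reading of part_of.

Evaluation is single-hop over subclass closures: the query holds when any
`part_of` edge connects a member of `closure(part)` (the term plus its
transitive subclasses) to a member of `closure(whole)`. This makes a
compound-encoded fact like *elytron side* ⊑ *side*, *elytron side* part_of
*elytron* license the generic query (*side*, *elytron*). Three further
choices:

- **Self-parthood is always rejected** (`may_be_part_of(x, x) = False`); an
  entity cannot be its own anchor.
- **Head-word fallback** (default on): a compound name absent from the
  ontology falls back to its head word, so (*upper side*, *elytron*) is
  licensed whenever (*side*, *elytron*) is. Curated ontologies rarely contain
  every adjective-modified compound a description uses.
- **`transitive_parts`** (default off): when enabled, single-hop licences are
  chained (*apex* part_of *leaf* part_of *shoot* ⇒ (*apex*, *shoot*)).
  Off by default because transitive anchoring usually over-generates
  candidates in practice.

Subclass cycles and self part_of edges are rejected at construction. Readers
exist for a simple CSV dialect (`child,relation,parent` with relation in
`{part_of, subclass_of}`) and for OBO files (via obonet; `is_a` maps to
subclass, `relationship: part_of` to part_of, term names are used).

## Rule cascade

For each NSS occurrence, candidate anchors are produced by three rules tried
in decreasing order of reliability; the first rule that yields any
ontology-licensed candidate decides, and its top-ranked candidate wins.

1. **of-phrase** — a syntactic relation "NSS of X" (*edges of the rhachis*).
2. **possession** — a relation whose trigger is a possession word
   (default lexicon: *with, contain, contains, containing, have, has,
   having*), read in the whole→part direction (*abdomen has a thin edge*).
3. **window** — all other entities within 3 sentences (|Δ sentence index|
   ≤ `window_size`), ordered by absolute head-token distance with ties
   preferring the preceding entity. Proximity ordering is the natural prior
   for associative anaphora; the window bound keeps far-away organs out.

Every candidate must pass `may_be_part_of(nss, candidate)` unless
`ontology_required` is disabled. The `ontology_only` variant keeps only the
window rule (dropping syntactic evidence) to measure how much the ontology
constraint alone contributes.

**Recursion.** If the chosen candidate is itself an unresolved NSS term, it
is pushed on a stack and resolved first; candidates already on the stack are
excluded, preventing cycles. On success the stack unwinds building compound
names outermost organ first: *edge* → *upper margin* → *abdomen* yields
*abdomen upper margin*. If any link in the chain fails, the entire stack is
reported unresolved (a partial chain would assert an unjustified anchor),
and an NSS term that failed to resolve is not accepted as anchor for others.

## Pairwise SVM

Resolution is cast as binary classification over (candidate, NSS) pairs. For
each gold NSS occurrence in the training data, every other entity in the
statement is a pair; the pair is positive when the candidate equals the gold
anchor (canonical-name equality) or, for chained gold anchors, when the
candidate is the NSS whose name is the final word(s) of the compound gold
name. At prediction time the anchor is the probability argmax over all
candidates, with ties broken by token distance then position; a
post-processing pass expands anchors that are themselves resolved NSS terms
into compound names.

Features come in three groups, individually switchable:

1. **positional** — candidate is the subject entity; candidate is the closest
   entity; absolute and relative (length-normalised) token distance; absolute
   and relative count of entities between the pair.
2. **lexical** — nine binary connector flags (*in, on, at, of, has, have,
   with, contains, without*) for words appearing between the pair, and a
   bag-of-words over a ±4-token context window around each mention. The BOW
   vocabulary keeps corpus tokens with frequency ≥ 9 (connectors excluded);
   counts are raw, not binary, so repeated context words weigh more.
3. **semantic** — the ontology licence bit `may_be_part_of(nss, candidate)`
   and whether the candidate is itself an NSS term.

The classifier is `sklearn.svm.SVC` with a polynomial kernel of degree 3,
`class_weight={1: 7}` to counter the heavy negative-pair imbalance (most
candidates are not the anchor), and Platt-scaled probabilities. A 5-fold
cross-validation helper (`cross_validate_degrees`) grids the kernel degree
and breaks ties toward the smaller degree. Excluded feature groups are
removed from the vector entirely (zero-width), not zeroed, so ablations
change dimensionality rather than silently feeding constant columns.

## Baselines and evaluation

- **baseline1 (subject)** — always the first entity of the statement; when
  the NSS term itself is the subject, the next entity.
- **baseline2 (closest)** — the entity at minimal head-token distance, ties
  preferring the preceding entity.

Scoring is micro-averaged over gold NSS occurrences: with S the system's
non-null resolutions and H the gold set, P = |S∩H|/|S|, R = |S∩H|/|H|, and
F1 their harmonic mean, reported as percentages. A resolution is correct
when its anchor name equals the gold anchor under canonicalisation. Methods
that always answer therefore have P = R = F1; the rule cascade may abstain,
trading recall for precision. `error_overlap` partitions two methods'
mistakes (wrong anchor or abstention on a gold occurrence) into A-only,
B-only and shared, the quantity that shows whether methods are
complementary.

## Synthetic corpus generator

Real annotated description corpora are small and encumbered, so the test
and acceptance harnesses use a deterministic generator whose statements
plant one signal each, drawn from a default mix: of-phrase 0.35, possession
0.20, window 0.25, chained NSS 0.10, distractor-only 0.10. Each planted
(NSS, organ) pair is licensed in the generated ontology — half the time via
a subclass-encoded compound (*organ nss* ⊑ *nss*, part_of *organ*) to
exercise the closure query — while distractor organs are booked as
*forbidden* and never subsequently licensed, guaranteeing that at
`noise = 0` the gold anchor is the unique licensed candidate and the rule
cascade recovers it exactly. Distractor position is randomised (before or
after the NSS term) so the closest-entity baseline is neither trivially
right nor trivially wrong.

`noise` (default 0.0) removes each planted licence with the given
probability, modelling ontology incompleteness: precision stays high while
recall degrades monotonically. The default is 0 because the study condition
of interest is a curator-complete ontology.

`generate_subject_signal` builds a second corpus family in which a fraction
of statements (default `subject_fraction = 0.8`) carry their gold anchor in
subject position and the rest place it elsewhere with no syntactic relation.
The fraction is deliberately below 1: with an always-subject gold the
subject baseline would be perfect and no learner could beat it; at 0.8 the
learnable positional signal is strong but imperfect, so the SVM's advantage
over both baselines is measurable.

What the generator does **not** emulate: real parser errors, discontinuous
mentions, coordination ambiguity, vocabulary of real floras/faunas beyond a
25-organ list, or statements with multiple competing licensed anchors.
Corpus sizes used in tests and the acceptance script (60–500 statements) are
chosen to keep the full suite under a few minutes on one CPU while leaving
the comparisons well away from small-sample flips.

The two walk-through statements (`worked_examples()`) are hand-built: a real
fern-description sentence with six NSS occurrences, and a one-line statement
exercising possession rejection, window fallback, recursion and compound
naming. Their lexicon extends the default with *axis*, since *long axes*
must be recognised as an NSS mention there.

## Limitations

- Syntactic relations (of-phrases, possession triggers) are taken from the
  input annotation; the package does not parse raw text.
- Single-hop ontology licensing can reject legitimate distant anchors;
  `transitive_parts` trades that for over-generation.
- Compound anchor naming concatenates resolved chains; it does not consult
  the ontology for a preferred label.
- The SVM's probability calibration (Platt scaling) is unreliable for very
  small training sets; the argmax decision is still well-defined, but
  probabilities should not be read as calibrated confidences there.
- Micro-averaged scores weight statements by their NSS count; descriptions
  with many NSS terms dominate the corpus-level number.
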