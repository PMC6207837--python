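# nssresolve

Resolve **non-specific structure (NSS) terms** in taxonomic morphological
descriptions to their anchor organs.

Terms such as *apex*, *base*, *margin*, *edge*, *side* and *surface* name
parts that could belong to almost any organ. A sentence like *"stomata on
lower surface only"* leaves implicit which organ's lower surface is meant;
downstream uses of parsed descriptions (trait databases, phenotype
annotation, ontology building) need the explicit anchored form *"leaflet
lower surface"*. Linking each NSS occurrence to its anchor organ is a
mereological bridging-reference problem: the antecedent is not the same
entity but the whole of which the NSS term names a part.

## What the package provides

- **`nssresolve.rules`** — an ontology-constrained syntactic rule cascade.
  Rules are tried in order of reliability: explicit *of*-phrases
  ("edges **of** the rhachis"), possession constructions ("abdomen **has** a
  thin edge"), then a cross-sentence candidate window. Every candidate must
  pass a part-of ontology check, `may_be_part_of(nss, candidate)`. When an
  NSS term's best anchor is itself an unresolved NSS term, resolution recurses
  through a stack and emits a compound anchor name ("abdomen upper margin").
- **`nssresolve.ontology`** — a soft-constraint part-of ontology over
  canonicalised term names, with `part_of` and `subclass_of` edges,
  subclass-closure-expanded single-hop queries, head-word fallback for
  compound names, and CSV/OBO readers.
- **`nssresolve.svm`** — a pairwise relation classifier. For each NSS
  occurrence every other entity in the statement is a candidate, and the
  predicted anchor is `argmax_x Pro(x, nss)` under a polynomial-kernel SVM
  with three feature groups: positional (subject flag, closest flag, token
  and entity distances), lexical (connector-word flags and a context-window
  bag of words), and semantic (ontology licensing, candidate-is-NSS).
- **`nssresolve.baselines`** — two position-only heuristics: always the
  subject (first) entity, and always the closest entity (ties prefer the
  preceding one).
- **`nssresolve.evaluation`** — micro-averaged precision/recall/F1 over gold
  NSS occurrences and an error-overlap partition (A-only / B-only / shared)
  for comparing two methods' mistakes.
- **`nssresolve.generate`** — a deterministic synthetic-corpus generator that
  plants each signal type (of-phrase, possession, window, chained NSS,
  distractor) with known gold anchors, plus the two hand-built walk-through
  statements.
- **`nssresolve.cli`** — a thin `nssresolve` command wrapping the library:
  `make-fixtures`, `train-svm`, `resolve`, `evaluate`.

## Worked example

```sh
python examples/01_resolve_worked_examples.py
```

prints (abridged):

```text
--- worked-1
leaflets articulated , inserted near the edges of the rhachis towards the
adaxial side , lacking a differently coloured basal gland ; stomata on lower
surface only or on both surfaces ; epidermal cells elongated parallel to long
axes of leaflets .
  'edges'            -> 'rhachis'                (rule: of_phrase)
  'adaxial side'     -> 'leaflets'               (rule: window)
  'lower surface'    -> 'leaflets'               (rule: window)
  'surfaces'         -> 'leaflets'               (rule: window)
  'cells'            -> 'epidermal'              (rule: window)
  'long axes'        -> 'leaflets'               (rule: of_phrase)

--- worked-2
abdomen has a thin edge at its upper margin .
  'edge'             -> 'abdomen upper margin'   (rule: window)
  'upper margin'     -> 'abdomen'                (rule: window)
```

In the second statement *edge* anchors to another NSS term, *upper margin*;
the resolver first resolves *upper margin* to *abdomen* and then names the
anchor of *edge* outermost-organ-first: **abdomen upper margin**.

Comparing all methods on a held-out synthetic corpus
(`python examples/02_compare_methods.py`):

```text
test corpus: 200 statements, 191 gold NSS occurrences

method                      P      R     F1
rule cascade            100.0  100.0  100.0
svm (all features)      100.0  100.0  100.0
baseline: subject        75.9   75.9   75.9
baseline: closest        42.4   42.4   42.4
```

At zero annotation noise the planted gold anchors are fully recoverable by
both informed methods, while the position-only baselines are defeated by
planted distractor organs.

## Command line

```sh
nssresolve make-fixtures --n 200 --seed 7 --out fixtures/
nssresolve train-svm --input fixtures/statements.json \
    --ontology fixtures/ontology.csv --model-out model.pkl
nssresolve resolve --method rule --input fixtures/statements.json \
    --ontology fixtures/ontology.csv --output rule.json
nssresolve evaluate --gold fixtures/statements.json --pred rule.json \
    --report report.json
```

Every output file gets a sibling `.manifest.json` recording the tool version,
arguments and input hashes.

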