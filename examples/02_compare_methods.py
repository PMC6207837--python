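"""Generate a synthetic corpus and compare all four resolution methods.

A training corpus and a disjoint test corpus are drawn from the default
generator mix (of-phrases, possession verbs, cross-sentence windows, chained
NSS terms and distractor organs).  The rule cascade and the ontology-informed
SVM recover the planted anchors exactly at zero noise; the position-only
baselines do not, which is the point of the comparison.
"""

from nssresolve import (
    GeneratorConfig,
    SvmConfig,
    baseline_corpus,
    generate,
    predict_corpus,
    resolve_corpus,
    score,
    train,
)

train_stmts, train_onto, _ = generate(GeneratorConfig(n_statements=300, seed=11))
test_stmts, test_onto, _ = generate(GeneratorConfig(n_statements=200, seed=12))
n = sum(len(s.gold or {}) for s in test_stmts)
print(f"test corpus: {len(test_stmts)} statements, {n} gold NSS occurrences\n")

model = train(train_stmts, train_onto, SvmConfig(random_seed=0))

rows = [
    ("rule cascade", resolve_corpus(test_stmts, test_onto)),
    ("svm (all features)", predict_corpus(test_stmts, model, test_onto)),
    ("baseline: subject", baseline_corpus(test_stmts, "baseline1")),
    ("baseline: closest", baseline_corpus(test_stmts, "baseline2")),
]
print(f"{'method':22} {'P':>6} {'R':>6} {'F1':>6}")
for name, resolutions in rows:
    r = score(resolutions, test_stmts)
    print(f"{name:22} {r.precision:6.1f} {r.recall:6.1f} {r.f1:6.1f}")

print()
print("The subject baseline profits from statements whose first entity happens")
print("to be the anchor; the closest-entity baseline is defeated by distractor")
print("organs planted adjacent to the NSS term.")
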