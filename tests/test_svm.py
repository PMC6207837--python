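import numpy as np
import pytest

from nssresolve import (
    GeneratorConfig,
    NssLexicon,
    SvmConfig,
    baseline_corpus,
    extract_features,
    generate,
    generate_subject_signal,
    make_statement,
    ontology_from_edges,
    predict,
    predict_corpus,
    score,
    train,
)
from nssresolve.model import OF_PHRASE, EntityMention, SyntacticRelation, Token
from nssresolve.svm import CONNECTORS, build_vocabulary


@pytest.fixture()
def base_of_leaves(default_lexicon):
    tokens = [
        Token(0, "base"),
        Token(1, "of"),
        Token(2, "the"),
        Token(3, "leaves"),
    ]
    ents = [
        EntityMention("b", 0, (0, 1), "base"),
        EntityMention("l", 3, (3, 4), "leaves"),
    ]
    rels = [SyntacticRelation(OF_PHRASE, "b", "l", "of")]
    return make_statement("bol", tokens, ents, rels, {"b": "leaves"}, default_lexicon)


def test_connector_and_position_features(base_of_leaves):
    s = base_of_leaves
    config = SvmConfig()
    feats = extract_features(s, s.entity("b"), s.entity("l"), None, (), config)
    flags = dict(zip(CONNECTORS, feats.connector_flags))
    assert flags["of"] == 1 and flags["with"] == 0
    assert feats.abs_entities_between == 0
    assert feats.is_closest == 1
    assert feats.abs_token_distance == 3
    assert feats.rel_token_distance == pytest.approx(3 / 4)
    assert feats.anchor_is_nss == 0


def test_only_candidate_is_closest_with_zero_between(base_of_leaves):
    s = base_of_leaves
    feats = extract_features(s, s.entity("b"), s.entity("l"), None, (), SvmConfig())
    assert feats.is_closest == 1 and feats.rel_entities_between == 0.0


def test_distances_match_naive_recount(small_corpus):
    statements, ontology, _ = small_corpus
    config = SvmConfig()
    for s in statements:
        for nss in s.nss_mentions():
            for cand in s.entities:
                if cand.id == nss.id:
                    continue
                f = extract_features(s, nss, cand, ontology, (), config)
                assert f.abs_token_distance == abs(cand.head_token - nss.head_token)
                assert f.rel_token_distance == f.abs_token_distance / len(s.tokens)
                between = [
                    e
                    for e in s.entities
                    if min(cand.head_token, nss.head_token)
                    < e.head_token
                    < max(cand.head_token, nss.head_token)
                ]
                assert f.abs_entities_between == len(between)
                assert 0.0 <= f.rel_entities_between <= 1.0


def test_group_exclusion_is_zero_width_not_zeroed(base_of_leaves):
    s = base_of_leaves
    all_groups = SvmConfig(feature_groups=(1, 2, 3))
    no_semantic = SvmConfig(feature_groups=(1, 2))
    f = extract_features(s, s.entity("b"), s.entity("l"), None, ("the",), all_groups)
    v_all = f.to_vector(("the",), all_groups.feature_groups)
    v_12 = f.to_vector(("the",), no_semantic.feature_groups)
    assert len(v_all) == len(v_12) + 2
    np.testing.assert_array_equal(v_all[: len(v_12)], v_12)


def test_vocabulary_respects_frequency_threshold(small_corpus):
    statements, _, _ = small_corpus
    vocab = build_vocabulary(statements, SvmConfig(word_freq_threshold=9))
    counts = {}
    for s in statements:
        for t in s.tokens:
            counts[t.text.lower()] = counts.get(t.text.lower(), 0) + 1
    assert vocab
    for w in vocab:
        assert counts[w] >= 9 and w not in CONNECTORS
    rare = [w for w, c in counts.items() if c < 9 and w not in CONNECTORS]
    assert not set(rare) & set(vocab)


def test_single_class_training_data_rejected(default_lexicon):
    tokens = [Token(0, "base"), Token(1, "of"), Token(2, "leaf")]
    ents = [
        EntityMention("b", 0, (0, 1), "base"),
        EntityMention("l", 2, (2, 3), "leaf"),
    ]
    s = make_statement("s", tokens, ents, gold={"b": "leaf"}, lexicon=default_lexicon)
    with pytest.raises(ValueError, match="single class"):
        train([s], None, SvmConfig())


def test_separable_pair_learned_perfectly(default_lexicon):
    # one positive (gold anchor) and one negative (distractor) candidate
    tokens = [
        Token(0, "stem"),
        Token(1, ";"),
        Token(2, "base"),
        Token(3, "of"),
        Token(4, "the"),
        Token(5, "leaf"),
    ]
    ents = [
        EntityMention("s", 0, (0, 1), "stem"),
        EntityMention("b", 2, (2, 3), "base"),
        EntityMention("l", 5, (5, 6), "leaf"),
    ]
    rels = [SyntacticRelation(OF_PHRASE, "b", "l", "of")]
    onto = ontology_from_edges(part_of=[("base", "leaf")])
    s = make_statement("t", tokens, ents, rels, {"b": "leaf"}, default_lexicon)
    model = train([s], onto, SvmConfig(word_freq_threshold=1))
    # the two training pairs are linearly separable: training accuracy 100%
    nss = s.entity("b")
    for cand, label in ((s.entity("s"), 0), (s.entity("l"), 1)):
        f = extract_features(s, nss, cand, onto, model.vocab, model.config)
        vec = f.to_vector(model.vocab, model.config.feature_groups).reshape(1, -1)
        assert model.clf.predict(vec)[0] == label


def test_argmax_equals_linear_probability_scan():
    statements, ontology, _ = generate(GeneratorConfig(n_statements=100, seed=17))
    model = train(statements, ontology, SvmConfig(random_seed=0))
    class_index = int(np.where(model.clf.classes_ == 1)[0][0])
    for s in statements[:100]:
        resolutions = {r.nss_mention: r for r in predict(s, model, ontology)}
        for nss in s.nss_mentions():
            cands = [e for e in s.entities if e.id != nss.id]
            scored = []
            for c in cands:
                f = extract_features(s, nss, c, ontology, model.vocab, model.config)
                vec = f.to_vector(model.vocab, model.config.feature_groups)
                p = model.clf.predict_proba(vec.reshape(1, -1))[0, class_index]
                scored.append((p, c))
            best_p = max(p for p, _ in scored)
            ties = [
                c
                for p, c in scored
                if p == best_p
            ]
            expected = min(
                ties,
                key=lambda c: (abs(c.head_token - nss.head_token), c.head_token),
            )
            assert resolutions[nss.id].anchor_mention == expected.id


def test_predict_always_answers_so_p_equals_r(small_corpus):
    statements, ontology, _ = small_corpus
    model = train(statements, ontology, SvmConfig(random_seed=0))
    rep = score(predict_corpus(statements, model, ontology), statements)
    assert rep.n_system == sum(len(s.nss_mentions()) for s in statements)
    assert rep.precision == rep.recall == rep.f1


def test_no_candidates_gives_null_with_warning(default_lexicon, caplog):
    s = make_statement(
        "solo",
        [Token(0, "apex")],
        [EntityMention("a", 0, (0, 1), "apex")],
        gold={"a": "leaf"},
        lexicon=default_lexicon,
    )
    statements, ontology, _ = generate(GeneratorConfig(n_statements=40, seed=3))
    model = train(statements, ontology, SvmConfig(random_seed=0))
    (res,) = predict(s, model, ontology)
    assert res.anchor_name is None


def test_model_roundtrip_preserves_predictions(tmp_path):
    statements, ontology, _ = generate(GeneratorConfig(n_statements=60, seed=5))
    model = train(statements, ontology, SvmConfig(random_seed=0))
    path = tmp_path / "model.pkl"
    model.save(path)
    from nssresolve import SvmModel

    back = SvmModel.load(path)
    assert back.vocab == model.vocab
    assert back.fingerprint == model.fingerprint
    before = predict_corpus(statements, model, ontology)
    after = predict_corpus(statements, back, ontology)
    assert before == after


def test_subject_signal_recovered_better_than_baselines():
    train_s, train_o, _ = generate_subject_signal(200, seed=21)
    test_s, test_o, _ = generate_subject_signal(120, seed=22)
    model = train(train_s, train_o, SvmConfig(random_seed=0))
    svm_f1 = score(predict_corpus(test_s, model, test_o), test_s).f1
    b1_f1 = score(baseline_corpus(test_s, "baseline1"), test_s).f1
    b2_f1 = score(baseline_corpus(test_s, "baseline2"), test_s).f1
    assert svm_f1 > b1_f1
    assert svm_f1 > b2_f1


def test_degree_grid_reproducible_and_exhaustive():
    from nssresolve import cross_validate_degrees

    statements, ontology, _ = generate(GeneratorConfig(n_statements=60, seed=13))
    cfg = SvmConfig(random_seed=7, cv_folds=3)
    best_a, grid_a = cross_validate_degrees(statements, ontology, cfg, degrees=(2, 3))
    best_b, grid_b = cross_validate_degrees(statements, ontology, cfg, degrees=(2, 3))
    assert grid_a == grid_b and best_a.degree == best_b.degree
    assert best_a.degree == max(grid_a, key=lambda d: (grid_a[d], -d))
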