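import logging

import pytest

from nssresolve import (
    GeneratorConfig,
    NssLexicon,
    PartOfOntology,
    RuleConfig,
    canonical,
    candidates_for,
    generate,
    make_statement,
    ontology_from_edges,
    resolve_corpus,
    resolve_statement,
)
from nssresolve.model import OF_PHRASE, POSSESSION, EntityMention, SyntacticRelation, Token

from oracles import brute_force_resolver, naive_window_order


def _by_name(statement, resolutions):
    return {
        statement.entity(r.nss_mention).name: r.anchor_name for r in resolutions
    }


def test_worked_example_anchor_mapping(worked):
    statements, ontology, _ = worked
    got = _by_name(statements[0], resolve_statement(statements[0], ontology))
    assert got == {
        "edges": "rhachis",
        "adaxial side": "leaflets",
        "lower surface": "leaflets",
        "surfaces": "leaflets",
        "cells": "epidermal",
        "long axes": "leaflets",
    }


def test_recursive_chain_builds_compound_anchor(worked):
    statements, ontology, _ = worked
    got = _by_name(statements[1], resolve_statement(statements[1], ontology))
    assert got == {"edge": "abdomen upper margin", "upper margin": "abdomen"}


def test_rule_provenance_recorded(worked):
    statements, ontology, _ = worked
    res = {r.nss_mention: r for r in resolve_statement(statements[0], ontology)}
    s1 = statements[0]
    edges = next(e for e in s1.entities if e.name == "edges")
    side = next(e for e in s1.entities if e.name == "adaxial side")
    assert res[edges.id].rule_fired == OF_PHRASE
    assert res[side.id].rule_fired == "window"


def test_unlicensed_nss_left_unresolved(worked):
    statements, _, _ = worked
    empty = PartOfOntology()
    for r in resolve_statement(statements[0], empty):
        assert r.anchor_name is None and r.anchor_mention is None


def _simple_statement(lexicon):
    # "stem rounded ; apex of the leaf ." — of-phrase says leaf, window says stem
    tokens = [
        Token(0, "stem"),
        Token(1, "rounded"),
        Token(2, ";"),
        Token(3, "apex"),
        Token(4, "of"),
        Token(5, "the"),
        Token(6, "leaf"),
        Token(7, "."),
    ]
    ents = [
        EntityMention("stem", 0, (0, 1), "stem"),
        EntityMention("apex", 3, (3, 4), "apex"),
        EntityMention("leaf", 6, (6, 7), "leaf"),
    ]
    rels = [SyntacticRelation(OF_PHRASE, "apex", "leaf", "of")]
    return make_statement("prio", tokens, ents, rels, lexicon=lexicon)


def test_of_phrase_outranks_closer_window_candidate(default_lexicon):
    """A licensed of-phrase candidate wins even when a licensed entity is closer."""
    s = _simple_statement(default_lexicon)
    onto = ontology_from_edges(part_of=[("apex", "leaf"), ("apex", "stem")])
    (res,) = resolve_statement(s, onto)
    assert res.anchor_name == "leaf" and res.rule_fired == OF_PHRASE
    # without the of-phrase license the cascade falls through to the window
    onto2 = ontology_from_edges(part_of=[("apex", "stem")])
    (res2,) = resolve_statement(s, onto2)
    assert res2.anchor_name == "stem" and res2.rule_fired == "window"


def test_ontology_only_variant_ignores_relations(default_lexicon):
    s = _simple_statement(default_lexicon)
    onto = ontology_from_edges(part_of=[("apex", "leaf"), ("apex", "stem")])
    config = RuleConfig(variant="ontology_only")
    assert config.rule_order == ("window",)
    (res,) = resolve_statement(s, onto, config)
    # stem is closer than leaf (3 vs 3 tokens, tie prefers the preceding)
    assert res.rule_fired == "window"
    assert res.anchor_name == "stem"


def test_cyclic_nss_chain_left_unresolved(caplog):
    lexicon = NssLexicon(["apex", "base"])
    tokens = [Token(0, "apex"), Token(1, "near"), Token(2, "base"), Token(3, ".")]
    ents = [
        EntityMention("a", 0, (0, 1), "apex"),
        EntityMention("b", 2, (2, 3), "base"),
    ]
    s = make_statement("cyc", tokens, ents, lexicon=lexicon)
    onto = ontology_from_edges(part_of=[("apex", "base"), ("base", "apex")])
    with caplog.at_level(logging.WARNING):
        res = resolve_statement(s, onto)
    assert all(r.anchor_name is None for r in res)
    assert any("unresolved" in m for m in caplog.messages)


def test_window_candidates_match_naive_sort(small_corpus):
    statements, ontology, _ = small_corpus
    config = RuleConfig(ontology_required=False)
    for s in statements:
        for nss in s.nss_mentions():
            got = [c.id for c in candidates_for(s, nss, "window", config)]
            assert got == naive_window_order(s, nss.id, config.window_size)


def test_window_respects_sentence_boundaries(default_lexicon):
    # entity 4 sentences away must be outside a window of 3
    tokens = []
    for i in range(5):
        tokens.append(Token(2 * i, "leaf" if i == 0 else "word", i))
        tokens.append(Token(2 * i + 1, ".", i))
    tokens.append(Token(10, "apex", 4))
    ents = [
        EntityMention("leaf", 0, (0, 1), "leaf"),
        EntityMention("apex", 10, (10, 11), "apex"),
    ]
    s = make_statement("win", tokens, ents, lexicon=default_lexicon)
    config = RuleConfig(ontology_required=False)
    assert candidates_for(s, s.entity("apex"), "window", config) == []
    wide = RuleConfig(ontology_required=False, window_size=4)
    assert [c.id for c in candidates_for(s, s.entity("apex"), "window", wide)] == ["leaf"]


def test_matches_brute_force_enumeration_oracle():
    """Cascade output equals exhaustive (rule, candidate) enumeration on 200+ statements."""
    config = GeneratorConfig(
        n_statements=220,
        seed=42,
        mix={"of": 0.4, "possession": 0.25, "window": 0.3, "chain": 0.0, "distractor": 0.05},
    )
    statements, ontology, _ = generate(config)
    resolutions = resolve_corpus(statements, ontology)
    for s in statements:
        expected = brute_force_resolver(s, ontology)
        for r in resolutions[s.id]:
            got = canonical(r.anchor_name) if r.anchor_name else None
            assert got == expected[r.nss_mention], s.id


def test_every_anchor_passed_the_ontology_check(small_corpus):
    statements, ontology, _ = small_corpus
    resolutions = resolve_corpus(statements, ontology)
    for s in statements:
        for r in resolutions[s.id]:
            if r.anchor_mention is None:
                continue
            nss = s.entity(r.nss_mention)
            anchor = s.entity(r.anchor_mention)
            assert ontology.may_be_part_of(nss.name, anchor.name)


def test_resolution_is_deterministic_and_compositional(small_corpus):
    statements, ontology, _ = small_corpus
    all_at_once = resolve_corpus(statements, ontology)
    again = resolve_corpus(statements, ontology)
    assert all_at_once == again
    for s in statements:
        assert all_at_once[s.id] == resolve_statement(s, ontology)


def test_empty_corpus_resolves_to_empty_map():
    assert resolve_corpus([], PartOfOntology()) == {}
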