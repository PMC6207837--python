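"""Independent brute-force oracles used by the test suite.

These re-derive the expected behaviour of the ontology query and of the rule
cascade by exhaustive enumeration, sharing no code with the implementation
paths they check.
"""

from __future__ import annotations

import random

from nssresolve.lexicon import canonical
from nssresolve.model import OF_PHRASE, POSSESSION, Statement
from nssresolve.ontology import PartOfOntology


def closure_oracle(
    terms: set[str],
    part_of: set[tuple[str, str]],
    subclass_of: set[tuple[str, str]],
    part: str,
    whole: str,
) -> bool:
    """Exhaustive subclass-closure membership test (no head fallback)."""
    if part not in terms or whole not in terms or part == whole:
        return False

    def descendants(t: str) -> set[str]:
        out = {t}
        changed = True
        while changed:
            changed = False
            for a, b in subclass_of:
                if b in out and a not in out:
                    out.add(a)
                    changed = True
        return out

    parts = descendants(part)
    wholes = descendants(whole)
    return any((p, w) in part_of for p in parts for w in wholes)


def random_ontology(rng: random.Random, max_terms: int = 30) -> PartOfOntology:
    """A random small ontology with an acyclic subclass DAG."""
    n = rng.randint(2, max_terms)
    terms = [f"t{i}" for i in range(n)]
    subclass_of = set()
    part_of = set()
    for _ in range(rng.randint(0, 2 * n)):
        i, j = rng.sample(range(n), 2)
        # edges go from higher to lower index only: acyclic by construction
        if i > j:
            i, j = j, i
        subclass_of.add((terms[j], terms[i]))
    for _ in range(rng.randint(0, 2 * n)):
        a, b = rng.sample(terms, 2)
        part_of.add((a, b))
    return PartOfOntology(part_of=part_of, subclass_of=subclass_of)


def naive_window_order(statement: Statement, nss_id: str, window_size: int) -> list[str]:
    """Entities within the sentence window, closest first, preceding on ties."""
    nss = statement.entity(nss_id)
    nss_sent = statement.tokens[nss.head_token].sentence_index
    eligible = [
        e
        for e in statement.entities
        if e.id != nss_id
        and abs(statement.tokens[e.head_token].sentence_index - nss_sent) <= window_size
    ]
    decorated = sorted(
        eligible,
        key=lambda e: (
            abs(e.head_token - nss.head_token),
            0 if e.head_token < nss.head_token else 1,
            e.head_token,
        ),
    )
    return [e.id for e in decorated]


def brute_force_resolver(
    statement: Statement, ontology: PartOfOntology, window_size: int = 3
) -> dict[str, str | None]:
    """Enumerate every (rule, candidate) pair at the cascade priority.

    Covers single-hop (non-chained) gold only: an NSS candidate is never
    selected, so statements with multi-NSS chains must not be fed to it.
    """
    out: dict[str, str | None] = {}
    for nss in statement.nss_mentions():
        chosen = None
        for rule in (OF_PHRASE, POSSESSION, "window"):
            if rule == OF_PHRASE:
                cand_ids = [
                    r.governor
                    for r in statement.relations
                    if r.kind == OF_PHRASE and r.dependent == nss.id
                ]
            elif rule == POSSESSION:
                cand_ids = [
                    r.governor
                    for r in statement.relations
                    if r.kind == POSSESSION and r.dependent == nss.id
                ]
            else:
                cand_ids = naive_window_order(statement, nss.id, window_size)
            licensed = [
                cid
                for cid in cand_ids
                if ontology.may_be_part_of(nss.name, statement.entity(cid).name)
            ]
            if licensed:
                chosen = statement.entity(licensed[0]).name
                break
        out[nss.id] = canonical(chosen) if chosen else None
    return out
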