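"""Ontology-constrained syntactic rule resolver for NSS mentions.

For each NSS mention of a statement the resolver tries, in order of
confidence, (1) of-phrase relations ("base *of the leaves*"), (2) possession
relations ("abdomen *has* a thin edge"), and (3) a proximity window of
candidate entities within a configurable number of sentence boundaries.
A candidate only wins if the part-of ontology licenses the (NSS, candidate)
pair.  When the winning candidate is itself an NSS, resolution recurses: the
chained term is pushed on a stack and resolved first, and the final anchor
names are compounds built outermost-organ-first ("abdomen upper margin").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import EntityMention, OF_PHRASE, POSSESSION, Resolution, Statement
from .ontology import PartOfOntology

logger = logging.getLogger(__name__)

WINDOW = "window"

DEFAULT_POSSESSION_LEXICON = frozenset(
    {"with", "contain", "contains", "containing", "have", "has", "having"}
)


@dataclass
class RuleConfig:
    """Configuration of the rule cascade.

    ``rule_order`` reflects rule confidence (of-phrase > possession > window);
    the ontology check applies to every rule when ``ontology_required``.
    ``window_size`` is the maximum number of sentence boundaries between an
    NSS and a window candidate, symmetric in both directions.  ``variant``
    "ontology_only" drops the of-phrase and possession rules and keeps only
    the windowed ontology lookup.
    """

    rule_order: tuple[str, ...] = (OF_PHRASE, POSSESSION, WINDOW)
    window_size: int = 3
    possession_lexicon: frozenset[str] = DEFAULT_POSSESSION_LEXICON
    ontology_required: bool = True
    variant: str = "all_rules"
    candidate_order: str = "proximity"  # or "document"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.variant not in ("all_rules", "ontology_only"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "ontology_only":
            self.rule_order = (WINDOW,)
        if not self.rule_order:
            raise ValueError("rule_order must be non-empty")


def _window_candidates(
    statement: Statement, nss: EntityMention, window_size: int, order: str
) -> list[EntityMention]:
    nss_sent = statement.tokens[nss.head_token].sentence_index
    cands = []
    for e in statement.entities:
        if e.id == nss.id:
            continue
        if abs(statement.tokens[e.head_token].sentence_index - nss_sent) <= window_size:
            cands.append(e)
    if order == "proximity":
        # closest first; ties prefer the preceding entity
        cands.sort(
            key=lambda e: (
                abs(e.head_token - nss.head_token),
                0 if e.head_token < nss.head_token else 1,
                e.head_token,
            )
        )
    return cands


def candidates_for(
    statement: Statement,
    nss_mention: EntityMention,
    rule: str,
    config: RuleConfig,
    ontology: Optional[PartOfOntology] = None,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[EntityMention]:
    """Ordered candidate anchors for *nss_mention* under a single rule.

    Candidates are filtered by the ontology check when the config requires
    it, and mention ids in *exclude* (e.g. NSS currently on the recursion
    stack) are dropped.
    """
    if rule == OF_PHRASE:
        cands = [
            statement.entity(r.governor)
            for r in statement.relations
            if r.kind == OF_PHRASE and r.dependent == nss_mention.id
        ]
    elif rule == POSSESSION:
        cands = [
            statement.entity(r.governor)
            for r in statement.relations
            if r.kind == POSSESSION
            and r.dependent == nss_mention.id
            and r.trigger.lower() in config.possession_lexicon
        ]
    elif rule == WINDOW:
        cands = _window_candidates(
            statement, nss_mention, config.window_size, config.candidate_order
        )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    cands = [c for c in cands if c.id not in exclude and c.id != nss_mention.id]
    if config.ontology_required:
        if ontology is None:
            raise ValueError("ontology required by config but not provided")
        cands = [c for c in cands if ontology.may_be_part_of(nss_mention.name, c.name)]
    return cands


def resolve_statement(
    statement: Statement,
    ontology: PartOfOntology,
    config: Optional[RuleConfig] = None,
) -> list[Resolution]:
    """Resolve every NSS mention of *statement*; one Resolution per mention.

    NSS mentions are processed in queue (document) order.  A mention already
    resolved as part of an earlier chain is not revisited; a chain that finds
    no licensed candidate, or that cycles, leaves every mention on its stack
    unresolved (null anchor).
    """
    config = config or RuleConfig()
    method = "rule"
    nss_list = statement.nss_mentions()
    results: dict[str, Resolution] = {}

    for start in nss_list:
        if start.id in results:
            continue
        # stack of (mention, rule that selected its anchor candidate)
        stack: list[tuple[EntityMention, Optional[str]]] = [(start, None)]
        on_stack = {start.id}
        current = start
        terminal: Optional[EntityMention] = None
        terminal_base: Optional[str] = None

        while True:
            chosen: Optional[EntityMention] = None
            fired: Optional[str] = None
            for rule in config.rule_order:
                cands = candidates_for(statement, current, rule, config, ontology, on_stack)
                # an NSS whose own resolution already failed cannot anchor
                cands = [
                    c
                    for c in cands
                    if not (
                        c.is_nss
                        and c.id in results
                        and results[c.id].anchor_name is None
                    )
                ]
                if cands:
                    chosen, fired = cands[0], rule
                    break
            if chosen is None:
                if len(stack) > 1:
                    logger.warning(
                        "statement %s: NSS chain starting at %r left unresolved",
                        statement.id,
                        start.name,
                    )
                for mention, _ in stack:
                    results[mention.id] = Resolution(
                        nss_mention=mention.id,
                        anchor_mention=None,
                        anchor_name=None,
                        method=method,
                    )
                break
            stack[-1] = (current, fired)
            if chosen.is_nss and chosen.id not in results:
                # recursion: resolve the chained NSS first
                stack.append((chosen, None))
                on_stack.add(chosen.id)
                current = chosen
                continue
            # terminal: a non-NSS entity, or an NSS already resolved whose
            # compound name stands in for it
            terminal = chosen
            if chosen.id in results and results[chosen.id].anchor_name is not None:
                terminal_base = f"{results[chosen.id].anchor_name} {chosen.name}"
            else:
                terminal_base = chosen.name
            break

        if terminal is None:
            continue
        # unwind the stack, building compound names outermost-organ-first
        name = terminal_base
        anchor_mention_id = terminal.id
        while stack:
            mention, link_rule = stack.pop()
            results[mention.id] = Resolution(
                nss_mention=mention.id,
                anchor_mention=anchor_mention_id,
                anchor_name=name,
                method=method,
                rule_fired=link_rule,
            )
            anchor_mention_id = mention.id
            name = f"{name} {mention.name}"

    return [results[m.id] for m in nss_list]


def resolve_corpus(
    statements: Iterable[Statement],
    ontology: PartOfOntology,
    config: Optional[RuleConfig] = None,
) -> dict[str, list[Resolution]]:
    """Apply :func:`resolve_statement` independently to each statement."""
    return {s.id: resolve_statement(s, ontology, config) for s in statements}
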