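"""Reference heuristics: subject-entity and closest-entity anchoring.

Baseline 1 links every NSS to the subject entity (the first entity mention
of the statement); Baseline 2 links it to the closest entity mention by head
token distance, preferring the preceding entity on ties.  Neither consults
relations or the ontology, and neither abstains when an eligible entity
exists.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .model import EntityMention, Resolution, Statement


def _closest(
    statement: Statement, nss: EntityMention, tie_prefer_preceding: bool = True
) -> Optional[EntityMention]:
    best = None
    best_key = None
    for e in statement.entities:
        if e.id == nss.id:
            continue
        d = abs(e.head_token - nss.head_token)
        precedes = e.head_token < nss.head_token
        key = (d, (0 if precedes else 1) if tie_prefer_preceding else (1 if precedes else 0))
        if best_key is None or key < best_key:
            best, best_key = e, key
    return best


def baseline_subject(statement: Statement) -> list[Resolution]:
    """Anchor every NSS to the first entity of the statement.

    When the NSS *is* the subject, the next entity is used instead (or the
    anchor is null if none exists): an entity never anchors itself.
    """
    out = []
    for nss in statement.nss_mentions():
        anchor: Optional[EntityMention] = None
        for e in statement.entities:
            if e.id != nss.id:
                anchor = e
                break
        out.append(
            Resolution(
                nss_mention=nss.id,
                anchor_mention=anchor.id if anchor else None,
                anchor_name=anchor.name if anchor else None,
                method="baseline1",
            )
        )
    return out


def baseline_closest(
    statement: Statement, tie_prefer_preceding: bool = True
) -> list[Resolution]:
    """Anchor every NSS to the closest entity by head-token distance."""
    out = []
    for nss in statement.nss_mentions():
        anchor = _closest(statement, nss, tie_prefer_preceding)
        out.append(
            Resolution(
                nss_mention=nss.id,
                anchor_mention=anchor.id if anchor else None,
                anchor_name=anchor.name if anchor else None,
                method="baseline2",
            )
        )
    return out


def baseline_corpus(
    statements: Iterable[Statement], which: str
) -> dict[str, list[Resolution]]:
    """Run a baseline over a corpus; *which* is "baseline1" or "baseline2"."""
    fn = {"baseline1": baseline_subject, "baseline2": baseline_closest}[which]
    return {s.id: fn(s) for s in statements}
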