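"""Domain types for annotated statements and their JSON/XML readers.

A *statement* is a sentence (or short span) from a morphological description
in which biological entity mentions, their syntactic relations (of-phrases,
possession phrases) and optionally a gold anchor map have already been
annotated by an upstream character-extraction tool.  This module only carries
those annotations; it performs no parsing of raw text.

The canonical on-disk format is a small documented JSON schema (see
:func:`write_statements`); an XML dialect mirroring upstream annotation tools
is supported as a best-effort alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from lxml import etree

from .lexicon import NssLexicon, canonical

OF_PHRASE = "of_phrase"
POSSESSION = "possession"
RELATION_KINDS = (OF_PHRASE, POSSESSION)


class StatementFormatError(ValueError):
    """Raised when an input document violates the statement schema."""


@dataclass(frozen=True)
class Token:
    """One token of a statement: w_i of the tokenized text segment."""

    index: int
    text: str
    sentence_index: int = 0


@dataclass
class EntityMention:
    """A biological entity mention (structure term) within a statement."""

    id: str
    head_token: int
    span: tuple[int, int]  # [start, end) token indices
    name: str  # canonical (lowercased) entity term
    is_nss: bool = False
    is_subject: bool = False


@dataclass(frozen=True)
class SyntacticRelation:
    """A pre-annotated of-phrase or possession link between two mentions.

    ``dependent`` is the NSS-side mention, ``governor`` the candidate-anchor
    side; ``trigger`` is the surface word ("of", "with", "has", ...).
    """

    kind: str
    dependent: str
    governor: str
    trigger: str


@dataclass
class Statement:
    """An annotated statement: tokens, entity mentions, relations and gold."""

    id: str
    tokens: list[Token]
    entities: list[EntityMention]
    relations: list[SyntacticRelation] = field(default_factory=list)
    gold: Optional[dict[str, str]] = None  # NSS mention id -> gold anchor name

    def entity(self, mention_id: str) -> EntityMention:
        for e in self.entities:
            if e.id == mention_id:
                return e
        raise KeyError(f"statement {self.id!r}: no mention {mention_id!r}")

    def nss_mentions(self) -> list[EntityMention]:
        """All NSS mentions, in document (queue) order."""
        return [e for e in self.entities if e.is_nss]

    @property
    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)

    def validate(self) -> None:
        sid = self.id
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise StatementFormatError(
                    f"statement {sid!r}: token indices must be contiguous from 0 "
                    f"(token {i} has index {tok.index})"
                )
        for a, b in zip(self.tokens, self.tokens[1:]):
            if b.sentence_index < a.sentence_index:
                raise StatementFormatError(
                    f"statement {sid!r}: sentence_index must be non-decreasing"
                )
        seen: set[str] = set()
        n = len(self.tokens)
        for e in self.entities:
            if e.id in seen:
                raise StatementFormatError(f"statement {sid!r}: duplicate mention id {e.id!r}")
            seen.add(e.id)
            start, end = e.span
            if not (0 <= start < end <= n):
                raise StatementFormatError(
                    f"statement {sid!r}: mention {e.id!r} span {e.span} out of range"
                )
            if not (start <= e.head_token < end):
                raise StatementFormatError(
                    f"statement {sid!r}: mention {e.id!r} head_token outside span"
                )
        for a, b in zip(self.entities, self.entities[1:]):
            if b.head_token < a.head_token:
                raise StatementFormatError(
                    f"statement {sid!r}: entities must be in head_token (queue) order"
                )
        if self.entities:
            subjects = [e for e in self.entities if e.is_subject]
            if len(subjects) != 1 or not self.entities[0].is_subject:
                raise StatementFormatError(
                    f"statement {sid!r}: exactly the first entity must be the subject"
                )
        for r in self.relations:
            if r.kind not in RELATION_KINDS:
                raise StatementFormatError(
                    f"statement {sid!r}: unknown relation kind {r.kind!r}"
                )
            if r.dependent == r.governor:
                raise StatementFormatError(
                    f"statement {sid!r}: relation dependent equals governor ({r.dependent!r})"
                )
            for mid in (r.dependent, r.governor):
                if mid not in seen:
                    raise StatementFormatError(
                        f"statement {sid!r}: relation refers to unknown mention {mid!r}"
                    )
        if self.gold:
            by_id = {e.id: e for e in self.entities}
            for mid in self.gold:
                if mid not in by_id:
                    raise StatementFormatError(
                        f"statement {sid!r}: gold refers to unknown mention {mid!r}"
                    )
                if not by_id[mid].is_nss:
                    raise StatementFormatError(
                        f"statement {sid!r}: gold mention {mid!r} is not an NSS"
                    )


@dataclass
class Resolution:
    """The outcome of resolving one NSS mention.

    ``anchor_name`` may be a compound built during recursive resolution,
    e.g. "abdomen upper margin".  A null anchor means the method abstained.
    """

    nss_mention: str
    anchor_mention: Optional[str]
    anchor_name: Optional[str]
    method: str
    rule_fired: Optional[str] = None
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.anchor_mention is None) != (self.anchor_name is None):
            raise ValueError("anchor_mention and anchor_name must both be set or both null")
        if self.anchor_mention == self.nss_mention and self.anchor_mention is not None:
            raise ValueError("an NSS mention cannot anchor itself")


def apply_lexicon(statement: Statement, lexicon: NssLexicon) -> None:
    """Recompute is_nss (from *lexicon*) and is_subject flags in place."""
    for i, e in enumerate(statement.entities):
        e.name = e.name.lower()
        e.is_nss = lexicon.is_nss(e.name)
        e.is_subject = i == 0


def make_statement(
    id: str,
    tokens: Sequence[Token],
    entities: Sequence[EntityMention],
    relations: Sequence[SyntacticRelation] = (),
    gold: Optional[Mapping[str, str]] = None,
    lexicon: Optional[NssLexicon] = None,
) -> Statement:
    """Build a validated statement, setting NSS/subject flags from *lexicon*."""
    stmt = Statement(
        id=id,
        tokens=list(tokens),
        entities=[replace(e) for e in entities],
        relations=list(relations),
        gold=dict(gold) if gold else None,
    )
    apply_lexicon(stmt, lexicon or NssLexicon.default())
    stmt.validate()
    return stmt


# ---------------------------------------------------------------------------
# JSON serialization


def _statement_to_dict(s: Statement) -> dict:
    return {
        "id": s.id,
        "tokens": [
            {"text": t.text, "sentence": t.sentence_index} for t in s.tokens
        ],
        "entities": [
            {
                "id": e.id,
                "name": e.name,
                "head": e.head_token,
                "span": list(e.span),
            }
            for e in s.entities
        ],
        "relations": [
            {
                "kind": r.kind,
                "dependent": r.dependent,
                "governor": r.governor,
                "trigger": r.trigger,
            }
            for r in s.relations
        ],
        **({"gold": dict(s.gold)} if s.gold else {}),
    }


def _require(cond: bool, sid: str, msg: str) -> None:
    if not cond:
        raise StatementFormatError(f"statement {sid!r}: {msg}")


def _statement_from_dict(d: dict, lexicon: NssLexicon) -> Statement:
    sid = str(d.get("id", "<missing id>"))
    _require("tokens" in d, sid, "missing field 'tokens'")
    _require("entities" in d, sid, "missing field 'entities'")
    tokens = [
        Token(index=i, text=str(t["text"]), sentence_index=int(t.get("sentence", 0)))
        for i, t in enumerate(d["tokens"])
    ]
    entities = []
    for e in d["entities"]:
        for key in ("id", "name", "head", "span"):
            _require(key in e, sid, f"entity missing field {key!r}")
        entities.append(
            EntityMention(
                id=str(e["id"]),
                head_token=int(e["head"]),
                span=(int(e["span"][0]), int(e["span"][1])),
                name=str(e["name"]).lower(),
            )
        )
    relations = [
        SyntacticRelation(
            kind=str(r["kind"]),
            dependent=str(r["dependent"]),
            governor=str(r["governor"]),
            trigger=str(r.get("trigger", "")),
        )
        for r in d.get("relations", [])
    ]
    gold = {str(k): str(v) for k, v in d.get("gold", {}).items()} or None
    return make_statement(sid, tokens, entities, relations, gold, lexicon)


def read_statements(
    path: str | Path,
    format: str = "json",
    lexicon: Optional[NssLexicon] = None,
) -> list[Statement]:
    """Read annotated statements from *path*.

    If the document embeds an ``nss_lexicon`` list it takes precedence over
    the *lexicon* argument (which defaults to the packaged lexicon).
    """
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(doc, dict) or "statements" not in doc:
            raise StatementFormatError("document must be an object with a 'statements' list")
        if "nss_lexicon" in doc:
            lexicon = NssLexicon(doc["nss_lexicon"])
        lexicon = lexicon or NssLexicon.default()
        return [_statement_from_dict(d, lexicon) for d in doc["statements"]]
    if format in ("xml", "xml-dialect"):
        return _read_xml(path, lexicon)
    raise ValueError(f"unknown statement format {format!r}")


def write_statements(
    statements: Iterable[Statement],
    path: str | Path,
    format: str = "json",
    lexicon: Optional[NssLexicon] = None,
) -> None:
    """Write statements so that :func:`read_statements` recovers equal values."""
    path = Path(path)
    statements = list(statements)
    if format == "json":
        doc: dict = {"statements": [_statement_to_dict(s) for s in statements]}
        if lexicon is not None:
            doc["nss_lexicon"] = sorted(lexicon.terms)
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
        return
    if format in ("xml", "xml-dialect"):
        _write_xml(statements, path, lexicon)
        return
    raise ValueError(f"unknown statement format {format!r}")


# ---------------------------------------------------------------------------
# XML dialect (best-effort mirror of upstream annotation-tool output)


def _read_xml(path: Path, lexicon: Optional[NssLexicon]) -> list[Statement]:
    root = etree.parse(str(path)).getroot()
    lex_el = root.find("nss_lexicon")
    if lex_el is not None:
        lexicon = NssLexicon(t.text or "" for t in lex_el.findall("term"))
    lexicon = lexicon or NssLexicon.default()
    out = []
    for st in root.findall("statement"):
        sid = st.get("id", "<missing id>")
        tokens = [
            Token(index=i, text=t.text or "", sentence_index=int(t.get("s", "0")))
            for i, t in enumerate(st.findall("token"))
        ]
        entities = [
            EntityMention(
                id=e.get("id", ""),
                head_token=int(e.get("head", "0")),
                span=(int(e.get("from", "0")), int(e.get("to", "0"))),
                name=(e.get("name") or "").lower(),
            )
            for e in st.findall("structure")
        ]
        relations = [
            SyntacticRelation(
                kind=r.get("kind", ""),
                dependent=r.get("dependent", ""),
                governor=r.get("governor", ""),
                trigger=r.get("trigger", ""),
            )
            for r in st.findall("relation")
        ]
        gold = {g.get("nss", ""): g.get("anchor", "") for g in st.findall("gold")} or None
        out.append(make_statement(sid, tokens, entities, relations, gold, lexicon))
    return out


def _write_xml(
    statements: Sequence[Statement], path: Path, lexicon: Optional[NssLexicon]
) -> None:
    root = etree.Element("statements")
    if lexicon is not None:
        lex_el = etree.SubElement(root, "nss_lexicon")
        for term in sorted(lexicon.terms):
            etree.SubElement(lex_el, "term").text = term
    for s in statements:
        st = etree.SubElement(root, "statement", id=s.id)
        for t in s.tokens:
            tok = etree.SubElement(st, "token", s=str(t.sentence_index))
            tok.text = t.text
        for e in s.entities:
            etree.SubElement(
                st,
                "structure",
                id=e.id,
                name=e.name,
                head=str(e.head_token),
                **{"from": str(e.span[0]), "to": str(e.span[1])},
            )
        for r in s.relations:
            etree.SubElement(
                st,
                "relation",
                kind=r.kind,
                dependent=r.dependent,
                governor=r.governor,
                trigger=r.trigger,
            )
        if s.gold:
            for nss_id, anchor in s.gold.items():
                etree.SubElement(st, "gold", nss=nss_id, anchor=anchor)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))


def nss_mentions(statement: Statement) -> list[EntityMention]:
    """NSS mentions of *statement* in document (queue) order."""
    return statement.nss_mentions()


def canonical_equal(a: Optional[str], b: Optional[str]) -> bool:
    """Name equality after canonicalization; None never matches."""
    if a is None or b is None:
        return False
    return canonical(a) == canonical(b)
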