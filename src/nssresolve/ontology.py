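"""Soft-constraint part-of ontology used to filter candidate anchors.

The ontology asserts *potential* part-of relationships ("an apex could be
part of a leaf", "an apex could be part of a stem"), deliberately violating
the 'all-some' rule of formal ontologies — non-specific parts cannot be
placed in an OBO-style ontology precisely because not every apex belongs to
a leaf.  Alongside part_of edges it carries subclass_of edges (e.g. *elytron
side* is a subclass of *side* and a part of *elytron*), which both resolvers
use to answer membership queries such as "could a side be part of an
elytron?".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .lexicon import canonical, head_word

logger = logging.getLogger(__name__)

PART_OF = "part_of"
SUBCLASS_OF = "subclass_of"


class OntologyFormatError(ValueError):
    """Raised for malformed ontology files (bad relation labels, cycles)."""


@dataclass
class PartOfOntology:
    """Terms plus part_of and subclass_of edge sets with soft query semantics.

    Queries expand both the part name and the whole name to their transitive
    subclass descendants before looking for a licensing part_of edge, so
    ``(side, elytron)`` is licensed by ``elytron side subclass_of side`` and
    ``elytron side part_of elytron``.  part_of itself is a single-hop soft
    constraint and is not chained unless ``transitive_parts`` is set.
    """

    terms: set[str] = field(default_factory=set)
    part_of: set[tuple[str, str]] = field(default_factory=set)
    subclass_of: set[tuple[str, str]] = field(default_factory=set)
    transitive_parts: bool = False
    head_fallback: bool = True

    def __post_init__(self) -> None:
        for child, parent in self.part_of:
            if child == parent:
                raise OntologyFormatError(f"self part_of edge on {child!r}")
        for edge in self.part_of | self.subclass_of:
            for t in edge:
                self.terms.add(t)
        g = nx.DiGraph(self.subclass_of)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise OntologyFormatError(f"subclass_of cycle: {cycle}")

    # -- queries ------------------------------------------------------------

    def _resolve_name(self, name: str) -> str | None:
        c = canonical(name)
        if c in self.terms:
            return c
        if self.head_fallback:
            h = head_word(c)
            if h and h in self.terms:
                return h
        return None

    def subclass_closure(self, term: str) -> set[str]:
        """*term* plus all its direct and transitive subclasses."""
        closure = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for sub, sup in self.subclass_of:
                if sup == t and sub not in closure:
                    closure.add(sub)
                    frontier.append(sub)
        return closure

    def _licensed_single_hop(self, part: str, whole: str) -> bool:
        parts = self.subclass_closure(part)
        wholes = self.subclass_closure(whole)
        return any(c in parts and p in wholes for c, p in self.part_of)

    def may_be_part_of(self, part_name: str, whole_name: str) -> bool:
        """Could *part_name* be a part of *whole_name* under the ontology?

        True iff some subclass (or self) of the part has a part_of edge to
        some subclass (or self) of the whole.  Absent names fall back to
        their head word (compound anchors built during recursion are not
        guaranteed ontology entries); names still absent yield False.

        With ``transitive_parts`` the subclass-lifted part_of relation is
        chained (apex part-of leaf, leaf part-of shoot => apex part-of
        shoot); by default it is a single-hop soft constraint.
        """
        part = self._resolve_name(part_name)
        whole = self._resolve_name(whole_name)
        if part is None or whole is None:
            logger.debug("ontology query with absent term: (%r, %r)", part_name, whole_name)
            return False
        if part == whole:
            # self-parthood is never licensed, whatever the edge structure
            return False
        if not self.transitive_parts:
            return self._licensed_single_hop(part, whole)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for a in self.terms:
            for b in self.terms:
                if a != b and self._licensed_single_hop(a, b):
                    g.add_edge(a, b)
        return nx.has_path(g, part, whole) and part != whole

    def stats(self) -> tuple[int, int]:
        """(number of unique structure terms, number of part_of edges)."""
        return len(self.terms), len(self.part_of)


def ontology_stats(ontology: PartOfOntology) -> tuple[int, int]:
    return ontology.stats()


def may_be_part_of(ontology: PartOfOntology, part_name: str, whole_name: str) -> bool:
    return ontology.may_be_part_of(part_name, whole_name)


# ---------------------------------------------------------------------------
# I/O


def load_ontology(path: str | Path, format: str = "csv") -> PartOfOntology:
    """Load an ontology from CSV (child,relation,parent) or OBO.

    CSV relation labels must be ``part_of`` or ``subclass_of``; duplicate rows
    are deduplicated.  OBO files are read with obonet, mapping ``is_a`` to
    subclass_of and ``relationship: part_of`` to part_of, using term names
    when available.
    """
    path = Path(path)
    if format == "csv":
        part_of: set[tuple[str, str]] = set()
        subclass_of: set[tuple[str, str]] = set()
        with path.open(newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != 3:
                    raise OntologyFormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
                child, rel, parent = (c.strip() for c in row)
                child, parent = canonical(child), canonical(parent)
                if rel == PART_OF:
                    part_of.add((child, parent))
                elif rel == SUBCLASS_OF:
                    subclass_of.add((child, parent))
                else:
                    raise OntologyFormatError(f"{path}:{lineno}: unknown relation {rel!r}")
        return PartOfOntology(part_of=part_of, subclass_of=subclass_of)
    if format in ("obo", "obo-lite"):
        return _load_obo(path)
    raise ValueError(f"unknown ontology format {format!r}")


def _load_obo(path: Path) -> PartOfOntology:
    import obonet

    graph = obonet.read_obo(str(path))
    names = {n: d.get("name", n) for n, d in graph.nodes(data=True)}
    part_of: set[tuple[str, str]] = set()
    subclass_of: set[tuple[str, str]] = set()
    for child, parent, key in graph.edges(keys=True):
        c, p = canonical(names[child]), canonical(names[parent])
        if key == "is_a":
            subclass_of.add((c, p))
        elif key == PART_OF:
            part_of.add((c, p))
    return PartOfOntology(part_of=part_of, subclass_of=subclass_of)


def save_ontology(ontology: PartOfOntology, path: str | Path) -> None:
    """Write the ontology as CSV rows (child,relation,parent), sorted."""
    rows = [(c, PART_OF, p) for c, p in sorted(ontology.part_of)] + [
        (c, SUBCLASS_OF, p) for c, p in sorted(ontology.subclass_of)
    ]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        csv.writer(fh).writerows(rows)


def ontology_from_edges(
    part_of: Iterable[tuple[str, str]] = (),
    subclass_of: Iterable[tuple[str, str]] = (),
    **kwargs,
) -> PartOfOntology:
    """Build an ontology from edge iterables, canonicalizing all names."""
    return PartOfOntology(
        part_of={(canonical(a), canonical(b)) for a, b in part_of},
        subclass_of={(canonical(a), canonical(b)) for a, b in subclass_of},
        **kwargs,
    )
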