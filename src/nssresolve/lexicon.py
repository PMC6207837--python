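"""Lexicon of non-specific structure (NSS) terms and name canonicalization.

An NSS term (apex, base, margin, ...) names an anatomical part that does not
denote an identifiable organ on its own: a *leaf*, a *stem* and a *petal* can
each have an *apex*.  Whether a mention is an NSS is decided against an active
lexicon; the packaged default covers the common non-specific parts of
morphological descriptions across plant, insect, fungal and other taxa.

Canonicalization is deliberately light: lowercase, collapse whitespace and
singularize the head (last) word, so that "edges of the rhachis" matches an
ontology entry for "edge".  It is applied consistently to mention names,
ontology terms and gold anchors, so over-stemming of unusual Latin plurals
cannot break a comparison as long as both sides go through the same function.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

_IRREGULAR_PLURALS = {
    "axes": "axis",
    "leaves": "leaf",
    "apices": "apex",
    "calyces": "calyx",
    "teeth": "tooth",
    "larvae": "larva",
    "antennae": "antenna",
    "hyphae": "hypha",
    "lamellae": "lamella",
    "sporangia": "sporangium",
}

# Singular nouns that must not be de-pluralized.
_SINGULAR_ENDINGS = ("ss", "is", "us")


def singularize(word: str) -> str:
    """Best-effort singular form of a single (lowercased) word."""
    if word in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[word]
    if word.endswith("ies") and len(word) > 3:
        return word[:-3] + "y"
    if word.endswith(_SINGULAR_ENDINGS):
        return word
    if word.endswith(("ches", "shes", "xes", "zes", "ses")):
        return word[:-2]
    if word.endswith("s") and len(word) > 2:
        return word[:-1]
    return word


def canonical(name: str) -> str:
    """Canonical matching form of an entity/ontology/gold name.

    Lowercases, collapses internal whitespace and singularizes the last word
    (the syntactic head of English noun compounds like "adaxial side").
    """
    words = name.lower().split()
    if not words:
        return ""
    return " ".join(words[:-1] + [singularize(words[-1])])


def head_word(name: str) -> str:
    """Head (last) word of a canonicalized name."""
    c = canonical(name)
    return c.split()[-1] if c else ""


class NssLexicon:
    """Set of NSS terms with head-word-aware membership tests."""

    def __init__(self, terms: Iterable[str]):
        self.terms = frozenset(canonical(t) for t in terms if t.strip())

    def is_nss(self, name: str) -> bool:
        """True if *name* (or its head word) is in the lexicon."""
        c = canonical(name)
        return bool(c) and (c in self.terms or head_word(c) in self.terms)

    def extended(self, extra_terms: Iterable[str]) -> "NssLexicon":
        return NssLexicon(set(self.terms) | {canonical(t) for t in extra_terms})

    def __contains__(self, name: str) -> bool:
        return self.is_nss(name)

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NssLexicon) and self.terms == other.terms

    def __repr__(self) -> str:
        return f"NssLexicon({len(self.terms)} terms)"

    @classmethod
    def from_file(cls, path: str | Path) -> "NssLexicon":
        text = Path(path).read_text(encoding="utf-8")
        return cls(line.strip() for line in text.splitlines())

    @classmethod
    def default(cls) -> "NssLexicon":
        """The packaged 39-term lexicon of common non-specific parts."""
        text = (
            resources.files("nssresolve").joinpath("data/nss_terms.txt").read_text("utf-8")
        )
        return cls(line.strip() for line in text.splitlines())
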