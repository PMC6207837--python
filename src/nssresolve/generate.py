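"""Deterministic synthetic statement/ontology generator.

The study corpora of annotated morphological statements are not distributed,
so this module emulates them: telegraphic, verb-light clauses in which
non-specific structure terms must be anchored to organs, with the gold anchor
determined by a controllable mix of signals — of-phrases ("base of the
leaves"), possession words ("abdomen with thin edge"), pure windowed
proximity plus ontology membership, and multi-NSS chains requiring recursive
resolution.  A matching soft part-of ontology is emitted alongside, licensing
exactly the gold pairs (half of them through a subclass-compound encoding so
that closure queries are exercised).  Distractor organs placed in each
statement are guaranteed never to be licensed for that statement's NSS, so
with ``noise = 0`` every gold anchor is recoverable by the rule cascade;
``noise`` removes a statement's licensing edge from the ontology with the
given probability, emulating ontology incompleteness.

All randomness flows from ``GeneratorConfig.seed``; identical configs yield
identical corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .lexicon import NssLexicon, canonical
from .model import (
    EntityMention,
    OF_PHRASE,
    POSSESSION,
    Statement,
    SyntacticRelation,
    Token,
    make_statement,
)
from .ontology import PartOfOntology, ontology_from_edges

DEFAULT_ORGANS = (
    "leaf",
    "stem",
    "petal",
    "sepal",
    "fruit",
    "seed",
    "rhachis",
    "leaflet",
    "petiole",
    "elytron",
    "abdomen",
    "thorax",
    "pronotum",
    "antenna",
    "femur",
    "tibia",
    "mandible",
    "stipe",
    "pileus",
    "lamella",
    "spore",
    "frond",
    "sporangium",
    "valve",
    "carapace",
)

DEFAULT_NSS = (
    "apex",
    "base",
    "margin",
    "edge",
    "side",
    "surface",
    "tip",
    "band",
    "groove",
    "notch",
    "pore",
    "wall",
    "zone",
    "layer",
    "line",
    "face",
    "area",
    "end",
    "middle",
    "portion",
)

ADJECTIVES = (
    "elongate",
    "rounded",
    "smooth",
    "dense",
    "obtuse",
    "acute",
    "glabrous",
    "pubescent",
    "thin",
    "narrow",
    "broad",
    "truncate",
)

DEFAULT_MIX = {
    "of": 0.35,
    "possession": 0.20,
    "window": 0.25,
    "chain": 0.10,
    "distractor": 0.10,
}


@dataclass
class GeneratorConfig:
    n_statements: int = 200
    seed: int = 0
    organ_vocabulary: tuple[str, ...] = DEFAULT_ORGANS
    nss_vocabulary: tuple[str, ...] = DEFAULT_NSS
    mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    noise: float = 0.0

    def __post_init__(self) -> None:
        if not self.organ_vocabulary or not self.nss_vocabulary:
            raise ValueError("organ and NSS vocabularies must be non-empty")
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix proportions must sum to 1 (got {total})")
        unknown = set(self.mix) - set(DEFAULT_MIX)
        if unknown:
            raise ValueError(f"unknown mix keys: {sorted(unknown)}")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be in [0, 1]")


class _Builder:
    """Token/entity accumulator for one statement."""

    def __init__(self) -> None:
        self.tokens: list[Token] = []
        self.entities: list[EntityMention] = []
        self.sentence = 0
        self._eid = 0

    def words(self, *ws: str) -> None:
        for w in ws:
            self.tokens.append(Token(len(self.tokens), w, self.sentence))

    def end_sentence(self) -> None:
        self.words(".")
        self.sentence += 1

    def entity(self, name: str) -> str:
        eid = f"e{self._eid}"
        self._eid += 1
        start = len(self.tokens)
        self.words(*name.split())
        self.entities.append(
            EntityMention(
                id=eid,
                head_token=len(self.tokens) - 1,
                span=(start, len(self.tokens)),
                name=name,
            )
        )
        return eid


def _pick_distinct(rng: random.Random, pool: tuple[str, ...], avoid: set[str]) -> str:
    choices = [x for x in pool if canonical(x) not in avoid]
    if not choices:
        raise ValueError("vocabulary exhausted while avoiding conflicts")
    return rng.choice(choices)


def generate(
    config: GeneratorConfig, lexicon: Optional[NssLexicon] = None
) -> tuple[list[Statement], PartOfOntology, list[dict]]:
    """Generate (statements with gold, licensing ontology, provenance log).

    The provenance log records, per statement, which signal determines each
    gold anchor and whether the statement's licensing edge was removed by
    noise.
    """
    lexicon = lexicon or NssLexicon.default()
    for term in config.nss_vocabulary:
        if not lexicon.is_nss(term):
            raise ValueError(f"generator NSS vocabulary term {term!r} not in active lexicon")
    rng = random.Random(config.seed)
    part_of: set[tuple[str, str]] = set()
    subclass_of: set[tuple[str, str]] = set()
    licensed: set[tuple[str, str]] = set()   # (nss, organ/nss) pairs licensed so far
    forbidden: set[tuple[str, str]] = set()  # pairs that must stay unlicensed
    statements: list[Statement] = []
    provenance: list[dict] = []

    def license_pair(part: str, whole: str, drop: bool) -> None:
        """Add a licensing edge for (part, whole), unless dropped by noise.

        Half the time the license is encoded through a subclass compound
        ("<whole> <part>" subclass_of part, part_of whole) to exercise
        closure queries.
        """
        p, w = canonical(part), canonical(whole)
        licensed.add((p, w))
        if drop:
            return
        if rng.random() < 0.5:
            compound = f"{w} {p}"
            subclass_of.add((compound, p))
            part_of.add((compound, w))
        else:
            part_of.add((p, w))

    def fresh_pair(nss: str, avoid: set[str]) -> str:
        """An organ licensable against *nss*: any pair not marked forbidden.

        Already-licensed pairs may be reused; they stay uniquely recoverable
        because distractors are drawn from the unlicensed pool.
        """
        c_nss = canonical(nss)
        pool = [
            o
            for o in config.organ_vocabulary
            if canonical(o) not in avoid and (c_nss, canonical(o)) not in forbidden
        ]
        if not pool:
            raise ValueError("organ vocabulary exhausted; enlarge it or lower n_statements")
        return rng.choice(pool)

    def distractor_for(nss_names: list[str], avoid: set[str]) -> str:
        """An organ that is not (and will never be) licensed for any given NSS."""
        pool = [
            o
            for o in config.organ_vocabulary
            if canonical(o) not in avoid
            and all((canonical(n), canonical(o)) not in licensed for n in nss_names)
        ]
        if not pool:
            raise ValueError("organ vocabulary exhausted while placing distractors")
        organ = rng.choice(pool)
        for n in nss_names:
            forbidden.add((canonical(n), canonical(organ)))
        return organ

    signals = list(DEFAULT_MIX)
    weights = [config.mix.get(s, 0.0) for s in signals]

    for i in range(config.n_statements):
        sid = f"s{i:04d}"
        signal = rng.choices(signals, weights=weights, k=1)[0]
        noised = signal != "distractor" and rng.random() < config.noise
        b = _Builder()
        adj = lambda: rng.choice(ADJECTIVES)  # noqa: E731
        relations: list[SyntacticRelation] = []
        gold: dict[str, str] = {}

        if signal == "of":
            # of-phrase determines gold; the distractor sits either before
            # the NSS (misleading the closest-entity heuristic) or at the end
            nss = rng.choice(config.nss_vocabulary)
            organ = fresh_pair(nss, avoid=set())
            d = distractor_for([nss], avoid={canonical(organ)})
            if rng.random() < 0.5:
                # "<d> <adj> ; <nss> of the <organ> <adj> ."
                b.entity(d)
                b.words(adj(), ";")
                nss_id = b.entity(nss)
                b.words("of", "the")
                organ_id = b.entity(organ)
                b.words(adj())
            else:
                # "<nss> of the <organ> ; <d> <adj> ."
                nss_id = b.entity(nss)
                b.words("of", "the")
                organ_id = b.entity(organ)
                b.words(";")
                b.entity(d)
                b.words(adj())
            b.end_sentence()
            relations.append(SyntacticRelation(OF_PHRASE, nss_id, organ_id, "of"))
            gold[nss_id] = organ
            license_pair(nss, organ, drop=noised)

        elif signal == "possession":
            # "<organ> <trigger> <adj> <nss> [near <distractor>] ."
            nss = rng.choice(config.nss_vocabulary)
            organ = fresh_pair(nss, avoid=set())
            organ_id = b.entity(organ)
            trigger = rng.choice(("with", "has", "have", "containing"))
            b.words(trigger, adj())
            nss_id = b.entity(nss)
            if rng.random() < 0.5:
                d = distractor_for([nss], avoid={canonical(organ)})
                b.words("near")
                b.entity(d)
            b.end_sentence()
            relations.append(SyntacticRelation(POSSESSION, nss_id, organ_id, trigger))
            gold[nss_id] = organ
            license_pair(nss, organ, drop=noised)

        elif signal == "window":
            # the organ is the only licensed candidate within the window; the
            # distractor lands in the same sentence as the NSS or a later one
            nss = rng.choice(config.nss_vocabulary)
            organ = fresh_pair(nss, avoid=set())
            d = distractor_for([nss], avoid={canonical(organ)})
            b.entity(organ)
            b.words(adj())
            b.end_sentence()
            nss_id = b.entity(nss)
            b.words(adj())
            if rng.random() < 0.5:
                # "<organ> <adj> . <nss> <adj> <d> ."
                b.entity(d)
                b.end_sentence()
            else:
                # "<organ> <adj> . <nss> <adj> . <d> <adj> ."
                b.end_sentence()
                b.entity(d)
                b.words(adj())
            b.end_sentence()
            gold[nss_id] = organ
            license_pair(nss, organ, drop=noised)

        elif signal == "chain":
            # "<organ> has <adj> <nss1> at its <nss2> ." — nss1 anchors to
            # nss2 (window), nss2 to the organ; the possession candidate for
            # nss1 is ontology-blocked, forcing the recursive path
            # the organ must anchor nss2 but must never license nss1, or the
            # possession rule would short-circuit the recursion
            nss1 = nss2 = organ = None
            for _ in range(50):
                cand2 = rng.choice(config.nss_vocabulary)
                cand_organ = fresh_pair(cand2, avoid=set())
                pool1 = [
                    n
                    for n in config.nss_vocabulary
                    if canonical(n) != canonical(cand2)
                    and (canonical(n), canonical(cand_organ)) not in licensed
                ]
                if pool1:
                    nss2, organ, nss1 = cand2, cand_organ, rng.choice(pool1)
                    break
            if nss1 is None:
                raise ValueError("organ vocabulary exhausted while building a chain")
            forbidden.add((canonical(nss1), canonical(organ)))
            organ_id = b.entity(organ)
            b.words("has", adj())
            nss1_id = b.entity(nss1)
            b.words("at", "its")
            nss2_id = b.entity(nss2)
            b.end_sentence()
            relations.append(SyntacticRelation(POSSESSION, nss1_id, organ_id, "has"))
            gold[nss1_id] = f"{organ} {nss2}"
            gold[nss2_id] = organ
            license_pair(nss1, nss2, drop=noised)
            license_pair(nss2, organ, drop=noised)

        else:  # distractor-only statement, no NSS
            o1 = rng.choice(config.organ_vocabulary)
            o2 = _pick_distinct(rng, config.organ_vocabulary, {canonical(o1)})
            b.entity(o1)
            b.words(adj(), ",")
            b.entity(o2)
            b.words(adj())
            b.end_sentence()

        statements.append(
            make_statement(sid, b.tokens, b.entities, relations, gold or None, lexicon)
        )
        provenance.append(
            {
                "id": sid,
                "signal": signal,
                "gold": {mid: gold[mid] for mid in gold},
                "noised": noised,
            }
        )

    ontology = ontology_from_edges(part_of=part_of, subclass_of=subclass_of)
    return statements, ontology, provenance


def generate_subject_signal(
    n_statements: int,
    seed: int,
    subject_fraction: float = 0.8,
    lexicon: Optional[NssLexicon] = None,
) -> tuple[list[Statement], PartOfOntology, list[dict]]:
    """Corpus with a dominant subject-anchor signal.

    In ``subject_fraction`` of statements the gold anchor is the subject
    entity (and the ontology licenses only that pair); in the rest the gold
    is a licensed non-subject entity.  A classifier combining subjecthood
    with ontology membership can resolve all statements; the subject-only
    heuristic caps at ``subject_fraction`` and the closest-entity heuristic
    is systematically misled by an adjacent distractor.
    """
    lexicon = lexicon or NssLexicon.default()
    rng = random.Random(seed)
    part_of: set[tuple[str, str]] = set()
    licensed: set[tuple[str, str]] = set()
    forbidden: set[tuple[str, str]] = set()
    statements: list[Statement] = []
    provenance: list[dict] = []
    for i in range(n_statements):
        sid = f"p{i:04d}"
        nss = rng.choice(DEFAULT_NSS)
        subject_gold = rng.random() < subject_fraction
        pool = [
            o
            for o in DEFAULT_ORGANS
            if (canonical(nss), canonical(o)) not in forbidden
        ]
        organ = rng.choice(pool)
        d_pool = [
            o
            for o in DEFAULT_ORGANS
            if canonical(o) != canonical(organ)
            and (canonical(nss), canonical(o)) not in licensed
        ]
        d = rng.choice(d_pool)
        licensed.add((canonical(nss), canonical(organ)))
        forbidden.add((canonical(nss), canonical(d)))
        b = _Builder()
        adj = rng.choice(ADJECTIVES)
        gold: dict[str, str] = {}
        if subject_gold:
            # "<organ> with <adj> <nss> near <distractor> ."
            b.entity(organ)
            b.words("with", adj)
            nss_id = b.entity(nss)
            b.words("near")
            b.entity(d)
            b.end_sentence()
        else:
            # "<distractor> <adj> ; <nss> of the <organ> ."
            b.entity(d)
            b.words(adj, ";")
            nss_id = b.entity(nss)
            b.words("of", "the")
            b.entity(organ)
            b.end_sentence()
        gold[nss_id] = organ
        part_of.add((canonical(nss), canonical(organ)))
        statements.append(make_statement(sid, b.tokens, b.entities, [], gold, lexicon))
        provenance.append({"id": sid, "signal": "subject" if subject_gold else "ontology", "gold": gold})
    ontology = ontology_from_edges(part_of=part_of)
    return statements, ontology, provenance


def worked_examples() -> tuple[list[Statement], PartOfOntology, NssLexicon]:
    """The two canonical walk-through statements with gold and ontology.

    The first statement exercises the of-phrase and window rules; the second
    exercises possession-rule rejection, recursion over a chained NSS and
    compound anchor naming ("abdomen upper margin").
    """
    lexicon = NssLexicon.default().extended(["axis"])

    # Statement 1: "Leaflets articulated , inserted near the edges of the
    # rhachis towards the adaxial side , lacking a differently coloured basal
    # gland ; stomata on lower surface only or on both surfaces ; epidermal
    # cells elongated parallel to long axes of leaflets ."
    b = _Builder()
    leaflets = b.entity("leaflets")
    b.words("articulated", ",", "inserted", "near", "the")
    edges = b.entity("edges")
    b.words("of", "the")
    rhachis = b.entity("rhachis")
    b.words("towards", "the")
    adaxial_side = b.entity("adaxial side")
    b.words(",", "lacking", "a", "differently", "coloured", "basal", "gland", ";")
    b.entity("stomata")
    b.words("on")
    lower_surface = b.entity("lower surface")
    b.words("only", "or", "on", "both")
    surfaces = b.entity("surfaces")
    b.words(";")
    epidermal = b.entity("epidermal")
    cells = b.entity("cells")
    b.words("elongated", "parallel", "to")
    long_axes = b.entity("long axes")
    b.words("of")
    leaflets2 = b.entity("leaflets")
    b.end_sentence()
    s1 = make_statement(
        "worked-1",
        b.tokens,
        b.entities,
        [
            SyntacticRelation(OF_PHRASE, edges, rhachis, "of"),
            SyntacticRelation(OF_PHRASE, long_axes, leaflets2, "of"),
        ],
        {
            edges: "rhachis",
            adaxial_side: "leaflets",
            lower_surface: "leaflets",
            surfaces: "leaflets",
            cells: "epidermal",
            long_axes: "leaflets",
        },
        lexicon,
    )

    # Statement 2: "abdomen has a thin edge at its upper margin ."
    b = _Builder()
    abdomen = b.entity("abdomen")
    b.words("has", "a", "thin")
    edge = b.entity("edge")
    b.words("at", "its")
    upper_margin = b.entity("upper margin")
    b.end_sentence()
    s2 = make_statement(
        "worked-2",
        b.tokens,
        b.entities,
        [SyntacticRelation(POSSESSION, edge, abdomen, "has")],
        {edge: "abdomen upper margin", upper_margin: "abdomen"},
        lexicon,
    )

    ontology = ontology_from_edges(
        part_of=[
            ("edge", "rhachis"),
            ("side", "leaflet"),
            ("surface", "leaflet"),
            ("cell", "epidermal"),
            ("axis", "leaflet"),
            ("edge", "margin"),
            ("margin", "abdomen"),
        ]
    )
    return [s1, s2], ontology, lexicon
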