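"""Pairwise SVM anchor classification.

Resolution is framed as pairwise relation classification: every (candidate,
NSS) pair within a statement is scored by a probability-estimating support
vector classifier, and the anchor for each NSS is the argmax candidate

    anchor_term(NSS) = argmax_{x in X} Pro(x, NSS)

where X is the set of entity mentions of the statement excluding the NSS
itself.  Three feature groups are used: (1) distance/position (subjecthood,
closestness, absolute/relative token distance, absolute/relative number of
intervening entities); (2) bag-of-words (indicator flags for the connector
words "in, on, at, of, has, have, with, contains, without" between the pair,
plus context-window token counts restricted to a frequency-thresholded
training vocabulary); (3) semantic (whether the pair is licensed by the
part-of ontology, and whether the candidate is itself an NSS).

The classifier is a polynomial-kernel SVC (libsvm backend) with the positive
(true-anchor) class up-weighted to counter the imbalance of pairwise
expansion.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .lexicon import canonical
from .model import EntityMention, Resolution, Statement
from .ontology import PartOfOntology

logger = logging.getLogger(__name__)

CONNECTORS = ("in", "on", "at", "of", "has", "have", "with", "contains", "without")


@dataclass
class SvmConfig:
    """Hyperparameters of the pairwise classifier.

    Defaults follow the tuned operating point: polynomial kernel of degree 3,
    positive class weight 7, bag-of-words frequency threshold 9 and context
    window 4 tokens on each side of each mention.
    """

    kernel: str = "poly"
    degree: int = 3
    class_weight_positive: float = 7.0
    word_freq_threshold: int = 9
    context_window: int = 4
    probability: bool = True
    feature_groups: tuple[int, ...] = (1, 2, 3)
    bow_binary: bool = False
    cv_folds: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.word_freq_threshold < 1:
            raise ValueError("word_freq_threshold must be >= 1")
        if self.context_window < 0:
            raise ValueError("context_window must be >= 0")
        self.feature_groups = tuple(sorted(set(self.feature_groups)))
        if not self.feature_groups or not set(self.feature_groups) <= {1, 2, 3}:
            raise ValueError("feature_groups must be a non-empty subset of {1, 2, 3}")


@dataclass(frozen=True)
class PairFeatures:
    """Feature values for one (candidate anchor, NSS) pair."""

    is_subject: int
    is_closest: int
    abs_token_distance: int
    rel_token_distance: float
    abs_entities_between: int
    rel_entities_between: float
    connector_flags: tuple[int, ...]
    bow: dict[str, int] = field(hash=False, default_factory=dict)
    in_ontology: int = 0
    anchor_is_nss: int = 0

    def to_vector(self, vocab: Sequence[str], feature_groups: Sequence[int]) -> np.ndarray:
        parts: list[float] = []
        if 1 in feature_groups:
            parts += [
                self.is_subject,
                self.is_closest,
                self.abs_token_distance,
                self.rel_token_distance,
                self.abs_entities_between,
                self.rel_entities_between,
            ]
        if 2 in feature_groups:
            parts += list(self.connector_flags)
            parts += [self.bow.get(w, 0) for w in vocab]
        if 3 in feature_groups:
            parts += [self.in_ontology, self.anchor_is_nss]
        return np.asarray(parts, dtype=float)


def _is_closest(statement: Statement, nss: EntityMention, cand: EntityMention) -> bool:
    d = abs(cand.head_token - nss.head_token)
    for e in statement.entities:
        if e.id in (nss.id, cand.id):
            continue
        d_e = abs(e.head_token - nss.head_token)
        if d_e < d:
            return False
        if d_e == d and e.head_token < cand.head_token:
            return False
    return True


def _context_tokens(statement: Statement, mention: EntityMention, window: int) -> list[str]:
    start, end = mention.span
    lo = max(0, start - window)
    hi = min(len(statement.tokens), end + window)
    return [
        statement.tokens[i].text.lower()
        for i in range(lo, hi)
        if not (start <= i < end)
    ]


def extract_features(
    statement: Statement,
    nss_mention: EntityMention,
    candidate_mention: EntityMention,
    ontology: Optional[PartOfOntology],
    vocab: Sequence[str],
    config: SvmConfig,
) -> PairFeatures:
    """Deterministic feature values for one (candidate, NSS) pair."""
    if not statement.tokens:
        raise ValueError(f"statement {statement.id!r} has no tokens")
    if candidate_mention.id == nss_mention.id:
        raise ValueError("candidate must differ from the NSS mention")
    n_tokens = len(statement.tokens)
    n_entities = len(statement.entities)
    abs_dist = abs(candidate_mention.head_token - nss_mention.head_token)
    lo, hi = sorted((candidate_mention.head_token, nss_mention.head_token))
    between = sum(1 for e in statement.entities if lo < e.head_token < hi)

    # connector flags: connector words occurring between the two mentions
    lo_end = min(candidate_mention.span[1], nss_mention.span[1])
    hi_start = max(candidate_mention.span[0], nss_mention.span[0])
    between_words = {
        statement.tokens[i].text.lower() for i in range(lo_end, max(lo_end, hi_start))
    }
    flags = tuple(1 if c in between_words else 0 for c in CONNECTORS)

    bow: Counter[str] = Counter()
    vocab_set = set(vocab)
    for m in (candidate_mention, nss_mention):
        for w in _context_tokens(statement, m, config.context_window):
            if w in CONNECTORS:
                continue
            if w in vocab_set:
                bow[w] += 1
    if config.bow_binary:
        bow = Counter({w: 1 for w in bow})

    in_ont = 0
    if ontology is not None:
        in_ont = int(ontology.may_be_part_of(nss_mention.name, candidate_mention.name))

    return PairFeatures(
        is_subject=int(candidate_mention.is_subject),
        is_closest=int(_is_closest(statement, nss_mention, candidate_mention)),
        abs_token_distance=abs_dist,
        rel_token_distance=abs_dist / n_tokens,
        abs_entities_between=between,
        rel_entities_between=between / n_entities if n_entities else 0.0,
        connector_flags=flags,
        bow=dict(bow),
        in_ontology=in_ont,
        anchor_is_nss=int(candidate_mention.is_nss),
    )


def build_vocabulary(statements: Iterable[Statement], config: SvmConfig) -> tuple[str, ...]:
    """Training vocabulary: tokens with frequency >= threshold, connectors excluded."""
    counts: Counter[str] = Counter()
    for s in statements:
        for t in s.tokens:
            w = t.text.lower()
            if w not in CONNECTORS:
                counts[w] += 1
    return tuple(sorted(w for w, c in counts.items() if c >= config.word_freq_threshold))


def _is_positive(candidate: EntityMention, gold_anchor: str) -> bool:
    """Is *candidate* the gold anchor (directly or as the NSS head of a compound)?"""
    g = canonical(gold_anchor)
    c = canonical(candidate.name)
    if c == g:
        return True
    return candidate.is_nss and g.endswith(" " + c)


@dataclass
class SvmModel:
    """A trained pairwise classifier bundle: estimator, vocabulary, config."""

    clf: SVC
    vocab: tuple[str, ...]
    config: SvmConfig

    @property
    def fingerprint(self) -> str:
        payload = repr((self.config, self.vocab)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with Path(path).open("wb") as fh:
            pickle.dump(
                {"fingerprint": self.fingerprint, "model": self},
                fh,
                protocol=pickle.HIGHEST_PROTOCOL,
            )

    @staticmethod
    def load(path: str | Path) -> "SvmModel":
        with Path(path).open("rb") as fh:
            bundle = pickle.load(fh)
        model = bundle["model"]
        if bundle.get("fingerprint") != model.fingerprint:
            raise ValueError(f"model bundle {path} is corrupt (fingerprint mismatch)")
        return model


def _pairs(
    statement: Statement, nss: EntityMention
) -> list[EntityMention]:
    """Candidate set X: all entity mentions of the statement except the NSS."""
    return [e for e in statement.entities if e.id != nss.id]


def train(
    statements_with_gold: Sequence[Statement],
    ontology: Optional[PartOfOntology],
    config: Optional[SvmConfig] = None,
) -> SvmModel:
    """Train the pairwise classifier on all (candidate, NSS) pairs.

    Each pair is labelled 1 iff the candidate is the gold anchor of the NSS.
    Raises if the expanded training pairs contain only one class.
    """
    config = config or SvmConfig()
    vocab = build_vocabulary(statements_with_gold, config)
    X_rows: list[np.ndarray] = []
    y: list[int] = []
    for s in statements_with_gold:
        for nss in s.nss_mentions():
            gold_anchor = (s.gold or {}).get(nss.id)
            if gold_anchor is None:
                continue
            for cand in _pairs(s, nss):
                feats = extract_features(s, nss, cand, ontology, vocab, config)
                X_rows.append(feats.to_vector(vocab, config.feature_groups))
                y.append(int(_is_positive(cand, gold_anchor)))
    if not X_rows:
        raise ValueError("no training pairs: statements have no gold-annotated NSS")
    y_arr = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("training pairs contain a single class; cannot train a classifier")
    clf = SVC(
        kernel=config.kernel,
        degree=config.degree,
        class_weight={1: config.class_weight_positive},
        probability=config.probability,
        random_state=config.random_seed,
    )
    clf.fit(np.vstack(X_rows), y_arr)
    return SvmModel(clf=clf, vocab=vocab, config=config)


def _expanded_anchor_name(
    statement: Statement,
    res_by_id: Mapping[str, Resolution],
    mention_id: str,
    visiting: set[str],
) -> str:
    """Name contributed by *mention_id* when used as an anchor.

    A predicted anchor that is itself a resolved NSS expands to the compound
    "<its own final anchor> <its name>", mirroring the rule module's naming.
    """
    mention = statement.entity(mention_id)
    res = res_by_id.get(mention_id)
    if res is None or res.anchor_mention is None or mention_id in visiting:
        return mention.name
    visiting.add(mention_id)
    prefix = _expanded_anchor_name(statement, res_by_id, res.anchor_mention, visiting)
    return f"{prefix} {mention.name}"


def predict(
    statement: Statement,
    model: SvmModel,
    ontology: Optional[PartOfOntology] = None,
) -> list[Resolution]:
    """Argmax-probability anchor for every NSS mention of *statement*.

    The anchor is never null when the candidate set is non-empty.  Probability
    ties break toward the smaller token distance, then the earlier mention.
    """
    config = model.config
    raw: dict[str, Resolution] = {}
    class_index = int(np.where(model.clf.classes_ == 1)[0][0])
    for nss in statement.nss_mentions():
        cands = _pairs(statement, nss)
        if not cands:
            logger.warning(
                "statement %s: NSS %r has no candidate anchors", statement.id, nss.name
            )
            raw[nss.id] = Resolution(
                nss_mention=nss.id, anchor_mention=None, anchor_name=None, method="svm"
            )
            continue
        vecs = np.vstack(
            [
                extract_features(statement, nss, c, ontology, model.vocab, config).to_vector(
                    model.vocab, config.feature_groups
                )
                for c in cands
            ]
        )
        probs = model.clf.predict_proba(vecs)[:, class_index]
        best = min(
            range(len(cands)),
            key=lambda i: (
                -probs[i],
                abs(cands[i].head_token - nss.head_token),
                cands[i].head_token,
            ),
        )
        raw[nss.id] = Resolution(
            nss_mention=nss.id,
            anchor_mention=cands[best].id,
            anchor_name=cands[best].name,
            method="svm",
            probability=float(probs[best]),
        )
    # expand compound names for anchors that are themselves resolved NSS
    out = []
    for nss in statement.nss_mentions():
        res = raw[nss.id]
        if res.anchor_mention is not None:
            name = _expanded_anchor_name(statement, raw, res.anchor_mention, {nss.id})
            res = Resolution(
                nss_mention=res.nss_mention,
                anchor_mention=res.anchor_mention,
                anchor_name=name,
                method=res.method,
                probability=res.probability,
            )
        out.append(res)
    return out


def predict_corpus(
    statements: Iterable[Statement],
    model: SvmModel,
    ontology: Optional[PartOfOntology] = None,
) -> dict[str, list[Resolution]]:
    return {s.id: predict(s, model, ontology) for s in statements}


def cross_validate_degrees(
    statements_with_gold: Sequence[Statement],
    ontology: Optional[PartOfOntology],
    config: Optional[SvmConfig] = None,
    degrees: Sequence[int] = (2, 3, 4),
) -> tuple[SvmConfig, dict[int, float]]:
    """K-fold cross-validation over polynomial degrees.

    Returns the config with the degree maximizing mean resolution-level F1
    over the folds (ties break toward the smaller degree), plus the mean F1
    per degree.  Reproducible under a fixed config.random_seed.
    """
    from dataclasses import replace

    from .evaluation import score

    config = config or SvmConfig()
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.random_seed)
    statements = list(statements_with_gold)
    mean_f1: dict[int, float] = {}
    for degree in degrees:
        cfg = replace(config, degree=degree)
        f1s = []
        for train_idx, test_idx in kf.split(statements):
            train_set = [statements[i] for i in train_idx]
            test_set = [statements[i] for i in test_idx]
            try:
                model = train(train_set, ontology, cfg)
            except ValueError:
                f1s.append(0.0)
                continue
            res = predict_corpus(test_set, model, ontology)
            f1s.append(score(res, test_set).f1)
        mean_f1[degree] = float(np.mean(f1s))
    best_degree = max(degrees, key=lambda d: (mean_f1[d], -d))
    return replace(config, degree=best_degree), mean_f1
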