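"""Micro-averaged precision/recall/F1 scoring and error-overlap analysis.

Let H be the set of gold-annotated NSS occurrences and S the set of
occurrences for which a method produced a (non-null) anchor.  Then

    P = |S ∩ H correct| / |S|,   R = |correct| / |H|,   F1 = 2PR / (P + R),

pooled over all NSS occurrences of a corpus (micro-averaging).  A resolution
is correct iff its final anchor name — compounds included — equals the gold
anchor name after canonicalization.  Methods that always answer (the
baselines, the SVM) have |S| = |H| and hence P = R = F1.

Error overlap partitions the mistakes of two methods into A-only, B-only and
shared, the complementarity view of two systems' errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .lexicon import canonical
from .model import Resolution, Statement


@dataclass(frozen=True)
class EvalReport:
    """Micro-averaged scores, as percentages rounded for display."""

    n_gold: int
    n_system: int
    n_correct: int
    precision: float
    recall: float
    f1: float

    @property
    def n_mistakes(self) -> int:
        """Gold occurrences not correctly resolved (wrong or abstained)."""
        return self.n_gold - self.n_correct

    def summary(self) -> str:
        return (
            f"P={self.precision:.1f}% R={self.recall:.1f}% F1={self.f1:.1f}% "
            f"({self.n_correct}/{self.n_system} system, {self.n_gold} gold)"
        )


@dataclass(frozen=True)
class OverlapReport:
    """Partition of two methods' mistakes over the same gold occurrences."""

    errors_a_only: int
    errors_b_only: int
    errors_both: int

    @property
    def errors_a(self) -> int:
        return self.errors_a_only + self.errors_both

    @property
    def errors_b(self) -> int:
        return self.errors_b_only + self.errors_both


def prf(n_correct: int, n_system: int, n_gold: int) -> tuple[float, float, float]:
    """Precision, recall and F1 as percentages from raw counts."""
    p = 100.0 * n_correct / n_system if n_system else 0.0
    r = 100.0 * n_correct / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def _gold_items(statements: Sequence[Statement]) -> dict[tuple[str, str], str]:
    gold: dict[tuple[str, str], str] = {}
    for s in statements:
        for mid, anchor in (s.gold or {}).items():
            gold[(s.id, mid)] = canonical(anchor)
    return gold


def _correct_keys(
    resolutions: Mapping[str, Sequence[Resolution]],
    statements: Sequence[Statement],
) -> tuple[set[tuple[str, str]], int, dict[tuple[str, str], str]]:
    """(correctly-resolved keys, |S|, gold map). Raises on unknown mentions."""
    gold = _gold_items(statements)
    by_id = {s.id: s for s in statements}
    n_system = 0
    correct: set[tuple[str, str]] = set()
    for sid, res_list in resolutions.items():
        if sid not in by_id:
            raise ValueError(f"resolutions for unknown statement {sid!r}")
        stmt = by_id[sid]
        known = {e.id for e in stmt.entities}
        for r in res_list:
            if r.nss_mention not in known:
                raise ValueError(
                    f"statement {sid!r}: resolution references unknown mention "
                    f"{r.nss_mention!r}"
                )
            if r.anchor_name is None:
                continue
            n_system += 1
            key = (sid, r.nss_mention)
            if key in gold and canonical(r.anchor_name) == gold[key]:
                correct.add(key)
    return correct, n_system, gold


def score(
    resolutions: Mapping[str, Sequence[Resolution]],
    statements: Sequence[Statement],
) -> EvalReport:
    """Score per-statement resolutions against the statements' gold maps."""
    correct, n_system, gold = _correct_keys(resolutions, statements)
    p, r, f1 = prf(len(correct), n_system, len(gold))
    return EvalReport(
        n_gold=len(gold),
        n_system=n_system,
        n_correct=len(correct),
        precision=p,
        recall=r,
        f1=f1,
    )


def error_overlap(
    resolutions_a: Mapping[str, Sequence[Resolution]],
    resolutions_b: Mapping[str, Sequence[Resolution]],
    statements: Sequence[Statement],
) -> OverlapReport:
    """Partition both methods' mistakes into A-only / B-only / shared.

    A mistake is a gold NSS occurrence that a method resolved wrongly or left
    unresolved.  Both resolution sets must cover the same corpus.
    """
    correct_a, _, gold_a = _correct_keys(resolutions_a, statements)
    correct_b, _, gold_b = _correct_keys(resolutions_b, statements)
    if set(resolutions_a) != set(resolutions_b):
        raise ValueError("the two resolution sets cover different statements")
    gold_keys = set(gold_a)
    mistakes_a = gold_keys - correct_a
    mistakes_b = gold_keys - correct_b
    return OverlapReport(
        errors_a_only=len(mistakes_a - mistakes_b),
        errors_b_only=len(mistakes_b - mistakes_a),
        errors_both=len(mistakes_a & mistakes_b),
    )
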