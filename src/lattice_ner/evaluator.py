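"""Strict entity-level precision / recall / F1.

A predicted entity counts as correct only if its sentence, boundaries
(begin and end) and category all equal a gold entity exactly — partial
overlaps and category confusions score zero.  Metrics are reported
per category and micro-averaged overall, as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus_io import repair_bio, spans_from_tags


@dataclass(frozen=True)
class CategoryCounts:
    precision: float
    recall: float
    f1: float
    n_gold: int
    n_pred: int
    n_match: int


@dataclass
class PRFReport:
    per_category: dict[str, CategoryCounts]
    precision: float
    recall: float
    f1: float
    n_gold: int
    n_pred: int
    n_match: int


def _prf(match: int, pred: int, gold: int) -> tuple[float, float, float]:
    p = 100.0 * match / pred if pred else 0.0
    r = 100.0 * match / gold if gold else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def strict_prf(gold: Sequence[Sequence[str]],
               pred: Sequence[Sequence[str]]) -> PRFReport:
    """Strict-match micro P/R/F1 with per-category breakdown.

    Predictions are repaired to BIO consistency before span extraction
    (a decoder without schema masking may emit stray I- tags); duplicate
    identical gold spans are collapsed.
    """
    if len(gold) != len(pred):
        raise ValueError("gold/pred sentence count mismatch")
    gold_spans: dict[str, set] = {}
    pred_spans: dict[str, set] = {}
    for si, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(f"sentence {si}: tag length mismatch")
        for s in spans_from_tags(repair_bio(g)):
            gold_spans.setdefault(s.category, set()).add((si, s.begin, s.end))
        for s in spans_from_tags(repair_bio(p)):
            pred_spans.setdefault(s.category, set()).add((si, s.begin, s.end))
    per: dict[str, CategoryCounts] = {}
    tm = tp = tg = 0
    for cat in sorted(set(gold_spans) | set(pred_spans)):
        gs = gold_spans.get(cat, set())
        ps = pred_spans.get(cat, set())
        m = len(gs & ps)
        prec, rec, f1 = _prf(m, len(ps), len(gs))
        per[cat] = CategoryCounts(prec, rec, f1, len(gs), len(ps), m)
        tm += m
        tp += len(ps)
        tg += len(gs)
    prec, rec, f1 = _prf(tm, tp, tg)
    return PRFReport(per, prec, rec, f1, tg, tp, tm)


def report_table(report: PRFReport, sep: str = "\t") -> str:
    """Per-category table plus an "All" row, percentages to 2 decimals."""
    lines = [sep.join(["category", "precision", "recall", "f1",
                       "gold", "pred", "match"])]
    rows = list(report.per_category.items())
    rows.append(("All", CategoryCounts(report.precision, report.recall,
                                       report.f1, report.n_gold,
                                       report.n_pred, report.n_match)))
    for cat, c in rows:
        lines.append(sep.join([cat, f"{c.precision:.2f}", f"{c.recall:.2f}",
                               f"{c.f1:.2f}", str(c.n_gold), str(c.n_pred),
                               str(c.n_match)]))
    return "\n".join(lines)


def average_reports(reports: Sequence[PRFReport]) -> tuple[float, float, float]:
    """Arithmetic mean of overall P, R, F1 across replicate runs."""
    n = len(reports)
    return (sum(r.precision for r in reports) / n,
            sum(r.recall for r in reports) / n,
            sum(r.f1 for r in reports) / n)
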