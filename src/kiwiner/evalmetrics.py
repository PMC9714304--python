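"""Entity-level precision / recall / F1.

Strict CoNLL-style matching: a predicted entity counts as a true positive
iff its (start, end, category) triple matches a gold entity exactly.  The
headline scores are micro-averaged over all sentences; per-category scores
use the same counting restricted to one category.  All three scores are
percentages:

    P = 100 * TP / (TP + FP),  R = 100 * TP / (TP + FN),  F1 = 2PR / (P + R).

Zero-denominator cases score 0 and set the ``undefined`` flag rather than
raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .corpus_io import TaggedSentence, tags_to_spans


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (both on the 0-100 scale)."""
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class PRFCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def p(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def r(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.p, self.r)

    @property
    def undefined(self) -> bool:
        """True when either denominator was zero."""
        return self.tp + self.fp == 0 or self.tp + self.fn == 0


@dataclass
class PRFReport(PRFCounts):
    per_category: Dict[str, PRFCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def block(c: PRFCounts) -> dict:
            return {
                "tp": c.tp, "fp": c.fp, "fn": c.fn,
                "precision": round(c.p, 2), "recall": round(c.r, 2),
                "f1": round(c.f1, 2), "undefined": c.undefined,
            }

        out = block(self)
        out["per_category"] = {cat: block(c) for cat, c in sorted(self.per_category.items())}
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def entity_prf(
    gold: Sequence[TaggedSentence], pred: Sequence[TaggedSentence]
) -> PRFReport:
    """Micro-averaged entity-level P/R/F1 of *pred* against *gold*.

    The two corpora must be aligned sentence by sentence with equal lengths;
    a mismatch raises naming the sentence index.  Sentence order does not
    affect the result beyond the alignment itself.
    """
    if len(gold) != len(pred):
        raise ValueError(f"gold has {len(gold)} sentences, pred has {len(pred)}")
    report = PRFReport()
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(
                f"sentence {i}: gold length {len(g)} != pred length {len(p)}"
            )
        g_spans = set(tags_to_spans(g.tags))
        p_spans = set(tags_to_spans(p.tags))
        for span in p_spans:
            cat = report.per_category.setdefault(span.category, PRFCounts())
            if span in g_spans:
                report.tp += 1
                cat.tp += 1
            else:
                report.fp += 1
                cat.fp += 1
        for span in g_spans - p_spans:
            cat = report.per_category.setdefault(span.category, PRFCounts())
            report.fn += 1
            cat.fn += 1
    return report
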