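"""The Bacteria-Biotope matching-similarity scorer.

A predicted Lives_In event matches a gold event iff its Bacterium argument
is the same entity as (or Equiv-equivalent to) the gold Bacterium and its
Location argument likewise matches the gold Location; matching similarity
is 1 or 0, nothing in between.  Matching is 1-to-1: each gold event can
absorb at most one prediction.  Precision, recall and F-score follow the
usual definitions with zero-valued conventions at empty denominators.
Gold relations whose arguments span sentence boundaries are unreachable
for an intra-sentence system and count as false negatives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .standoff import Document, EquivGroup, RelationAnn


@dataclass(frozen=True)
class EvalCounts:
    TP: int
    FP: int
    FN: int
    P: float
    R: float
    F: float

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return prf(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


def prf(tp: int, fp: int, fn: int) -> EvalCounts:
    """Precision/recall/F from raw counts, guarding empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return EvalCounts(TP=tp, FP=fp, FN=fn, P=p, R=r, F=f)


def _canonical_map(equiv: list[EquivGroup]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for g in equiv:
        rep = min(g.members)
        for m in g.members:
            mapping[m] = rep
    return mapping


def match_events(
    gold: list[RelationAnn],
    pred: list[RelationAnn],
    equiv: list[EquivGroup] | None = None,
) -> EvalCounts:
    """Greedy 1-to-1 matching of predictions against gold under Equiv.

    Arguments are first canonicalized to their Equiv-class representative;
    a prediction is a true positive iff an unmatched gold relation has the
    same canonical argument pair.  Since matching is pure pair equality,
    greedy assignment attains the maximum matching.  Duplicate predictions
    of one canonical pair are deduplicated before scoring.
    """
    ids = [r.id for r in pred]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate prediction ids")
    canon = _canonical_map(equiv or [])

    def key(rel: RelationAnn) -> tuple[str, str]:
        return canon.get(rel.bacterium, rel.bacterium), canon.get(rel.location, rel.location)

    gold_pairs = Counter(key(r) for r in gold)
    pred_pairs = set(key(r) for r in pred)  # dedupe identical predictions
    tp = sum(min(gold_pairs[pair], 1) for pair in pred_pairs if pair in gold_pairs)
    fp = len(pred_pairs) - tp
    fn = sum(gold_pairs.values()) - tp
    return prf(tp, fp, fn)


def evaluate_documents(
    gold_docs: dict[str, Document], pred_relations: dict[str, list[RelationAnn]]
) -> tuple[dict[str, EvalCounts], EvalCounts]:
    """Score each document and the micro-averaged corpus total.

    Gold annotations (relations and Equiv groups) come from *gold_docs*;
    cross-sentence gold relations are simply gold relations no prediction
    matches, so the false-negative rule needs no special casing here.
    """
    per_doc: dict[str, EvalCounts] = {}
    tp = fp = fn = 0
    for doc_id, doc in sorted(gold_docs.items()):
        counts = match_events(doc.relations, pred_relations.get(doc_id, []), doc.equiv)
        per_doc[doc_id] = counts
        tp, fp, fn = tp + counts.TP, fp + counts.FP, fn + counts.FN
    return per_doc, prf(tp, fp, fn)


def format_report(per_doc: dict[str, EvalCounts], total: EvalCounts) -> str:
    """TSV report: per-document counts and a global P/R/F line (percent)."""
    lines = ["doc_id\tTP\tFP\tFN"]
    for doc_id, c in sorted(per_doc.items()):
        lines.append(f"{doc_id}\t{c.TP}\t{c.FP}\t{c.FN}")
    lines.append(
        f"TOTAL\tP={100 * total.P:.2f}%\tR={100 * total.R:.2f}%\tF={100 * total.F:.2f}%"
    )
    return "\n".join(lines) + "\n"
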