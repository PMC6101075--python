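"""Intra-sentence candidate enumeration for Lives_In classification.

Every co-occurring (Bacteria, Habitat-or-Geographical) entity pair inside
one sentence becomes a :class:`CandidateInstance`: the sentence tokens with
the two mentions replaced by ``entity_1``/``entity_2`` placeholders, a
dependency-derived token subsequence for the encoder, and a binary gold
label.  Gold relations whose arguments live in different sentences cannot
yield a candidate; they are returned separately so the scorer can count
them as unreachable positives (false negatives).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .parse import (
    E1_PLACEHOLDER,
    E2_PLACEHOLDER,
    LinearizedInput,
    ParseGraph,
    fallback_parse,
    linearize_candidate,
)
from .standoff import Document, Entity, LOCATION_TYPES, RelationAnn

logger = logging.getLogger(__name__)

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")


@dataclass
class SentenceSpan:
    """One sentence: its character interval and token offsets."""

    index: int
    start: int
    end: int
    token_offsets: list[tuple[int, int]]
    graph: ParseGraph


@dataclass
class CandidateInstance:
    doc_id: str
    sentence_index: int
    e1: Entity
    e2: Entity
    tokens: list[str]
    e1_pos: int
    e2_pos: int
    label: int
    linearized: LinearizedInput | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tokens.count(E1_PLACEHOLDER) != 1 or self.tokens.count(E2_PLACEHOLDER) != 1:
            raise ValueError("candidate tokens must contain each placeholder exactly once")
        if self.e1_pos == self.e2_pos:
            raise ValueError("placeholder positions coincide")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def align_sentences(text: str, graphs: list[ParseGraph]) -> list[SentenceSpan]:
    """Locate each parse token in the raw text, left to right.

    Token surfaces are matched greedily from the current cursor; a token
    that cannot be found raises, since offsets would be meaningless.
    """
    spans: list[SentenceSpan] = []
    cursor = 0
    for si, g in enumerate(graphs):
        offsets: list[tuple[int, int]] = []
        for tok in g.surface:
            idx = text.find(tok, cursor)
            if idx < 0:
                raise ValueError(f"parse token {tok!r} not found in text after offset {cursor}")
            offsets.append((idx, idx + len(tok)))
            cursor = idx + len(tok)
        spans.append(
            SentenceSpan(index=si, start=offsets[0][0], end=offsets[-1][1],
                         token_offsets=offsets, graph=g)
        )
    return spans


def segment_fallback(text: str) -> list[ParseGraph]:
    """Sentence-split on [.!?]+whitespace and whitespace-tokenize.

    Only used when no parse file accompanies a document.
    """
    return [fallback_parse(s) for s in _SENT_SPLIT.split(text) if s.strip()]


def entity_token_run(sent: SentenceSpan, ent: Entity) -> list[int]:
    """Token indices whose character span overlaps any span of *ent*."""
    run = []
    for i, (ts, te) in enumerate(sent.token_offsets):
        if any(ts < e and s < te for s, e in ent.spans):
            run.append(i)
    return run


def replace_entities(
    tokens: list[str], e1_run: list[int], e2_run: list[int]
) -> tuple[list[str], int, int]:
    """Collapse the two entity token runs to single placeholder tokens.

    Pure token-level counterpart of the graph-level collapse: each run is
    replaced by one placeholder at the position of its first token; all
    other tokens keep their order.
    """
    if not e1_run or not e2_run:
        raise ValueError("entity not aligned to any sentence token")
    if set(e1_run) & set(e2_run):
        raise ValueError("entity token runs overlap")
    keep_as: dict[int, str] = {e1_run[0]: E1_PLACEHOLDER, e2_run[0]: E2_PLACEHOLDER}
    drop = (set(e1_run) | set(e2_run)) - set(keep_as)
    out: list[str] = []
    pos = {}
    for i, tok in enumerate(tokens):
        if i in drop:
            continue
        if i in keep_as:
            pos[keep_as[i]] = len(out)
            out.append(keep_as[i])
        else:
            out.append(tok)
    return out, pos[E1_PLACEHOLDER], pos[E2_PLACEHOLDER]


def _gold_pairs(doc: Document) -> set[tuple[str, str]]:
    """Canonicalized (bacterium, location) pairs of the gold relations."""
    return {(doc.canonical(r.bacterium), doc.canonical(r.location)) for r in doc.relations}


def enumerate_candidates(
    doc: Document,
    sentences: list[SentenceSpan],
    replace_mode: str = "span",
    use_det: bool = True,
) -> tuple[list[CandidateInstance], list[RelationAnn]]:
    """All intra-sentence bacterium x location candidates, plus the gold
    relations that no candidate can reach (cross-sentence arguments)."""
    ent_sentence: dict[str, int] = {}
    ent_run: dict[str, list[int]] = {}
    for ent in doc.entities.values():
        homes = [s.index for s in sentences if entity_token_run(s, ent)]
        if len(homes) != 1:
            logger.warning(
                "%s: entity %s aligns to %d sentences; skipped",
                doc.doc_id, ent.id, len(homes),
            )
            continue
        ent_sentence[ent.id] = homes[0]
        ent_run[ent.id] = entity_token_run(sentences[homes[0]], ent)

    gold = _gold_pairs(doc)
    candidates: list[CandidateInstance] = []
    for sent in sentences:
        bacteria = [e for e in doc.entities.values()
                    if ent_sentence.get(e.id) == sent.index and e.type == "Bacteria"]
        locations = [e for e in doc.entities.values()
                     if ent_sentence.get(e.id) == sent.index and e.type in LOCATION_TYPES]
        for b in sorted(bacteria, key=lambda e: e.start):
            for l in sorted(locations, key=lambda e: e.start):
                run_b, run_l = ent_run[b.id], ent_run[l.id]
                if set(run_b) & set(run_l):
                    logger.warning("%s: overlapping pair (%s, %s) skipped",
                                   doc.doc_id, b.id, l.id)
                    continue
                tokens, p1, p2 = replace_entities(list(sent.graph.surface), run_b, run_l)
                lin = linearize_candidate(sent.graph, run_b, run_l,
                                          mode=replace_mode, use_det=use_det)
                label = int((doc.canonical(b.id), doc.canonical(l.id)) in gold)
                candidates.append(
                    CandidateInstance(
                        doc_id=doc.doc_id, sentence_index=sent.index,
                        e1=b, e2=l, tokens=tokens, e1_pos=p1, e2_pos=p2,
                        label=label, linearized=lin,
                    )
                )

    unreachable = []
    for rel in doc.relations:
        sb, sl = ent_sentence.get(rel.bacterium), ent_sentence.get(rel.location)
        if sb is None or sl is None or sb != sl:
            unreachable.append(rel)
    return candidates, unreachable
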