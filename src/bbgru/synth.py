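"""Synthetic Bacteria-Biotope corpus generator.

Emits standoff triples (.txt/.a1/.a2) together with consistent CoNLL-style
parse files so the whole pipeline — candidate generation, dependency-path
extraction, training and scoring — runs without any corpus download.

Each sentence is one clause: a conjoined list of Bacteria subjects, a verb,
and a conjoined list of location objects (Habitat or Geographical).  The
sentence's entity pairs are gold-positive iff the sentence was drawn
positive, and positive sentences use the lexical cue verb (default
``inhabits``) with probability ``p_cue``.  The head assignment makes the
clause verb govern both entity heads, so the cue lies on the dependency
path between every entity pair of its sentence: the planted signal sits on
the shortest path, not merely in the bag of words, which is what makes the
path-based inputs measurably useful.  Negative sentences may carry the cue
as a distractor inside a relative clause under a location, where it is off
the path.  Equiv groups are planted as parenthesized abbreviations of a
bacterium, and a small rate of cross-sentence gold relations exercises the
scorer's false-negative rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parse import ParseGraph, write_conll
from .standoff import Document, Entity, EquivGroup, RelationAnn, write_a2

CUE_DEFAULT = "inhabits"


@dataclass
class SynthConfig:
    n_docs: int = 20
    sentences_per_doc: int = 5
    n_bacteria_vocab: int = 40
    n_habitat_vocab: int = 40
    n_geo_vocab: int = 12
    n_host_vocab: int = 20
    cue: str = CUE_DEFAULT
    neutral_verbs: tuple[str, ...] = ("resembles", "precedes", "follows")
    p_cue: float = 0.95
    p_positive: float = 0.5
    p_distractor: float = 0.2
    p_geo: float = 0.25
    p_multiword: float = 0.3
    equiv_rate: float = 0.1
    cross_sentence_rate: float = 0.05
    doc_prefix: str = "SYND"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cue", "p_positive", "p_distractor", "p_geo",
                     "p_multiword", "equiv_rate", "cross_sentence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if min(self.n_bacteria_vocab, self.n_habitat_vocab,
               self.n_geo_vocab, self.n_host_vocab) < 1:
            raise ValueError("vocabulary sizes must be >= 1")
        if self.n_docs < 0 or self.sentences_per_doc < 1:
            raise ValueError("need n_docs >= 0 and sentences_per_doc >= 1")


@dataclass
class SynthDoc:
    doc_id: str
    text: str
    a1: str
    a2: str
    conll: str


@dataclass
class _Tok:
    surface: str
    pos: str
    chunk: str
    deplabel: str
    head: "_Tok | None" = None  # None = artificial root
    ent: str = "O"


@dataclass
class _Mention:
    type: str
    toks: list[_Tok] = field(default_factory=list)


def _stem(surface: str) -> str:
    s = surface.lower()
    if len(s) > 3 and s.endswith("s"):
        return s[:-1]
    return s


def simple_clause_parse(bacterium: str, verb: str, location: str) -> ParseGraph:
    """The minimal template 'B verb L .': the verb governs both entities."""
    return ParseGraph(
        surface=[bacterium, verb, location, "."],
        stem=[_stem(bacterium), _stem(verb), _stem(location), "."],
        pos=["NNP", "VBZ", "NN", "."],
        chunk=["B-NP", "B-VP", "B-NP", "O"],
        entity=["B-Bacteria", "O", "B-Habitat", "O"],
        head=[2, 0, 2, 2],
        deplabel=["nsubj", "root", "dobj", "punct"],
    )


def _pick_sizes(rng: np.random.Generator) -> int:
    return int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))


def _gen_sentence(cfg: SynthConfig, rng: np.random.Generator):
    """One clause: tokens, entity mentions, local gold pairs, equiv groups."""
    positive = bool(rng.random() < cfg.p_positive)
    nb, nl = _pick_sizes(rng), _pick_sizes(rng)

    toks: list[_Tok] = []
    mentions: list[_Mention] = []
    equiv_local: list[tuple[int, int]] = []

    verb_surface = (
        cfg.cue if (positive and rng.random() < cfg.p_cue)
        else str(rng.choice(cfg.neutral_verbs))
    )
    verb = _Tok(verb_surface, "VBZ", "B-VP", "root", head=None)

    # subject noun phrase: "The bacterium B1 [( Abbr )] [and B2 ...]"
    first_b = _Tok(f"Bacterium{rng.integers(cfg.n_bacteria_vocab)}", "NNP", "I-NP",
                   "nsubj", head=verb, ent="B-Bacteria")
    toks.append(_Tok("The", "DT", "B-NP", "det", head=first_b))
    toks.append(_Tok("bacterium", "NN", "I-NP", "nn", head=first_b))
    toks.append(first_b)
    bact_idx = [len(mentions)]
    mentions.append(_Mention("Bacteria", [first_b]))

    if rng.random() < cfg.equiv_rate:
        abbr = _Tok(f"Bsp{rng.integers(cfg.n_bacteria_vocab)}", "NNP", "B-NP",
                    "appos", head=first_b, ent="B-Bacteria")
        toks.append(_Tok("(", "(", "O", "punct", head=first_b))
        toks.append(abbr)
        toks.append(_Tok(")", ")", "O", "punct", head=first_b))
        equiv_local.append((bact_idx[0], len(mentions)))
        mentions.append(_Mention("Bacteria", [abbr]))

    for _ in range(nb - 1):
        b = _Tok(f"Bacterium{rng.integers(cfg.n_bacteria_vocab)}", "NNP", "B-NP",
                 "conj", head=first_b, ent="B-Bacteria")
        toks.append(_Tok("and", "CC", "O", "cc", head=first_b))
        toks.append(b)
        bact_idx.append(len(mentions))
        mentions.append(_Mention("Bacteria", [b]))

    toks.append(verb)

    # object noun phrases
    loc_idx: list[int] = []
    first_loc_head: _Tok | None = None
    for j in range(nl):
        attach = verb if first_loc_head is None else first_loc_head
        label = "dobj" if first_loc_head is None else "conj"
        if j > 0:
            toks.append(_Tok("and", "CC", "O", "cc", head=first_loc_head))
        if rng.random() < cfg.p_geo:
            head_tok = _Tok(f"Geoland{rng.integers(cfg.n_geo_vocab)}", "NNP", "B-NP",
                            label, head=attach, ent="B-Geographical")
            toks.append(head_tok)
            mention = _Mention("Geographical", [head_tok])
        else:
            toks.append(_Tok("the", "DT", "B-NP", "det",
                             head=None))  # head fixed below
            det = toks[-1]
            if rng.random() < cfg.p_multiword:
                head_tok = _Tok(f"tissue{rng.integers(cfg.n_habitat_vocab)}", "NN",
                                "I-NP", label, head=attach, ent="B-Habitat")
                of = _Tok("of", "IN", "O", "prep", head=head_tok, ent="I-Habitat")
                host = _Tok(f"host{rng.integers(cfg.n_host_vocab)}", "NN", "B-NP",
                            "pobj", head=of, ent="I-Habitat")
                toks.extend([head_tok, of, host])
                mention = _Mention("Habitat", [head_tok, of, host])
            else:
                head_tok = _Tok(f"habitat{rng.integers(cfg.n_habitat_vocab)}", "NN",
                                "I-NP", label, head=attach, ent="B-Habitat")
                toks.append(head_tok)
                mention = _Mention("Habitat", [head_tok])
            det.head = head_tok
        if first_loc_head is None:
            first_loc_head = head_tok
        loc_idx.append(len(mentions))
        mentions.append(mention)

    # distractor cue inside a relative clause, off every entity-pair path
    if not positive and rng.random() < cfg.p_distractor:
        rc_verb = _Tok(cfg.cue, "VBZ", "B-VP", "rcmod", head=head_tok)
        toks.append(_Tok("that", "WDT", "B-NP", "nsubj", head=rc_verb))
        toks.append(rc_verb)
        toks.append(_Tok("samples", "NNS", "B-NP", "dobj", head=rc_verb))

    toks.append(_Tok(".", ".", "O", "punct", head=verb))

    gold_local = [(b, l) for b in bact_idx for l in loc_idx] if positive else []
    return toks, mentions, gold_local, equiv_local, positive


def _graph_from_tokens(toks: list[_Tok]) -> ParseGraph:
    index = {id(t): i + 1 for i, t in enumerate(toks)}
    return ParseGraph(
        surface=[t.surface for t in toks],
        stem=[_stem(t.surface) for t in toks],
        pos=[t.pos for t in toks],
        chunk=[t.chunk for t in toks],
        entity=[t.ent for t in toks],
        head=[0 if t.head is None else index[id(t.head)] for t in toks],
        deplabel=[t.deplabel for t in toks],
    )


def generate_document(cfg: SynthConfig, doc_id: str, rng: np.random.Generator) -> SynthDoc:
    sentences = [_gen_sentence(cfg, rng) for _ in range(cfg.sentences_per_doc)]

    # assemble text and character offsets
    text_parts: list[str] = []
    offset = 0
    tok_offsets: dict[int, tuple[int, int]] = {}
    for toks, *_ in sentences:
        for t in toks:
            if text_parts:
                offset += 1  # single space separator
            tok_offsets[id(t)] = (offset, offset + len(t.surface))
            text_parts.append(t.surface)
            offset += len(t.surface)
    text = " ".join(text_parts)

    # entities, in sentence/mention order
    entities: list[Entity] = []
    mention_tid: dict[tuple[int, int], str] = {}
    for si, (_, mentions, _, _, _) in enumerate(sentences):
        for mi, m in enumerate(mentions):
            start = tok_offsets[id(m.toks[0])][0]
            end = tok_offsets[id(m.toks[-1])][1]
            tid = f"T{len(entities) + 1}"
            entities.append(Entity(id=tid, type=m.type,
                                   spans=((start, end),), surface=text[start:end]))
            mention_tid[(si, mi)] = tid

    relations: list[RelationAnn] = []
    equiv_groups: list[EquivGroup] = []
    for si, (_, _, gold_local, equiv_local, _) in enumerate(sentences):
        for b, l in gold_local:
            relations.append(RelationAnn(id=f"R{len(relations) + 1}",
                                         bacterium=mention_tid[(si, b)],
                                         location=mention_tid[(si, l)]))
        for a, b in equiv_local:
            equiv_groups.append(EquivGroup(frozenset({mention_tid[(si, a)],
                                                      mention_tid[(si, b)]})))

    # cross-sentence gold relations (unreachable for an intra-sentence system)
    if cfg.sentences_per_doc >= 2 and rng.random() < cfg.cross_sentence_rate:
        with_bact = [si for si, (_, ms, _, _, _) in enumerate(sentences)
                     if any(m.type == "Bacteria" for m in ms)]
        with_loc = [si for si, (_, ms, _, _, _) in enumerate(sentences)
                    if any(m.type != "Bacteria" for m in ms)]
        choices = [(sb, sl) for sb in with_bact for sl in with_loc if sb != sl]
        if choices:
            sb, sl = choices[int(rng.integers(len(choices)))]
            bi = next(mi for mi, m in enumerate(sentences[sb][1]) if m.type == "Bacteria")
            li = next(mi for mi, m in enumerate(sentences[sl][1]) if m.type != "Bacteria")
            relations.append(RelationAnn(id=f"R{len(relations) + 1}",
                                         bacterium=mention_tid[(sb, bi)],
                                         location=mention_tid[(sl, li)]))

    a1 = "".join(
        f"{e.id}\t{e.type} {e.start} {e.end}\t{e.surface}\n" for e in entities
    )
    a2 = write_a2(relations)
    a2 += "".join(f"*\tEquiv {' '.join(sorted(g.members))}\n" for g in equiv_groups)
    conll = write_conll([_graph_from_tokens(toks) for toks, *_ in sentences])
    return SynthDoc(doc_id=doc_id, text=text + "\n", a1=a1, a2=a2, conll=conll)


def generate_corpus(cfg: SynthConfig) -> list[SynthDoc]:
    """Deterministic corpus: the same config (seed included) gives
    byte-identical files."""
    rng = np.random.default_rng(cfg.seed)
    return [
        generate_document(cfg, f"{cfg.doc_prefix}{i:04d}", rng)
        for i in range(cfg.n_docs)
    ]


def write_corpus(docs: list[SynthDoc], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for d in docs:
        (out / f"{d.doc_id}.txt").write_text(d.text, encoding="utf-8")
        (out / f"{d.doc_id}.a1").write_text(d.a1, encoding="utf-8")
        (out / f"{d.doc_id}.a2").write_text(d.a2, encoding="utf-8")
        (out / f"{d.doc_id}.conll").write_text(d.conll, encoding="utf-8")
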