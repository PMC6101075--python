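"""Dependency-parse handling: the CoNLL-style dialect, entity-run collapse,
and the shortest-path / extended-tree token subsequences fed to the model.

Parse dialect (GDep-compatible column order): one token per line, TAB
separated columns ``index surface stem pos chunk entity head deplabel``
with 1-based token indices, ``head == 0`` for the artificial root, and a
blank line between sentences.

The model never sees whole parse trees.  For a candidate entity pair it
sees the tokens on the shortest undirected dependency path between the two
placeholders (the linearization of the shortest-path-enclosed tree, SPT),
optionally extended by the nearest governing verb (the dynamic extended
tree, DET) — re-ordered by original sentence position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx

logger = logging.getLogger(__name__)

E1_PLACEHOLDER = "entity_1"
E2_PLACEHOLDER = "entity_2"


@dataclass
class ParseGraph:
    """One sentence's tokens and dependency edges.

    All per-token columns are parallel lists; ``head[i]`` is the 1-based
    index of token i's governor (0 = artificial root).
    """

    surface: list[str]
    stem: list[str]
    pos: list[str]
    chunk: list[str]
    entity: list[str]
    head: list[int]
    deplabel: list[str]

    def __post_init__(self) -> None:
        n = len(self.surface)
        for name in ("stem", "pos", "chunk", "entity", "head", "deplabel"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        for h in self.head:
            if not 0 <= h <= n:
                raise ValueError(f"head index {h} outside [0, {n}]")

    def __len__(self) -> int:
        return len(self.surface)

    def depth(self, i: int) -> int:
        """Distance from token i (0-based) to the artificial root."""
        d, cur = 0, i
        seen = set()
        while self.head[cur] != 0:
            if cur in seen:  # malformed cycle; treat as root-attached
                break
            seen.add(cur)
            cur = self.head[cur] - 1
            d += 1
        return d

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        for i, h in enumerate(self.head):
            if h != 0:
                g.add_edge(i, h - 1)
        return g


@dataclass
class LinearizedInput:
    """A token subsequence (sentence order preserved) ready for encoding."""

    tokens: list[str]
    pos: list[str]
    e1_pos: int
    e2_pos: int
    indices: list[int] = field(default_factory=list)  # positions in the source graph

    def __post_init__(self) -> None:
        if self.tokens.count(E1_PLACEHOLDER) != 1 or self.tokens.count(E2_PLACEHOLDER) != 1:
            raise ValueError("linearized input must contain each placeholder exactly once")
        if self.e1_pos == self.e2_pos:
            raise ValueError("placeholder positions must differ")

    def __len__(self) -> int:
        return len(self.tokens)


def read_conll(path_or_text, from_string: bool = False) -> list[ParseGraph]:
    """Parse the CoNLL-style dialect into one :class:`ParseGraph` per sentence."""
    if from_string:
        text = path_or_text
    else:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    graphs: list[ParseGraph] = []
    block: list[list[str]] = []

    def flush() -> None:
        if not block:
            return
        cols = list(zip(*block))
        graphs.append(
            ParseGraph(
                surface=list(cols[1]),
                stem=list(cols[2]),
                pos=list(cols[3]),
                chunk=list(cols[4]),
                entity=list(cols[5]),
                head=[int(h) for h in cols[6]],
                deplabel=list(cols[7]),
            )
        )
        block.clear()

    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            flush()
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 8:
            raise ValueError(f"parse line {lineno}: expected 8 columns, got {len(fields)}")
        block.append(fields)
    flush()
    return graphs


def write_conll(graphs: list[ParseGraph]) -> str:
    out = []
    for g in graphs:
        for i in range(len(g)):
            out.append(
                "\t".join(
                    [
                        str(i + 1),
                        g.surface[i],
                        g.stem[i],
                        g.pos[i],
                        g.chunk[i],
                        g.entity[i],
                        str(g.head[i]),
                        g.deplabel[i],
                    ]
                )
            )
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


def fallback_parse(sentence: str) -> ParseGraph:
    """Whitespace tokenization with a flat left-headed chain.

    Used only when no parse file is available: every token attaches to its
    predecessor so the dependency path between two tokens is simply the
    surface span between them.
    """
    toks = sentence.split()
    n = len(toks)
    return ParseGraph(
        surface=toks,
        stem=[t.lower() for t in toks],
        pos=["UNK"] * n,
        chunk=["O"] * n,
        entity=["O"] * n,
        head=[i for i in range(n)],  # token 0 -> root, token i -> i (1-based i)
        deplabel=["dep"] * n,
    )


def run_head(g: ParseGraph, run: list[int]) -> int:
    """Head token of a contiguous-or-not entity token run: the token whose
    governor lies outside the run (fallback: the last token)."""
    run_set = set(run)
    for i in run:
        h = g.head[i]
        if h == 0 or (h - 1) not in run_set:
            return i
    return run[-1]


def collapse_entity_runs(
    g: ParseGraph, e1_run: list[int], e2_run: list[int], mode: str = "span"
) -> tuple[ParseGraph, int, int]:
    """Replace the two entity mentions by ``entity_1``/``entity_2`` placeholders.

    ``mode='span'`` collapses each full token run to a single placeholder
    (well-defined for arbitrary spans); ``mode='head'`` renames only the
    run's head token and keeps the remaining entity tokens — the behaviour
    suggested by replacing just the mention head.  Returns the rewritten
    graph and the two placeholder positions.
    """
    if set(e1_run) & set(e2_run):
        raise ValueError("entity token runs overlap")
    if not e1_run or not e2_run:
        raise ValueError("empty entity token run")
    h1, h2 = run_head(g, e1_run), run_head(g, e2_run)
    if mode == "head":
        drop: set[int] = set()
    elif mode == "span":
        drop = (set(e1_run) | set(e2_run)) - {h1, h2}
    else:
        raise ValueError(f"unknown replace mode {mode!r}")

    keep = [i for i in range(len(g)) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}

    def new_head(old: int) -> int:
        """Follow governors of dropped tokens until a kept one (or root)."""
        h = g.head[old]
        seen = set()
        while h != 0 and (h - 1) in drop and h not in seen:
            seen.add(h)
            h = g.head[h - 1]
        if h != 0 and (h - 1) in drop:  # cycle entirely inside the run
            return 0
        return 0 if h == 0 else remap[h - 1] + 1

    collapsed = ParseGraph(
        surface=[
            E1_PLACEHOLDER if i == h1 else E2_PLACEHOLDER if i == h2 else g.surface[i]
            for i in keep
        ],
        stem=[
            E1_PLACEHOLDER if i == h1 else E2_PLACEHOLDER if i == h2 else g.stem[i]
            for i in keep
        ],
        pos=[g.pos[i] for i in keep],
        chunk=[g.chunk[i] for i in keep],
        entity=[g.entity[i] for i in keep],
        head=[new_head(i) for i in keep],
        deplabel=[g.deplabel[i] for i in keep],
    )
    return collapsed, remap[h1], remap[h2]


def _linearize(g: ParseGraph, indices: list[int], e1_pos: int, e2_pos: int) -> LinearizedInput:
    ordered = sorted(set(indices))
    return LinearizedInput(
        tokens=[g.surface[i] for i in ordered],
        pos=[g.pos[i] for i in ordered],
        e1_pos=ordered.index(e1_pos),
        e2_pos=ordered.index(e2_pos),
        indices=ordered,
    )


def shortest_path_tokens(g: ParseGraph, e1_pos: int, e2_pos: int) -> LinearizedInput:
    """Tokens on the shortest undirected dependency path between the two
    placeholders, inclusive, re-ordered by sentence position.

    A disconnected graph falls back to the full sentence with a warning.
    """
    if not (0 <= e1_pos < len(g) and 0 <= e2_pos < len(g)):
        raise ValueError("entity position outside sentence")
    try:
        path = nx.shortest_path(g.to_undirected(), e1_pos, e2_pos)
    except nx.NetworkXNoPath:
        logger.warning("disconnected dependency graph; falling back to full sentence")
        path = list(range(len(g)))
    return _linearize(g, path, e1_pos, e2_pos)


def dynamic_extended_tokens(g: ParseGraph, spt: LinearizedInput) -> LinearizedInput:
    """Extend the SPT with the nearest governing verb.

    From the shallower path endpoint, head links are walked upward until a
    token with a verb tag (``VB*``) is found; that token joins the
    subsequence.  Sentences with no verb ancestor return the SPT unchanged.
    """
    p1 = spt.indices[spt.e1_pos]
    p2 = spt.indices[spt.e2_pos]
    start = p1 if g.depth(p1) <= g.depth(p2) else p2
    cur = g.head[start]
    seen = set()
    verb = None
    while cur != 0 and cur not in seen:
        seen.add(cur)
        if g.pos[cur - 1].startswith("VB"):
            verb = cur - 1
            break
        cur = g.head[cur - 1]
    if verb is None:
        return replace(spt)
    return _linearize(g, spt.indices + [verb], p1, p2)


def linearize_candidate(
    g: ParseGraph,
    e1_run: list[int],
    e2_run: list[int],
    mode: str = "span",
    use_det: bool = True,
) -> LinearizedInput:
    """Full pipeline: collapse entity mentions, take the SPT, extend to DET."""
    collapsed, p1, p2 = collapse_entity_runs(g, e1_run, e2_run, mode=mode)
    spt = shortest_path_tokens(collapsed, p1, p2)
    return dynamic_extended_tokens(collapsed, spt) if use_det else spt
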