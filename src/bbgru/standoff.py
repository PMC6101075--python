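"""Reader/writer for BioNLP-ST standoff annotation triples.

A document is stored as three files sharing a basename: ``doc_id.txt`` (UTF-8
text), ``doc_id.a1`` (entities) and ``doc_id.a2`` (relations and Equiv
groups).  Entity lines look like::

    T3\tHabitat 21 52\tpopulations of gopher tortoises

with 0-based half-open character offsets; discontinuous spans are separated
by ``;`` and their surface fragments joined by single spaces.  Relation lines
look like::

    R1\tLives_In Bacterium:T3 Location:T2

and equivalence lines ``*\tEquiv T1 T4 ...``.  Other annotation layers
(events, normalizations, notes) that Bacteria-Biotope corpora may carry are
skipped with a warning — the relation model does not use them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset({"Bacteria", "Habitat", "Geographical"})
LOCATION_TYPES = frozenset({"Habitat", "Geographical"})
RELATION_TYPE = "Lives_In"


class StandoffParseError(ValueError):
    """Malformed standoff line; message names file and line number."""


class StandoffReferenceError(ValueError):
    """An .a2 annotation refers to an entity id absent from the .a1 file."""


@dataclass(frozen=True)
class Entity:
    id: str
    type: str
    spans: tuple[tuple[int, int], ...]
    surface: str

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    def validate(self, text: str) -> None:
        if self.type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.type!r} for {self.id}")
        for s, e in self.spans:
            if not (0 <= s < e <= len(text)):
                raise ValueError(
                    f"entity {self.id}: span ({s},{e}) outside text of length {len(text)}"
                )
        joined = " ".join(text[s:e] for s, e in self.spans)
        if joined != self.surface:
            raise ValueError(
                f"entity {self.id}: surface {self.surface!r} does not match text slice {joined!r}"
            )


@dataclass(frozen=True)
class RelationAnn:
    id: str
    bacterium: str
    location: str
    type: str = RELATION_TYPE


@dataclass(frozen=True)
class EquivGroup:
    members: frozenset[str]


@dataclass
class Document:
    doc_id: str
    text: str
    entities: dict[str, Entity] = field(default_factory=dict)
    relations: list[RelationAnn] = field(default_factory=list)
    equiv: list[EquivGroup] = field(default_factory=list)

    def equiv_class(self, entity_id: str) -> frozenset[str]:
        """The Equiv class containing *entity_id* (singleton if ungrouped)."""
        for group in self.equiv:
            if entity_id in group.members:
                return group.members
        return frozenset({entity_id})

    def canonical(self, entity_id: str) -> str:
        """Deterministic representative of the entity's Equiv class."""
        return min(self.equiv_class(entity_id))


def _parse_a1_line(line: str, text: str, path: str, lineno: int) -> Entity | None:
    parts = line.split("\t")
    if not parts[0].startswith("T"):
        logger.warning("%s:%d: skipping non-entity a1 line %r", path, lineno, parts[0])
        return None
    if len(parts) != 3:
        raise StandoffParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
    eid, type_and_spans, surface = parts
    head, _, span_str = type_and_spans.partition(" ")
    spans: list[tuple[int, int]] = []
    try:
        for frag in span_str.split(";"):
            s, e = frag.split()
            spans.append((int(s), int(e)))
    except ValueError as exc:
        raise StandoffParseError(f"{path}:{lineno}: bad span list {span_str!r}") from exc
    ent = Entity(id=eid, type=head, spans=tuple(spans), surface=surface)
    try:
        ent.validate(text)
    except ValueError as exc:
        raise StandoffParseError(f"{path}:{lineno}: {exc}") from exc
    return ent


def _parse_a2_line(
    line: str, entities: dict[str, Entity], path: str, lineno: int
) -> RelationAnn | EquivGroup | None:
    parts = line.split("\t")
    if len(parts) < 2:
        raise StandoffParseError(f"{path}:{lineno}: expected at least 2 fields")
    aid, body = parts[0], parts[1]
    fields = body.split()
    if aid == "*":
        if fields[0] != "Equiv" or len(fields) < 3:
            raise StandoffParseError(f"{path}:{lineno}: malformed Equiv line")
        for ref in fields[1:]:
            if ref not in entities:
                raise StandoffReferenceError(
                    f"{path}:{lineno}: Equiv references unknown entity {ref}"
                )
        return EquivGroup(members=frozenset(fields[1:]))
    if aid.startswith("R"):
        if fields[0] != RELATION_TYPE or len(fields) != 3:
            raise StandoffParseError(
                f"{path}:{lineno}: expected '{RELATION_TYPE} Bacterium:Tx Location:Ty'"
            )
        args: dict[str, str] = {}
        for f in fields[1:]:
            role, _, ref = f.partition(":")
            args[role] = ref
        if set(args) != {"Bacterium", "Location"}:
            raise StandoffParseError(f"{path}:{lineno}: bad argument roles {sorted(args)}")
        for ref in args.values():
            if ref not in entities:
                raise StandoffReferenceError(
                    f"{path}:{lineno}: relation references unknown entity {ref}"
                )
        bact, loc = entities[args["Bacterium"]], entities[args["Location"]]
        if bact.type != "Bacteria":
            raise StandoffParseError(
                f"{path}:{lineno}: Bacterium argument {bact.id} has type {bact.type}"
            )
        if loc.type not in LOCATION_TYPES:
            raise StandoffParseError(
                f"{path}:{lineno}: Location argument {loc.id} has type {loc.type}"
            )
        return RelationAnn(id=aid, bacterium=bact.id, location=loc.id)
    logger.warning("%s:%d: skipping unsupported annotation %r", path, lineno, aid)
    return None


def _close_equiv(groups: list[EquivGroup]) -> list[EquivGroup]:
    """Merge overlapping groups so equivalence classes are disjoint."""
    merged: list[set[str]] = []
    for g in groups:
        members = set(g.members)
        keep: list[set[str]] = []
        for m in merged:
            if m & members:
                members |= m
            else:
                keep.append(m)
        keep.append(members)
        merged = keep
    return [EquivGroup(frozenset(m)) for m in sorted(merged, key=min)]


def read_document(txt_path, a1_path, a2_path=None) -> Document:
    """Load one standoff triple into a :class:`Document`.

    ``a2_path`` may be ``None`` or point to a missing file; the document then
    carries no relations and no Equiv groups (the unannotated/test case).
    """
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    doc = Document(doc_id=txt_path.stem, text=text)

    for lineno, line in enumerate(Path(a1_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        ent = _parse_a1_line(line, text, str(a1_path), lineno)
        if ent is None:
            continue
        if ent.id in doc.entities:
            raise StandoffParseError(f"{a1_path}:{lineno}: duplicate entity id {ent.id}")
        doc.entities[ent.id] = ent

    if a2_path is not None and Path(a2_path).exists():
        raw_groups: list[EquivGroup] = []
        for lineno, line in enumerate(
            Path(a2_path).read_text(encoding="utf-8").splitlines(), 1
        ):
            if not line.strip():
                continue
            ann = _parse_a2_line(line, doc.entities, str(a2_path), lineno)
            if isinstance(ann, RelationAnn):
                doc.relations.append(ann)
            elif isinstance(ann, EquivGroup):
                raw_groups.append(ann)
        doc.equiv = _close_equiv(raw_groups)
    return doc


def write_a2(relations: list[RelationAnn], entities: dict[str, Entity] | None = None) -> str:
    """Serialize relations as .a2 text, renumbering ids R1..Rn in order.

    If *entities* is given, argument types are checked against it.
    """
    lines = []
    for i, rel in enumerate(relations, 1):
        if entities is not None:
            bact = entities.get(rel.bacterium)
            if bact is None or bact.type != "Bacteria":
                raise ValueError(
                    f"relation {rel.id}: first argument {rel.bacterium} is not a Bacteria entity"
                )
            loc = entities.get(rel.location)
            if loc is None or loc.type not in LOCATION_TYPES:
                raise ValueError(
                    f"relation {rel.id}: second argument {rel.location} is not a location entity"
                )
        lines.append(f"R{i}\t{RELATION_TYPE} Bacterium:{rel.bacterium} Location:{rel.location}")
    return "\n".join(lines) + ("\n" if lines else "")
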