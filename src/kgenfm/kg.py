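"""Knowledge-graph data model and triple I/O.

A biomedical knowledge graph is a set of (head, relation, tail) triples over
typed entities (drugs, proteins, diseases, pathways, annotation hubs, ...).
One relation id may be designated as the drug-target interaction (DTI)
relation; those triples are the prediction task, all others are the
"supporting" graph that is always available at training time.

File dialect: UTF-8 TSV with columns head<TAB>relation<TAB>tail, lines
starting with '#' ignored.  Duplicate triples are silently deduplicated (the
KG is a set of facts).  Entity/relation integer indices are assigned by
lexicographic sort of ids, so vocabularies are reproducible without seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .errors import LookupEntityError, ParseError

ENTITY_TYPES = ("drug", "protein", "disease", "pathway", "hub", "other")


class Triple(NamedTuple):
    head: str
    relation: str
    tail: str

    def validate(self) -> "Triple":
        for part in self:
            if part == "" or "\t" in part or "\n" in part:
                raise ParseError(f"invalid id in triple {self!r}")
        return self


@dataclass
class KnowledgeGraph:
    """Deduplicated triple set with an entity-type map.

    ``triples`` preserves first-seen order but compares as a set;
    ``entity_types`` maps every entity appearing in a triple to one of
    :data:`ENTITY_TYPES` (default ``"other"``).  ``dti_relation`` names the
    relation whose triples are drug-target interactions; it is configuration,
    never inferred from the data.
    """

    triples: list[Triple] = field(default_factory=list)
    entity_types: dict[str, str] = field(default_factory=dict)
    dti_relation: str | None = None

    def __post_init__(self) -> None:
        seen: set[Triple] = set()
        unique: list[Triple] = []
        for t in self.triples:
            t = Triple(*t).validate()
            if t not in seen:
                seen.add(t)
                unique.append(t)
        self.triples = unique
        self._triple_set = seen
        for e in self.entities():
            self.entity_types.setdefault(e, "other")
        if self.dti_relation is not None:
            for t in unique:
                if t.relation == self.dti_relation:
                    ht, tt = self.entity_types[t.head], self.entity_types[t.tail]
                    if ht != "drug" or tt != "protein":
                        raise ParseError(
                            f"DTI triple {t} must link a drug to a protein "
                            f"(got {ht} -> {tt})"
                        )

    def __contains__(self, triple: Triple) -> bool:
        return Triple(*triple) in self._triple_set

    def __len__(self) -> int:
        return len(self.triples)

    def entities(self) -> list[str]:
        out: dict[str, None] = {}
        for h, _, t in self.triples:
            out.setdefault(h)
            out.setdefault(t)
        return list(out)

    def relations(self) -> list[str]:
        out: dict[str, None] = {}
        for _, r, _ in self.triples:
            out.setdefault(r)
        return list(out)

    def triple_set(self) -> frozenset[Triple]:
        return frozenset(self._triple_set)

    def dti_pairs(self) -> list[tuple[str, str]]:
        """(drug, protein) pairs of all triples under the DTI relation."""
        if self.dti_relation is None:
            return []
        return [(h, t) for h, r, t in self.triples if r == self.dti_relation]

    def sub_kg(self, triples: Iterable[Triple]) -> "KnowledgeGraph":
        """A KG over a triple subset, inheriting types and the DTI relation."""
        kept = [t for t in triples]
        ids = {e for tr in kept for e in (tr.head, tr.tail)}
        return KnowledgeGraph(
            triples=kept,
            entity_types={e: self.entity_types.get(e, "other") for e in ids},
            dti_relation=self.dti_relation,
        )


@dataclass(frozen=True)
class EntityVocab:
    """Dense, deterministic integer indices for entities and relations."""

    entity_index: Mapping[str, int]
    relation_index: Mapping[str, int]

    @classmethod
    def from_kg(cls, kg: KnowledgeGraph) -> "EntityVocab":
        ents = sorted(kg.entities())
        rels = sorted(kg.relations())
        return cls(
            entity_index={e: i for i, e in enumerate(ents)},
            relation_index={r: i for i, r in enumerate(rels)},
        )

    @property
    def n_entities(self) -> int:
        return len(self.entity_index)

    @property
    def n_relations(self) -> int:
        return len(self.relation_index)

    def entity_ids(self) -> list[str]:
        return sorted(self.entity_index, key=self.entity_index.__getitem__)

    def relation_ids(self) -> list[str]:
        return sorted(self.relation_index, key=self.relation_index.__getitem__)


def read_type_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV entity-id<TAB>type map."""
    types: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            types[parts[0]] = parts[1]
    return types


def read_triples(
    path: str | Path,
    type_map: str | Path | Mapping[str, str] | None = None,
    dti_relation: str | None = None,
) -> KnowledgeGraph:
    """Read a head/relation/tail TSV into a :class:`KnowledgeGraph`.

    Line order does not affect the resulting triple set.  Entities absent
    from ``type_map`` get type ``"other"``.
    """
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            if any(p == "" for p in parts):
                raise ParseError(f"{path}:{lineno}: empty id")
            triples.append(Triple(*parts))
    if type_map is None:
        types: dict[str, str] = {}
    elif isinstance(type_map, Mapping):
        types = dict(type_map)
    else:
        types = read_type_map(type_map)
    return KnowledgeGraph(triples=triples, entity_types=types, dti_relation=dti_relation)


def write_triples(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write the KG as TSV; round-trips with :func:`read_triples`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# head\trelation\ttail\n")
        for h, r, t in kg.triples:
            fh.write(f"{h}\t{r}\t{t}\n")


def write_type_map(kg: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# entity\ttype\n")
        for e in sorted(kg.entity_types):
            fh.write(f"{e}\t{kg.entity_types[e]}\n")


def extract_neighborhood(
    kg: KnowledgeGraph, seeds: Iterable[str], order: int = 1
) -> KnowledgeGraph:
    """First- or second-order neighborhood sub-KG around seed entities.

    Order 1 keeps every triple incident to a seed; order 2 additionally keeps
    every triple incident to any entity touched by the order-1 set.  Edge
    direction is ignored (incidence at either endpoint counts).
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    seeds = set(seeds)
    known = set(kg.entities())
    for s in seeds:
        if s not in known:
            raise LookupEntityError(f"unknown seed entity {s!r}")
    frontier = seeds
    kept: list[Triple] = []
    kept_set: set[Triple] = set()
    for _ in range(order):
        touched: set[str] = set()
        for t in kg.triples:
            if (t.head in frontier or t.tail in frontier) and t not in kept_set:
                kept.append(t)
                kept_set.add(t)
            if t in kept_set:
                touched.update((t.head, t.tail))
        frontier = frontier | touched
    return kg.sub_kg(kept)


def remove_nodes(kg: KnowledgeGraph, victims: Iterable[str]) -> KnowledgeGraph:
    """Drop every triple incident to a victim entity or victim type label.

    Victim set members matching a type label (e.g. ``"hub"``) remove all
    entities of that type.  Removing absent nodes is a no-op.  Used to prune
    high-betweenness "identifier" nodes that inject noise into embeddings.
    """
    victims = set(victims)
    doomed = {e for e, ty in kg.entity_types.items() if ty in victims}
    doomed |= victims & set(kg.entity_types)
    kept = [t for t in kg.triples if t.head not in doomed and t.tail not in doomed]
    return kg.sub_kg(kept)
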