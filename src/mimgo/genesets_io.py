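"""Gene-set collections: GMT read/write, GAF + OBO construction, merge/filter.

Gene sets are GO terms treated as named sets of gene identifiers. They can be
read directly from GMT, or built from a GAF 2.x annotation file plus an
OBO 1.2 ontology (optionally propagating annotations up the is_a hierarchy).
GMT is the canonical interchange format for everything downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet


class ParseError(ValueError):
    """Raised for malformed GMT/GAF input lines."""


@dataclass
class GeneSet:
    """A named gene set (typically a GO term).

    ``aliases`` records accessions of other terms merged into this one
    because they annotated an identical gene membership.
    """

    term_id: str
    term_name: str
    genes: set[str]
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.term_id} is empty")


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets with unique term ids."""

    sets: list[GeneSet]

    def __post_init__(self):
        ids = [s.term_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term_id in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)

    @property
    def term_ids(self) -> list[str]:
        return [s.term_id for s in self.sets]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``id <TAB> description <TAB> gene1 <TAB> gene2 ...``

    Duplicate genes within a line are collapsed. Blank lines are skipped;
    a line with fewer than three fields is a parse error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term_id, name, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(term_id, name, set(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT; genes sorted for a canonical byte layout."""
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.genes)]))
            fh.write("\n")


# GAF 2.x column indices (0-based)
_GAF_QUALIFIER = 3
_GAF_GO_ID = 4
_GAF_SYMBOL = 2
_GAF_NCOL = 17


def read_gaf_obo(gaf_path, obo_path, propagate: bool = False,
                 namespace: str | None = None) -> GeneSetCollection:
    """Build gene sets from a GAF 2.x annotation file and an OBO 1.2 ontology.

    One gene set per GO id with at least one (non-NOT) annotation. Obsolete
    terms are dropped. With ``propagate`` on, each gene is also added to all
    is_a ancestors of its directly annotated terms. ``namespace`` optionally
    restricts output to one GO namespace (e.g. ``biological_process``).

    A GO id present in the GAF but absent from the ontology triggers a
    warning; the term is kept with an empty name.
    """
    graph = obonet.read_obo(obo_path)  # obsolete terms are excluded

    direct: dict[str, set[str]] = {}
    with open(gaf_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) != _GAF_NCOL:
                raise ParseError(
                    f"{gaf_path}: line {lineno}: expected {_GAF_NCOL} "
                    f"columns, got {len(fields)}"
                )
            if "NOT" in fields[_GAF_QUALIFIER].split("|"):
                continue
            go_id = fields[_GAF_GO_ID]
            gene = fields[_GAF_SYMBOL]
            direct.setdefault(go_id, set()).add(gene)

    membership: dict[str, set[str]] = {}
    for go_id, genes in direct.items():
        if go_id in graph:
            membership.setdefault(go_id, set()).update(genes)
            if propagate:
                for anc in _isa_ancestors(graph, go_id):
                    membership.setdefault(anc, set()).update(genes)
        else:
            # obsolete (dropped from the graph) or unknown id
            if _is_obsolete(obo_path, go_id):
                continue
            warnings.warn(
                f"GO id {go_id} in GAF absent from ontology; kept unnamed"
            )
            membership.setdefault(go_id, set()).update(genes)

    sets = []
    for go_id in sorted(membership):
        node = graph.nodes.get(go_id, {})
        if namespace is not None and node.get("namespace") != namespace:
            if go_id in graph:
                continue
        sets.append(GeneSet(go_id, node.get("name", ""), membership[go_id]))
    return GeneSetCollection(sets)


def _isa_ancestors(graph: nx.MultiDiGraph, node: str) -> set[str]:
    """Transitive is_a ancestors (obonet edges point child -> parent)."""
    seen: set[str] = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        for _, parent, key in graph.out_edges(cur, keys=True):
            if key == "is_a" and parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def _is_obsolete(obo_path, go_id: str) -> bool:
    """Scan the OBO text for an obsolete [Term] stanza with this id."""
    in_term = False
    cur_id = None
    obsolete = False
    with open(obo_path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                if in_term and cur_id == go_id and obsolete:
                    return True
                in_term, cur_id, obsolete = True, None, False
            elif in_term and line.startswith("id:"):
                cur_id = line[3:].strip()
            elif in_term and line.startswith("is_obsolete:"):
                obsolete = line.split(":", 1)[1].strip() == "true"
    return in_term and cur_id == go_id and obsolete


def merge_and_filter(collection: GeneSetCollection, universe: set[str],
                     min_size: int = 3) -> GeneSetCollection:
    """Intersect with the universe, merge identical sets, drop small sets.

    Sets whose surviving membership is identical are merged into one set
    under the lexicographically smallest term id, with the other ids
    recorded as aliases. Sets with fewer than ``min_size`` surviving genes
    are removed.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not universe:
        raise ValueError("universe is empty")

    by_membership: dict[frozenset, list[GeneSet]] = {}
    order: list[frozenset] = []
    for s in collection.sets:
        genes = frozenset(s.genes & universe)
        if len(genes) < min_size:
            continue
        if genes not in by_membership:
            by_membership[genes] = []
            order.append(genes)
        by_membership[genes].append(s)

    merged: list[GeneSet] = []
    for genes in order:
        members = by_membership[genes]
        # all ids pointing at this membership, including earlier aliases
        all_ids = sorted({m.term_id for m in members}
                         | {a for m in members for a in m.aliases})
        rep_id = all_ids[0]
        rep = next((m for m in members if m.term_id == rep_id), members[0])
        merged.append(GeneSet(rep_id, rep.term_name, set(genes),
                              aliases=[i for i in all_ids if i != rep_id]))
    return GeneSetCollection(merged)
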