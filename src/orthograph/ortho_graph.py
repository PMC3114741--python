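"""Construction of the adaptive near-best-hit graph and its symmetric part.

For every query protein and every target species, only the hits whose bit
score is within a factor ``f`` of the query's best bit score against that
species are retained (``f = 1`` is the classical reciprocal-best-hit rule;
``f < 1`` additionally admits slightly weaker hits, which recovers divergent
co-orthologs). The retained directed arcs are then symmetrized: an
undirected edge exists only where both directions survived. Only sparse
adjacency is ever stored; the dense all-against-all hit matrix never exists
in memory because each species-pair table is reduced on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .similarity_io import Hit

#: a retained directed arc: (subject id, bit score, E-value)
Arc = tuple[str, float, float]


def adaptive_arcs(hits: list[Hit], f: float) -> list[Hit]:
    """Retain the near-best hits of one query against one target species.

    All hits must share ``query_id`` and ``subject_species`` and be already
    filtered/deduplicated. With best bit score ``B``, exactly the hits with
    ``bitscore >= f * B`` are returned, sorted by descending bit score and
    then subject id. Tied maxima are always all retained.
    """
    if not hits:
        return []
    best = max(h.bitscore for h in hits)
    cutoff = f * best
    kept = [h for h in hits if h.bitscore >= cutoff]
    kept.sort(key=lambda h: (-h.bitscore, h.subject_id))
    return kept


@dataclass
class DirectedArcSet:
    """Sparse store of retained arcs, keyed by (query id, target species)."""

    arcs: dict[tuple[str, str], list[Arc]] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_arcs(self) -> int:
        return sum(len(v) for v in self.arcs.values())

    def max_group_size_per_species(self) -> dict[str, int]:
        """Largest retained-arc list per target species (the k of the n*k
        storage contract)."""
        out: dict[str, int] = {}
        for (_, species), arcs in self.arcs.items():
            if len(arcs) > out.get(species, 0):
                out[species] = len(arcs)
        return out

    def ingest(self, filtered_hits: Iterable[Hit], f: float) -> None:
        """Reduce one species-pair's filtered hits to their near-best arcs.

        Grouping must be complete: all hits of a given (query, target
        species) pair arrive in a single call, which holds when each
        species-pair table is processed as a whole.
        """
        groups: dict[tuple[str, str], list[Hit]] = {}
        for h in filtered_hits:
            self.species_of.setdefault(h.query_id, h.query_species)
            self.species_of.setdefault(h.subject_id, h.subject_species)
            groups.setdefault((h.query_id, h.subject_species), []).append(h)
        for key, group in groups.items():
            if key in self.arcs:
                raise ValueError(
                    f"arcs for query {key[0]!r} vs species {key[1]!r} "
                    "ingested twice; species-pair tables must be disjoint"
                )
            self.arcs[key] = [
                (h.subject_id, h.bitscore, h.evalue)
                for h in adaptive_arcs(group, f)
            ]


def build_directed(hits: Iterable[Hit], f: float) -> DirectedArcSet:
    """Build the directed near-best-arc set from a stream of filtered hits."""
    g = DirectedArcSet()
    groups: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.query_id, h.subject_species), []).append(h)
    for key in groups:
        g.ingest(groups[key], f)
    return g


@dataclass
class OrthologyGraph:
    """Undirected weighted graph of reciprocally retained protein pairs.

    ``adj`` maps each vertex to a sorted list of (neighbor, weight); every
    edge is stored twice (once per endpoint), so the structure is exactly
    the sparse n*k chained-array layout. Vertices without any reciprocal
    partner are not present.
    """

    species: dict[str, str] = field(default_factory=dict)
    adj: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.adj)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adj.values()) // 2

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield each undirected edge once, as (u, v, weight) with u < v."""
        for u in sorted(self.adj):
            for v, w in self.adj[u]:
                if u < v:
                    yield u, v, w


def symmetrize(g: DirectedArcSet) -> OrthologyGraph:
    """Extract the symmetric part of the directed arc set.

    An undirected edge {x, y} exists iff both arcs x->y and y->x were
    retained; its weight is the arithmetic mean of the two directed bit
    scores. Vertices with no incident edge are dropped.
    """
    directed: dict[tuple[str, str], float] = {}
    for (q, _), arcs in g.arcs.items():
        for sid, bits, _ev in arcs:
            directed[(q, sid)] = bits
    out = OrthologyGraph()
    for (q, s), bits in directed.items():
        if q >= s:
            continue
        back = directed.get((s, q))
        if back is None:
            continue
        w = (bits + back) / 2.0
        out.adj.setdefault(q, []).append((s, w))
        out.adj.setdefault(s, []).append((q, w))
        out.species[q] = g.species_of[q]
        out.species[s] = g.species_of[s]
    for u in out.adj:
        out.adj[u].sort()
    return out


def write_edges_tsv(g: OrthologyGraph, path: str | Path) -> None:
    """Debug dump of the orthology graph as a sorted edge-list TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# u\tv\tweight\tu_species\tv_species\n")
        for u, v, w in g.edges():
            fh.write(
                f"{u}\t{v}\t{w:.6g}\t{g.species[u]}\t{g.species[v]}\n"
            )
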