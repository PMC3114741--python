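"""Shared helpers: quick Hit construction and species-labeled graph builders."""

from __future__ import annotations

import itertools

import pytest

from orthograph import Hit
from orthograph.spectral import Component


def mk_hit(
    q: str,
    s: str,
    bits: float,
    qspecies: str = "A",
    sspecies: str = "B",
    evalue: float | None = None,
    pident: float = 90.0,
    q_start: int = 1,
    q_end: int = 100,
) -> Hit:
    """A filtered-quality hit with sensible defaults (length-100 query)."""
    return Hit(
        query_id=q,
        subject_id=s,
        query_species=qspecies,
        subject_species=sspecies,
        pct_identity=pident,
        q_start=q_start,
        q_end=q_end,
        evalue=10.0 ** (-bits / 10.0) if evalue is None else evalue,
        bitscore=bits,
    )


def mk_component(
    nodes: list[tuple[str, str]], edges: list[tuple[str, str]]
) -> Component:
    """Component from (id, species) nodes and id-pair edges."""
    nodes = sorted(nodes)
    ids = [n[0] for n in nodes]
    idx = {pid: i for i, pid in enumerate(ids)}
    return Component(
        vertex_ids=ids,
        edges=sorted(
            (min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in edges
        ),
        species_of=[n[1] for n in nodes],
    )


def complete_multipartite(parts: list[list[tuple[str, str]]]) -> Component:
    """Complete multipartite component; each part is a list of (id, species)."""
    nodes = [n for part in parts for n in part]
    edges = []
    for pa, pb in itertools.combinations(parts, 2):
        for (a, _), (b, _) in itertools.product(pa, pb):
            edges.append((a, b))
    return mk_component(nodes, edges)


def two_cliques_with_bridges(
    k: int, n_bridges: int, shift: int = 1
) -> Component:
    """Two k-cliques over the same k species joined by cross-species bridges.

    Clique A has vertices a1..ak on species s1..sk, clique B likewise; the
    i-th bridge joins a_i with b_(i+shift mod k), so bridges never connect
    two proteins of the same species.
    """
    nodes = []
    for i in range(k):
        nodes.append((f"a{i}", f"s{i}"))
        nodes.append((f"b{i}", f"s{i}"))
    edges = []
    for i, j in itertools.combinations(range(k), 2):
        edges.append((f"a{i}", f"a{j}"))
        edges.append((f"b{i}", f"b{j}"))
    for i in range(n_bridges):
        edges.append((f"a{i}", f"b{(i + shift) % k}"))
    return mk_component(nodes, edges)


@pytest.fixture
def filter_defaults():
    from orthograph import FilterParams

    return FilterParams()
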