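"""Spectral decomposition of the orthology graph into (co-)ortholog groups.

A set of (co-)orthologs ideally forms a complete multipartite subgraph
(classes = species / co-ortholog sets), so real groups appear as dense,
nearly complete multipartite connected components. Each component is tested
via its normalized algebraic connectivity alpha_2 / n, where alpha_2 is the
second-smallest eigenvalue of the (unweighted) graph Laplacian L = D - A.
Components below the threshold are recursively bipartitioned along the sign
pattern of the Fiedler vector; tree-like protrusions — which most likely
correspond to false-positive edges — are pruned (iterated degree-1 removal)
before every connectivity computation, except in two-species analyses where
no cross-species information exists to correct the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .ortho_graph import OrthologyGraph
from .similarity_io import FilterParams

#: entries of the Fiedler vector with |x| <= ZERO_TOL count as "zero" and
#: are assigned to the positive side of the split
ZERO_TOL = 1e-12


@dataclass
class Component:
    """A connected subgraph: ordered vertex ids, index edges, species labels."""

    vertex_ids: list[str]
    edges: list[tuple[int, int]]
    species_of: list[str]

    @property
    def n(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_species(self) -> int:
        return len(set(self.species_of))

    def degrees(self) -> list[int]:
        deg = [0] * self.n
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def induced(self, keep: list[int]) -> "Component":
        """Induced subgraph on the given (sorted) vertex indices."""
        keep = sorted(keep)
        remap = {old: new for new, old in enumerate(keep)}
        kept = set(keep)
        edges = [
            (remap[i], remap[j])
            for i, j in self.edges
            if i in kept and j in kept
        ]
        return Component(
            vertex_ids=[self.vertex_ids[i] for i in keep],
            edges=sorted(
                (min(a, b), max(a, b)) for a, b in edges
            ),
            species_of=[self.species_of[i] for i in keep],
        )

    def laplacian(self) -> sp.csr_matrix:
        """Unweighted combinatorial Laplacian L = D - A."""
        n = self.n
        rows, cols, vals = [], [], []
        deg = self.degrees()
        for i, j in self.edges:
            rows += [i, j]
            cols += [j, i]
            vals += [-1.0, -1.0]
        rows += list(range(n))
        cols += list(range(n))
        vals += [float(d) for d in deg]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass
class SpectralResult:
    """alpha_2, its n-normalized value, and the associated Fiedler vector."""

    alpha2: float
    normalized_conn: float
    fiedler: np.ndarray


@dataclass
class OrthoGroup:
    """One reported (co-)ortholog group with per-species member lists."""

    members: dict[str, list[str]]
    conn: float

    @property
    def n_species(self) -> int:
        return len(self.members)

    @property
    def n_proteins(self) -> int:
        return sum(len(v) for v in self.members.values())

    def all_ids(self) -> list[str]:
        return sorted(pid for ids in self.members.values() for pid in ids)

    def sort_key(self) -> tuple:
        return (-self.n_species, -self.n_proteins, self.all_ids()[0])


def connected_components(g: OrthologyGraph) -> list[Component]:
    """Split the orthology graph into its connected components (BFS).

    Components are returned ordered by their smallest member id; vertices
    inside a component are sorted. Singletons cannot occur because isolated
    vertices are never stored in the graph.
    """
    seen: set[str] = set()
    comps: list[Component] = []
    for start in sorted(g.adj):
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        members: list[str] = []
        while queue:
            u = queue.pop(0)
            members.append(u)
            for v, _w in g.adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        members.sort()
        index = {pid: k for k, pid in enumerate(members)}
        edges = sorted(
            (index[u], index[v])
            for u in members
            for v, _w in g.adj[u]
            if index[u] < index[v]
        )
        comps.append(
            Component(
                vertex_ids=members,
                edges=edges,
                species_of=[g.species[m] for m in members],
            )
        )
    return comps


def _component_split(c: Component, indices: list[int]) -> list[Component]:
    """Connected components of the subgraph of ``c`` induced on ``indices``."""
    sub = c.induced(indices)
    adj = sub.adjacency_lists()
    seen = [False] * sub.n
    parts: list[Component] = []
    for s in range(sub.n):
        if seen[s]:
            continue
        queue = [s]
        seen[s] = True
        block = []
        while queue:
            u = queue.pop(0)
            block.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    queue.append(v)
        parts.append(sub.induced(block))
    parts.sort(key=lambda p: p.vertex_ids[0])
    return parts


def prune_trees(
    c: Component, n_species_total: int
) -> tuple[Component | None, list[str]]:
    """Iteratively strip degree-1 vertices (reduce to the 2-core).

    Tree-like protrusions usually stem from spurious reciprocal hits, so
    they are removed before any eigencomputation. The 2-core is unique, so
    removal order is irrelevant. In a two-species analysis nothing is
    pruned: with only two species every correct group is a tree (a single
    edge or a small star) and there is no third species to corroborate it.
    Returns (core or None if everything was removed, removed ids).
    """
    if n_species_total == 2:
        return c, []
    adj = [set(nbrs) for nbrs in c.adjacency_lists()]
    alive = [True] * c.n
    stack = [i for i in range(c.n) if len(adj[i]) <= 1]
    while stack:
        i = stack.pop()
        if not alive[i]:
            continue
        alive[i] = False
        for j in adj[i]:
            adj[j].discard(i)
            if alive[j] and len(adj[j]) == 1:
                stack.append(j)
        adj[i].clear()
    keep = [i for i in range(c.n) if alive[i]]
    removed = [c.vertex_ids[i] for i in range(c.n) if not alive[i]]
    if not keep:
        return None, removed
    return c.induced(keep), removed


def _dense_alpha2(L: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(L)
    return float(vals[1]), vecs[:, 1]


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    for x in v:
        if abs(x) > ZERO_TOL:
            return v if x > 0 else -v
    return v


def algebraic_connectivity(
    c: Component,
    tol: float = 1e-9,
    max_iter: int = 10000,
    seed: int = 42,
    method: str = "auto",
) -> SpectralResult:
    """Compute alpha_2 and the Fiedler vector of a connected component.

    The iterative path runs power iteration on M = 2n*I - L with the
    trivial all-ones eigenvector projected out at every step: eigenvalues of
    M are 2n - lambda_i, and 2n exceeds the largest Laplacian eigenvalue
    (lambda_max <= n), so the dominant non-trivial direction of M is the
    Fiedler vector and alpha_2 = 2n - mu. Convergence is declared when the
    eigenpair residual ||M v - mu v|| drops below 10 * tol * |mu| (for a
    symmetric matrix the eigenvalue error is bounded by the residual norm,
    so this controls the accuracy of alpha_2 directly, which a
    successive-difference test does not when the spectral gap is small).

    ``method``: "auto" uses a dense eigendecomposition for n <= 64 and the
    power iteration above for larger components; "dense" and "iterative"
    force one path. Non-convergence of the iteration falls back to the
    dense solver. The Fiedler vector is unit norm with its first
    nonzero entry positive; ``normalized_conn`` is alpha_2 / n.
    """
    n = c.n
    if n < 2:
        raise ValueError("connectivity undefined for n < 2")
    if not _is_connected(c):
        raise ValueError("component is disconnected; split it first")
    L = c.laplacian()
    use_dense = method == "dense" or (method == "auto" and n <= 64)
    alpha2 = None
    fiedler = None
    if not use_dense:
        est = _power_iteration(L, n, tol, max_iter, seed)
        if est is not None:
            alpha2, fiedler = est
    if alpha2 is None:
        alpha2, fiedler = _dense_alpha2(L.toarray())
    fiedler = _sign_normalize(np.asarray(fiedler, dtype=float))
    nrm = np.linalg.norm(fiedler)
    if nrm > 0:
        fiedler = fiedler / nrm
    alpha2 = max(float(alpha2), 0.0)
    return SpectralResult(
        alpha2=alpha2,
        normalized_conn=alpha2 / n,
        fiedler=fiedler,
    )


def _power_iteration(
    L: sp.csr_matrix, n: int, tol: float, max_iter: int, seed: int
) -> tuple[float, np.ndarray] | None:
    """Deflated power iteration for the Fiedler pair; None on non-convergence."""
    shift = 2.0 * n
    rng = np.random.default_rng(seed)
    ones = np.full(n, 1.0 / np.sqrt(n))
    v = rng.standard_normal(n)
    v -= ones * (ones @ v)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:  # astronomically unlikely; reseed deterministically
        v = np.arange(n, dtype=float)
        v -= ones * (ones @ v)
        nrm = np.linalg.norm(v)
    v /= nrm
    for _ in range(max_iter):
        w = shift * v - L @ v
        w -= ones * (ones @ w)
        mu = float(v @ w)
        if np.linalg.norm(w - mu * v) <= 10.0 * tol * abs(mu):
            return shift - mu, v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            return None
        v = w / nrm
    return None


def _is_connected(c: Component) -> bool:
    if c.n == 0:
        return False
    adj = c.adjacency_lists()
    seen = [False] * c.n
    queue = [0]
    seen[0] = True
    count = 1
    while queue:
        u = queue.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                count += 1
                queue.append(v)
    return count == c.n


def fiedler_split(
    c: Component, s: SpectralResult, z: float = ZERO_TOL
) -> tuple[list[str], list[str]]:
    """Bipartition a component by the sign pattern of its Fiedler vector.

    Entries > z go to the positive part, entries < -z to the negative part;
    numerically-zero entries join the positive part. Both parts are
    non-empty for any genuine Fiedler vector (it is orthogonal to the
    all-ones vector); if rounding ever collapses one side, a median split
    of the entry values is used instead. The parts need not be internally
    connected — the caller re-extracts connected components.
    """
    x = s.fiedler
    pos = [i for i in range(c.n) if x[i] >= -z]
    neg = [i for i in range(c.n) if x[i] < -z]
    if not pos or not neg:
        order = sorted(range(c.n), key=lambda i: (x[i], i))
        half = c.n // 2
        neg = order[:half]
        pos = order[half:]
    return (
        [c.vertex_ids[i] for i in sorted(pos)],
        [c.vertex_ids[i] for i in sorted(neg)],
    )


def _emit(c: Component, conn: float) -> OrthoGroup:
    members: dict[str, list[str]] = {}
    for pid, spec in zip(c.vertex_ids, c.species_of):
        members.setdefault(spec, []).append(pid)
    for ids in members.values():
        ids.sort()
    return OrthoGroup(members=members, conn=conn)


def decompose(
    c: Component,
    p: FilterParams,
    n_species_total: int,
    tol: float = 1e-9,
    max_iter: int = 10000,
    seed: int = 42,
    removed_log: list[str] | None = None,
) -> list[OrthoGroup]:
    """Recursively split a connected component into (co-)ortholog groups.

    Per recursion level: prune tree-like parts (unless the whole analysis
    covers only two species); discard cores spanning fewer than two species
    or vertices; accept a core whose normalized algebraic connectivity
    reaches the threshold as one group; otherwise split along the Fiedler
    sign pattern and recurse into the connected components of each side.
    Every split strictly shrinks the part, so the recursion is finite.
    ``removed_log`` (optional) collects ids of pruned/dropped vertices.
    """
    out: list[OrthoGroup] = []
    stack: list[Component] = [c]
    while stack:
        cur = stack.pop()
        core, removed = prune_trees(cur, n_species_total)
        if removed_log is not None:
            removed_log.extend(removed)
        if core is None or core.n < 2 or core.n_species < 2:
            if removed_log is not None and core is not None:
                removed_log.extend(core.vertex_ids)
            continue
        res = algebraic_connectivity(
            core, tol=tol, max_iter=max_iter, seed=seed
        )
        if res.normalized_conn >= p.conn_threshold:
            out.append(_emit(core, res.normalized_conn))
            continue
        pos_ids, neg_ids = fiedler_split(core, res)
        index = {pid: i for i, pid in enumerate(core.vertex_ids)}
        for side in (pos_ids, neg_ids):
            idx = [index[pid] for pid in side]
            stack.extend(_component_split(core, idx))
    out.sort(key=lambda grp: grp.sort_key())
    return out
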