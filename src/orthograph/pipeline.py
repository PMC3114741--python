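"""End-to-end orchestration: job planning, filtering, graph, clustering, reports.

The pipeline never executes a similarity-search program. It plans the list
of species-pair searches, consumes their precomputed tabular results from a
cache directory (files named ``<query>__vs__<subject>.tsv``), builds the
adaptive reciprocal-best-hit graph, decomposes every connected component
independently, and writes the group table plus a run summary. Because each
species pair is searched against that species' own database, pair files are
independent: adding or removing a species never changes the others' scores,
which is what makes the cache sound.
"""

from __future__ import annotations

import sys
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .ortho_graph import DirectedArcSet, OrthologyGraph, symmetrize, write_edges_tsv
from .similarity_io import (
    FilterParams,
    InputError,
    Protein,
    filter_hits,
    parse_hit_table,
    read_fasta,
)
from .spectral import Component, OrthoGroup, connected_components, decompose


class MissingHitFilesError(InputError):
    """Raised when required species-pair hit tables are absent."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(
            "missing hit files for %d species pair(s):\n  %s"
            % (len(missing), "\n  ".join(missing))
        )


@dataclass
class ProjectConfig:
    """Everything needed for one run."""

    species_files: list[tuple[str, Path]]
    hits_dir: Path
    params: FilterParams = field(default_factory=FilterParams)
    threads: int = 1
    seed: int = 42
    output_prefix: str = "orthograph"
    write_edges: bool = False
    write_components: bool = False
    quiet: bool = True

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.species_files]
        if len(labels) < 2:
            raise InputError("at least two species are required")
        if len(set(labels)) != len(labels):
            raise InputError(f"duplicate species labels in {labels}")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.species_files]


@dataclass(frozen=True)
class PairJob:
    query_species: str
    subject_species: str
    path: Path
    cached: bool


@dataclass
class JobList:
    pairs: list[PairJob]

    @property
    def pending(self) -> list[PairJob]:
        return [p for p in self.pairs if not p.cached]


def hit_table_path(hits_dir: Path, query: str, subject: str) -> Path:
    return Path(hits_dir) / f"{query}__vs__{subject}.tsv"


def plan_jobs(cfg: ProjectConfig) -> JobList:
    """All ordered cross-species search jobs, flagged cached when the pair's
    hit table already exists (self-searches are never planned)."""
    pairs = []
    for a in cfg.labels:
        for b in cfg.labels:
            if a == b:
                continue
            path = hit_table_path(cfg.hits_dir, a, b)
            pairs.append(
                PairJob(
                    query_species=a,
                    subject_species=b,
                    path=path,
                    cached=path.exists(),
                )
            )
    return JobList(pairs=pairs)


def load_proteomes(cfg: ProjectConfig) -> dict[str, Protein]:
    """Read all species FASTA files; protein ids must be globally unique."""
    proteins: dict[str, Protein] = {}
    for label, path in cfg.species_files:
        for p in read_fasta(path, label):
            if p.id in proteins:
                raise InputError(
                    f"duplicate id {p.id!r}: appears in species "
                    f"{proteins[p.id].species!r} and {label!r}"
                )
            proteins[p.id] = p
    return proteins


@dataclass
class RunSummary:
    n_proteins: int
    n_species: int
    n_arcs: int
    n_edges: int
    n_components: int
    n_groups: int
    pruned_ids: list[str] = field(default_factory=list)

    def format_text(self) -> str:
        lines = [
            f"proteins\t{self.n_proteins}",
            f"species\t{self.n_species}",
            f"retained_arcs\t{self.n_arcs}",
            f"reciprocal_edges\t{self.n_edges}",
            f"connected_components\t{self.n_components}",
            f"groups\t{self.n_groups}",
            f"pruned_vertices\t{len(self.pruned_ids)}",
        ]
        return "\n".join(lines) + "\n"


def _log(cfg: ProjectConfig, msg: str) -> None:
    if not cfg.quiet:
        print(f"[orthograph] {msg}", file=sys.stderr)


def build_graph(cfg: ProjectConfig, proteins: dict[str, Protein]) -> tuple[
    DirectedArcSet, OrthologyGraph
]:
    """Parse, filter and reduce every species-pair table; symmetrize."""
    jobs = plan_jobs(cfg)
    missing = [str(j.path) for j in jobs.pairs if not j.path.exists()]
    if missing:
        raise MissingHitFilesError(missing)
    lengths = {pid: p.length for pid, p in proteins.items()}
    by_species: dict[str, dict[str, int]] = {}
    for pid, p in proteins.items():
        by_species.setdefault(p.species, {})[pid] = p.length
    arcset = DirectedArcSet()
    for pid, p in proteins.items():
        arcset.species_of[pid] = p.species
    for job in jobs.pairs:
        hits = parse_hit_table(
            job.path,
            job.query_species,
            job.subject_species,
            by_species[job.query_species],
        )
        kept = filter_hits(hits, lengths, cfg.params)
        arcset.ingest(kept, cfg.params.sim_factor_f)
    graph = symmetrize(arcset)
    return arcset, graph


def cluster_graph(
    cfg: ProjectConfig, graph: OrthologyGraph
) -> tuple[list[OrthoGroup], list[Component], list[str]]:
    """Decompose every connected component; deterministic canonical merge.

    Components are independent, so with ``threads > 1`` they are processed
    concurrently; results are merged and re-sorted canonically, making the
    output independent of scheduling.
    """
    comps = connected_components(graph)
    n_species_total = len(cfg.labels)
    removed_logs: list[list[str]] = [[] for _ in comps]

    def work(k: int) -> list[OrthoGroup]:
        return decompose(
            comps[k],
            cfg.params,
            n_species_total,
            seed=cfg.seed,
            removed_log=removed_logs[k],
        )

    if cfg.threads > 1 and len(comps) > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            per_comp = list(pool.map(work, range(len(comps))))
    else:
        per_comp = [work(k) for k in range(len(comps))]
    groups = [g for sub in per_comp for g in sub]
    groups.sort(key=lambda g: g.sort_key())
    removed = sorted(pid for log in removed_logs for pid in log)
    return groups, comps, removed


def run_project(cfg: ProjectConfig) -> tuple[list[OrthoGroup], RunSummary]:
    """Execute the full pipeline and write all output files."""
    _log(cfg, f"reading {len(cfg.species_files)} proteomes")
    proteins = load_proteomes(cfg)
    _log(cfg, f"{len(proteins)} proteins loaded")
    arcset, graph = build_graph(cfg, proteins)
    _log(
        cfg,
        f"{arcset.n_arcs} retained arcs, {graph.n_edges} reciprocal edges",
    )
    groups, comps, removed = cluster_graph(cfg, graph)
    _log(cfg, f"{len(comps)} components -> {len(groups)} groups")
    summary = RunSummary(
        n_proteins=len(proteins),
        n_species=len(cfg.labels),
        n_arcs=arcset.n_arcs,
        n_edges=graph.n_edges,
        n_components=len(comps),
        n_groups=len(groups),
        pruned_ids=removed,
    )
    prefix = Path(cfg.output_prefix)
    if prefix.parent != Path("."):
        prefix.parent.mkdir(parents=True, exist_ok=True)
    write_groups_tsv(groups, cfg.labels, f"{prefix}.groups.tsv")
    with open(f"{prefix}.summary.txt", "w", encoding="utf-8") as fh:
        fh.write(summary.format_text())
    if cfg.write_edges:
        write_edges_tsv(graph, f"{prefix}.edges.tsv")
    if cfg.write_components:
        write_components_tsv(comps, cfg, f"{prefix}.components.tsv")
    return groups, summary


def format_conn(conn: float) -> str:
    """Three decimals, half-up rounding."""
    return str(
        Decimal(repr(conn)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    )


def write_groups_tsv(
    groups: list[OrthoGroup], species_labels: list[str], path: str | Path
) -> None:
    """Write the group table.

    Header: ``# Species\\tGenes\\tAlg.-Conn.`` followed by one column per
    species label; each row carries the species count, protein count,
    normalized connectivity (3 decimals) and per-species comma-separated
    sorted gene lists (``*`` where the species is absent).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# Species\tGenes\tAlg.-Conn.\t" + "\t".join(species_labels))
        fh.write("\n")
        for g in groups:
            cells = [str(g.n_species), str(g.n_proteins), format_conn(g.conn)]
            for label in species_labels:
                ids = g.members.get(label)
                cells.append(",".join(sorted(ids)) if ids else "*")
            fh.write("\t".join(cells) + "\n")


def parse_groups_tsv(path: str | Path) -> tuple[list[OrthoGroup], list[str]]:
    """Read a group table back; returns (groups, species labels)."""
    groups: list[OrthoGroup] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[:3] != ["# Species", "Genes", "Alg.-Conn."]:
            raise InputError(f"{path}: unrecognized group-table header")
        labels = cols[3:]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 3 + len(labels):
                raise InputError(f"{path}:{lineno}: wrong column count")
            conn = float(cells[2])
            members = {
                lab: cell.split(",")
                for lab, cell in zip(labels, cells[3:])
                if cell != "*"
            }
            groups.append(OrthoGroup(members=members, conn=conn))
    return groups, labels


def write_components_tsv(
    comps: list[Component], cfg: ProjectConfig, path: str | Path
) -> None:
    """Debug dump: per raw component its size, species span and connectivity."""
    from .spectral import algebraic_connectivity

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# component\tn\tn_species\tnormalized_conn\n")
        for k, c in enumerate(comps):
            res = algebraic_connectivity(c, seed=cfg.seed)
            fh.write(
                f"{k}\t{c.n}\t{c.n_species}\t{format_conn(res.normalized_conn)}\n"
            )


def coverage_census(
    groups: list[OrthoGroup], n_species_total: int
) -> list[tuple[int, int]]:
    """Cumulative presence census: for x = N..2, how many groups span >= x
    species. A group present in x species is also counted at every x' < x,
    so the census is non-decreasing toward smaller x."""
    out = []
    for x in range(n_species_total, 1, -1):
        out.append((x, sum(1 for g in groups if g.n_species >= x)))
    return out
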