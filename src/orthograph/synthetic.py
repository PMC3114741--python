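"""Planted-truth fixtures: species, proteins, pairwise hit tables, oracle.

The generator emulates the regimes the method is designed for: an idealized
dataset (one ortholog per species, unique best hits), in-paralog/co-ortholog
duplication, divergent co-ortholog pairs, and rare spurious cross-family
hits. It emits exactly the files the pipeline consumes (per-species FASTA,
per-ordered-pair 12-column hit tables) plus the ground-truth family
partition, so end-to-end recovery can be scored.

Score model. Same-family cross-species protein pairs receive reciprocal
hits with bit score ~ Normal(ortho_bits_mean, ortho_bits_sd), drawn once
per pair (both directions report the same alignment). When a family is
duplicated in a species, the two copies are subfunctionalized paralogs:
copy 0 and copy 1 of two *duplicated* species pair up like-with-like, and
arcs between unlike copies are divergent co-ortholog arcs, scaled by
``co_ortho_penalty``. A species that retained a single copy is an
unbiased ortholog of both copies elsewhere, so its arcs are not penalized.
E-values are a deterministic monotone transform of the bit score,
10**(-bits/10): only ordering and thresholds matter downstream, so a
realistic E-value model would add nothing but nondeterminism.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pipeline import ProjectConfig, hit_table_path
from .similarity_io import FilterParams, write_fasta
from .spectral import Component, OrthoGroup

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_LEN = 100


@dataclass
class PlantSpec:
    """Parameters of one planted dataset."""

    n_species: int = 3
    n_families: int = 5
    presence_prob: float = 1.0
    dup_prob: float = 0.0
    ortho_bits_mean: float = 300.0
    ortho_bits_sd: float = 15.0
    co_ortho_penalty: float = 0.9
    spurious_prob: float = 0.0
    spurious_bits_mean: float = 60.0
    spurious_bits_sd: float = 8.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_families < 1:
            raise ValueError("need at least 1 family")
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0, 1]")
        if not 0 <= self.dup_prob < 1:
            raise ValueError("dup_prob must be in [0, 1)")
        if not 0 <= self.spurious_prob < 1:
            raise ValueError("spurious_prob must be in [0, 1)")
        if not 0 <= self.co_ortho_penalty <= 1:
            raise ValueError("co_ortho_penalty must be in [0, 1]")

    @property
    def separable(self) -> bool:
        """True when planted and spurious score bands are 3 sigma apart."""
        return (
            self.spurious_bits_mean + 3 * self.spurious_bits_sd
            < self.ortho_bits_mean - 3 * self.ortho_bits_sd
        )


@dataclass
class GroundTruth:
    """The planted family partition."""

    family_of: dict[str, str]
    families: dict[str, dict[str, list[str]]]

    def families_with_min_species(self, k: int = 2) -> dict[str, set[str]]:
        """Member-id sets of families present in at least k species."""
        out = {}
        for fam, per_species in self.families.items():
            present = {s for s, ids in per_species.items() if ids}
            if len(present) >= k:
                out[fam] = {
                    pid for ids in per_species.values() for pid in ids
                }
        return out


@dataclass
class _Member:
    pid: str
    species: str
    family: str
    copy: int
    has_sibling: bool


def _species_labels(n: int) -> list[str]:
    return [f"s{i:02d}" for i in range(1, n + 1)]


def _dummy_seq(rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_RESIDUES), size=_PROTEIN_LEN)
    return "".join(_RESIDUES[i] for i in idx)


def generate(
    spec: PlantSpec, out_dir: str | Path
) -> tuple[list[tuple[str, Path]], Path, GroundTruth]:
    """Write FASTA files, hit tables and truth.json for one planted dataset.

    Returns (species_files, hits_dir, truth). Fully deterministic for a
    given spec (including the seed).
    """
    out_dir = Path(out_dir)
    hits_dir = out_dir / "hits"
    out_dir.mkdir(parents=True, exist_ok=True)
    hits_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    labels = _species_labels(spec.n_species)

    # --- plant membership -------------------------------------------------
    members: list[_Member] = []
    families: dict[str, dict[str, list[str]]] = {}
    for fi in range(spec.n_families):
        fam = f"fam{fi:04d}"
        per_species: dict[str, list[str]] = {}
        for s in labels:
            present = rng.random() < spec.presence_prob
            if not present:
                continue
            n_copies = 2 if rng.random() < spec.dup_prob else 1
            ids = []
            for c in range(n_copies):
                suffix = "" if c == 0 else "b"
                pid = f"{s}_g{fi:04d}{suffix}"
                ids.append(pid)
                members.append(
                    _Member(
                        pid=pid,
                        species=s,
                        family=fam,
                        copy=c,
                        has_sibling=n_copies == 2,
                    )
                )
            per_species[s] = ids
        families[fam] = per_species
    family_of = {m.pid: m.family for m in members}
    truth = GroundTruth(family_of=family_of, families=families)

    # --- FASTA ------------------------------------------------------------
    species_files: list[tuple[str, Path]] = []
    by_species: dict[str, list[_Member]] = {s: [] for s in labels}
    for m in members:
        by_species[m.species].append(m)
    for s in labels:
        path = out_dir / f"{s}.fasta"
        write_fasta(
            path, [(m.pid, _dummy_seq(rng)) for m in by_species[s]]
        )
        species_files.append((s, path))

    # --- same-family reciprocal hits (one draw per unordered pair) --------
    rows: dict[tuple[str, str], list[str]] = {
        (a, b): [] for a in labels for b in labels if a != b
    }
    by_family: dict[str, list[_Member]] = {}
    for m in members:
        by_family.setdefault(m.family, []).append(m)
    for fam in sorted(by_family):
        fam_members = by_family[fam]
        for x, y in itertools.combinations(fam_members, 2):
            if x.species == y.species:
                continue
            base = spec.ortho_bits_mean
            divergent = (
                x.has_sibling and y.has_sibling and x.copy != y.copy
            )
            bits = float(rng.normal(base, spec.ortho_bits_sd))
            if divergent:
                bits *= spec.co_ortho_penalty
            bits = max(bits, 35.0)
            pident = float(rng.uniform(80.0, 95.0))
            row = _format_row(
                bits, pident, q_start=1, q_end=_PROTEIN_LEN
            )
            rows[(x.species, y.species)].append(
                f"{x.pid}\t{y.pid}\t{row}"
            )
            rows[(y.species, x.species)].append(
                f"{y.pid}\t{x.pid}\t{row}"
            )

    # --- spurious cross-family arcs (directed, independent) ---------------
    if spec.spurious_prob > 0:
        for a, b in sorted(rows):
            for x in by_species[a]:
                for y in by_species[b]:
                    if x.family == y.family:
                        continue
                    if rng.random() >= spec.spurious_prob:
                        continue
                    bits = max(
                        float(
                            rng.normal(
                                spec.spurious_bits_mean,
                                spec.spurious_bits_sd,
                            )
                        ),
                        20.0,
                    )
                    pident = float(rng.uniform(25.0, 35.0))
                    row = _format_row(bits, pident, q_start=1, q_end=60)
                    rows[(a, b)].append(f"{x.pid}\t{y.pid}\t{row}")

    for (a, b), lines in rows.items():
        with open(
            hit_table_path(hits_dir, a, b), "w", encoding="utf-8"
        ) as fh:
            for line in sorted(lines):
                fh.write(line + "\n")

    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"family_of": truth.family_of, "families": truth.families},
            fh,
            indent=1,
            sort_keys=True,
        )
    return species_files, hits_dir, truth


def _format_row(
    bits: float, pident: float, q_start: int, q_end: int
) -> str:
    """Columns 3..12 of a tabular row (qseqid/sseqid are prepended)."""
    span = q_end - q_start + 1
    evalue = min(max(10.0 ** (-bits / 10.0), 1e-180), 1.0)
    return (
        f"{pident:.1f}\t{span}\t0\t0\t{q_start}\t{q_end}\t1\t{span}"
        f"\t{evalue:.3e}\t{bits:.1f}"
    )


def generate_project(
    spec: PlantSpec,
    out_dir: str | Path,
    params: FilterParams | None = None,
    threads: int = 1,
    output_prefix: str | None = None,
) -> tuple[ProjectConfig, GroundTruth]:
    """Generate a dataset and wrap it into a ready-to-run ProjectConfig."""
    out_dir = Path(out_dir)
    species_files, hits_dir, truth = generate(spec, out_dir)
    cfg = ProjectConfig(
        species_files=species_files,
        hits_dir=hits_dir,
        params=params or FilterParams(),
        threads=threads,
        seed=spec.seed,
        output_prefix=output_prefix or str(out_dir / "result"),
    )
    return cfg, truth


# ---------------------------------------------------------------------------
# Brute-force minimum edge-edit decomposition (tiny-scale test oracle)
# ---------------------------------------------------------------------------

def _set_partitions(items: list[int]):
    """All partitions of ``items`` into non-empty blocks (restricted growth)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def edit_oracle(
    c: Component,
) -> tuple[int, list[frozenset[str]], bool]:
    """Exhaustive minimum edge-edit decomposition into complete multipartite
    blocks (classes = species).

    Enumerates every partition of the vertex set; the cost of a partition is
    the number of present cross-block edges (deletions) plus the number of
    absent within-block cross-species pairs (insertions), scoring each block
    against the complete multipartite graph on its species classes. Returns
    (minimum cost, one optimal partition as id sets, optimum unique?).
    Exponential — restricted to n <= 8.
    """
    if c.n > 8:
        raise ValueError("edit_oracle is exhaustive; n must be <= 8")
    edge_set = {(min(i, j), max(i, j)) for i, j in c.edges}
    best_cost: int | None = None
    best_parts: list[list[list[int]]] = []
    for part in _set_partitions(list(range(c.n))):
        block_of = {}
        for bi, block in enumerate(part):
            for v in block:
                block_of[v] = bi
        cost = 0
        # deletions: edges across blocks
        for i, j in edge_set:
            if block_of[i] != block_of[j]:
                cost += 1
        # insertions: absent cross-species pairs within a block
        for block in part:
            for i, j in itertools.combinations(sorted(block), 2):
                if c.species_of[i] == c.species_of[j]:
                    continue
                if (i, j) not in edge_set:
                    cost += 1
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_parts = [part]
        elif cost == best_cost:
            best_parts.append(part)
    assert best_cost is not None
    canon = {
        frozenset(
            frozenset(c.vertex_ids[v] for v in block) for block in part
        )
        for part in best_parts
    }
    blocks = sorted(
        (frozenset(c.vertex_ids[v] for v in block) for block in best_parts[0]),
        key=lambda s: min(s),
    )
    return best_cost, blocks, len(canon) == 1


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def score_against_truth(
    groups: list[OrthoGroup], truth: GroundTruth
) -> tuple[float, float]:
    """Compare emitted groups with the planted families.

    Returns (exact_match_fraction, adjusted_rand). The exact-match fraction
    counts planted families (restricted to those present in >= 2 species)
    whose full member set equals some emitted group. The adjusted Rand
    index is computed on the protein partition, with proteins missing from
    the output treated as singletons.
    """
    from sklearn.metrics import adjusted_rand_score

    eligible = truth.families_with_min_species(2)
    emitted_sets = {frozenset(g.all_ids()) for g in groups}
    if eligible:
        exact = sum(
            1 for fam_ids in eligible.values()
            if frozenset(fam_ids) in emitted_sets
        ) / len(eligible)
    else:
        exact = 1.0 if not groups else 0.0

    all_ids = sorted(truth.family_of)
    true_labels = [truth.family_of[pid] for pid in all_ids]
    pred: dict[str, str] = {}
    for k, g in enumerate(groups):
        for pid in g.all_ids():
            pred[pid] = f"grp{k}"
    pred_labels = [
        pred.get(pid, f"single::{pid}") for pid in all_ids
    ]
    ari = float(adjusted_rand_score(true_labels, pred_labels))
    return exact, ari


def plant_spec_to_yaml_dict(spec: PlantSpec) -> dict:
    return asdict(spec)
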