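"""Sequence and similarity-table input.

Reads per-species FASTA files (for protein ids and lengths only — residues
are never interpreted) and 12-column BLAST tabular hit files, and applies the
per-hit quality filters (E-value, percent identity, query coverage) that
precede graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class InputError(ValueError):
    """Fatal problem with user-supplied input (bad FASTA, malformed table)."""


@dataclass(frozen=True)
class Protein:
    """A protein known only by its id, source species and length in residues."""

    id: str
    species: str
    length: int

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("protein id must be non-empty")
        if self.length < 1:
            raise InputError(f"protein {self.id!r} has non-positive length")


@dataclass(frozen=True)
class Hit:
    """One directed similarity record query -> subject between two species.

    Coordinates are 1-based inclusive on the query, as printed by BLAST
    tabular output.
    """

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    pct_identity: float
    q_start: int
    q_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.query_species == self.subject_species:
            raise InputError(
                f"self-species hit {self.query_id}->{self.subject_id} "
                f"within {self.query_species}"
            )
        if self.q_start < 1 or self.q_end < self.q_start:
            raise InputError(
                f"hit {self.query_id}->{self.subject_id}: bad query "
                f"coordinates {self.q_start}..{self.q_end}"
            )


@dataclass(frozen=True)
class FilterParams:
    """Thresholds controlling hit filtering and graph construction.

    e_cutoff
        Maximum E-value for a hit to enter the graph (inclusive).
    min_identity_pct
        Minimum percent identity (inclusive), on the 0-100 scale.
    min_coverage_frac
        Minimum fraction of the query protein covered by the aligned span
        (inclusive), in (0, 1].
    sim_factor_f
        Adaptive similarity factor: per query and target species, all hits
        with bit score >= f * best bit score are retained. f = 1 reduces to
        the classical reciprocal-best-hit rule.
    conn_threshold
        Normalized algebraic connectivity above which a connected component
        is accepted as a single (co-)ortholog group.
    """

    e_cutoff: float = 1e-10
    min_identity_pct: float = 25.0
    min_coverage_frac: float = 0.5
    sim_factor_f: float = 0.95
    conn_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.sim_factor_f <= 1:
            raise ValueError("sim_factor_f must be in (0, 1]")
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")
        if not 0 < self.min_coverage_frac <= 1:
            raise ValueError("min_coverage_frac must be in (0, 1]")
        if self.conn_threshold < 0:
            raise ValueError("conn_threshold must be >= 0")


def read_fasta(path: str | Path, species_label: str) -> list[Protein]:
    """Read one species' FASTA file into ``Protein`` records.

    The protein id is the first whitespace-delimited token of the header;
    length is the residue count. Duplicate ids within the file and empty
    records are fatal.
    """
    path = Path(path)
    proteins: list[Protein] = []
    seen: dict[str, int] = {}
    for i, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        pid = record.id
        if not pid:
            raise InputError(f"{path}: record {i} has an empty id")
        if pid in seen:
            raise InputError(
                f"duplicate id {pid!r} in {path} "
                f"(records {seen[pid]} and {i})"
            )
        seen[pid] = i
        length = len(str(record.seq).replace(" ", "").replace("\t", ""))
        if length == 0:
            raise InputError(f"{path}: record {pid!r} has an empty sequence")
        proteins.append(Protein(id=pid, species=species_label, length=length))
    if not proteins:
        raise InputError(f"{path}: no FASTA records found")
    return proteins


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA. Used by fixtures and round-trips."""
    out = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records
    ]
    SeqIO.write(out, str(path), "fasta")


#: column layout of the accepted tabular dialect (BLAST -outfmt 6)
TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def parse_hit_table(
    path: str | Path,
    query_species: str,
    subject_species: str,
    query_lengths: Mapping[str, int],
) -> list[Hit]:
    """Parse a 12-column tab-separated similarity table into ``Hit`` records.

    The dialect is fixed: exactly the 12 standard tabular columns. Rows with
    a different column count, non-numeric fields, or query ids missing from
    ``query_lengths`` raise :class:`InputError` with the line number.
    """
    path = Path(path)
    hits: list[Hit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise InputError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                pident = float(fields[2])
                q_start = int(fields[6])
                q_end = int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: non-numeric field ({exc})"
                ) from None
            qid, sid = fields[0], fields[1]
            if qid not in query_lengths:
                raise InputError(
                    f"{path}:{lineno}: unknown query id {qid!r} "
                    f"for species {query_species!r}"
                )
            if q_end > query_lengths[qid]:
                raise InputError(
                    f"{path}:{lineno}: alignment end {q_end} exceeds "
                    f"length {query_lengths[qid]} of query {qid!r}"
                )
            hits.append(
                Hit(
                    query_id=qid,
                    subject_id=sid,
                    query_species=query_species,
                    subject_species=subject_species,
                    pct_identity=pident,
                    q_start=q_start,
                    q_end=q_end,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def query_coverage(h: Hit, query_length: int) -> float:
    """Fraction of the query protein covered by the aligned span."""
    return (h.q_end - h.q_start + 1) / query_length


def filter_hits(
    hits: Iterable[Hit],
    lengths: Mapping[str, int],
    p: FilterParams,
) -> list[Hit]:
    """Apply the per-hit quality filters and per-pair deduplication.

    A hit survives iff evalue <= e_cutoff, identity >= min_identity_pct and
    query coverage >= min_coverage_frac (all boundaries inclusive). Among
    several surviving hits for the same ordered (query, subject) pair only
    the highest-bitscore one is kept (ties broken by lowest E-value, then
    input order), so the downstream graph sees at most one arc per pair.
    Output is sorted by query id, then descending bit score, then subject id.
    """
    best: dict[tuple[str, str], tuple[float, float, int, Hit]] = {}
    for idx, h in enumerate(hits):
        if h.evalue > p.e_cutoff:
            continue
        if h.pct_identity < p.min_identity_pct:
            continue
        if query_coverage(h, lengths[h.query_id]) < p.min_coverage_frac:
            continue
        key = (h.query_id, h.subject_id)
        cand = (-h.bitscore, h.evalue, idx, h)
        if key not in best or cand[:3] < best[key][:3]:
            best[key] = cand
    kept = [entry[3] for entry in best.values()]
    kept.sort(key=lambda h: (h.query_id, -h.bitscore, h.subject_id))
    return kept
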