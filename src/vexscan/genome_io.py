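"""Genome FASTA input, overlapping chunking, and chunk-result merging.

Whole-genome assemblies arrive as large multi-record FASTA files of
contigs/scaffolds/chromosomes. Contigs are split into overlapping chunks
(defaults: 20 kbp chunks, 1 kbp overlap) so scanning is embarrassingly
parallel; because the overlap exceeds the maximum candidate span, every
candidate lies wholly inside at least one chunk, and merging with
duplicate removal makes the chunked scan exactly equivalent to scanning
the whole contig at once.

Coordinates are 0-based half-open throughout. FASTA headers are truncated
at the first whitespace for the contig id.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .exon_scan import CandidateExon, group_overlaps, scan_sequence

logger = logging.getLogger(__name__)

_STANDARD = set("ACGTN")


@dataclass(frozen=True)
class ContigRecord:
    """One contig/scaffold/chromosome from an assembly FASTA."""

    contig_id: str
    sequence: str  # upper-cased IUPAC DNA
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty contig sequence")
        if not self.contig_id:
            raise ValueError("empty contig id")


@dataclass(frozen=True)
class Chunk:
    """A slice of a contig; ``chunk_start`` is its 0-based contig offset."""

    contig_id: str
    chunk_start: int
    sequence: str


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> Iterator[ContigRecord]:
    """Stream contigs from a (possibly gzipped) FASTA file in file order.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are preserved
    but counted and reported in a warning. Duplicate ids within one file
    violate the contig-record invariant and raise. An empty file yields an
    empty stream with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: set[str] = set()
    n_records = 0
    n_nonstandard = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if rec.id in seen:
                raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
            seen.add(rec.id)
            n_records += 1
            extra = set(seq) - _STANDARD
            if extra:
                n_nonstandard += sum(seq.count(c) for c in extra)
            yield ContigRecord(contig_id=rec.id, sequence=seq, source=str(path))
    if n_records == 0:
        logger.warning("no FASTA records in %s", path)
    if n_nonstandard:
        logger.warning("%d non-ACGTN characters in %s", n_nonstandard, path)


def chunk_contig(contig: ContigRecord, chunk_size: int = 20000,
                 overlap: int = 1000) -> list[Chunk]:
    """Split a contig into overlapping chunks.

    Chunk i starts at ``i * (chunk_size - overlap)``; the last chunk may be
    shorter. Every position is covered, and any interval no longer than
    ``overlap`` lies wholly inside at least one chunk.
    """
    if chunk_size <= 0 or overlap <= 0:
        raise ValueError("chunk_size and overlap must be positive")
    if overlap >= chunk_size:
        raise ValueError("overlap must be < chunk_size")
    step = chunk_size - overlap
    n = len(contig.sequence)
    chunks = []
    start = 0
    while start < n:
        chunks.append(Chunk(contig_id=contig.contig_id, chunk_start=start,
                            sequence=contig.sequence[start:start + chunk_size]))
        start += step
    return chunks


def merge_candidates(per_chunk_lists: list[list[CandidateExon]]
                     ) -> list[CandidateExon]:
    """Concatenate chunk results, collapsing duplicates.

    Candidates identical in (contig_id, strand, start, end) — i.e. the same
    interval seen from two overlapping chunks — collapse to one. Output is
    sorted by (contig_id, start).
    """
    seen: dict[tuple, CandidateExon] = {}
    for lst in per_chunk_lists:
        for c in lst:
            key = (c.contig_id, c.strand, c.start, c.end)
            seen.setdefault(key, c)
    return sorted(seen.values(),
                  key=lambda c: (c.contig_id, c.start, c.end, c.strand))


def scan_contig(contig: ContigRecord, chunk_size: int = 20000,
                overlap: int = 1000, min_len: int = 275, max_len: int = 330,
                group: bool = True) -> list[CandidateExon]:
    """Chunked scan of one contig: map over chunks, lift coordinates to the
    contig frame, merge duplicates, and (optionally) assign overlap groups.

    Chunk processing is order-independent and side-effect-free, so results
    do not depend on how chunks are distributed over workers.
    """
    per_chunk = []
    for chunk in chunk_contig(contig, chunk_size, overlap):
        found = scan_sequence(chunk.sequence, contig.contig_id,
                              min_len, max_len)
        per_chunk.append([
            replace(c, start=c.start + chunk.chunk_start,
                    end=c.end + chunk.chunk_start)
            for c in found])
    merged = merge_candidates(per_chunk)
    return group_overlaps(merged) if group else merged


def scan_genome(path: str | Path, chunk_size: int = 20000,
                overlap: int = 1000, min_len: int = 275,
                max_len: int = 330) -> list[CandidateExon]:
    """Scan every contig of a FASTA file; candidates carry absolute
    contig coordinates and per-contig overlap groups."""
    out: list[CandidateExon] = []
    gid_offset = 0
    for contig in read_fasta(path):
        found = scan_contig(contig, chunk_size, overlap, min_len, max_len)
        # keep group ids unique across contigs
        out.extend(replace(c, group_id=c.group_id + gid_offset)
                   for c in found)
        if found:
            gid_offset += max(c.group_id for c in found) + 1
    return out


# -- output writers ----------------------------------------------------

def write_candidate_fasta(path: str | Path, rows: list[tuple[CandidateExon, object]]
                          ) -> None:
    """Write accepted candidates as an amino-acid FASTA.

    Header: ``contig:start-end(strand) locus=<L> score=<combined>``.
    """
    with open(path, "w") as fh:
        for cand, prof in rows:
            locus = prof.assigned_locus
            score = prof.combined[locus]
            fh.write(f">{cand.contig_id}:{cand.start}-{cand.end}"
                     f"({cand.strand}) locus={locus} score={score:.6f}\n")
            fh.write(cand.aa_sequence + "\n")


def write_annotation_tsv(path: str | Path,
                         rows: list[tuple[CandidateExon, object]]) -> None:
    """BED-compatible annotation table: contig, start, end first."""
    header = ["contig_id", "start", "end", "strand", "frame_trim",
              "locus", "score", "mr_score"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for cand, prof in rows:
            locus = prof.assigned_locus
            fh.write("\t".join(map(str, [
                cand.contig_id, cand.start, cand.end, cand.strand,
                cand.frame_trim, locus,
                f"{prof.combined[locus]:.6f}", f"{prof.mr_score:.6f}"])) + "\n")
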