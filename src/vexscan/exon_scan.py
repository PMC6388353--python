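"""Enumeration and filtering of candidate V-exon intervals in DNA.

V-exons sit between a splice-acceptor AG dinucleotide at their 5' end and
the recombination signal sequence (RSS) at their 3' end; the first three
bases of the canonical RSS heptamer CACAGTG — the CAC motif — are conserved
across jawed vertebrates. The scan therefore enumerates *every* interval
bounded by an AG occurrence and a downstream CAC occurrence whose inner
span (exclusive of both motifs) lies in a configurable window, 275-330 bp
by default, on both strands. Intervals are translated in a reading frame
anchored at the 3' (RSS) end — the conserved YYC motif immediately
preceding the RSS fixes the 3' codon boundary — trimming ``len mod 3``
bases at the 5' end. Intervals containing an in-frame stop codon or an
ambiguous base are discarded. Surviving candidates that overlap on the
same strand are grouped into connected components; after classification
each group is resolved to its single best-scoring candidate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

from Bio.Seq import Seq
from intervaltree import IntervalTree

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Locus order used when breaking exact score ties.
_STRAND_ORDER = {"+": 0, "-": 1}


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class MotifInterval:
    """An AG..CAC bounded interval, in forward-contig coordinates.

    ``start`` is the first base after the AG dinucleotide and ``end`` the
    first base of the CAC trinucleotide, both 0-based half-open on the
    forward strand; for ``strand == "-"`` the motifs are read on the
    reverse complement and coordinates mapped back.
    """

    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class CandidateExon:
    """A motif-bounded, length-filtered, in-frame-translated interval."""

    contig_id: str
    strand: str
    start: int  # forward-contig, 0-based half-open, AG/CAC exclusive
    end: int
    nt_sequence: str  # strand-oriented (reverse-complemented for "-")
    frame_trim: int  # bases trimmed at the 5' end to anchor the frame 3'
    aa_sequence: str
    group_id: int = -1

    def __post_init__(self) -> None:
        n = len(self.nt_sequence)
        if n != self.end - self.start:
            raise ValueError("nt_sequence length does not match coordinates")
        if self.frame_trim not in (0, 1, 2):
            raise ValueError("frame_trim must be in {0,1,2}")
        if (n - self.frame_trim) % 3 != 0:
            raise ValueError("trimmed length must be a codon multiple")
        if len(self.aa_sequence) != (n - self.frame_trim) // 3:
            raise ValueError("aa_sequence length inconsistent with trim")
        if "*" in self.aa_sequence:
            raise ValueError("aa_sequence contains a stop symbol")


def _find_all(seq: str, motif: str) -> list[int]:
    """All (overlapping) occurrence start positions of ``motif`` in ``seq``."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _enumerate_one_strand(seq: str, min_len: int, max_len: int
                          ) -> list[tuple[int, int]]:
    """(start, end) inner spans for one strand; linear scan + bisection."""
    starts = [p + 2 for p in _find_all(seq, "AG")]  # first base after AG
    ends = _find_all(seq, "CAC")  # first base of CAC
    out = []
    for e in ends:
        lo = bisect.bisect_left(starts, e - max_len)
        hi = bisect.bisect_right(starts, e - min_len)
        for s in starts[lo:hi]:
            out.append((s, e))
    return out


def enumerate_motif_intervals(seq: str, min_len: int = 275, max_len: int = 330,
                              both_strands: bool = True) -> list[MotifInterval]:
    """Every AG..CAC pair with inner span in [min_len, max_len], inclusive.

    Nested and overlapping pairs are all reported. With ``both_strands``
    the reverse complement is rescanned and hits mapped back to forward
    coordinates.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    out = [MotifInterval(start=s, end=e, strand="+")
           for s, e in _enumerate_one_strand(seq, min_len, max_len)]
    if both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        out += [MotifInterval(start=n - e, end=n - s, strand="-")
                for s, e in _enumerate_one_strand(rc, min_len, max_len)]
    out.sort(key=lambda m: (m.start, m.end, _STRAND_ORDER[m.strand]))
    return out


_VALID_NT = set("ACGT")


def translate_candidates(intervals: list[MotifInterval], seq: str,
                         contig_id: str = "") -> list[CandidateExon]:
    """Translate intervals in the 3'-anchored frame; drop stop-containing
    and ambiguous (non-ACGT) intervals."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for iv in intervals:
        nt = seq[iv.start:iv.end]
        if iv.strand == "-":
            nt = reverse_complement(nt)
        if set(nt) - _VALID_NT:
            continue  # ambiguity codes: cannot translate unambiguously
        trim = len(nt) % 3
        aa = str(Seq(nt[trim:]).translate())
        if "*" in aa:
            continue
        out.append(CandidateExon(
            contig_id=contig_id, strand=iv.strand, start=iv.start, end=iv.end,
            nt_sequence=nt, frame_trim=trim, aa_sequence=aa))
    assert all(0 <= c.start < c.end <= n for c in out)
    return out


def scan_sequence(seq: str, contig_id: str = "", min_len: int = 275,
                  max_len: int = 330, both_strands: bool = True
                  ) -> list[CandidateExon]:
    """Enumerate + translate in one call."""
    if not seq:
        return []
    return translate_candidates(
        enumerate_motif_intervals(seq, min_len, max_len, both_strands),
        seq, contig_id)


def group_overlaps(candidates: list[CandidateExon]) -> list[CandidateExon]:
    """Assign ``group_id`` by transitive overlap closure, per strand.

    Two same-strand candidates share a group iff their half-open intervals
    are connected through a chain of pairwise overlaps (touching intervals
    do not overlap). Implemented with an interval tree plus union-find.
    Group ids are dense, deterministic (ordered by strand then leftmost
    start), and unique across strands.
    """
    if not candidates:
        return []
    contigs = {c.contig_id for c in candidates}
    if len(contigs) > 1:
        raise ValueError("group_overlaps expects candidates from one contig")

    parent = list(range(len(candidates)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for strand in ("+", "-"):
        idxs = [k for k, c in enumerate(candidates) if c.strand == strand]
        if not idxs:
            continue
        tree = IntervalTree()
        for k in idxs:
            tree.addi(candidates[k].start, candidates[k].end, k)
        for k in idxs:
            for hit in tree.overlap(candidates[k].start, candidates[k].end):
                union(k, hit.data)

    # dense deterministic numbering: by (strand, min start in group)
    roots: dict[int, list[int]] = {}
    for k in range(len(candidates)):
        roots.setdefault(find(k), []).append(k)
    ordered = sorted(
        roots.values(),
        key=lambda ks: (_STRAND_ORDER[candidates[ks[0]].strand],
                        min(candidates[k].start for k in ks)))
    out = list(candidates)
    for gid, ks in enumerate(ordered):
        for k in ks:
            out[k] = replace(out[k], group_id=gid)
    return out


def resolve_overlaps(candidates: list[CandidateExon],
                     profiles: list) -> list[tuple[CandidateExon, object]]:
    """Keep one candidate per overlap group: the maximal combined-score one.

    ``profiles`` align with ``candidates`` and must already be assigned
    (see :func:`vexscan.classify.assign_locus`). A group whose best
    candidate is not accepted yields nothing. Exact score ties break by
    (smaller start, longer interval, '+' before '-').
    """
    if len(candidates) != len(profiles):
        raise ValueError("candidates and profiles must align")
    groups: dict[int, list[int]] = {}
    for k, c in enumerate(candidates):
        if c.group_id < 0:
            raise ValueError("candidates must be grouped first")
        groups.setdefault(c.group_id, []).append(k)
    winners = []
    for gid in sorted(groups):
        ks = groups[gid]

        def key(k: int):
            c, p = candidates[k], profiles[k]
            score = p.combined[p.assigned_locus]
            return (-score, c.start, -(c.end - c.start),
                    _STRAND_ORDER[c.strand])

        best = min(ks, key=key)
        if profiles[best].accepted:
            winners.append((candidates[best], profiles[best]))
    winners.sort(key=lambda cp: (cp[0].contig_id, cp[0].start))
    return winners
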