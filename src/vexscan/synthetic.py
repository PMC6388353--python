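"""Seeded synthetic benchmarks: V-exon families, decoys, and genome-like
contigs with ground truth.

The generator emulates the germline architecture the scanner exploits: a
planted exon is an amino-acid sequence carrying the conserved elements of
V domains — a cysteine in the 15-28 window, a tryptophan in the 25-40
window, and a YYC-like motif within the final 15 residues — reverse
translated (uniform among synonymous codons), padded with 0-2 frame bases,
and embedded as ``AG + pad + exon + CACAGTG`` in random background DNA, on
either strand. Six mutually divergent locus consensus sequences stand in
for the six IG/TCR V loci; families are drawn from a consensus at three
divergence tiers (5% / 15% / 30% substitutions by default, conserved
positions mutating at one tenth the global rate), emulating increasingly
distant taxa. Decoys are AG..CAC intervals of valid length whose
translation is stop-free but has no V structure (uniform residues): they
survive the scan stage by construction and exercise the classifier's
false-acceptance rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .config import LOCI, derive_seed
from .exon_scan import reverse_complement
from .properties import AA_ALPHABET

#: Default per-tier amino-acid substitution rates (fraction of positions).
TIER_RATES = {0: 0.05, 1: 0.15, 2: 0.30}

#: Synonymous codons per amino acid, standard genetic code.
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


@dataclass(frozen=True)
class LocusProfile:
    """Consensus sequence and conserved-position map for one locus."""

    locus: str
    consensus: str
    conserved: tuple[int, ...]  # 0-based positions of C, W, Y, Y, C
    tolerance: np.ndarray  # per-position substitution-rate multiplier

    def __post_init__(self) -> None:
        L = len(self.consensus)
        if not (92 <= L <= 110):
            raise ValueError("consensus length must be in [92, 110]")
        if len(self.tolerance) != L:
            raise ValueError("tolerance length mismatch")


@dataclass(frozen=True)
class PlantedElement:
    """Ground truth for one planted exon or decoy.

    ``start``/``end`` delimit the scannable inner AG..CAC interval
    (frame-pad inclusive) in forward-contig coordinates.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str  # "exon" | "decoy"
    locus: str  # "" for decoys
    tier: int  # -1 for decoys
    aa_sequence: str
    nt_sequence: str  # exon coding part, strand-oriented, pad excluded


@dataclass
class BenchmarkConfig:
    """Layout of one synthetic benchmark genome."""

    n_per_locus_per_tier: dict[int, int] = field(
        default_factory=lambda: {0: 20})
    n_decoys: int = 60
    n_contigs: int = 6
    contig_length: int = 30000
    min_spacer: int = 60
    seed: int = 0
    gc: float = 0.5  # background G+C fraction


@dataclass
class Benchmark:
    contigs: list  # of genome_io.ContigRecord
    truth: pd.DataFrame
    elements: list[PlantedElement]
    profiles: dict[str, LocusProfile]


def _random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def make_locus_profiles(seed: int) -> dict[str, LocusProfile]:
    """Six mutually divergent consensus sequences honoring the conserved
    C / W / YYC architecture (pairwise identity < 0.6)."""
    rng = np.random.default_rng(derive_seed(seed, "profiles"))
    for _attempt in range(100):
        profiles: dict[str, LocusProfile] = {}
        for locus in LOCI:
            L = int(rng.integers(92, 111))
            seq = list(_random_aa(rng, L))
            pos_c = int(rng.integers(14, 28))  # C in the 15-28 window
            pos_w = int(rng.integers(max(24, pos_c + 1), 40))  # W in 25-40
            yyc = int(rng.integers(L - 15, L - 2))  # YYC in the last 15
            seq[pos_c] = "C"
            seq[pos_w] = "W"
            seq[yyc:yyc + 3] = ["Y", "Y", "C"]
            conserved = (pos_c, pos_w, yyc, yyc + 1, yyc + 2)
            tol = np.ones(L)
            tol[list(conserved)] = 0.1
            profiles[locus] = LocusProfile(locus=locus, consensus="".join(seq),
                                           conserved=conserved, tolerance=tol)
        idents = [_identity(profiles[a].consensus, profiles[b].consensus)
                  for ai, a in enumerate(LOCI) for b in LOCI[ai + 1:]]
        if max(idents) < 0.6:
            return profiles
    raise RuntimeError("could not generate mutually divergent profiles")


def sample_family(profile: LocusProfile, n: int, tier: int, seed: int,
                  rates: dict[int, float] | None = None) -> list[str]:
    """Draw ``n`` family members at the tier's divergence from consensus.

    Each position mutates independently with probability
    ``rate * tolerance[pos]`` (conserved positions are 10x less mutable),
    substituting a uniformly chosen different residue.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rates is None:
        rates = TIER_RATES
    if tier not in rates:
        raise ValueError(f"unknown tier {tier}")
    rng = np.random.default_rng(derive_seed(seed, "family", profile.locus, tier))
    rate = rates[tier]
    out = []
    alphabet = np.array(list(AA_ALPHABET))
    for _ in range(n):
        seq = list(profile.consensus)
        hits = rng.random(len(seq)) < rate * profile.tolerance
        for pos in np.flatnonzero(hits):
            choices = alphabet[alphabet != seq[pos]]
            seq[pos] = str(rng.choice(choices))
        out.append("".join(seq))
    return out


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Uniform choice among synonymous codons; never emits a stop codon."""
    return "".join(str(rng.choice(_CODONS[aa])) for aa in aa_seq)


def _cassette(aa_seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """``AG + pad + coding + CACAGTG``; pad in {0,1,2} constrained so the
    inner span stays within the 275-330 scan window."""
    coding = reverse_translate(aa_seq, rng)
    max_pad = min(2, 330 - len(coding))
    if max_pad < 0:
        raise ValueError("coding sequence exceeds the scan window")
    pad_n = int(rng.integers(0, max_pad + 1))
    pad = "".join(rng.choice(list("ACGT"), size=pad_n))
    return "AG" + pad + coding + "CACAGTG", pad_n


def _background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def build_benchmark(cfg: BenchmarkConfig,
                    profiles: dict[str, LocusProfile] | None = None
                    ) -> Benchmark:
    """Generate contigs with planted exons and decoys plus a truth table.

    Elements are distributed round-robin over contigs, separated by random
    background spacers of at least ``min_spacer`` bases; each is planted on
    a random strand. The truth table is BED-like: contig, start, end,
    strand, locus, tier, kind, aa_sequence.
    """
    from .genome_io import ContigRecord  # local import avoids a cycle

    rng = np.random.default_rng(derive_seed(cfg.seed, "benchmark"))
    if profiles is None:
        profiles = make_locus_profiles(cfg.seed)

    # assemble the cassette pool
    pool: list[dict] = []
    for tier, n in sorted(cfg.n_per_locus_per_tier.items()):
        for locus in LOCI:
            for aa in sample_family(profiles[locus], n, tier, cfg.seed):
                cassette, pad = _cassette(aa, rng)
                pool.append({"kind": "exon", "locus": locus, "tier": tier,
                             "aa": aa, "cassette": cassette, "pad": pad})
    for _ in range(cfg.n_decoys):
        aa = _random_aa(rng, int(rng.integers(92, 111)))
        cassette, pad = _cassette(aa, rng)
        pool.append({"kind": "decoy", "locus": "", "tier": -1,
                     "aa": aa, "cassette": cassette, "pad": pad})
    order = rng.permutation(len(pool))
    pool = [pool[k] for k in order]

    per_contig: list[list[dict]] = [[] for _ in range(cfg.n_contigs)]
    for k, item in enumerate(pool):
        per_contig[k % cfg.n_contigs].append(item)

    contigs: list[ContigRecord] = []
    elements: list[PlantedElement] = []
    for ci, items in enumerate(per_contig):
        contig_id = f"synthetic_contig_{ci}"
        total_cassette = sum(len(it["cassette"]) for it in items)
        free = cfg.contig_length - total_cassette
        n_gaps = len(items) + 1
        if free < n_gaps * cfg.min_spacer:
            raise ValueError(
                f"contig_length {cfg.contig_length} too small for "
                f"{len(items)} elements")
        # random spacer lengths >= min_spacer summing to `free`
        cuts = np.sort(rng.integers(0, free - n_gaps * cfg.min_spacer + 1,
                                    size=n_gaps - 1))
        raw = np.diff(np.concatenate([[0], cuts,
                                      [free - n_gaps * cfg.min_spacer]]))
        spacers = raw + cfg.min_spacer
        parts: list[str] = []
        pos = 0
        for gi, item in enumerate(items):
            sp = _background(rng, int(spacers[gi]), cfg.gc)
            parts.append(sp)
            pos += len(sp)
            cassette = item["cassette"]
            Lc = len(cassette)
            strand = "+" if rng.random() < 0.5 else "-"
            inner_len = Lc - 9  # minus AG and CACAGTG
            if strand == "+":
                parts.append(cassette)
                start, end = pos + 2, pos + 2 + inner_len
            else:
                parts.append(reverse_complement(cassette))
                start, end = pos + 7, pos + 7 + inner_len
            coding = cassette[2 + item["pad"]:Lc - 7]
            elements.append(PlantedElement(
                contig_id=contig_id, start=start, end=end, strand=strand,
                kind=item["kind"], locus=item["locus"], tier=item["tier"],
                aa_sequence=item["aa"], nt_sequence=coding))
            pos += Lc
        parts.append(_background(rng, int(spacers[-1]), cfg.gc))
        sequence = "".join(parts)
        assert len(sequence) == cfg.contig_length
        contigs.append(ContigRecord(contig_id=contig_id, sequence=sequence,
                                    source="synthetic"))
        _assert_planted(sequence, [e for e in elements
                                   if e.contig_id == contig_id])

    truth = pd.DataFrame([{
        "contig": e.contig_id, "start": e.start, "end": e.end,
        "strand": e.strand, "locus": e.locus, "tier": e.tier,
        "kind": e.kind, "aa_sequence": e.aa_sequence} for e in elements])
    truth = truth.sort_values(["contig", "start"]).reset_index(drop=True)
    return Benchmark(contigs=contigs, truth=truth, elements=elements,
                     profiles=profiles)


def _assert_planted(sequence: str, elements: list[PlantedElement]) -> None:
    """Generation-time self-check: every element is a scannable, in-frame,
    stop-free AG..CAC interval reproducing its amino-acid sequence."""
    from Bio.Seq import Seq

    for e in elements:
        inner = sequence[e.start:e.end]
        if e.strand == "-":
            inner = reverse_complement(inner)
            assert reverse_complement(sequence[e.end:e.end + 2]) == "AG"
            assert reverse_complement(sequence[e.start - 3:e.start]) == "CAC"
        else:
            assert sequence[e.start - 2:e.start] == "AG"
            assert sequence[e.end:e.end + 3] == "CAC"
        assert 275 <= len(inner) <= 330, len(inner)
        trim = len(inner) % 3
        aa = str(Seq(inner[trim:]).translate())
        assert aa == e.aa_sequence and "*" not in aa


def write_benchmark(bench: Benchmark, fasta_path: str | Path,
                    truth_path: str | Path) -> None:
    """Write contigs as FASTA and the truth table as TSV."""
    with open(fasta_path, "w") as fh:
        for contig in bench.contigs:
            fh.write(f">{contig.contig_id}\n")
            for k in range(0, len(contig.sequence), 80):
                fh.write(contig.sequence[k:k + 80] + "\n")
    bench.truth.to_csv(truth_path, sep="\t", index=False)
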