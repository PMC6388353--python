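"""Unit tests for motif-interval enumeration, translation filtering,
overlap grouping and maximum-likelihood resolution."""

import numpy as np
import pytest

from vexscan.classify import PredictionProfile
from vexscan.config import LOCI
from vexscan.exon_scan import CandidateExon, MotifInterval, \
    enumerate_motif_intervals, group_overlaps, resolve_overlaps, \
    reverse_complement, scan_sequence, translate_candidates


def brute_force_intervals(seq, min_len=275, max_len=330):
    """Quadratic oracle: every AG x every CAC within the span window."""
    seq = seq.upper()
    out = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        ag = [i + 2 for i in range(len(s) - 1) if s[i:i + 2] == "AG"]
        cac = [i for i in range(len(s) - 2) if s[i:i + 3] == "CAC"]
        for a in ag:
            for c in cac:
                if min_len <= c - a <= max_len:
                    if strand == "+":
                        out.append((a, c, "+"))
                    else:
                        out.append((len(s) - c, len(s) - a, "-"))
    return sorted(out)


class TestEnumerate:
    def test_single_planted_interval(self):
        seq = "AG" + "A" * 300 + "CAC"
        hits = [m for m in enumerate_motif_intervals(seq)
                if m.strand == "+"]
        assert [(m.start, m.end) for m in hits] == [(2, 302)]

    def test_short_interval_outside_window(self):
        assert all(m.end - m.start >= 275
                   for m in enumerate_motif_intervals("AG" + "A" * 10 + "CAC"))
        assert enumerate_motif_intervals("AG" + "A" * 10 + "CAC") == []

    def test_window_bounds_inclusive(self):
        for n in (275, 330):
            seq = "AG" + "T" * n + "CAC"
            assert any(m.end - m.start == n and m.strand == "+"
                       for m in enumerate_motif_intervals(seq))
        for n in (274, 331):
            seq = "AG" + "T" * n + "CAC"
            assert not any(m.end - m.start == n
                           for m in enumerate_motif_intervals(seq))

    def test_matches_quadratic_oracle_on_random_sequences(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=5000))
            got = sorted((m.start, m.end, m.strand)
                         for m in enumerate_motif_intervals(seq))
            assert got == brute_force_intervals(seq)

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement mirrors the candidate set."""
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        fwd = {(m.start, m.end, m.strand)
               for m in enumerate_motif_intervals(seq)}
        n = len(seq)
        rev = {(n - m.end, n - m.start, "+" if m.strand == "-" else "-")
               for m in enumerate_motif_intervals(reverse_complement(seq))}
        assert fwd == rev

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            enumerate_motif_intervals("")


class TestTranslate:
    def test_frame_trim_zero(self):
        nt = "GCA" * 100  # Ala x100, no stops
        cands = translate_candidates(
            [MotifInterval(start=0, end=300, strand="+")], nt, "c")
        assert len(cands) == 1
        assert cands[0].frame_trim == 0
        assert cands[0].aa_sequence == "A" * 100

    def test_frame_trim_one(self):
        nt = "T" + "GCA" * 100
        cands = translate_candidates(
            [MotifInterval(start=0, end=301, strand="+")], nt, "c")
        assert cands[0].frame_trim == 1
        assert len(cands[0].aa_sequence) == 100

    def test_stop_codon_discards(self):
        nt = "GCA" * 50 + "TAA" + "GCA" * 49
        assert translate_candidates(
            [MotifInterval(start=0, end=300, strand="+")], nt, "c") == []

    def test_ambiguous_base_discards(self):
        nt = "GCA" * 50 + "NCA" + "GCA" * 49
        assert translate_candidates(
            [MotifInterval(start=0, end=300, strand="+")], nt, "c") == []

    def test_minus_strand_translates_reverse_complement(self):
        aa = "MKLV" * 25
        from vexscan.synthetic import reverse_translate
        rng = np.random.default_rng(3)
        coding = reverse_translate(aa, rng)
        seq = reverse_complement(coding)
        cands = translate_candidates(
            [MotifInterval(start=0, end=300, strand="-")], seq, "c")
        assert cands[0].aa_sequence == aa

    def test_candidate_invariants_enforced(self):
        with pytest.raises(ValueError):
            CandidateExon(contig_id="c", strand="+", start=0, end=300,
                          nt_sequence="GCA" * 100, frame_trim=1,
                          aa_sequence="A" * 100)


def _mk_cand(start, end, strand="+", gid=-1):
    n = end - start
    trim = n % 3
    naa = (n - trim) // 3
    return CandidateExon(contig_id="c", strand=strand, start=start, end=end,
                         nt_sequence="T" * trim + "GCA" * naa,
                         frame_trim=trim, aa_sequence="A" * naa, group_id=gid)


class TestGroupOverlaps:
    def test_overlapping_share_group(self):
        cands = group_overlaps([_mk_cand(0, 300), _mk_cand(100, 400)])
        assert cands[0].group_id == cands[1].group_id

    def test_touching_do_not_overlap(self):
        cands = group_overlaps([_mk_cand(0, 300), _mk_cand(300, 600)])
        assert cands[0].group_id != cands[1].group_id

    def test_strands_never_grouped_together(self):
        cands = group_overlaps([_mk_cand(0, 300, "+"), _mk_cand(0, 300, "-")])
        assert cands[0].group_id != cands[1].group_id

    def test_matches_transitive_closure_oracle(self, rng):
        """Union-find over the full pairwise overlap graph is the oracle."""
        cands = []
        for _ in range(200):
            start = int(rng.integers(0, 5000))
            cands.append(_mk_cand(start, start + int(rng.integers(276, 330)),
                                  "+" if rng.random() < 0.5 else "-"))
        got = group_overlaps(cands)
        # brute-force closure
        n = len(cands)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                a, b = cands[i], cands[j]
                if (a.strand == b.strand and a.start < b.end
                        and b.start < a.end):
                    parent[find(j)] = find(i)
        for i in range(n):
            for j in range(n):
                same_oracle = find(i) == find(j)
                same_got = got[i].group_id == got[j].group_id
                assert same_oracle == same_got


def _profile(score, locus="TRBV", accepted=True):
    combined = {k: 0.1 for k in LOCI}
    combined[locus] = score
    return PredictionProfile(probs={}, combined=combined,
                             assigned_locus=locus, accepted=accepted)


class TestResolveOverlaps:
    def test_argmax_survives(self):
        cands = group_overlaps([_mk_cand(0, 300), _mk_cand(50, 350),
                                _mk_cand(100, 400)])
        profs = [_profile(0.4), _profile(0.9), _profile(0.7)]
        winners = resolve_overlaps(cands, profs)
        assert len(winners) == 1
        assert winners[0][0].start == 50

    def test_singleton_passing_survives(self):
        cands = group_overlaps([_mk_cand(0, 300)])
        winners = resolve_overlaps(cands, [_profile(0.9)])
        assert len(winners) == 1

    def test_failing_group_yields_nothing(self):
        cands = group_overlaps([_mk_cand(0, 300), _mk_cand(100, 400)])
        profs = [_profile(0.9, accepted=False), _profile(0.5, accepted=False)]
        assert resolve_overlaps(cands, profs) == []

    def test_tie_breaks_smaller_start_then_longer(self):
        cands = group_overlaps([_mk_cand(10, 310), _mk_cand(5, 305),
                                _mk_cand(5, 293)])
        profs = [_profile(0.8), _profile(0.8), _profile(0.8)]
        winners = resolve_overlaps(cands, profs)
        assert (winners[0][0].start, winners[0][0].end) == (5, 305)

    def test_ungrouped_input_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlaps([_mk_cand(0, 300)], [_profile(0.9)])


class TestScanStageRecall:
    def test_every_planted_exon_is_a_candidate(self, small_benchmark):
        """The scan stage has 100% recall on planted exons and decoys."""
        truth = small_benchmark.truth
        for contig in small_benchmark.contigs:
            found = {(c.start, c.end, c.strand): c.aa_sequence
                     for c in scan_sequence(contig.sequence,
                                            contig.contig_id)}
            sub = truth[truth.contig == contig.contig_id]
            for row in sub.itertuples():
                key = (row.start, row.end, row.strand)
                assert key in found
                assert found[key] == row.aa_sequence
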