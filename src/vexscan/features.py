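"""Alignment-free featurization of deduced V-exon amino-acid sequences.

A candidate sequence is recursively halved into a multiresolution (MR)
binary tree: node (0,0) is the whole sequence, node (i,j) splits into
(i+1, 2j) and (i+1, 2j+1), with the left child one residue longer when the
length is odd. Each node is then mapped to a fixed-length numeric vector by
one of two transforms:

* **AA pairs** — 20 single-residue counts followed by the 400 counts of
  ordered *consecutive* residue pairs, zero-padded to the published width
  of 440 integers. Vector length does not depend on sequence length, so
  unaligned sequences become comparable.
* **PDT** (physicochemical distance transform) — for each of 500
  standardized amino-acid property scales P, the mean squared difference
  ``(1/(L-lam)) * sum_i (P(a_i) - P(a_{i+lam}))**2`` between residues at
  lag ``lam``; the 500-vector is scaled to unit Euclidean norm (an all-zero
  raw vector is left as zeros).

A hybrid scheme may apply different transforms (or different PDT lags) at
different tree levels, probing long-range structure near the root and local
neighbor correlations at the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .properties import AA_ALPHABET, AA_INDEX, PropertyTable, default_table

AA_PAIR_DIM = 440
PDT_DIM = 500


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric representation of one (sub)sequence."""

    values: np.ndarray
    transform_id: str

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class MRDecomposition:
    """Recursive binary subdivision of one amino-acid sequence.

    ``nodes[(i, j)]`` is the j-th subsequence at level i; level i holds
    2**i nodes and concatenating the children of any node reproduces it.
    """

    nodes: dict[tuple[int, int], str]
    depth: int

    def level(self, i: int) -> list[str]:
        return [self.nodes[(i, j)] for j in range(2**i)]

    @property
    def sequence(self) -> str:
        return self.nodes[(0, 0)]

    def terminal_left(self) -> tuple[int, int]:
        return (self.depth, 0)

    def terminal_right(self) -> tuple[int, int]:
        return (self.depth, 2**self.depth - 1)


def decompose(aa_seq: str, depth: int) -> MRDecomposition:
    """Build the MR tree of ``aa_seq`` down to ``depth`` levels.

    Odd-length nodes split with the left child one residue longer. Requires
    ``len(aa_seq) >= 2**depth`` so every terminal node is non-empty.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if len(aa_seq) < 2**depth:
        raise ValueError(
            f"sequence of length {len(aa_seq)} too short for depth {depth}")
    nodes: dict[tuple[int, int], str] = {(0, 0): aa_seq}
    for i in range(depth):
        for j in range(2**i):
            s = nodes[(i, j)]
            cut = (len(s) + 1) // 2  # left child longer on odd lengths
            nodes[(i + 1, 2 * j)] = s[:cut]
            nodes[(i + 1, 2 * j + 1)] = s[cut:]
    return MRDecomposition(nodes=nodes, depth=depth)


def _check_alphabet(aa_seq: str) -> None:
    bad = set(aa_seq) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in sequence")


def _aa_pair_values(aa_seq: str) -> np.ndarray:
    idx = np.fromiter((AA_INDEX[c] for c in aa_seq), dtype=np.int64,
                      count=len(aa_seq))
    vec = np.zeros(AA_PAIR_DIM, dtype=np.float64)
    vec[:20] = np.bincount(idx, minlength=20)
    if len(idx) > 1:
        pair_idx = 20 * idx[:-1] + idx[1:]
        vec[20:420] = np.bincount(pair_idx, minlength=400)
    return vec


def aa_pair_transform(aa_seq: str) -> FeatureVector:
    """Residue + consecutive-ordered-pair count histogram (440 entries).

    Entries 0..19 are per-residue counts in alphabetical one-letter order;
    entries 20..419 are consecutive-pair counts with index
    ``20 + 20*idx(first) + idx(second)``; entries 420..439 are a reserved
    all-zero block that pads the vector to its published width of 440
    (20 single counts plus 400 ordered-pair counts only account for 420).
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    _check_alphabet(aa_seq)
    return FeatureVector(values=_aa_pair_values(aa_seq), transform_id="aa_pairs")


def _pdt_values(aa_seq: str, lam: int, table: PropertyTable) -> np.ndarray:
    idx = np.fromiter((AA_INDEX[c] for c in aa_seq), dtype=np.int64,
                      count=len(aa_seq))
    vals = table.values[:, idx]  # (n_props, L)
    diffs = vals[:, :-lam] - vals[:, lam:]
    raw = (diffs**2).mean(axis=1)
    norm = np.linalg.norm(raw)
    return raw / norm if norm > 0 else raw


def pdt_transform(aa_seq: str, lam: int = 1,
                  table: PropertyTable | None = None) -> FeatureVector:
    """Physicochemical distance transform at lag ``lam`` (500 entries)."""
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if lam >= len(aa_seq):
        raise ValueError(f"lam={lam} must be < sequence length {len(aa_seq)}")
    _check_alphabet(aa_seq)
    if table is None:
        table = default_table()
    return FeatureVector(values=_pdt_values(aa_seq, lam, table),
                         transform_id="pdt")


# -- per-level transform plumbing -------------------------------------

def parse_level_transform(spec: str) -> tuple[str, int]:
    """``"aa_pairs"`` -> ("aa_pairs", 0); ``"pdt"``/``"pdt:3"`` -> ("pdt", lam)."""
    if spec == "aa_pairs":
        return ("aa_pairs", 0)
    if spec == "pdt":
        return ("pdt", 1)
    if spec.startswith("pdt:"):
        lam = int(spec.split(":", 1)[1])
        if lam < 1:
            raise ValueError("pdt lag must be >= 1")
        return ("pdt", lam)
    raise ValueError(f"unknown transform spec {spec!r}")


def level_transforms(depth: int, transform: str, pdt_lambda: int = 1,
                     level_map: dict[int, str] | None = None
                     ) -> dict[int, tuple[str, int]]:
    """Resolve the transform applied at each MR level 0..depth."""
    if transform == "hybrid":
        if not level_map:
            raise ValueError("hybrid transform requires level_map")
        out = {}
        for lvl in range(depth + 1):
            if lvl not in {int(k) for k in level_map}:
                raise ValueError(f"level {lvl} missing from level_map")
            out[lvl] = parse_level_transform(level_map[lvl])
        return out
    if transform == "aa_pairs":
        return {lvl: ("aa_pairs", 0) for lvl in range(depth + 1)}
    if transform == "pdt":
        return {lvl: ("pdt", pdt_lambda) for lvl in range(depth + 1)}
    raise ValueError(f"unknown transform {transform!r}")


def node_values(aa_seq: str, kind: str, lam: int,
                table: PropertyTable) -> np.ndarray:
    if kind == "aa_pairs":
        return _aa_pair_values(aa_seq)
    return _pdt_values(aa_seq, lam, table)


def hybrid_transform(mr: MRDecomposition, level_map: dict[int, str],
                     table: PropertyTable | None = None
                     ) -> dict[tuple[int, int], FeatureVector]:
    """Featurize every MR node with its level's transform."""
    if table is None:
        table = default_table()
    plan = {lvl: parse_level_transform(level_map[lvl])
            for lvl in range(mr.depth + 1)
            if lvl in {int(k) for k in level_map}}
    missing = set(range(mr.depth + 1)) - set(plan)
    if missing:
        raise ValueError(f"level_map misses levels {sorted(missing)}")
    out: dict[tuple[int, int], FeatureVector] = {}
    for (i, j), sub in mr.nodes.items():
        kind, lam = plan[i]
        _check_alphabet(sub)
        if kind == "pdt" and lam >= len(sub):
            raise ValueError(
                f"pdt lag {lam} too large for node ({i},{j}) of length {len(sub)}")
        out[(i, j)] = FeatureVector(values=node_values(sub, kind, lam, table),
                                    transform_id=kind)
    return out


def featurize_nodes(mr: MRDecomposition, plan: dict[int, tuple[str, int]],
                    table: PropertyTable) -> dict[tuple[int, int], np.ndarray]:
    """Raw per-node feature arrays under a resolved per-level plan."""
    out = {}
    for (i, j), sub in mr.nodes.items():
        kind, lam = plan[i]
        out[(i, j)] = node_values(sub, kind, lam, table)
    return out
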