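"""The online iterative learning loop.

Starting from a small labeled seed set T_0 of known V-exon amino-acid
sequences, each iteration (i) retrains the per-locus, per-node ensembles
from scratch on T_n, (ii) scans the genome corpus end to end (chunked
read, motif-interval enumeration, translation filter, overlap grouping,
classification, per-group maximum-likelihood resolution), and (iii) adds
the accepted, previously unseen discoveries D_o to form T_{n+1}. Because
newly accepted homologs pull the decision surface toward more divergent
sequences, successive iterations recover V-exons increasingly far from
the seed set. The loop stops when the discovery yield becomes negligible
(|D_o| / |T_n| below ``min_new_fraction``) or an iteration cap is hit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import LocusModelSet, assign_locus, build_training_matrices, \
    predict_profiles, train
from .config import LOCI, RunConfig
from .exon_scan import CandidateExon, resolve_overlaps
from .genome_io import read_fasta, scan_contig
from .properties import PropertyTable, default_table

logger = logging.getLogger(__name__)


@dataclass
class Discovery:
    """One accepted, newly seen candidate."""

    locus: str
    aa_sequence: str
    candidate: CandidateExon
    score: float
    mr_score: float
    genome: str


@dataclass
class IterationState:
    """State entering iteration ``t``: the training set T_n, and the
    discoveries/diagnostics recorded when the iteration ran."""

    t: int
    training: dict[str, list[str]]  # locus -> aa sequences (T_n)
    discoveries: list[Discovery] = field(default_factory=list)  # D_o
    n_accepted: int = 0
    n_rejected: int = 0
    score_samples: dict[str, list[float]] = field(default_factory=dict)
    models: LocusModelSet | None = None
    wall_time: float = 0.0

    @property
    def training_size(self) -> int:
        return sum(len(v) for v in self.training.values())

    def training_aa_set(self) -> set[str]:
        return {s for v in self.training.values() for s in v}


@dataclass(frozen=True)
class ConvergenceRule:
    """Stop when the discovery yield is negligible or a cap is reached."""

    min_new_fraction: float = 0.01
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.min_new_fraction < 1):
            raise ValueError("min_new_fraction must be in [0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def run_iteration(state: IterationState, genomes: list[str | Path],
                  config: RunConfig,
                  table: PropertyTable | None = None) -> IterationState:
    """Train on T_n, scan all genomes, and return the t+1 state.

    Accepted candidates whose amino-acid sequence is not already in T_n
    (exact match, also deduplicated within the iteration) form D_o;
    T_{n+1} = T_n plus D_o under each discovery's assigned locus. With a
    fixed config/seed the result is deterministic.
    """
    if table is None:
        table = default_table()
    if state.training_size == 0:
        raise ValueError("training set is empty")
    t0 = time.monotonic()
    matrices = build_training_matrices(state.training, config, table)
    models = train(matrices, config, table)
    state.models = models

    known = state.training_aa_set()
    seen_new: set[str] = set()
    n_accepted = 0
    n_rejected = 0
    score_samples: dict[str, list[float]] = {k: [] for k in LOCI}
    discoveries: list[Discovery] = []
    for path in genomes:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"genome file not found: {path}")
        for contig in read_fasta(path):
            candidates = scan_contig(contig, config.chunk_size, config.overlap,
                                     config.len_min, config.len_max)
            if not candidates:
                continue
            profiles = predict_profiles([c.aa_sequence for c in candidates],
                                        models, config)
            profiles = [assign_locus(p, config) for p in profiles]
            winners = resolve_overlaps(candidates, profiles)
            n_accepted += len(winners)
            n_rejected += len(candidates) - len(winners)
            for cand, prof in winners:
                locus = prof.assigned_locus
                score_samples[locus].append(prof.combined[locus])
                aa = cand.aa_sequence
                if aa in known or aa in seen_new:
                    continue
                seen_new.add(aa)
                discoveries.append(Discovery(
                    locus=locus, aa_sequence=aa, candidate=cand,
                    score=prof.combined[locus], mr_score=prof.mr_score,
                    genome=str(path)))

    state.discoveries = discoveries
    state.n_accepted = n_accepted
    state.n_rejected = n_rejected
    state.score_samples = score_samples
    state.wall_time = time.monotonic() - t0
    logger.info("iteration %d: |T|=%d accepted=%d new=%d rejected=%d (%.1fs)",
                state.t, state.training_size, n_accepted, len(discoveries),
                n_rejected, state.wall_time)

    next_training = {k: list(v) for k, v in state.training.items()}
    for d in discoveries:
        next_training.setdefault(d.locus, []).append(d.aa_sequence)
    return IterationState(t=state.t + 1, training=next_training)


def is_converged(history: list[IterationState],
                 rule: ConvergenceRule) -> bool:
    """True iff the latest completed iteration discovered a negligible
    fraction of new sequences, or the iteration cap is reached."""
    if not history:
        raise ValueError("empty history")
    last = history[-1]
    if last.t >= rule.max_iterations:
        return True
    frac = len(last.discoveries) / max(last.training_size, 1)
    return frac < rule.min_new_fraction


def run_bootstrap(training: dict[str, list[str]], genomes: list[str | Path],
                  config: RunConfig,
                  table: PropertyTable | None = None
                  ) -> list[IterationState]:
    """Iterate :func:`run_iteration` until :func:`is_converged`.

    Returns the full iteration history; ``history[-1].training`` is the
    converged training set and each earlier entry carries its discoveries
    and score distributions.
    """
    rule = ConvergenceRule(min_new_fraction=config.min_new_fraction,
                           max_iterations=config.max_iterations)
    state = IterationState(t=0, training={k: list(v)
                                          for k, v in training.items()})
    history: list[IterationState] = []
    while True:
        next_state = run_iteration(state, genomes, config, table)
        history.append(state)
        if is_converged(history, rule):
            break
        state = next_state
    return history


def score_density(scores: list[float], bandwidth: float | None = None,
                  grid_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of classifier scores on a [0, 1] grid.

    Boundary mass is handled by reflection at 0 and 1 (scores live in
    [0, 1]), and the result is renormalized over the grid (trapezoid rule)
    so the density integrates to 1 even for boundary-crowded samples.
    Fewer than two scores yield an empty (zero) density with a warning.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    if len(scores) < 2:
        logger.warning("score_density needs >= 2 scores, got %d", len(scores))
        return grid, np.zeros_like(grid)
    x = np.asarray(scores, dtype=float)
    if bandwidth is None:
        sd = x.std(ddof=1)
        bandwidth = max(1.06 * sd * len(x) ** (-1 / 5), 1e-2)  # Silverman
    dens = np.zeros_like(grid)
    for pts in (x, -x, 2.0 - x):  # sample + reflections at both edges
        z = (grid[:, None] - pts[None, :]) / bandwidth
        dens += np.exp(-0.5 * z**2).sum(axis=1)
    dens /= len(x) * bandwidth * np.sqrt(2 * np.pi)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return grid, dens


def iteration_report(history: list[IterationState]) -> pd.DataFrame:
    """Per-iteration table: t, |T_n|, |D_o|, acceptance counts, and
    per-locus cumulative training sizes."""
    if not history:
        raise ValueError("empty history")
    rows = []
    for st in history:
        row = {"t": st.t, "T_size": st.training_size,
               "D_size": len(st.discoveries), "n_accepted": st.n_accepted,
               "n_rejected": st.n_rejected}
        for locus in LOCI:
            row[f"T_{locus}"] = len(st.training.get(locus, []))
        rows.append(row)
    return pd.DataFrame(rows)
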