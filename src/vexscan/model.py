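"""Model/Results front end for the discovery pipeline.

:class:`VExonDiscovery` bundles a genome corpus, a labeled seed training
set, and a :class:`~vexscan.config.RunConfig`; ``fit()`` runs the
iterative bootstrap loop and returns a :class:`DiscoveryResults` holding
the iteration history, the final trained ensembles, the discovery table,
and a ``summary()`` in the spirit of statistical modelling packages.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .bootstrap import IterationState, iteration_report, run_bootstrap, \
    score_density
from .classify import LocusModelSet
from .config import LOCI, RunConfig

_LOCUS_TAG = re.compile(r"locus=([A-Za-z_]+)")


def read_training_fasta(path: str | Path) -> dict[str, list[str]]:
    """Read a seed training FASTA with ``locus=<LABEL>`` header tags."""
    out: dict[str, list[str]] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _LOCUS_TAG.search(rec.description)
        if not m:
            raise ValueError(
                f"record {rec.id!r} lacks a locus=<LABEL> header tag")
        locus = m.group(1)
        if locus not in LOCI:
            raise ValueError(f"unknown locus label {locus!r} on {rec.id!r}")
        out.setdefault(locus, []).append(str(rec.seq).upper())
        n += 1
    if n == 0:
        raise ValueError(f"no training records in {path}")
    return out


def write_training_fasta(path: str | Path,
                         training: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for locus in LOCI:
            for k, aa in enumerate(training.get(locus, [])):
                fh.write(f">{locus}_{k} locus={locus}\n{aa}\n")


class VExonDiscovery:
    """Iterative V-exon discovery over a genome corpus.

    Parameters
    ----------
    genomes : list of FASTA paths to scan each iteration.
    training : locus -> list of amino-acid sequences (the seed set T_0),
        or use :meth:`from_fasta`.
    config : pipeline configuration; defaults to ``RunConfig()``.
    """

    def __init__(self, genomes: list[str | Path],
                 training: dict[str, list[str]],
                 config: RunConfig | None = None):
        if not genomes:
            raise ValueError("need at least one genome")
        if not any(training.values()):
            raise ValueError("empty seed training set")
        unknown = set(training) - set(LOCI)
        if unknown:
            raise ValueError(f"unknown locus labels {sorted(unknown)}")
        self.genomes = [Path(g) for g in genomes]
        self.training = {k: list(v) for k, v in training.items()}
        self.config = config or RunConfig()

    @classmethod
    def from_fasta(cls, genomes: list[str | Path],
                   training_fasta: str | Path,
                   config: RunConfig | None = None) -> "VExonDiscovery":
        return cls(genomes, read_training_fasta(training_fasta), config)

    def fit(self) -> "DiscoveryResults":
        history = run_bootstrap(self.training, self.genomes, self.config)
        return DiscoveryResults(self, history)


class DiscoveryResults:
    """Fitted results: iteration history, discoveries, and final models."""

    def __init__(self, model: VExonDiscovery,
                 history: list[IterationState]):
        self.model = model
        self.history = history

    @property
    def n_iterations(self) -> int:
        return len(self.history)

    @property
    def models(self) -> LocusModelSet:
        return self.history[-1].models

    @property
    def converged(self) -> bool:
        last = self.history[-1]
        frac = len(last.discoveries) / max(last.training_size, 1)
        return (frac < self.model.config.min_new_fraction
                or last.t >= self.model.config.max_iterations)

    def discoveries(self) -> pd.DataFrame:
        """All discoveries across iterations, one row per sequence."""
        rows = []
        for st in self.history:
            for d in st.discoveries:
                rows.append({
                    "iteration": st.t, "locus": d.locus,
                    "contig": d.candidate.contig_id,
                    "start": d.candidate.start, "end": d.candidate.end,
                    "strand": d.candidate.strand, "score": d.score,
                    "mr_score": d.mr_score, "genome": d.genome,
                    "aa_sequence": d.aa_sequence})
        cols = ["iteration", "locus", "contig", "start", "end", "strand",
                "score", "mr_score", "genome", "aa_sequence"]
        return pd.DataFrame(rows, columns=cols)

    def final_training(self) -> dict[str, list[str]]:
        return self.history[-1].training

    def report(self) -> pd.DataFrame:
        return iteration_report(self.history)

    def score_densities(self, iteration: int = -1,
                        grid_size: int = 256) -> dict[str, tuple]:
        """Per-locus KDE of accepted-candidate scores at one iteration."""
        st = self.history[iteration]
        return {locus: score_density(scores, grid_size=grid_size)
                for locus, scores in st.score_samples.items() if scores}

    def plot_score_densities(self, iteration: int = -1, ax=None):
        """Diagnostic plot of the per-locus score KDEs (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        for locus, (grid, dens) in self.score_densities(iteration).items():
            ax.plot(grid, dens, label=locus)
        ax.set_xlabel("combined classifier score")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        disc = self.discoveries()
        lines = [
            "V-exon discovery results",
            "=" * 60,
            f"genomes scanned:     {len(self.model.genomes)}",
            f"iterations run:      {self.n_iterations}"
            f"  (converged: {self.converged})",
            f"seed training size:  {self.history[0].training_size}",
            f"final training size: {self.history[-1].training_size}",
            f"total discoveries:   {len(disc)}",
            "",
            "config: depth=%d transform=%s n_trees=%d ratio=%g:1" % (
                cfg.depth, cfg.transform, cfg.n_trees, cfg.signal_ratio),
            "        eps=%g terminal_tau=%g sigma=%g p_min=%g seed=%d" % (
                cfg.eps, cfg.terminal_tau, cfg.sigma, cfg.p_min, cfg.seed),
            "",
            "per-iteration history:",
            self.report().to_string(index=False),
        ]
        if len(disc):
            lines += ["", "discoveries per locus:",
                      disc.groupby("locus").size().to_string()]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<DiscoveryResults: {self.n_iterations} iterations, "
                f"{len(self.discoveries())} discoveries>")
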