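"""Per-locus, per-node Random Forest ensembles and acceptance criteria.

For each of the six V loci (IGHV, IGKV, IGLV, TRAV/DV combined, TRBV,
TRGV) and each node (i, j) of the multiresolution tree, a binary Random
Forest is trained to separate that locus's node-subsequences (signal) from
residue-shuffled versions of the same sequences (background), at a 3:1
signal:background ratio. Shuffled positives preserve composition while
destroying order, which forces the forests to learn sequential structure
rather than composition alone.

At predict time a candidate yields the signal probability p_ij(L_k) for
every (locus, node); per locus these are combined (arithmetic mean by
default) and the winning locus chosen by maximum likelihood. A candidate
is accepted only if

* its combined probability reaches ``p_min``,
* adjacent-level probabilities agree within ``eps`` (homology throughout
  the sequence, not just on average), and
* both terminal subsequences — the extreme left and right of the deepest
  level — exceed ``terminal_tau`` (exon boundaries look V-like).

The MR consistency score ``((N-1)/N) * sum_{(k,m) != (0,0)}
(1 - exp(|p_00 - p_km|**2 / sigma))`` (N = node count) is 0 when every
node agrees with the root and strictly decreases as any node deviates; it
ranks accepted candidates and feeds the per-iteration diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import LOCI, RunConfig, derive_seed
from .features import decompose, featurize_nodes, level_transforms
from .properties import PropertyTable, default_table, table_from_manifest

NodeKey = tuple[int, int]


@dataclass
class TrainingMatrix:
    """Signal/background design matrix for one (locus, node) pair."""

    locus: str
    node: NodeKey
    X: np.ndarray  # (n_rows, n_features)
    y: np.ndarray  # 1 = signal, 0 = background

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X/y row mismatch")


@dataclass
class LocusModelSet:
    """Trained ensembles for every (locus, node), plus the manifest needed
    to re-featurize identically at predict time."""

    models: dict[tuple[str, NodeKey], RandomForestClassifier]
    manifest: dict

    @property
    def depth(self) -> int:
        return int(self.manifest["depth"])

    @property
    def nodes(self) -> list[NodeKey]:
        return [(i, j) for i in range(self.depth + 1) for j in range(2**i)]

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.manifest["loci"])

    def property_table(self) -> PropertyTable:
        return table_from_manifest(self.manifest["property_table"])

    def save(self, path: str | Path) -> None:
        joblib.dump({"models": self.models, "manifest": self.manifest}, path)

    @classmethod
    def load(cls, path: str | Path) -> "LocusModelSet":
        blob = joblib.load(path)
        return cls(models=blob["models"], manifest=blob["manifest"])


@dataclass
class PredictionProfile:
    """Per-node, per-locus signal probabilities for one candidate, plus
    combined scores and the acceptance verdict.

    Only the signal probability p1 is stored; the background probability
    is its complement for a binary ensemble.
    """

    probs: dict[tuple[str, NodeKey], float]
    combined: dict[str, float]
    mr_score: float = float("nan")
    assigned_locus: str | None = None
    accepted: bool = False
    ambiguous: bool = False

    def locus_probs(self, locus: str) -> dict[NodeKey, float]:
        return {node: p for (k, node), p in self.probs.items() if k == locus}


# -- training ----------------------------------------------------------


def _shuffle_seq(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def _uniform_seq(length: int, rng: np.random.Generator) -> str:
    from .properties import AA_ALPHABET
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def build_training_matrices(positives: dict[str, list[str]],
                            config: RunConfig,
                            table: PropertyTable | None = None
                            ) -> dict[tuple[str, NodeKey], TrainingMatrix]:
    """Featurize per-locus positives and per-node fresh backgrounds.

    Signal rows at node (i,j) are that node's subsequences of the locus's
    positives; background rows are node-subsequences of residue-shuffled
    positives (a fresh shuffle per node), ``ceil(n_signal / ratio)`` of
    them. Row order is shuffled. Everything is seeded from the master seed.
    """
    if table is None:
        table = default_table()
    plan = level_transforms(config.depth, config.transform,
                            config.pdt_lambda, config.level_map)
    nodes = [(i, j) for i in range(config.depth + 1) for j in range(2**i)]
    out: dict[tuple[str, NodeKey], TrainingMatrix] = {}
    for locus in LOCI:
        seqs = positives.get(locus, [])
        if not seqs:
            continue
        if len(seqs) < 2:
            raise ValueError(f"need >= 2 positives for locus {locus}")
        decomps = [decompose(s, config.depth) for s in seqs]
        feats = [featurize_nodes(d, plan, table) for d in decomps]
        n_bg = math.ceil(len(seqs) / config.signal_ratio)
        for node in nodes:
            rng = np.random.default_rng(
                derive_seed(config.seed, "train_matrix", locus, node))
            X_sig = np.stack([f[node] for f in feats])
            pick = rng.choice(len(seqs), size=n_bg,
                              replace=n_bg > len(seqs))
            bg_rows = []
            for k in pick:
                if config.background == "shuffle":
                    bg_seq = _shuffle_seq(seqs[k], rng)
                else:
                    bg_seq = _uniform_seq(len(seqs[k]), rng)
                bg_feats = featurize_nodes(decompose(bg_seq, config.depth),
                                           plan, table)
                bg_rows.append(bg_feats[node])
            X = np.vstack([X_sig, np.stack(bg_rows)])
            y = np.concatenate([np.ones(len(seqs), dtype=np.int64),
                                np.zeros(n_bg, dtype=np.int64)])
            order = rng.permutation(len(y))
            out[(locus, node)] = TrainingMatrix(locus=locus, node=node,
                                                X=X[order], y=y[order])
    return out


def train(matrices: dict[tuple[str, NodeKey], TrainingMatrix],
          config: RunConfig,
          table: PropertyTable | None = None) -> LocusModelSet:
    """Fit one Random Forest per (locus, node)."""
    if table is None:
        table = default_table()
    models: dict[tuple[str, NodeKey], RandomForestClassifier] = {}
    for key in sorted(matrices):
        m = matrices[key]
        if len(np.unique(m.y)) < 2:
            raise ValueError(f"degenerate training matrix for {key}")
        clf = RandomForestClassifier(
            n_estimators=config.n_trees, n_jobs=1,
            random_state=derive_seed(config.seed, "forest", *key))
        clf.fit(m.X, m.y)
        models[key] = clf
    loci = sorted({k for k, _ in models})
    manifest = {
        "depth": config.depth,
        "transform": config.transform,
        "pdt_lambda": config.pdt_lambda,
        "level_map": config.level_map,
        "loci": [k for k in LOCI if k in loci],
        "n_trees": config.n_trees,
        "seed": config.seed,
        "property_table": table.manifest,
        "version": 1,
    }
    return LocusModelSet(models=models, manifest=manifest)


# -- prediction --------------------------------------------------------


def _signal_column(clf: RandomForestClassifier) -> int:
    return int(np.where(clf.classes_ == 1)[0][0])


def predict_profiles(aa_seqs: list[str], models: LocusModelSet,
                     config: RunConfig) -> list[PredictionProfile]:
    """Batch prediction: one profile per sequence.

    Sequences are decomposed and featurized once per node; each of the
    (locus, node) forests then scores the whole batch.
    """
    if not aa_seqs:
        return []
    depth = models.depth
    plan = level_transforms(depth, models.manifest["transform"],
                            models.manifest["pdt_lambda"],
                            models.manifest["level_map"])
    table = models.property_table()
    feats = [featurize_nodes(decompose(s, depth), plan, table)
             for s in aa_seqs]
    nodes = models.nodes
    node_X = {node: np.stack([f[node] for f in feats]) for node in nodes}
    loci = models.loci
    probs = np.empty((len(aa_seqs), len(loci), len(nodes)))
    for ki, locus in enumerate(loci):
        for ni, node in enumerate(nodes):
            clf = models.models[(locus, node)]
            p = clf.predict_proba(node_X[node])[:, _signal_column(clf)]
            probs[:, ki, ni] = p
    profiles = []
    for s in range(len(aa_seqs)):
        pdict = {(loci[ki], nodes[ni]): float(probs[s, ki, ni])
                 for ki in range(len(loci)) for ni in range(len(nodes))}
        if config.combine == "geometric":
            combined = {loci[ki]: float(np.exp(np.mean(np.log(
                np.clip(probs[s, ki], 1e-12, None)))))
                for ki in range(len(loci))}
        else:
            combined = {loci[ki]: float(probs[s, ki].mean())
                        for ki in range(len(loci))}
        profiles.append(PredictionProfile(probs=pdict, combined=combined))
    return profiles


def predict_profile(aa_seq: str, models: LocusModelSet,
                    config: RunConfig) -> PredictionProfile:
    return predict_profiles([aa_seq], models, config)[0]


# -- acceptance criteria ----------------------------------------------


def consistency_ok(profile: PredictionProfile, locus: str, eps: float = 0.17,
                   depth: int | None = None) -> bool:
    """True iff every parent/child probability pair at adjacent levels
    differs by less than ``eps`` for the given locus."""
    lp = profile.locus_probs(locus)
    if depth is None:
        depth = max(i for i, _ in lp)
    for i in range(depth):
        for j in range(2**i):
            parent = lp[(i, j)]
            for child in ((i + 1, 2 * j), (i + 1, 2 * j + 1)):
                if abs(parent - lp[child]) >= eps:
                    return False
    return True


def terminal_ok(profile: PredictionProfile, locus: str, tau: float = 0.7,
                depth: int | None = None) -> bool:
    """True iff both terminal subsequences (left-most and right-most nodes
    of the deepest level) score above ``tau`` — the exon boundaries must
    themselves look V-like."""
    lp = profile.locus_probs(locus)
    if depth is None:
        depth = max(i for i, _ in lp)
    if depth == 0:
        import logging
        logging.getLogger(__name__).warning(
            "terminal criterion is vacuous at depth 0")
        return True
    return lp[(depth, 0)] > tau and lp[(depth, 2**depth - 1)] > tau


def mr_consistency_score(profile: PredictionProfile, locus: str,
                         sigma: float, sign: str = "as_printed") -> float:
    """MR score: 0 when all nodes agree with the root, decreasing with any
    deviation (``as_printed`` convention: terms 1 - exp(+d**2/sigma) <= 0).

    The ``negated`` variant uses exp(-d**2/sigma), yielding a score in
    [0, (N-1)/N * (N-1)] that *increases* with deviation; it is offered
    because the printed positive exponent is plausibly a typo, but the
    as-printed form is the default.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lp = profile.locus_probs(locus)
    n_nodes = len(lp)
    p00 = lp[(0, 0)]
    total = 0.0
    for node, p in lp.items():
        if node == (0, 0):
            continue
        d2 = (p00 - p)**2
        if sign == "as_printed":
            total += 1.0 - math.exp(d2 / sigma)
        elif sign == "negated":
            total += 1.0 - math.exp(-d2 / sigma)
        else:
            raise ValueError(f"unknown score_exponent_sign {sign!r}")
    return (n_nodes - 1) / n_nodes * total


def assign_locus(profile: PredictionProfile,
                 config: RunConfig) -> PredictionProfile:
    """Maximum-likelihood locus assignment plus the acceptance verdict.

    The assigned locus maximizes the combined probability (exact ties break
    by the fixed locus order and are flagged ambiguous). Acceptance
    requires the combined probability to reach ``p_min`` and the
    consistency and terminal criteria to hold for the assigned locus.
    """
    loci = [k for k in LOCI if k in profile.combined]
    best = max(loci, key=lambda k: profile.combined[k])
    ties = [k for k in loci if profile.combined[k] == profile.combined[best]]
    profile.assigned_locus = min(ties, key=LOCI.index)
    profile.ambiguous = len(ties) > 1
    depth = max(i for (_, (i, _j)) in profile.probs)
    ok = (profile.combined[profile.assigned_locus] >= config.p_min
          and consistency_ok(profile, profile.assigned_locus, config.eps, depth)
          and terminal_ok(profile, profile.assigned_locus,
                          config.terminal_tau, depth))
    profile.accepted = bool(ok)
    profile.mr_score = mr_consistency_score(
        profile, profile.assigned_locus, config.sigma,
        config.score_exponent_sign)
    return profile
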