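"""Unit tests for training-matrix assembly, ensemble training/prediction,
the acceptance criteria, the MR score, and locus assignment."""

import math

import numpy as np
import pytest

from vexscan import RunConfig
from vexscan.classify import LocusModelSet, PredictionProfile, assign_locus, \
    build_training_matrices, consistency_ok, mr_consistency_score, \
    predict_profile, predict_profiles, terminal_ok, train
from vexscan.config import LOCI


@pytest.fixture(scope="module")
def trained(profiles, tier0_training):
    """Forests trained once on tier-0 families (module scope for speed)."""
    cfg = RunConfig(n_trees=80, seed=9)
    matrices = build_training_matrices(tier0_training, cfg)
    return train(matrices, cfg), cfg


class TestTrainingMatrices:
    def test_shapes_and_ratio(self, tier0_training):
        cfg = RunConfig(n_trees=10, seed=1)
        mats = build_training_matrices(tier0_training, cfg)
        # 6 loci x 7 nodes at depth 2
        assert len(mats) == 6 * 7
        for (locus, node), m in mats.items():
            n_sig = int(m.y.sum())
            n_bg = len(m.y) - n_sig
            assert n_sig == 12
            assert n_bg == math.ceil(12 / 3)
            assert m.X.shape == (16, 440)

    def test_depth_zero_single_matrix_per_locus(self, tier0_training):
        cfg = RunConfig(n_trees=10, depth=0, seed=1)
        mats = build_training_matrices(tier0_training, cfg)
        assert len(mats) == 6
        assert all(node == (0, 0) for _, node in mats)

    def test_deterministic_given_seed(self, tier0_training):
        cfg = RunConfig(n_trees=10, seed=4)
        a = build_training_matrices(tier0_training, cfg)
        b = build_training_matrices(tier0_training, cfg)
        for key in a:
            np.testing.assert_array_equal(a[key].X, b[key].X)
            np.testing.assert_array_equal(a[key].y, b[key].y)

    def test_too_few_positives_rejected(self):
        cfg = RunConfig(n_trees=10, seed=1)
        with pytest.raises(ValueError):
            build_training_matrices({"IGHV": ["ACDEFGHI"]}, cfg)


class TestTrainPredict:
    def test_training_positive_scores_high_for_own_locus(
            self, trained, tier0_training):
        models, cfg = trained
        hits = 0
        probes = [(locus, seqs[0]) for locus, seqs in tier0_training.items()]
        for locus, aa in probes:
            prof = predict_profile(aa, models, cfg)
            if prof.probs[(locus, (0, 0))] > 0.5:
                hits += 1
        assert hits >= len(probes) - 1  # >= 95% style margin at n=6

    def test_shuffled_probe_scores_low(self, trained, tier0_training, rng):
        models, cfg = trained
        low = 0
        n = 0
        for locus in LOCI:
            aa = tier0_training[locus][0]
            shuffled = "".join(rng.permutation(list(aa)))
            prof = predict_profile(shuffled, models, cfg)
            n += 1
            if all(prof.combined[k] < 0.5 for k in LOCI):
                low += 1
        assert low >= n - 1

    def test_probabilities_in_unit_interval_and_combined_is_mean(
            self, trained, tier0_training):
        models, cfg = trained
        prof = predict_profile(tier0_training["TRBV"][2], models, cfg)
        assert all(0 <= p <= 1 for p in prof.probs.values())
        for locus in LOCI:
            node_ps = list(prof.locus_probs(locus).values())
            assert prof.combined[locus] == pytest.approx(np.mean(node_ps))

    def test_repeat_prediction_identical(self, trained, tier0_training):
        models, cfg = trained
        aa = tier0_training["IGKV"][1]
        a = predict_profile(aa, models, cfg)
        b = predict_profile(aa, models, cfg)
        assert a.probs == b.probs

    def test_serialization_round_trip(self, trained, tier0_training,
                                      tmp_path):
        models, cfg = trained
        path = tmp_path / "models.joblib"
        models.save(path)
        reloaded = LocusModelSet.load(path)
        probes = [tier0_training[k][0] for k in LOCI]
        before = predict_profiles(probes, models, cfg)
        after = predict_profiles(probes, reloaded, cfg)
        for x, y in zip(before, after):
            assert x.probs == y.probs

    def test_degenerate_matrix_rejected(self, tier0_training):
        cfg = RunConfig(n_trees=10, seed=1)
        mats = build_training_matrices(tier0_training, cfg)
        key = next(iter(mats))
        mats[key].y[:] = 1
        with pytest.raises(ValueError, match="degenerate"):
            train(mats, cfg)


def _profile_from_levels(levels, locus="IGHV"):
    """Build a profile with the given per-level probabilities for one
    locus (other loci at 0.1)."""
    probs = {}
    depth = len(levels) - 1
    for k in LOCI:
        for i, row in enumerate(levels):
            assert len(row) == 2**i
            for j, p in enumerate(row):
                probs[(k, (i, j))] = p if k == locus else 0.1
    combined = {k: float(np.mean([p for (kk, _), p in probs.items()
                                  if kk == k])) for k in LOCI}
    return PredictionProfile(probs=probs, combined=combined), depth


class TestCriteria:
    def test_consistency_within_eps(self):
        prof, depth = _profile_from_levels([[0.90], [0.85, 0.80],
                                            [0.85, 0.85, 0.80, 0.80]])
        assert consistency_ok(prof, "IGHV", eps=0.17, depth=depth)

    def test_consistency_violated(self):
        prof, depth = _profile_from_levels([[0.90], [0.60, 0.85],
                                            [0.60, 0.60, 0.85, 0.85]])
        assert not consistency_ok(prof, "IGHV", eps=0.17, depth=depth)

    def test_consistency_vacuous_at_eps_one(self):
        prof, depth = _profile_from_levels([[0.9], [0.0, 1.0], [0, 1, 0, 1]])
        assert consistency_ok(prof, "IGHV", eps=1.0 + 1e-9, depth=depth)

    def test_terminal_both_above_tau(self):
        prof, depth = _profile_from_levels([[0.9], [0.8, 0.8],
                                            [0.80, 0.1, 0.1, 0.75]])
        assert terminal_ok(prof, "IGHV", tau=0.7, depth=depth)

    def test_terminal_right_below_tau(self):
        prof, depth = _profile_from_levels([[0.9], [0.8, 0.8],
                                            [0.80, 0.9, 0.9, 0.65]])
        assert not terminal_ok(prof, "IGHV", tau=0.7, depth=depth)

    def test_terminal_vacuous_at_zero_tau(self):
        prof, depth = _profile_from_levels([[0.9], [0.5, 0.5],
                                            [0.4, 0.4, 0.4, 0.4]])
        assert terminal_ok(prof, "IGHV", tau=0.0, depth=depth)


class TestMRScore:
    def test_zero_when_all_nodes_equal_root(self):
        prof, _ = _profile_from_levels([[0.8], [0.8, 0.8],
                                        [0.8, 0.8, 0.8, 0.8]])
        assert mr_consistency_score(prof, "IGHV", sigma=0.05) == 0.0

    def test_hand_computed_single_deviation(self):
        """Depth 1, p00 = 0.9, children {0.9, 0.4}, sigma = 0.1:
        score = (2/3) * (1 - exp(0.25 / 0.1))."""
        prof, _ = _profile_from_levels([[0.9], [0.9, 0.4]])
        expected = (2 / 3) * (1.0 - math.exp(0.25 / 0.1))
        got = mr_consistency_score(prof, "IGHV", sigma=0.1)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_deviation(self):
        scores = []
        for child in (0.9, 0.8, 0.6, 0.3, 0.0):
            prof, _ = _profile_from_levels([[0.9], [0.9, child]])
            scores.append(mr_consistency_score(prof, "IGHV", sigma=0.05))
        assert scores[0] == 0.0
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert all(s <= 0 for s in scores)

    def test_negated_variant_nonnegative_increasing(self):
        scores = []
        for child in (0.9, 0.6, 0.2):
            prof, _ = _profile_from_levels([[0.9], [0.9, child]])
            scores.append(mr_consistency_score(prof, "IGHV", sigma=0.05,
                                               sign="negated"))
        assert scores[0] == 0.0
        assert scores[1] < scores[2]

    def test_invalid_sigma_rejected(self):
        prof, _ = _profile_from_levels([[0.9], [0.9, 0.4]])
        with pytest.raises(ValueError):
            mr_consistency_score(prof, "IGHV", sigma=0.0)


class TestAssignLocus:
    def _cfg(self, **kw):
        return RunConfig(n_trees=10, **kw)

    def test_clear_winner_accepted(self):
        prof, _ = _profile_from_levels([[0.92], [0.92, 0.92],
                                        [0.92, 0.92, 0.92, 0.92]],
                                       locus="TRBV")
        out = assign_locus(prof, self._cfg())
        assert out.assigned_locus == "TRBV"
        assert out.accepted and not out.ambiguous
        assert out.mr_score == 0.0

    def test_below_p_min_not_accepted(self):
        prof, _ = _profile_from_levels([[0.55], [0.55, 0.55],
                                        [0.55, 0.55, 0.55, 0.55]],
                                       locus="TRBV")
        out = assign_locus(prof, self._cfg())
        assert out.assigned_locus == "TRBV" and not out.accepted

    def test_terminal_failure_blocks_acceptance(self):
        prof, _ = _profile_from_levels([[0.9], [0.9, 0.8],
                                        [0.9, 0.9, 0.9, 0.6]], locus="IGLV")
        out = assign_locus(prof, self._cfg(eps=0.5))
        assert not out.accepted

    def test_exact_tie_breaks_by_locus_order_and_flags(self):
        probs = {(k, (i, j)): 0.9 if k in ("IGKV", "TRGV") else 0.1
                 for k in LOCI for i in range(3) for j in range(2**i)}
        combined = {k: 0.9 if k in ("IGKV", "TRGV") else 0.1 for k in LOCI}
        prof = PredictionProfile(probs=probs, combined=combined)
        out = assign_locus(prof, self._cfg())
        assert out.assigned_locus == "IGKV"  # earlier in the fixed order
        assert out.ambiguous
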