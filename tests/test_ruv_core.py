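"""Replicate-anchored RUV: estimation algebra against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from hruv.ruv_core import (
    RuvError,
    adjust_group,
    build_replicate_matrix,
    mean_center,
    restore_mean,
    ruv3_adjust,
    select_negative_controls,
)
from hruv.synthetic import simulate_experiment
from .conftest import tiny_sim_config


def brute_force_ruv3(Z, indicator, controls, k):
    """Independent reference: explicit projector and least-squares formulas,
    each step spelled out with dense linear algebra."""
    M = indicator
    P_rep = M @ np.linalg.inv(M.T @ M) @ M.T
    R = np.eye(M.shape[0]) - P_rep
    resid = R @ Z
    _, _, vt = np.linalg.svd(resid)
    alpha = vt[:k, :]
    ac = alpha[:, controls]
    W = Z[:, controls] @ ac.T @ np.linalg.inv(ac @ ac.T)
    return Z - W @ alpha


class TestReplicateMap:
    def test_simple_groups(self):
        rm = build_replicate_matrix(["A", "A", "B"])
        assert rm.indicator.shape == (3, 2)
        assert list(rm.indicator.sum(axis=0)) == [2, 1]
        assert rm.replicated_groups() == ["A"]
        assert rm.residual_rank == 1

    def test_all_distinct_has_zero_residual_rank(self):
        rm = build_replicate_matrix(["a", "b", "c"])
        assert rm.residual_rank == 0
        np.testing.assert_array_equal(rm.indicator, np.eye(3))

    def test_empty_and_missing_labels_raise(self):
        with pytest.raises(RuvError):
            build_replicate_matrix([])
        with pytest.raises(RuvError):
            build_replicate_matrix(["a", None])


class TestMeanCenter:
    def test_constant_metabolite_becomes_zero(self):
        Y = np.full((4, 1), 3.5)
        Z, means = mean_center(Y)
        np.testing.assert_array_equal(Z, np.zeros((4, 1)))
        assert means[0] == 3.5

    def test_round_trip_exact(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(7, 5)) * 100
        Z, means = mean_center(Y)
        np.testing.assert_allclose(restore_mean(Z, means), Y, rtol=1e-14)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)


class TestRuv3Adjust:
    def test_k_zero_is_identity(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(6, 4))
        rm = build_replicate_matrix(["a", "a", "b", "b", "c", "d"])
        np.testing.assert_array_equal(ruv3_adjust(Z, rm, k=0), Z)

    def test_no_replicates_with_positive_k_raises(self):
        Z = np.zeros((3, 4))
        rm = build_replicate_matrix(["a", "b", "c"])
        with pytest.raises(RuvError, match="singleton"):
            ruv3_adjust(Z, rm, k=1)

    def test_k_above_rank_errors_or_caps(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(4, 5))
        rm = build_replicate_matrix(["a", "a", "b", "c"])
        with pytest.raises(RuvError):
            ruv3_adjust(Z, rm, k=3, k_policy="error")
        with pytest.warns(UserWarning, match="capping"):
            out = ruv3_adjust(Z, rm, k=3, k_policy="cap")
        assert out.shape == Z.shape

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, k, seed):
        """Random 10-measurement x 8-metabolite instances agree with the
        explicit projector/least-squares reference to 1e-10."""
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(10, 8))
        Z -= Z.mean(axis=0)
        rm = build_replicate_matrix(
            ["a", "a", "b", "b", "c", "c", "d", "e", "f", "g"]
        )
        controls = np.arange(8) if seed % 2 == 0 else np.array([0, 2, 4, 5, 6])
        expected = brute_force_ruv3(Z, rm.indicator, controls, k)
        got = ruv3_adjust(Z, rm, controls=controls, k=k)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_noiseless_factor_model_recovers_interest_part(self):
        """Y = X beta + W alpha with replicate pairs sharing X rows and
        controls carrying no biology: pairs agree and controls are cleaned."""
        rng = np.random.default_rng(3)
        S, Mm, k = 8, 6, 2
        groups = ["a", "a", "b", "b", "c", "c", "d", "d"]
        X = np.repeat(rng.normal(size=(4, 1)), 2, axis=0)
        beta = np.zeros((1, Mm))
        beta[0, :3] = rng.normal(size=3)  # metabolites 3..5 are controls
        W = rng.normal(size=(S, k))
        alpha = rng.normal(size=(k, Mm))
        Z = X @ beta + W @ alpha
        Z -= Z.mean(axis=0)
        rm = build_replicate_matrix(groups)
        out = ruv3_adjust(Z, rm, controls=np.array([3, 4, 5]), k=k)
        for i in range(0, S, 2):
            np.testing.assert_allclose(out[i], out[i + 1], atol=1e-6)
        np.testing.assert_allclose(out[:, 3:], np.zeros((S, 3)), atol=1e-6)

    def test_full_rank_k_enforces_replicate_agreement(self):
        """With controls = all and k = residual rank, noiseless replicate
        groups collapse to their means exactly."""
        rng = np.random.default_rng(4)
        groups = ["a", "a", "b", "b", "c", "d"]
        W = rng.normal(size=(6, 2))
        alpha = rng.normal(size=(2, 5))
        bio = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0])[:, None]
        Z = bio @ rng.normal(size=(1, 5)) + W @ alpha
        Z -= Z.mean(axis=0)
        rm = build_replicate_matrix(groups)
        out = ruv3_adjust(Z, rm, k=rm.residual_rank)
        for g in ("a", "b"):
            idx = [i for i, lbl in enumerate(groups) if lbl == g]
            np.testing.assert_allclose(out[idx[0]], out[idx[1]], atol=1e-8)


class TestAdjustGroup:
    def test_identical_batches_nearly_unchanged(self):
        """Two concatenated copies of one batch with honest replicate links
        carry no unwanted variation; adjustment is a near no-op."""
        rng = np.random.default_rng(5)
        half = rng.normal(size=(6, 5))
        Y = np.vstack([half, half])
        groups = [f"s{i}" for i in range(6)] * 2
        rm = build_replicate_matrix(groups)
        out = adjust_group(Y, rm, k=2)
        np.testing.assert_allclose(out, Y, atol=1e-6)

    def test_constant_offset_removed_via_cross_links(self):
        """Batches differing by a per-metabolite offset with 5 linking
        pairs: k=1 removes the offset to numerical zero (noiseless)."""
        rng = np.random.default_rng(6)
        n, m = 12, 7
        base = rng.normal(size=(n, m))
        delta = rng.normal(size=m) * 2
        # batch 2 re-measures the same biology shifted by delta; the first
        # 5 samples keep their labels (linking pairs), the rest are relabeled
        Y = np.vstack([base, base + delta])
        groups = (
            [f"s{i}" for i in range(n)]
            + [f"s{i}" for i in range(5)]
            + [f"t{i}" for i in range(5, n)]
        )
        rm = build_replicate_matrix(groups)
        out = adjust_group(Y, rm, k=1)
        gap_before = np.abs(Y[n:].mean(axis=0) - Y[:n].mean(axis=0))
        gap_after = np.abs(out[n:].mean(axis=0) - out[:n].mean(axis=0))
        assert gap_after.max() < 1e-6 * gap_before.max()

    def test_dimensions_preserved_and_reorder_invariance(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(8, 5))
        groups = ["a", "a", "b", "b", "c", "d", "e", "f"]
        rm = build_replicate_matrix(groups)
        out = adjust_group(Y, rm, k=1)
        assert out.shape == Y.shape
        perm = rng.permutation(8)
        rm_p = build_replicate_matrix([groups[i] for i in perm])
        out_p = adjust_group(Y[perm], rm_p, k=1)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-8)


class TestNegativeControlSelection:
    def test_trivial_and_error_cases(self, tiny_batches):
        batches, truth = tiny_batches
        pheno = truth.phenotype
        mets = list(batches[0].values.index)
        assert set(select_negative_controls(batches, pheno, len(mets))) == set(mets)
        with pytest.raises(RuvError):
            select_negative_controls(batches, pheno, len(mets) + 1)

    def test_strongly_affected_metabolites_are_excluded(self):
        """Metabolites carrying a large phenotype effect rank associated and
        drop out of the control set in most simulations."""
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = tiny_sim_config(seed=seed, n_metabolites=50, n_affected=5,
                                  effect_size=2.0, batch_shift_sd=0.5,
                                  technical_jitter_sd=0.1)
            batches, truth = simulate_experiment(cfg)
            chosen = select_negative_controls(batches, truth.phenotype, 40)
            if not set(truth.affected_set) & set(chosen):
                hits += 1
        assert hits >= int(0.75 * n_rep)

    def test_single_class_batch_skipped_with_warning(self, tiny_batches):
        batches, truth = tiny_batches
        pheno = pd.Series(1, index=truth.phenotype.index)  # one class only
        with pytest.raises(RuvError):
            select_negative_controls(batches, pheno, 5)
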