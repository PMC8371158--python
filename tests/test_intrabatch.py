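"""Within-batch drift correction: QC ratio, smoothers, short-replicate RUV."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hruv.intrabatch import (
    IntrabatchError,
    SmootherSpec,
    loess_smooth,
    parse_intra_tag,
    ratio_adjust,
    run_intrabatch,
    ruv_short,
    smooth_adjust,
)
from hruv.synthetic import simulate_experiment
from .conftest import tiny_sim_config, toy_batch


class TestRatioAdjust:
    def _batch(self):
        # runs 1..11: QC at run 1 (L) and run 11 (L+M, M=10)
        types = ["pooledQC"] + ["individual"] * 9 + ["pooledQC"]
        vals = np.array([[100.0, 200.0, 150, 120, 130, 140, 160, 170, 180,
                          190, 400.0]])
        return toy_batch(vals, sample_types=types, scale="raw")

    def test_early_half_divides_by_previous_qc(self):
        out = ratio_adjust(self._batch())
        # run 2 = L+1 <= L+M/2: s/P_L = 200/100
        assert out.values.iloc[0, 1] == pytest.approx(2.0)
        # run 6 = L+5, the boundary l <= L+M/2 maps to the previous QC
        assert out.values.iloc[0, 5] == pytest.approx(140 / 100)
        # run 7 = L+6 > L+M/2: next QC
        assert out.values.iloc[0, 6] == pytest.approx(160 / 400)

    def test_qc_measurement_maps_to_one(self):
        out = ratio_adjust(self._batch())
        assert out.values.iloc[0, 0] == pytest.approx(1.0)
        assert out.values.iloc[0, 10] == pytest.approx(1.0)
        assert out.scale == "ratio"

    def test_zero_qc_signal_raises_with_metabolite(self):
        b = self._batch()
        b.values.iloc[0, 0] = 0.0
        with pytest.raises(IntrabatchError, match="M1"):
            ratio_adjust(b)

    def test_log_scale_input_rejected(self):
        b = self._batch().copy_with(scale="log2")
        with pytest.raises(IntrabatchError, match="raw"):
            ratio_adjust(b)


class TestLoess:
    def test_matches_r_loess_on_fixture(self, tmp_path):
        """Direct comparison with R stats::loess (span 0.75, degree 2,
        gaussian family, exact surface) on a deterministic 20-point series."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(7)
        x = np.arange(1.0, 21.0)
        y = np.sin(x / 4.0) + 0.1 * rng.standard_normal(20)
        data = tmp_path / "xy.csv"
        pd.DataFrame({"x": x, "y": y}).to_csv(data, index=False)
        script = (
            f'd <- read.csv("{data}"); '
            'f <- loess(y ~ x, data=d, span=0.75, degree=2, '
            'family="gaussian", control=loess.control(surface="direct")); '
            'cat(sprintf("%.12f\\n", fitted(f)))'
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120,
        )
        r_fit = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(
            loess_smooth(x, y, x), r_fit, atol=1e-8
        )

    def test_reproduces_exact_polynomial(self):
        x = np.linspace(0, 10, 30)
        y = 1.0 - 0.4 * x + 0.03 * x**2
        np.testing.assert_allclose(loess_smooth(x, y, x), y, atol=1e-9)


class TestSmoothAdjust:
    def _drifting_batch(self, drift=lambda r: 0.1 * r, n=24, seed=0):
        rng = np.random.default_rng(seed)
        types = (["individual"] * 5 + ["pooledQC"]) * (n // 6)
        base = rng.normal(10, 0.3, size=(3, n))
        runs = np.arange(1, n + 1)
        vals = base + drift(runs)[None, :]
        return toy_batch(vals, sample_types=types)

    def test_constant_signal_unchanged(self):
        types = ["individual"] * 8 + ["pooledQC"] * 4
        b = toy_batch(np.full((2, 12), 7.0), sample_types=types)
        for spec in (SmootherSpec("loess", "all_samples"),
                     SmootherSpec("rlm", "all_samples"),
                     SmootherSpec("rlm", "pooled_qc")):
            out = smooth_adjust(b, spec)
            np.testing.assert_allclose(out.values.to_numpy(), 7.0, atol=1e-8)

    def test_rlm_removes_exact_linear_drift(self):
        types = ["individual"] * 20
        runs = np.arange(1, 21)
        vals = (2.0 + 0.1 * runs)[None, :]
        b = toy_batch(vals, sample_types=types)
        out = smooth_adjust(b, SmootherSpec("rlm", "all_samples"))
        med = np.median(vals)
        np.testing.assert_allclose(out.values.to_numpy(), med, atol=1e-8)
        slope = np.polyfit(runs, out.values.to_numpy()[0], 1)[0]
        assert abs(slope) < 1e-8

    def test_adjustment_is_median_minus_fit(self):
        """The corrected value equals input + (batch median - fitted value)
        elementwise, with the fit recomputed independently."""
        b = self._drifting_batch()
        out = smooth_adjust(b, SmootherSpec("loess", "all_samples"))
        ann = b.annotation
        scope = ann.index[ann["sample_type"] == "individual"]
        runs_all = ann["run_index"].to_numpy(dtype=float)
        for met in b.values.index:
            x = ann.loc[scope, "run_index"].to_numpy(dtype=float)
            y = b.values.loc[met, scope].to_numpy()
            fitted = loess_smooth(x, y, np.clip(runs_all, x.min(), x.max()))
            med = np.median(b.values.loc[met])
            np.testing.assert_allclose(
                out.values.loc[met].to_numpy(),
                b.values.loc[met].to_numpy() + (med - fitted),
                atol=1e-10,
            )

    def test_pooled_qc_scope_uses_qc_fit_for_all_samples(self):
        # QC rows carry drift 0.2*run; biological samples drift differently,
        # but the correction must come from the QC fit evaluated at their runs
        types = (["individual"] * 2 + ["pooledQC"]) * 8
        runs = np.arange(1, 25, dtype=float)
        vals = np.where(
            np.array(types) == "pooledQC", 5.0 + 0.2 * runs, 8.0 + 0.2 * runs
        )[None, :]
        b = toy_batch(vals, sample_types=types)
        out = smooth_adjust(b, SmootherSpec("rlm", "pooled_qc"))
        resid = out.values.to_numpy()[0] - np.where(
            np.array(types) == "pooledQC", 0.0, 3.0
        )
        assert np.ptp(resid) < 1e-6  # drift gone, QC/sample gap intact

    def test_monotone_drift_rank_correlation_flattened(self):
        rng = np.random.default_rng(3)
        b = self._drifting_batch(
            drift=lambda r: 0.08 * r, n=48, seed=4
        )
        out = smooth_adjust(b, SmootherSpec("loess", "all_samples"))
        runs = b.annotation["run_index"].to_numpy()
        for met in out.values.index:
            rho = stats.spearmanr(runs, out.values.loc[met]).statistic
            assert abs(rho) < 0.1

    def test_too_few_scope_points_raise(self):
        types = ["individual"] * 6 + ["pooledQC"] * 3
        b = toy_batch(np.ones((1, 9)), sample_types=types)
        with pytest.raises(IntrabatchError, match=">= 4"):
            smooth_adjust(b, SmootherSpec("loess", "pooled_qc"))


class TestRuvShort:
    def _batch_with_pairs(self, seed=0):
        cfg = tiny_sim_config(seed=seed, n_batches=1, noise_sd=0.05)
        batches, _ = simulate_experiment(cfg)
        return batches[0]

    def test_k_zero_identity_and_dims(self):
        b = self._batch_with_pairs()
        out = ruv_short(b, k=0)
        pd.testing.assert_frame_equal(out.values, b.values)
        out = ruv_short(b, k=2)
        assert out.values.shape == b.values.shape

    def test_rank1_unwanted_factor_removed(self):
        """A rank-1 unwanted factor orthogonal to biology, revealed by a
        replicate pair, is eliminated: the pair agrees to 1e-6."""
        rng = np.random.default_rng(8)
        m = 6
        bio = rng.normal(10, 1, size=(m, 4))
        bio = np.column_stack([bio, bio[:, 0]])  # column 4 replicates 0
        w = np.array([0.3, -0.1, 0.4, 0.2, 0.9])
        alpha = rng.normal(size=m)
        vals = bio + np.outer(alpha, w)
        types = ["individual"] * 4 + ["shortReplicate"]
        groups = ["S0", "S1", "S2", "S3", "S0"]
        b = toy_batch(vals, sample_types=types, groups=groups)
        out = ruv_short(b, k=1)
        np.testing.assert_allclose(
            out.values.iloc[:, 4], out.values.iloc[:, 0], atol=1e-6
        )

    def test_no_pairs_instructs_to_skip(self):
        b = toy_batch(np.ones((2, 4)), sample_types=["individual"] * 4)
        with pytest.raises(IntrabatchError, match="skip"):
            ruv_short(b, k=1)


class TestTags:
    @pytest.mark.parametrize(
        "tag,kind,scope,short",
        [
            ("loessSampleShort", "loess", "all_samples", True),
            ("loessAllShort", "loess", "all_samples", True),
            ("rlmShort", "rlm", "pooled_qc", True),
            ("rlm", "rlm", "pooled_qc", False),
            ("loess", "loess", "pooled_qc", False),
            ("rlmSample", "rlm", "all_samples", False),
        ],
    )
    def test_tag_grammar(self, tag, kind, scope, short):
        spec = parse_intra_tag(tag)
        assert (spec.kind, spec.scope, spec.short_ruv) == (kind, scope, short)

    def test_unknown_tag_lists_valid_ones(self):
        with pytest.raises(IntrabatchError, match="loessSampleShort"):
            parse_intra_tag("foo")

    def test_ratio_on_log_scale_errors(self):
        b = toy_batch(np.ones((1, 6)),
                      sample_types=["pooledQC"] + ["individual"] * 5)
        with pytest.raises(IntrabatchError, match="raw"):
            run_intrabatch(b, "ratio")

    def test_run_intrabatch_applies_smoother_then_ruv(self):
        cfg = tiny_sim_config(seed=5, n_batches=1)
        batches, _ = simulate_experiment(cfg)
        out = run_intrabatch(batches[0], "loessSampleShort", k=2)
        assert out.values.shape == batches[0].values.shape
        assert not out.values.equals(batches[0].values)
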