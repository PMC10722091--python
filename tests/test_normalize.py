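"""Cyclic loess and empirical-Bayes batch correction."""

import numpy as np
import pandas as pd
import pytest

from abarray.core import AntigenMatrix, ValidationError
from abarray.normalize import LoessConfig, cyclic_loess, eb_batch_correct
from abarray import simulate


def _matrix(values, stage="ncf"):
    vals = pd.DataFrame(
        values,
        index=[f"A{i}" for i in range(values.shape[0])],
        columns=[f"S{i}" for i in range(values.shape[1])],
    )
    return AntigenMatrix(vals, pd.DataFrame(True, index=vals.index, columns=vals.columns), stage)


def _manifest(n, batches=("2021",), groups=("control", "dementia")):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "group": [groups[(i // 2) % len(groups)] for i in range(n)],
            "age": 70.0 + (np.arange(n) % 7),
            "sex": ["F", "M"][0],
            "diabetes": False,
            "batch": [batches[i % len(batches)] for i in range(n)],
            "moca_raw": 25,
            "low_education": False,
        }
    ).set_index("sample_id", drop=False)


def max_residual_trend(m: AntigenMatrix, span=0.7) -> float:
    """Post-hoc per-sample M-on-A trend magnitude against the row mean."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    X = m.masked_values().to_numpy()
    ref = np.nanmean(X, axis=1)
    worst = 0.0
    for j in range(X.shape[1]):
        M = X[:, j] - ref
        A = (X[:, j] + ref) / 2
        fit = lowess(M, A, frac=span, it=0, return_sorted=False)
        worst = max(worst, float(np.max(np.abs(fit))))
    return worst


class TestCyclicLoess:
    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.normal(8, 1.5, 200)
        m = _matrix(np.column_stack([col, col]))
        out = cyclic_loess(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-9)
        assert out.stage == "loess"

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 1.5, 300)
        vals = np.column_stack([base, base + 0.8, base - 0.8])
        out = cyclic_loess(_matrix(vals))
        col_means = out.values.mean(axis=0)
        assert np.ptp(col_means.to_numpy()) < 0.01

    def test_smooth_intensity_bias_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(8, 1.5, 400)
        biased = base + 0.4 * ((base - 8) / 4) ** 2
        vals = np.column_stack([base, biased, base + rng.normal(0, 0.05, 400)])
        m = _matrix(vals)
        before = max_residual_trend(m)
        after = max_residual_trend(cyclic_loess(m))
        assert after < 0.1 * before

    def test_preserves_row_means_under_mean_zero_bias(self):
        # shared antigen baselines + small per-cell noise: the M-vs-A fit has
        # no systematic trend, so antigen means must be (nearly) preserved.
        # (With large per-cell noise, loess regression-to-the-mean shifts
        # every sample identically per antigen — harmless for contrasts but
        # not mean-preserving, so that regime is not asserted here.)
        rng = np.random.default_rng(3)
        base = rng.normal(8, 1.5, 250)[:, None] + rng.normal(0, 0.1, (250, 20))
        m = _matrix(base)
        out = cyclic_loess(m)
        drift = (out.values.mean(axis=1) - m.values.mean(axis=1)).abs()
        assert drift.mean() < 0.02

    def test_requires_ncf_stage_and_enough_antigens(self):
        m = _matrix(np.zeros((5, 3)) + np.arange(5)[:, None].astype(float))
        with pytest.raises(ValidationError, match="fewer than 10|valid antigens"):
            cyclic_loess(m)
        good = _matrix(np.random.default_rng(0).normal(8, 1, (30, 3)), stage="consensus")
        with pytest.raises(ValidationError, match="stage"):
            cyclic_loess(good)

    def test_pairs_variant_agrees_on_constant_offsets(self):
        rng = np.random.default_rng(4)
        base = rng.normal(8, 1.5, 200)
        vals = np.column_stack([base, base + 0.6, base - 0.6])
        out = cyclic_loess(_matrix(vals), LoessConfig(method="pairs"))
        assert np.ptp(out.values.mean(axis=0).to_numpy()) < 0.02

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(8, 1.5, (150, 4))
        a = cyclic_loess(_matrix(vals)).values
        b = cyclic_loess(_matrix(vals)).values
        pd.testing.assert_frame_equal(a, b)


class TestBatchCorrection:
    def _batched_matrix(self, n_ag=200, n_per_batch=30, gamma=0.8, delta2=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_batch
        base = rng.normal(8, 1.5, n_ag)
        noise = rng.normal(0, 0.5, (n_ag, n))
        batch2 = np.arange(n) % 2 == 1
        vals = base[:, None] + noise
        vals[:, batch2] += gamma
        vals[:, batch2] += noise[:, batch2] * (np.sqrt(delta2) - 1)
        m = _matrix(vals, stage="loess")
        manifest = _manifest(n, batches=("2021", "2022"))
        return m, manifest, batch2

    def test_single_batch_identity(self):
        m, manifest, _ = self._batched_matrix()
        manifest["batch"] = "2021"
        out, model = eb_batch_correct(m, manifest)
        assert model is None
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.stage == "batch_corrected"

    def test_gamma_recovered_and_batch_difference_removed(self):
        m, manifest, batch2 = self._batched_matrix(gamma=0.8, seed=1)
        out, model = eb_batch_correct(m, manifest)
        # estimated location effect on the data scale (difference between batches)
        est = (
            model.gamma_star.loc["2022"] - model.gamma_star.loc["2021"]
        ) * np.sqrt(model.var_pooled)
        assert abs(est.mean() - 0.8) < 0.1
        diff = (
            out.values.loc[:, batch2].mean(axis=1)
            - out.values.loc[:, ~batch2].mean(axis=1)
        )
        # the systematic batch offset is removed; per-antigen residuals are
        # sampling noise partially retained by EB shrinkage
        assert abs(diff.mean()) < 0.05
        assert diff.abs().mean() < 0.1

    def test_variance_inflation_deflated(self):
        # batches large enough that F-sampling noise of the per-batch
        # variances does not swamp the band being checked
        m, manifest, batch2 = self._batched_matrix(
            n_ag=150, n_per_batch=250, gamma=0.0, delta2=4.0, seed=2
        )
        out, _ = eb_batch_correct(m, manifest)
        v2 = out.values.loc[:, batch2].var(axis=1, ddof=1)
        v1 = out.values.loc[:, ~batch2].var(axis=1, ddof=1)
        ratio = v2 / v1
        assert (ratio.between(0.8, 1.25)).mean() >= 0.9

    def test_group_effect_protected(self):
        # planted group effect must survive correction even though the
        # batch estimate is taken on group-containing data
        rng = np.random.default_rng(3)
        n_ag, n = 150, 60
        base = rng.normal(8, 1.5, n_ag)
        vals = base[:, None] + rng.normal(0, 0.5, (n_ag, n))
        manifest = _manifest(n, batches=("2021", "2022"))
        dem = (manifest["group"] == "dementia").to_numpy()
        vals[:30, dem] += 1.0  # planted effect on 30 antigens
        batch2 = (manifest["batch"] == "2022").to_numpy()
        vals[:, batch2] += 0.8
        out, _ = eb_batch_correct(_matrix(vals, stage="loess"), manifest)
        realized = (
            out.values.iloc[:30].loc[:, dem].mean(axis=1)
            - out.values.iloc[:30].loc[:, ~dem].mean(axis=1)
        )
        assert abs(realized.mean() - 1.0) < 0.1

    def test_confounded_batch_rejected(self):
        m, manifest, _ = self._batched_matrix()
        manifest["batch"] = np.where(manifest["group"] == "dementia", "2022", "2021")
        with pytest.raises(ValidationError, match="confounded"):
            eb_batch_correct(m, manifest)

    def test_deterministic(self):
        m, manifest, _ = self._batched_matrix(seed=4)
        a, _ = eb_batch_correct(m, manifest)
        b, _ = eb_batch_correct(m, manifest)
        pd.testing.assert_frame_equal(a.values, b.values)
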