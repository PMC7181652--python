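"""WA-PLS fitting, prediction, bootstrap validation, reconstruction."""

import numpy as np
import pandas as pd
import pytest

from palaeocoast import synthetic
from palaeocoast.errors import PredictionError, ValidationError
from palaeocoast.wapls import (
    CrossValidation,
    TrainingSet,
    bootstrap_validate,
    fit_wapls,
    predict,
    reconstruct_salinity,
)


def classical_wa_inverse(Y, x):
    """Independent oracle: classical WA regression + inverse deshrinking.

    Operates on relative composition with ordinary least-squares
    deshrinking (sample weights are equal after closure).
    """
    P = Y / Y.sum(axis=1, keepdims=True)
    optima = (P.T @ x) / P.sum(axis=0)
    wa = (P @ optima) / P.sum(axis=1)
    X = np.column_stack([np.ones_like(wa), wa])
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    return X @ coef


def one_to_one_set(n=6, reps=1):
    """Each sample holds exactly one taxon, each taxon one sample group."""
    env = np.repeat(np.linspace(2.0, 12.0, n), reps)
    Y = np.kron(np.eye(n), np.ones((reps, 1))) * 5.0
    return TrainingSet(Y, env, [f"t{i}" for i in range(n)], transform="none")


class TestFit:
    def test_one_taxon_per_sample_is_exact(self):
        ts = one_to_one_set()
        m = fit_wapls(ts, 1)
        assert m.apparent_rmse[0] == pytest.approx(0.0, abs=1e-10)
        pred = predict(m, ts.abundances, k=1, taxon_names=ts.taxon_names)
        assert np.allclose(pred, ts.env, atol=1e-10)

    def test_component1_equals_classical_wa(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        pred1 = predict(m, ts.abundances, k=1, taxon_names=ts.taxon_names)
        oracle = classical_wa_inverse(ts.abundances, ts.env_transformed())
        assert np.abs(pred1 - oracle).max() < 1e-8

    def test_standard_set_apparent_r2(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        assert m.apparent_r2[1] >= 0.9

    def test_apparent_rmse_nonincreasing(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 4)
        assert np.all(np.diff(m.apparent_rmse) <= 1e-12)

    def test_scale_equivariance(self, std_training):
        """Per-assemblage rescaling leaves the fitted model unchanged."""
        ts, _ = std_training
        scale = np.random.default_rng(0).uniform(0.2, 5.0,
                                                 size=(ts.n_samples, 1))
        ts2 = TrainingSet(ts.abundances * scale, ts.env, ts.taxon_names,
                          transform=ts.transform)
        m1, m2 = fit_wapls(ts, 2), fit_wapls(ts2, 2)
        assert np.allclose(m1.beta, m2.beta, atol=1e-10)
        assert np.allclose(m1.intercepts, m2.intercepts, atol=1e-10)

    def test_optima_recovery(self, std_training):
        """Component-1 taxon scores track the true niche optima."""
        ts, truth = std_training
        m = fit_wapls(ts, 2)
        r = np.corrcoef(m.taxon_scores[:, 0], truth.params["optima"])[0, 1]
        assert r >= 0.95

    def test_degenerate_component_named(self):
        # one taxon, constant composition: component 1 has no variance
        Y = np.ones((8, 2))
        ts = TrainingSet(Y, np.linspace(0, 7, 8), ["a", "b"])
        with pytest.raises(Exception, match="component 1"):
            fit_wapls(ts, 1)


class TestPredict:
    def test_in_sample_identity(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        fitted = predict(m, ts.abundances, taxon_names=ts.taxon_names)
        row = predict(m, ts.abundances[3], taxon_names=ts.taxon_names)
        assert row[0] == pytest.approx(fitted[3], abs=1e-10)

    def test_column_permutation_invariance(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        df = pd.DataFrame(ts.abundances, columns=ts.taxon_names)
        perm = df.sample(frac=1.0, axis=1, random_state=4)
        assert np.allclose(predict(m, df), predict(m, perm), atol=1e-12)

    def test_unknown_taxa_dropped_with_warning(self, std_training, caplog):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        df = pd.DataFrame(ts.abundances, columns=ts.taxon_names)
        df["ghost_taxon"] = 3.0
        with caplog.at_level("WARNING"):
            out = predict(m, df)
        assert "ghost_taxon" in caplog.text
        assert out.shape == (ts.n_samples,)

    def test_all_unknown_row_raises(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        with pytest.raises(PredictionError):
            predict(m, np.ones((1, 2)), taxon_names=["x", "y"])


class TestBootstrap:
    def test_perfectly_learnable_rmsep_near_zero(self):
        ts = one_to_one_set(n=6, reps=10)
        cv = bootstrap_validate(ts, 1, n_boot=30, seed=1)
        assert cv.rmsep_boot[0] < 1e-6

    def test_optimism_inequality_over_seeded_sets(self):
        """Out-of-bag RMSEP >= apparent RMSE at the same component count."""
        for seed in range(20):
            ts, _ = synthetic.make_training_set(
                n_samples=70, n_taxa=18, seed=seed)
            m = fit_wapls(ts, 2)
            cv = bootstrap_validate(ts, 2, n_boot=25, seed=seed)
            assert np.all(cv.rmsep_boot >= m.apparent_rmse - 1e-12), seed

    def test_seed_determinism(self, std_training):
        ts, _ = std_training
        a = bootstrap_validate(ts, 2, n_boot=20, seed=7)
        b = bootstrap_validate(ts, 2, n_boot=20, seed=7)
        assert np.array_equal(a.rmsep_boot, b.rmsep_boot)
        assert np.array_equal(a.r2_boot, b.r2_boot)

    def test_s1_s2_decomposition_reported(self, std_training):
        ts, _ = std_training
        cv = bootstrap_validate(ts, 2, n_boot=30, seed=2)
        assert np.all(cv.s1 >= 0) and np.all(cv.s2 >= 0)
        assert isinstance(cv, CrossValidation)


class TestReconstruct:
    @staticmethod
    def _cv(rmsep):
        return CrossValidation(n_boot=1, rmsep_boot=np.asarray(rmsep),
                               r2_boot=np.zeros(len(rmsep)),
                               s1=np.zeros(len(rmsep)), s2=np.zeros(len(rmsep)))

    def test_backtransform_arithmetic(self):
        ts = one_to_one_set()
        ts = TrainingSet(ts.abundances, ts.env ** 2, ts.taxon_names,
                         transform="sqrt")
        m = fit_wapls(ts, 1)
        # model predicts env on sqrt scale; a training row with sqrt env 4
        i = int(np.argmin(np.abs(ts.env_transformed() - 4.0)))
        rec = reconstruct_salinity(m, self._cv([0.44]), ts.abundances[[i]],
                                   modern_reference=12.0, k=1,
                                   taxon_names=ts.taxon_names)
        est_t = predict(m, ts.abundances[[i]], k=1,
                        taxon_names=ts.taxon_names)[0]
        assert rec.estimate[0] == pytest.approx(est_t ** 2, abs=1e-10)
        assert rec.deviation_from_modern[0] == pytest.approx(
            est_t ** 2 - 12.0, abs=1e-10)
        assert rec.bootstrap_se[0] == pytest.approx(2 * abs(est_t) * 0.44,
                                                    abs=1e-10)

    def test_modern_fixed_point(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 2)
        pred_t = predict(m, ts.abundances, taxon_names=ts.taxon_names)
        modern = float(pred_t[5] ** 2)
        rec = reconstruct_salinity(m, self._cv([0.1, 0.1]),
                                   ts.abundances[[5]], modern,
                                   taxon_names=ts.taxon_names)
        assert rec.deviation_from_modern[0] == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_at_known_salinity(self, std_training):
        """Fossil assemblages drawn at salinity 20 reconstruct ~ +5 vs 15."""
        ts, truth = std_training
        m = fit_wapls(ts, 2)
        cv = bootstrap_validate(ts, 2, n_boot=50, seed=3)
        rng = np.random.default_rng(17)
        t = truth.params
        lam = t["max_abundance"] * np.exp(
            -((20.0 - np.asarray(t["optima"])[None, :]) ** 2)
            / (2.0 * np.asarray(t["tolerances"])[None, :] ** 2))
        fossil = rng.poisson(np.repeat(lam, 40, axis=0)).astype(float)
        fossil = fossil[fossil.sum(axis=1) > 0]
        rec = reconstruct_salinity(m, cv, fossil, modern_reference=15.0,
                                   taxon_names=ts.taxon_names)
        se = rec.deviation_from_modern.std(ddof=1) / np.sqrt(len(fossil))
        bse = float(rec.bootstrap_se.mean())
        assert rec.deviation_from_modern.mean() == pytest.approx(
            5.0, abs=2 * max(se, bse))

    def test_missing_modern_reference(self, std_training):
        ts, _ = std_training
        m = fit_wapls(ts, 1)
        with pytest.raises(ValidationError):
            reconstruct_salinity(m, None, ts.abundances[[0]], None,
                                 taxon_names=ts.taxon_names)


class TestRMSEPShape:
    def test_component2_beats_component1_on_standard_set(self, std_training):
        ts, _ = std_training
        cv = bootstrap_validate(ts, 2, n_boot=100, seed=5)
        assert cv.rmsep_boot[1] < cv.rmsep_boot[0]
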