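"""RR-BLUP fitting, hybrid prediction and training-set management."""

import numpy as np
import pytest

from rrsim import (TrainingSet, code_genotypes, fit_rrblup,
                   hybrid_codes_from_lines, predict_hybrids,
                   update_training_set_gpo)
from rrsim.exceptions import FittingError


def _nc2_data(rng, n_lines_a=20, n_lines_b=20, p=60, su=0.3, se=0.5,
              dominance=None):
    """Factorial (NC II) single-cross data with known marker effects."""
    ga = rng.choice([-1, 1], size=(n_lines_a, p)).astype(np.int8)
    gb = rng.choice([-1, 1], size=(n_lines_b, p)).astype(np.int8)
    ii, jj = np.meshgrid(np.arange(n_lines_a), np.arange(n_lines_b), indexing="ij")
    G, T = hybrid_codes_from_lines(ga[ii.ravel()], gb[jj.ravel()])
    u = rng.normal(0, su, p)
    signal = G @ u
    if dominance is not None:
        signal = signal + T @ rng.normal(0, dominance, p)
    y = signal + rng.normal(0, se, len(G))
    return ga, gb, G, T, y, u


class TestCoding:
    def test_additive_and_dominance_codes(self, rng):
        haps = rng.integers(0, 2, size=(30, 2, 50)).astype(np.uint8)
        sites = np.arange(0, 50, 2)
        G, T = code_genotypes(haps, sites)
        assert set(np.unique(G)) <= {-1, 0, 1}
        assert set(np.unique(T)) <= {0, 1}
        het = haps[:, 0, sites] != haps[:, 1, sites]
        assert np.array_equal(T.astype(bool), het)
        assert np.array_equal(T == 1, G == 0)  # biallelic: het iff G == 0
        # coding change oracle: (G + 1) equals allele-count dosage
        assert np.array_equal(G + 1, haps[:, :, sites].sum(axis=1, dtype=np.int8))

    def test_inbred_line_has_zero_dominance_row(self, rng):
        hap = rng.integers(0, 2, 40).astype(np.uint8)
        haps = np.stack([hap, hap])[None]
        _, T = code_genotypes(haps, np.arange(40))
        assert not T.any()

    def test_deduced_hybrid_codes(self):
        ga = np.array([[1, -1, 1, -1]], dtype=np.int8)
        gb = np.array([[1, 1, -1, -1]], dtype=np.int8)
        G, T = hybrid_codes_from_lines(ga, gb)
        assert np.array_equal(G[0], [1, 0, 0, -1])
        assert np.array_equal(T[0], [0, 1, 1, 0])


class TestFitRRBLUP:
    def test_fixed_lambda_matches_dense_normal_equations(self, rng):
        # 8 hybrids x 5 SNPs, lambda fixed: u_hat = (Z'Z + lam I)^-1 Z'y
        G = rng.choice([-1, 0, 1], size=(8, 5)).astype(np.int8)
        T = (G == 0).astype(np.int8)
        y = rng.normal(size=8)
        ts = TrainingSet(G, T, y, np.zeros(8, dtype=np.int32))
        lam = 2.5
        model = fit_rrblup(ts, "A", ridge_lambda=lam)
        Z = G.astype(float)
        yc = y - y.mean()
        expected = np.linalg.solve(Z.T @ Z + lam * np.eye(5), Z.T @ yc)
        assert np.allclose(model.u, expected, atol=1e-10)

    def test_fixed_lambda_ad_matches_joint_dense_solve(self, rng):
        G = rng.choice([-1, 0, 1], size=(12, 6)).astype(np.int8)
        T = (G == 0).astype(np.int8)
        y = rng.normal(size=12)
        ts = TrainingSet(G, T, y, np.zeros(12, dtype=np.int32))
        model = fit_rrblup(ts, "AD", ridge_lambda=1.5, ridge_lambda_d=4.0)
        Z = np.hstack([G, T]).astype(float)
        yc = y - y.mean()
        penalty = np.diag([1.5] * 6 + [4.0] * 6)
        expected = np.linalg.solve(Z.T @ Z + penalty, Z.T @ yc)
        assert np.allclose(np.concatenate([model.u, model.d]), expected, atol=1e-10)

    def test_infinite_shrinkage_limit(self, rng):
        G = rng.choice([-1, 0, 1], size=(10, 4)).astype(np.int8)
        y = rng.normal(size=10)
        ts = TrainingSet(G, (G == 0).astype(np.int8), y, np.zeros(10, dtype=np.int32))
        model = fit_rrblup(ts, "A", ridge_lambda=1e12)
        assert np.all(np.abs(model.u) < 1e-9)
        assert np.allclose(model.predict(G), y.mean(), atol=1e-6)

    def test_reml_recovers_variance_ratio(self):
        rng = np.random.default_rng(42)
        _, _, G, T, y, _ = _nc2_data(rng, 25, 25, 80, su=0.2, se=0.8)
        ts = TrainingSet(G, T, y, np.zeros(len(y), dtype=np.int32))
        model = fit_rrblup(ts, "A")
        # true lambda = se2 / su2 = 0.64 / 0.04 = 16
        assert 5 < model.ridge_lambda < 50

    def test_prediction_equivariant_to_phenotype_shift(self, rng):
        _, _, G, T, y, _ = _nc2_data(rng)
        ts1 = TrainingSet(G, T, y, np.zeros(len(y), dtype=np.int32))
        ts2 = TrainingSet(G, T, y + 100.0, np.zeros(len(y), dtype=np.int32))
        m1 = fit_rrblup(ts1, "A", ridge_lambda=3.0)
        m2 = fit_rrblup(ts2, "A", ridge_lambda=3.0)
        assert np.allclose(m2.predict(G), m1.predict(G) + 100.0, atol=1e-8)

    def test_additive_and_ad_agree_without_dominance(self):
        rng = np.random.default_rng(11)
        ga, gb, G, T, y, _ = _nc2_data(rng, 30, 30, 80, su=0.3, se=0.3)
        ts = TrainingSet(G, T, y, np.zeros(len(y), dtype=np.int32))
        pa = fit_rrblup(ts, "A").predict(G, T)
        pad = fit_rrblup(ts, "AD").predict(G, T)
        assert np.corrcoef(pa, pad)[0, 1] > 0.99

    def test_accuracy_positive_and_grows_with_training_size(self):
        rng = np.random.default_rng(17)
        ga, gb, G, T, y, u = _nc2_data(rng, 40, 40, 100, su=0.25, se=0.6)
        n = len(y)
        holdout = np.arange(0, n, 2)
        train = np.setdiff1d(np.arange(n), holdout)
        true_held = G[holdout].astype(float) @ u

        def acc(n_train):
            sub = train[:n_train]
            ts = TrainingSet(G[sub], T[sub], y[sub], np.zeros(n_train, dtype=np.int32))
            m = fit_rrblup(ts, "A")
            return np.corrcoef(m.predict(G[holdout]), true_held)[0, 1]

        small, large = acc(60), acc(800)
        assert small > 0
        assert large > small

    def test_degenerate_training_sets_raise(self):
        with pytest.raises(FittingError):
            fit_rrblup(TrainingSet(np.zeros((1, 4), dtype=np.int8),
                                   np.zeros((1, 4), dtype=np.int8),
                                   np.zeros(1), np.zeros(1, dtype=np.int32)), "A")
        zeros = TrainingSet(np.zeros((6, 4), dtype=np.int8),
                            np.zeros((6, 4), dtype=np.int8),
                            np.arange(6.0), np.zeros(6, dtype=np.int32))
        with pytest.raises(FittingError):
            fit_rrblup(zeros, "A")


class TestPredictHybrids:
    def test_factorial_size_and_deduction_consistency(self, rng):
        ga, gb, G, T, y, _ = _nc2_data(rng, 8, 6, 30)
        ts = TrainingSet(G, T, y, np.zeros(len(y), dtype=np.int32))
        model = fit_rrblup(ts, "AD", ridge_lambda=2.0, ridge_lambda_d=2.0)
        pred = predict_hybrids(model, ga, gb)
        assert pred.shape == (8, 6)
        # same predictions via explicit per-hybrid deduced codes
        ii, jj = np.meshgrid(np.arange(8), np.arange(6), indexing="ij")
        Gh, Th = hybrid_codes_from_lines(ga[ii.ravel()], gb[jj.ravel()])
        assert np.allclose(pred.ravel(), model.predict(Gh, Th), atol=1e-10)

    def test_zero_effects_predict_training_mean(self, rng):
        ga, gb, G, T, y, _ = _nc2_data(rng, 5, 5, 20)
        ts = TrainingSet(G, T, y, np.zeros(len(y), dtype=np.int32))
        model = fit_rrblup(ts, "A", ridge_lambda=1e12)
        pred = predict_hybrids(model, ga, gb)
        assert np.allclose(pred, y.mean(), atol=1e-6)


class TestGPOWindow:
    def _ts(self, tags):
        n = len(tags)
        return TrainingSet(np.zeros((n, 3), dtype=np.int8),
                           np.zeros((n, 3), dtype=np.int8),
                           np.arange(float(n)),
                           np.asarray(tags, dtype=np.int32))

    def _add(self, ts, cycle, n=2):
        return update_training_set_gpo(ts, np.zeros((n, 3), dtype=np.int8),
                                       np.zeros((n, 3), dtype=np.int8),
                                       np.zeros(n), cycle)

    def test_window_slides_after_three_cycles(self):
        ts = self._ts([1, 1, 2, 2, 3, 3])
        out = self._add(ts, 4)
        assert set(out.tags) == {2, 3, 4}

    def test_everything_retained_below_window(self):
        ts = self._ts([0, 0])
        out = self._add(ts, 1)
        assert set(out.tags) == {0, 1}
        assert len(out) == 4

    def test_idempotent_on_repeated_tag(self):
        ts = self._ts([1, 2, 3])
        out = self._add(self._ts([1, 2, 3]), 3)
        assert set(out.tags) == {1, 2, 3}
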