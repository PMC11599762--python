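"""PLSC: subdomain aggregation, SVD, permutation, bootstrap, robustness."""

import numpy as np
import pandas as pd
import pytest

from hobrain import (bootstrap_salience, covariance_explained,
                     permutation_significance, plsc, robustness_loop,
                     subdomain_scores)
from hobrain.behavior import PLSCResult
from hobrain.errors import DegenerateSignalError, DimensionError


def planted_xy(rng, s=60, f=30, q=5, strength=3.0, noise=0.1):
    # column-centered orthonormal features make the noise-free rank-1
    # recovery exact (X'X proportional to the identity)
    m = rng.normal(size=(s, f))
    x = np.linalg.qr(m - m.mean(axis=0))[0]
    w = np.zeros(f)
    w[:4] = [2.0, -1.0, 1.5, 0.5]
    w /= np.linalg.norm(w)
    u = np.ones(q) / np.sqrt(q)
    latent = (x - x.mean(0)) @ w
    latent /= latent.std(ddof=1)
    y = strength * np.outer(latent, u) + noise * rng.normal(size=(s, q))
    return x, y, w, u


class TestSubdomainScores:
    def test_single_score_subdomains_pass_through_zscored(self, rng):
        raw = pd.DataFrame({"a": rng.normal(2, 3, 40), "b": rng.normal(size=40)})
        table = subdomain_scores(raw, {"memory": ["a"], "speed": ["b"]})
        np.testing.assert_allclose(table.values.mean(axis=0), 0.0, atol=1e-12)
        expect = (raw["a"] - raw["a"].mean()) / raw["a"].std(ddof=1)
        np.testing.assert_allclose(table.values[:, 0], expect, atol=1e-12)

    def test_duplicate_columns_pc1_explains_everything(self, rng):
        a = rng.normal(size=50)
        raw = pd.DataFrame({"x1": a, "x2": a + 0.0})
        table = subdomain_scores(raw, {"exec": ["x1", "x2"]})
        za = (a - a.mean()) / a.std(ddof=1)
        # PC1 of two identical z-scored columns is proportional to either
        assert abs(np.corrcoef(table.values[:, 0], za)[0, 1]) == pytest.approx(1.0)

    def test_anticorrelated_pair_pc1_is_their_difference(self, rng):
        a = rng.normal(size=80)
        raw = pd.DataFrame({"x1": a, "x2": -a + 1e-9 * rng.normal(size=80)})
        table = subdomain_scores(raw, {"fluid": ["x1", "x2"]})
        diff = (a - a.mean())
        assert abs(np.corrcoef(table.values[:, 0], diff)[0, 1]) == pytest.approx(
            1.0, abs=1e-6)

    def test_constant_raw_column_rejected(self):
        raw = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(DegenerateSignalError):
            subdomain_scores(raw, {"m": ["a"]})


class TestPLSC:
    def test_exact_rank_one_recovery_without_noise(self, rng):
        x, y, w, u = planted_xy(rng, noise=0.0)
        res = plsc(x, y)
        cos = abs(res.brain_saliences[:, 0] @ w)
        assert cos > 0.999
        assert res.singular_values[0] / res.singular_values.sum() > 0.98
        assert res.covariance_shares[0] > 0.999

    def test_salience_columns_unit_norm_and_ordering(self, rng):
        x, y, *_ = planted_xy(rng)
        res = plsc(x, y)
        np.testing.assert_allclose(np.linalg.norm(res.brain_saliences, axis=0),
                                   1.0, atol=1e-10)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_duplicating_null_feature_column_preserves_structure(self, rng):
        # duplicating a feature outside the planted support only adds that
        # column's own (noise-level) contribution to the spectrum
        x, y, w, _ = planted_xy(rng, noise=0.05)
        assert w[10] == 0.0
        x2 = np.column_stack([x, x[:, 10]])
        r1 = plsc(x, y)
        r2 = plsc(x2, y)
        assert r2.singular_values[0] == pytest.approx(r1.singular_values[0],
                                                      rel=1e-3)
        v1 = r1.brain_saliences[:, 0]
        v2 = r2.brain_saliences[:-1, 0]
        assert abs(v1 @ v2 / np.linalg.norm(v2)) > 0.999

    def test_dimension_and_size_guards(self, rng):
        with pytest.raises(DimensionError):
            plsc(rng.normal(size=(5, 3)), rng.normal(size=(6, 2)))
        with pytest.raises(DimensionError):
            plsc(rng.normal(size=(2, 3)), rng.normal(size=(2, 2)))


class TestPermutation:
    def test_planted_component_attains_minimum_p(self, rng):
        x, y, *_ = planted_xy(rng, strength=5.0, noise=0.05)
        p = permutation_significance(x, y, n_perm=99, seed=0)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_null_first_component_p_roughly_uniform(self, rng):
        ps = []
        for rep in range(60):
            x = rng.normal(size=(40, 15))
            y = rng.normal(size=(40, 4))
            ps.append(permutation_significance(x, y, n_perm=60, seed=rep)[0])
        ps = np.asarray(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.2).mean() < 0.45

    def test_identical_y_rows_degenerate(self, rng):
        x = rng.normal(size=(10, 5))
        y = np.tile(rng.normal(size=3), (10, 1))
        with pytest.raises(DegenerateSignalError):
            permutation_significance(x, y, n_perm=10)

    def test_invalid_arguments(self, rng):
        x = rng.normal(size=(10, 5))
        y = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            permutation_significance(x, y, n_perm=0)
        with pytest.raises(ValueError):
            permutation_significance(x, y, n_perm=10, null="bogus")


class TestBootstrap:
    def test_planted_entries_have_large_standard_scores(self, rng):
        x, y, w, u = planted_xy(rng, s=80, strength=5.0, noise=0.05)
        brain_z, cog_z = bootstrap_salience(x, y, n_boot=80, seed=2)
        # entries carrying a substantial planted weight are clearly reliable;
        # the smallest planted weight sits near the resampling noise floor
        strong = np.abs(w) > 0.3
        assert np.abs(brain_z[strong, 0]).min() > 2.0
        assert np.abs(cog_z[:, 0]).min() > 2.0

    def test_null_entries_rarely_flagged_reliable(self, rng):
        x = rng.normal(size=(60, 25))
        y = rng.normal(size=(60, 5))
        brain_z, _ = bootstrap_salience(x, y, n_boot=80, seed=3)
        assert (np.abs(brain_z[:, 0]) > 2.0).mean() <= 0.15

    def test_single_resample_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_salience(rng.normal(size=(10, 4)),
                               rng.normal(size=(10, 3)), n_boot=1)


class TestCovarianceExplained:
    def test_single_significant_component_is_everything(self):
        res = PLSCResult(np.array([2.0]), np.ones((3, 1)), np.ones((2, 1)),
                         np.zeros((5, 1)), np.zeros((5, 1)))
        assert covariance_explained(res, np.array([0.01])) == 1.0

    def test_no_significant_components_is_zero(self):
        res = PLSCResult(np.array([2.0, 1.0]), np.ones((3, 2)), np.ones((2, 2)),
                         np.zeros((5, 2)), np.zeros((5, 2)))
        assert covariance_explained(res, np.array([0.5, 0.9])) == 0.0

    def test_two_components_first_significant(self):
        res = PLSCResult(np.array([2.0, 1.0]), np.ones((3, 2)), np.ones((2, 2)),
                         np.zeros((5, 2)), np.zeros((5, 2)))
        assert covariance_explained(res, np.array([0.01, 0.5])) == pytest.approx(0.8)


class TestRobustnessLoop:
    def test_planted_component_concentrates_high_share(self, rng):
        x, y, *_ = planted_xy(rng, s=60, strength=5.0, noise=0.05)
        out = robustness_loop(x, y, n_sub=48, n_rep=8, n_perm=60, seed=0)
        assert out["covariance_explained"].shape == (8,)
        assert np.median(out["covariance_explained"]) > 0.9

    def test_null_data_concentrates_near_zero(self, rng):
        x = rng.normal(size=(60, 20))
        y = rng.normal(size=(60, 5))
        out = robustness_loop(x, y, n_sub=48, n_rep=8, n_perm=60, seed=1)
        assert np.median(out["covariance_explained"]) == 0.0

    def test_reliability_flags_with_bootstrap(self, rng):
        x, y, w, _ = planted_xy(rng, s=60, strength=5.0, noise=0.05)
        out = robustness_loop(x, y, n_sub=50, n_rep=4, n_perm=30, n_boot=40,
                              seed=2)
        assert out["reliable"][np.abs(w) > 0.3].all()

    def test_oversized_subsample_rejected(self, rng):
        with pytest.raises(DimensionError):
            robustness_loop(rng.normal(size=(10, 4)), rng.normal(size=(10, 3)),
                            n_sub=11, n_rep=1)
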