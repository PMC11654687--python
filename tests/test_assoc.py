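"""Mass-univariate GLM, permutation FWE and IDP extraction."""
import numpy as np
import pandas as pd
import pytest

from impactmodes.assoc import (
    build_design,
    fit_glm,
    idp_extract,
    permutation_fwe,
    variant_tmaps,
)
from impactmodes.synth import gen_covariates, gen_genotypes, gen_maps, gen_truth
from impactmodes.types import ConfigError, DataError

from conftest import toy_genotypes


def ols_t_oracle(y, x, design):
    """Brute-force full-design OLS t for the x coefficient (normal equations)."""
    full = np.column_stack([x, design])
    beta, _, _, _ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ beta
    df = len(y) - full.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(full.T @ full)
    return beta[0] / np.sqrt(cov[0, 0]), df


class TestBuildDesign:
    def test_default_columns(self, small_cfg):
        cov = gen_covariates(small_cfg)
        design = build_design(cov)
        # intercept + everything except subject_id and head_size
        assert design.n_columns == 1 + (len(cov.columns) - 2)
        assert design.columns[0] == "intercept"
        assert "head_size" not in design.columns

    def test_head_size_adds_one_column(self, small_cfg):
        cov = gen_covariates(small_cfg)
        base = build_design(cov)
        adj = build_design(cov, head_size_adjust=True)
        assert adj.n_columns == base.n_columns + 1
        assert adj.columns[-1] == "head_size"

    def test_log_transform_of_unit_maps(self, small_cfg):
        cov = gen_covariates(small_cfg)
        design = build_design(cov, log_transform=True)
        from impactmodes.assoc import transform_values

        values = np.ones((small_cfg.n_subjects, 4))
        np.testing.assert_array_equal(transform_values(values, design), 0.0)

    def test_missing_values_listed(self, small_cfg):
        cov = gen_covariates(small_cfg).copy()
        cov.loc[3, "age"] = np.nan
        with pytest.raises(DataError, match=cov.loc[3, "subject_id"]):
            build_design(cov)


class TestFitGlm:
    def test_orthogonal_values_give_zero_t(self, rng):
        n = 40
        design = np.column_stack([np.ones(n), rng.normal(size=n)])
        x = rng.normal(size=n)
        q, _ = np.linalg.qr(np.column_stack([design, x]))
        y = rng.normal(size=(n, 3))
        y -= q @ (q.T @ y)  # orthogonal to x and design
        res = fit_glm(y, x, design)
        np.testing.assert_allclose(res.t, 0.0, atol=1e-8)

    def test_matches_full_design_ols_oracle(self, rng):
        for _ in range(25):
            n, n_elem, n_cov = 50, 10, 5
            design = np.column_stack([np.ones(n), rng.normal(size=(n, n_cov))])
            x = rng.normal(size=n)
            y = rng.normal(size=(n, n_elem))
            res = fit_glm(y, x, design)
            for e in range(n_elem):
                t_ref, df_ref = ols_t_oracle(y[:, e], x, design)
                assert res.t[e] == pytest.approx(t_ref, abs=1e-8)
                assert res.df == df_ref

    def test_partial_r2_identity(self, rng):
        n = 107
        design = np.ones((n, 1))
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 5))
        res = fit_glm(y, x, design)
        # t = 3 with df = 100 gives partial r2 = 9/109; check the identity
        np.testing.assert_allclose(
            res.partial_r2, res.t**2 / (res.t**2 + res.df), atol=1e-12
        )
        assert 9 / 109 == pytest.approx(0.08257, abs=1e-5)

    def test_collinear_predictor_errors(self, rng):
        n = 30
        z = rng.normal(size=n)
        design = np.column_stack([np.ones(n), z])
        with pytest.raises(DataError, match="collinear"):
            fit_glm(rng.normal(size=(n, 2)), 2.0 * z + 1.0, design)

    def test_orthogonal_covariate_leaves_t_scaled_by_df(self, rng):
        # adding a covariate orthogonal to x and maps changes t only through df
        n = 60
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 4))
        base = np.ones((n, 1))
        extra = rng.normal(size=n)
        q, _ = np.linalg.qr(np.column_stack([base, x, y]))
        extra -= q @ (q.T @ extra)
        res1 = fit_glm(y, x, base)
        res2 = fit_glm(y, x, np.column_stack([base, extra]))
        assert res2.df == res1.df - 1
        np.testing.assert_allclose(
            res2.t / np.sqrt(res2.df), res1.t / np.sqrt(res1.df), atol=1e-10
        )


class TestVariantTmaps:
    def test_single_variant_equals_fit_glm(self, small_cfg, small_cohort):
        g, cov, truth, maps, ss, _ = small_cohort
        design = build_design(cov)
        vid = g.variants["id"].iloc[0]
        tmat = variant_tmaps(g, [vid], maps, design)
        direct = fit_glm(maps, g.dosages[:, 0], design)
        np.testing.assert_allclose(tmat.t[0], direct.t)
        assert tmat.df == direct.df

    def test_duplicated_variant_identical_rows(self, small_cohort):
        g, cov, truth, maps, ss, _ = small_cohort
        design = build_design(cov)
        vid = g.variants["id"].iloc[3]
        tmat = variant_tmaps(g, [vid, vid], maps, design)
        np.testing.assert_array_equal(tmat.t[0], tmat.t[1])

    def test_monomorphic_variant_flagged(self, rng):
        d = rng.binomial(2, 0.4, size=(50, 2)).astype(float)
        d[:, 1] = 2.0
        g = toy_genotypes(d)
        maps_vals = rng.normal(size=(50, 6))
        tmat = variant_tmaps(g, ["v0", "v1"], maps_vals_to_maps(maps_vals), np.ones((50, 1)))
        assert np.all(np.isfinite(tmat.t[0]))
        assert np.all(np.isnan(tmat.t[1]))

    def test_planted_sign_recovered_noiseless(self):
        from impactmodes.synth import SimConfig

        cfg = SimConfig(n_subjects=80, n_variants=20, n_modes=1,
                        grid_shape=(6, 6, 6), noise_sd=1e-6,
                        covariate_effects={}, loading_sparsity=0.2, seed=12)
        g = gen_genotypes(cfg)
        cov = gen_covariates(cfg)
        truth = gen_truth(cfg)
        maps = gen_maps(g, cov, truth, cfg)
        design = build_design(cov)
        loaders = np.flatnonzero(truth.variant_loadings[:, 0] != 0)
        ids = g.variants["id"].iloc[loaders].tolist()
        tmat = variant_tmaps(g, ids, maps, design)
        for row, v in zip(tmat.t, loaders):
            active = truth.effect_maps[v] != 0
            expected = np.sign(truth.effect_maps[v, active])
            assert np.all(np.sign(row[active]) == expected)


def maps_vals_to_maps(values):
    """Wrap a plain matrix in ElementMaps with generic fixel geometry."""
    from impactmodes.types import ElementMaps, FixelGeometry

    n_sub, n_elem = values.shape
    dirs = np.tile([1.0, 0.0, 0.0], (n_elem, 1))
    geom = FixelGeometry(np.arange(n_elem), dirs)
    return ElementMaps(values, geom, np.array([f"S{i}" for i in range(n_sub)]))


class TestPermutationFwe:
    def test_huge_effect_reaches_minimum_p(self, rng):
        n = 80
        design = np.ones((n, 1))
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 10))
        y[:, 4] += 10.0 * x  # overwhelming signal
        res = permutation_fwe(y, x, design, n_perm=200, seed=1)
        assert res.p[4] == pytest.approx(1.0 / 201.0)

    def test_p_monotone_in_abs_t(self, rng):
        n = 60
        design = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 30))
        res = permutation_fwe(y, x, design, n_perm=150, seed=3)
        order = np.argsort(np.abs(res.t_obs))
        assert np.all(np.diff(res.p[order]) <= 1e-12)

    def test_degenerate_elements_p_one(self, rng):
        n = 50
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 5))
        y[:, 2] = 7.0  # constant element
        res = permutation_fwe(y, x, np.ones((n, 1)), n_perm=120, seed=5)
        assert res.p[2] == 1.0
        assert res.t_obs[2] == 0.0

    def test_seed_determinism(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 8))
        a = permutation_fwe(y, x, np.ones((n, 1)), n_perm=100, seed=11)
        b = permutation_fwe(y, x, np.ones((n, 1)), n_perm=100, seed=11)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.null_max, b.null_max)

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ConfigError):
            permutation_fwe(rng.normal(size=(20, 3)), rng.normal(size=20),
                            np.ones((20, 1)), n_perm=50)


class TestIdpExtract:
    def test_rank_two_fully_reconstructed(self, rng):
        n, n_elem = 30, 40
        scores = rng.normal(size=(n, 2))
        loadings = rng.normal(size=(2, n_elem))
        values = scores @ loadings
        idps, labels = idp_extract(values, [2])
        assert labels == ["d2_pc1", "d2_pc2"]
        centered = values - values.mean(axis=0)
        recon, _, _, _ = np.linalg.lstsq(idps, centered, rcond=None)
        resid = centered - idps @ recon
        assert (resid**2).sum() < 1e-18 * max((centered**2).sum(), 1.0)

    def test_columns_orthogonal_within_dimension(self, rng):
        values = rng.normal(size=(50, 25))
        idps, _ = idp_extract(values, [5])
        gram = idps.T @ idps
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_dimension_too_large_errors(self, rng):
        with pytest.raises(ConfigError):
            idp_extract(rng.normal(size=(10, 50)), [10])

    def test_top_idp_tracks_planted_mode_expression(self):
        from impactmodes.synth import SimConfig

        cfg = SimConfig(n_subjects=150, n_variants=40, n_modes=1,
                        grid_shape=(8, 8, 8), noise_sd=0.01,
                        loading_sparsity=0.3, covariate_effects={}, seed=6)
        g = gen_genotypes(cfg)
        cov = gen_covariates(cfg)
        truth = gen_truth(cfg)
        maps = gen_maps(g, cov, truth, cfg)
        gc = g.dosages - g.dosages.mean(axis=0)
        expression = gc @ truth.variant_loadings[:, 0]  # subject-level mode score
        idps, _ = idp_extract(maps, [1])
        r = np.corrcoef(idps[:, 0], expression)[0, 1]
        assert abs(r) >= 0.9
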