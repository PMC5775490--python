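import numpy as np
import pandas as pd
import pytest

import landgen
from landgen import GenotypeMatrix
from landgen.gdm_model import (
    GEO_NAME,
    IsplineBasis,
    SitePairTable,
    _ispline_eval,
)
from landgen.io_formats import LandgenError

from conftest import make_sample_table


def planted_gdm_dataset(seed=15, n=100, noise=True, nu=100.0,
                        coef_sum=1.2, alpha=0.05):
    """Site pairs whose dissimilarities come from a known GDM: only
    'rainfall' has non-zero spline coefficients."""
    rng = np.random.default_rng(seed)
    env = pd.DataFrame(
        {
            "rainfall": rng.uniform(800, 6200, n),
            "temp_min": rng.uniform(5, 20, n),
            "isothermality": rng.uniform(0.5, 0.8, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    X = env.to_numpy()
    names = list(env.columns)
    basis = IsplineBasis.from_values(
        {nm: X[:, p] for p, nm in enumerate(names)}, 3
    )
    true = {nm: np.zeros(3) for nm in names}
    true["rainfall"] = np.full(3, coef_sum / 3)
    iu, ju = np.triu_indices(n, k=1)
    eta = np.full(len(iu), alpha)
    for p, nm in enumerate(names):
        Z = np.abs(basis.evaluate(nm, X[iu, p]) - basis.evaluate(nm, X[ju, p]))
        eta += Z @ true[nm]
    mu = 1 - np.exp(-eta)
    d = rng.beta(mu * nu, (1 - mu) * nu) if noise else mu
    spt = SitePairTable(
        list(env.index), np.column_stack([iu, ju]), d,
        np.zeros(len(iu)), names, X[iu], X[ju],
    )
    return spt, basis, true, mu


class TestIspline:
    def test_boundary_values_and_monotone(self):
        knots = np.array([0.0, 3.0, 10.0])
        x = np.linspace(0, 10, 201)
        B = _ispline_eval(x, knots)
        np.testing.assert_allclose(B[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(B[-1], 1.0, atol=1e-12)
        assert (np.diff(B, axis=0) >= -1e-12).all()

    def test_degenerate_knots_give_zero_basis(self):
        B = _ispline_eval(np.array([1.0, 2.0]), np.array([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(B, 0.0)

    def test_knots_at_percentiles_with_geo_pinned_at_zero(self):
        basis = IsplineBasis.from_values(
            {"a": np.array([2.0, 4.0, 6.0, 100.0]),
             GEO_NAME: np.array([3.0, 5.0, 9.0])},
        )
        np.testing.assert_allclose(basis.knots["a"], [2.0, 5.0, 100.0])
        assert basis.knots[GEO_NAME][0] == 0.0


class TestBuildSitePairs:
    def test_identical_rows_distance_zero(self):
        d = np.tile([0.0, 0.5, 1.0, 0.5], (3, 5))[:3]
        gm = GenotypeMatrix(["a", "b", "c"], [f"l{j}" for j in range(20)], d)
        st = make_sample_table(gm.sample_ids)
        pred = pd.DataFrame({"e": [1.0, 2.0, 3.0]}, index=gm.sample_ids)
        spt = landgen.build_site_pairs(gm, st, pred)
        assert spt.d[0] == pytest.approx(0.0, abs=1e-9)  # pair (a, b)

    def test_fully_opposite_rows_distance_one(self):
        d = np.array([np.zeros(10), np.ones(10), np.full(10, 0.5)])
        gm = GenotypeMatrix(["a", "b", "c"], [f"l{j}" for j in range(10)], d)
        st = make_sample_table(gm.sample_ids)
        pred = pd.DataFrame({"e": [1.0, 2.0, 3.0]}, index=gm.sample_ids)
        spt = landgen.build_site_pairs(gm, st, pred)
        assert spt.d[0] == pytest.approx(1.0)  # (a, b) is the max pair

    def test_pair_count_n201(self):
        rng = np.random.default_rng(0)
        n = 201
        d = rng.choice([0.0, 0.5, 1.0], size=(n, 10))
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], [f"l{j}" for j in range(10)], d
        )
        st = make_sample_table(gm.sample_ids, coords=rng.uniform(0, 1, (n, 2)))
        pred = pd.DataFrame({"e": rng.normal(size=n)}, index=gm.sample_ids)
        spt = landgen.build_site_pairs(gm, st, pred)
        assert spt.n_pairs == n * (n - 1) // 2 == 20100

    def test_zero_shared_loci_raises_with_names(self):
        d = np.array([[0.0, np.nan], [np.nan, 1.0], [0.0, 1.0]])
        gm = GenotypeMatrix(["a", "b", "c"], ["l1", "l2"], d)
        st = make_sample_table(gm.sample_ids)
        pred = pd.DataFrame({"e": [1.0, 2.0, 3.0]}, index=gm.sample_ids)
        with pytest.raises(LandgenError, match="a.*b"):
            landgen.build_site_pairs(gm, st, pred)

    def test_geographic_distance_is_euclidean(self):
        d = np.tile([0.0, 0.5, 1.0], (4, 1)).T
        gm = GenotypeMatrix(["a", "b", "c"], [f"l{j}" for j in range(4)], d)
        coords = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 1.0]])
        st = make_sample_table(gm.sample_ids, coords=coords)
        pred = pd.DataFrame({"e": [1.0, 2.0, 3.0]}, index=gm.sample_ids)
        spt = landgen.build_site_pairs(gm, st, pred)
        assert spt.geo[0] == pytest.approx(5.0)


class TestFitGdm:
    def test_zero_model_predicts_zero(self):
        spt, basis, _, _ = planted_gdm_dataset(n=20, noise=False)
        model = landgen.GdmModel(
            intercept=0.0,
            coefs={nm: np.zeros(3) for nm in spt.predictor_names},
            basis=basis, deviance=0.0, null_deviance=1.0, converged=True,
        )
        env = pd.DataFrame(spt.Xi, columns=spt.predictor_names)
        env2 = pd.DataFrame(spt.Xj, columns=spt.predictor_names)
        mu = landgen.gdm_predict(model, env, env2)
        np.testing.assert_array_equal(mu, 0.0)

    def test_recovers_planted_coefficients(self):
        spt, basis, true, _ = planted_gdm_dataset(seed=15)
        model = landgen.fit_gdm(spt, basis, include_geo=False)
        imp = landgen.gdm_importance(model)
        assert abs(imp["rainfall"] - 1.2) / 1.2 < 0.15
        assert imp["temp_min"] < 0.1 and imp["isothermality"] < 0.1
        assert imp.index[0] == "rainfall"

    def test_noise_free_deviance_explained(self):
        spt, basis, _, _ = planted_gdm_dataset(seed=15, noise=False)
        model = landgen.fit_gdm(spt, basis, include_geo=False)
        assert model.pct_deviance_explained >= 99.0

    def test_deviance_trace_monotone_and_bounded(self):
        spt, basis, _, _ = planted_gdm_dataset(seed=16)
        model = landgen.fit_gdm(spt, basis, include_geo=False)
        tr = np.array(model.deviance_trace)
        assert (np.diff(tr) <= 1e-6 * max(1.0, tr[0])).all()
        assert 0.0 <= model.pct_deviance_explained <= 100.0
        assert model.deviance <= model.null_deviance

    def test_nonnegative_coefficients(self, gdm_island_model):
        model, _ = gdm_island_model
        assert model.intercept >= 0
        for c in model.coefs.values():
            assert (c >= 0).all()

    def test_pair_end_swap_symmetry(self):
        spt, basis, _, _ = planted_gdm_dataset(seed=17, n=30)
        model = landgen.fit_gdm(spt, basis, include_geo=False)
        env_i = pd.DataFrame(spt.Xi, columns=spt.predictor_names)
        env_j = pd.DataFrame(spt.Xj, columns=spt.predictor_names)
        np.testing.assert_allclose(
            landgen.gdm_predict(model, env_i, env_j),
            landgen.gdm_predict(model, env_j, env_i),
        )

    def test_constant_dissimilarity_raises(self):
        spt, basis, _, _ = planted_gdm_dataset(n=10, noise=False)
        spt.d = np.full_like(spt.d, 0.3)
        with pytest.raises(LandgenError, match="constant"):
            landgen.fit_gdm(spt, basis)

    def test_ibd_only_data_shrinks_env_importance(self):
        """Pure isolation by distance: environmental importances shrink
        relative to geography as pair count grows."""
        ratios = []
        for n in (20, 40, 80):
            rng = np.random.default_rng(19)
            coords = rng.uniform(0, 10, (n, 2))
            env = pd.DataFrame(
                {"e1": rng.uniform(0, 1, n), "e2": rng.uniform(0, 1, n)},
                index=[f"s{i}" for i in range(n)],
            )
            iu, ju = np.triu_indices(n, k=1)
            geo = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
            mu = 1 - np.exp(-(0.02 + 0.15 * geo))
            d = rng.beta(mu * 200, (1 - mu) * 200)
            spt = SitePairTable(
                list(env.index), np.column_stack([iu, ju]), d, geo,
                list(env.columns), env.to_numpy()[iu], env.to_numpy()[ju],
            )
            model = landgen.fit_gdm(spt)
            imp = landgen.gdm_importance(model)
            env_sum = imp.drop(GEO_NAME).sum()
            ratios.append(env_sum / max(imp[GEO_NAME], 1e-9))
        assert ratios[-1] < 0.2
        assert ratios[-1] <= ratios[0] + 1e-9


class TestPredictTransform:
    @pytest.fixture()
    def model(self):
        spt, basis, _, _ = planted_gdm_dataset(seed=15)
        return landgen.fit_gdm(spt, basis, include_geo=False), spt

    def test_identical_ends_give_intercept_floor(self, model):
        m, spt = model
        env = pd.DataFrame(spt.Xi[:5], columns=spt.predictor_names)
        mu = landgen.gdm_predict(m, env, env, geo=0.0)
        np.testing.assert_allclose(mu, 1 - np.exp(-m.intercept), atol=1e-12)

    def test_mu_nondecreasing_in_single_env_gap(self, model):
        m, spt = model
        base = {"rainfall": 800.0, "temp_min": 10.0, "isothermality": 0.6}
        rains = np.linspace(800, 6200, 25)
        env_i = pd.DataFrame([base] * 25)
        env_j = pd.DataFrame([base] * 25)
        env_j["rainfall"] = rains
        mu = landgen.gdm_predict(m, env_i, env_j)
        assert (np.diff(mu) >= -1e-12).all()

    def test_transform_zero_at_knot_minimum(self, model):
        m, _ = model
        mask = landgen.EnvRaster(4, 3, 0, 0, 1, -9999.0, np.ones((3, 4)))
        rasters = {
            nm: mask.copy_with(np.full((3, 4), m.basis.knots[nm][0]))
            for nm in m.coefs
        }
        tg = landgen.gdm_transform(m, rasters, mask)
        np.testing.assert_array_equal(tg.vectors, 0.0)

    def test_json_roundtrip(self, model, tmp_path):
        m, spt = model
        p = tmp_path / "gdm.json"
        m.to_json(p)
        back = landgen.GdmModel.from_json(p)
        assert back.intercept == pytest.approx(m.intercept)
        env_i = pd.DataFrame(spt.Xi[:10], columns=spt.predictor_names)
        env_j = pd.DataFrame(spt.Xj[:10], columns=spt.predictor_names)
        np.testing.assert_allclose(
            landgen.gdm_predict(back, env_i, env_j),
            landgen.gdm_predict(m, env_i, env_j),
        )

    def test_island_importance_ranks_rainfall_first(self, gdm_island_model):
        model, _ = gdm_island_model
        imp = landgen.gdm_importance(model)
        assert imp.index[0] == "rainfall"
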