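import numpy as np
import pytest

import buvspatial as bv
from buvspatial.evaluate import krige_moments
from conftest import make_obs


def concordance_auc(y, p):
    """Exhaustive pairwise-concordance oracle, ties credited 1/2."""
    y = np.asarray(y)
    p = np.asarray(p)
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert bv.auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert bv.auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_four_pair_example(self):
        assert bv.auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(bv.UndefinedMetricError):
            bv.auc([1, 1, 1], [0.2, 0.5, 0.9])

    def test_matches_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(4, 31)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # discretized probabilities so ties actually occur
            p = rng.integers(0, 6, size=n) / 5.0
            assert bv.auc(y, p) == pytest.approx(concordance_auc(y, p))


class TestMetricSummaries:
    def test_hand_computed_ll_and_mse(self):
        summ = bv.metric_summaries([1, 0], [[0.8, 0.2]])
        assert np.isclose(summ["LL"].posterior_mean, 2 * np.log(0.8))
        assert np.isclose(summ["LL"].posterior_mean, -0.4463, atol=5e-5)
        assert np.isclose(summ["MSE"].posterior_mean, 0.04)

    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0, 1])
        P = np.tile(y, (3, 1)).astype(float)
        summ = bv.metric_summaries(y, P)
        assert abs(summ["LL"].posterior_mean) < 1e-8
        assert summ["MSE"].posterior_mean == 0.0
        assert summ["AUC"].posterior_mean == 1.0

    def test_interval_brackets_mean(self, small_fits, small_survey):
        data, _ = small_survey
        for draws in small_fits.values():
            P = bv.predict_probabilities(draws, data)
            for ms in bv.metric_summaries(data.presence, P).values():
                assert ms.interval_low <= ms.posterior_mean <= ms.interval_high

    def test_intervals_widen_under_subsampling(self, small_fits, small_survey):
        data, _ = small_survey
        draws = small_fits["nonspatial"]
        P = bv.predict_probabilities(draws, data)
        full = bv.metric_summaries(data.presence, P)
        rng = np.random.default_rng(5)
        widths = {m: [] for m in full}
        for _ in range(20):
            idx = rng.choice(P.shape[0], P.shape[0] // 10, replace=False)
            sub = bv.metric_summaries(data.presence, P[idx])
            for m in full:
                widths[m].append(sub[m].interval_high - sub[m].interval_low)
        for m, ms in full.items():
            assert np.mean(widths[m]) >= (ms.interval_high - ms.interval_low)


class TestPredict:
    def test_logistic_of_unit_predictor(self):
        obs = make_obs([
            ("A", 0, 0, "summer", "open", 10.0, 5.0, 0, 0, 0, 0, 1),
            ("B", 500, 0, "summer", "open", 20.0, 6.0, 0, 0, 0, 0, 0),
        ])
        data = bv.SurveyDataset(obs, standardized=True)
        beta = np.zeros((1, 10))
        beta[0, 0] = 1.0
        draws = bv.PosteriorDraws(
            beta=beta, columns=bv.DESIGN_COLUMNS, sites=data.sites,
            spatial=False,
        )
        P = bv.predict_probabilities(draws, data)
        assert np.allclose(P, 1.0 / (1.0 + np.exp(-1.0)))
        assert np.isclose(P[0, 0], 0.7311, atol=5e-5)

    def test_probabilities_strictly_inside_unit_interval(
            self, small_fits, small_survey):
        data, _ = small_survey
        for draws in small_fits.values():
            P = bv.predict_probabilities(draws, data)
            assert (P > 0).all() and (P < 1).all()
            assert P.shape == (draws.n_draws, data.n_obs)

    def test_unknown_site_without_rng_errors(self, small_fits, small_survey):
        data, _ = small_survey
        obs = data.obs.copy()
        obs.loc[0, "site_id"] = "unseen"
        obs.loc[0, ["easting", "northing"]] = (123.0, 456.0)
        new = bv.SurveyDataset(obs.iloc[[0]])
        with pytest.raises(ValueError, match="krige"):
            bv.predict_probabilities(small_fits["spatial"], new)


class TestFolds:
    def test_near_equal_deal_of_174_sites(self):
        data = bv.generate_survey(bv.SimulationConfig(seed=2))
        fa = bv.assign_location_folds(data, 5, seed=0)
        sizes = sorted(
            np.bincount(list(fa.site_to_fold.values())).tolist()
        )
        assert sizes == [34, 35, 35, 35, 35]

    def test_observations_inherit_site_fold(self, small_survey):
        data, _ = small_survey
        fa = bv.assign_location_folds(data, 4, seed=1)
        obs_folds = fa.fold_of_obs(data)
        for sid, group in data.obs.groupby("site_id"):
            assert np.unique(obs_folds[group.index]).size == 1

    def test_deterministic_per_seed(self, small_survey):
        data, _ = small_survey
        a = bv.assign_location_folds(data, 5, seed=3)
        b = bv.assign_location_folds(data, 5, seed=3)
        assert a.site_to_fold == b.site_to_fold

    def test_k_less_than_two_errors(self, small_survey):
        data, _ = small_survey
        with pytest.raises(ValueError):
            bv.assign_location_folds(data, 1, seed=0)


class TestKriging:
    def test_coincident_site_interpolates_exactly(self):
        train = np.array([[0.0, 0.0], [800.0, 0.0]])
        eta = np.array([1.3, -0.4])
        mean, cov = krige_moments(eta, 2.0, 1e-3, train, train[[0]])
        assert np.isclose(mean[0], 1.3, atol=1e-10)
        assert abs(cov[0, 0]) < 1e-10

    def test_distant_site_reverts_to_prior(self):
        train = np.array([[0.0, 0.0]])
        eta = np.array([2.0])
        mean, cov = krige_moments(eta, 1.7, 1e-3, train,
                                  np.array([[1e7, 0.0]]))
        assert abs(mean[0]) < 1e-12
        assert np.isclose(cov[0, 0], 1.7)

    def test_single_training_point_closed_form(self):
        # mean = e^(-phi d) eta, var = sigma2 (1 - e^(-2 phi d))
        sigma2, phi, d, eta0 = 2.3, 2e-3, 700.0, 1.1
        mean, cov = krige_moments(np.array([eta0]), sigma2, phi,
                                  np.array([[0.0, 0.0]]),
                                  np.array([[d, 0.0]]))
        rho = np.exp(-phi * d)
        assert abs(mean[0] - rho * eta0) < 1e-10
        assert abs(cov[0, 0] - sigma2 * (1 - rho**2)) < 1e-10

    def test_sampled_draws_match_conditional_moments(self):
        train = np.array([[0.0, 0.0], [500.0, 100.0], [900.0, 0.0]])
        new = np.array([[300.0, 50.0], [2000.0, 0.0]])
        eta = np.array([0.8, -0.5, 0.2])
        sigma2, phi = 1.4, 2.5e-3
        mean, cov = krige_moments(eta, sigma2, phi, train, new)
        rng = np.random.default_rng(0)
        draws = np.array([
            bv.krige_random_effect(eta, sigma2, phi, train, new, rng)
            for _ in range(6000)
        ])
        assert np.allclose(draws.mean(axis=0), mean,
                           atol=4 * np.sqrt(np.diag(cov) / 6000))
        assert np.allclose(np.cov(draws.T), cov, atol=0.08)

    def test_mean_only_mode(self):
        train = np.array([[0.0, 0.0]])
        out = bv.krige_random_effect(
            np.array([1.0]), 1.0, 1e-3, train, np.array([[600.0, 0.0]]),
            np.random.default_rng(0), mean_only=True,
        )
        assert np.isclose(out[0], np.exp(-0.6))


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def cv_result(self):
        cfg = bv.SimulationConfig(
            n_clusters=4, sites_per_cluster=12, band_length=8000.0,
            band_width=1500.0, cluster_spread=350.0, seed=6,
        )
        data, _ = bv.simulate_survey(cfg)
        fit_cfg = bv.FitConfig(spatial=True, n_retained=200, burn_in=100,
                               thin=1, seed=0)
        return data, bv.cross_validate(data, bv.PriorSpec(), fit_cfg, k=3,
                                       seed=1, keep_draws=True)

    def test_output_shape_contract(self, cv_result):
        _, res = cv_result
        t = res.table
        # k rows + 1 mean row per (metric, model)
        for metric in ("LL", "MSE", "AUC"):
            for model in ("spatial", "nonspatial"):
                sub = t[(t["metric"] == metric) & (t["model"] == model)]
                assert len(sub) == 4
                assert (sub["fold"] == "mean").sum() == 1

    def test_mean_row_averages_folds(self, cv_result):
        _, res = cv_result
        t = res.table
        sub = t[(t["metric"] == "MSE") & (t["model"] == "spatial")]
        folds = sub[sub["fold"] != "mean"]["posterior_mean"]
        mean = sub[sub["fold"] == "mean"]["posterior_mean"].iloc[0]
        assert np.isclose(mean, folds.mean())

    def test_fitting_never_sees_heldout_sites(self, cv_result):
        data, res = cv_result
        obs_folds = res.folds.fold_of_obs(data)
        for (model, f), draws in res.draws.items():
            held = set(data.obs.loc[obs_folds == f, "site_id"])
            assert held.isdisjoint(set(draws.sites["site_id"]))
            assert draws.sites.shape[0] < data.n_sites
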