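"""Conditional-logistic SSF machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import seismove as sm
from seismove import ssf as S


def toy_strata(edist_by_stratum, weights=None):
    """Long-format strata from per-stratum eDist lists (first row = used)."""
    rows = []
    for sid, values in enumerate(edist_by_stratum):
        for j, v in enumerate(values):
            rows.append({"stratum_id": sid, "case": int(j == 0),
                         "edist": float(v),
                         "weight": 1.0 if weights is None else weights[sid]})
    return pd.DataFrame(rows)


def grid_search_mle(strata, lo=-10.0, hi=10.0):
    """Dense-grid oracle for the single-coefficient conditional MLE.

    Three zoom rounds of 2001 points reach ~1e-7 resolution.
    """
    X, w, names, sid = S._stratum_tensors(strata, ("eDist",))

    def nll(beta):
        ll, _, _ = S._clogit_parts(X, w, np.array([beta]))
        return -ll

    for _ in range(3):
        grid = np.linspace(lo, hi, 2001)
        vals = [nll(b) for b in grid]
        best = grid[int(np.argmin(vals))]
        span = (hi - lo) / 2000
        lo, hi = best - span, best + span
    return best


# ---------------------------------------------------------------------------
# Pre-fit screens
# ---------------------------------------------------------------------------

class TestLengthAngleCorrelation:
    def make_steps(self, lengths, angles):
        return pd.DataFrame({"length": lengths, "turn_angle": angles})

    def test_monotone_and_antimonotone_extremes(self):
        n = 20
        lengths = np.arange(1.0, n + 1)
        angles = np.linspace(0.1, 3.0, n)
        assert sm.check_lt_ta_correlation(
            self.make_steps(lengths, angles)) == pytest.approx(1.0)
        assert sm.check_lt_ta_correlation(
            self.make_steps(lengths, angles[::-1])) == pytest.approx(-1.0)

    def test_independent_draws_uncorrelated(self, rng):
        steps = self.make_steps(rng.gamma(2, 150, 1000),
                                rng.vonmises(0, 1, 1000))
        assert abs(sm.check_lt_ta_correlation(steps)) < 0.1

    def test_insufficient_steps_rejected(self):
        with pytest.raises(ValueError):
            sm.check_lt_ta_correlation(self.make_steps([1.0] * 5, [0.1] * 5))


class TestScreenCollinearity:
    def test_duplicated_column_dropped(self, rng):
        x = rng.normal(size=200)
        tab = pd.DataFrame({"a": x, "b": rng.normal(size=200), "c": x})
        retained, report = sm.screen_collinearity(tab)
        assert retained == ["a", "b"]
        assert (report["reason"] == "correlation").any()

    def test_independent_covariates_untouched(self, rng):
        tab = pd.DataFrame(rng.normal(size=(500, 4)),
                           columns=list("abcd"))
        retained, report = sm.screen_collinearity(tab)
        assert retained == list("abcd")
        assert len(report) == 0

    def test_near_duplicate_flagged_by_vif(self, rng):
        # x4 = x1 + x2 + x3 + noise: every pairwise |r| ~ 0.52 stays under
        # the 0.6 gate, but VIF(x4) ~ 5 exceeds 3
        x1, x2, x3 = rng.normal(size=(3, 2000))
        x4 = x1 + x2 + x3 + np.sqrt(0.698) * rng.normal(size=2000)
        tab = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "x4": x4})
        retained, report = sm.screen_collinearity(tab)
        assert "x4" not in retained
        assert (report["reason"] == "vif").any()


# ---------------------------------------------------------------------------
# Stratum construction
# ---------------------------------------------------------------------------

class TestSampleAvailable:
    def used_step(self):
        return pd.Series({"x0": 0.0, "y0": 0.0, "bearing": 0.3,
                          "turn_angle": 0.1})

    def test_degenerate_pool_gives_identical_endpoints(self, rng):
        pts = sm.sample_available(self.used_step(), [100.0], [0.25], 10, rng)
        assert np.allclose(pts, pts[0])

    def test_missing_previous_bearing_rejected(self, rng):
        used = self.used_step()
        used["turn_angle"] = np.nan
        with pytest.raises(ValueError):
            sm.sample_available(used, [100.0], [0.25], 10, rng)

    def test_stratum_size_is_k_plus_one(self, wolf_strata):
        sizes = wolf_strata.groupby("stratum_id").size()
        assert (sizes == 11).all()

    def test_sampled_lengths_match_pool_cdf(self, rng):
        pool = rng.gamma(2.0, 150.0, 5000)
        used = self.used_step()
        pts = sm.sample_available(used, pool, [0.0], 10_000, rng)
        lengths = np.hypot(pts[:, 0], pts[:, 1])

        def pool_cdf(v):
            return np.searchsorted(np.sort(pool), v, side="right") / len(pool)

        ks = kstest(lengths, pool_cdf).statistic
        assert ks < 0.02


class TestPackFilter:
    def make_steps(self, positions, t="2006-07-01 00:00", group="p1"):
        return pd.DataFrame({
            "group": group, "t0": pd.Timestamp(t),
            "x0": [p[0] for p in positions], "y0": [p[1] for p in positions],
        })

    def test_within_radius_reduced_to_one(self):
        steps = self.make_steps([(0, 0), (150, 0)])
        assert len(sm.filter_pack_correlated(steps, 200.0, seed=0)) == 1

    def test_outside_radius_both_kept(self):
        steps = self.make_steps([(0, 0), (250, 0)])
        assert len(sm.filter_pack_correlated(steps, 200.0, seed=0)) == 2

    def test_transitive_closure_matches_brute_force(self, rng):
        # chains like A-B-C within 200 m pairwise-linked collapse to one
        steps = self.make_steps([(0, 0), (180, 0), (360, 0)])
        assert len(sm.filter_pack_correlated(steps, 200.0, seed=0)) == 1
        # randomized comparison against an independent component count
        import networkx as nx
        pos = rng.uniform(0, 1500, size=(25, 2))
        steps = self.make_steps([tuple(p) for p in pos])
        g = nx.Graph()
        g.add_nodes_from(range(25))
        for i in range(25):
            for j in range(i + 1, 25):
                if np.hypot(*(pos[i] - pos[j])) <= 200.0:
                    g.add_edge(i, j)
        expected = nx.number_connected_components(g)
        got = len(sm.filter_pack_correlated(steps, 200.0, seed=1))
        assert got == expected

    def test_different_timestamps_not_grouped(self):
        a = self.make_steps([(0, 0)], t="2006-07-01 00:00")
        b = self.make_steps([(50, 0)], t="2006-07-01 02:00")
        steps = pd.concat([a, b], ignore_index=True)
        assert len(sm.filter_pack_correlated(steps, 200.0, seed=0)) == 2


class TestAssignClusters:
    def make_steps(self, hours):
        t0 = pd.Timestamp("2006-07-01")
        return pd.DataFrame({"t0": [t0 + pd.Timedelta(hours=h)
                                    for h in hours]})

    def test_wolf_five_day_gap_over_ten_days(self):
        steps = self.make_steps(np.arange(0, 240, 2.0))
        ids = sm.assign_clusters(steps, 5 * 24.0)
        assert len(np.unique(ids)) == 2

    def test_single_step_single_cluster(self):
        ids = sm.assign_clusters(self.make_steps([0.0]), 24.0)
        assert list(ids) == [0]

    def test_bear_rolling_24h_rule(self):
        steps = self.make_steps(np.arange(0, 72, 1.0))
        ids = sm.assign_clusters(steps, 24.0)
        assert len(np.unique(ids)) == 3

    def test_long_gap_starts_new_cluster(self):
        steps = self.make_steps([0, 2, 4, 200, 202])
        ids = sm.assign_clusters(steps, 5 * 24.0)
        assert len(np.unique(ids)) == 2


# ---------------------------------------------------------------------------
# Conditional logistic regression
# ---------------------------------------------------------------------------

class TestFitClogit:
    def test_loglik_at_zero_beta(self, rng):
        # uniform conditional probability 1/11 per stratum
        strata = toy_strata(rng.normal(size=(40, 11)))
        X, w, names, sid = S._stratum_tensors(strata, ("eDist",))
        ll, scores, info = S._clogit_parts(X, w, np.zeros(1))
        assert ll == pytest.approx(-40 * np.log(11.0), rel=1e-12)

    def test_conditional_probabilities_sum_to_one(self, rng):
        strata = toy_strata(rng.normal(size=(10, 11)))
        X, w, names, sid = S._stratum_tensors(strata, ("eDist",))
        for beta in (-2.0, 0.0, 3.7):
            eta = X @ np.array([beta])
            p = np.exp(eta - eta.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            assert np.allclose(p.sum(axis=1), 1.0)

    def test_mle_matches_dense_grid_oracle(self, rng):
        strata = toy_strata([[0.9, 0.2, 0.5], [0.1, 0.8, 0.4]])
        fit = sm.fit_clogit(strata, ("eDist",))
        oracle = grid_search_mle(strata)
        assert fit.beta.iloc[0] == pytest.approx(oracle, abs=1e-6)

    def test_mle_matches_statsmodels_conditional_logit(self, rng):
        # independent cross-check on a 30-stratum two-covariate problem
        from statsmodels.discrete.conditional_models import ConditionalLogit
        edist = rng.uniform(0, 1, size=(30, 5))
        veght = rng.gamma(1.0, 1.0, size=(30, 5))
        rows = []
        for sid in range(30):
            eta = -1.2 * edist[sid] + 0.4 * veght[sid]
            p = np.exp(eta) / np.exp(eta).sum()
            used = rng.choice(5, p=p)
            order = [used] + [j for j in range(5) if j != used]
            for rank, j in enumerate(order):
                rows.append({"stratum_id": sid, "case": int(rank == 0),
                             "edist": edist[sid, j],
                             "veght": veght[sid, j], "weight": 1.0})
        strata = pd.DataFrame(rows)
        fit = sm.fit_clogit(strata, ("eDist", "Veght"))
        ref = ConditionalLogit(strata["case"],
                               strata[["edist", "veght"]],
                               groups=strata["stratum_id"]).fit(disp=False)
        assert np.allclose(fit.beta.to_numpy(), ref.params, atol=1e-5)
        assert np.allclose(np.sqrt(np.diag(fit.naive_cov)), ref.bse,
                           atol=1e-4)

    def test_likelihood_invariant_to_stratum_constant_shift(self, rng):
        strata = toy_strata(rng.normal(size=(25, 11)))
        fit1 = sm.fit_clogit(strata, ("eDist",))
        shifted = strata.copy()
        # add a different constant to every member of each stratum
        shifts = dict(zip(range(25), rng.normal(size=25) * 5))
        shifted["edist"] = shifted["edist"] + \
            shifted["stratum_id"].map(shifts)
        fit2 = sm.fit_clogit(shifted, ("eDist",))
        assert fit2.beta.iloc[0] == pytest.approx(fit1.beta.iloc[0],
                                                  abs=1e-7)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-7)

    def test_separation_detected(self):
        # the used step always has the strictly largest covariate
        strata = toy_strata([[1.0, 0.0, 0.1], [0.9, 0.2, 0.0],
                             [0.8, 0.0, 0.3]])
        with pytest.raises(ValueError, match="separation|singular"):
            sm.fit_clogit(strata, ("eDist",))

    def test_rank_deficiency_detected(self, rng):
        strata = toy_strata(rng.normal(size=(10, 11)))
        strata["veght"] = 2.0 * strata["edist"]
        with pytest.raises(ValueError, match="rank"):
            sm.fit_clogit(strata, ("eDist", "Veght"))

    def test_weighted_fit_equals_duplication(self, rng):
        values = rng.normal(size=(15, 6))
        w2 = toy_strata(values, weights=[2.0] * 15)
        dup = toy_strata(np.vstack([values, values]))
        f_w = sm.fit_clogit(w2, ("eDist",))
        f_d = sm.fit_clogit(dup, ("eDist",))
        assert f_w.beta.iloc[0] == pytest.approx(f_d.beta.iloc[0], abs=1e-8)


class TestRobustCov:
    def test_symmetric_psd(self, rng):
        strata = toy_strata(rng.normal(size=(40, 11)))
        fit = sm.fit_clogit(strata, ("eDist",))
        cov = sm.robust_cov(fit, np.arange(40) // 5)
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_duplication_shrinks_se_by_sqrt2(self, rng):
        values = rng.normal(size=(30, 6))
        base = toy_strata(values)
        dup = toy_strata(np.vstack([values, values]))
        f1 = sm.fit_clogit(base, ("eDist",))
        f2 = sm.fit_clogit(dup, ("eDist",))
        assert f2.beta.iloc[0] == pytest.approx(f1.beta.iloc[0], abs=1e-8)
        se1 = np.sqrt(f1.naive_cov[0, 0])
        se2 = np.sqrt(f2.naive_cov[0, 0])
        assert se2 == pytest.approx(se1 / np.sqrt(2), rel=1e-6)
        r1 = np.sqrt(sm.robust_cov(f1, np.arange(30))[0, 0])
        r2 = np.sqrt(sm.robust_cov(f2, np.r_[np.arange(30),
                                             30 + np.arange(30)])[0, 0])
        assert r2 == pytest.approx(r1 / np.sqrt(2), rel=1e-6)

    def test_robust_close_to_naive_when_well_specified(self, wolf_strata):
        fit = sm.fit_clogit(wolf_strata, sm.SSF_MODELS["M2"])
        n = fit.n_strata
        cov = sm.robust_cov(fit, np.arange(n))  # singleton clusters
        ratio = np.sqrt(np.diag(cov)) / np.sqrt(np.diag(fit.naive_cov))
        assert np.all(ratio > 0.8) and np.all(ratio < 1.25)

    def test_too_few_clusters_rejected(self, rng):
        strata = toy_strata(rng.normal(size=(10, 11)))
        fit = sm.fit_clogit(strata, ("eDist",))
        with pytest.raises(ValueError):
            sm.robust_cov(fit, np.zeros(10, dtype=int))


# ---------------------------------------------------------------------------
# Model competition, pooling, prediction
# ---------------------------------------------------------------------------

def fake_fit(qicu, n_strata=100, n_params=1):
    beta = pd.Series(np.zeros(n_params),
                     index=[f"b{i}" for i in range(n_params)])
    return S.CLogitFit(beta=beta, naive_cov=np.eye(n_params),
                       loglik=-(qicu - 2 * n_params) / 2, qicu=qicu,
                       n_strata=n_strata, converged=True)


class TestQicuSelect:
    def test_equal_qicu_gives_equal_weights(self):
        tab = sm.qicu_select({"A": fake_fit(100.0), "B": fake_fit(100.0)})
        assert np.allclose(tab["weight"], 0.5)

    def test_delta_two_weight_ratio(self):
        tab = sm.qicu_select({"A": fake_fit(100.0), "B": fake_fit(102.0)})
        tab = tab.set_index("model")
        assert tab.loc["A", "weight"] == pytest.approx(0.731, abs=1e-3)
        assert tab.loc["B", "weight"] == pytest.approx(0.269, abs=1e-3)
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_differing_strata_counts_rejected(self):
        with pytest.raises(ValueError):
            sm.qicu_select({"A": fake_fit(100.0, n_strata=50),
                            "B": fake_fit(100.0, n_strata=60)})

    def test_noise_covariate_raises_qicu_on_null_data(self, rng):
        # adding a pure-noise term costs ~2 QIC_U points in expectation
        diffs = []
        for s in range(6):
            r = np.random.default_rng(s)
            strata = toy_strata(r.normal(size=(80, 11)))
            strata["density"] = r.normal(size=len(strata))
            f1 = sm.fit_clogit(strata, ("eDist",))
            f2 = sm.fit_clogit(strata, ("eDist", "Density"))
            diffs.append(f2.qicu - f1.qicu)
        assert np.mean(diffs) > 0


class TestPopulationAverage:
    def make(self, beta, var):
        f = fake_fit(100.0)
        f.beta = pd.Series([beta], index=["eDist"])
        f.robust_cov = np.array([[var]])
        return f

    def test_equal_inputs_pool_to_same_value(self):
        pooled = sm.population_average([self.make(1.5, 1.0),
                                        self.make(1.5, 1.0)])
        assert pooled["beta"].iloc[0] == pytest.approx(1.5)

    def test_hand_computed_weighted_means(self):
        pooled = sm.population_average([self.make(1.0, 1.0),
                                        self.make(3.0, 1.0)])
        assert pooled["beta"].iloc[0] == pytest.approx(2.0)
        pooled = sm.population_average([self.make(1.0, 0.25),
                                        self.make(3.0, 1.0)])
        assert pooled["beta"].iloc[0] == pytest.approx(1.4)

    def test_ci_halfwidth_formula(self):
        pooled = sm.population_average([self.make(1.0, 1.0),
                                        self.make(3.0, 1.0)])
        assert pooled["ci_halfwidth"].iloc[0] == \
            pytest.approx(1.96 / np.sqrt(2.0))

    def test_nonconverged_fit_excluded(self):
        bad = self.make(99.0, 1.0)
        bad.converged = False
        pooled = sm.population_average([self.make(1.0, 1.0),
                                        self.make(3.0, 1.0), bad])
        assert pooled["beta"].iloc[0] == pytest.approx(2.0)
        assert pooled["n_individuals"].iloc[0] == 2

    def test_pooled_beta_within_individual_hull(self, wolf_strata):
        fits = []
        for _, sub in wolf_strata.groupby("animal_id"):
            f = sm.fit_clogit(sub.reset_index(drop=True),
                              sm.SSF_MODELS["M2"])
            sm.robust_cov(f, np.arange(f.n_strata) // 10)
            fits.append(f)
        pooled = sm.population_average(fits)
        for k, term in enumerate(pooled["term"]):
            betas = [f.beta.iloc[k] for f in fits]
            assert min(betas) <= pooled["beta"].iloc[k] <= max(betas)


class TestPredictRelativeProb:
    def test_zero_predictor_gives_half(self):
        beta = pd.Series([0.0], index=["eDist"])
        cov = pd.DataFrame({"edist": [0.7]})
        assert sm.predict_relative_prob(beta, cov)[0] == pytest.approx(0.5)

    def test_wolf_nomadic_coefficient_scale(self):
        # beta_eDist = -0.33 evaluated at eDist = 1
        beta = pd.Series([-0.33], index=["eDist"])
        cov = pd.DataFrame({"edist": [1.0]})
        assert sm.predict_relative_prob(beta, cov)[0] == \
            pytest.approx(0.418, abs=1e-3)

    def test_monotone_decreasing_under_negative_beta(self):
        beta = pd.Series([-1.0], index=["eDist"])
        cov = pd.DataFrame({"edist": np.linspace(0, 1, 9)})
        p = sm.predict_relative_prob(beta, cov)
        assert np.all(np.diff(p) < 0)


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

class TestKfoldCV:
    def test_seeded_determinism(self, wolf_strata):
        a = sm.kfold_cv(wolf_strata, sm.SSF_MODELS["M2"], reps=5, seed=3)
        b = sm.kfold_cv(wolf_strata, sm.SSF_MODELS["M2"], reps=5, seed=3)
        assert a == b

    def test_true_model_discriminates(self, wolf_strata):
        cv = sm.kfold_cv(wolf_strata, sm.SSF_MODELS["M2"], reps=20, seed=5)
        assert cv["rs1_mean"] > cv["rs0_mean"]
        assert cv["rs1_mean"] > 0.5

    def test_forced_null_beta_centres_on_zero(self, wolf_strata):
        null = pd.Series([0.0], index=["eDist"])
        cv = sm.kfold_cv(wolf_strata, ("eDist",), reps=30, seed=7,
                         forced_beta=null)
        assert abs(cv["rs1_mean"]) < 0.35

    def test_too_few_strata_rejected(self, rng):
        strata = toy_strata(rng.normal(size=(10, 11)))
        with pytest.raises(ValueError):
            sm.kfold_cv(strata, ("eDist",), reps=2, seed=0)
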