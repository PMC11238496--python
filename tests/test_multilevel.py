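import math

import numpy as np
import pandas as pd
import pytest

from mdfps.dataset import SurveyDataset
from mdfps.multilevel import (
    DesignBundle,
    MultilevelLogistic,
    build_design,
    log_posterior,
)


def tiny_dataset(n=10, seed=0):
    rng = np.random.default_rng(seed)
    women = pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "cluster_id": rng.integers(1, 4, n),
            # tile so every level is guaranteed present at any n
            "residence": np.tile(["urban", "rural"], (n + 1) // 2)[:n],
            "head_sex": np.tile(["male", "male", "female"], (n + 2) // 3)[:n],
            "weight": np.ones(n),
        }
    )
    clusters = pd.DataFrame(
        {"cluster_id": [1, 2, 3], "x_km": [1.0, 2.0, 3.0], "y_km": [1.0, 2.0, 3.0],
         "admin_id": [1, 1, 2]}
    )
    indicator = pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "has_demand": True,
            "mdfps": rng.integers(0, 2, n).astype(bool),
        }
    )
    return SurveyDataset(period="t1", women=women, clusters=clusters), indicator


class TestBuildDesign:
    def test_two_level_field_yields_single_dummy(self):
        ds, ind = tiny_dataset()
        design = build_design(ds, ind, covariates=["residence"], reference={"residence": "urban"})
        assert design.columns == [("residence", "rural")]
        np.testing.assert_array_equal(
            design.X[:, 0], (ds.women["residence"] == "rural").to_numpy(float)
        )

    def test_reference_row_is_all_zero(self):
        ds, ind = tiny_dataset()
        design = build_design(
            ds, ind, ["residence", "head_sex"], {"residence": "urban", "head_sex": "male"}
        )
        ref_rows = (ds.women["residence"] == "urban") & (ds.women["head_sex"] == "male")
        assert (design.X[ref_rows.to_numpy()] == 0).all()

    def test_matches_hand_built_design(self):
        ds, ind = tiny_dataset(10, seed=3)
        design = build_design(
            ds, ind, ["residence", "head_sex"], {"residence": "urban", "head_sex": "male"}
        )
        hand = np.column_stack(
            [
                (ds.women["residence"] == "rural").to_numpy(float),
                (ds.women["head_sex"] == "female").to_numpy(float),
            ]
        )
        np.testing.assert_array_equal(design.X, hand)
        assert design.columns == [("residence", "rural"), ("head_sex", "female")]

    def test_clusters_nested_in_regions(self):
        ds, ind = tiny_dataset(30, seed=1)
        design = build_design(ds, ind, ["residence"], {"residence": "urban"})
        # every cluster index maps to exactly one region index
        pairs = set(zip(design.cluster_idx, design.region_idx))
        assert len(pairs) == design.n_clusters

    def test_absent_reference_level_rejected(self):
        ds, ind = tiny_dataset()
        with pytest.raises(ValueError, match="penthouse"):
            build_design(ds, ind, ["residence"], {"residence": "penthouse"})


class TestLogPosterior:
    def make_design(self, y, X, cluster_idx, region_idx):
        return DesignBundle(
            y=np.asarray(y, float),
            X=np.asarray(X, float),
            columns=[("x", str(j)) for j in range(np.asarray(X).shape[1])],
            cluster_idx=np.asarray(cluster_idx),
            region_idx=np.asarray(region_idx),
            region_of_cluster=np.zeros(np.max(cluster_idx) + 1, dtype=int),
        )

    def test_single_observation_null_model(self):
        design = self.make_design([1.0], np.zeros((1, 0)), [0], [0])
        lp = log_posterior(design, np.zeros(1), np.zeros(1), np.zeros(1), 1.0, 1.0)
        # isolate the Bernoulli term by subtracting the zero-effect prior mass
        lp0 = log_posterior(
            self.make_design([0.0], np.zeros((1, 0)), [0], [0]),
            np.zeros(1), np.zeros(1), np.zeros(1), 1.0, 1.0,
        )
        assert lp == pytest.approx(lp0)  # y=1 and y=0 symmetric at eta=0
        # direct check: the likelihood contribution is log(0.5)
        lp_two = log_posterior(
            self.make_design([1.0, 1.0], np.zeros((2, 0)), [0, 0], [0, 0]),
            np.zeros(1), np.zeros(1), np.zeros(1), 1.0, 1.0,
        )
        assert lp_two - lp == pytest.approx(math.log(0.5), abs=1e-12)

    def test_duplicate_observation_adds_its_likelihood_term(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((5, 2))
        y = rng.integers(0, 2, 5).astype(float)
        beta = np.array([0.1, -0.2, 0.3])
        u, v = np.array([0.05, -0.1]), np.array([0.2, -0.15, 0.1])
        cidx, ridx = np.array([0, 1, 2, 0, 1]), np.array([0, 0, 1, 0, 0])
        d5 = self.make_design(y, X, cidx, ridx)
        d5.region_of_cluster = np.array([0, 0, 1])
        d6 = self.make_design(
            np.append(y, y[2]), np.vstack([X, X[2]]), np.append(cidx, cidx[2]),
            np.append(ridx, ridx[2]),
        )
        d6.region_of_cluster = np.array([0, 0, 1])
        lp5 = log_posterior(d5, beta, u, v, 0.5, 0.5)
        lp6 = log_posterior(d6, beta, u, v, 0.5, 0.5)
        eta = beta[0] + X[2] @ beta[1:] + u[1] + v[2]
        expected = y[2] * eta - math.log1p(math.exp(eta))
        assert lp6 - lp5 == pytest.approx(expected, abs=1e-10)

    def test_matches_naive_term_by_term_oracle(self):
        """Brute-force oracle: sum scalar Bernoulli + Normal terms in python."""
        rng = np.random.default_rng(9)
        n, p, C, R = 40, 3, 6, 2
        X = rng.standard_normal((n, p))
        y = rng.integers(0, 2, n).astype(float)
        cidx = rng.integers(0, C, n)
        ridx = np.array([0, 0, 0, 1, 1, 1])[cidx]
        design = self.make_design(y, X, cidx, ridx)
        design.region_of_cluster = np.array([0, 0, 0, 1, 1, 1])
        beta = rng.normal(scale=0.3, size=p + 1)
        u = rng.normal(scale=0.4, size=R)
        v = rng.normal(scale=0.3, size=C)
        s2r, s2c = 0.16, 0.09
        got = log_posterior(design, beta, u, v, s2r, s2c, prior_beta_sd=10.0, prior_sigma_sd=1.0)

        expected = 0.0
        for i in range(n):
            eta = beta[0] + float(X[i] @ beta[1:]) + u[ridx[i]] + v[cidx[i]]
            pi = 1.0 / (1.0 + math.exp(-eta))
            expected += math.log(pi) if y[i] == 1 else math.log(1.0 - pi)
        for val, s2 in [(ui, s2r) for ui in u] + [(vi, s2c) for vi in v]:
            expected += -0.5 * val**2 / s2 - 0.5 * math.log(2 * math.pi * s2)
        for b in beta:
            expected += -0.5 * b**2 / 100.0 - 0.5 * math.log(2 * math.pi * 100.0)
        for s2 in (s2r, s2c):
            expected += -0.5 * s2 / 1.0 + 0.5 * math.log(2 / math.pi)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        design = self.make_design([1.0], np.zeros((1, 0)), [0], [0])
        assert log_posterior(design, np.zeros(1), np.zeros(1), np.zeros(1), 0.0, 1.0) == -np.inf


class TestSummaries:
    def make_fitted(self, beta_draws):
        m = MultilevelLogistic()
        m.columns_ = [("intercept", ""), ("residence", "rural")]
        m.beta_draws_ = beta_draws
        m.sigma2_cluster_draws_ = np.full(len(beta_draws), 0.2)
        m.sigma2_region_draws_ = np.full(len(beta_draws), 0.3)
        return m

    def test_zero_draws_give_unit_or(self):
        m = self.make_fitted(np.zeros((100, 2)))
        tab = m.summarize().set_index("field")
        row = tab.loc["residence"]
        assert (row["or_mean"], row["or_2.5%"], row["or_97.5%"]) == (1.0, 1.0, 1.0)

    def test_constant_log2_draws_give_or_two(self):
        m = self.make_fitted(np.full((50, 2), np.log(2.0)))
        assert m.summarize()["or_mean"].iloc[1] == pytest.approx(2.0, abs=1e-12)

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(400, 2))
        m = self.make_fitted(draws)
        tab = m.summarize()
        orr = np.sort(np.exp(draws[:, 1]))
        assert tab["or_2.5%"].iloc[1] == pytest.approx(np.quantile(orr, 0.025), rel=1e-12)
        assert tab["or_97.5%"].iloc[1] == pytest.approx(np.quantile(orr, 0.975), rel=1e-12)


class TestFit:
    def test_fit_recovers_rural_deficit(self, multilevel_survey, multilevel_indicator):
        m = MultilevelLogistic(
            covariates=["residence"],
            n_chains=2,
            n_warmup=300,
            n_draws=250,
            seed=11,
        ).fit(multilevel_survey, multilevel_indicator)
        tab = m.summarize().set_index(["field", "level"])
        orr = tab.loc[("residence", "rural"), "or_mean"]
        assert 0.3 < orr < 1.0  # truth 0.6, generous Monte Carlo band
        assert m.diagnostics_["divergent_frac"] <= 0.1

    def test_permuting_cluster_labels_leaves_summaries_stable(
        self, multilevel_survey, multilevel_indicator
    ):
        rng = np.random.default_rng(0)
        relabel = dict(
            zip(
                multilevel_survey.clusters["cluster_id"],
                rng.permutation(multilevel_survey.clusters["cluster_id"].to_numpy()),
            )
        )
        women = multilevel_survey.women.copy()
        women["cluster_id"] = women["cluster_id"].map(relabel)
        clusters = multilevel_survey.clusters.copy()
        clusters["cluster_id"] = clusters["cluster_id"].map(relabel)
        shuffled = SurveyDataset(period="t1", women=women, clusters=clusters)
        kw = dict(covariates=["residence"], n_chains=2, n_warmup=300, n_draws=250, seed=11)
        a = MultilevelLogistic(**kw).fit(multilevel_survey, multilevel_indicator)
        b = MultilevelLogistic(**kw).fit(shuffled, multilevel_indicator)
        ora = a.summarize().set_index(["field", "level"])["or_mean"]
        orb = b.summarize().set_index(["field", "level"])["or_mean"]
        assert ora.loc[("residence", "rural")] == pytest.approx(
            orb.loc[("residence", "rural")], abs=0.12
        )

    def test_single_class_outcome_rejected(self):
        ds, ind = tiny_dataset(12, seed=2)
        ind["mdfps"] = True
        with pytest.raises(ValueError, match="both classes"):
            MultilevelLogistic(covariates=["residence"]).fit(ds, ind)

    def test_separation_warns_with_level_name(self):
        ds, ind = tiny_dataset(40, seed=4)
        ind["mdfps"] = (ds.women["head_sex"] == "female").to_numpy()
        ds.clusters.loc[:, "admin_id"] = [1, 2, 2]
        with pytest.warns(UserWarning, match="head_sex=female"):
            try:
                MultilevelLogistic(
                    covariates=["head_sex"], n_chains=2, n_warmup=80, n_draws=50,
                    check_convergence=False,
                ).fit(ds, ind)
            except RuntimeError:
                pass  # a divergence failure on separated data is acceptable here

    def test_get_set_params_roundtrip(self):
        m = MultilevelLogistic(n_draws=123)
        params = m.get_params()
        assert params["n_draws"] == 123
        m.set_params(n_warmup=77)
        assert m.n_warmup == 77
        with pytest.raises(ValueError, match="invalid parameter"):
            m.set_params(banana=1)
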