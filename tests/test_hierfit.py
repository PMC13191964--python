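"""Model-fitting core: likelihood arithmetic, starting values, sampler
validity against a deterministic quadrature oracle, and chain diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from lbwsae import (
    FitConfig,
    GeneratorConfig,
    ModelParams,
    diagnose,
    fit_mcmc,
    generate_survey,
    log_likelihood,
    quadrature_posterior,
    starting_values,
)

from conftest import make_survey


def _zero_residuals(data):
    return {
        "u": {c: 0.0 for c in data["cluster_id"].unique()},
        "v": {d: 0.0 for d in data["district_id"].unique()},
        "f": {s: 0.0 for s in data["state_id"].unique()},
    }


class TestLogLikelihood:
    def test_single_birth_at_even_odds(self):
        data = make_survey({("S1", "D1", "c1"): [1]})
        ll = log_likelihood(data, ModelParams(0.0, 1, 1, 1), _zero_residuals(data))
        assert ll == pytest.approx(math.log(0.5))

    def test_two_births_zero_linear_predictor(self):
        data = make_survey({("S1", "D1", "c1"): [1, 0]})
        ll = log_likelihood(data, ModelParams(0.0, 1, 1, 1), _zero_residuals(data))
        assert ll == pytest.approx(2 * math.log(0.5))

    def test_matches_per_row_brute_force(self, rng):
        data = make_survey({
            ("S1", "D1", "c1"): rng.integers(0, 2, 7).tolist(),
            ("S1", "D1", "c2"): rng.integers(0, 2, 4).tolist(),
            ("S1", "D2", "c3"): rng.integers(0, 2, 6).tolist(),
            ("S2", "D3", "c4"): rng.integers(0, 2, 5).tolist(),
        })
        res = {
            "u": {c: rng.normal() for c in data["cluster_id"].unique()},
            "v": {d: rng.normal() for d in data["district_id"].unique()},
            "f": {s: rng.normal() for s in data["state_id"].unique()},
        }
        params = ModelParams(-0.7, 1, 1, 1)
        # independent per-row oracle
        expected = 0.0
        for _, row in data.iterrows():
            eta = (params.beta0 + res["u"][row.cluster_id]
                   + res["v"][row.district_id] + res["f"][row.state_id])
            p = 1 / (1 + math.exp(-eta))
            expected += math.log(p if row.lbw == 1 else 1 - p)
        assert log_likelihood(data, params, res) == pytest.approx(expected)

    def test_unmatched_identifier_is_named(self):
        data = make_survey({("S1", "D1", "c1"): [1]})
        res = _zero_residuals(data)
        del res["u"]["c1"]
        with pytest.raises(KeyError, match="c1"):
            log_likelihood(data, ModelParams(0.0, 1, 1, 1), res)


class TestStartingValues:
    def test_even_prevalence_starts_at_zero(self):
        data = make_survey({("S1", "D1", "c1"): [1, 0, 1, 0]})
        params, res = starting_values(data)
        assert params.beta0 == pytest.approx(0.0)
        assert all(v == 0.0 for v in res["u"].values())

    def test_logit_of_pooled_prevalence(self):
        # 1824 of 10000 positive -> logit(0.1824) ~ -1.5
        ys = [1] * 1824 + [0] * (10_000 - 1824)
        data = make_survey({("S1", "D1", "c1"): ys})
        params, _ = starting_values(data)
        assert params.beta0 == pytest.approx(math.log(0.1824 / 0.8176), abs=1e-9)
        assert abs(params.beta0 - (-1.5)) < 0.01

    def test_all_one_outcomes_clamped_with_warning(self):
        data = make_survey({("S1", "D1", "c1"): [1, 1, 1]})
        with pytest.warns(RuntimeWarning, match="clamped"):
            params, _ = starting_values(data)
        assert np.isfinite(params.beta0)

    def test_empty_data_is_an_error(self):
        data = make_survey({("S1", "D1", "c1"): [1]}).iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            starting_values(data)


class TestFitMcmc:
    def test_single_iteration_chain(self, two_cluster_data):
        with pytest.warns(RuntimeWarning, match="shallow"):
            draws = fit_mcmc(two_cluster_data, FitConfig(n_burnin=0, n_iter=1, seed=0))
        assert draws.n_draws == 1
        assert draws.u.shape == (1, 2)

    def test_variance_draws_positive_residuals_finite(self):
        survey = generate_survey(GeneratorConfig(
            n_states=4, districts_per_state=3, clusters_per_district=4,
            births_per_cluster=15, missing_rate=0.0, waves=("W",), seed=6))
        draws = fit_mcmc(survey.data, FitConfig(n_burnin=100, n_iter=300, seed=1))
        for name in ("sigma2_u", "sigma2_v", "sigma2_f"):
            assert (getattr(draws, name) > 0).all()
        for name in ("u", "v", "f"):
            assert np.isfinite(getattr(draws, name)).all()
        assert draws.meta["n_burnin"] == 100

    def test_row_order_does_not_change_the_chain(self, rng):
        survey = generate_survey(GeneratorConfig(
            n_states=3, districts_per_state=2, clusters_per_district=3,
            births_per_cluster=10, missing_rate=0.0, waves=("W",), seed=8))
        cfg = FitConfig(n_burnin=50, n_iter=200, seed=99)
        a = fit_mcmc(survey.data, cfg)
        shuffled = survey.data.sample(frac=1.0, random_state=4).reset_index(drop=True)
        b = fit_mcmc(shuffled, cfg)
        np.testing.assert_array_equal(a.beta0, b.beta0)
        np.testing.assert_array_equal(a.u, b.u)
        assert list(a.cluster_ids) == list(b.cluster_ids)

    def test_multiple_waves_rejected(self):
        df = pd.concat([
            make_survey({("S1", "D1", "c1"): [1, 0]}, wave="W1"),
            make_survey({("S1", "D1", "c1"): [1, 0]}, wave="W2"),
        ])
        with pytest.raises(ValueError, match="wave"):
            fit_mcmc(df)

    def test_missing_outcomes_rejected(self, two_cluster_data):
        df = two_cluster_data.copy()
        df.loc[0, "lbw"] = pd.NA
        with pytest.raises(ValueError, match="missing"):
            fit_mcmc(df)

    @pytest.mark.parametrize("sampler", ["mh", "pg"])
    def test_posterior_matches_quadrature_oracle(self, sampler, two_cluster_data):
        """Reduced model (district/state levels off, cluster variance fixed):
        MCMC means must sit within 3 Monte-Carlo SEs of grid integration."""
        import arviz as az

        oracle = quadrature_posterior([1, 4], [5, 5], sigma2_u=0.5)
        cfg = FitConfig(n_burnin=1000, n_iter=8000, sampler=sampler, seed=17,
                        fixed_sigma2={"u": 0.5, "v": 0.0, "f": 0.0})
        with pytest.warns(RuntimeWarning, match="shallow"):
            draws = fit_mcmc(two_cluster_data, cfg)
        chains = {"beta0": draws.beta0,
                  "u1": draws.u[:, 0].astype(float), "u2": draws.u[:, 1].astype(float)}
        targets = {"beta0": oracle["beta0_mean"],
                   "u1": oracle["u_mean"][0], "u2": oracle["u_mean"][1]}
        for name, chain in chains.items():
            ess = float(az.ess(chain[None, :]))
            mcse = chain.std(ddof=1) / math.sqrt(ess)
            assert abs(chain.mean() - targets[name]) < 3 * mcse, name
        # inactive levels pinned exactly
        assert np.all(draws.v == 0.0) and np.all(draws.f == 0.0)


class TestDiagnose:
    def _draws_from_chain(self, x):
        from lbwsae.hierfit import PosteriorDraws
        n = x.size
        return PosteriorDraws(
            beta0=x, sigma2_u=np.full(n, 0.2), sigma2_v=np.full(n, 0.2),
            sigma2_f=np.full(n, 0.2), u=np.zeros((n, 1), np.float32),
            v=np.zeros((n, 1), np.float32), f=np.zeros((n, 1), np.float32),
            cluster_ids=np.array(["c"]), district_ids=np.array(["d"]),
            state_ids=np.array(["s"]), cluster_district=np.array([0]),
            cluster_state=np.array([0]), district_state=np.array([0]), meta={})

    def test_iid_chain_ess_near_n(self, rng):
        n = 4000
        rep = diagnose(self._draws_from_chain(rng.standard_normal(n)))
        ess = rep.table.set_index("param").loc["beta0", "ess"]
        assert abs(ess - n) < 0.2 * n

    def test_constant_chain_flagged_degenerate(self, rng):
        rep = diagnose(self._draws_from_chain(np.zeros(100)))
        row = rep.table.set_index("param").loc["sigma2_u"]
        assert row["degenerate"]
        assert any("degenerate" in f for f in rep.flags)

    def test_ar1_chain_ess_matches_closed_form(self, rng):
        n, rho = 40_000, 0.7
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        rep = diagnose(self._draws_from_chain(x))
        ess = rep.table.set_index("param").loc["beta0", "ess"]
        closed = n * (1 - rho) / (1 + rho)
        assert abs(ess - closed) < 0.2 * closed
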