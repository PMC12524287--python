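"""Royle-Nichols and MacKenzie likelihoods against independent oracles,
parameter recovery, derived quantities."""

import math

import numpy as np
import pandas as pd
import pytest

from occumap import (
    DetectionHistory,
    MacKenzieOccupancy,
    ModelSpec,
    RoyleNichols,
    choose_truncation,
    rn_loglik,
)
from conftest import rn_dataset


def make_history(matrix):
    m = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(
        m,
        index=pd.Index([f"s{i}" for i in range(m.shape[0])], name="station_id"),
        columns=[f"occ_{j + 1}" for j in range(m.shape[1])],
    )
    return DetectionHistory(df, 5, {})


def brute_force_rn(matrix, lam, r, K):
    """Term-by-term truncated enumeration of the Royle-Nichols likelihood."""
    total = 0.0
    for i, row in enumerate(matrix):
        site = 0.0
        for n in range(K + 1):
            pois = math.exp(-lam[i]) * lam[i] ** n / math.factorial(n)
            prod = 1.0
            for y in row:
                if np.isnan(y):
                    continue
                p_det = 1.0 - (1.0 - r[i]) ** n
                prod *= p_det if y == 1 else (1.0 - p_det)
            site += prod * pois
        total += math.log(site)
    return total


class TestRNLoglik:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        matrix = (rng.uniform(size=(3, 4)) < 0.4).astype(float)
        if seed == 3:  # exercise missing occasions too
            matrix[1, 3] = np.nan
        hist = make_history(matrix)
        x = rng.normal(size=3)
        w = rng.normal(size=3)
        X = np.column_stack([np.ones(3), x])
        W = np.column_stack([np.ones(3), w])
        params = np.array([-0.2, 0.4, -0.6, 0.3])
        lam = np.exp(X @ params[:2])
        r = 1 / (1 + np.exp(-(W @ params[2:])))
        expect = brute_force_rn(matrix, lam, r, 15)
        got = rn_loglik(params, hist, X, W, K=15)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_all_zero_history_closed_form_grid(self):
        # site likelihood -> exp(-lam (1 - (1-r)^J)) as K -> infinity
        for lam in (0.2, 1.0, 3.0):
            for r in (0.05, 0.3, 0.8):
                for J in (3, 5, 10):
                    hist = make_history(np.zeros((1, J)))
                    X = W = np.ones((1, 1))
                    params = np.array([np.log(lam), np.log(r / (1 - r))])
                    got = rn_loglik(params, hist, X, W)
                    expect = -lam * (1 - (1 - r) ** J)
                    assert got == pytest.approx(expect, abs=1e-8)

    def test_certain_detection_with_mixed_history_is_impossible(self):
        hist = make_history([[1.0, 0.0, 1.0]])
        X = W = np.ones((1, 1))
        params = np.array([0.0, 40.0])  # r -> 1
        assert rn_loglik(params, hist, X, W) < -1e8 or np.isinf(
            rn_loglik(params, hist, X, W)
        )

    def test_truncation_increase_changes_nothing_beyond_tolerance(self):
        hist = make_history((np.arange(12).reshape(4, 3) % 2).astype(float))
        X = W = np.ones((4, 1))
        params = np.array([0.5, -0.5])
        K0 = choose_truncation(float(np.exp(0.5)))
        base = rn_loglik(params, hist, X, W, K=K0)
        assert rn_loglik(params, hist, X, W, K=K0 + 50) == pytest.approx(base, abs=1e-9)

    def test_station_and_occasion_reordering_invariance(self):
        rng = np.random.default_rng(11)
        matrix = (rng.uniform(size=(6, 5)) < 0.5).astype(float)
        X = W = np.ones((6, 1))
        params = np.array([0.1, -0.4])
        base = rn_loglik(params, make_history(matrix), X, W)
        assert rn_loglik(params, make_history(matrix[::-1]), X, W) == pytest.approx(base)
        assert rn_loglik(params, make_history(matrix[:, ::-1]), X, W) == pytest.approx(base)

    def test_insufficient_truncation_rejected(self):
        hist = make_history(np.zeros((1, 3)))
        X = W = np.ones((1, 1))
        with pytest.raises(ValueError, match="tail mass"):
            rn_loglik(np.array([np.log(40.0), 0.0]), hist, X, W, K=10)


class TestFitRN:
    def test_intercept_recovery_within_three_se(self):
        history, cov, _ = rn_dataset(seed=3, n=500, J=10, beta0=0.0)
        res = RoyleNichols(history, cov, ModelSpec()).fit(restarts=1, seed=0)
        assert res.converged
        b0, se = res.params["lam:(Intercept)"], res.bse["lam:(Intercept)"]
        assert abs(b0 - 0.0) <= 3 * se

    def test_duplicated_covariate_rejected(self):
        history, cov, _ = rn_dataset(seed=4, n=60, J=6, beta_x=0.5)
        cov = cov.copy()
        cov["x2"] = cov["x"]
        with pytest.raises(ValueError, match="rank"):
            RoyleNichols(history, cov, ModelSpec(("x", "x2"), ()))

    def test_aic_identity_and_serialization(self, small_fit, tmp_path):
        assert small_fit.aic == pytest.approx(-2 * small_fit.llf + 2 * small_fit.df_model)
        small_fit.to_json(tmp_path / "fit.json")
        import json

        payload = json.loads((tmp_path / "fit.json").read_text())
        assert payload["n_params"] == 2 and payload["converged"]

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec(("a", "a:b"), ())


class TestDerivedParameters:
    def test_psi_and_p_closed_forms(self, small_fit):
        der = small_fit.derived_parameters()
        lam = small_fit.station_lambda().to_numpy()
        r = small_fit.station_r().to_numpy()
        assert np.allclose(der["psi"], 1 - np.exp(-lam))
        # p = 1 - E[(1-r)^N] = 1 - exp(-lam r) for Poisson N
        assert np.allclose(der["p"], 1 - np.exp(-lam * r), atol=1e-8)
        assert ((der["psi"] >= 0) & (der["psi"] <= 1)).all()

    def test_psi_half_when_lambda_is_log_two(self):
        assert 1 - np.exp(-np.log(2.0)) == pytest.approx(0.5)

    def test_station_detection_given_two_individuals(self):
        # 1 - (1-r)^N at r = 0.5, N = 2
        assert 1 - (1 - 0.5) ** 2 == pytest.approx(0.75)


def brute_force_mackenzie(matrix, psi, p):
    total = 0.0
    for i, row in enumerate(matrix):
        obs = [y for y in row if not np.isnan(y)]
        lik_occ = psi[i]
        for y in obs:
            lik_occ *= p[i] if y == 1 else (1 - p[i])
        lik = lik_occ + (0.0 if any(y == 1 for y in obs) else 1 - psi[i])
        total += math.log(lik)
    return total


class TestMacKenzie:
    def test_two_site_toy_matches_hand_computation(self):
        matrix = np.array([[1.0, 0.0], [0.0, 0.0]])
        hist = make_history(matrix)
        model = MacKenzieOccupancy(hist, None, ModelSpec())
        psi, p = 0.6, 0.3
        params = np.array([np.log(psi / (1 - psi)), np.log(p / (1 - p))])
        # hand computation: site1 psi*p*(1-p); site2 psi*(1-p)^2 + (1-psi)
        expect = math.log(0.6 * 0.3 * 0.7) + math.log(0.6 * 0.7**2 + 0.4)
        assert model.loglik(params) == pytest.approx(expect, abs=1e-12)
        assert model.loglik(params) == pytest.approx(
            brute_force_mackenzie(matrix, [psi] * 2, [p] * 2), abs=1e-12
        )

    def test_all_one_histories_hit_boundary(self):
        hist = make_history(np.ones((20, 5)))
        res = MacKenzieOccupancy(hist, None, ModelSpec()).fit(restarts=1, seed=0)
        assert res.psi().iloc[0] > 0.99
        assert res.p().iloc[0] > 0.99
        assert res.at_boundary

    def test_rn_preferred_on_abundance_heterogeneous_data(self):
        history, cov, _ = rn_dataset(seed=5, n=300, J=10)
        rn = RoyleNichols(history, cov, ModelSpec()).fit(restarts=1, seed=0)
        mk = MacKenzieOccupancy(history, cov, ModelSpec()).fit(restarts=1, seed=0)
        assert rn.aic < mk.aic
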