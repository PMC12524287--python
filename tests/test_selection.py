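"""AIC ranking, univariate screening, all-subsets enumeration, conditional
model averaging."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from occumap import (
    ModelSpec,
    RoyleNichols,
    akaike_weights,
    all_subsets,
    model_average,
    univariate_screen,
)
from occumap.selection import enumerate_subsets
from conftest import rn_dataset


class FakeSpec:
    def __init__(self, terms, label):
        self.abundance_terms = tuple(terms)
        self._label = label

    def label(self):
        return self._label


class FakeFit:
    """Minimal stand-in exposing the results interface the selection code uses."""

    def __init__(self, aic, k=3, betas=None, ses=None, label="m"):
        self.aic = aic
        self.df_model = k
        self.llf = -(aic - 2 * k) / 2
        self.converged = True
        self._betas = betas or {}
        self._ses = ses or {name: 0.1 for name in self._betas}
        self.spec = FakeSpec(self._betas, label)

    def abundance_params(self):
        return pd.Series(self._betas)

    def abundance_bse(self):
        return pd.Series(self._ses)


class TestAkaikeWeights:
    def test_delta_two_gives_073_027(self):
        ms = akaike_weights([FakeFit(100.0), FakeFit(102.0)])
        assert np.round(ms.weights, 3).tolist() == [0.731, 0.269]

    def test_single_model_weight_one(self):
        ms = akaike_weights([FakeFit(10.0)])
        assert ms.weights.tolist() == [1.0]

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        ms = akaike_weights([FakeFit(a) for a in rng.uniform(100, 120, 12)])
        assert ms.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_aic_ties_broken_by_fewer_parameters(self):
        ms = akaike_weights([FakeFit(100.0, k=5), FakeFit(100.0, k=3)])
        assert ms.fits[0].df_model == 3

    def test_all_unconverged_rejected(self):
        bad = FakeFit(10.0)
        bad.converged = False
        with pytest.raises(ValueError, match="converged"):
            akaike_weights([bad])


class TestEnumerateSubsets:
    def test_two_mains_no_interaction_gives_four_models(self):
        assert len(enumerate_subsets(["a", "b"])) == 4

    def test_interaction_only_atop_both_mains_gives_five(self):
        subsets = enumerate_subsets(["a", "b"], ["a:b"])
        assert len(subsets) == 5
        assert ("a", "b", "a:b") in subsets
        assert all("a:b" not in s or ("a" in s and "b" in s) for s in subsets)

    def test_matches_independent_powerset_enumeration_m4(self):
        mains = ["a", "b", "c", "d"]
        got = {frozenset(s) for s in enumerate_subsets(mains, ["a:b"])}
        # independent enumeration: every powerset member, duplicated with the
        # interaction wherever both parents are present
        expect = set()
        for sub in chain.from_iterable(combinations(mains, k) for k in range(5)):
            expect.add(frozenset(sub))
            if "a" in sub and "b" in sub:
                expect.add(frozenset(sub) | {"a:b"})
        assert got == expect
        assert len(got) == 16 + 4


class TestModelAverage:
    def test_single_model_returns_its_betas(self):
        fit = FakeFit(100.0, betas={"(Intercept)": 0.5, "x": 1.2})
        avg = model_average(akaike_weights([fit]), 0.95)
        assert avg.table.loc["x", "estimate"] == pytest.approx(1.2)

    def test_equal_weight_models_average_to_midpoint(self):
        f1 = FakeFit(100.0, betas={"(Intercept)": 0.0, "z": 1.0})
        f2 = FakeFit(100.0, betas={"(Intercept)": 0.0, "z": 3.0})
        avg = model_average(akaike_weights([f1, f2]), 0.95)
        assert avg.table.loc["z", "estimate"] == pytest.approx(2.0)

    def test_conditional_rule_single_containing_model(self):
        f1 = FakeFit(100.0, betas={"(Intercept)": 0.1, "z": 1.7})
        f2 = FakeFit(100.5, betas={"(Intercept)": 0.2})
        avg = model_average(akaike_weights([f1, f2]), 0.95)
        assert avg.table.loc["z", "estimate"] == pytest.approx(1.7)
        assert avg.table.loc["z", "n_models"] == 1

    def test_subset_is_smallest_prefix_reaching_threshold(self):
        fits = [FakeFit(a) for a in (100.0, 101.0, 102.0, 110.0)]
        ms = akaike_weights(fits)
        avg = model_average(ms, 0.95)
        n = len(avg.subset)
        assert ms.weights[:n].sum() >= 0.95
        assert ms.weights[: n - 1].sum() < 0.95
        assert avg.cumulative_weight == pytest.approx(ms.weights[:n].sum())

    def test_average_within_component_range(self):
        rng = np.random.default_rng(1)
        fits = []
        for i in range(6):
            betas = {"(Intercept)": rng.normal()}
            if i % 2 == 0:
                betas["z"] = rng.normal()
            fits.append(FakeFit(float(100 + rng.uniform(0, 4)), betas=betas))
        avg = model_average(akaike_weights(fits), 0.95)
        zs = [f._betas["z"] for f in fits if "z" in f._betas]
        assert min(zs) <= avg.table.loc["z", "estimate"] <= max(zs)

    def test_unconditional_se_combines_within_and_between(self):
        f1 = FakeFit(100.0, betas={"z": 1.0}, ses={"z": 0.5})
        f2 = FakeFit(100.0, betas={"z": 3.0}, ses={"z": 0.5})
        avg = model_average(akaike_weights([f1, f2]), 0.95)
        expect = np.sqrt(0.5 * (0.25 + 1.0) + 0.5 * (0.25 + 1.0))
        assert avg.table.loc["z", "se"] == pytest.approx(expect)


class TestScreeningAndDredge:
    def test_strong_covariate_retained_and_null_not(self):
        history, cov, _ = rn_dataset(seed=2, n=300, J=8, beta_x=1.0)
        out = univariate_screen(history, cov, ["x"], restarts=0)
        assert out["retained"] == ["x"]

    def test_screening_power_and_false_retention(self):
        keep_signal = 0
        keep_noise = 0
        n_rep = 40
        for s in range(n_rep):
            history, cov, _ = rn_dataset(seed=100 + s, n=300, J=8, beta_x=1.0)
            rng = np.random.default_rng(1000 + s)
            cov = cov.copy()
            cov["noise"] = rng.normal(size=len(cov))
            out = univariate_screen(history, cov, ["x", "noise"], restarts=0)
            keep_signal += "x" in out["retained"]
            keep_noise += "noise" in out["retained"]
        assert keep_signal / n_rep >= 0.95
        assert keep_noise / n_rep <= 0.40  # chance retention (delta-AIC < 0)

    def test_dredge_enumeration_and_weights(self):
        history, cov, _ = rn_dataset(seed=6, n=200, J=8, beta_x=0.8)
        cov = cov.copy()
        rng = np.random.default_rng(60)
        cov["w"] = rng.normal(size=len(cov))
        ms, excluded = all_subsets(
            ModelSpec(("x", "w", "x:w"), ()), history, cov, restarts=0
        )
        assert len(ms.fits) + len(excluded) == 5
        assert ms.weights.sum() == pytest.approx(1.0)
        # the data-generating covariate should top the ranking
        assert "x" in ms.best.spec.abundance_terms

    def test_averaged_sign_matches_truth(self):
        hits = 0
        n_rep = 30
        for s in range(n_rep):
            history, cov, _ = rn_dataset(seed=300 + s, n=300, J=8, beta_x=0.8)
            cov = cov.copy()
            cov["w"] = np.random.default_rng(2000 + s).normal(size=len(cov))
            ms, _ = all_subsets(ModelSpec(("x", "w"), ()), history, cov, restarts=0)
            avg = model_average(ms, 0.95)
            if "x" in avg.table.index and avg.table.loc["x", "estimate"] > 0:
                hits += 1
        assert hits / n_rep >= 0.9
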