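"""Cox screening, lasso path, risk scores; partial-likelihood oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from irlncpair._stats import breslow_partial_loglik
from irlncpair.errors import DegenerateFitError, FormatError
from irlncpair.pairs import PairMatrix
from irlncpair.signature import (
    SignatureModel,
    compute_risk_score,
    fit_lasso_cox,
    lasso_path,
    screen_pairs,
    univariate_cox,
)

from conftest import exponential_survival


def max_pl_beta(x, time, event):
    """Oracle: scalar maximizer of the Breslow partial likelihood."""
    res = minimize_scalar(
        lambda b: -breslow_partial_loglik(b * np.asarray(x), time, event),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-8},
    )
    return res.x


class TestUnivariateCox:
    def test_closed_form_four_subjects(self, toy_survival):
        surv, x = toy_survival
        fit = univariate_cox(x, surv)
        # dlogPL/dbeta = 0  =>  exp(2 beta) = 2
        assert fit.beta == pytest.approx(0.5 * np.log(2), abs=1e-3)
        assert fit.ci_low < fit.hr < fit.ci_high
        assert 0 <= fit.p <= 1

    def test_sign_equivariance(self, toy_survival):
        surv, x = toy_survival
        plus = univariate_cox(x, surv)
        minus = univariate_cox(-x, surv)
        assert minus.beta == pytest.approx(-plus.beta, abs=1e-6)

    def test_constant_covariate_is_degenerate(self, toy_survival):
        surv, x = toy_survival
        with pytest.raises(DegenerateFitError, match="constant"):
            univariate_cox(pd.Series(1.0, index=x.index), surv)

    def test_too_few_events_is_degenerate(self, toy_survival):
        surv, x = toy_survival
        surv.data["event"] = [1, 0, 0, 0]
        with pytest.raises(DegenerateFitError, match="events"):
            univariate_cox(x, surv)

    def test_matches_partial_likelihood_maximizer(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 8
            x = rng.standard_normal(n)
            samples = [f"S{i}" for i in range(n)]
            surv = exponential_survival(rng, 0.7 * x, samples, baseline=1e-3)
            if surv.event.sum() < 3:
                continue
            fit = univariate_cox(pd.Series(x, index=samples, name="x"), surv)
            oracle = max_pl_beta(x, surv.time.to_numpy(), surv.event.to_numpy())
            assert fit.beta == pytest.approx(oracle, abs=1e-4)


def planted_pair_cohort(rng, n=300, k_signal=5, k_null=15, beta=0.8):
    cols = {}
    for i in range(k_signal + k_null):
        cols[f"P{i:02d}a|P{i:02d}b"] = rng.integers(0, 2, size=n)
    pm = PairMatrix(pd.DataFrame(cols, index=[f"S{i}" for i in range(n)]))
    lp = pm.values.iloc[:, :k_signal].to_numpy() @ np.full(k_signal, beta)
    surv = exponential_survival(rng, lp, pm.sample_ids)
    return pm, surv


class TestScreen:
    def test_planted_pairs_have_power(self):
        rng = np.random.default_rng(1)
        pm, surv = planted_pair_cohort(rng, k_signal=10, k_null=0)
        kept, fits = screen_pairs(pm, surv)
        assert len(kept.pair_names) >= 9  # >=90% of beta=0.8 pairs at n=300

    def test_invalid_threshold_rejected(self):
        rng = np.random.default_rng(2)
        pm, surv = planted_pair_cohort(rng, n=50)
        with pytest.raises(ValueError):
            screen_pairs(pm, surv, p_max=0.0)

    def test_constant_pairs_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        pm, surv = planted_pair_cohort(rng, n=100, k_signal=3, k_null=0)
        vals = pm.values.copy()
        vals["Z0|Z1"] = 0
        pm2 = PairMatrix(vals)
        with caplog.at_level("WARNING"):
            kept, _ = screen_pairs(pm2, surv)
        assert "Z0|Z1" not in kept.pair_names
        assert "dropping pair" in caplog.text


class TestLassoCox:
    def test_full_shrinkage_at_large_lambda(self):
        rng = np.random.default_rng(4)
        pm, surv = planted_pair_cohort(rng, n=150)
        alphas, coefs = lasso_path(pm, surv, alphas=[1e3])
        assert np.all(coefs == 0.0)
        with pytest.raises(DegenerateFitError, match="no pairs"):
            fit_lasso_cox(pm, surv, alphas=[1e3], seed=0)

    def test_nonzero_count_monotone_along_path(self):
        rng = np.random.default_rng(5)
        pm, surv = planted_pair_cohort(rng, n=200)
        alphas, coefs = lasso_path(pm, surv)
        nnz = (coefs != 0).sum(axis=0)
        # alphas descending: support can only grow (weak monotonicity)
        assert np.all(np.diff(nnz) >= 0)

    def test_unpenalized_single_feature_matches_max_partial_likelihood(self):
        rng = np.random.default_rng(6)
        n = 120
        x = rng.integers(0, 2, size=n)
        samples = [f"S{i}" for i in range(n)]
        surv = exponential_survival(rng, 0.9 * x, samples)
        pm = PairMatrix(pd.DataFrame({"A|B": x}, index=samples))
        model = fit_lasso_cox(pm, surv, alphas=[1e-9], seed=0)
        oracle = max_pl_beta(x, surv.time.to_numpy(), surv.event.to_numpy())
        assert model.betas[0] == pytest.approx(oracle, abs=1e-4)

    def test_recovers_planted_support(self):
        rng = np.random.default_rng(7)
        pm, surv = planted_pair_cohort(rng)
        kept, _ = screen_pairs(pm, surv)
        model = fit_lasso_cox(kept, surv, seed=0)
        planted = {f"P{i:02d}a|P{i:02d}b" for i in range(5)}
        assert len(planted & set(model.pair_names)) >= 3

    def test_cv_metadata_recorded(self):
        rng = np.random.default_rng(8)
        pm, surv = planted_pair_cohort(rng, n=120, k_signal=3, k_null=5)
        model = fit_lasso_cox(pm, surv, k_folds=5, seed=42)
        assert model.cv["folds"] == 5
        assert model.cv["seed"] == 42
        assert len(model.cv["lambda_path"]) == len(model.cv["mean_deviance"])


class TestRiskScore:
    def _model(self, names, betas):
        return SignatureModel(list(names), np.asarray(betas, dtype=float), 0.1)

    def test_hand_sum(self):
        model = self._model(["A|B", "C|D"], [0.5, -1.0])
        pm = PairMatrix(pd.DataFrame({"A|B": [1], "C|D": [0]}, index=["S1"]))
        assert compute_risk_score(model, pm).loc["S1"] == pytest.approx(0.5)

    def test_all_zero_features(self):
        model = self._model(["A|B"], [2.0])
        pm = PairMatrix(pd.DataFrame({"A|B": [0, 0]}, index=["S1", "S2"]))
        assert (compute_risk_score(model, pm) == 0).all()

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(9)
        names = [f"A{i}|B{i}" for i in range(6)]
        betas = rng.normal(size=6)
        model = self._model(names, betas)
        vals = pd.DataFrame(
            rng.integers(0, 2, size=(10, 6)), columns=names,
            index=[f"S{i}" for i in range(10)],
        )
        scores = compute_risk_score(model, PairMatrix(vals))
        for s in vals.index:
            manual = sum(betas[j] * vals.loc[s, names[j]] for j in range(6))
            assert scores.loc[s] == pytest.approx(manual)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(10)
        names = ["A|B", "C|D"]
        vals = pd.DataFrame(
            rng.integers(0, 2, size=(8, 2)), columns=names,
            index=[f"S{i}" for i in range(8)],
        )
        model = self._model(names, [1.0, -0.5])
        s1 = compute_risk_score(model, PairMatrix(vals))
        s2 = compute_risk_score(model, PairMatrix(vals.iloc[::-1]))
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index())

    def test_missing_pair_named_in_error(self):
        model = self._model(["A|B", "C|D"], [0.5, 1.0])
        pm = PairMatrix(pd.DataFrame({"A|B": [1]}, index=["S1"]))
        with pytest.raises(FormatError, match="C\\|D"):
            compute_risk_score(model, pm)

    def test_model_json_round_trip(self, tmp_path):
        model = self._model(["A|B"], [0.7])
        p = tmp_path / "m.json"
        model.to_json(p)
        back = SignatureModel.from_json(p)
        assert back.pair_names == model.pair_names
        assert back.betas == pytest.approx(model.betas)
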