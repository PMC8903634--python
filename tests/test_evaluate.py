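"""Survival comparison, independence models, group contrasts, enrichment."""
import numpy as np
import pandas as pd
import pytest

from irlncpair.errors import DegenerateFitError, FormatError
from irlncpair.evaluate import (
    compare_by_group,
    contrast_table,
    encode_clinical,
    km_estimate,
    logrank_test,
    multivariate_cox,
    significance_stars,
    ssgsea_scores,
    wilcoxon_rank_sum,
)
from irlncpair.io import GeneSetCollection, SurvivalTable
from irlncpair.signature import univariate_cox
from irlncpair.stratify import assign_groups

from conftest import exponential_survival


def surv_from(times, events, samples=None, **cov):
    samples = samples or [f"S{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events, **cov},
                      index=pd.Index(samples, name="sample_id"))
    return SurvivalTable(df)


class TestKM:
    def test_product_limit_toy(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk)
        km = km_estimate(surv_from([1, 2, 3], [1, 0, 1]))
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)
        assert list(km.at_risk) == [3, 2, 1]

    def test_no_events_flat_at_one(self):
        km = km_estimate(surv_from([5, 6, 7], [0, 0, 0]))
        assert np.all(km.survival == 1.0)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(1, 100, size=25)
        km = km_estimate(surv_from(times, np.ones(25, dtype=int)))
        for t in km.times:
            assert km.at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_group_is_error(self):
        surv = surv_from([1.0], [1])
        with pytest.raises(KeyError):
            surv.subset(["missing"])


def numpy_logrank_chi2(time, event, grp):
    """Independent O-E / hypergeometric-variance log-rank for the oracle."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & grp).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & grp).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def _strat(self, scores, cutoff):
        return assign_groups(scores, cutoff)

    def test_identical_groups_null(self):
        times = [5.0, 10.0, 15.0, 20.0]
        events = [1, 0, 1, 1]
        surv = surv_from(times * 2, events * 2,
                         samples=[f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)])
        scores = pd.Series([1.0] * 4 + [2.0] * 4, index=surv.sample_ids)
        res = logrank_test(self._strat(scores, 1.5), surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_matches_permutation_null(self):
        rng = np.random.default_rng(1)
        n = 20
        time = rng.uniform(1, 100, size=n)
        event = rng.integers(0, 2, size=n).astype(int)
        event[:4] = 1  # ensure events
        grp = np.zeros(n, dtype=bool)
        grp[: n // 2] = True
        samples = [f"S{i}" for i in range(n)]
        surv = surv_from(time, event, samples)
        scores = pd.Series(np.where(grp, 2.0, 1.0), index=samples)
        res = logrank_test(self._strat(scores, 1.5), surv)

        observed = numpy_logrank_chi2(time, event, grp)
        count = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            perm = rng.permutation(grp)
            if numpy_logrank_chi2(time, event, perm) >= observed - 1e-12:
                count += 1
        p_perm = count / n_shuffles
        assert res.p == pytest.approx(p_perm, abs=0.05)

    def test_single_group_is_error(self):
        surv = surv_from([1, 2, 3], [1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0], index=surv.sample_ids)
        strat = self._strat(scores, 1.5)
        with pytest.raises(DegenerateFitError):
            logrank_test(strat, surv.subset(["S1", "S2"]))


class TestMultivariateCox:
    def test_single_covariate_reduces_to_univariate(self):
        rng = np.random.default_rng(2)
        n = 120
        x = rng.standard_normal(n)
        samples = [f"S{i}" for i in range(n)]
        surv = exponential_survival(rng, 0.6 * x, samples)
        cov = pd.DataFrame({"x": x}, index=samples)
        mv = multivariate_cox(surv, cov)[0]
        uv = univariate_cox(cov["x"], surv)
        assert mv.beta == pytest.approx(uv.beta, abs=1e-6)
        assert mv.se == pytest.approx(uv.se, abs=1e-6)

    def test_duplicated_column_named_as_collinear(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.standard_normal(n)
        samples = [f"S{i}" for i in range(n)]
        surv = exponential_survival(rng, 0.5 * x, samples)
        cov = pd.DataFrame({"a": x, "b": x}, index=samples)
        with pytest.raises(DegenerateFitError, match="collinear"):
            multivariate_cox(surv, cov)

    def test_listwise_deletion_of_missing(self):
        rng = np.random.default_rng(4)
        n = 100
        x = rng.standard_normal(n)
        samples = [f"S{i}" for i in range(n)]
        surv = exponential_survival(rng, 0.5 * x, samples)
        cov = pd.DataFrame({"x": x, "age": rng.normal(60, 8, n)}, index=samples)
        cov.loc[samples[:10], "age"] = np.nan
        fits = multivariate_cox(surv, cov)
        assert fits[0].n == n - 10

    def test_clinical_encoding(self):
        surv = surv_from(
            [10, 20], [1, 0],
            age=[61.0, 55.0], grade=["G3", "G1"], stage=["IV", "I"],
            residual=["R1", "R0"], vital=["Dead", "Alive"],
        )
        enc = encode_clinical(surv)
        assert enc.loc["S0"].tolist() == [61.0, 3, 4, 1]
        assert enc.loc["S1"].tolist() == [55.0, 1, 1, 0]


class TestWilcoxon:
    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0, abs=0.01)

    def test_exact_and_asymptotic_agree_at_boundary(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            exact = wilcoxon_rank_sum(x, y).p
            approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert exact == pytest.approx(approx, abs=0.02)

    def test_empty_group_is_error(self):
        with pytest.raises(DegenerateFitError):
            wilcoxon_rank_sum([], [1.0])


class TestStarsAndContrasts:
    @pytest.mark.parametrize(
        "p,stars", [(0.0005, "***"), (0.005, "**"), (0.02, "*"), (0.05, ""), (0.2, "")]
    )
    def test_star_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def _strat(self, n=40, seed=6):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        return assign_groups(scores, float(np.median(scores)))

    def test_compare_by_group_detects_shift(self):
        strat = self._strat()
        vals = pd.Series(0.0, index=strat.scores.index, name="drugA")
        vals.loc[strat.high_samples] = 5.0
        vals += np.random.default_rng(7).normal(0, 0.1, len(vals))
        res = compare_by_group(vals, strat)
        assert res.p < 0.001
        assert res.stars == "***"

    def test_all_missing_one_group_is_error(self):
        strat = self._strat()
        vals = pd.Series(np.nan, index=strat.scores.index, name="v")
        vals.loc[strat.low_samples] = 1.0
        with pytest.raises(DegenerateFitError, match="missing"):
            compare_by_group(vals, strat)

    def test_contrast_table_columns(self):
        strat = self._strat()
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            {"a": rng.normal(size=40), "b": rng.normal(size=40)},
            index=strat.scores.index,
        )
        t = contrast_table(vals, strat)
        assert list(t["variable"]) == ["a", "b"]
        assert {"p", "stars", "median_high", "median_low"} <= set(t.columns)


class TestSsgsea:
    def test_identical_profiles_identical_scores(self):
        expr = pd.DataFrame(
            {"S1": [5.0, 4.0, 3.0, 2.0, 1.0], "S2": [5.0, 4.0, 3.0, 2.0, 1.0]},
            index=[f"G{i}" for i in range(5)],
        )
        sets = GeneSetCollection({"A": ["G0", "G3"], "B": ["G1"]})
        scores = ssgsea_scores(expr, sets)
        pd.testing.assert_series_equal(scores.loc["S1"], scores.loc["S2"], check_names=False)

    def test_top_genes_outscore_bottom_genes(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(
            rng.normal(size=(30, 3)), index=[f"G{i}" for i in range(30)],
            columns=["S1", "S2", "S3"],
        )
        top = list(expr["S1"].nlargest(5).index)
        bottom = list(expr["S1"].nsmallest(5).index)
        sets = GeneSetCollection({"top": top, "bottom": bottom})
        scores = ssgsea_scores(expr, sets)
        assert scores.loc["S1", "top"] > scores.loc["S1", "bottom"]

    def test_matches_hand_running_sum(self):
        expr = pd.DataFrame({"S1": [9.0, 7.0, 5.0, 3.0, 1.0]},
                            index=["G0", "G1", "G2", "G3", "G4"])
        sets = GeneSetCollection({"A": ["G0", "G3"]})
        alpha = 0.25
        # descending order G0..G4, rank values 5..1
        ranks = np.array([5, 4, 3, 2, 1], dtype=float)
        in_set = np.array([1, 0, 0, 1, 0], dtype=bool)
        w = ranks**alpha
        inc = np.where(in_set, w, 0.0) / w[in_set].sum()
        dec = np.where(in_set, 0.0, 1.0 / 3)
        expected = np.cumsum(inc - dec).sum()
        score = ssgsea_scores(expr, sets, alpha=alpha).loc["S1", "A"]
        assert score == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_skipped_with_warning(self, caplog):
        expr = pd.DataFrame({"S1": [1.0, 2.0]}, index=["G0", "G1"])
        sets = GeneSetCollection({"none": ["X1"], "ok": ["G0"]})
        with caplog.at_level("WARNING"):
            scores = ssgsea_scores(expr, sets)
        assert list(scores.columns) == ["ok"]
        assert "skipped" in caplog.text

    def test_all_sets_skipped_is_error(self):
        expr = pd.DataFrame({"S1": [1.0, 2.0]}, index=["G0", "G1"])
        sets = GeneSetCollection({"none": ["X1"]})
        with pytest.raises(FormatError):
            ssgsea_scores(expr, sets)

    def test_min_max_normalization(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(
            rng.normal(size=(20, 5)), index=[f"G{i}" for i in range(20)],
            columns=[f"S{i}" for i in range(5)],
        )
        sets = GeneSetCollection({"A": [f"G{i}" for i in range(4)]})
        scores = ssgsea_scores(expr, sets, normalize=True)
        assert scores["A"].min() == pytest.approx(0.0)
        assert scores["A"].max() == pytest.approx(1.0)
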