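"""Time-dependent ROC, horizon choice, Youden cutoff, group assignment."""
import numpy as np
import pandas as pd
import pytest

from irlncpair.errors import DegenerateFitError
from irlncpair.io import SurvivalTable
from irlncpair.stratify import (
    HIGH,
    LOW,
    assign_groups,
    select_horizon,
    stratify_samples,
    time_dependent_roc,
    youden_cutoff,
)

from conftest import exponential_survival


def surv_from(times, events, samples=None):
    samples = samples or [f"S{i}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"time": times, "event": events},
                     index=pd.Index(samples, name="sample_id"))
    )


def series(values, samples=None):
    samples = samples or [f"S{i}" for i in range(len(values))]
    return pd.Series(values, index=samples, name="risk_score", dtype=float)


def mann_whitney_auc(case_scores, control_scores):
    wins = ties = 0
    for c in case_scores:
        for k in control_scores:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(case_scores) * len(control_scores))


class TestTimeROC:
    def test_perfect_separation_auc_one(self):
        scores = series([5, 4, 1, 0])
        surv = surv_from([10, 20, 300, 400], [1, 1, 1, 1])
        roc = time_dependent_roc(scores, surv, horizon=100)
        assert roc.auc == pytest.approx(1.0)

    def test_toy_mann_whitney_three_quarters(self):
        # cases {3, 2}, controls {1, 2.5}: 3 of 4 case-control pairs concordant
        scores = series([3, 2, 1, 2.5])
        surv = surv_from([50, 60, 300, 400], [1, 1, 0, 0])
        roc = time_dependent_roc(scores, surv, horizon=100)
        assert roc.auc == pytest.approx(0.75)

    def test_censor_free_equals_mann_whitney(self):
        rng = np.random.default_rng(0)
        n = 60
        scores = series(rng.normal(size=n))
        times = rng.uniform(10, 1000, size=n)
        surv = surv_from(times, np.ones(n, dtype=int))
        h = 400.0
        roc = time_dependent_roc(scores, surv, h)
        cases = scores[(times <= h)]
        controls = scores[(times > h)]
        assert roc.auc == pytest.approx(mann_whitney_auc(cases, controls), abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        n = 800
        scores = series(rng.normal(size=n))
        surv = exponential_survival(rng, np.zeros(n), scores.index, baseline=1e-3)
        roc = time_dependent_roc(scores, surv, 600.0)
        assert roc.auc == pytest.approx(0.5, abs=0.08)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        n = 100
        scores = series(rng.normal(size=n))
        surv = exponential_survival(rng, scores.to_numpy(), scores.index, baseline=1e-3)
        roc1 = time_dependent_roc(scores, surv, 700.0)
        roc2 = time_dependent_roc(np.exp(scores * 2) + 3, surv, 700.0)
        assert roc1.auc == pytest.approx(roc2.auc, abs=1e-12)

    def test_curves_monotone_under_censoring(self):
        rng = np.random.default_rng(3)
        n = 150
        scores = series(rng.normal(size=n))
        surv = exponential_survival(rng, 0.5 * scores.to_numpy(), scores.index,
                                    baseline=5e-4, censor_max=1500)
        roc = time_dependent_roc(scores, surv, 365.0)
        assert np.all(np.diff(roc.sensitivity) >= -1e-12)
        assert np.all(np.diff(roc.specificity) <= 1e-12)
        assert np.all((roc.sensitivity >= 0) & (roc.sensitivity <= 1))
        assert np.all((roc.specificity >= 0) & (roc.specificity <= 1))

    def test_no_cases_is_error(self):
        scores = series([1, 2, 3])
        surv = surv_from([500, 600, 700], [1, 1, 1])
        with pytest.raises(DegenerateFitError, match="case"):
            time_dependent_roc(scores, surv, 100.0)


class TestSelectHorizon:
    def test_picks_argmax_of_per_horizon_aucs(self):
        rng = np.random.default_rng(4)
        n = 200
        scores = series(rng.normal(size=n))
        surv = exponential_survival(rng, scores.to_numpy(), scores.index)
        horizons = (365.0, 1095.0, 1825.0)
        aucs = {h: time_dependent_roc(scores, surv, h).auc for h in horizons}
        chosen, roc = select_horizon(scores, surv, horizons)
        assert roc.auc == max(aucs.values())
        assert aucs[chosen] == roc.auc

    def test_single_computable_horizon(self):
        scores = series([3, 2, 1, 0.5])
        surv = surv_from([50, 60, 300, 400], [1, 1, 0, 0])
        chosen, roc = select_horizon(scores, surv, (100.0, 1e6))
        assert chosen == 100.0

    def test_ties_break_toward_longest(self):
        # perfectly separating scores: AUC 1.0 at both horizons
        scores = series([9, 8, 7, 1, 2, 3])
        surv = surv_from([10, 20, 30, 900, 950, 990], [1] * 6)
        chosen, roc = select_horizon(scores, surv, (100.0, 500.0))
        assert roc.auc == 1.0
        assert chosen == 500.0

    def test_all_incomputable_is_error(self):
        scores = series([1, 2])
        surv = surv_from([10, 20], [1, 1])
        with pytest.raises(DegenerateFitError):
            select_horizon(scores, surv, (5.0,))


class TestYouden:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n = 80
        scores = series(rng.normal(size=n))
        surv = exponential_survival(rng, scores.to_numpy(), scores.index)
        roc = time_dependent_roc(scores, surv, 600.0)
        cutoff = youden_cutoff(roc)
        j = roc.sensitivity + roc.specificity - 1.0
        best = j.max()
        candidates = roc.thresholds[j == best]
        assert cutoff == candidates.min()  # lowest tied threshold
        assert j[np.where(roc.thresholds == cutoff)[0][0]] == pytest.approx(best)

    def test_perfect_separation_groups_pure(self):
        scores = series([3, 2, 1.5, 1, 0.5])
        surv = surv_from([10, 20, 500, 600, 700], [1, 1, 0, 0, 0])
        roc = time_dependent_roc(scores, surv, 100.0)
        cutoff = youden_cutoff(roc)
        strat = assign_groups(scores, cutoff)
        assert set(strat.high_samples) == {"S0", "S1"}
        assert set(strat.low_samples) == {"S2", "S3", "S4"}

    def test_flat_curve_falls_back_to_median(self, caplog):
        scores = series([2.0, 2.0, 2.0, 2.0])
        surv = surv_from([50, 80, 300, 400], [1, 1, 0, 0])
        roc = time_dependent_roc(scores, surv, 100.0)
        with caplog.at_level("WARNING"):
            cutoff = youden_cutoff(roc)
        assert cutoff == 2.0
        assert "median" in caplog.text


class TestAssignGroups:
    def test_strict_threshold_split(self):
        strat = assign_groups(series([1, 2, 3]), 1.5)
        assert strat.group.tolist() == [LOW, HIGH, HIGH]

    def test_boundary_goes_low(self):
        strat = assign_groups(series([1, 2, 3]), 2.0)
        assert strat.group.loc["S1"] == LOW

    def test_empty_group_is_error(self):
        with pytest.raises(DegenerateFitError):
            assign_groups(series([1, 2, 3]), 0.0)  # all high
        with pytest.raises(DegenerateFitError):
            assign_groups(series([1, 2, 3]), 5.0)  # all low

    def test_non_finite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(series([1, 2]), float("nan"))


class TestEndToEndStratification:
    def test_planted_effect_auc_above_threshold(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.integers(0, 2, size=(n, 5))
        lp = x @ np.full(5, 0.8)
        scores = series(lp)
        surv = exponential_survival(rng, lp, scores.index)
        strat, roc = stratify_samples(scores, surv)
        assert roc.auc > 0.7
        assert len(strat.high_samples) > 0 and len(strat.low_samples) > 0
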