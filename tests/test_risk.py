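"""Risk scoring, maximally selected cutpoint, log-rank, KM, and AUC(t)."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from miromics.risk import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_PANEL,
    RiskModel,
    RiskScoreModel,
    best_cutpoint,
    km_estimate,
    logrank_statistic,
    logrank_test,
    risk_score,
    time_dependent_auc,
)


def _panel_expr(values_per_mirna, samples):
    return pd.DataFrame(values_per_mirna, index=list(DEFAULT_PANEL), columns=samples)


class TestRiskScore:
    def test_zero_input_zero_score(self):
        expr = _panel_expr(np.zeros((8, 3)), ["a", "b", "c"])
        out = risk_score(expr, RiskModel(normalization="none"))
        assert (out == 0).all()

    def test_single_mirna_unit_returns_printed_coefficient(self):
        vals = np.zeros((8, 1))
        vals[list(DEFAULT_PANEL).index("hsa-miR-155-5p"), 0] = 1.0
        out = risk_score(_panel_expr(vals, ["a"]), RiskModel(normalization="none"))
        assert out["a"] == pytest.approx(0.3419)

    def test_all_units_return_coefficient_total(self):
        total = float(np.sum(DEFAULT_COEFFICIENTS))  # independent summation
        out = risk_score(_panel_expr(np.ones((8, 1)), ["a"]), RiskModel(normalization="none"))
        assert out["a"] == pytest.approx(total)
        assert out["a"] == pytest.approx(1.2515)

    def test_linearity_under_fixed_normalization(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 5))
        y = rng.normal(size=(8, 5))
        model = RiskModel(normalization="none")
        sx = risk_score(_panel_expr(x, list("abcde")), model)
        sy = risk_score(_panel_expr(y, list("abcde")), model)
        sxy = risk_score(_panel_expr(2 * x + 3 * y, list("abcde")), model)
        np.testing.assert_allclose(sxy, 2 * sx + 3 * sy, atol=1e-12)

    def test_missing_panel_mirna_named(self):
        expr = _panel_expr(np.ones((8, 2)), ["a", "b"]).drop(index="hsa-miR-204-5p")
        with pytest.raises(ValueError, match="hsa-miR-204-5p"):
            risk_score(expr)


def _surv(times, events, samples=None):
    if samples is None:
        samples = [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=samples)


def _brute_force_cutpoint(scores, survival, min_group_fraction=0.1):
    """Exhaustive scan using the independent lifelines statistic per split."""
    s = scores.to_numpy()
    n = len(s)
    min_n = max(int(np.ceil(min_group_fraction * n)), 1)
    best = (-np.inf, None)
    for cut in np.unique(s)[:-1]:
        high = s > cut
        if high.sum() < min_n or (n - high.sum()) < min_n:
            continue
        res = ll_logrank(
            survival["time"][high], survival["time"][~high],
            survival["event"][high], survival["event"][~high],
        )
        if res.test_statistic > best[0] + 1e-12:
            best = (float(res.test_statistic), float(cut))
    return best[1], best[0]


class TestCutpoint:
    def test_separated_clusters(self):
        # non-overlapping survival between two score clusters: every
        # between-cluster split maximizes the statistic and the tie-break
        # picks the lowest admissible threshold, i.e. between the clusters
        rng = np.random.default_rng(1)
        n = 60
        scores = pd.Series(np.r_[rng.normal(0, 0.1, 30), rng.normal(5, 0.1, 30)])
        times = np.r_[rng.uniform(50, 100, 30), rng.uniform(1, 5, 30)]
        surv = _surv(times, np.ones(n, dtype=int), samples=scores.index)
        cut, _ = best_cutpoint(scores, surv)
        assert scores[:30].max() <= cut < scores[30:].min()

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        surv = _surv(rng.exponential(50, n), rng.integers(0, 2, n).clip(min=0))
        if surv["event"].sum() == 0:
            surv.iloc[0, surv.columns.get_loc("event")] = 1
        cut, stat = best_cutpoint(scores, surv)
        cut_bf, stat_bf = _brute_force_cutpoint(scores, surv)
        assert cut == pytest.approx(cut_bf)
        assert stat == pytest.approx(stat_bf, rel=1e-9)

    def test_null_cutpoint_not_pinned_to_edges(self):
        """With survival independent of score the selected quantile spreads
        over the admissible range instead of hugging one edge."""
        rng = np.random.default_rng(5)
        quantiles = []
        for _ in range(20):
            n = 80
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            surv = _surv(rng.exponential(50, n), np.ones(n, dtype=int))
            cut, _ = best_cutpoint(scores, surv)
            quantiles.append((scores <= cut).mean())
        assert 0.15 < np.mean(quantiles) < 0.85
        assert np.std(quantiles) > 0.05

    def test_identical_scores_error(self):
        surv = _surv([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="identical"):
            best_cutpoint(pd.Series([1.0, 1.0, 1.0], index=surv.index), surv)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        surv = _surv([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.index)
        stat, p = logrank_test(groups, surv)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_toy(self):
        # A: death@1, death@4; B: death@2, censored@6.
        # Risk tables give O_A - E_A = 2/3 and V = 13/18, chi2 = 8/13.
        surv = _surv([1, 4, 2, 6], [1, 1, 1, 0])
        groups = pd.Series(["A", "A", "B", "B"], index=surv.index)
        stat, _ = logrank_test(groups, surv)
        assert stat == pytest.approx(8 / 13, abs=1e-9)
        high = (groups == "A").to_numpy()
        assert logrank_statistic(
            high, surv["time"].to_numpy(float), surv["event"].to_numpy(int)
        ) == pytest.approx(8 / 13, abs=1e-9)

    def test_internal_statistic_matches_lifelines(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 40
            time = rng.exponential(30, n)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            high = rng.random(n) < 0.5
            if high.all() or not high.any():
                continue
            mine = logrank_statistic(high, time, event)
            ref = ll_logrank(time[high], time[~high], event[high], event[~high])
            assert mine == pytest.approx(float(ref.test_statistic), rel=1e-9, abs=1e-12)

    def test_permutation_null_p_uniform(self):
        rng = np.random.default_rng(7)
        n = 30
        time = rng.exponential(20, n)
        event = np.ones(n, dtype=int)
        surv = _surv(time, event)
        ps = []
        for _ in range(200):
            labels = pd.Series(rng.permutation(["a"] * 15 + ["b"] * 15), index=surv.index)
            ps.append(logrank_test(labels, surv)[1])
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").pvalue > 0.01


def _km_oracle(times, events):
    """Literal product-limit recomputation."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, out = 1.0, {}
    for t in np.unique(times[events == 1]):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_all_censored_flat_one(self):
        curve = km_estimate(_surv([5, 10, 15], [0, 0, 0]))
        assert (curve["survival"] == 1.0).all()

    def test_single_event_halves_survival(self):
        curve = km_estimate(_surv([5, 10], [1, 0]))
        assert curve.set_index("time")["survival"].loc[5.0] == pytest.approx(0.5)

    def test_matches_product_limit_oracle(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(20, 50).round(1) + 0.1
        events = rng.integers(0, 2, 50)
        curve = km_estimate(_surv(times, events)).set_index("time")["survival"]
        for t, s in _km_oracle(times, events).items():
            assert curve.loc[t] == pytest.approx(s, abs=1e-12)

    def test_nonpositive_times_error(self):
        with pytest.raises(ValueError):
            km_estimate(_surv([0, 5], [1, 1]))


def _auc_pairwise_oracle(scores, times, horizon):
    """Concordance counting among (case, control) pairs, no censoring."""
    cases = times <= horizon
    controls = times > horizon
    num = den = 0.0
    for i in np.flatnonzero(cases):
        for j in np.flatnonzero(controls):
            num += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
            den += 1
    return num / den


class TestTimeDependentAuc:
    def test_perfect_ranking_gives_one(self):
        n = 20
        times = np.arange(1, n + 1, dtype=float)
        scores = pd.Series(-times, index=[f"s{i}" for i in range(n)])
        surv = _surv(times, np.ones(n, dtype=int), samples=scores.index)
        aucs = time_dependent_auc(scores, surv, [5, 10, 15])
        np.testing.assert_allclose(aucs.to_numpy(), 1.0)

    def test_matches_pairwise_counting_without_censoring(self):
        rng = np.random.default_rng(9)
        n = 40
        times = rng.exponential(10, n) + 0.1
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        surv = _surv(times, np.ones(n, dtype=int), samples=scores.index)
        horizon = float(np.median(times))
        auc = time_dependent_auc(scores, surv, [horizon]).iloc[0]
        assert auc == pytest.approx(
            _auc_pairwise_oracle(scores.to_numpy(), times, horizon), abs=1e-9
        )

    def test_score_independent_survival_near_half(self):
        rng = np.random.default_rng(10)
        aucs = []
        for _ in range(20):
            n = 500
            times = rng.exponential(100, n)
            cens = rng.uniform(0, 300, n)
            time = np.minimum(times, cens)
            event = (times <= cens).astype(int)
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            surv = _surv(np.maximum(time, 0.01), event, samples=scores.index)
            aucs.append(float(time_dependent_auc(scores, surv, [80]).iloc[0]))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_horizon_beyond_follow_up_is_nan_with_warning(self, caplog):
        surv = _surv([5.0, 10.0], [1, 1])
        scores = pd.Series([1.0, 2.0], index=surv.index)
        with caplog.at_level("WARNING", logger="miromics.risk"):
            aucs = time_dependent_auc(scores, surv, [7.0, 100.0])
        assert np.isnan(aucs.loc[100.0])
        assert "skipped" in caplog.text


class TestRiskScoreModel:
    def test_power_on_proportional_hazards_cohorts(self):
        """Cohorts with hazard proportional to exp(score) split into groups
        with log-rank p < 0.01 for nearly every seed at n=300, log-HR = 1."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            n = 300
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            t = rng.exponential(1.0 / (0.01 * np.exp(scores.to_numpy())))
            c = rng.uniform(0, 300, n)
            surv = _surv(
                np.maximum(np.minimum(t, c), 1e-3), (t <= c).astype(int),
                samples=scores.index,
            )
            cut, _ = best_cutpoint(scores, surv)
            groups = pd.Series(
                np.where(scores > cut, "high", "low"), index=scores.index
            )
            _, p = logrank_test(groups, surv)
            hits += p < 0.01
        assert hits >= 18

    def test_fit_on_synthetic_cohort(self):
        from miromics import generate_cohort

        cohort = generate_cohort(n_samples=300, n_mirnas=30, seed=17)
        res = RiskScoreModel(cohort.expression, cohort.survival).fit(
            horizons=[365.0, 730.0]
        )
        assert set(res.groups.unique()) == {"high", "low"}
        assert res.logrank_p < 0.05  # survival was generated from the score
        text = res.summary()
        assert "cutpoint" in text and "log-rank p" in text
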