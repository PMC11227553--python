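"""Eight-miRNA prognostic risk score and its survival evaluation.

The score is a fixed linear combination of normalized panel-miRNA expression
values with published penalized-Cox coefficients; the coefficients are data,
not something this package re-estimates.  Patients are split into high/low
risk at the maximally selected log-rank cutpoint, and the split is evaluated
with Kaplan-Meier / log-rank statistics and time-dependent (cumulative-case /
dynamic-control, IPCW-weighted) ROC AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

logger = logging.getLogger(__name__)

DEFAULT_PANEL = (
    "hsa-miR-10b-5p",
    "hsa-miR-155-5p",
    "hsa-miR-196a-5p",
    "hsa-miR-196b-5p",
    "hsa-miR-200a-3p",
    "hsa-miR-204-5p",
    "hsa-miR-503-5p",
    "hsa-miR-15b-5p",
)
DEFAULT_COEFFICIENTS = (0.1617, 0.3419, 0.0695, 0.1391, 0.1474, 0.0840, 0.0996, 0.2083)


@dataclass(frozen=True)
class RiskModel:
    """Fixed panel + coefficients + normalization scheme.

    ``normalization``: 'zscore' (per-miRNA z across the scoring cohort,
    default), 'minmax' (per-miRNA [0,1] scaling) or 'none' (expression used as
    given).  Scores are not transferable across schemes, so the scheme is part
    of the model.
    """

    panel: tuple[str, ...] = DEFAULT_PANEL
    coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.coefficients):
            raise ValueError("panel and coefficients must have equal length")
        if self.normalization not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _normalize(expr: pd.DataFrame, scheme: str) -> pd.DataFrame:
    if scheme == "none":
        return expr
    if scheme == "zscore":
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1).replace(0, 1.0)
        return expr.sub(mu, axis=0).div(sd, axis=0)
    lo = expr.min(axis=1)
    span = (expr.max(axis=1) - lo).replace(0, 1.0)
    return expr.sub(lo, axis=0).div(span, axis=0)


def risk_score(expr: pd.DataFrame, model: RiskModel = RiskModel()) -> pd.Series:
    """Per-sample risk score: sum of coefficient * normalized panel expression.

    Linear in the normalized expression; raises when a panel miRNA is absent.
    """
    missing = [m for m in model.panel if m not in expr.index]
    if missing:
        raise ValueError(f"panel miRNAs missing from expression matrix: {missing}")
    norm = _normalize(expr.loc[list(model.panel)], model.normalization)
    coef = pd.Series(model.coefficients, index=list(model.panel))
    return norm.mul(coef, axis=0).sum(axis=0).rename("risk_score")


def _validate_survival(survival: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in survival.columns:
            raise ValueError(f"survival table needs a '{col}' column")
    if (survival["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not survival["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return survival


def logrank_statistic(high: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Two-group log-rank chi-square statistic (O-E)^2 / V, vectorized."""
    order = np.argsort(time, kind="stable")
    time, event, high = time[order], event[order], high[order].astype(bool)
    event_times, first_idx = np.unique(time[event == 1], return_index=True)
    if len(event_times) == 0:
        return 0.0
    n = len(time)
    # at-risk counts just before each event time
    idx = np.searchsorted(time, event_times, side="left")
    at_risk = n - idx
    cum_high = np.concatenate([[0], np.cumsum(high)])
    at_risk_high = cum_high[-1] - cum_high[idx]
    # observed events at each event time, overall and in the high group
    d = np.zeros(len(event_times))
    d_high = np.zeros(len(event_times))
    ev_idx = np.searchsorted(event_times, time[event == 1])
    np.add.at(d, ev_idx, 1)
    np.add.at(d_high, ev_idx, high[event == 1].astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d * at_risk_high / at_risk
        var = (
            d
            * (at_risk_high / at_risk)
            * (1 - at_risk_high / at_risk)
            * (at_risk - d)
            / np.maximum(at_risk - 1, 1)
        )
    o_minus_e = float(np.nansum(d_high - expected))
    v = float(np.nansum(var))
    if v == 0:
        return 0.0
    return o_minus_e**2 / v


def best_cutpoint(
    scores: pd.Series,
    survival: pd.DataFrame,
    min_group_fraction: float = 0.1,
) -> tuple[float, float]:
    """Maximally selected log-rank cutpoint.

    Scans every admissible threshold (splits leaving at least
    ``min_group_fraction`` of samples on each side; the high group is
    score > threshold) and returns the one maximizing the two-group log-rank
    statistic; ties break to the lowest threshold.
    """
    survival = _validate_survival(survival)
    common = scores.index.intersection(survival.index)
    s = scores.loc[common].to_numpy(dtype=float)
    time = survival.loc[common, "time"].to_numpy(dtype=float)
    event = survival.loc[common, "event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("cohort has no events")
    if np.all(s == s[0]):
        raise ValueError("all scores identical; no cutpoint exists")
    n = len(s)
    min_n = max(int(np.ceil(min_group_fraction * n)), 1)
    candidates = np.unique(s)[:-1]  # score > cut: the max can never be a cut
    best_stat, best_cut = -np.inf, None
    for cut in candidates:
        high = s > cut
        n_high = int(high.sum())
        if n_high < min_n or n - n_high < min_n:
            continue
        stat = logrank_statistic(high, time, event)
        if stat > best_stat + 1e-12:
            best_stat, best_cut = stat, float(cut)
    if best_cut is None:
        raise ValueError("no admissible split under the minimum group fraction")
    return best_cut, best_stat


def logrank_test(groups: pd.Series, survival: pd.DataFrame) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square statistic, p)."""
    survival = _validate_survival(survival)
    common = groups.index.intersection(survival.index)
    g = groups.loc[common]
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {len(labels)}")
    mask = (g == labels[0]).to_numpy()
    time = survival.loc[common, "time"].to_numpy(dtype=float)
    event = survival.loc[common, "event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the cohort")
    res = _ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


def km_estimate(survival: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: DataFrame with columns time, survival."""
    survival = _validate_survival(survival)
    if len(survival) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(survival["time"], survival["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def time_dependent_auc(
    scores: pd.Series, survival: pd.DataFrame, horizons
) -> pd.Series:
    """Cumulative-cases / dynamic-controls AUC(t) with KM-based IPCW weights.

    Horizons at or beyond the last observed follow-up (or before the first)
    are reported as NaN with a warning.
    """
    survival = _validate_survival(survival)
    common = scores.index.intersection(survival.index)
    time = survival.loc[common, "time"].to_numpy(dtype=float)
    event = survival.loc[common, "event"].to_numpy(dtype=bool)
    s = scores.loc[common].to_numpy(dtype=float)
    horizons = np.asarray(list(horizons), dtype=float)
    out = pd.Series(np.nan, index=horizons, name="auc")
    tmin, tmax = time[event].min() if event.any() else np.inf, time.max()
    valid = (horizons >= tmin) & (horizons < tmax)
    if not valid.all():
        logger.warning(
            "horizons outside the evaluable follow-up range were skipped: %s",
            horizons[~valid].tolist(),
        )
    if valid.any():
        y = Surv.from_arrays(event=event, time=time)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, _ = cumulative_dynamic_auc(y, y, s, horizons[valid])
        out.loc[horizons[valid]] = auc
    return out


# ---------------------------------------------------------------------------
# model-object surface


class RiskScoreModel:
    """Prognostic risk-score model over a miRNA expression matrix and a
    survival table (index = sample id, columns time, event).

    ``fit`` scores the cohort, selects the maximal log-rank cutpoint, labels
    high/low-risk groups, and evaluates the split; the result object carries
    scores, cutpoint, group labels, the log-rank test and AUC(t).
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        survival: pd.DataFrame,
        model: RiskModel = RiskModel(),
        time_unit: str = "days",
    ):
        self.expr = expr
        self.survival = _validate_survival(survival)
        self.model = model
        self.time_unit = time_unit

    def fit(
        self,
        min_group_fraction: float = 0.1,
        horizons=None,
    ) -> "RiskScoreResults":
        scores = risk_score(self.expr, self.model)
        common = scores.index.intersection(self.survival.index)
        scores = scores.loc[common]
        surv = self.survival.loc[common]
        cut, stat = best_cutpoint(scores, surv, min_group_fraction)
        groups = pd.Series(
            np.where(scores > cut, "high", "low"), index=scores.index, name="risk_group"
        )
        chi2, p = logrank_test(groups, surv)
        aucs = None
        if horizons is not None:
            aucs = time_dependent_auc(scores, surv, horizons)
        return RiskScoreResults(self, scores, cut, groups, chi2, p, aucs)


@dataclass
class RiskScoreResults:
    model: RiskScoreModel
    scores: pd.Series
    cutpoint: float
    groups: pd.Series
    logrank_chi2: float
    logrank_p: float
    aucs: pd.Series | None = field(default=None)

    def km_curves(self) -> dict[str, pd.DataFrame]:
        surv = self.model.survival.loc[self.groups.index]
        return {
            label: km_estimate(surv[self.groups == label])
            for label in ("high", "low")
        }

    def summary(self) -> str:
        n_high = int((self.groups == "high").sum())
        n_low = int((self.groups == "low").sum())
        lines = [
            "Risk-score model summary",
            "=" * 42,
            f"samples scored        {len(self.scores)}",
            f"normalization         {self.model.model.normalization}",
            f"time unit             {self.model.time_unit}",
            f"cutpoint              {self.cutpoint:.4f}",
            f"high / low risk       {n_high} / {n_low}",
            f"log-rank chi-square   {self.logrank_chi2:.3f}",
            f"log-rank p            {self.logrank_p:.3g}",
        ]
        if self.aucs is not None:
            for t, a in self.aucs.items():
                lines.append(f"AUC(t={t:g})           {a:.3f}")
        return "\n".join(lines)
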