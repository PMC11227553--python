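"""Correlation/regression screens that classify miRNAs as CNV-driven or
DNAm-driven, plus the generic correlation screen reused for infiltration,
PD-L1 and TIDE covariates.

A miRNA is called CNV-driven when its expression correlates positively with
copy number (BH-FDR < 0.05 within the CNV family) and DNAm-driven when it
correlates negatively with promoter methylation (BH within the DNAm family);
the two labels may co-occur.  A bivariate OLS decomposition
``Y ~ b0 + bm * M + bn * N`` separates the two influences and defines the
"core" subsets (bm < 0, bn > 0 at BH-FDR < 0.05, families per coefficient).
Fisher's Z transform, z = arctanh(r), is computed for distributional analyses
(skewness of the Z landscape); significance always comes from the
correlation-test p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_z",
    "benjamini_hochberg",
    "correlate_pairs",
    "call_drivers",
    "decompose_regression",
    "skewness_test",
    "correlation_screen",
    "DriverScreenModel",
    "DriverScreenResults",
]

DEFAULT_MIN_PAIRS = 10


def fisher_z(r):
    """Fisher's variance-stabilizing transform, z = arctanh(r) = 0.5*ln((1+r)/(1-r)).

    Odd and strictly increasing on (-1, 1); undefined at |r| >= 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z is undefined for |r| >= 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def benjamini_hochberg(p):
    """BH step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int, str]:
    """Pearson r and two-sided t-test p over complete pairs of two vectors."""
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n, "insufficient_pairs"
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n, "zero_variance"
    r = float(np.corrcoef(xv, yv)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0, n, "collinear"
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n, "ok"


def correlate_pairs(
    expr: pd.DataFrame, covar: pd.DataFrame, min_pairs: int = DEFAULT_MIN_PAIRS
) -> pd.DataFrame:
    """Feature-wise Pearson correlation between two aligned matrices.

    Rows are matched by feature id, columns by shared sample id; missing cells
    are dropped pairwise per feature.  Features with fewer than ``min_pairs``
    complete pairs, or a zero-variance vector, are reported as undetermined
    with a reason code instead of propagating NaN silently.

    Returns a DataFrame indexed by feature with columns r, p, n, status.
    """
    samples = expr.columns.intersection(covar.columns)
    features = expr.index.intersection(covar.index)
    if len(samples) < min_pairs:
        raise ValueError(
            f"only {len(samples)} shared samples; need at least min_pairs={min_pairs}"
        )
    E = expr.loc[features, samples].to_numpy(dtype=float)
    C = covar.loc[features, samples].to_numpy(dtype=float)
    rows = []
    for i in range(len(features)):
        r, p, n, status = _pearson_with_p(E[i], C[i])
        if status == "ok" and n < min_pairs:
            status = "insufficient_pairs"
            r, p = np.nan, np.nan
        rows.append((r, p, n, status))
    return pd.DataFrame(
        rows, index=pd.Index(features, name="mirna_id"), columns=["r", "p", "n", "status"]
    )


def _bh_within(screen: pd.DataFrame) -> pd.Series:
    fdr = pd.Series(np.nan, index=screen.index)
    ok = screen["status"].isin(["ok", "collinear"]) & screen["p"].notna()
    if ok.any():
        fdr.loc[ok] = benjamini_hochberg(screen.loc[ok, "p"].to_numpy())
    return fdr


def call_drivers(
    screen_cnv: pd.DataFrame,
    screen_dnam: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Label miRNAs from the two correlation screens.

    CNV_miR iff r_cnv > 0 and BH-FDR < threshold (BH within the CNV family);
    DNAm_miR iff r_dnam < 0 and BH-FDR < threshold (BH within the DNAm
    family).  Both labels may co-occur.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    mirnas = screen_cnv.index.union(screen_dnam.index)
    cnv = screen_cnv.reindex(mirnas)
    dnam = screen_dnam.reindex(mirnas)
    out = pd.DataFrame(index=pd.Index(mirnas, name="mirna_id"))
    out["r_cnv"] = cnv["r"]
    out["p_cnv"] = cnv["p"]
    out["n_cnv"] = cnv["n"]
    out["fdr_cnv"] = _bh_within(cnv)
    out["r_dnam"] = dnam["r"]
    out["p_dnam"] = dnam["p"]
    out["n_dnam"] = dnam["n"]
    out["fdr_dnam"] = _bh_within(dnam)
    with np.errstate(invalid="ignore"):
        out["z_cnv"] = np.arctanh(out["r_cnv"].clip(-1 + 1e-15, 1 - 1e-15))
        out["z_dnam"] = np.arctanh(out["r_dnam"].clip(-1 + 1e-15, 1 - 1e-15))
    out["cnv_mir"] = (out["r_cnv"] > 0) & (out["fdr_cnv"] < fdr_threshold)
    out["dnam_mir"] = (out["r_dnam"] < 0) & (out["fdr_dnam"] < fdr_threshold)
    return out


def decompose_regression(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    cnv: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA OLS ``Y ~ b0 + bm*M + bn*N`` separating DNAm and CNV effects.

    Coefficient t-test p-values are BH-adjusted across miRNAs separately per
    coefficient; core_DNAm iff bm < 0 at FDR < threshold, core_CNV iff bn > 0
    at FDR < threshold.  miRNAs with fewer than 4 complete (Y, M, N) triples,
    or with collinear/constant regressors, are undetermined with a reason code.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    samples = expr.columns.intersection(meth.columns).intersection(cnv.columns)
    features = expr.index.intersection(meth.index).intersection(cnv.index)
    rows = []
    for mid in features:
        y = expr.loc[mid, samples].to_numpy(dtype=float)
        m = meth.loc[mid, samples].to_numpy(dtype=float)
        n = cnv.loc[mid, samples].to_numpy(dtype=float)
        mask = ~(np.isnan(y) | np.isnan(m) | np.isnan(n))
        if mask.sum() < 4:
            rows.append((np.nan,) * 6 + ("insufficient_pairs",))
            continue
        yv, mv, nv = y[mask], m[mask], n[mask]
        X = np.column_stack([np.ones(mask.sum()), mv, nv])
        if yv.std() == 0 or np.linalg.matrix_rank(X) < 3:
            rows.append((np.nan,) * 6 + ("degenerate",))
            continue
        coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ coef
        dof = mask.sum() - 3
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = coef / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        rows.append((coef[0], coef[1], coef[2], pvals[1], pvals[2], mask.sum(), "ok"))
    out = pd.DataFrame(
        rows,
        index=pd.Index(features, name="mirna_id"),
        columns=["beta0", "beta_m", "beta_n", "p_beta_m", "p_beta_n", "n", "status"],
    )
    ok = out["status"] == "ok"
    out["fdr_beta_m"] = np.nan
    out["fdr_beta_n"] = np.nan
    if ok.any():
        out.loc[ok, "fdr_beta_m"] = benjamini_hochberg(out.loc[ok, "p_beta_m"].to_numpy())
        out.loc[ok, "fdr_beta_n"] = benjamini_hochberg(out.loc[ok, "p_beta_n"].to_numpy())
    out["core_dnam"] = (out["beta_m"] < 0) & (out["fdr_beta_m"] < fdr_threshold)
    out["core_cnv"] = (out["beta_n"] > 0) & (out["fdr_beta_n"] < fdr_threshold)
    return out


def skewness_test(values, bias_corrected: bool = False) -> tuple[float, float]:
    """Sample skewness with D'Agostino's two-sided normality-of-skew p-value.

    Default is the moment estimator g1 = m3 / m2^(3/2); ``bias_corrected``
    switches to G1.  Requires n >= 8 (the transformed-Z approximation) and
    non-zero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError("skewness test requires n >= 8")
    if x.std() == 0:
        raise ValueError("zero variance: skewness undefined")
    skew = float(stats.skew(x, bias=not bias_corrected))
    _, p = stats.skewtest(x)
    return skew, float(p)


def correlation_screen(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr_threshold: float = 0.05,
    sign: str = "any",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.DataFrame:
    """Pearson screen of every (feature, covariate) pair, BH over the full grid.

    ``covariates`` is a covariate x sample matrix (e.g. six immune-cell
    infiltration estimates, a PD-L1 expression row, or TIDE scores).  BH runs
    across the whole declared family of pairs; ``significant`` then reflects
    both the FDR threshold and the requested sign ('any', 'positive',
    'negative').

    Returns a long DataFrame with columns feature, covariate, r, p, n, status,
    fdr, sign, significant.
    """
    if sign not in ("any", "positive", "negative"):
        raise ValueError("sign must be 'any', 'positive' or 'negative'")
    samples = expr.columns.intersection(covariates.columns)
    if len(samples) < min_pairs:
        raise ValueError(f"only {len(samples)} shared samples; need {min_pairs}")
    rows = []
    E = expr.loc[:, samples].to_numpy(dtype=float)
    for cov_id in covariates.index:
        c = covariates.loc[cov_id, samples].to_numpy(dtype=float)
        for i, feat in enumerate(expr.index):
            r, p, n, status = _pearson_with_p(E[i], c)
            if status == "ok" and n < min_pairs:
                status, r, p = "insufficient_pairs", np.nan, np.nan
            rows.append((feat, cov_id, r, p, n, status))
    out = pd.DataFrame(rows, columns=["feature", "covariate", "r", "p", "n", "status"])
    out["fdr"] = np.nan
    ok = out["status"].isin(["ok", "collinear"])
    if ok.any():
        out.loc[ok, "fdr"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    out["sign"] = np.where(out["r"] > 0, "positive", np.where(out["r"] < 0, "negative", "zero"))
    sig = out["fdr"] < fdr_threshold
    if sign != "any":
        sig &= out["sign"] == sign
    out["significant"] = sig.fillna(False)
    return out


def significant_covariate_counts(screen: pd.DataFrame) -> pd.Series:
    """Per-feature count of significant covariates (e.g. how many of the six
    immune cell types a miRNA's expression tracks)."""
    return screen[screen["significant"]].groupby("feature")["covariate"].nunique()


# ---------------------------------------------------------------------------
# model-object surface


class DriverScreenModel:
    """Driver classification model over paired expression / CNV / methylation
    matrices (features x samples, shared sample columns).

    ``fit`` runs both correlation screens, the labelling rules, and (when
    methylation and CNV are both supplied) the bivariate OLS decomposition,
    returning a :class:`DriverScreenResults`.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        cnv: pd.DataFrame | None = None,
        meth: pd.DataFrame | None = None,
        min_pairs: int = DEFAULT_MIN_PAIRS,
    ):
        if cnv is None and meth is None:
            raise ValueError("provide at least one of cnv or meth")
        self.expr = expr
        self.cnv = cnv
        self.meth = meth
        self.min_pairs = min_pairs

    def fit(self, fdr_threshold: float = 0.05) -> "DriverScreenResults":
        screen_cnv = screen_dnam = None
        if self.cnv is not None:
            screen_cnv = correlate_pairs(self.expr, self.cnv, self.min_pairs)
        if self.meth is not None:
            screen_dnam = correlate_pairs(self.expr, self.meth, self.min_pairs)
        empty = pd.DataFrame(columns=["r", "p", "n", "status"])
        calls = call_drivers(
            screen_cnv if screen_cnv is not None else empty,
            screen_dnam if screen_dnam is not None else empty,
            fdr_threshold,
        )
        decomposition = None
        if self.cnv is not None and self.meth is not None:
            decomposition = decompose_regression(
                self.expr, self.meth, self.cnv, fdr_threshold
            )
        return DriverScreenResults(self, calls, decomposition, fdr_threshold)


class DriverScreenResults:
    """Per-miRNA driver calls with correlation, Fisher-Z and regression statistics."""

    def __init__(self, model, calls, decomposition, fdr_threshold):
        self.model = model
        self.calls = calls
        self.decomposition = decomposition
        self.fdr_threshold = fdr_threshold

    @property
    def cnv_mirs(self) -> pd.Index:
        return self.calls.index[self.calls["cnv_mir"].fillna(False)]

    @property
    def dnam_mirs(self) -> pd.Index:
        return self.calls.index[self.calls["dnam_mir"].fillna(False)]

    def z_distribution(self, which: str = "cnv") -> pd.Series:
        """Fisher-Z values of the chosen screen, for landscape/skewness analysis."""
        col = {"cnv": "z_cnv", "dnam": "z_dnam"}[which]
        return self.calls[col].dropna()

    def skewness(self, which: str = "cnv") -> tuple[float, float]:
        return skewness_test(self.z_distribution(which).to_numpy())

    def summary(self) -> str:
        lines = [
            "Driver screen summary",
            "=" * 42,
            f"miRNAs screened        {len(self.calls)}",
            f"FDR threshold          {self.fdr_threshold}",
            f"CNV-miRs (r>0)         {len(self.cnv_mirs)}",
            f"DNAm-miRs (r<0)        {len(self.dnam_mirs)}",
            f"both labels            {int((self.calls['cnv_mir'] & self.calls['dnam_mir']).sum())}",
        ]
        if self.decomposition is not None:
            core_cnv = int(self.decomposition["core_cnv"].sum())
            core_dnam = int(self.decomposition["core_dnam"].sum())
            lines += [
                f"core CNV (bn>0)        {core_cnv}",
                f"core DNAm (bm<0)       {core_dnam}",
            ]
        for which in ("cnv", "dnam"):
            z = self.z_distribution(which)
            if len(z) >= 8 and z.std() > 0:
                s, p = skewness_test(z.to_numpy())
                lines.append(f"Z skewness ({which:<4})      {s:+.3f} (p={p:.3g})")
        return "\n".join(lines)
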