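"""Probe-level beta-matrix cleaning: missingness filter, KNN imputation, and
type-II probe-bias correction.

The 450K array mixes two probe chemistries; type II betas are compressed
toward 0.5 relative to type I.  ``correct_type2_bias`` quantile-maps the
type II distribution onto the type I distribution within three methylation
states (unmethylated / hemimethylated / methylated) estimated by a
three-component beta-mixture EM fit, in the spirit of beta-mixture quantile
normalization.  The canonical order is filter -> impute -> correct; correction
refuses matrices that still contain missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

_EPS = 1e-6


def filter_by_missingness(
    beta: pd.DataFrame, max_missing_fraction: float = 0.30
) -> pd.DataFrame:
    """Drop probes whose missing fraction across samples strictly exceeds the cut.

    A probe missing in exactly ``max_missing_fraction`` of samples is retained.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = beta.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("missingness filter removed every probe")
    logger.info("missingness filter removed %d of %d probes", n_removed, len(beta))
    return beta.loc[keep]


def knn_impute(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing betas with the mean over the k nearest probes.

    Neighbours are probes (rows) closest in Euclidean distance over
    co-observed samples; the missing cell takes the mean of the neighbours'
    values in that sample.  Deterministic; imputed values are clipped to [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not beta.isna().to_numpy().any():
        return beta.copy()
    if beta.notna().sum(axis=1).min() == 0:
        raise ValueError("every probe must have at least one observed value")
    n_candidates = len(beta) - 1
    if k > n_candidates:
        logger.warning("k=%d exceeds %d candidate neighbour probes; using all", k, n_candidates)
        k = max(n_candidates, 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(beta.to_numpy(dtype=float))
    out = pd.DataFrame(np.clip(filled, 0.0, 1.0), index=beta.index, columns=beta.columns)
    # observed cells pass through untouched
    out = out.where(beta.isna(), beta)
    return out


# ---------------------------------------------------------------------------
# three-state beta mixture


@dataclass
class BetaMixture:
    weights: np.ndarray  # (3,)
    a: np.ndarray  # (3,) beta shape a per state, U/H/M order
    b: np.ndarray  # (3,)
    converged: bool

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        dens = np.stack(
            [w * stats.beta.pdf(x, a, b) for w, a, b in zip(self.weights, self.a, self.b)],
            axis=1,
        )
        dens = np.clip(dens, 1e-300, None)
        return dens / dens.sum(axis=1, keepdims=True)

    def classify(self, x: np.ndarray) -> np.ndarray:
        return self.responsibilities(x).argmax(axis=1)


def _moments_to_beta(mean: float, var: float) -> tuple[float, float]:
    mean = min(max(mean, _EPS), 1 - _EPS)
    var = min(max(var, 1e-6), mean * (1 - mean) * 0.999)
    common = mean * (1 - mean) / var - 1.0
    return mean * common, (1 - mean) * common


def fit_beta_mixture(
    x: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 300,
    init_thresholds: tuple[float, float] = (0.2, 0.8),
    init: "BetaMixture | None" = None,
) -> BetaMixture:
    """Three-state beta-mixture fit by EM with weighted method-of-moments M-step.

    States are initialized by hard thresholds on beta (unmethylated < 0.2,
    methylated > 0.8) unless an ``init`` mixture is given (used to anchor the
    type II fit to the type I states); empty initial states fall back to
    canonical priors.  Convergence is declared when the mean per-observation
    log-likelihood changes by less than ``tol`` between iterations; EM on
    strongly overlapping components converges slowly, hence the generous
    iteration cap.
    """
    x = np.clip(np.asarray(x, dtype=float), _EPS, 1 - _EPS)
    if init is not None:
        a = init.a.copy()
        b = init.b.copy()
        w = init.weights.copy()
    else:
        lo, hi = init_thresholds
        groups = [x[x < lo], x[(x >= lo) & (x <= hi)], x[x > hi]]
        prior = [(2.0, 12.0), (5.0, 5.0), (12.0, 2.0)]
        a = np.empty(3)
        b = np.empty(3)
        w = np.empty(3)
        for s, g in enumerate(groups):
            if len(g) >= 5:
                a[s], b[s] = _moments_to_beta(float(g.mean()), float(g.var()) + 1e-8)
            else:
                a[s], b[s] = prior[s]
            w[s] = max(len(g), 1) / max(len(x), 1)
        w /= w.sum()

    mix = BetaMixture(w, a, b, converged=False)
    prev_ll = -np.inf
    for _ in range(max_iter):
        resp = mix.responsibilities(x)
        nk = resp.sum(axis=0)
        w = nk / nk.sum()
        for s in range(3):
            r = resp[:, s]
            if nk[s] < 1e-8:
                continue
            mean = float((r * x).sum() / nk[s])
            var = float((r * (x - mean) ** 2).sum() / nk[s]) + 1e-8
            a[s], b[s] = _moments_to_beta(mean, var)
        mix = BetaMixture(w, a, b, converged=False)
        dens = np.stack(
            [wk * stats.beta.pdf(x, ak, bk) for wk, ak, bk in zip(w, a, b)], axis=1
        )
        ll = float(np.log(np.clip(dens.sum(axis=1), 1e-300, None)).sum())
        if abs(ll - prev_ll) < tol * len(x):
            mix.converged = True
            break
        prev_ll = ll
    return mix


def _rank_quantile_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map values onto the empirical distribution of reference by rank quantile."""
    order = stats.rankdata(values, method="average") / (len(values) + 1)
    ref_sorted = np.sort(reference)
    grid = (np.arange(1, len(ref_sorted) + 1)) / (len(ref_sorted) + 1)
    return np.interp(order, grid, ref_sorted)


def correct_type2_bias(
    beta: pd.DataFrame,
    design_types: pd.Series,
    tol: float = 1e-4,
    max_iter: int = 300,
    fallback: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Quantile-map type II betas onto the type I distribution, per sample.

    For each sample a three-component beta mixture is fit separately to the
    type I and type II probes; each type II value is assigned to its most
    probable state under the type II fit and mapped through the state's beta
    CDF onto the matching type I state quantile.  Type I values pass through
    bit-for-bit.  On EM non-convergence the sample falls back to rank-based
    quantile normalization of type II onto type I, with a warning.

    Returns the corrected matrix and a metadata dict with the method used per
    sample (``"bmiq"`` or ``"rank-quantile"``).
    """
    if beta.isna().to_numpy().any():
        raise ValueError("matrix contains missing cells; impute before correction")
    design = design_types.reindex(beta.index)
    if design.isna().any():
        missing = design.index[design.isna()].tolist()[:5]
        raise ValueError(f"design type missing for probes, e.g. {missing}")
    is_two = (design == "II").to_numpy()
    if not is_two.any() or is_two.all():
        raise ValueError("both design types must be present for bias correction")

    out = beta.copy()
    info: dict[str, str] = {}
    for sample in beta.columns:
        col = beta[sample].to_numpy(dtype=float)
        x1 = col[~is_two]
        x2 = col[is_two]
        corrected = None
        try:
            mix1 = fit_beta_mixture(x1, tol=tol, max_iter=max_iter)
            mix2 = fit_beta_mixture(x2, tol=tol, max_iter=max_iter, init=mix1)
            if mix1.converged and mix2.converged:
                states = mix2.classify(np.clip(x2, _EPS, 1 - _EPS))
                mapped = np.empty_like(x2)
                for s in range(3):
                    sel = states == s
                    if not sel.any():
                        continue
                    q = stats.beta.cdf(np.clip(x2[sel], _EPS, 1 - _EPS), mix2.a[s], mix2.b[s])
                    q = np.clip(q, 1e-9, 1 - 1e-9)
                    mapped[sel] = stats.beta.ppf(q, mix1.a[s], mix1.b[s])
                corrected = mapped
                info[sample] = "bmiq"
        except (ValueError, FloatingPointError):  # degenerate fit
            corrected = None
        if corrected is None:
            if not fallback:
                raise RuntimeError(f"beta-mixture EM did not converge for sample {sample}")
            logger.warning(
                "EM non-convergence for sample %s; rank-quantile fallback used", sample
            )
            corrected = _rank_quantile_map(x2, x1)
            info[sample] = "rank-quantile"
        vals = out[sample].to_numpy(dtype=float)
        vals[is_two] = np.clip(corrected, 0.0, 1.0)
        out[sample] = vals
    return out, {"method_per_sample": info}
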