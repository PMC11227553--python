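"""Immune activity scores from a gene-expression matrix.

Three marker-panel scores quantify antitumor immunoactivity per sample:

* CYT — cytolytic activity, the geometric mean of GZMA and PRF1;
* MHC — antigen presentation, the arithmetic mean of a nine-gene MHC-I core
  panel (HLA-A, PSMB9, HLA-B, PSMB8, HLA-C, B2M, TAP2, NLRC5, TAP1);
* CTL — cytotoxic T-lymphocyte activity, the mean of CD8A, CD8B, GZMA,
  GZMB and PRF1.

All three expect linear-scale, non-negative expression (e.g. FPKM) and refuse
negative input rather than guessing the scale.  Signature activities are
estimated by a single-sample rank-based running-sum enrichment score
(ssGSEA); T/I/S factor scores summarize z-scored signature activities
allocated to tumor-proliferation (T), antitumor-immunity (I) and
immunosuppression (S) factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MHC_PANEL = ("HLA-A", "PSMB9", "HLA-B", "PSMB8", "HLA-C", "B2M", "TAP2", "NLRC5", "TAP1")
CTL_PANEL = ("CD8A", "CD8B", "GZMA", "GZMB", "PRF1")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    factor_allocation: str | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.factor_allocation not in (None, "T", "I", "S"):
            raise ValueError(f"factor allocation must be T, I or S, not {self.factor_allocation!r}")


def _require_nonnegative(values: np.ndarray, what: str) -> None:
    if np.any(values < 0):
        raise ValueError(
            f"negative {what} values: these scores need linear-scale, non-negative "
            "expression (log-scale input suspected; undo the log transform first)"
        )


def cyt_score(expr_gzma, expr_prf1):
    """Cytolytic activity: geometric mean sqrt(GZMA * PRF1). Scalar or array."""
    g = np.asarray(expr_gzma, dtype=float)
    p = np.asarray(expr_prf1, dtype=float)
    _require_nonnegative(g, "GZMA")
    _require_nonnegative(p, "PRF1")
    out = np.sqrt(g * p)
    return float(out) if out.ndim == 0 else out


def _panel_mean(expr: pd.DataFrame, panel: tuple[str, ...], name: str) -> pd.Series:
    missing = [g for g in panel if g not in expr.index]
    if missing:
        raise ValueError(f"{name} panel genes missing from expression matrix: {missing}")
    sub = expr.loc[list(panel)]
    _require_nonnegative(sub.to_numpy(dtype=float), name)
    return sub.mean(axis=0).rename(name)


def mhc_score(expr: pd.DataFrame) -> pd.Series:
    """MHC-I antigen-presentation score: mean expression of the nine-gene panel."""
    return _panel_mean(expr, MHC_PANEL, "MHC")


def ctl_score(expr: pd.DataFrame) -> pd.Series:
    """Cytotoxic T-lymphocyte score: mean expression of the five-gene panel."""
    return _panel_mean(expr, CTL_PANEL, "CTL")


def cyt_score_matrix(expr: pd.DataFrame) -> pd.Series:
    """CYT score per sample from a genes x samples matrix containing GZMA and PRF1."""
    for g in ("GZMA", "PRF1"):
        if g not in expr.index:
            raise ValueError(f"CYT requires gene {g} in the expression matrix")
    return pd.Series(
        cyt_score(expr.loc["GZMA"].to_numpy(), expr.loc["PRF1"].to_numpy()),
        index=expr.columns,
        name="CYT",
    )


def ssgsea(
    expr: pd.DataFrame,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (gene sets x samples).

    Per sample, genes are ranked by expression (rank 1 = lowest, N = highest;
    ties broken by gene identifier through a stable sort) and walked in
    descending order.  The enrichment score is the sum over all positions of
    the difference between the weighted in-set ECDF (weights = rank^alpha) and
    the out-of-set ECDF.  With ``normalize`` the whole score matrix is divided
    by its (max - min), the usual cross-sample normalization.

    Scores are rank-based, hence invariant to any strictly monotone transform
    of a sample's expression values.  Gene sets with no member in the matrix
    get an all-NaN row and a warning.
    """
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix must have no missing values")
    genes = np.asarray(expr.index, dtype=object)
    n_genes = len(genes)
    X = expr.to_numpy(dtype=float)

    memberships = []
    for gs in gene_sets:
        hit = np.isin(genes, list(gs.members))
        if not hit.any():
            logger.warning("gene set %s has zero overlap with the matrix", gs.name)
        memberships.append(hit)

    scores = np.full((len(gene_sets), expr.shape[1]), np.nan)
    gene_order_key = np.argsort(genes, kind="stable")
    tie_rank = np.empty(n_genes, dtype=int)
    for j in range(expr.shape[1]):
        col = X[:, j]
        # descending expression; ties resolved by gene id (stable sort on a
        # gene-id-sorted base ordering)
        order = gene_order_key[np.argsort(-col[gene_order_key], kind="stable")]
        # rank value: N for the top gene down to 1
        tie_rank[order] = np.arange(n_genes, 0, -1)
        weights = tie_rank.astype(float) ** alpha
        for k, hit in enumerate(memberships):
            if not hit.any() or hit.all():
                if hit.all():
                    logger.warning("gene set %s covers every gene; score undefined", gene_sets[k].name)
                continue
            hit_ord = hit[order]
            w_ord = weights[order]
            cum_hit = np.cumsum(np.where(hit_ord, w_ord, 0.0))
            total_hit = cum_hit[-1]
            cum_miss = np.cumsum(~hit_ord)
            total_miss = cum_miss[-1]
            scores[k, j] = float(np.sum(cum_hit / total_hit - cum_miss / total_miss))

    out = pd.DataFrame(
        scores, index=pd.Index([gs.name for gs in gene_sets], name="gene_set"), columns=expr.columns
    )
    if normalize:
        finite = out.to_numpy()[np.isfinite(out.to_numpy())]
        if finite.size:
            spread = finite.max() - finite.min()
            if spread > 0:
                out = out / spread
    return out


def tis_scores(
    ssgsea_scores: pd.DataFrame, allocation: dict[str, str]
) -> pd.DataFrame:
    """T/I/S factor scores: z-score each gene-set row across samples, then
    average within each factor per sample.

    ``allocation`` maps gene-set name to 'T', 'I' or 'S'.  Zero-variance rows
    are excluded with a warning.  Each factor score has cohort mean 0 by
    construction.
    """
    factors = {"T": [], "I": [], "S": []}
    for name, factor in allocation.items():
        if factor not in factors:
            raise ValueError(f"unknown factor {factor!r} for gene set {name!r}")
        if name not in ssgsea_scores.index:
            raise ValueError(f"gene set {name!r} absent from the score matrix")
        row = ssgsea_scores.loc[name]
        if row.std(ddof=1) == 0 or row.isna().any():
            logger.warning("gene set %s excluded from factor %s (zero variance or NaN)", name, factor)
            continue
        factors[factor].append((row - row.mean()) / row.std(ddof=1))
    for factor, rows in factors.items():
        if not rows:
            raise ValueError(f"factor {factor} has no usable gene set")
    out = pd.DataFrame(
        {f"{f.lower()}_score": pd.concat(rows, axis=1).mean(axis=1) for f, rows in factors.items()}
    ).T
    out.index.name = "factor_score"
    return out


def score_panel(
    expr: pd.DataFrame,
    gene_sets: list[GeneSet] | None = None,
    allocation: dict[str, str] | None = None,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """All per-sample immune scores in one table (scores x samples)."""
    parts = [
        cyt_score_matrix(expr),
        mhc_score(expr),
        ctl_score(expr),
    ]
    out = pd.concat(parts, axis=1).T
    if gene_sets:
        ss = ssgsea(expr, gene_sets, alpha=alpha)
        out = pd.concat([out, ss])
        if allocation:
            out = pd.concat([out, tis_scores(ss, allocation)])
    out.index.name = "score"
    return out
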