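"""Two-group differential expression with a negative-binomial Wald test.

A deliberately self-contained estimator: median-of-ratios size factors,
method-of-moments gene-wise dispersion shrunk halfway toward a
mean-dispersion trend, and a Wald test on the log2 fold change with BH
adjustment across all tested features.  Calling up/down additionally
requires the configured absolute log2 fold-change threshold, so the
status rule is |log2FC| >= T and adjusted p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix

logger = logging.getLogger(__name__)

_PSEUDO = 0.5  # added to group means when one side is all-zero
_DISP_FLOOR = 1e-8


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    log2fc: float
    p: float
    padj: float
    status: str  # up | down | ns


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features with all-positive
    counts; falls back to scaled column totals if none qualify."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.mean(np.log(totals)))
        return sf
    logg = np.log(positive.to_numpy(dtype=float))
    log_geo_mean = logg.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logg - log_geo_mean, axis=0))
    return pd.Series(sf, index=counts.columns)


def normalize_counts(matrix: CountMatrix) -> CountMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    sf = size_factors(matrix.counts)
    return CountMatrix(
        matrix.counts.astype(float).div(sf, axis=1),
        matrix.meta,
        require_integer=False,
    )


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit disp ~ a1/mu + a0 by least squares and evaluate at mu."""
    usable = (mu > 0) & np.isfinite(disp)
    if usable.sum() < 3:
        return np.full_like(mu, max(np.nanmedian(disp), _DISP_FLOOR))
    X = np.column_stack([1.0 / mu[usable], np.ones(usable.sum())])
    coef, *_ = np.linalg.lstsq(X, disp[usable], rcond=None)
    trend = coef[0] / np.maximum(mu, 1e-12) + coef[1]
    return np.maximum(trend, _DISP_FLOOR)


def differential_expression(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test of group B vs. group A, feature by feature.

    Returns a DataFrame with columns feature_id, log2fc, p, padj,
    status.  log2fc > 0 means higher expression in group B.  Features
    with zero counts in every sample are excluded (logged).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    sub = matrix.subset_samples(group_a + group_b)
    sf = size_factors(sub.counts)
    norm = sub.counts.astype(float).div(sf, axis=1)

    nonzero = (norm.sum(axis=1) > 0).to_numpy()
    if (~nonzero).any():
        logger.warning(
            "excluding %d features with zero counts everywhere",
            int((~nonzero).sum()),
        )
    norm = norm.loc[nonzero]

    a = norm[group_a].to_numpy()
    b = norm[group_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)

    # pooled within-group moments for the NB dispersion
    var_pooled = (a.var(axis=1, ddof=1) * (na - 1) +
                  b.var(axis=1, ddof=1) * (nb - 1)) / (na + nb - 2)
    mu_pooled = (mu_a * na + mu_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (var_pooled - mu_pooled) / mu_pooled**2
    disp_mom = np.where(np.isfinite(disp_mom), disp_mom, 0.0)
    disp_mom = np.maximum(disp_mom, _DISP_FLOOR)
    trend = _dispersion_trend(mu_pooled, disp_mom)
    disp = np.maximum(0.5 * disp_mom + 0.5 * trend, _DISP_FLOOR)

    zero_sided = (mu_a == 0) | (mu_b == 0)
    ma = np.where(zero_sided, mu_a + _PSEUDO, mu_a)
    mb = np.where(zero_sided, mu_b + _PSEUDO, mu_b)
    log2fc = np.log2(mb / ma)

    # delta-method variance of log(mean) under NB sampling
    var_log_a = (1.0 / np.maximum(ma, _PSEUDO) + disp) / na
    var_log_b = (1.0 / np.maximum(mb, _PSEUDO) + disp) / nb
    se_ln = np.sqrt(var_log_a + var_log_b)
    wald = np.log(mb / ma) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(wald))

    padj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    status = np.where(
        (log2fc >= lfc_threshold) & (padj < alpha),
        "up",
        np.where((log2fc <= -lfc_threshold) & (padj < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature_id": norm.index,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "status": status,
        }
    ).reset_index(drop=True)
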