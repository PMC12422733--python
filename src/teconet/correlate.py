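"""All-pairs gene x TE Pearson correlation within a sample group.

Correlations are computed on normalized (typically log-transformed)
expression, BH-adjusted jointly across every gene-TE pair in the group,
and filtered by the configured |r| and adjusted-p thresholds.  A
leave-one-out consensus over biological individuals guards against
single-individual artifacts when comparing species with unequal
replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CONFIG, AnalysisConfig
from .data_io import CountMatrix
from .diffexp import normalize_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    te_id: str
    r: float
    n: int
    p: float
    padj: float
    group: str
    significant: bool


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Requires at least 3 paired observations and nonzero variance in
    both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient via the t-transform
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.

    |r| = 1 is a degenerate perfect fit and returns exactly 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def presence_filter(
    expr: pd.DataFrame,
    feature_ids: Sequence[str],
    min_fraction: float = 0.8,
) -> list[str]:
    """Features detected (> 0) in at least ``min_fraction`` of samples."""
    ids = [f for f in feature_ids if f in expr.index]
    if not ids:
        return []
    frac = (expr.loc[ids] > 0).mean(axis=1)
    return list(frac.index[frac >= min_fraction])


def correlate_all(
    expr: pd.DataFrame,
    genes: Sequence[str],
    tes: Sequence[str],
    samples: Sequence[str] | None = None,
    group: str = "",
    config: AnalysisConfig = DEFAULT_CONFIG,
    apply_presence_filter: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of every gene-TE pair across the selected
    samples.

    BH adjustment spans all pairs in the group jointly; a pair is
    significant when padj < ``config.corr_alpha`` and
    |r| > ``config.min_abs_r``.  Zero-variance features are dropped
    with a warning.  Output is a DataFrame with one row per pair,
    ordered gene-major / TE-minor in sorted id order, fully
    deterministic given the inputs.
    """
    if samples is None:
        samples = list(expr.columns)
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    genes = sorted(set(genes))
    tes = sorted(set(tes))
    if not genes or not tes:
        raise ValueError("gene and TE sets must be nonempty")
    if set(genes) & set(tes):
        raise ValueError("gene and TE sets must be disjoint")

    sub = expr[samples]
    if apply_presence_filter:
        genes = presence_filter(sub, genes, config.presence_min_fraction)
        tes = presence_filter(sub, tes, config.presence_min_fraction)
    else:
        genes = [g for g in genes if g in sub.index]
        tes = [t for t in tes if t in sub.index]
    if not genes or not tes:
        return _empty_records()

    gmat = sub.loc[genes].to_numpy(dtype=float)
    tmat = sub.loc[tes].to_numpy(dtype=float)
    g_ok = gmat.std(axis=1) > 0
    t_ok = tmat.std(axis=1) > 0
    if (~g_ok).any() or (~t_ok).any():
        logger.warning(
            "dropping %d genes / %d TEs with zero variance",
            int((~g_ok).sum()),
            int((~t_ok).sum()),
        )
    genes = [g for g, ok in zip(genes, g_ok) if ok]
    tes = [t for t, ok in zip(tes, t_ok) if ok]
    if not genes or not tes:
        return _empty_records()
    gmat, tmat = gmat[g_ok], tmat[t_ok]

    gz = gmat - gmat.mean(axis=1, keepdims=True)
    tz = tmat - tmat.mean(axis=1, keepdims=True)
    gz /= np.sqrt((gz**2).sum(axis=1, keepdims=True))
    tz /= np.sqrt((tz**2).sum(axis=1, keepdims=True))
    r = np.clip(gz @ tz.T, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0

    flat_p = p.ravel()
    padj = bh_adjust(flat_p).reshape(p.shape)
    sig = (padj < config.corr_alpha) & (np.abs(r) > config.min_abs_r)

    gene_col = np.repeat(genes, len(tes))
    te_col = np.tile(tes, len(genes))
    return pd.DataFrame(
        {
            "gene_id": gene_col,
            "te_id": te_col,
            "r": r.ravel(),
            "n": n,
            "p": flat_p,
            "padj": padj.ravel(),
            "group": group,
            "significant": sig.ravel(),
        }
    )


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": pd.Series(dtype=str),
            "te_id": pd.Series(dtype=str),
            "r": pd.Series(dtype=float),
            "n": pd.Series(dtype=int),
            "p": pd.Series(dtype=float),
            "padj": pd.Series(dtype=float),
            "group": pd.Series(dtype=str),
            "significant": pd.Series(dtype=bool),
        }
    )


def leave_one_out_consensus(
    expr: pd.DataFrame,
    genes: Sequence[str],
    tes: Sequence[str],
    sample_individuals: Mapping[str, str],
    samples: Sequence[str] | None = None,
    group: str = "",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Correlations significant, with consistent sign, in every
    leave-one-individual-out subset.

    Each excluded unit is a biological individual: all of its samples
    are removed together.  Reported r / p / padj come from the
    full-sample run; ``significant`` marks consensus pairs.
    """
    if samples is None:
        samples = list(expr.columns)
    samples = list(samples)
    individuals = sorted({sample_individuals[s] for s in samples})
    if len(individuals) < 3:
        raise ValueError("need at least 3 individuals for leave-one-out")

    full = correlate_all(expr, genes, tes, samples, group, config)
    consensus = None
    for ind in individuals:
        kept = [s for s in samples if sample_individuals[s] != ind]
        if len(kept) < 3:
            raise ValueError(
                f"excluding individual {ind!r} leaves fewer than 3 samples"
            )
        sub = correlate_all(expr, genes, tes, kept, group, config)
        sub_sig = sub[sub["significant"]]
        keyed = set(
            zip(sub_sig["gene_id"], sub_sig["te_id"], np.sign(sub_sig["r"]))
        )
        consensus = keyed if consensus is None else (consensus & keyed)

    keys = list(
        zip(full["gene_id"], full["te_id"], np.sign(full["r"]))
    )
    in_consensus = np.array([k in consensus for k in keys])
    out = full.copy()
    out["significant"] = out["significant"].to_numpy() & in_consensus
    return out


def log_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """log2(1 + x) of size-factor-normalized expression.

    The standard variance-stabilizing transform applied before
    correlation; returns a features x samples DataFrame.
    """
    norm = normalize_counts(matrix)
    return np.log2(norm.counts + 1.0)
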