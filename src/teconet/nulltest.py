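"""Permutation nulls and binding-evidence validation for correlations.

Two questions are answered here: do the focal genes (e.g. KRAB-ZNFs)
have more significant TE correlations than random gene sets of the same
size, and do the significant pairs overlap binding evidence (ChIP-exo
derived KRAB-ZNF / TE pairs) more than random pair sets?  Both use
one-sided "greater" empirical p-values with the plus-one rule, so p is
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .correlate import correlate_all


@dataclass
class PermutationSummary:
    """observed statistic, null draws, and the empirical p-value
    (1 + #{null >= observed}) / (1 + B)."""

    observed: float
    null_values: np.ndarray
    B: int = field(init=False)
    empirical_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        self.B = int(len(self.null_values))
        self.empirical_p = float(
            (1 + np.sum(self.null_values >= self.observed)) / (1 + self.B)
        )


def _sig_counts(records: pd.DataFrame) -> tuple[int, int, int]:
    sig = records[records["significant"]]
    pos = int((sig["r"] > 0).sum())
    neg = int((sig["r"] < 0).sum())
    return pos + neg, pos, neg


def random_geneset_null(
    expr: pd.DataFrame,
    focal_genes: Sequence[str],
    tes: Sequence[str],
    pool: Sequence[str],
    samples: Sequence[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    group: str = "",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, PermutationSummary]:
    """Are there more significant correlations for the focal genes than
    for random same-size gene sets drawn from ``pool``?

    Each iteration redraws |focal| genes without replacement and pushes
    them through the identical correlation pipeline.  Returns three
    summaries keyed "all", "positive", "negative".
    """
    focal_genes = sorted(set(focal_genes))
    pool = sorted(set(pool) - set(focal_genes))
    if len(pool) < len(focal_genes):
        raise ValueError(
            f"null pool ({len(pool)}) smaller than focal set "
            f"({len(focal_genes)})"
        )
    if B < 100:
        raise ValueError("need at least 100 iterations")

    observed = _sig_counts(
        correlate_all(expr, focal_genes, tes, samples, group, config)
    )
    rng = np.random.default_rng(seed)
    null = np.empty((B, 3), dtype=float)
    pool_arr = np.asarray(pool)
    for i in range(B):
        draw = rng.choice(pool_arr, size=len(focal_genes), replace=False)
        null[i] = _sig_counts(
            correlate_all(expr, list(draw), tes, samples, group, config)
        )
    return {
        name: PermutationSummary(observed[j], null[:, j])
        for j, name in enumerate(("all", "positive", "negative"))
    }


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; two empty sets give 0 by convention."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def evidence_overlap_test(
    sig_pairs: set[tuple[str, str]],
    evidence: set[tuple[str, str]],
    universe: Sequence[tuple[str, str]],
    B: int = 1000,
    seed: int = 0,
) -> PermutationSummary:
    """Jaccard overlap of significant pairs with binding evidence,
    against random same-size pair sets drawn from the universe."""
    if not sig_pairs:
        raise ValueError("significant pair set is empty")
    universe = sorted(set(universe))
    if not set(sig_pairs) <= set(universe):
        raise ValueError("sig_pairs must be a subset of the universe")
    evidence_in = set(evidence) & set(universe)
    observed = jaccard(sig_pairs, evidence_in)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(universe))
    null = np.empty(B)
    for i in range(B):
        draw = rng.choice(idx, size=len(sig_pairs), replace=False)
        null[i] = jaccard({universe[j] for j in draw}, evidence_in)
    return PermutationSummary(observed, null)


def filter_by_evidence(
    records: pd.DataFrame, evidence: set[tuple[str, str]]
) -> pd.DataFrame:
    """Keep records whose (gene, TE) pair has binding evidence; order
    is preserved."""
    keys = list(zip(records["gene_id"], records["te_id"]))
    mask = np.array([k in evidence for k in keys], dtype=bool)
    return records[mask].reset_index(drop=True)
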