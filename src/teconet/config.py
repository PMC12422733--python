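"""Analysis configuration.

All filtering thresholds used across the pipeline live in one immutable
object so that every stage (differential expression, correlation
discovery, age classification, network analysis) reads the same values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sizes shared by the whole workflow.

    Attributes
    ----------
    min_abs_r:
        Minimum absolute Pearson coefficient for a gene-TE correlation
        to be called significant.
    corr_alpha:
        BH-adjusted p-value cutoff for correlations.
    lfc_threshold:
        Absolute log2 fold-change cutoff for differential expression in
        the cross-species comparison.
    lfc_threshold_condition:
        Relaxed log2 fold-change cutoff used for within-species
        condition contrasts (control vs. disease), where expression
        differences are smaller.
    de_alpha:
        BH-adjusted p-value cutoff for differential expression.
    age_split_mya:
        Age (million years) separating evolutionary *young* features
        (emerged at or after the split, i.e. age <= split) from *old*
        ones.  The default corresponds to the emergence of Simiiformes.
    hub_top_fraction:
        Fraction of top-scoring nodes (by degree and by strength)
        selected as network hubs.
    permutation_iterations:
        Default number of iterations for permutation null tests.
    fisher_n_sim:
        Number of Monte-Carlo tables for the simulated Fisher test in
        module enrichment.
    presence_min_fraction:
        A feature counts as "expressed" in a sample group when it is
        nonzero in at least this fraction of the group's samples.
    scaling_alpha:
        Nominal type-I error level targeted by the cross-species
        scaling-factor estimator.
    grid_points / grid_log2_halfwidth:
        Scaling-factor search grid: ``grid_points`` log2-spaced values
        spanning ``2**±grid_log2_halfwidth`` around a moment estimate.
    min_conserved:
        Minimum number of usable conserved features required to
        estimate a scaling factor.
    ortholog_confidence:
        Keep only ortholog rows at this confidence ("high") or any
        confidence ("all") when building the conserved set.
    """

    min_abs_r: float = 0.4
    corr_alpha: float = 0.01
    lfc_threshold: float = 1.5
    lfc_threshold_condition: float = 0.5
    de_alpha: float = 0.05
    age_split_mya: float = 44.2
    hub_top_fraction: float = 0.05
    permutation_iterations: int = 1000
    fisher_n_sim: int = 1_000_000
    presence_min_fraction: float = 0.8
    scaling_alpha: float = 0.05
    grid_points: int = 401
    grid_log2_halfwidth: float = 2.0
    min_conserved: int = 20
    ortholog_confidence: str = "high"

    def with_overrides(self, **kwargs: Any) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


DEFAULT_CONFIG = AnalysisConfig()
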