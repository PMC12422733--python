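"""Cross-species and control-vs-disease comparison of correlation sets.

Significant gene-TE links from several groups (species, or condition
within a species) are lined up on a shared feature universe and each
pair is categorized relative to a reference group: conserved (also
significant with the same sign in a comparison group), reference-
specific (significant only in the reference), sign-flipped (significant
with opposite signs in two groups), or other.  A separate operation
intersects condition-lost links (significant in control but not in
disease) with an externally supplied reference-specific pair set.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .correlate import presence_filter
from .data_io import CountMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("conserved", "reference_specific", "sign_flip", "other")


def restrict_to_shared_features(
    matrices: Mapping[str, CountMatrix],
    annotation: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[list[str], list[str]]:
    """Genes and TEs expressed in every species.

    Presence means nonzero in at least the configured fraction of a
    species' samples; the returned sets are the intersections across
    all species, sorted.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 species to intersect")
    genes_all = annotation.index[annotation["kind"] == "gene"]
    tes_all = annotation.index[annotation["kind"] == "TE"]
    gene_sets, te_sets = [], []
    for name, matrix in matrices.items():
        expr = matrix.counts
        gene_sets.append(
            set(presence_filter(expr, genes_all, config.presence_min_fraction))
        )
        te_sets.append(
            set(presence_filter(expr, tes_all, config.presence_min_fraction))
        )
    genes = sorted(set.intersection(*gene_sets))
    tes = sorted(set.intersection(*te_sets))
    if not genes and not tes:
        raise ValueError("no feature is expressed in all species")
    return genes, tes


def _status_map(records: pd.DataFrame) -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    for row in records.itertuples(index=False):
        if row.significant:
            out[(row.gene_id, row.te_id)] = (
                "sig_pos" if row.r > 0 else "sig_neg"
            )
    return out


def compare_groups(
    records_by_group: Mapping[str, pd.DataFrame],
    reference: str,
) -> pd.DataFrame:
    """Per-pair link status across groups and a single category each.

    Categories, applied in order of precedence to pairs significant in
    the reference group: ``sign_flip`` (significant with the opposite
    sign in some comparison group), ``conserved`` (same sign in some
    comparison group), ``reference_specific`` (ns in every comparison
    group).  Pairs significant only outside the reference are
    ``other``.
    """
    if reference not in records_by_group:
        raise ValueError(f"reference group {reference!r} not provided")
    groups = sorted(records_by_group)
    status = {g: _status_map(records_by_group[g]) for g in groups}
    pairs = sorted(set().union(*[set(s) for s in status.values()]))

    rows = []
    for pair in pairs:
        per_group = {g: status[g].get(pair, "ns") for g in groups}
        ref = per_group[reference]
        others = [per_group[g] for g in groups if g != reference]
        flip_partner = ""
        if ref in ("sig_pos", "sig_neg"):
            opposite = "sig_neg" if ref == "sig_pos" else "sig_pos"
            if opposite in others:
                category = "sign_flip"
                flip_partner = next(
                    g
                    for g in groups
                    if g != reference and per_group[g] == opposite
                )
            elif ref in others:
                category = "conserved"
            else:
                category = "reference_specific"
        else:
            category = "other"
        rows.append(
            {
                "gene_id": pair[0],
                "te_id": pair[1],
                **{f"status_{g}": per_group[g] for g in groups},
                "category": category,
                "sign_flip_group": flip_partner,
            }
        )
    return pd.DataFrame(rows)


def category_counts(comparison: pd.DataFrame) -> dict[str, int]:
    counts = comparison["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def condition_lost_links(
    control: pd.DataFrame,
    disease: pd.DataFrame,
    external_specific: set[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Pairs significant in control but not in disease, restricted to
    an externally derived reference-specific pair set (e.g. the
    human-specific links from a cross-species comparison)."""
    control_sig = set(_status_map(control))
    disease_sig = set(_status_map(disease))
    return (control_sig - disease_sig) & set(external_specific)
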