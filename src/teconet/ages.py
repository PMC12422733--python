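"""Evolutionary-age classification of features and correlation links.

Features are split at a configurable age (default 44.2 Mya, roughly the
emergence of Simiiformes) into *young* (age <= split) and *old*
(age > split).  A correlation link is young when either endpoint is
young and old only when both endpoints are old; combined with the sign
of the coefficient this yields four link classes: P-O, P-Y, N-O, N-Y.
Per-TE-family composition tests ask whether a family's links are
distributed across the four classes differently from all other
families pooled.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LINK_CLASSES = ("P-O", "P-Y", "N-O", "N-Y")


def age_class(age_mya: float, split: float = 44.2) -> str:
    """'young' when age <= split, 'old' when age > split."""
    if age_mya < 0:
        raise ValueError("age must be nonnegative")
    return "young" if age_mya <= split else "old"


def link_class(r: float, gene_age: str, te_age: str) -> str:
    """Four-way class of a link: sign of r x (young if any endpoint is
    young, old only if both are old)."""
    if r == 0:
        raise ValueError("r = 0 carries no sign; cannot classify link")
    for a in (gene_age, te_age):
        if a not in ("young", "old"):
            raise ValueError(f"invalid age class {a!r}")
    sign = "P" if r > 0 else "N"
    age = "Y" if "young" in (gene_age, te_age) else "O"
    return f"{sign}-{age}"


def classify_links(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    split: float = 44.2,
) -> pd.DataFrame:
    """Attach gene_age / te_age / link_class columns to correlation
    records.

    Links whose endpoints lack an age (NaN in the annotation, i.e.
    elements that could not be placed on a branch) are excluded with a
    warning.
    """
    ages = annotation["age_mya"]
    out = records.copy()
    gene_age = out["gene_id"].map(ages)
    te_age = out["te_id"].map(ages)
    usable = gene_age.notna() & te_age.notna()
    if (~usable).any():
        logger.warning(
            "excluding %d links with un-aged endpoints", int((~usable).sum())
        )
    out = out[usable].copy()
    out["gene_age"] = [
        age_class(a, split) for a in gene_age[usable].to_numpy()
    ]
    out["te_age"] = [age_class(a, split) for a in te_age[usable].to_numpy()]
    out["link_class"] = [
        link_class(r, g, t)
        for r, g, t in zip(out["r"], out["gene_age"], out["te_age"])
    ]
    return out.reset_index(drop=True)


def class_table(records: pd.DataFrame) -> pd.Series:
    """Counts of the four link classes in a fixed order."""
    counts = records["link_class"].value_counts()
    return pd.Series(
        [int(counts.get(c, 0)) for c in LINK_CLASSES], index=LINK_CLASSES
    )


def _mc_chi2_p(
    table: np.ndarray, n_sim: int, seed: int
) -> float:
    """Monte-Carlo chi-squared p for a 2 x k table with fixed margins."""
    observed_chi2 = stats.chi2_contingency(table, correction=False)[0]
    dist = stats.random_table(
        table.sum(axis=1), table.sum(axis=0), seed=np.random.default_rng(seed)
    )
    sims = dist.rvs(n_sim)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_sims = np.nansum(
            (sims - expected) ** 2 / expected, axis=(1, 2)
        )
    return float((1 + np.sum(chi2_sims >= observed_chi2 - 1e-12)) / (1 + n_sim))


def family_class_test(
    records: pd.DataFrame,
    family_of: Mapping[str, str],
    alpha: float = 0.001,
    n_sim: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-TE-family test of link-class composition.

    For each family, a 2 x 4 contingency table (family vs. all other
    families, by link class) is tested with a chi-squared test; when
    any expected cell is below 5 the asymptotic p is replaced by a
    Monte-Carlo p under fixed margins.  A family is flagged when
    p < alpha.
    """
    classified = records.copy()
    classified["family"] = classified["te_id"].map(dict(family_of))
    families = sorted(classified["family"].dropna().unique())
    if len(families) < 2:
        raise ValueError("need links from at least 2 TE families")

    global_counts = class_table(classified)
    rows = []
    for fam in families:
        fam_counts = class_table(classified[classified["family"] == fam])
        rest = global_counts - fam_counts
        if fam_counts.sum() == 0:
            logger.warning("family %r has no classified links; skipped", fam)
            continue
        table = np.vstack([fam_counts.to_numpy(), rest.to_numpy()])
        # drop classes absent everywhere (zero-margin columns)
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            logger.warning(
                "family %r leaves a degenerate table; skipped", fam
            )
            continue
        chi2, p, _, expected = stats.chi2_contingency(
            table, correction=False
        )
        monte_carlo = bool((expected < 5).any())
        if monte_carlo:
            p = _mc_chi2_p(table, n_sim, seed)
        rows.append(
            {
                "family": fam,
                **{c: int(fam_counts[c]) for c in LINK_CLASSES},
                "chi2": float(chi2),
                "p": float(p),
                "monte_carlo": monte_carlo,
                "flagged": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
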