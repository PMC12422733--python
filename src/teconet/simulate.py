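"""Synthetic multi-species brain-expression fixtures with known truth.

The generator emulates the structure of the two study designs the
pipeline targets: a multi-species primate dataset (several species,
few biological individuals each, samples from grouped brain regions)
and a single-species control/disease dataset.  Counts are negative
binomial around log-normal latent expression; selected gene-TE pairs
share a Gaussian-copula latent factor tuned so that the *observed*
Pearson correlation of log-normalized counts matches the requested
target, and each species' measured features carry a known composition
scaling factor relative to the nominal sequencing depth.

Every downstream stage can be tested against the emitted ground truth
without touching generator internals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountMatrix, validate_annotation, validate_ortholog_map

TE_FAMILIES = {
    "Alu": "SINE",
    "MIR": "SINE",
    "L1": "LINE",
    "L2": "LINE",
    "ERV1": "LTR",
    "ERVK": "LTR",
    "ERVL": "LTR",
    "SVA": "SVA",
    "TcMar-Tigger": "DNA",
    "hAT-Charlie": "DNA",
}


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    scaling_factor: float = 1.0
    n_individuals: int = 3


@dataclass(frozen=True)
class PlantedLink:
    """A gene-TE pair with a target observed correlation.

    ``species`` / ``conditions`` restrict where the correlation holds
    (None = everywhere); elsewhere the pair is independent.
    ``in_evidence`` marks the pair for inclusion in the simulated
    binding-evidence list.
    """

    gene_id: str
    te_id: str
    target_r: float
    sign: int = 1
    species: tuple[str, ...] | None = None
    conditions: tuple[str, ...] | None = None
    in_evidence: bool = True


@dataclass(frozen=True)
class SimSpec:
    """Scenario description for :func:`simulate`.

    Defaults mirror the shape of a primate brain comparison: four
    species (one reference with four individuals, three with three),
    seven region groups with a handful of samples per individual and
    group, and feature counts of the order of hundreds of KRAB-ZNFs
    and TE subfamilies.
    """

    n_genes: int = 120
    n_tes: int = 90
    n_krabznf: int = 34
    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("human", 1.0, 4),
        SpeciesSpec("chimp", 0.8, 3),
        SpeciesSpec("bonobo", 1.2, 3),
        SpeciesSpec("macaque", 1.5, 3),
    )
    groups: tuple[str, ...] = ("cortex", "limbic")
    conditions: tuple[str, ...] = ("control",)
    samples_per_group: int = 4  # per individual, group, and condition
    planted_links: tuple[PlantedLink, ...] = ()
    age_fraction_young: float = 0.3
    nb_dispersion: float = 0.05
    latent_sd: float = 0.8
    base_log_mean: float = np.log(30.0)
    depth: float = 2e6  # nominal total mapped reads per sample
    n_background_factors: int = 0
    background_strength: float = 0.0
    n_evidence_decoys: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_krabznf > self.n_genes:
            raise ValueError("n_krabznf cannot exceed n_genes")
        for link in self.planted_links:
            if not (0 < link.target_r < 1):
                raise ValueError(
                    f"planted |target_r| must be in (0,1); got {link.target_r}"
                )
            if link.sign not in (-1, 1):
                raise ValueError("planted sign must be +1 or -1")
        planted_features = [
            f for l in self.planted_links for f in (l.gene_id, l.te_id)
        ]
        if len(planted_features) != len(set(planted_features)):
            raise ValueError("each feature may appear in one planted link")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def default_primate_spec(**overrides) -> SimSpec:
    """Full-size scenario matching the study shape (~340 KRAB-ZNFs,
    ~900 TE subfamilies, 4+3+3+3 individuals, 7 region groups)."""
    base = dict(
        n_genes=1200,
        n_tes=900,
        n_krabznf=340,
        groups=(
            "primary_secondary_cortices",
            "limbic_association_cortices",
            "archicortex",
            "thalamus_hypothalamus",
            "basal_ganglia",
            "cerebellar_gray",
            "cerebellar_white",
        ),
        samples_per_group=5,
    )
    base.update(overrides)
    return SimSpec(**base)


def null_spec(spec: SimSpec) -> SimSpec:
    """Copy of the spec with no planted links (pure null)."""
    return dataclasses.replace(spec, planted_links=())


@dataclass
class SimulatedData:
    matrices: dict[str, CountMatrix]
    annotation: pd.DataFrame
    orthologs: pd.DataFrame
    evidence: set[tuple[str, str]]
    truth: dict


def gene_ids(spec: SimSpec) -> list[str]:
    krab = [f"ZNF{i + 1:04d}" for i in range(spec.n_krabznf)]
    rest = [f"GENE{i + 1:04d}" for i in range(spec.n_genes - spec.n_krabznf)]
    return krab + rest


def te_ids(spec: SimSpec) -> list[str]:
    return [f"TE{i + 1:04d}" for i in range(spec.n_tes)]


def _make_annotation(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    genes = gene_ids(spec)
    tes = te_ids(spec)
    families = list(TE_FAMILIES)
    fam_assign = [families[i % len(families)] for i in range(spec.n_tes)]
    n_young_g = int(round(spec.age_fraction_young * spec.n_genes))
    n_young_t = int(round(spec.age_fraction_young * spec.n_tes))
    young_g = np.zeros(spec.n_genes, bool)
    young_g[rng.choice(spec.n_genes, n_young_g, replace=False)] = True
    young_t = np.zeros(spec.n_tes, bool)
    young_t[rng.choice(spec.n_tes, n_young_t, replace=False)] = True
    age_g = np.where(
        young_g, rng.uniform(0.5, 44.2, spec.n_genes),
        rng.uniform(44.3, 180.0, spec.n_genes),
    )
    age_t = np.where(
        young_t, rng.uniform(0.5, 44.2, spec.n_tes),
        rng.uniform(44.3, 180.0, spec.n_tes),
    )
    ann = pd.DataFrame(
        {
            "kind": ["gene"] * spec.n_genes + ["TE"] * spec.n_tes,
            "te_class": [""] * spec.n_genes
            + [TE_FAMILIES[f] for f in fam_assign],
            "te_family": [""] * spec.n_genes + fam_assign,
            "is_krab_znf": [i < spec.n_krabznf for i in range(spec.n_genes)]
            + [False] * spec.n_tes,
            "length_bp": np.concatenate(
                [
                    rng.integers(500, 5000, spec.n_genes),
                    rng.integers(300, 6000, spec.n_tes),
                ]
            ),
            "age_mya": np.round(np.concatenate([age_g, age_t]), 2),
        },
        index=pd.Index(genes + tes, name="feature_id"),
    )
    return validate_annotation(ann)


def _tuned_latent_rho(
    link: PlantedLink,
    mu_g: float,
    mu_t: float,
    spec: SimSpec,
) -> float:
    """Latent normal correlation whose induced log-count correlation
    approximates the requested target, correcting for NB counting noise
    on both endpoints."""
    s2 = spec.latent_sd**2
    v_g = 1.0 / max(mu_g, 1e-9) + spec.nb_dispersion
    v_t = 1.0 / max(mu_t, 1e-9) + spec.nb_dispersion
    rho = link.target_r * np.sqrt((s2 + v_g) * (s2 + v_t)) / s2
    if rho >= 1.0:
        rho = 0.995  # attenuation-limited; land as close as feasible
    return float(link.sign * rho)


def simulate(spec: SimSpec) -> SimulatedData:
    """Generate per-species count matrices plus annotation, ortholog
    map, binding-evidence pairs, and ground-truth tables.

    Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_ids(spec)
    tes = te_ids(spec)
    features = genes + tes
    n_feat = len(features)
    feat_index = {f: i for i, f in enumerate(features)}

    annotation = _make_annotation(spec, rng)
    baseline = spec.base_log_mean + rng.normal(0.0, 1.0, n_feat)

    # per-species effective lengths for orthologous genes
    len_a = annotation["length_bp"].to_numpy(dtype=float)
    gene_len_b = {}
    for sp in spec.species[1:]:
        gene_len_b[sp.name] = np.maximum(
            1,
            np.round(
                len_a[: spec.n_genes] * rng.uniform(0.9, 1.1, spec.n_genes)
            ),
        )

    planted = list(spec.planted_links)
    for link in planted:
        for fid in (link.gene_id, link.te_id):
            if fid not in feat_index:
                raise ValueError(f"planted feature {fid!r} not in id space")

    # sample table
    sample_rows = []
    for sp in spec.species:
        for ind in range(1, sp.n_individuals + 1):
            for grp in spec.groups:
                for cond in spec.conditions:
                    for k in range(1, spec.samples_per_group + 1):
                        sample_rows.append(
                            {
                                "sample_id": f"{sp.name}_i{ind}_{grp}_{cond}_s{k}",
                                "species": sp.name,
                                "individual": f"{sp.name}_i{ind}",
                                "group": grp,
                                "condition": cond,
                            }
                        )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # latent per-sample noise, with copula coupling for planted pairs
    factors_by_species = {sp.name: sp.scaling_factor for sp in spec.species}
    ref = spec.species[0].name
    matrices: dict[str, CountMatrix] = {}
    tuned = {}
    for link in planted:
        gi, ti = feat_index[link.gene_id], feat_index[link.te_id]
        mu_g = (
            np.exp(baseline[gi] + spec.latent_sd**2 / 2)
            * len_a[gi] / 1e3 * spec.depth / 1e6
        )
        mu_t = (
            np.exp(baseline[ti] + spec.latent_sd**2 / 2)
            * len_a[ti] / 1e3 * spec.depth / 1e6
        )
        tuned[(link.gene_id, link.te_id)] = _tuned_latent_rho(
            link, mu_g, mu_t, spec
        )

    for sp in spec.species:
        sp_samples = samples[samples["species"] == sp.name]
        n_s = len(sp_samples)
        eps = rng.standard_normal((n_feat, n_s))
        if spec.n_background_factors > 0 and spec.background_strength > 0:
            loadings = rng.normal(
                0.0,
                spec.background_strength,
                (n_feat, spec.n_background_factors),
            )
            factors = rng.standard_normal((spec.n_background_factors, n_s))
            background = loadings @ factors
        else:
            background = 0.0

        for link in planted:
            active_sp = link.species is None or sp.name in link.species
            if not active_sp:
                continue
            cond_mask = np.ones(n_s, dtype=bool)
            if link.conditions is not None:
                cond_mask = sp_samples["condition"].isin(
                    link.conditions
                ).to_numpy()
            gi, ti = feat_index[link.gene_id], feat_index[link.te_id]
            rho = tuned[(link.gene_id, link.te_id)]
            eps[ti, cond_mask] = rho * eps[gi, cond_mask] + np.sqrt(
                1 - rho**2
            ) * eps[ti, cond_mask]

        z = baseline[:, None] + spec.latent_sd * eps + background
        lengths = len_a.copy()
        if sp.name != ref:
            lengths[: spec.n_genes] = gene_len_b[sp.name]
        depth_jitter = rng.uniform(0.9, 1.1, n_s)
        mean = (
            np.exp(z)
            * (lengths[:, None] / 1e3)
            * (spec.depth * depth_jitter[None, :] / 1e6)
            * sp.scaling_factor
        )
        shape = 1.0 / spec.nb_dispersion
        counts = rng.poisson(rng.gamma(shape, mean / shape))
        meta = sp_samples.copy()
        meta["lib_size"] = spec.depth * depth_jitter
        matrices[sp.name] = CountMatrix(
            pd.DataFrame(
                counts, index=pd.Index(features, name="feature_id"),
                columns=sp_samples.index,
            ),
            meta,
        )

    # one-to-one ortholog map over genes (shared symbols across species)
    second = spec.species[1].name if len(spec.species) > 1 else ref
    orthologs = validate_ortholog_map(
        pd.DataFrame(
            {
                "feature_id_a": genes,
                "feature_id_b": genes,
                "length_a_bp": len_a[: spec.n_genes].astype(int),
                "length_b_bp": (
                    gene_len_b[second].astype(int)
                    if second != ref
                    else len_a[: spec.n_genes].astype(int)
                ),
                "confidence": np.where(
                    rng.uniform(size=spec.n_genes) < 0.9, "high", "low"
                ),
            }
        )
    )

    evidence = {
        (l.gene_id, l.te_id) for l in planted if l.in_evidence
    }
    planted_pairs = {(l.gene_id, l.te_id) for l in planted}
    krab = [g for g in genes[: spec.n_krabznf]]
    while len(evidence) < len(planted_pairs & evidence) + spec.n_evidence_decoys:
        pair = (
            krab[rng.integers(len(krab))],
            tes[rng.integers(len(tes))],
        )
        if pair not in planted_pairs:
            evidence.add(pair)

    truth = {
        "factors": factors_by_species,
        "planted": pd.DataFrame(
            [
                {
                    "gene_id": l.gene_id,
                    "te_id": l.te_id,
                    "target_r": l.sign * l.target_r,
                    "latent_rho": tuned[(l.gene_id, l.te_id)],
                    "species": ";".join(l.species)
                    if l.species is not None
                    else "",
                    "conditions": ";".join(l.conditions)
                    if l.conditions is not None
                    else "",
                    "in_evidence": l.in_evidence,
                }
                for l in planted
            ],
            columns=[
                "gene_id", "te_id", "target_r", "latent_rho",
                "species", "conditions", "in_evidence",
            ],
        ),
        "spec": spec,
    }
    return SimulatedData(matrices, annotation, orthologs, evidence, truth)
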