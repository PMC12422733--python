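"""End-to-end workflows tying the stages together.

``cross_species_analysis`` runs the full multi-species route: shared
feature restriction, between-species normalization, leave-one-out
correlation discovery in the reference species, plain discovery in the
others, binding-evidence filtering, bipartite network construction with
module detection, and cross-species link categorization.
``condition_analysis`` is the single-species control/disease route.
``planted_benchmark`` builds the paired synthetic scenario (a primate
style multi-species dataset plus a control/disease dataset) with known
conserved, reference-specific, and condition-lost links, for recovery
benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ages import classify_links
from .config import DEFAULT_CONFIG, AnalysisConfig
from .contrasts import compare_groups, restrict_to_shared_features
from .correlate import correlate_all, leave_one_out_consensus, log_normalize
from .crossnorm import apply_scaling, estimate_gene_scaling
from .network import build_network, detect_modules, hubs
from .nulltest import filter_by_evidence
from .simulate import PlantedLink, SimSpec, SimulatedData, SpeciesSpec, simulate


@dataclass
class CrossSpeciesResult:
    scaling_factors: dict[str, float]
    records_by_species: dict[str, pd.DataFrame]
    evidence_records: pd.DataFrame
    network: object
    partition: dict[str, int]
    modularity: float
    hubs: set[str]
    comparison: pd.DataFrame
    reference_specific: set[tuple[str, str]]
    shared_genes: list[str]
    shared_tes: list[str]


def cross_species_analysis(
    data: SimulatedData,
    reference: str | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    group: str | None = None,
    detect_seed: int = 0,
) -> CrossSpeciesResult:
    """Multi-species correlation discovery, network, and contrasts."""
    species = list(data.matrices)
    reference = reference or species[0]
    group = group or data.matrices[reference].meta["group"].iloc[0]

    shared_genes, shared_tes = restrict_to_shared_features(
        data.matrices, data.annotation, config
    )
    krab = set(
        data.annotation.index[data.annotation["is_krab_znf"].astype(bool)]
    )
    genes = sorted(set(shared_genes) & krab)

    # between-species scaling against the reference (a species-level
    # constant; within-species correlations are unaffected by design)
    factors = {reference: 1.0}
    matrices = {reference: data.matrices[reference]}
    for sp in species:
        if sp == reference:
            continue
        result = estimate_gene_scaling(
            data.matrices[reference], data.matrices[sp], data.orthologs, config
        )
        factors[sp] = result.factor
        matrices[sp] = apply_scaling(data.matrices[sp], result)

    records = {}
    for sp in species:
        matrix = matrices[sp]
        expr = log_normalize(matrix)
        samples = matrix.samples_where(group=group)
        if sp == reference:
            records[sp] = leave_one_out_consensus(
                expr,
                genes,
                shared_tes,
                matrix.meta["individual"].to_dict(),
                samples,
                group=f"{sp}:{group}",
                config=config,
            )
        else:
            records[sp] = correlate_all(
                expr, genes, shared_tes, samples, f"{sp}:{group}", config
            )

    ref_sig = records[reference][records[reference]["significant"]]
    evidence_records = filter_by_evidence(
        ref_sig.reset_index(drop=True), data.evidence
    )
    classified = classify_links(
        evidence_records, data.annotation, config.age_split_mya
    )
    net = build_network(classified)
    if net.n_edges:
        partition, modularity = detect_modules(net, seed=detect_seed)
        net.partition, net.modularity = partition, modularity
        hub_nodes = hubs(net, config.hub_top_fraction)
    else:
        partition, modularity, hub_nodes = {}, float("nan"), set()

    comparison = compare_groups(records, reference)
    ref_specific = set(
        zip(
            comparison.loc[
                comparison["category"] == "reference_specific", "gene_id"
            ],
            comparison.loc[
                comparison["category"] == "reference_specific", "te_id"
            ],
        )
    )
    return CrossSpeciesResult(
        scaling_factors=factors,
        records_by_species=records,
        evidence_records=evidence_records,
        network=net,
        partition=partition,
        modularity=modularity,
        hubs=hub_nodes,
        comparison=comparison,
        reference_specific=ref_specific,
        shared_genes=genes,
        shared_tes=shared_tes,
    )


def condition_analysis(
    data: SimulatedData,
    evidence: set[tuple[str, str]] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, pd.DataFrame]:
    """Per-condition correlation discovery within one species."""
    (species,) = list(data.matrices)
    matrix = data.matrices[species]
    expr = log_normalize(matrix)
    ann = data.annotation
    genes = sorted(ann.index[ann["is_krab_znf"].astype(bool)])
    tes = sorted(ann.index[ann["kind"] == "TE"])
    out = {}
    for condition in sorted(matrix.meta["condition"].unique()):
        samples = matrix.samples_where(condition=condition)
        recs = correlate_all(
            expr, genes, tes, samples, f"{species}:{condition}", config
        )
        if evidence is not None:
            sig = recs[recs["significant"]].reset_index(drop=True)
            recs = filter_by_evidence(sig, evidence)
        out[condition] = recs
    return out


def planted_benchmark(seed: int = 0):
    """Paired synthetic scenario with 30 true links: 20 conserved
    across species, 6 reference-specific only, and 4 reference-specific
    links additionally lost in the disease condition of the companion
    control/disease dataset.

    Returns (primate_data, condition_data, truth) where truth maps
    link-category names to pair sets.
    """

    def link(i, **kw):
        sign = 1 if i % 2 == 0 else -1
        return PlantedLink(
            f"ZNF{i + 1:04d}", f"TE{i + 1:04d}", 0.9, sign=sign, **kw
        )

    conserved = [link(i) for i in range(20)]
    ref_only = [link(i, species=("human",)) for i in range(20, 26)]
    lost = [link(i, species=("human",)) for i in range(26, 30)]

    primate_spec = SimSpec(
        n_genes=60,
        n_tes=90,
        n_krabznf=30,
        species=(
            SpeciesSpec("human", 1.0, 4),
            SpeciesSpec("chimp", 0.9, 3),
            SpeciesSpec("bonobo", 1.1, 3),
            SpeciesSpec("macaque", 1.4, 3),
        ),
        groups=("cortex",),
        samples_per_group=8,
        planted_links=tuple(conserved + ref_only + lost),
        seed=seed,
    )
    condition_spec = SimSpec(
        n_genes=60,
        n_tes=90,
        n_krabznf=30,
        species=(SpeciesSpec("human", 1.0, 23),),
        groups=("tcx",),
        conditions=("control", "AD"),
        samples_per_group=1,
        # the robust conserved links persist in both conditions (real
        # control/disease pairs overlap heavily); only the "lost" links
        # are restricted to the control arm
        planted_links=tuple(
            [
                PlantedLink(l.gene_id, l.te_id, l.target_r, l.sign)
                for l in conserved
            ]
            + [
                PlantedLink(
                    l.gene_id, l.te_id, l.target_r, l.sign,
                    conditions=("control",),
                )
                for l in lost
            ]
        ),
        seed=seed + 1,
    )
    truth = {
        "all": {(l.gene_id, l.te_id) for l in conserved + ref_only + lost},
        "conserved": {(l.gene_id, l.te_id) for l in conserved},
        "reference_specific": {
            (l.gene_id, l.te_id) for l in ref_only + lost
        },
        "condition_lost": {(l.gene_id, l.te_id) for l in lost},
    }
    return simulate(primate_spec), simulate(condition_spec), truth
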