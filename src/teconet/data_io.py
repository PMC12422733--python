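"""Readers and writers for the tabular formats used by the pipeline.

Everything is tab-separated UTF-8 text with ``#`` comment lines, the
dialect produced by common TE-aware quantifiers.  Feature identifiers
are case-sensitive and compared exactly, because TE subfamily names may
differ only by case or a short suffix (AluYa5 vs. AluYc).

Readers validate eagerly and never silently drop rows: malformed input
raises ``ValueError`` naming the offending feature / cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ("species", "individual", "group", "condition")
TE_CLASSES_FOR_SCALING = frozenset({"LTR", "LINE", "SINE", "SVA", "DNA"})

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """A feature x sample expression matrix with per-sample metadata.

    ``counts`` is a features-by-samples DataFrame; ``meta`` is indexed
    by sample id with columns species / individual / group / condition.
    Raw quantifier output is nonnegative integers; normalized matrices
    (``require_integer=False``) hold nonnegative reals.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    require_integer: bool = True

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "feature id")
        _check_unique(list(self.counts.columns), "sample id")
        values = self.counts.to_numpy()
        if not np.all(np.isfinite(values.astype(float))):
            raise ValueError("count matrix contains non-finite entries")
        if np.any(values.astype(float) < 0):
            r, c = np.argwhere(values.astype(float) < 0)[0]
            raise ValueError(
                f"negative count at feature {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if self.require_integer and not np.allclose(
            values.astype(float) % 1, 0
        ):
            r, c = np.argwhere(values.astype(float) % 1 != 0)[0]
            raise ValueError(
                f"non-integer count at feature {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        # keep metadata aligned to the matrix columns
        self.meta = self.meta.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        """Per-sample totals.

        Uses the ``lib_size`` metadata column (total mapped reads) when
        present, otherwise falls back to column sums of this matrix.
        """
        if "lib_size" in self.meta.columns:
            return self.meta["lib_size"].astype(float)
        return self.counts.sum(axis=0).astype(float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)],
            self.meta.loc[list(sample_ids)],
            require_integer=self.require_integer,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(feature_ids)],
            self.meta,
            require_integer=self.require_integer,
        )

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose metadata matches all given column=value pairs."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            mask &= self.meta[col] == val
        return list(self.meta.index[mask])


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a count TSV (header = sample ids, first column = feature ids)
    plus a metadata TSV keyed by sample id."""
    raw = pd.read_csv(path, index_col=0, **_READ_KW)
    _check_unique(list(raw.index), "feature id")
    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted % 1 != 0)
        if bad.any():
            feat = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-integer count at feature {feat!r}, sample {col!r}: "
                f"{raw.loc[feat, col]!r}"
            )
        if (converted < 0).any():
            feat = raw.index[(converted < 0).to_numpy().argmax()]
            raise ValueError(
                f"negative count at feature {feat!r}, sample {col!r}"
            )
        counts[col] = converted.astype(np.int64)
    meta = pd.read_csv(meta_path, index_col=0, **_READ_KW)
    if "lib_size" in meta.columns:
        meta["lib_size"] = pd.to_numeric(meta["lib_size"])
    return CountMatrix(counts, meta)


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id")
    if meta_path is not None:
        matrix.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# feature annotation

ANNOTATION_COLUMNS = (
    "kind",
    "te_class",
    "is_krab_znf",
    "length_bp",
    "age_mya",
)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a feature annotation table and normalize its dtypes.

    Columns: kind (gene|TE), te_class, is_krab_znf, length_bp, age_mya.
    age_mya may be missing (NaN); such features are excluded from
    age-classified analyses downstream with a warning.
    """
    _check_unique(list(annotation.index), "feature id")
    for col in ANNOTATION_COLUMNS:
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks column {col!r}")
    ann = annotation.copy()
    bad_kind = ~ann["kind"].isin(["gene", "TE"])
    if bad_kind.any():
        raise ValueError(
            f"invalid kind for feature {ann.index[bad_kind.to_numpy().argmax()]!r}"
        )
    if not pd.api.types.is_bool_dtype(ann["is_krab_znf"]):
        ann["is_krab_znf"] = ann["is_krab_znf"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
        if ann["is_krab_znf"].isna().any():
            raise ValueError("is_krab_znf must be boolean")
        ann["is_krab_znf"] = ann["is_krab_znf"].astype(bool)
    gene_with_class = (ann["kind"] == "gene") & (ann["te_class"] != "")
    if gene_with_class.any():
        raise ValueError(
            "gene feature carries a TE class: "
            f"{ann.index[gene_with_class.to_numpy().argmax()]!r}"
        )
    te_krab = (ann["kind"] == "TE") & ann["is_krab_znf"]
    if te_krab.any():
        raise ValueError(
            f"TE flagged as KRAB-ZNF: {ann.index[te_krab.to_numpy().argmax()]!r}"
        )
    ann["length_bp"] = pd.to_numeric(ann["length_bp"]).astype(np.int64)
    if (ann["length_bp"] < 1).any():
        raise ValueError("length_bp must be >= 1")
    ann["age_mya"] = pd.to_numeric(
        ann["age_mya"].replace("", np.nan), errors="raise"
    )
    if (ann["age_mya"].dropna() < 0).any():
        raise ValueError("age_mya must be nonnegative")
    return ann


def read_annotation(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, index_col=0, **_READ_KW)
    return validate_annotation(raw)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# ortholog map

ORTHOLOG_COLUMNS = (
    "feature_id_a",
    "feature_id_b",
    "length_a_bp",
    "length_b_bp",
    "confidence",
)


def validate_ortholog_map(orthologs: pd.DataFrame) -> pd.DataFrame:
    for col in ORTHOLOG_COLUMNS:
        if col not in orthologs.columns:
            raise ValueError(f"ortholog map lacks column {col!r}")
    om = orthologs.copy().reset_index(drop=True)
    _check_unique(list(om["feature_id_a"]), "ortholog feature (species A)")
    _check_unique(list(om["feature_id_b"]), "ortholog feature (species B)")
    for col in ("length_a_bp", "length_b_bp"):
        om[col] = pd.to_numeric(om[col]).astype(np.int64)
        if (om[col] < 1).any():
            raise ValueError(f"{col} must be >= 1")
    bad = ~om["confidence"].isin(["high", "low"])
    if bad.any():
        raise ValueError("ortholog confidence must be 'high' or 'low'")
    return om


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    return validate_ortholog_map(pd.read_csv(path, **_READ_KW))


def write_ortholog_map(orthologs: pd.DataFrame, path: str | Path) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# binding-evidence pairs (e.g. ChIP-exo KRAB-ZNF / TE subfamily hits)


def read_evidence_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column (krab_znf_id, te_id) pair list into a set."""
    raw = pd.read_csv(path, **_READ_KW)
    if raw.shape[1] < 2:
        raise ValueError("evidence pair list needs two columns (gene, TE)")
    pairs = list(zip(raw.iloc[:, 0], raw.iloc[:, 1]))
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate evidence pairs in input")
    return set(pairs)


def write_evidence_pairs(
    pairs: Iterable[tuple[str, str]], path: str | Path
) -> None:
    df = pd.DataFrame(sorted(pairs), columns=["gene_id", "te_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export

EDGE_COLUMNS = ("gene_id", "te_id", "r", "padj", "link_class", "module")


def write_edges(
    network,
    path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Export a bipartite network as an edge-list TSV and GraphML.

    The TSV has columns gene / TE / r / padj / link class / module and
    round-trips exactly through :func:`read_edges`.
    """
    rows = []
    partition = network.partition or {}
    for gene, te, attrs in network.edges():
        rows.append(
            {
                "gene_id": gene,
                "te_id": te,
                "r": attrs.get("r", np.nan),
                "padj": attrs.get("padj", np.nan),
                "link_class": attrs.get("link_class", ""),
                "module": partition.get(gene, ""),
            }
        )
    df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(_as_graphml_graph(network), graphml_path)


def _as_graphml_graph(network) -> nx.Graph:
    g = nx.Graph()
    partition = network.partition or {}
    for node in sorted(network.gene_nodes):
        g.add_node(node, kind="gene", module=str(partition.get(node, "")))
    for node in sorted(network.te_nodes):
        g.add_node(node, kind="TE", module=str(partition.get(node, "")))
    for gene, te, attrs in network.edges():
        clean = {
            k: v
            for k, v in attrs.items()
            if isinstance(v, (str, int, float, bool))
        }
        g.add_edge(gene, te, **clean)
    return g


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"edge list lacks column {col!r}")
    df["r"] = pd.to_numeric(df["r"])
    df["padj"] = pd.to_numeric(df["padj"])
    return df
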