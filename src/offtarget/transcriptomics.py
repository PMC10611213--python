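"""Tissue-expression atlases: loading, prediction refinement and clustered heatmaps.

A prediction is only worth pursuing for a tissue program if its target gene
is expressed there. Expression matrices are gene × tissue in log2(TPM+1);
the default "expressed" threshold is 1.0 (≈ TPM 1). Genes absent from an
atlas are kept and flagged ``no_data`` — absence of data is not evidence of
absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger("offtarget.transcriptomics")

#: Default log2(TPM+1) threshold above which a gene counts as expressed.
DEFAULT_EXPRESSION_THRESHOLD = 1.0

#: Per-gene percentile defining "relatively high" expression in a tissue.
HIGH_EXPRESSION_PERCENTILE = 75.0


class AtlasError(ValueError):
    pass


@dataclass
class ExpressionAtlas:
    species: str
    matrix: pd.DataFrame          # genes (index) × tissues (columns), log2(TPM+1)
    provenance: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.matrix.columns)


def load_atlas(path, species: str) -> ExpressionAtlas:
    """Load a gene × tissue TSV (first column = gene symbols, header = tissues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None and df.index.isnull().any():
        raise AtlasError("missing gene symbols in first column")
    if any(str(c).strip() == "" or str(c).startswith("Unnamed") for c in df.columns):
        raise AtlasError("empty tissue column header")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise AtlasError(f"duplicate gene rows: {dup}")
    if df.isna().any().any():
        raise AtlasError("ragged rows / missing values in atlas")
    if (df.values < 0).any():
        raise AtlasError("negative expression values")
    return ExpressionAtlas(species=species, matrix=df, provenance=str(path))


@dataclass(frozen=True)
class ExpressionAnnotation:
    drug_id: str
    target_id: str
    gene: str
    per_tissue: dict[str, float]
    max_value: float
    expressed: bool
    status: str                    # expressed | not_expressed | no_data


def filter_by_expression(predictions, atlas: ExpressionAtlas,
                         tissues: list[str],
                         theta: float = DEFAULT_EXPRESSION_THRESHOLD,
                         gene_of: dict[str, str] | None = None
                         ) -> list[ExpressionAnnotation]:
    """Annotate each prediction with expression over the requested tissues.

    A prediction is ``expressed`` iff the maximum over the requested tissues
    is ≥ theta. Genes missing from the atlas are retained with ``no_data``
    and a logged warning; conservation: the three statuses partition the
    input exactly.
    """
    if theta < 0:
        raise AtlasError("theta must be non-negative")
    unknown = [t for t in tissues if t not in atlas.matrix.columns]
    if unknown:
        raise AtlasError(f"unknown tissue labels: {unknown}")
    out = []
    for pred in predictions:
        gene = (gene_of or {}).get(pred.target_id, pred.target_id)
        if gene not in atlas.matrix.index:
            log.warning("gene %s absent from %s atlas; prediction retained as no_data",
                        gene, atlas.species)
            out.append(ExpressionAnnotation(
                drug_id=pred.drug_id, target_id=pred.target_id, gene=gene,
                per_tissue={}, max_value=float("nan"), expressed=False,
                status="no_data"))
            continue
        values = {t: float(atlas.matrix.at[gene, t]) for t in tissues}
        mx = max(values.values())
        expressed = mx >= theta
        out.append(ExpressionAnnotation(
            drug_id=pred.drug_id, target_id=pred.target_id, gene=gene,
            per_tissue=values, max_value=mx, expressed=expressed,
            status="expressed" if expressed else "not_expressed"))
    return out


def high_expression_tissues(atlas: ExpressionAtlas, gene: str,
                            percentile: float = HIGH_EXPRESSION_PERCENTILE
                            ) -> list[str]:
    """Tissues where the gene sits at or above its own cross-tissue percentile
    (report annotation of "relatively high" expression)."""
    if gene not in atlas.matrix.index:
        return []
    row = atlas.matrix.loc[gene]
    cut = np.percentile(row.values, percentile)
    return [t for t in atlas.tissues if row[t] >= cut and row[t] > 0]


# ---------------------------------------------------------------------------
# clustering

def _correlation_distances(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed distance vector, d = 1 − Pearson r across tissues.

    Constant (zero-variance) rows cannot be correlated; they are assigned the
    maximum distance 2.0 to every other row, with a log warning.
    """
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("constant expression rows assigned max distance: %s",
                    list(matrix.index[constant]))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dist[dist < 0] = 0.0
    return squareform(dist, checks=False)


def cluster_rows(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering on 1 − Pearson correlation.

    Rows are sorted lexicographically by gene symbol before clustering so the
    result is deterministic and invariant to input row order (lexicographic
    tie-breaking by construction). Returns (ordered gene list, linkage Z).
    """
    if len(matrix) < 2:
        raise AtlasError("need at least 2 rows to cluster")
    matrix = matrix.sort_index(kind="stable")
    condensed = _correlation_distances(matrix)
    Z = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(Z)
    return [matrix.index[i] for i in order], Z


def export_heatmap(matrix: pd.DataFrame, path,
                   ordering: list[str] | None = None) -> pd.DataFrame:
    """Write a clustered heatmap image and the ordered matrix as TSV.

    The TSV (row-wise z-scored values, clustered row order) is written next
    to the image so downstream checks never read pixels. Returns the ordered
    z-scored frame.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ordering is None:
        ordering, _ = cluster_rows(matrix)
    ordered = matrix.loc[ordering]
    sd = ordered.std(axis=1, ddof=0).replace(0, 1.0)
    z = ordered.sub(ordered.mean(axis=1), axis=0).div(sd, axis=0)

    path = Path(path)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(z.columns)), max(3, 0.3 * len(z))))
    im = ax.imshow(z.values, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(z.columns)), z.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(z)), z.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="row z-score of log2(TPM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    z.round(6).to_csv(path.with_suffix(".tsv"), sep="\t")
    return z


# ---------------------------------------------------------------------------
# orthologs

def load_ortholog_map(path) -> pd.DataFrame:
    """Ortholog TSV with columns human_symbol, species, species_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"human_symbol", "species", "species_symbol"}
    if not need.issubset(df.columns):
        raise AtlasError(f"ortholog map must have columns {sorted(need)}")
    dup = df.duplicated(["human_symbol", "species"])
    if dup.any():
        raise AtlasError("ortholog map is not a function: duplicate "
                         "(human_symbol, species) pairs")
    return df


def map_orthologs(genes: list[str], ortholog_map: pd.DataFrame,
                  species: str) -> tuple[list[str], list[str]]:
    """Map human symbols to a species; returns (mapped in input order, unmapped)."""
    sub = ortholog_map[ortholog_map["species"] == species]
    lookup = dict(zip(sub["human_symbol"], sub["species_symbol"]))
    mapped, unmapped = [], []
    for g in genes:
        if g in lookup:
            mapped.append(lookup[g])
        else:
            unmapped.append(g)
    return mapped, unmapped
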