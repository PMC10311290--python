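"""Normalization and the shared cross-species feature space.

Raw counts are library-size normalized (default target 10 000 counts per
cell), natural-log transformed, and z-scored per gene. The two species'
matrices are then placed on one feature axis spanning the union of both
matched gene sets: a species' own genes keep their z-scored values, and the
other species' genes are imputed as the weighted average of the within-
species genes they are matched to in the bipartite gene-match graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gene_matching import GeneMatchGraph

#: library-size normalization target (total counts per cell after scaling)
DEFAULT_NORM_SCALE = 1e4


@dataclass
class ExpressionDataset:
    """Raw scRNA-seq counts with per-cell type labels for one species."""

    species: str
    counts: np.ndarray  # cells x genes, nonnegative integers
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts")
        if len(self.cell_ids) != n_cells or len(self.cell_types) != n_cells:
            raise ValueError("cell_ids/cell_types length does not match counts")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def type_names(self) -> list[str]:
        return sorted(set(self.cell_types))

    def to_anndata(self):
        import anndata as ad
        import pandas as pd

        return ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=pd.DataFrame({"cell_type": self.cell_types},
                             index=list(self.cell_ids)),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )

    @classmethod
    def from_anndata(cls, adata, species: str,
                     cell_type_key: str = "cell_type",
                     layer: str | None = None) -> "ExpressionDataset":
        X = adata.layers[layer] if layer else adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        counts = np.asarray(X)
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("expected raw integer counts")
        return cls(species, counts.astype(np.int64),
                   list(adata.var_names), list(adata.obs_names),
                   list(adata.obs[cell_type_key].astype(str)))


@dataclass
class SharedFeatureMatrix:
    """One species' cells over the shared feature axis G_A union G_B.

    ``origin`` flags each feature as native (measured in this species) or
    imputed from the gene-match graph.
    """

    species: str
    values: np.ndarray  # cells x features
    feature_ids: list[str]
    origin: list[str]  # per-feature: native | imputed
    cell_ids: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in shared feature matrix")
        if self.values.shape[1] != len(self.feature_ids) or len(self.feature_ids) != len(self.origin):
            raise ValueError("feature metadata does not match matrix width")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def lognormalize(X: ExpressionDataset, scale: float = DEFAULT_NORM_SCALE) -> np.ndarray:
    """Library-size normalize and log-transform raw counts.

    x'_ij = ln(x_ij / sum_k x_ik * scale + 1), so every cell's normalized
    total equals ``scale`` before the log.
    """
    counts = X.counts.astype(float)
    totals = counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"zero-count cell(s): {[X.cell_ids[i] for i in zero[:5]]}")
    return np.log1p(counts / totals[:, None] * scale)


def zscore(M: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Per-column standardization to mean 0, sd 1 (population sd by default).

    Zero-variance columns are mapped to all-zeros rather than NaN.
    """
    M = np.asarray(M, dtype=float)
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=ddof)
    out = np.zeros_like(M)
    ok = sd > 0
    out[:, ok] = (M[:, ok] - mean[ok]) / sd[ok]
    return out


def _namespaced_features(g: GeneMatchGraph) -> tuple[list[str], list[str], list[str]]:
    """Ordered shared feature axis: species-A genes then species-B genes."""
    genes_a = sorted(g.genes_a)
    genes_b = sorted(g.genes_b)
    feats = [f"{g.species_a}:{x}" for x in genes_a] + [f"{g.species_b}:{x}" for x in genes_b]
    return feats, genes_a, genes_b


def _impute_block(X_native: np.ndarray, native_genes: list[str],
                  targets: list[str], edges_by_target: dict[str, list[tuple[str, float]]]
                  ) -> np.ndarray:
    """Weighted-average imputation of cross-species features from native columns."""
    col = {gid: i for i, gid in enumerate(native_genes)}
    out = np.zeros((X_native.shape[0], len(targets)))
    for j, t in enumerate(targets):
        nb = edges_by_target.get(t, [])
        wsum = sum(w for _, w in nb)
        if wsum == 0:
            warnings.warn(f"feature {t!r}: incident weights sum to 0; column set to 0",
                          stacklevel=3)
            continue
        for v, w in nb:
            out[:, j] += (w / wsum) * X_native[:, col[v]]
    return out


def impute_shared(X_A_norm: np.ndarray, genes_a_order: list[str],
                  X_B_norm: np.ndarray, genes_b_order: list[str],
                  g: GeneMatchGraph,
                  cells_a: tuple[list[str], list[str]] | None = None,
                  cells_b: tuple[list[str], list[str]] | None = None,
                  ) -> tuple[SharedFeatureMatrix, SharedFeatureMatrix]:
    """Construct both species' shared feature matrices over G_A union G_B.

    ``X_A_norm``/``X_B_norm`` are the z-scored normalized matrices whose
    columns (``genes_a_order``/``genes_b_order``) must cover the graph's
    matched gene sets G_A/G_B. For species A, features from G_A are native
    columns; each feature u from G_B is imputed as
    sum_v e_uv X^A_v / sum_v e_uv over the species-A genes v matched to u.
    Symmetrically for B. Both outputs share one feature ordering.
    """
    if len(g) == 0:
        raise ValueError("empty gene-match graph")
    feats, genes_a, genes_b = _namespaced_features(g)
    missing_a = set(genes_a) - set(genes_a_order)
    missing_b = set(genes_b) - set(genes_b_order)
    if missing_a or missing_b:
        raise ValueError(f"normalized matrices do not cover matched genes: "
                         f"{sorted(missing_a)[:3]} / {sorted(missing_b)[:3]}")

    col_a = {gid: i for i, gid in enumerate(genes_a_order)}
    col_b = {gid: i for i, gid in enumerate(genes_b_order)}
    XA = np.asarray(X_A_norm, dtype=float)[:, [col_a[x] for x in genes_a]]
    XB = np.asarray(X_B_norm, dtype=float)[:, [col_b[x] for x in genes_b]]

    to_b: dict[str, list[tuple[str, float]]] = {}  # target gene in G_B -> [(gene in G_A, w)]
    to_a: dict[str, list[tuple[str, float]]] = {}
    for e in g.edges:
        to_b.setdefault(e.gene_b, []).append((e.gene_a, e.weight))
        to_a.setdefault(e.gene_a, []).append((e.gene_b, e.weight))

    imputed_for_a = _impute_block(XA, genes_a, genes_b, to_b)
    imputed_for_b = _impute_block(XB, genes_b, genes_a, to_a)

    values_a = np.hstack([XA, imputed_for_a])
    values_b = np.hstack([imputed_for_b, XB])
    origin_a = ["native"] * len(genes_a) + ["imputed"] * len(genes_b)
    origin_b = ["imputed"] * len(genes_a) + ["native"] * len(genes_b)

    ids_a, types_a = cells_a if cells_a else ([], [])
    ids_b, types_b = cells_b if cells_b else ([], [])
    return (
        SharedFeatureMatrix(g.species_a, values_a, feats, origin_a, ids_a, types_a),
        SharedFeatureMatrix(g.species_b, values_b, feats, origin_b, ids_b, types_b),
    )


def build_shared_space(X_A: ExpressionDataset, X_B: ExpressionDataset,
                       g: GeneMatchGraph,
                       scale: float = DEFAULT_NORM_SCALE,
                       ) -> tuple[SharedFeatureMatrix, SharedFeatureMatrix]:
    """Full normalization + imputation path from raw counts to shared features.

    Restricts each species to its matched genes, log-normalizes, z-scores,
    then imputes the cross-species block.
    """
    genes_a = sorted(g.genes_a)
    genes_b = sorted(g.genes_b)
    idx_a = [list(X_A.gene_ids).index(x) for x in genes_a]
    idx_b = [list(X_B.gene_ids).index(x) for x in genes_b]
    ZA = zscore(lognormalize(X_A, scale)[:, idx_a])
    ZB = zscore(lognormalize(X_B, scale)[:, idx_b])
    return impute_shared(ZA, genes_a, ZB, genes_b, g,
                         cells_a=(list(X_A.cell_ids), list(X_A.cell_types)),
                         cells_b=(list(X_B.cell_ids), list(X_B.cell_types)))
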