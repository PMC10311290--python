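"""Cross-species gene matching from protein embeddings or BLAST tables.

Genes are matched between two species by building a weighted bipartite
graph. In embedding mode, per-gene protein-language-model vectors are
compared by cosine distance; pairs closer than a threshold ``tau`` become
candidate edges, each gene keeps only its ``k_max`` closest partners, and
edges are finally filtered to those touching at least one highly variable
gene. In BLAST mode the same top-k and HVG filters are applied to pairs
passing an E-value cutoff, scored by (average) bitscore; a one-to-one mode
keeps only reciprocal best hits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cosine-distance threshold for candidate gene matches
DEFAULT_TAU = 0.005
#: per-gene cap on retained partners
DEFAULT_K_MAX = 5
#: number of highly variable genes selected per species
DEFAULT_N_HVG = 2000
#: residue-level embeddings are truncated to this many positions before pooling
MAX_RESIDUES = 2500
#: E-value cutoff for BLAST candidate matches
DEFAULT_EVALUE_MAX = 1e-6


@dataclass
class ProteinEmbeddingSet:
    """Per-gene protein embeddings for one species.

    ``vectors`` maps gene id to either a single vector of length ``dim`` or,
    when a gene has several protein isoforms, a 2-D array of shape
    (n_isoforms, dim).
    """

    species: str
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = set()
        normalized = {}
        for gid, v in self.vectors.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.ndim != 2 or arr.shape[0] < 1:
                raise ValueError(f"embedding for {gid!r} must be 1-D or 2-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite embedding entries for gene {gid!r}")
            normalized[gid] = arr
            dims.add(arr.shape[1])
        self.vectors = normalized
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self._dim = dims.pop() if dims else 0

    @property
    def dim(self) -> int:
        return self._dim

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class ResidueEmbeddingMatrix:
    """Per-residue embedding matrix (L x D) for one protein."""

    gene_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("empty sequence")


@dataclass(frozen=True)
class GeneMatch:
    """One weighted edge of the bipartite gene-match graph.

    ``distance`` is the cosine distance in embedding mode, or the (average)
    bitscore in BLAST mode where larger means closer. ``weight`` is in [0, 1].
    """

    gene_a: str
    gene_b: str
    distance: float
    weight: float
    source: str  # embedding | blast_mm | blast_11


@dataclass
class GeneMatchGraph:
    """Weighted bipartite graph of gene matches between species A and B."""

    edges: list[GeneMatch]
    species_a: str = "A"
    species_b: str = "B"
    params: dict = field(default_factory=dict)

    @property
    def genes_a(self) -> set[str]:
        return {e.gene_a for e in self.edges}

    @property
    def genes_b(self) -> set[str]:
        return {e.gene_b for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.gene_a, e.gene_b) for e in self.edges}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_a, e.gene_b, e.distance, e.weight, e.source) for e in self.edges],
            columns=["gene_a", "gene_b", "distance", "weight", "source"],
        )


@dataclass(frozen=True)
class BlastHit:
    """One directional BLAST hit (query -> subject)."""

    query: str
    subject: str
    evalue: float
    bitscore: float


def pool_residue_embedding(m: ResidueEmbeddingMatrix, max_len: int = MAX_RESIDUES) -> np.ndarray:
    """Mean-pool a residue-level embedding matrix into one protein vector.

    Proteins longer than ``max_len`` residues are truncated to their first
    ``max_len`` positions before pooling.
    """
    mat = m.matrix
    if mat.shape[0] < 1:
        raise ValueError("empty sequence")
    return mat[: min(mat.shape[0], max_len)].mean(axis=0)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 - u.v / (|u||v|), in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-norm embedding")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def edge_weight(distance: float, tau: float = DEFAULT_TAU) -> float:
    """Map a cosine distance to an edge weight: 1 - d/tau, clamped to [0, 1].

    Weight is 1 at distance 0 and 0 at the threshold and beyond.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    return float(np.clip(1.0 - distance / tau, 0.0, 1.0))


def _pairwise_cosine(A: ProteinEmbeddingSet, B: ProteinEmbeddingSet,
                     isoform_agg: str = "min") -> tuple[np.ndarray, list[str], list[str]]:
    """All-pairs gene-gene cosine distances, reducing over isoform pairs.

    Returns (|G_A| x |G_B| matrix, gene ids A, gene ids B), gene ids sorted.
    """
    from scipy.spatial.distance import cdist

    if A.dim != B.dim:
        raise ValueError(f"embedding dimension mismatch: {A.dim} vs {B.dim}")
    ids_a, ids_b = A.gene_ids, B.gene_ids
    rows_a, idx_a = [], []
    for i, g in enumerate(ids_a):
        arr = A.vectors[g]
        rows_a.append(arr)
        idx_a.extend([i] * arr.shape[0])
    rows_b, idx_b = [], []
    for j, g in enumerate(ids_b):
        arr = B.vectors[g]
        rows_b.append(arr)
        idx_b.extend([j] * arr.shape[0])
    Ma, Mb = np.vstack(rows_a), np.vstack(rows_b)
    if np.any(np.linalg.norm(Ma, axis=1) == 0) or np.any(np.linalg.norm(Mb, axis=1) == 0):
        raise ValueError("zero-norm embedding")
    D_iso = cdist(Ma, Mb, metric="cosine")
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    red = np.minimum if isoform_agg == "min" else np.add
    if isoform_agg not in ("min", "mean"):
        raise ValueError(f"unknown isoform_agg {isoform_agg!r}")
    init = np.inf if isoform_agg == "min" else 0.0
    D = np.full((len(ids_a), len(ids_b)), init)
    counts = np.zeros_like(D)
    # group-reduce isoform rows/cols onto genes
    for r in range(D_iso.shape[0]):
        i = idx_a[r]
        row = D_iso[r]
        acc = np.full(len(ids_b), init)
        cnt = np.zeros(len(ids_b))
        np.minimum.at(acc, idx_b, row) if isoform_agg == "min" else np.add.at(acc, idx_b, row)
        np.add.at(cnt, idx_b, 1.0)
        D[i] = red(D[i], acc)
        counts[i] += cnt
    if isoform_agg == "mean":
        D = D / counts
    return D, ids_a, ids_b


def _directional_topk(D: np.ndarray, ids_a: list[str], ids_b: list[str],
                      tau: float, k_max: int,
                      higher_is_closer: bool = False) -> tuple[set, set]:
    """Per-gene top-k candidate selection in both directions.

    Returns (selected-by-A pairs, selected-by-B pairs) as (i, j) index sets.
    Candidates are entries with distance <= tau (or score threshold already
    applied when ``higher_is_closer``: non-candidates are NaN). Ties at the
    k-th position are broken lexicographically by partner gene id.
    """
    if higher_is_closer:
        valid = np.isfinite(D)
        order_key = -D
    else:
        valid = D <= tau
        order_key = D

    sel_a: set[tuple[int, int]] = set()
    for i in range(D.shape[0]):
        js = np.where(valid[i])[0]
        if js.size == 0:
            continue
        ranked = sorted(js, key=lambda j: (order_key[i, j], ids_b[j]))
        sel_a.update((i, j) for j in ranked[:k_max])
    sel_b: set[tuple[int, int]] = set()
    for j in range(D.shape[1]):
        is_ = np.where(valid[:, j])[0]
        if is_.size == 0:
            continue
        ranked = sorted(is_, key=lambda i: (order_key[i, j], ids_a[i]))
        sel_b.update((i, j) for i in ranked[:k_max])
    return sel_a, sel_b


def build_match_graph(A: ProteinEmbeddingSet, B: ProteinEmbeddingSet,
                      tau: float = DEFAULT_TAU, k_max: int = DEFAULT_K_MAX,
                      topk_rule: str = "union",
                      isoform_agg: str = "min") -> GeneMatchGraph:
    """Build the bipartite match graph from two protein-embedding sets.

    An edge (u, v) is a candidate iff cosine_distance(u, v) <= ``tau``; each
    gene's candidates are cut to its ``k_max`` closest partners, and an edge
    is retained iff it survives the cut for at least one endpoint
    (``topk_rule="union"``, default) or for both (``"intersection"``).
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty embedding set")
    if tau <= 0 or k_max < 1:
        raise ValueError("tau must be > 0 and k_max >= 1")
    D, ids_a, ids_b = _pairwise_cosine(A, B, isoform_agg=isoform_agg)
    sel_a, sel_b = _directional_topk(D, ids_a, ids_b, tau, k_max)
    if topk_rule == "union":
        retained = sel_a | sel_b
    elif topk_rule == "intersection":
        retained = sel_a & sel_b
    else:
        raise ValueError(f"unknown topk_rule {topk_rule!r}")
    edges = [
        GeneMatch(ids_a[i], ids_b[j], float(D[i, j]),
                  edge_weight(float(D[i, j]), tau), "embedding")
        for i, j in sorted(retained, key=lambda ij: (ids_a[ij[0]], ids_b[ij[1]]))
    ]
    return GeneMatchGraph(edges, A.species, B.species,
                          params={"tau": tau, "k_max": k_max, "topk_rule": topk_rule,
                                  "mode": "embedding"})


def select_hvg(X, n_hvg: int = DEFAULT_N_HVG) -> set[str]:
    """Select the top highly variable genes of one dataset.

    ``X`` is an :class:`~crosstype.feature_space.ExpressionDataset`. Selection
    runs scanpy's seurat-flavor dispersion ranking on the log-normalized
    counts. If fewer than ``n_hvg`` genes qualify, all qualifying genes are
    returned with a warning.
    """
    import anndata as ad
    import scanpy as sc

    from .feature_space import lognormalize

    counts = np.asarray(X.counts)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    logX = lognormalize(X)
    adata = ad.AnnData(X=logX, var=pd.DataFrame(index=list(X.gene_ids)))
    n_usable = int((counts.sum(axis=0) > 0).sum())
    n_top = min(n_hvg, n_usable)
    if n_top < n_hvg:
        warnings.warn(
            f"only {n_usable} expressed genes available; returning {n_top} < {n_hvg} HVGs",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    return set(adata.var_names[adata.var["highly_variable"]])


def hvg_filter(g: GeneMatchGraph, hvg_a: set[str], hvg_b: set[str]) -> GeneMatchGraph:
    """Keep edges where at least one endpoint is highly variable in its species."""
    edges = [e for e in g.edges if e.gene_a in hvg_a or e.gene_b in hvg_b]
    return GeneMatchGraph(edges, g.species_a, g.species_b, params=dict(g.params))


def blast_to_matches(hits: list[BlastHit], species_a: str, species_b: str,
                     genes_a: set[str], genes_b: set[str],
                     evalue_max: float = DEFAULT_EVALUE_MAX,
                     mode: str = "many_to_many",
                     k_max: int = DEFAULT_K_MAX,
                     hvg_a: set[str] | None = None,
                     hvg_b: set[str] | None = None) -> GeneMatchGraph:
    """Build a match graph from directional BLAST hits.

    Hits are directional: a pair (a, b) qualifies if at least one direction
    has E-value < ``evalue_max``; its score is the bitscore of the qualifying
    direction, or the mean of the two bitscores when both qualify. In
    ``many_to_many`` mode the per-gene top-``k_max`` cut (higher bitscore =
    closer) and the HVG filter follow. In ``one_to_one`` mode each gene keeps
    its single best-scoring partner, non-reciprocal pairs are discarded, then
    the HVG filter applies. Hits naming genes absent from the expression data
    are dropped (logged).
    """
    best: dict[tuple[str, str], list[float]] = {}
    n_dropped = 0
    for h in hits:
        if h.query in genes_a and h.subject in genes_b:
            a, b, direction = h.query, h.subject, 0
        elif h.query in genes_b and h.subject in genes_a:
            a, b, direction = h.subject, h.query, 1
        else:
            n_dropped += 1
            continue
        if h.evalue >= evalue_max:
            continue
        slot = best.setdefault((a, b), [np.nan, np.nan])
        # keep the best bitscore per direction if a pair appears repeatedly
        if np.isnan(slot[direction]) or h.bitscore > slot[direction]:
            slot[direction] = h.bitscore
    if n_dropped:
        logger.info("dropped %d BLAST hits naming genes absent from the expression data",
                    n_dropped)

    scores = {pair: float(np.nanmean(s)) for pair, s in best.items()}
    if not scores:
        return GeneMatchGraph([], species_a, species_b,
                              params={"mode": f"blast_{mode}", "evalue_max": evalue_max})

    source = "blast_mm" if mode == "many_to_many" else "blast_11"
    if mode == "many_to_many":
        ids_a = sorted({a for a, _ in scores})
        ids_b = sorted({b for _, b in scores})
        pos_a = {g: i for i, g in enumerate(ids_a)}
        pos_b = {g: j for j, g in enumerate(ids_b)}
        D = np.full((len(ids_a), len(ids_b)), np.nan)
        for (a, b), s in scores.items():
            D[pos_a[a], pos_b[b]] = s
        sel_a, sel_b = _directional_topk(D, ids_a, ids_b, np.inf, k_max,
                                         higher_is_closer=True)
        retained = {(ids_a[i], ids_b[j]) for i, j in sel_a | sel_b}
    elif mode == "one_to_one":
        best_of_a: dict[str, str] = {}
        best_of_b: dict[str, str] = {}
        for (a, b), s in sorted(scores.items()):
            if a not in best_of_a or s > scores[(a, best_of_a[a])]:
                best_of_a[a] = b
        for (a, b), s in sorted(scores.items()):
            if b not in best_of_b or s > scores[(best_of_b[b], b)]:
                best_of_b[b] = a
        retained = {(a, b) for a, b in scores
                    if best_of_a.get(a) == b and best_of_b.get(b) == a}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    max_score = max(scores[p] for p in retained) if retained else 1.0
    edges = [GeneMatch(a, b, scores[(a, b)], scores[(a, b)] / max_score, source)
             for a, b in sorted(retained)]
    g = GeneMatchGraph(edges, species_a, species_b,
                       params={"mode": f"blast_{mode}", "evalue_max": evalue_max,
                               "k_max": k_max})
    if hvg_a is not None and hvg_b is not None:
        g = hvg_filter(g, hvg_a, hvg_b)
    return g


def compare_match_ranks(blast_11: GeneMatchGraph, A: ProteinEmbeddingSet,
                        B: ProteinEmbeddingSet,
                        isoform_agg: str = "min") -> pd.DataFrame:
    """Rank each one-to-one BLAST partner by embedding distance.

    For every 1:1 BLAST match (a, b), reports the 1-based rank of b among all
    species-B genes ordered by cosine distance to a's embedding. Genes without
    an embedding get a NaN rank.
    """
    D, ids_a, ids_b = _pairwise_cosine(A, B, isoform_agg=isoform_agg)
    pos_a = {g: i for i, g in enumerate(ids_a)}
    pos_b = {g: j for j, g in enumerate(ids_b)}
    rows = []
    for e in sorted(blast_11.edges, key=lambda e: (e.gene_a, e.gene_b)):
        if e.gene_a not in pos_a or e.gene_b not in pos_b:
            rows.append((e.gene_a, e.gene_b, np.nan))
            continue
        drow = D[pos_a[e.gene_a]]
        order = sorted(range(len(ids_b)), key=lambda j: (drow[j], ids_b[j]))
        rank = order.index(pos_b[e.gene_b]) + 1
        rows.append((e.gene_a, e.gene_b, float(rank)))
    return pd.DataFrame(rows, columns=["gene_a", "blast_match", "embed_rank_of_blast_match"])


def expression_correlation_report(X_A, X_B, pairs: list[tuple[str, str]],
                                  harmonized_types: list[str]) -> pd.DataFrame:
    """Pearson correlation of per-type mean expression for gene pairs.

    For each (gene_a, gene_b) pair, computes the mean log-normalized
    expression per harmonized cell type in each species and the Pearson r
    between the two per-type profiles. Constant profiles yield NaN.
    """
    from scipy.stats import pearsonr

    from .feature_space import lognormalize

    def type_means(X, gene):
        logX = lognormalize(X)
        col = logX[:, list(X.gene_ids).index(gene)]
        ct = np.asarray(X.cell_types)
        return np.array([col[ct == t].mean() if (ct == t).any() else np.nan
                         for t in harmonized_types])

    rows = []
    for ga, gb in pairs:
        pa, pb = type_means(X_A, ga), type_means(X_B, gb)
        ok = np.isfinite(pa) & np.isfinite(pb)
        if ok.sum() < 2 or pa[ok].std() == 0 or pb[ok].std() == 0:
            r = np.nan
        else:
            r = float(pearsonr(pa[ok], pb[ok]).statistic)
        rows.append((ga, gb, r))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pearson_r"])
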