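"""Paired-species synthetic data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
homologous genes have nearby protein embeddings (a shared latent vector
plus independent per-species noise), matched cell types share per-gene mean
expression profiles up to a divergence factor, and counts follow a
negative-binomial model with log-normal type/gene means and optional
dropout. A BLAST-style hit table is emitted alongside, with bitscores
decreasing in embedding distance, so all three gene-matching modes can be
exercised against the same known homology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_space import ExpressionDataset
from .gene_matching import (BlastHit, GeneMatch, GeneMatchGraph,
                            ProteinEmbeddingSet, ResidueEmbeddingMatrix,
                            cosine_distance)
from .transfer import TypeCorrespondence


@dataclass
class SimulationConfig:
    """Study conditions for one paired-species synthetic dataset.

    Defaults give five well-separated matched cell types with a species
    proportion imbalance (60 vs 45 cells per type), 150 one-to-one homology
    latents plus 40 species-specific genes per species, and embedding noise
    small relative to inter-gene spacing so true homologs sit well inside
    the default cosine-distance threshold.
    """

    n_types: int = 5
    cells_per_type_a: int = 60
    cells_per_type_b: int = 45
    n_genes_shared: int = 150
    n_genes_specific_a: int = 40
    n_genes_specific_b: int = 40
    embedding_dim: int = 32
    embedding_noise_sd: float = 0.02
    mean_log_sd: float = 1.0        # sd of log-normal per-type per-gene means
    nb_dispersion: float = 2.0      # NB size parameter; var = mu + mu^2 / size
    dropout_rate: float = 0.1
    frac_one_to_one: float = 1.0
    frac_one_to_two: float = 0.0    # duplications: latent -> two species-B genes
    type_divergence: float = 0.05   # sd of per-species log-scale mean perturbation
    n_specific_types_a: int = 0     # cell types with no counterpart
    n_specific_types_b: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_types, self.cells_per_type_a, self.cells_per_type_b,
               self.n_genes_shared, self.embedding_dim) < 1:
            raise ValueError("counts parameters must be positive")
        if self.frac_one_to_one + self.frac_one_to_two > 1 + 1e-12:
            raise ValueError("homology fractions must sum to at most 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class SimulatedPair:
    """Everything one pipeline run needs, with full ground truth."""

    expr_a: ExpressionDataset
    expr_b: ExpressionDataset
    emb_a: ProteinEmbeddingSet
    emb_b: ProteinEmbeddingSet
    true_graph: GeneMatchGraph
    correspondence: TypeCorrespondence
    blast_hits: list[BlastHit]


def _nb_counts(mu: np.ndarray, size: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with mean mu and dispersion (size) parameter."""
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_pair(cfg: SimulationConfig) -> SimulatedPair:
    """Generate a matched pair of species datasets with known homology."""
    rng = np.random.default_rng(cfg.seed)

    # --- homology structure: latents -> genes per species
    n_lat = cfg.n_genes_shared
    n_dup = int(round(cfg.frac_one_to_two * n_lat))
    genes_a = [f"gA{i:04d}" for i in range(n_lat)]
    genes_b, latent_of_b = [], []
    true_pairs: list[tuple[str, str]] = []
    bi = 0
    for lat in range(n_lat):
        copies = 2 if lat < n_dup else 1
        for _ in range(copies):
            gb = f"gB{bi:04d}"
            genes_b.append(gb)
            latent_of_b.append(lat)
            true_pairs.append((genes_a[lat], gb))
            bi += 1
    spec_a = [f"sA{i:04d}" for i in range(cfg.n_genes_specific_a)]
    spec_b = [f"sB{i:04d}" for i in range(cfg.n_genes_specific_b)]
    all_a = genes_a + spec_a
    all_b = genes_b + spec_b

    # --- protein embeddings: shared latent + per-species noise
    D = cfg.embedding_dim
    latents = rng.normal(size=(n_lat, D))
    vec_a = {g: latents[i] + rng.normal(scale=cfg.embedding_noise_sd, size=D)
             for i, g in enumerate(genes_a)}
    vec_a.update({g: rng.normal(size=D) for g in spec_a})
    vec_b = {g: latents[latent_of_b[j]] + rng.normal(scale=cfg.embedding_noise_sd, size=D)
             for j, g in enumerate(genes_b)}
    vec_b.update({g: rng.normal(size=D) for g in spec_b})
    emb_a = ProteinEmbeddingSet("A", vec_a)
    emb_b = ProteinEmbeddingSet("B", vec_b)

    # --- cell types and mean expression
    shared_types = cfg.n_types
    types_a = [f"T{i}" for i in range(shared_types)] + \
              [f"Ta{i}" for i in range(cfg.n_specific_types_a)]
    types_b = [f"U{i}" for i in range(shared_types)] + \
              [f"Ub{i}" for i in range(cfg.n_specific_types_b)]
    corr = TypeCorrespondence(
        pairs=[(f"T{i}", f"U{i}") for i in range(shared_types)],
        species_specific_a={f"Ta{i}" for i in range(cfg.n_specific_types_a)},
        species_specific_b={f"Ub{i}" for i in range(cfg.n_specific_types_b)},
    )

    # latent per-type per-gene means shared by matched types
    mu_lat = np.exp(rng.normal(scale=cfg.mean_log_sd, size=(shared_types, n_lat)))
    mu_spec_a = np.exp(rng.normal(scale=cfg.mean_log_sd,
                                  size=(len(types_a), len(spec_a))))
    mu_spec_b = np.exp(rng.normal(scale=cfg.mean_log_sd,
                                  size=(len(types_b), len(spec_b))))

    def species_means(n_types_total, latent_cols, n_shared_rows):
        """Per-type means for one species: shared latents diverged, plus extras."""
        mu = np.exp(rng.normal(scale=cfg.mean_log_sd,
                               size=(n_types_total, len(latent_cols))))
        div = np.exp(rng.normal(scale=cfg.type_divergence,
                                size=(n_shared_rows, len(latent_cols))))
        mu[:n_shared_rows] = mu_lat[:, latent_cols] * div
        return mu

    mu_a = species_means(len(types_a), np.arange(n_lat), shared_types)
    mu_b = species_means(len(types_b), np.array(latent_of_b), shared_types)
    mu_a = np.hstack([mu_a, mu_spec_a])
    mu_b = np.hstack([mu_b, mu_spec_b])

    def make_counts(types, cells_per_type, mu, prefix):
        rows, labels, ids = [], [], []
        for t_idx, t in enumerate(types):
            m = np.tile(mu[t_idx], (cells_per_type, 1))
            c = _nb_counts(m, cfg.nb_dispersion, rng)
            if cfg.dropout_rate > 0:
                keep = rng.random(c.shape) >= cfg.dropout_rate
                c = c * keep
            rows.append(c)
            labels.extend([t] * cells_per_type)
            ids.extend([f"{prefix}{t_idx}_{i}" for i in range(cells_per_type)])
        counts = np.vstack(rows)
        empty = counts.sum(axis=1) == 0
        counts[empty, 0] = 1  # guarantee positive library size
        return counts, ids, labels

    counts_a, cells_a, labels_a = make_counts(types_a, cfg.cells_per_type_a, mu_a, "cA")
    counts_b, cells_b, labels_b = make_counts(types_b, cfg.cells_per_type_b, mu_b, "cB")
    expr_a = ExpressionDataset("A", counts_a, all_a, cells_a, labels_a)
    expr_b = ExpressionDataset("B", counts_b, all_b, cells_b, labels_b)

    # --- true graph and BLAST-style hit table
    edges = []
    hits: list[BlastHit] = []
    for ga, gb in true_pairs:
        d = cosine_distance(vec_a[ga], vec_b[gb])
        edges.append(GeneMatch(ga, gb, d, 1.0, "truth"))
        bit = max(50.0, 500.0 * (1.0 - d))
        jitter = rng.uniform(0, 2.0)
        hits.append(BlastHit(ga, gb, 1e-50, round(bit + jitter, 1)))
        hits.append(BlastHit(gb, ga, 1e-50, round(bit - jitter, 1)))
    # decoy hits above the E-value cutoff exercise the threshold filter
    n_decoys = min(20, n_lat)
    for i in range(n_decoys):
        ga = genes_a[i]
        gb = genes_b[(i + 7) % len(genes_b)]
        if (ga, gb) not in set(true_pairs):
            hits.append(BlastHit(ga, gb, 1.0, 30.0))
    true_graph = GeneMatchGraph(edges, "A", "B", params={"mode": "truth"})

    return SimulatedPair(expr_a, expr_b, emb_a, emb_b, true_graph, corr, hits)


def simulate_residue_embeddings(gene_lengths: dict[str, int], dim: int = 8,
                                seed: int = 0) -> dict[str, ResidueEmbeddingMatrix]:
    """Per-residue embedding matrices with controllable lengths.

    Lengths above the pooling truncation limit are allowed so the truncation
    path can be exercised.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for gid, L in gene_lengths.items():
        if L < 1:
            raise ValueError(f"length for {gid!r} must be >= 1")
        out[gid] = ResidueEmbeddingMatrix(gid, rng.normal(size=(L, dim)))
    return out
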