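"""End-to-end orchestration: gene matching -> shared space -> training -> evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .feature_space import (DEFAULT_NORM_SCALE, ExpressionDataset,
                            SharedFeatureMatrix, build_shared_space)
from .gene_matching import (DEFAULT_EVALUE_MAX, DEFAULT_K_MAX, DEFAULT_N_HVG,
                            DEFAULT_TAU, BlastHit, GeneMatchGraph,
                            ProteinEmbeddingSet, blast_to_matches,
                            build_match_graph, hvg_filter, select_hvg)
from .model import ModelConfig, TrainedModel, train
from .transfer import MatchResult, TypeCorrespondence, evaluate_transfer

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one full run; defaults follow the method's published values."""

    mode: str = "embedding"           # embedding | blast_mm | blast_11
    tau: float = DEFAULT_TAU
    k_max: int = DEFAULT_K_MAX
    n_hvg: int = DEFAULT_N_HVG
    topk_rule: str = "union"
    isoform_agg: str = "min"
    evalue_max: float = DEFAULT_EVALUE_MAX
    norm_scale: float = DEFAULT_NORM_SCALE
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("embedding", "blast_mm", "blast_11"):
            raise ValueError(f"unknown matching mode {self.mode!r}")
        self.model.seed = self.seed


def match_genes(cfg: PipelineConfig,
                expr_a: ExpressionDataset, expr_b: ExpressionDataset,
                emb_a: ProteinEmbeddingSet | None = None,
                emb_b: ProteinEmbeddingSet | None = None,
                blast_hits: list[BlastHit] | None = None) -> GeneMatchGraph:
    """Matching stage: candidate edges, top-k cut, HVG filter.

    Embedding mode drops genes without an embedding or without expression
    data (counts logged); BLAST mode drops hits naming unknown genes.
    """
    hvg_a = select_hvg(expr_a, cfg.n_hvg)
    hvg_b = select_hvg(expr_b, cfg.n_hvg)
    if cfg.mode == "embedding":
        if emb_a is None or emb_b is None:
            raise ValueError("embedding mode requires both embedding sets")
        usable_a = {g: v for g, v in emb_a.vectors.items() if g in set(expr_a.gene_ids)}
        usable_b = {g: v for g, v in emb_b.vectors.items() if g in set(expr_b.gene_ids)}
        if not usable_a or not usable_b:
            raise ValueError("no overlap between embedding and expression gene ids")
        logger.info("genes with embeddings: %d/%d (A), %d/%d (B)",
                    len(usable_a), expr_a.n_genes, len(usable_b), expr_b.n_genes)
        g = build_match_graph(ProteinEmbeddingSet(emb_a.species, usable_a),
                              ProteinEmbeddingSet(emb_b.species, usable_b),
                              cfg.tau, cfg.k_max, cfg.topk_rule, cfg.isoform_agg)
        logger.info("candidate edges after top-%d cut: %d", cfg.k_max, len(g))
        g = hvg_filter(g, hvg_a, hvg_b)
    else:
        if blast_hits is None:
            raise ValueError("BLAST mode requires a hit table")
        mode = "many_to_many" if cfg.mode == "blast_mm" else "one_to_one"
        g = blast_to_matches(blast_hits, expr_a.species, expr_b.species,
                             set(expr_a.gene_ids), set(expr_b.gene_ids),
                             cfg.evalue_max, mode, cfg.k_max, hvg_a, hvg_b)
    g.species_a, g.species_b = expr_a.species, expr_b.species
    logger.info("retained edges after HVG filter: %d (|G_A|=%d, |G_B|=%d)",
                len(g), len(g.genes_a), len(g.genes_b))
    return g


def run_pipeline(expr_a: ExpressionDataset, expr_b: ExpressionDataset,
                 corr: TypeCorrespondence,
                 cfg: PipelineConfig | None = None,
                 emb_a: ProteinEmbeddingSet | None = None,
                 emb_b: ProteinEmbeddingSet | None = None,
                 blast_hits: list[BlastHit] | None = None,
                 graph: GeneMatchGraph | None = None,
                 ) -> tuple[MatchResult, TrainedModel, GeneMatchGraph]:
    """Run matching, shared-space construction, training, and evaluation."""
    cfg = cfg or PipelineConfig()
    if graph is None:
        graph = match_genes(cfg, expr_a, expr_b, emb_a, emb_b, blast_hits)
    if len(graph) == 0:
        raise ValueError("gene-match graph is empty; nothing to train on")
    shared_a, shared_b = build_shared_space(expr_a, expr_b, graph, cfg.norm_scale)
    model = train(shared_a.values, shared_b.values,
                  list(expr_a.cell_types), list(expr_b.cell_types),
                  cfg.model, feature_ids=shared_a.feature_ids)
    result = evaluate_transfer(model, shared_a, shared_b, corr)
    return result, model, graph


def build_shared(expr_a: ExpressionDataset, expr_b: ExpressionDataset,
                 graph: GeneMatchGraph, cfg: PipelineConfig | None = None,
                 ) -> tuple[SharedFeatureMatrix, SharedFeatureMatrix]:
    cfg = cfg or PipelineConfig()
    return build_shared_space(expr_a, expr_b, graph, cfg.norm_scale)
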