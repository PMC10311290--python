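"""Gene matching: pooling, distances, graph construction, filters, BLAST modes."""

import math

import numpy as np
import pytest

import crosstype as ct
from crosstype.gene_matching import _pairwise_cosine

from conftest import random_embedding_sets


# --------------------------------------------------------------------------- pooling

class TestResiduePooling:
    def test_single_row_is_identity(self, rng):
        row = rng.normal(size=8)
        m = ct.ResidueEmbeddingMatrix("g", row[None, :])
        np.testing.assert_allclose(ct.pool_residue_embedding(m), row)

    def test_mean_of_symmetric_rows(self):
        m = ct.ResidueEmbeddingMatrix("g", np.vstack([np.zeros(4), np.full(4, 2.0)]))
        np.testing.assert_allclose(ct.pool_residue_embedding(m), np.ones(4))

    def test_long_proteins_truncated_to_2500_positions(self, rng):
        mat = rng.normal(size=(3000, 5))
        pooled = ct.pool_residue_embedding(ct.ResidueEmbeddingMatrix("g", mat))
        np.testing.assert_allclose(pooled, mat[:2500].mean(axis=0))
        assert not np.allclose(pooled, mat.mean(axis=0))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty sequence"):
            ct.ResidueEmbeddingMatrix("g", np.empty((0, 4)))


# --------------------------------------------------------------------------- cosine distance

class TestCosineDistance:
    @pytest.mark.parametrize("u, v, expected", [
        (np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), 0.0),
        (np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0),
        (np.array([1.0, 0.0]), np.array([1.0, 1.0]), 1.0 - 1.0 / math.sqrt(2)),
        (np.array([1.0, 0.0]), np.array([-1.0, 0.0]), 2.0),
    ])
    def test_known_values(self, u, v, expected):
        assert ct.cosine_distance(u, v) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            ct.cosine_distance(np.zeros(3), np.ones(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ct.cosine_distance(np.ones(3), np.ones(4))


# --------------------------------------------------------------------------- edge weight

class TestEdgeWeight:
    @pytest.mark.parametrize("d, tau, expected", [
        (0.0, 0.005, 1.0),
        (0.005, 0.005, 0.0),
        (0.0025, 0.005, 0.5),
        (0.9, 0.005, 0.0),  # beyond threshold -> 0
    ])
    def test_linear_interpolation(self, d, tau, expected):
        assert ct.edge_weight(d, tau) == pytest.approx(expected)

    def test_monotone_decreasing_in_distance(self):
        tau = 0.01
        ds = np.linspace(0, 2 * tau, 50)
        ws = [ct.edge_weight(d, tau) for d in ds]
        assert all(w1 >= w2 for w1, w2 in zip(ws, ws[1:]))
        assert all(0 <= w <= 1 for w in ws)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            ct.edge_weight(0.001, 0.0)


# --------------------------------------------------------------------------- graph construction

def brute_force_graph(A, B, tau, k_max, rule="union"):
    """Independent all-pairs oracle: threshold, per-gene sort, top-k, union/intersection."""
    def cos(u, v):
        return 1 - sum(x * y for x, y in zip(u, v)) / (
            math.sqrt(sum(x * x for x in u)) * math.sqrt(sum(y * y for y in v)))

    d = {}
    for ga in A.gene_ids:
        for gb in B.gene_ids:
            dd = min(cos(u, v) for u in A.vectors[ga] for v in B.vectors[gb])
            if dd <= tau:
                d[(ga, gb)] = dd
    sel_a = set()
    for ga in A.gene_ids:
        cands = sorted((b for (a, b) in d if a == ga), key=lambda b: (d[(ga, b)], b))
        sel_a.update((ga, b) for b in cands[:k_max])
    sel_b = set()
    for gb in B.gene_ids:
        cands = sorted((a for (a, b) in d if b == gb), key=lambda a: (d[(a, gb)], a))
        sel_b.update((a, gb) for a in cands[:k_max])
    return sel_a | sel_b if rule == "union" else sel_a & sel_b


class TestBuildMatchGraph:
    def test_no_candidates_gives_empty_graph(self, rng):
        A, B = random_embedding_sets(rng)
        g = ct.build_match_graph(A, B, tau=1e-9, k_max=5)
        assert len(g) == 0

    def test_top_k_cap_for_crowded_gene(self, rng):
        # hub has 8 candidates under tau, but each candidate has 5 dedicated
        # nearer partners of its own, so only the hub's own top-5 survive
        center = rng.normal(size=16)
        vecs_b = {f"b{j}": center + rng.normal(scale=0.05, size=16) for j in range(8)}
        vecs_a = {"hub": center + rng.normal(scale=0.1, size=16)}
        for j, (gb, v) in enumerate(vecs_b.items()):
            for m in range(5):
                vecs_a[f"near{j}_{m}"] = v + rng.normal(scale=1e-4, size=16)
        A = ct.ProteinEmbeddingSet("A", vecs_a)
        B = ct.ProteinEmbeddingSet("B", vecs_b)
        g = ct.build_match_graph(A, B, tau=0.5, k_max=5)
        assert sum(p[0] == "hub" for p in g.pairs()) == 5

    @pytest.mark.parametrize("rule", ["union", "intersection"])
    @pytest.mark.parametrize("tau", [2.0, 1.0, 0.9])
    def test_matches_brute_force_oracle(self, rng, rule, tau):
        A, B = random_embedding_sets(rng, n_a=10, n_b=10)
        g = ct.build_match_graph(A, B, tau=tau, k_max=3, topk_rule=rule)
        assert g.pairs() == brute_force_graph(A, B, tau, 3, rule)

    def test_degree_cap_on_self_selected_edges(self, rng):
        A, B = random_embedding_sets(rng, n_a=12, n_b=12)
        g = ct.build_match_graph(A, B, tau=2.0, k_max=4)
        D, ids_a, ids_b = _pairwise_cosine(A, B)
        for ga in g.genes_a:
            i = ids_a.index(ga)
            own = sorted(range(len(ids_b)), key=lambda j: (D[i, j], ids_b[j]))[:4]
            own_pairs = {(ga, ids_b[j]) for j in own}
            incident = {p for p in g.pairs() if p[0] == ga}
            # edges beyond the gene's own selection must come from the partner side
            assert len(incident & own_pairs) <= 4

    def test_dimension_mismatch_rejected(self, rng):
        A = ct.ProteinEmbeddingSet("A", {"a": rng.normal(size=4)})
        B = ct.ProteinEmbeddingSet("B", {"b": rng.normal(size=5)})
        with pytest.raises(ValueError, match="dimension"):
            ct.build_match_graph(A, B, tau=1.0)

    def test_isoform_minimum_aggregation(self):
        # gene a has two isoforms; one is identical to b's vector
        iso = np.vstack([[1.0, 0.0], [0.0, 1.0]])
        A = ct.ProteinEmbeddingSet("A", {"a": iso})
        B = ct.ProteinEmbeddingSet("B", {"b": np.array([1.0, 0.0])})
        g = ct.build_match_graph(A, B, tau=0.5, k_max=1, isoform_agg="min")
        assert g.edges[0].distance == pytest.approx(0.0)

    def test_synthetic_homolog_recovery_rank_one(self):
        sim = ct.simulate_pair(ct.SimulationConfig(seed=7, n_genes_shared=60,
                                                   n_genes_specific_a=10,
                                                   n_genes_specific_b=10))
        g = ct.build_match_graph(sim.emb_a, sim.emb_b)
        D, ids_a, ids_b = _pairwise_cosine(sim.emb_a, sim.emb_b)
        true = dict(sim.true_graph.pairs())
        for ga, gb in true.items():
            i = ids_a.index(ga)
            assert ids_b[int(np.argmin(D[i]))] == gb  # true homolog is rank 1
        assert sim.true_graph.pairs() <= g.pairs()


# --------------------------------------------------------------------------- HVG

def seurat_dispersion_oracle(logX, n_top):
    """Independent normalized-dispersion ranking (20 equal-width mean bins)."""
    import pandas as pd

    Xlin = np.expm1(logX)
    mean = Xlin.mean(axis=0)
    var = Xlin.var(axis=0, ddof=1)
    disp = np.full_like(mean, np.nan)
    ok = mean > 0
    disp[ok] = var[ok] / mean[ok]
    disp[disp == 0] = np.nan
    df = pd.DataFrame({"m": np.log1p(mean), "d": np.log(disp)})
    df["bin"] = pd.cut(df["m"], bins=20)
    grp = df.groupby("bin", observed=True)["d"]
    norm = ((df["d"] - grp.transform("mean")) / grp.transform("std")).fillna(0).values
    return set(np.argsort(-norm, kind="stable")[:n_top])


class TestSelectHVG:
    def test_returns_requested_count_on_large_dataset(self, rng):
        lam = rng.lognormal(0, 1, size=5000)
        counts = rng.poisson(lam[None, :], size=(500, 5000))
        X = ct.ExpressionDataset("A", counts, [f"g{i}" for i in range(5000)],
                                 [f"c{i}" for i in range(500)], ["t"] * 500)
        assert len(ct.select_hvg(X, 2000)) == 2000

    def test_clamps_with_warning_when_few_genes(self, rng):
        counts = rng.poisson(2.0, size=(50, 100))
        X = ct.ExpressionDataset("A", counts, [f"g{i}" for i in range(100)],
                                 [f"c{i}" for i in range(50)], ["t"] * 50)
        with pytest.warns(UserWarning, match="expressed genes"):
            hv = ct.select_hvg(X, 2000)
        assert len(hv) == 100

    def test_all_zero_matrix_rejected(self):
        X = ct.ExpressionDataset("A", np.zeros((5, 4), dtype=int),
                                 list("abcd"), [f"c{i}" for i in range(5)], ["t"] * 5)
        with pytest.raises(ValueError):
            ct.select_hvg(X, 10)

    def test_matches_dispersion_ranking_oracle(self, rng):
        # background genes span a broad mean range; ten genes get
        # mean-spread, variance-inflated bimodal expression
        lam = np.exp(rng.uniform(np.log(0.5), np.log(20), size=100))
        counts = rng.poisson(lam[None, :], size=(200, 100))
        lam_special = np.exp(np.linspace(np.log(1), np.log(16), 10))
        for g in range(10):
            col = np.zeros(200, dtype=int)
            col[150:] = rng.poisson(4 * lam_special[g], size=50)
            counts[:, g] = col
        genes = [f"g{i}" for i in range(100)]
        X = ct.ExpressionDataset("A", counts, genes,
                                 [f"c{i}" for i in range(200)], ["t"] * 200)
        got = ct.select_hvg(X, 10)
        expected = {genes[i] for i in
                    seurat_dispersion_oracle(ct.lognormalize(X), 10)}
        assert got == expected
        # most of the constructed high-dispersion genes are recovered
        assert len(got & set(genes[:10])) >= 8


class TestHVGFilter:
    def test_empty_hvg_sets_empty_graph(self, rng):
        A, B = random_embedding_sets(rng)
        g = ct.build_match_graph(A, B, tau=2.0, k_max=3)
        assert len(ct.hvg_filter(g, set(), set())) == 0

    def test_single_variable_endpoint_retained(self):
        e = ct.GeneMatch("a1", "b1", 0.0, 1.0, "embedding")
        g = ct.GeneMatchGraph([e])
        assert len(ct.hvg_filter(g, {"a1"}, set())) == 1
        assert len(ct.hvg_filter(g, set(), {"b1"})) == 1
        assert len(ct.hvg_filter(g, set(), set())) == 0

    def test_matches_predicate_oracle(self, rng):
        A, B = random_embedding_sets(rng, n_a=15, n_b=15)
        g = ct.build_match_graph(A, B, tau=2.0, k_max=4)
        hvg_a = {f"a{i}" for i in rng.choice(15, 5, replace=False)}
        hvg_b = {f"b{i}" for i in rng.choice(15, 5, replace=False)}
        got = ct.hvg_filter(g, hvg_a, hvg_b).pairs()
        expected = {(a, b) for a, b in g.pairs() if a in hvg_a or b in hvg_b}
        assert got == expected


# --------------------------------------------------------------------------- BLAST

class TestBlastMatching:
    def _graph(self, hits, mode="many_to_many", **kw):
        genes_a = {h.query for h in hits if h.query.startswith("a")} | \
                  {h.subject for h in hits if h.subject.startswith("a")}
        genes_b = {h.query for h in hits if h.query.startswith("b")} | \
                  {h.subject for h in hits if h.subject.startswith("b")}
        return ct.blast_to_matches(list(hits), "A", "B", genes_a, genes_b,
                                   mode=mode, **kw)

    def test_reciprocal_pair_scores_average_bitscore(self):
        hits = [ct.BlastHit("a1", "b1", 1e-20, 100.0),
                ct.BlastHit("b1", "a1", 1e-20, 200.0)]
        g = self._graph(hits)
        assert len(g) == 1
        assert g.edges[0].distance == pytest.approx(150.0)

    def test_single_direction_uses_its_bitscore(self):
        hits = [ct.BlastHit("a1", "b1", 1e-20, 80.0),
                ct.BlastHit("b1", "a1", 1e-3, 999.0)]  # fails E-value cutoff
        g = self._graph(hits)
        assert g.edges[0].distance == pytest.approx(80.0)

    def test_evalue_threshold_excludes_pairs(self):
        hits = [ct.BlastHit("a1", "b1", 1e-3, 500.0)]
        assert len(self._graph(hits)) == 0

    def test_reciprocal_best_hit_oracle(self):
        # A1<->B1 best both ways; A2's best is B1 but B1's best is A1
        hits = [ct.BlastHit("a1", "b1", 1e-20, 300.0),
                ct.BlastHit("b1", "a1", 1e-20, 300.0),
                ct.BlastHit("a2", "b1", 1e-20, 200.0),
                ct.BlastHit("b1", "a2", 1e-20, 200.0),
                ct.BlastHit("a2", "b2", 1e-20, 100.0),
                ct.BlastHit("b2", "a2", 1e-20, 100.0)]
        g = self._graph(hits, mode="one_to_one")
        expected = rbh_oracle(hits, 1e-6)
        assert g.pairs() == expected == {("a1", "b1")}

    def test_one_to_one_is_partial_matching_and_species_symmetric(self, rng):
        hits = []
        for i in range(6):
            for j in range(6):
                s = float(rng.integers(50, 500))
                hits.append(ct.BlastHit(f"a{i}", f"b{j}", 1e-20, s))
                hits.append(ct.BlastHit(f"b{j}", f"a{i}", 1e-20, s + 1.0))
        g = self._graph(hits, mode="one_to_one")
        degrees_a = [p[0] for p in g.pairs()]
        degrees_b = [p[1] for p in g.pairs()]
        assert len(degrees_a) == len(set(degrees_a))
        assert len(degrees_b) == len(set(degrees_b))
        # swapping the species yields the same pair set
        swapped = [ct.BlastHit(h.query, h.subject, h.evalue, h.bitscore) for h in hits]
        g2 = ct.blast_to_matches(swapped, "B", "A",
                                 {f"b{j}" for j in range(6)},
                                 {f"a{i}" for i in range(6)}, mode="one_to_one")
        assert {(b, a) for a, b in g.pairs()} == g2.pairs()

    def test_synthetic_rbh_recovers_true_homologs(self, sim_default):
        sim = sim_default
        g = ct.blast_to_matches(sim.blast_hits, "A", "B",
                                set(sim.expr_a.gene_ids), set(sim.expr_b.gene_ids),
                                mode="one_to_one")
        assert g.pairs() == sim.true_graph.pairs()

    def test_unknown_genes_dropped(self):
        hits = [ct.BlastHit("zz", "b1", 1e-20, 100.0)]
        g = ct.blast_to_matches(hits, "A", "B", {"a1"}, {"b1"})
        assert len(g) == 0


def rbh_oracle(hits, evalue_max):
    """Exhaustive reciprocal-best-hit scan."""
    score = {}
    for h in hits:
        if h.evalue < evalue_max:
            pair = (h.query, h.subject) if h.query.startswith("a") else (h.subject, h.query)
            score.setdefault(pair, []).append(h.bitscore)
    s = {p: sum(v) / len(v) for p, v in score.items()}
    out = set()
    for a, b in s:
        best_a = max((p for p in s if p[0] == a), key=lambda p: s[p])
        best_b = max((p for p in s if p[1] == b), key=lambda p: s[p])
        if best_a == (a, b) == best_b:
            out.add((a, b))
    return out


# --------------------------------------------------------------------------- reporting

class TestCompareMatchRanks:
    def _sets(self):
        A = ct.ProteinEmbeddingSet("A", {"a1": np.array([1.0, 0.0, 0.0])})
        # b1 nearest, b2 second, b3 third
        B = ct.ProteinEmbeddingSet("B", {
            "b1": np.array([1.0, 0.05, 0.0]),
            "b2": np.array([1.0, 0.4, 0.0]),
            "b3": np.array([1.0, 1.0, 0.0]),
            "b4": np.array([0.0, 1.0, 0.0]),
            "b5": np.array([-1.0, 0.0, 0.0])})
        return A, B

    def test_nearest_partner_has_rank_one(self):
        A, B = self._sets()
        g = ct.GeneMatchGraph([ct.GeneMatch("a1", "b1", 0.0, 1.0, "blast_11")])
        tab = ct.compare_match_ranks(g, A, B)
        assert tab["embed_rank_of_blast_match"].iloc[0] == 1

    def test_third_nearest_partner_has_rank_three(self):
        A, B = self._sets()
        g = ct.GeneMatchGraph([ct.GeneMatch("a1", "b3", 0.0, 1.0, "blast_11")])
        tab = ct.compare_match_ranks(g, A, B)
        assert tab["embed_rank_of_blast_match"].iloc[0] == 3

    def test_missing_embedding_gives_nan(self):
        A, B = self._sets()
        g = ct.GeneMatchGraph([ct.GeneMatch("a_missing", "b1", 0.0, 1.0, "blast_11")])
        tab = ct.compare_match_ranks(g, A, B)
        assert np.isnan(tab["embed_rank_of_blast_match"].iloc[0])


class TestExpressionCorrelation:
    # a filler gene keeps per-cell library sizes varying so normalization
    # does not flatten the gene of interest
    def _datasets(self, col_a, col_b, filler_a, filler_b, types):
        n = len(types)
        Xa = ct.ExpressionDataset("A", np.column_stack([col_a, filler_a]),
                                  ["ga", "fa"], [f"c{i}" for i in range(n)], types)
        Xb = ct.ExpressionDataset("B", np.column_stack([col_b, filler_b]),
                                  ["gb", "fb"], [f"d{i}" for i in range(n)], types)
        return Xa, Xb

    def test_identical_profiles_give_r_one(self):
        col = np.array([1, 1, 5, 5, 20, 20])
        filler = np.full(6, 10)
        types = ["t1", "t1", "t2", "t2", "t3", "t3"]
        Xa, Xb = self._datasets(col, col, filler, filler, types)
        tab = ct.expression_correlation_report(Xa, Xb, [("ga", "gb")],
                                               ["t1", "t2", "t3"])
        assert tab["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self, rng):
        types = [f"t{i}" for i in range(6) for _ in range(4)]
        ca, cb = rng.integers(1, 50, size=24), rng.integers(1, 50, size=24)
        fa, fb = rng.integers(1, 50, size=24), rng.integers(1, 50, size=24)
        Xa, Xb = self._datasets(ca, cb, fa, fb, types)
        vocab = [f"t{i}" for i in range(6)]
        tab = ct.expression_correlation_report(Xa, Xb, [("ga", "gb")], vocab)
        la, lb = ct.lognormalize(Xa)[:, 0], ct.lognormalize(Xb)[:, 0]
        ta = np.array([la[np.array(types) == t].mean() for t in vocab])
        tb = np.array([lb[np.array(types) == t].mean() for t in vocab])
        expected = (((ta - ta.mean()) * (tb - tb.mean())).sum()
                    / np.sqrt(((ta - ta.mean()) ** 2).sum() * ((tb - tb.mean()) ** 2).sum()))
        assert tab["pearson_r"].iloc[0] == pytest.approx(expected)

    def test_constant_profile_gives_nan(self):
        col = np.full(4, 3)
        filler = np.full(4, 7)
        types = ["t1", "t1", "t2", "t2"]
        Xa, Xb = self._datasets(col, col, filler, filler, types)
        tab = ct.expression_correlation_report(Xa, Xb, [("ga", "gb")], ["t1", "t2"])
        assert np.isnan(tab["pearson_r"].iloc[0])
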