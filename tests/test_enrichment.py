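"""GSEA running-sum vs exhaustive oracle, permutation p, ORA exactness, GMT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from lofproxy import enrichment as en
from lofproxy.dataio import ExpressionMatrix
from lofproxy.enrichment import (
    EnrichmentResult,
    RankedList,
    gsea_collection,
    gsea_es,
    gsea_pvalue,
    ora_test,
    rank_by_log2fc,
    read_gmt,
    write_gmt,
)
from lofproxy.stratify import assign_strata, rank_focal


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def es_oracle(genes, scores, members, w):
    """Exhaustive prefix-sum enrichment score: plain-loop reference."""
    hits = [g in members for g in genes]
    n, k = len(genes), sum(hits)
    assert 0 < k < n
    wsum = sum(abs(s) ** w for s, h in zip(scores, hits) if h)
    rs = 0.0
    best, best_abs = 0.0, -1.0
    for s, h in zip(scores, hits):
        if h:
            rs += (abs(s) ** w / wsum) if wsum > 0 else 1.0 / k
        else:
            rs -= 1.0 / (n - k)
        if abs(rs) > best_abs:
            best_abs, best = abs(rs), rs
    return best


def hypergeom_upper_oracle(k, N, K, n):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def ranked_from(scores_desc, prefix="g"):
    return RankedList(
        genes=tuple(f"{prefix}{i}" for i in range(len(scores_desc))),
        scores=np.asarray(scores_desc, dtype=float),
    )


# --------------------------------------------------------------------------
# gsea_es
# --------------------------------------------------------------------------

class TestGseaES:
    def test_top_gene_only_es_one(self):
        rl = ranked_from(np.linspace(10, 1, 10))
        es, edge = gsea_es(rl, ["g0"])
        assert es == pytest.approx(1.0)
        assert edge == ["g0"]

    def test_bottom_gene_only_negative(self):
        rl = ranked_from(np.linspace(10, 1, 10))
        es, edge = gsea_es(rl, ["g9"])
        assert es < 0
        assert edge == ["g9"]

    def test_toy_unweighted_matches_oracle(self):
        scores = np.linspace(5, -4, 10)
        rl = ranked_from(scores)
        members = {"g1", "g4", "g8"}
        es, _ = gsea_es(rl, members, weight_exponent=0)
        assert es == pytest.approx(es_oracle(rl.genes, scores, members, 0), abs=1e-12)

    @given(
        n=hst.integers(min_value=3, max_value=50),
        w=hst.sampled_from([0.0, 1.0]),
        data=hst.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_random_instances(self, n, w, data):
        seed = data.draw(hst.integers(min_value=0, max_value=10**6))
        r = np.random.default_rng(seed)
        scores = np.sort(r.normal(size=n))[::-1]
        k = data.draw(hst.integers(min_value=1, max_value=n - 1))
        members = set(r.choice([f"g{i}" for i in range(n)], size=k, replace=False))
        rl = ranked_from(scores)
        es, _ = gsea_es(rl, members, weight_exponent=w)
        assert es == pytest.approx(es_oracle(rl.genes, scores, members, w), abs=1e-9)
        assert abs(es) <= 1.0

    def test_complement_negates_unweighted(self, rng):
        scores = np.sort(rng.normal(size=30))[::-1]
        rl = ranked_from(scores)
        members = {f"g{i}" for i in rng.choice(30, size=8, replace=False)}
        complement = set(rl.genes) - members
        es_a, _ = gsea_es(rl, members, weight_exponent=0)
        es_b, _ = gsea_es(rl, complement, weight_exponent=0)
        assert es_a == pytest.approx(-es_b, abs=1e-12)

    def test_empty_intersection_errors(self):
        rl = ranked_from([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="no overlap"):
            gsea_es(rl, ["nope"])

    def test_whole_universe_errors(self):
        rl = ranked_from([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="universe"):
            gsea_es(rl, ["g0", "g1", "g2"])

    def test_leading_edge_subset_of_set(self, rng):
        scores = np.sort(rng.normal(size=40))[::-1]
        rl = ranked_from(scores)
        members = {f"g{i}" for i in rng.choice(40, size=10, replace=False)}
        _, edge = gsea_es(rl, members)
        assert set(edge) <= members


# --------------------------------------------------------------------------
# gsea_pvalue / gsea_collection
# --------------------------------------------------------------------------

class TestGseaPvalue:
    def test_plus_one_estimator_floor(self, monkeypatch):
        # all 100 null draws same-sign and below the observed ES -> p = 1/101
        scores = np.r_[np.full(5, 50.0), np.linspace(1, 0, 195)]
        rl = ranked_from(scores)
        monkeypatch.setattr(
            en, "_null_es", lambda *a, **k: np.linspace(0.01, 0.5, 100)
        )
        res = gsea_pvalue(rl, [f"g{i}" for i in range(5)], n_perm=100, seed=0)
        assert res.p == pytest.approx(1 / 101)
        assert res.es > 0.99

    def test_plus_one_estimator_unmocked_small_p(self):
        scores = np.r_[np.full(5, 50.0), np.linspace(1, 0, 195)]
        rl = ranked_from(scores)
        res = gsea_pvalue(rl, [f"g{i}" for i in range(5)], n_perm=100, seed=0)
        assert 1 / 101 <= res.p < 0.02  # beats every same-sign null draw

    def test_degenerate_null_warns(self, monkeypatch):
        rl = ranked_from(np.linspace(5, 1, 20))
        monkeypatch.setattr(
            en, "_null_es", lambda *a, **k: np.full(100, 0.5)
        )
        with pytest.warns(UserWarning, match="degenerate"):
            res = gsea_pvalue(rl, ["g19"], n_perm=100, seed=0)
        assert res.p == pytest.approx(1 / 101)

    def test_nperm_floor(self):
        rl = ranked_from(np.linspace(5, 1, 20))
        with pytest.raises(ValueError, match="n_perm"):
            gsea_pvalue(rl, ["g0"], n_perm=10)

    def test_random_set_on_shuffled_ranking_p_uniform(self):
        # Monte-Carlo: null p-values across seeds should look uniform
        ps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            scores = np.sort(r.normal(size=120))[::-1]
            rl = ranked_from(scores)
            members = r.choice(120, size=12, replace=False)
            res = gsea_pvalue(
                rl, [f"g{i}" for i in members], n_perm=200, seed=seed + 1000
            )
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_collection_by_adjusted_and_size_filter(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(
            rank_focal(panel, truth.focal_gene), fraction=0.25, focal=truth.focal_gene
        )
        ranked = rank_by_log2fc(panel, strata)
        sets = {m: truth.module_genes(m) for m in truth.coupling_signs}
        sets["tiny"] = truth.module_genes("mod_ribo")[:2]  # filtered out
        results = gsea_collection(ranked, sets, n_perm=200, seed=1)
        names = {r.name for r in results}
        assert "tiny" not in names
        assert {"mod_ribo", "mod_oxphos"} <= names
        ps = [r.p for r in results]
        adj = [r.p_adj for r in results]
        order = np.argsort(ps)
        assert np.all(np.diff(np.array(adj)[order]) >= -1e-12)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_planted_module_recovered(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(
            rank_focal(panel, truth.focal_gene), fraction=0.25, focal=truth.focal_gene
        )
        ranked = rank_by_log2fc(panel, strata)
        res = gsea_pvalue(
            ranked, truth.module_genes("mod_ribo"), n_perm=200, seed=4, name="mod_ribo"
        )
        assert res.nes > 0 and res.p < 0.05

    def test_determinism(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(rank_focal(panel, truth.focal_gene), fraction=0.25)
        ranked = rank_by_log2fc(panel, strata)
        a = gsea_pvalue(ranked, truth.module_genes("mod_ribo"), n_perm=150, seed=7)
        b = gsea_pvalue(ranked, truth.module_genes("mod_ribo"), n_perm=150, seed=7)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)


# --------------------------------------------------------------------------
# rank_by_log2fc
# --------------------------------------------------------------------------

class TestRanking:
    def test_identical_gene_scores_zero(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(rank_focal(panel, truth.focal_gene), fraction=0.25)
        values = panel.values.copy()
        values["flat"] = 4.2
        m2 = ExpressionMatrix(values, panel.sample_meta)
        ranked = rank_by_log2fc(m2, strata)
        score = dict(zip(ranked.genes, ranked.scores))["flat"]
        assert score == pytest.approx(0.0)

    def test_negative_module_scores_positive(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(rank_focal(panel, truth.focal_gene), fraction=0.25)
        ranked = rank_by_log2fc(panel, strata)
        scores = dict(zip(ranked.genes, ranked.scores))
        module_scores = [scores[g] for g in truth.module_genes("mod_ribo")]
        assert np.mean(module_scores) > 0
        assert np.mean(np.array(module_scores) > 0) > 0.9

    def test_swapping_labels_negates_scores(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(rank_focal(panel, truth.focal_gene), fraction=0.25)
        fwd = en.rank_by_contrast(panel, strata.low_samples, strata.high_samples)
        rev = en.rank_by_contrast(panel, strata.high_samples, strata.low_samples)
        f = dict(zip(fwd.genes, fwd.scores))
        r = dict(zip(rev.genes, rev.scores))
        assert all(f[g] == pytest.approx(-r[g], abs=1e-12) for g in f)

    def test_empty_stratum_errors(self, demo_panel):
        panel, _ = demo_panel
        with pytest.raises(ValueError):
            en.rank_by_contrast(panel, [], panel.samples[:3])

    def test_scores_non_increasing(self, demo_panel):
        panel, truth = demo_panel
        strata = assign_strata(rank_focal(panel, truth.focal_gene), fraction=0.25)
        ranked = rank_by_log2fc(panel, strata)
        assert np.all(np.diff(ranked.scores) <= 1e-12)


# --------------------------------------------------------------------------
# ORA
# --------------------------------------------------------------------------

class TestORA:
    def test_worked_case(self):
        universe = [f"g{i}" for i in range(20)]
        the_set = universe[:5]
        hits = universe[:4] + [universe[10]]  # k=4 of K=5, n=5
        res = ora_test(hits, universe, {"s": the_set})[0]
        assert (res.k, res.K, res.n, res.N) == (4, 5, 5, 20)
        assert res.p == pytest.approx(76 / 15504, rel=1e-12)

    def test_hits_equal_universe_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_test(universe, universe, {"s": universe[:4]})[0]
        assert res.k == res.K == 4
        assert res.p == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_test(universe[5:7], universe, {"s": universe[:3]})[0]
        assert res.k == 0
        assert res.p == pytest.approx(1.0)

    def test_hits_outside_universe_error(self):
        with pytest.raises(ValueError, match="ghost"):
            ora_test(["ghost"], ["a", "b"], {"s": ["a"]})

    @given(
        N=hst.integers(min_value=2, max_value=25),
        data=hst.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration(self, N, data):
        K = data.draw(hst.integers(min_value=1, max_value=N))
        n = data.draw(hst.integers(min_value=0, max_value=N))
        universe = [f"g{i}" for i in range(N)]
        the_set = universe[:K]
        k_max = min(n, K)
        k = data.draw(hst.integers(min_value=max(0, n + K - N), max_value=k_max))
        hits = the_set[:k] + universe[K:][: n - k]
        res = ora_test(hits, universe, {"s": the_set})[0]
        assert res.k == k
        assert res.p == pytest.approx(hypergeom_upper_oracle(k, N, K, n), rel=1e-9)

    def test_enrichment_ratio(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_test(universe[:4] + [universe[10]], universe, {"s": universe[:5]})[0]
        assert res.ratio == pytest.approx(4 * 20 / (5 * 5))


# --------------------------------------------------------------------------
# GMT
# --------------------------------------------------------------------------

class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {"alpha": ["a", "b", "c"], "beta": ["d", "e"]}
        path = tmp_path / "c.gmt"
        write_gmt(sets, path, descriptions={"alpha": "first"})
        back = read_gmt(path)
        assert back == sets

    def test_malformed_line_errors(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(path)

    def test_duplicate_set_name_errors(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("s\tna\ta\tb\ns\tna\tc\td\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)
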