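import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn import ArgumentError
from chromdyn import synthetic_data as sd
from chromdyn.coverage_peaks import CountMatrix
from chromdyn.expression_integration import (GeneSet, QCThresholds,
                                             accessibility_by_geneset_ks,
                                             find_markers, gsea, gsea_es,
                                             qc_filter, read_gene_sets_gmt,
                                             wilcoxon_rank_sum,
                                             write_gene_sets_gmt)


def _qc_matrix(specs):
    cm, truth = sd.simulate_cell_matrix(specs=pd.DataFrame(specs), seed=1)
    mito = [g for g in cm.counts.index if g.startswith("mt-")]
    return cm, mito


class TestQcFilter:
    def test_boundary_barcodes(self):
        cm, mito = _qc_matrix({
            "n_genes": [499, 500, 8000, 8001, 600, 600],
            "mito_pct": [0.0, 10.0, 0.0, 0.0, 10.01, 9.99],
        })
        retained, report = qc_filter(cm, mito)
        names = list(cm.counts.columns)
        # strict removal: <500, >8000, >10% fail; 500/10.0/8000 pass
        assert names[0] not in retained
        assert names[1] in retained
        assert names[2] in retained
        assert names[3] not in retained
        assert names[4] not in retained
        assert names[5] in retained

    def test_idempotent(self):
        cm, mito = _qc_matrix({"n_genes": [600, 450, 900],
                               "mito_pct": [1.0, 1.0, 12.0]})
        retained, _ = qc_filter(cm, mito)
        sub = CountMatrix(cm.counts[retained])
        retained2, _ = qc_filter(sub, mito)
        assert retained2 == retained

    def test_monotone_as_thresholds_tighten(self):
        cm, mito = _qc_matrix({"n_genes": [600, 700, 900, 2000],
                               "mito_pct": [1.0, 5.0, 8.0, 9.5]})
        prev = None
        for thr in (QCThresholds(500, 8000, 10.0), QCThresholds(650, 1500, 6.0)):
            retained, _ = qc_filter(cm, mito, thr)
            if prev is not None:
                assert set(retained) <= set(prev)
            prev = retained

    def test_missing_mito_genes_rejected(self):
        cm, _ = _qc_matrix({"n_genes": [600], "mito_pct": [1.0]})
        with pytest.raises(ArgumentError, match="absent"):
            qc_filter(cm, ["mt-999"])


class TestWilcoxon:
    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(20):
            x = rng.integers(0, 8, size=12).astype(float)
            y = rng.integers(0, 8, size=15).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            _, p = wilcoxon_rank_sum(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=True)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_close_to_exact_enumeration_small_n(self, rng):
        # The normal approximation should track the exact permutation null
        # within its known error at n1=n2=8 for mid-range p-values.
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p = wilcoxon_rank_sum(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            assert abs(p - ref.pvalue) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ArgumentError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestFindMarkers:
    def test_planted_markers_recovered(self):
        cm, labels, planted = sd.simulate_marker_matrix(
            n_clusters=2, cells_per_cluster=50, seed=3)
        found = find_markers(cm, labels)
        for c, gs in planted.items():
            assert gs <= found[c].genes

    def test_low_detection_gene_excluded(self):
        # a gene expressed in <25% of in-cluster cells never reaches the test
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(1.0, size=(20, 40)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"c{i}" for i in range(40)])
        counts.loc["g0"] = 0
        in_cluster = [f"c{i}" for i in range(20)]
        counts.loc["g0", in_cluster[:4]] = 100  # 20% of cluster A
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=counts.columns)
        found = find_markers(CountMatrix(counts), labels)
        assert "g0" not in found.get("A", GeneSet("empty", {"_"})).genes

    def test_missing_cluster_cells_rejected(self):
        cm, labels, _ = sd.simulate_marker_matrix(seed=1)
        bad = labels.copy()
        bad.iloc[:] = "1"
        bad.iloc[0] = "2"
        with pytest.raises(ArgumentError):
            find_markers(cm, bad)


class TestGsea:
    def _ranked(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                             "score": scores})

    def test_top_k_set_attains_maximum_running_sum(self):
        ranked = self._ranked()
        members = set(ranked["gene"].head(10))
        es, running = gsea_es(ranked, members)
        # brute-force: ES of the top-k set is the running sum right after
        # the last hit, and no larger ES is attainable for that k
        w = np.abs(ranked["score"].values)
        brute = (w[:10] / w[:10].sum()).sum()  # all hits first, no misses yet
        assert es == pytest.approx(brute)
        assert es == running[9]

    def test_reversing_ranking_negates_es(self):
        ranked = self._ranked()
        members = set(ranked["gene"].head(10))
        es_fwd, _ = gsea_es(ranked, members)
        reversed_rank = ranked.iloc[::-1].reset_index(drop=True)
        es_rev, _ = gsea_es(reversed_rank, members)
        assert es_rev == pytest.approx(-es_fwd, rel=1e-6)

    def test_es_matches_brute_force_running_sum(self, rng):
        ranked = self._ranked(n=1000, seed=1)
        genes = ranked["gene"].values
        w = np.abs(ranked["score"].values)
        for _ in range(10):
            members = set(rng.choice(genes, size=30, replace=False))
            es, _ = gsea_es(ranked, members)
            run, best = 0.0, 0.0
            hit_w = sum(w[i] for i, g in enumerate(genes) if g in members)
            for i, g in enumerate(genes):
                if g in members:
                    run += w[i] / hit_w
                else:
                    run -= 1.0 / (len(genes) - 30)
                if abs(run) > abs(best):
                    best = run
            assert es == pytest.approx(best, abs=1e-12)

    def test_planted_set_strongly_enriched(self):
        ranked, members = sd.simulate_ranked_genes(n_genes=800, set_size=40,
                                                   shift=2.0, seed=5)
        res = gsea(ranked, GeneSet("planted", members), n_perm=2000, seed=6)
        assert res.nes > 1.5
        assert res.fdr < 0.05
        assert np.sign(res.nes) == np.sign(res.es)

    def test_deterministic_given_seed(self):
        ranked, members = sd.simulate_ranked_genes(seed=7)
        a = gsea(ranked, GeneSet("s", members), n_perm=500, seed=8)
        b = gsea(ranked, GeneSet("s", members), n_perm=500, seed=8)
        assert (a.es, a.nes, a.fdr) == (b.es, b.nes, b.fdr)

    def test_insufficient_overlap_rejected(self):
        ranked = self._ranked()
        with pytest.raises(ArgumentError):
            gsea(ranked, GeneSet("tiny", {"g0", "g1", "zzz"}), n_perm=10)

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"s1": GeneSet("s1", {"a", "b", "c"}),
                "s2": GeneSet("s2", {"x", "y", "z", "w", "v"})}
        path = tmp_path / "sets.gmt"
        write_gene_sets_gmt(sets, path)
        got = read_gene_sets_gmt(path)
        assert {k: v.genes for k, v in got.items()} == \
               {k: v.genes for k, v in sets.items()}


class TestKsComparison:
    def _run(self, scores_a, scores_b):
        scores = pd.Series(
            list(scores_a) + list(scores_b),
            index=[f"a{i}" for i in range(len(scores_a))]
            + [f"b{i}" for i in range(len(scores_b))])
        assignment = {f"a{i}": {"gA"} for i in range(len(scores_a))}
        assignment.update({f"b{i}": {"gB"} for i in range(len(scores_b))})
        return accessibility_by_geneset_ks(
            scores, assignment, GeneSet("A", {"gA"}), GeneSet("B", {"gB"}))

    def test_identical_distributions(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = self._run(vals, vals)
        assert res["D"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        res = self._run([1, 2, 3, 1.5, 2.5], [4, 5, 6, 4.5, 5.5])
        assert res["D"] == pytest.approx(1.0)

    def test_matches_brute_force_ecdf(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.5, 1, 100)
        res = self._run(a, b)
        grid = np.concatenate([a, b])
        d_brute = max(abs((a <= v).mean() - (b <= v).mean()) for v in grid)
        assert res["D"] == pytest.approx(d_brute, abs=1e-12)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_dual_assigned_elements_excluded(self):
        scores = pd.Series([1.0] * 12, index=[f"e{i}" for i in range(12)])
        assignment = {f"e{i}": {"gA"} for i in range(5)}
        assignment.update({f"e{i}": {"gB"} for i in range(5, 10)})
        assignment.update({f"e{i}": {"gA", "gB"} for i in range(10, 12)})
        res = accessibility_by_geneset_ks(
            scores, assignment, GeneSet("A", {"gA"}), GeneSet("B", {"gB"}))
        assert res["n_excluded_dual"] == 2
        assert res["n_a"] == 5 and res["n_b"] == 5

    def test_small_groups_rejected(self):
        with pytest.raises(ArgumentError):
            self._run([1.0, 2.0], [3.0, 4.0])
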