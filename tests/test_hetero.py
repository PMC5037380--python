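"""Normalization, HVG selection, clustering, subtype scores, enrichment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from wellcount import hetero, simdata
from wellcount.hetero import (
    ExpressionMatrix,
    correlation_matrix,
    embed_and_cluster,
    enrichment_test,
    normalize,
    select_hvg,
    subtype_score,
)
from wellcount.molcount import CountMatrix


def _expr(fractions, genes=None):
    fractions = np.asarray(fractions, dtype=float)
    genes = genes or [f"g{j}" for j in range(fractions.shape[1])]
    return ExpressionMatrix(
        barcodes=[f"c{i}" for i in range(fractions.shape[0])],
        genes=genes,
        fractions=sp.csr_matrix(fractions),
    )


class TestNormalize:
    def test_row_fractions(self):
        m = CountMatrix.from_dense(np.array([[2, 2, 0], [1, 0, 3]]))
        expr = normalize(m)
        assert np.allclose(expr.fractions.toarray()[0], [0.5, 0.5, 0.0])
        assert np.allclose(expr.fractions.toarray().sum(axis=1), 1.0)

    def test_empty_cell_rejected(self):
        m = CountMatrix.from_dense(np.array([[0, 0], [1, 2]]))
        with pytest.raises(ValueError, match="empty cell"):
            normalize(m)


class TestSelectHvg:
    def test_outlier_z_matches_direct_computation(self):
        """One high-CV gene among 30 same-mean genes: z checked by hand."""
        n_cells = 40
        rows = []
        for i in range(n_cells):
            hi = 1.1 if i % 2 == 0 else 0.9       # background: cv ~ 0.1
            spike = 1.9 if i % 2 == 0 else 0.1    # outlier: cv ~ 0.9
            rows.append([hi] * 30 + [spike])
        F = np.array(rows) * 1e-3
        expr = _expr(F)
        report = select_hvg(expr, n_bins=1, min_frac=0.0)
        assert report["bin"].nunique() == 1
        cv = F.std(axis=0, ddof=1) / F.mean(axis=0)
        log_cv = np.log10(cv)
        z_expected = (log_cv[-1] - log_cv.mean()) / log_cv.std(ddof=0)
        assert report["dispersion_z"].iloc[-1] == pytest.approx(z_expected)
        assert report["selected"].iloc[-1] == (z_expected > 3)
        assert not report["selected"].iloc[:-1].any()

    def test_min_cells_filter_is_absolute(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(0.5, 1.5, size=(30, 20)) * 1e-3
        F[:, 0] = 0.0
        F[:4, 0] = 5e-3  # detected in exactly 4 cells, wildly variable
        report = select_hvg(_expr(F))
        assert report["detected_cells"].iloc[0] == 4
        assert not report["selected"].iloc[0]
        assert report["dispersion_z"].iloc[0] == 0.0

    def test_min_fraction_filter_is_absolute(self):
        n_cells = 60
        rows = []
        for i in range(n_cells):
            base = [1.1 if i % 2 == 0 else 0.9] * 100
            sparse = 12.0 if i < 5 else 0.0  # mean matches background
            rows.append(base + [sparse])
        report = select_hvg(_expr(np.array(rows) * 1e-3), n_bins=1)
        last = report.iloc[-1]
        assert last["detected_cells"] == 5
        assert last["dispersion_z"] > 3  # dispersion alone would select it
        assert last["detected_fraction"] < 0.10
        assert not last["selected"]

    def test_lonely_bin_gets_zero_z(self):
        rng = np.random.default_rng(9)
        F = rng.uniform(0.5, 1.5, size=(30, 40)) * 1e-4
        F[:, 0] *= 1e3  # unique extreme mean -> bin of its own
        report = select_hvg(_expr(F))
        assert report["dispersion_z"].iloc[0] == 0.0
        assert not report["selected"].iloc[0]

    def test_invariant_to_gene_and_cell_order(self):
        counts, _ = simdata.simulate_hvg_matrix(n_cells=80, n_background=300, seed=2)
        m = CountMatrix.from_dense(counts)
        sel1 = set(select_hvg(normalize(m)).query("selected").index)

        perm_g = np.random.default_rng(1).permutation(counts.shape[1])
        perm_c = np.random.default_rng(2).permutation(counts.shape[0])
        shuffled = counts.iloc[perm_c, perm_g]
        m2 = CountMatrix.from_dense(shuffled)
        sel2 = set(select_hvg(normalize(m2)).query("selected").index)
        assert sel1 == sel2

    def test_planted_high_variance_genes_recovered(self):
        counts, planted = simdata.simulate_hvg_matrix(seed=11)
        report = select_hvg(normalize(CountMatrix.from_dense(counts)))
        selected = set(report.query("selected").index)
        recall = sum(g in selected for g in planted) / len(planted)
        assert recall >= 0.9


class TestCorrelationMatrix:
    def test_identical_cells_correlate_perfectly(self):
        F = np.array([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5], [0.5, 0.3, 0.2]])
        C = correlation_matrix(_expr(F), ["g0", "g1", "g2"])
        assert C[0, 1] == pytest.approx(1.0)
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)

    def test_reversed_profile_anticorrelates(self):
        F = np.array([[0.1, 0.9], [0.9, 0.1]])
        C = correlation_matrix(_expr(F), ["g0", "g1"])
        assert C[0, 1] == pytest.approx(-1.0)

    def test_entries_bounded(self):
        rng = np.random.default_rng(8)
        F = rng.dirichlet(np.ones(20), size=15)
        expr = _expr(F)
        C = correlation_matrix(expr, expr.genes[:10])
        assert (C <= 1.0 + 1e-12).all() and (C >= -1.0 - 1e-12).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(_expr(np.eye(3)), ["g0"])


@pytest.fixture(scope="module")
def two_pop():
    counts, labels = simdata.simulate_populations(
        n_cells=(60, 60), n_genes=600, depth=1500, seed=6
    )
    m = CountMatrix.from_dense(counts)
    expr = normalize(m)
    hvg = select_hvg(expr)
    sel = hetero.hvg_gene_list(hvg, min_genes=50)
    return correlation_matrix(expr, sel), labels, m


class TestEmbedAndCluster:
    def test_two_populations_found(self, two_pop):
        corr, labels, m = two_pop
        res = embed_and_cluster(corr, perplexity=15.0, seed=0, matrix=m)
        found = set(res.labels) - {-1}
        assert len(found) == 2
        # label purity vs truth
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, res.labels) >= 0.95

    def test_deterministic_given_seed(self, two_pop):
        corr, _, _ = two_pop
        a = embed_and_cluster(corr, perplexity=15.0, seed=3)
        b = embed_and_cluster(corr, perplexity=15.0, seed=3)
        assert (a.labels == b.labels).all()
        assert np.allclose(a.cells[["x", "y"]], b.cells[["x", "y"]])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="perplexity"):
            embed_and_cluster(np.eye(20), perplexity=30.0)

    def test_median_molecules_reported(self, two_pop):
        corr, _, m = two_pop
        res = embed_and_cluster(corr, perplexity=15.0, seed=0, matrix=m)
        assert "median_molecules" in res.clusters.columns


class TestSubtypeScore:
    def _matrix(self):
        # 3 cells; 5 subtype genes + background
        n_genes = 205
        counts = np.zeros((3, n_genes), dtype=int)
        counts[0, :100] = 1            # detects subtype genes 0-4 among 100 genes
        counts[1, 5:105] = 1           # detects no subtype gene
        counts[2, :5] = 1              # all subtype genes among 200 genes
        counts[2, 5:200] = 1
        genes = [f"S{j}" for j in range(5)] + [f"g{j}" for j in range(n_genes - 5)]
        return CountMatrix.from_dense(counts, genes=genes)

    def test_worked_example(self):
        res = subtype_score(self._matrix(), [f"S{j}" for j in range(5)])
        assert res.n_subtype_dataset == 5
        assert res.values.iloc[0] == pytest.approx(1 / 100)

    def test_zero_when_no_subtype_genes_detected(self):
        res = subtype_score(self._matrix(), [f"S{j}" for j in range(5)])
        assert res.values.iloc[1] == 0.0

    def test_doubling_gene_count_halves_score(self):
        res = subtype_score(self._matrix(), [f"S{j}" for j in range(5)])
        assert res.values.iloc[2] == pytest.approx(res.values.iloc[0] / 2)

    def test_absent_gene_set_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            subtype_score(self._matrix(), ["nope1", "nope2"])


class TestEnrichment:
    def test_exact_combinatorial_value(self):
        # population 10, successes 5, cluster of 4 all successes
        scores = np.arange(1, 11, dtype=float)
        labels = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1])
        r = enrichment_test(scores, labels, 1)
        assert r.overlap == 4 and r.cluster_size == 4 and r.n_successes == 5
        assert r.p_value == pytest.approx(5 / 210)

    def test_zero_overlap_upper_tail_is_one(self):
        scores = np.arange(1, 11, dtype=float)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        r = enrichment_test(scores, labels, 1)
        assert r.overlap == 0
        assert r.p_value == pytest.approx(1.0)

    def test_ties_at_median_are_not_successes(self):
        scores = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        r = enrichment_test(scores, labels, 1)
        assert r.n_successes == 2  # only the two 3.0 scores are above median 2

    def test_noise_cells_excluded_from_population(self):
        scores = np.arange(6, dtype=float)
        labels = np.array([-1, -1, 0, 0, 1, 1])
        r = enrichment_test(scores, labels, 1)
        assert r.population == 4

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        n_perm = 20_000
        for _ in range(5):
            M = int(rng.integers(20, 60))
            scores = rng.normal(size=M)
            n_clusters = int(rng.integers(2, 4))
            labels = rng.integers(0, n_clusters, size=M)
            c = int(rng.integers(0, n_clusters))
            if (labels == c).sum() == 0:
                labels[0] = c
            r = enrichment_test(scores, labels, c)
            success = scores > np.median(scores)
            n = (labels == c).sum()
            draws = np.array(
                [success[rng.permutation(M)[:n]].sum() for _ in range(n_perm)]
            )
            p_mc = (draws >= r.overlap).mean()
            se = max(np.sqrt(p_mc * (1 - p_mc) / n_perm), 1.0 / n_perm)
            assert abs(r.p_value - p_mc) <= 3 * se
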