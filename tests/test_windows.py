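"""Window aggregation, Gaussian smoothing, window correlation, group
graph and Leiden SNV groups."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spotsnv import windows as win
from spotsnv.types import SNVCallSet, SNVRecord, SpotSNVMatrix, WindowMatrix

from conftest import lattice_spots


def _matrix(counts, snvs, spots=None):
    counts = np.asarray(counts)
    spots = spots or lattice_spots(int(np.ceil(np.sqrt(counts.shape[0]))))
    from spotsnv.types import SpotTable

    spots = SpotTable(spots.df.iloc[: counts.shape[0]].copy())
    return SpotSNVMatrix(
        spots=spots, snv_ids=snvs.ids, counts=sp.csr_matrix(counts),
        layer="raw", snvs=snvs,
    )


class TestWindowAggregate:
    def test_label_convention(self):
        assert win.window_label("chr22", 32_812_345) == "chr22@328"
        assert win.window_label("chr7", 23_200_000) == "chr7@232"

    def test_random_loci_match_integer_division_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            pos = int(rng.integers(1, 3_000_000_000))
            chrom = f"chr{rng.integers(1, 23)}"
            assert win.window_label(chrom, pos) == f"{chrom}@{pos // 100_000}"

    def test_counts_conserved_and_snvs_partitioned(self):
        rng = np.random.default_rng(1)
        snvs = SNVCallSet(
            [
                SNVRecord(f"chr{1 + i % 3}", int(rng.integers(1, 10_000_000)), "A", "G")
                for i in range(0, 60, 2)
            ]
        )
        counts = rng.poisson(0.5, size=(16, len(snvs)))
        m = _matrix(counts, snvs)
        wm = win.window_aggregate(m)
        assert wm.counts.sum() == counts.sum()
        # brute-force per-window sums
        for j, (chrom, idx) in enumerate(wm.windows):
            member = [
                k for k, r in enumerate(snvs)
                if r.chrom == chrom and r.pos // 100_000 == idx
            ]
            assert np.array_equal(
                np.asarray(wm.counts[:, j].todense()).ravel(),
                counts[:, member].sum(axis=1),
            )

    def test_huge_window_means_one_per_chrom(self):
        snvs = SNVCallSet(
            [
                SNVRecord("chr1", 5, "A", "G"),
                SNVRecord("chr1", 99_999, "C", "T"),
                SNVRecord("chr2", 7, "G", "A"),
            ]
        )
        m = _matrix(np.ones((4, 3)), snvs)
        wm = win.window_aggregate(m, window_size=10**9)
        assert wm.labels == ["chr1@0", "chr2@0"]


class TestSpatialWeights:
    def test_gaussian_values(self):
        spots = lattice_spots(3)
        w = win.spatial_weights(spots, k=2, alpha=1.0)
        # D = 0 (diagonal)
        assert w.W.diagonal().min() == 1.0
        # D = alpha: adjacent lattice neighbors at distance 1
        i = spots.barcode_index()["s1_1"]
        j = spots.barcode_index()["s1_2"]
        assert w.W[i, j] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_monotone_in_distance_and_symmetric(self):
        rng = np.random.default_rng(2)
        import pandas as pd
        from spotsnv.types import SpotTable

        spots = SpotTable(
            pd.DataFrame(
                {
                    "barcode": [f"r{i}" for i in range(40)],
                    "x": rng.uniform(0, 10, 40),
                    "y": rng.uniform(0, 10, 40),
                    "total_umi": 1,
                }
            )
        )
        w = win.spatial_weights(spots, k=5, alpha=2.0)
        assert (abs(w.W - w.W.T) > 1e-12).nnz == 0
        coords = spots.coords
        W = w.W.tocoo()
        d = np.hypot(
            coords[W.row, 0] - coords[W.col, 0],
            coords[W.row, 1] - coords[W.col, 1],
        )
        order = np.argsort(d)
        assert np.all(np.diff(W.data[order]) <= 1e-12)

    def test_k_must_be_less_than_n(self):
        with pytest.raises(ValueError):
            win.spatial_weights(lattice_spots(2), k=4)

    def test_default_alpha_is_mean_knn_distance(self):
        spots = lattice_spots(5)
        w = win.spatial_weights(spots, k=4)
        assert w.alpha == pytest.approx(win.mean_knn_distance(spots, 4))


def _window_matrix(counts, spots):
    counts = np.asarray(counts)
    return WindowMatrix(
        spots=spots,
        windows=[("chr1", i) for i in range(counts.shape[1])],
        counts=sp.csr_matrix(counts),
        window_size=100_000,
    )


class TestSmooth:
    def test_identity_weights_leave_matrix_unchanged(self):
        spots = lattice_spots(3)
        counts = np.arange(27).reshape(9, 3)
        wm = _window_matrix(counts, spots)
        from spotsnv.types import SpatialWeights

        weights = SpatialWeights(W=sp.eye(9, format="csr"), k=0, alpha=1.0)
        out = win.smooth(wm, weights)
        assert np.allclose(out.smoothed, counts)

    def test_matches_dense_product_and_spreads_to_neighbors(self):
        spots = lattice_spots(4)
        rng = np.random.default_rng(3)
        counts = np.zeros((16, 2))
        counts[5, 0] = 4.0
        counts[:, 1] = rng.poisson(1.0, 16)
        wm = _window_matrix(counts, spots)
        weights = win.spatial_weights(spots, k=3, alpha=1.0)
        out = win.smooth(wm, weights)
        dense = np.asarray(weights.W.todense()) @ counts
        assert np.allclose(out.smoothed, dense, atol=1e-12)
        # single nonzero spot spreads exactly to its weight-graph neighbors
        support = np.flatnonzero(out.smoothed[:, 0])
        neighbors = np.flatnonzero(np.asarray(weights.W[:, 5].todense()).ravel())
        assert set(support) == set(neighbors)

    def test_zero_column_stays_zero(self):
        spots = lattice_spots(3)
        wm = _window_matrix(np.zeros((9, 2)), spots)
        weights = win.spatial_weights(spots, k=2)
        assert not win.smooth(wm, weights).smoothed.any()

    def test_row_normalized_preserves_constant_column(self):
        spots = lattice_spots(4)
        wm = _window_matrix(np.full((16, 1), 3.0), spots)
        weights = win.spatial_weights(spots, k=3, alpha=1.0)
        out = win.smooth(wm, weights, row_normalize=True)
        assert np.allclose(out.smoothed[:, 0], 3.0)


class TestWindowCorrelation:
    def _smoothed(self, M, spots):
        wm = _window_matrix(np.zeros_like(M), spots)
        wm.smoothed = np.asarray(M, dtype=float)
        return wm

    def test_identical_windows_score_maximal(self):
        spots = lattice_spots(3)
        col = np.array([3, 0, 1, 0, 2, 0, 0, 4, 1], dtype=float)
        wm = self._smoothed(np.column_stack([col, col]), spots)
        corr = win.window_correlation(wm)
        assert corr[0, 1] == pytest.approx(corr[0, 0])
        assert corr[0, 1] == pytest.approx(1.0)  # cosine of identical masked cols

    def test_disjoint_support_scores_zero(self):
        spots = lattice_spots(3)
        a = np.array([1, 2, 3, 0, 0, 0, 0, 0, 0], dtype=float)
        b = np.array([0, 0, 0, 0, 1, 2, 3, 0, 0], dtype=float)
        wm = self._smoothed(np.column_stack([a, b]), spots)
        corr = win.window_correlation(wm)
        assert corr[0, 1] == 0.0

    def test_under_two_nonzero_spots_gives_zero_row(self):
        spots = lattice_spots(3)
        a = np.zeros(9)
        a[4] = 5.0
        b = np.arange(9, dtype=float)
        wm = self._smoothed(np.column_stack([a, b]), spots)
        corr = win.window_correlation(wm)
        assert corr[0].sum() == 0.0

    def test_matches_dense_masked_oracle(self):
        rng = np.random.default_rng(4)
        spots = lattice_spots(5)
        M = rng.poisson(1.0, size=(25, 10)).astype(float)
        wm = self._smoothed(M, spots)
        for normalize in (False, True):
            corr = win.window_correlation(wm, top_fraction=0.5, normalize=normalize)
            masked = M.copy()
            for j in range(10):
                nz = M[M[:, j] > 0, j]
                if nz.size < 2:
                    masked[:, j] = 0
                    continue
                thr = np.quantile(nz, 0.5)
                masked[M[:, j] < thr, j] = 0
            if normalize:
                norms = np.linalg.norm(masked, axis=0)
                masked = masked / np.where(norms > 0, norms, 1)
            oracle = masked.T @ masked
            assert np.allclose(corr, oracle, atol=1e-12)
            assert np.allclose(corr, corr.T, atol=1e-12)  # symmetric pre-pruning


class TestGroupGraph:
    def test_identical_rows_give_symmetric_graph(self):
        corr = np.full((4, 4), 2.0)
        np.fill_diagonal(corr, 5.0)
        g = win.build_group_graph(corr)
        pairs = set(zip(g.source, g.target))
        assert all((b, a) in pairs for a, b in pairs)

    def test_top_partner_gets_row_maximal_weight(self):
        rng = np.random.default_rng(5)
        corr = rng.uniform(0.1, 1.0, size=(8, 8))
        corr = (corr + corr.T) / 2
        g = win.build_group_graph(corr)
        for i, sub in g.groupby("source"):
            jmax = sub.loc[sub.weight.idxmax(), "target"]
            assert corr[i, jmax] == corr[i][np.arange(8) != i].max()

    def test_matches_sort_and_decay_oracle(self):
        rng = np.random.default_rng(6)
        corr = rng.uniform(0, 1, size=(12, 12))
        corr = (corr + corr.T) / 2
        top_fraction, da = 0.5, 0.5
        g = win.build_group_graph(corr, top_fraction, da)
        got = {(r.source, r.target): r.weight for r in g.itertuples(index=False)}
        for i in range(12):
            row = corr[i].copy()
            row[i] = -np.inf
            pos = np.flatnonzero(row > 0)
            ranked = pos[np.argsort(row[pos])[::-1]]
            cutoff = row[ranked[int(np.ceil(top_fraction * pos.size)) - 1]]
            keep = ranked[row[ranked] >= cutoff]
            mx = row[keep[0]]
            for j in keep:
                r = 1 - row[j] / mx
                expect = row[j] * math.exp(-(r**2) / (2 * da**2))
                assert got[(i, int(j))] == pytest.approx(expect, rel=1e-12)
        assert len(got) == sum(
            int(np.ceil(top_fraction * 11)) for _ in range(12)
        )


class TestLeidenGroups:
    def _clique_graph(self, sizes, w_in=1.0):
        edges = []
        start = 0
        for s in sizes:
            nodes = range(start, start + s)
            for i in nodes:
                for j in nodes:
                    if i < j:
                        edges.append((i, j, w_in))
            start += s
        return pd.DataFrame(edges, columns=["source", "target", "weight"]), start

    def test_two_disconnected_cliques(self):
        g, n = self._clique_graph([6, 6])
        a = win.leiden_groups(g, n, resolution=1.0, seed=0)
        assert len(set(a)) == 2
        assert len(set(a[:6])) == 1 and len(set(a[6:])) == 1

    def test_planted_four_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        truth = np.repeat(np.arange(4), 10)
        rows = []
        for i in range(40):
            for j in range(i + 1, 40):
                if truth[i] == truth[j]:
                    rows.append((i, j, rng.uniform(0.8, 1.0)))
                elif rng.random() < 0.05:
                    rows.append((i, j, 0.05))
        g = pd.DataFrame(rows, columns=["source", "target", "weight"])
        a = win.leiden_groups(g, 40, resolution=1.0, seed=0)
        assert adjusted_rand_score(truth, a) == 1.0

    def test_extreme_resolution_gives_singletons(self):
        g, n = self._clique_graph([6, 6])
        a = win.leiden_groups(g, n, resolution=1e6, seed=0)
        assert len(set(a)) == n

    def test_deterministic_under_seed(self):
        g, n = self._clique_graph([5, 5, 5])
        a1 = win.leiden_groups(g, n, resolution=1.0, seed=3)
        a2 = win.leiden_groups(g, n, resolution=1.0, seed=3)
        assert np.array_equal(a1, a2)

    def test_groups_ranked_by_internal_weight(self):
        g1, _ = self._clique_graph([4], w_in=0.2)
        g2, _ = self._clique_graph([4], w_in=1.0)
        g2[["source", "target"]] += 4
        g = pd.concat([g1, g2], ignore_index=True)
        a = win.leiden_groups(g, 8, resolution=1.0, seed=0)
        # the heavier clique gets group id 0
        assert set(a[4:]) == {0} and set(a[:4]) == {1}


class TestGroupScores:
    def test_formula_against_direct_sum(self):
        spots = lattice_spots(2, umi=50)
        counts = np.array([[1, 2, 0], [0, 3, 1], [4, 0, 0], [0, 0, 0]])
        wm = _window_matrix(counts, spots)
        assignment = np.array([0, 0, 1])
        scores = win.group_scores(wm, assignment)
        expect0 = np.log1p(counts[:, :2].sum(axis=1) / 50)
        expect1 = np.log1p(counts[:, 2] / 50)
        assert np.allclose(scores["group_0"], expect0)
        assert np.allclose(scores["group_1"], expect1)

    def test_single_window_group_equals_normalized_column(self):
        spots = lattice_spots(2, umi=10)
        counts = np.array([[2], [0], [5], [1]])
        wm = _window_matrix(counts, spots)
        scores = win.group_scores(wm, np.array([0]))
        assert np.allclose(scores["group_0"], np.log1p(counts[:, 0] / 10))


class TestRepresentativeGene:
    def _setup(self):
        spots = lattice_spots(4)
        snvs = SNVCallSet(
            [
                SNVRecord("chr1", 50, "A", "G", gene="ALPHA"),
                SNVRecord("chr1", 90, "C", "T", gene="BETA"),
                SNVRecord("chr1", 100_050, "G", "A", gene="GAMMA"),
                SNVRecord("chr2", 10, "T", "C"),  # intergenic
            ]
        )
        counts = np.zeros((16, 3))
        counts[:8, 0] = 3  # window chr1@0 active in first half
        counts[8:, 1] = 2  # window chr1@1 active in second half
        counts[:4, 2] = 1  # window chr2@0
        wm = WindowMatrix(
            spots=spots,
            windows=[("chr1", 0), ("chr1", 1), ("chr2", 0)],
            counts=sp.csr_matrix(counts),
            window_size=100_000,
        )
        return spots, snvs, wm

    def test_single_gene_window(self):
        _, snvs, wm = self._setup()
        assert win.representative_gene(1, wm, snvs) == "GAMMA"

    def test_all_intergenic_window_has_none(self):
        _, snvs, wm = self._setup()
        assert win.representative_gene(2, wm, snvs) is None

    def test_best_correlated_candidate_wins(self):
        _, snvs, wm = self._setup()
        rng = np.random.default_rng(8)
        wvec = np.asarray(wm.counts[:, 0].todense()).ravel()
        expr = np.column_stack(
            [wvec * 2 + rng.normal(0, 0.01, 16), rng.normal(5, 1, 16)]
        )
        gene = win.representative_gene(
            0, wm, snvs, expression=sp.csr_matrix(np.abs(expr)),
            gene_names=["ALPHA", "BETA"],
        )
        assert gene == "ALPHA"
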