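"""Moran's I, tumor-distance decay, signature scoring and burden
correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spotsnv import spatial as sst
from spotsnv import windows as win
from spotsnv.types import LabelingError, SpotTable

from conftest import lattice_spots


def brute_force_moran(values, W):
    n = len(values)
    z = values - values.mean()
    num = S0 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                num += W[i, j] * z[i] * z[j]
                S0 += W[i, j]
    return (n / S0) * num / (z @ z)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        spots = lattice_spots(10)
        W = sst.rook_adjacency(spots)
        vals = ((spots.coords[:, 0] + spots.coords[:, 1]) % 2).astype(float)
        assert sst.morans_i(vals, W).I == pytest.approx(-1.0, abs=1e-14)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "barcode": [f"s{i}" for i in range(50)],
                "x": rng.uniform(0, 10, 50),
                "y": rng.uniform(0, 10, 50),
                "total_umi": 1,
            }
        )
        spots = SpotTable(df)
        w = win.spatial_weights(spots, k=5, alpha=1.5)
        vals = rng.normal(size=50)
        Wd = np.asarray(w.without_self().todense())
        assert sst.morans_i(vals, w).I == pytest.approx(
            brute_force_moran(vals, Wd), abs=1e-10
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        spots = lattice_spots(8)
        W = sst.rook_adjacency(spots)
        vals = rng.normal(size=64)
        base = sst.morans_i(vals, W).I
        assert sst.morans_i(3.7 * vals - 11.0, W).I == pytest.approx(base, abs=1e-12)

    def test_constant_feature_raises(self):
        spots = lattice_spots(4)
        W = sst.rook_adjacency(spots)
        with pytest.raises(ValueError):
            sst.morans_i(np.ones(16), W)

    def test_permutation_mean_matches_theory(self):
        """E[I] under random labeling is -1/(n-1)."""
        rng = np.random.default_rng(2)
        n = 400
        spots = lattice_spots(20)
        W = sst.rook_adjacency(spots)
        vals = rng.normal(size=n)
        Is = np.array(
            [sst.morans_i(rng.permutation(vals), W).I for _ in range(1000)]
        )
        se = Is.std() / np.sqrt(len(Is))
        assert abs(Is.mean() - (-1 / (n - 1))) < 4 * se


class TestDistanceToTumor:
    def _spots(self, coords_regions):
        rows = [
            {"barcode": f"s{i}", "x": x, "y": y, "total_umi": 1, "region": r}
            for i, (x, y, r) in enumerate(coords_regions)
        ]
        return SpotTable(pd.DataFrame(rows))

    def test_unit_distance_cluster(self):
        spots = self._spots(
            [(0, 0, "margin")]
            + [(1, 0, "tumor"), (-1, 0, "tumor"), (0, 1, "tumor"),
               (0, -1, "tumor"), (1, 0.0, "normal")]
            + [(0.6, 0.8, "tumor")]
        )
        d = sst.distance_to_tumor(spots, k=5)
        assert d.iloc[0] == pytest.approx(1.0)

    def test_k1_is_nearest_tumor(self):
        spots = self._spots(
            [(0, 0, "margin"), (3, 4, "tumor"), (10, 0, "tumor")]
        )
        d = sst.distance_to_tumor(spots, k=1)
        assert d.iloc[0] == pytest.approx(5.0)

    def test_matches_exhaustive_all_pairs_sort(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 30, size=(200, 2))
        regions = rng.choice(["tumor", "margin", "normal"], size=200, p=[0.4, 0.3, 0.3])
        spots = self._spots(
            [(x, y, r) for (x, y), r in zip(coords, regions)]
        )
        d = sst.distance_to_tumor(spots, k=5)
        tumor = coords[regions == "tumor"]
        for bc, got in d.items():
            i = int(bc[1:])
            dists = np.sort(np.hypot(*(tumor - coords[i]).T))
            assert got == pytest.approx(dists[:5].mean(), abs=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 10, size=(50, 2))
        regions = ["tumor"] * 30 + ["margin"] * 20
        spots = self._spots([(x, y, r) for (x, y), r in zip(coords, regions)])
        d0 = sst.distance_to_tumor(spots, k=5).to_numpy()
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = coords @ R.T + np.array([100.0, -40.0])
        spots2 = self._spots([(x, y, r) for (x, y), r in zip(moved, regions)])
        d1 = sst.distance_to_tumor(spots2, k=5).to_numpy()
        assert np.allclose(d0, d1, atol=1e-9)

    def test_missing_labels_raise(self):
        spots = self._spots([(0, 0, "margin"), (1, 1, "normal")])
        with pytest.raises(LabelingError):
            sst.distance_to_tumor(spots, k=1)


class TestBurdenDistanceFit:
    def test_noiseless_power_law_exact(self):
        d = np.linspace(1.0, 15.0, 200)
        for beta, c in [(-0.8, 0.02), (1.3, 0.5)]:
            burden = c * d**beta
            fit = sst.burden_distance_fit(burden, d)
            assert fit.slope == pytest.approx(beta, abs=1e-10)
            assert fit.intercept == pytest.approx(np.log(c), abs=1e-10)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_zero_burden_spots_dropped(self):
        d = np.linspace(1, 10, 50)
        burden = 0.1 * d**-0.5
        burden[::7] = 0.0
        fit = sst.burden_distance_fit(burden, d)
        assert fit.n_dropped == len(d[::7])
        assert fit.n_margin_spots == 50 - fit.n_dropped

    def test_shuffled_pairs_lose_association(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(1, 20, 500)
        burden = 0.05 * d**-0.8 * np.exp(rng.normal(0, 0.1, 500))
        fit0 = sst.burden_distance_fit(burden, d)
        fit1 = sst.burden_distance_fit(rng.permutation(burden), d)
        assert fit0.r_squared > 0.8
        assert fit1.r_squared < 0.05


class TestSlopeVsImmune:
    def test_perfect_linear(self):
        slopes = np.array([-0.2, -0.5, -0.9, -1.4])
        r, p = sst.slope_vs_immune(slopes, 2.0 * slopes + 1.0)
        assert r == pytest.approx(1.0)

    def test_two_sections_rejected(self):
        with pytest.raises(ValueError):
            sst.slope_vs_immune([1.0, 2.0], [3.0, 4.0])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(size=20)
        r, _ = sst.slope_vs_immune(a, b)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        assert r == pytest.approx((za * zb).mean(), abs=1e-12)


class TestSignatureScore:
    def _expr(self, seed=0, n=300, g=200):
        rng = np.random.default_rng(seed)
        return sp.csr_matrix(rng.poisson(2.0, size=(n, g)).astype(float)), [
            f"g{i}" for i in range(g)
        ]

    def test_self_control_scores_near_zero(self):
        X, names = self._expr()
        score = sst.signature_score(X, names, names, n_ctrl=200, seed=0)
        assert np.abs(score).max() < 0.3

    def test_planted_upshift_detected(self):
        X, names = self._expr(seed=1)
        X = X.toarray()
        region = np.zeros(300, dtype=bool)
        region[:100] = True
        gene_set = names[:5]
        X[np.ix_(region, range(5))] += 5.0
        score = sst.signature_score(sp.csr_matrix(X), names, gene_set, seed=0)
        assert score[region].mean() > score[~region].mean() + 2.0

    def test_deterministic_under_seed(self):
        X, names = self._expr(seed=2)
        s1 = sst.signature_score(X, names, names[:7], seed=11)
        s2 = sst.signature_score(X, names, names[:7], seed=11)
        assert np.array_equal(s1, s2)

    def test_agrees_with_scanpy_on_planted_shift(self):
        """Independent cross-check: the expression-binned control scheme
        should rank spots like Scanpy's score_genes."""
        import anndata as ad
        import scanpy as sc

        X, names = self._expr(seed=3)
        Xd = X.toarray()
        Xd[:80, :6] += 4.0
        gene_set = names[:6]
        ours = sst.signature_score(sp.csr_matrix(Xd), names, gene_set, seed=0)
        adata = ad.AnnData(Xd.copy())
        adata.var_names = names
        sc.tl.score_genes(adata, gene_set, ctrl_size=50, n_bins=25, random_state=0)
        theirs = adata.obs["score"].to_numpy()
        assert np.corrcoef(ours, theirs)[0, 1] > 0.95


class TestBurdenPathwayCorrelation:
    def test_self_and_anticorrelated(self):
        rng = np.random.default_rng(7)
        burden = rng.uniform(0, 1, 200)
        scores = pd.DataFrame(
            {
                "self": burden,
                "anti": -burden + rng.normal(0, 0.01, 200),
                "noise": rng.normal(size=200),
            }
        )
        out = sst.burden_pathway_correlation(burden, scores).set_index("pathway")
        assert out.loc["self", "r"] == pytest.approx(1.0)
        assert out.loc["anti", "r"] < -0.9
        assert abs(out.loc["noise", "r"]) < 0.2
        assert list(out.index)[0] == "self"  # sorted by r


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("SET_A\tdesc\tG1\tG2\tG3\nSET_B\tdesc\tG9\n\nshort\n")
    sets = sst.read_gmt(p)
    assert sets == {"SET_A": ["G1", "G2", "G3"], "SET_B": ["G9"]}


class TestRegionAssociation:
    def test_planted_tumor_enrichment(self):
        region = np.array(["tumor"] * 100 + ["normal"] * 100)
        presence = np.concatenate([np.ones(80), np.zeros(20), np.zeros(90), np.ones(10)])
        chi2, p = sst.region_association(presence, region)
        assert p < 1e-10
        rng = np.random.default_rng(8)
        chi2_null, p_null = sst.region_association(
            rng.permutation(presence), region
        )
        assert chi2 > chi2_null
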