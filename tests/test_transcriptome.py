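"""Sample-to-gradient mapping, closed-form PLS1, permutation test, gene selection."""

import itertools

import numpy as np
import pytest

from seedgrad import io
from seedgrad.transcriptome import (
    gene_loadings,
    map_samples_to_gradient,
    pls1_fit,
    pls_permutation_test,
    select_contributing_genes,
)


def _lattice_grid(spacing=3.0, half=2):
    axes = np.arange(-half, half + 1) * spacing
    coords = np.array([[x, y, z] for x in axes for y in axes for z in axes])
    n = coords.shape[0]
    return io.VoxelGrid(
        voxel_ids=np.arange(n),
        coords_mm=coords,
        region_label=np.full(n, "seed"),
        hemisphere=np.full(n, "L"),
    )


def _panel(coords, expr=None, genes=("G1",)):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if expr is None:
        expr = np.zeros((n, len(genes)))
    return io.ExpressionPanel(
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        sample_coords_mm=coords,
        expression=np.asarray(expr, dtype=float),
        gene_symbols=np.asarray(genes),
    )


class TestMapSamplesToGradient:
    def test_closed_ball_includes_face_neighbours(self):
        grid = _lattice_grid(spacing=3.0)
        panel = _panel([[0.0, 0.0, 0.0]])
        g = np.zeros(grid.n_voxels)
        centre = np.flatnonzero((grid.coords_mm == 0).all(axis=1))[0]
        g[centre] = 7.0
        vals, kept = map_samples_to_gradient(panel, g, grid, radius_mm=3.0)
        # sphere = centre voxel + its 6 face neighbours at distance exactly 3.0
        assert kept.all()
        assert vals[0] == pytest.approx(7.0 / 7.0)

    def test_constant_field_maps_to_constant(self):
        grid = _lattice_grid()
        panel = _panel([[0, 0, 0], [3, 0, 0]])
        vals, _ = map_samples_to_gradient(panel, np.full(grid.n_voxels, 0.7), grid)
        np.testing.assert_allclose(vals, 0.7)

    def test_out_of_range_sample_dropped_with_warning(self):
        grid = _lattice_grid()
        panel = _panel([[0, 0, 0], [500, 500, 500]])
        with pytest.warns(UserWarning, match="dropped"):
            vals, kept = map_samples_to_gradient(
                panel, np.arange(grid.n_voxels, dtype=float), grid
            )
        assert kept.tolist() == [True, False]
        assert vals.shape == (1,)

    def test_all_samples_dropped_is_error(self):
        grid = _lattice_grid()
        panel = _panel([[900, 900, 900]])
        with pytest.raises(ValueError, match="no sample"):
            map_samples_to_gradient(panel, np.zeros(grid.n_voxels), grid)


class TestPls1Fit:
    def test_single_informative_gene(self):
        rng = np.random.default_rng(50)
        y = rng.standard_normal(20)
        x = np.zeros((20, 5))
        x[:, 2] = y
        fit = pls1_fit(x, y)
        assert fit.r_scores_gradient == pytest.approx(1.0)
        np.testing.assert_allclose(np.corrcoef(fit.scores, y)[0, 1], 1.0)

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(51)
        for _ in range(20):
            x = rng.standard_normal((12, 30))
            y = rng.standard_normal(12)
            fit = pls1_fit(x, y)
            xc = x - x.mean(axis=0)
            yc = y - y.mean()
            direction = xc @ (xc.T @ yc)
            direction /= np.linalg.norm(direction)
            scores = fit.scores / np.linalg.norm(fit.scores)
            err = min(np.abs(scores - direction).max(),
                      np.abs(scores + direction).max())
            assert err < 1e-8

    def test_matches_sklearn_first_component(self):
        """Independent cross-check against the NIPALS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(52)
        x = rng.standard_normal((15, 40))
        y = x[:, :4].sum(axis=1) + 0.1 * rng.standard_normal(15)
        fit = pls1_fit(x, y)
        sk = PLSRegression(n_components=1, scale=False).fit(x, y)
        r = np.corrcoef(fit.scores, sk.x_scores_[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_nonnegative_r(self):
        rng = np.random.default_rng(53)
        x = rng.standard_normal((10, 8))
        y = -x[:, 0]
        fit = pls1_fit(x, y)
        assert fit.r_scores_gradient >= 0

    def test_centring_invariance(self):
        rng = np.random.default_rng(54)
        x = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        a = pls1_fit(x, y)
        x2 = x.copy()
        x2[:, 3] += 100.0
        b = pls1_fit(x2, y)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_constant_gene_weight_zero(self):
        rng = np.random.default_rng(55)
        x = rng.standard_normal((10, 4))
        x[:, 1] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            fit = pls1_fit(x, rng.standard_normal(10))
        assert fit.weights[1] == 0.0
        assert fit.loadings[1] == 0.0

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pls1_fit(np.random.default_rng(56).standard_normal((5, 3)), np.ones(5))


class TestPermutationTest:
    def test_exhaustive_matches_oracle(self):
        rng = np.random.default_rng(57)
        x = rng.standard_normal((5, 7))
        y = rng.standard_normal(5)
        fit = pls1_fit(x, y)
        fit = pls_permutation_test(x, fit, exhaustive=True)
        xc = x - x.mean(axis=0)
        gram = xc @ xc.T
        count = 0
        for p in itertools.permutations(range(5)):
            yp = y[list(p)]
            s = gram @ (yp - yp.mean())
            r = abs(np.corrcoef(s, yp)[0, 1])
            if r >= fit.r_scores_gradient - 1e-12:
                count += 1
        assert fit.n_perm == 120
        assert fit.p_perm == pytest.approx(count / 120)

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(58)
        x = rng.standard_normal((10, 20))
        y = rng.standard_normal(10)
        a = pls_permutation_test(x, pls1_fit(x, y), n_perm=100, seed=3)
        b = pls_permutation_test(x, pls1_fit(x, y), n_perm=100, seed=3)
        assert a.p_perm == b.p_perm


class TestLoadings:
    def test_self_and_sign(self):
        rng = np.random.default_rng(59)
        s = rng.standard_normal(25)
        x = np.column_stack([s, -s, rng.standard_normal(25)])
        ld = gene_loadings(x, s)
        assert ld[0] == pytest.approx(1.0, abs=1e-12)
        assert ld[1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_pearson(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(60)
        x = rng.standard_normal((25, 10))
        s = rng.standard_normal(25)
        ld = gene_loadings(x, s)
        for g in range(10):
            assert ld[g] == pytest.approx(pearsonr(x[:, g], s).statistic, abs=1e-12)


class TestSelection:
    def test_exact_quartile(self):
        loadings = np.linspace(0.01, 1.0, 100)
        genes = np.array([f"g{i}" for i in range(100)])
        plus, minus = select_contributing_genes(loadings, genes, 0.25)
        assert len(plus) == 25
        assert plus == [f"g{i}" for i in range(99, 74, -1)]
        assert minus == []

    def test_floor_arithmetic_matches_reported_splits(self):
        n_pos, n_neg = 1988, 3025
        loadings = np.concatenate([
            np.linspace(1, 0.001, n_pos), np.linspace(-0.001, -1, n_neg)
        ])
        genes = np.array([f"g{i}" for i in range(n_pos + n_neg)])
        plus, minus = select_contributing_genes(loadings, genes, 0.25)
        assert (len(plus), len(minus)) == (497, 756)

    def test_zero_loadings_in_neither_pool(self):
        loadings = np.array([0.5, 0.0, -0.5, 0.0])
        genes = np.array(["a", "b", "c", "d"])
        plus, minus = select_contributing_genes(loadings, genes, 0.5)
        assert "b" not in plus + minus and "d" not in plus + minus

    def test_all_negative_warns_empty_plus(self):
        with pytest.warns(UserWarning, match="PLS\\+"):
            plus, minus = select_contributing_genes(
                np.array([-0.1, -0.2, -0.3, -0.4]), np.array(list("abcd")), 0.25
            )
        assert plus == []
        assert minus == ["d"]

    def test_invariant_to_gene_reordering(self):
        rng = np.random.default_rng(61)
        loadings = rng.standard_normal(40)
        genes = np.array([f"g{i}" for i in range(40)])
        perm = rng.permutation(40)
        a = select_contributing_genes(loadings, genes, 0.25)
        b = select_contributing_genes(loadings[perm], genes[perm], 0.25)
        assert set(a[0]) == set(b[0]) and set(a[1]) == set(b[1])


class TestRecovery:
    def test_tracking_genes_dominate_loadings(self, world, oriented_gradient):
        from seedgrad import synthetic

        _, _, seed_grid, _, truth = world
        panel = synthetic.make_expression_panel(truth, seed_grid, seed=880)
        y, kept = map_samples_to_gradient(panel, oriented_gradient, seed_grid)
        fit = pls1_fit(panel.expression[kept], y, panel.gene_symbols)
        assert fit.r_scores_gradient >= 0.8
        k = panel.n_genes // 10
        top = set(panel.gene_symbols[np.argsort(-np.abs(fit.loadings))[:k]])
        frac = len(top & set(truth.tracking_genes)) / k
        assert frac >= 0.8

    def test_noiseless_tracking_gene_loads_unity(self, world, oriented_gradient):
        from seedgrad import synthetic

        _, _, seed_grid, _, truth = world
        panel = synthetic.make_expression_panel(truth, seed_grid, sigma=0.0, seed=881)
        # response = the planted sample latent itself: no mapping noise either
        import scipy.spatial.distance as ssd

        vox = ssd.cdist(panel.sample_coords_mm, seed_grid.coords_mm).argmin(axis=1)
        y = truth.latent[vox]
        fit = pls1_fit(panel.expression, y, panel.gene_symbols)
        # scores retain a small contribution from the background-noise genes,
        # so tracking loadings approach +/-1 without reaching it exactly
        for gene, beta in truth.tracking_genes.items():
            idx = list(panel.gene_symbols).index(gene)
            assert abs(fit.loadings[idx]) == pytest.approx(1.0, abs=5e-3)
            assert np.sign(fit.loadings[idx]) == np.sign(beta)
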