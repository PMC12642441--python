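"""Connectivity gradients: FC, sparsification, affinity, diffusion embedding,
Procrustes alignment, and dispersion summaries."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group, spearmanr

from medstates import gradients as gr
from medstates.simulate import population_hierarchy_correlation


def embed_pipeline(R, n_components=10):
    return gr.diffusion_map_embed(
        gr.cosine_affinity(gr.sparsify(R.copy(), 0.90)), n_components)


class TestFunctionalConnectivity:
    def test_duplicated_parcel_unit_correlation(self, rng):
        x = rng.standard_normal(50)
        data = np.vstack([x, x, rng.standard_normal(50)])
        R = gr.functional_connectivity(gr.ParcelSeries(data))
        assert R[0, 1] == pytest.approx(1.0)
        assert np.allclose(R, R.T, atol=1e-12)
        assert np.allclose(np.diag(R), 1.0)

    def test_independent_series_near_zero(self, rng):
        T = 2000
        R = gr.functional_connectivity(
            gr.ParcelSeries(rng.standard_normal((5, T))))
        off = R[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(T)

    def test_anticorrelated_pair(self, rng):
        x = rng.standard_normal(40)
        R = gr.functional_connectivity(gr.ParcelSeries(np.vstack([x, -x])))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_parcel_warns(self, rng):
        data = np.vstack([np.ones(30), rng.standard_normal(30)])
        with pytest.warns(UserWarning, match="zero-variance"):
            gr.functional_connectivity(gr.ParcelSeries(data))


class TestSparsify:
    def test_sparsity_zero_keeps_positives(self, rng):
        R = np.abs(rng.standard_normal((6, 6)))
        out = gr.sparsify(R, 0.0)
        off = ~np.eye(6, dtype=bool)
        assert np.array_equal(out[off], R[off])
        assert np.all(np.diag(out) == 0)

    def test_top_one_kept_at_90_percent(self):
        # each row of 9 off-diagonal values keeps ceil(0.1*9) = 1 entry
        R = np.zeros((10, 10))
        for i in range(10):
            vals = np.roll(np.arange(1.0, 10.0), i)
            R[i, [j for j in range(10) if j != i]] = vals
        out = gr.sparsify(R, 0.90)
        assert np.array_equal((out > 0).sum(axis=1), np.ones(10))
        for i in range(10):
            assert out[i].max() == 9.0

    def test_all_negative_gives_zero_matrix(self):
        R = -np.abs(np.random.default_rng(0).standard_normal((5, 5)))
        with pytest.warns(UserWarning):
            out = gr.sparsify(R, 0.5)
        assert not out.any()

    def test_ties_at_cutoff_all_kept(self):
        R = np.ones((5, 5))
        out = gr.sparsify(R, 0.75)  # cutoff value 1 is tied everywhere
        off = ~np.eye(5, dtype=bool)
        assert np.all(out[off] == 1.0)


class TestCosineAffinity:
    def test_identical_rows_unit_affinity(self):
        A = gr.cosine_affinity(np.tile([1.0, 2.0, 3.0], (4, 1)))
        assert np.allclose(A, 1.0)

    def test_orthogonal_rows_zero(self):
        A = gr.cosine_affinity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert A[0, 1] == pytest.approx(0.0)

    def test_45_degree_rows(self):
        A = gr.cosine_affinity(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert A[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-12)


class TestDiffusionEmbedding:
    def test_two_block_toy_signs_separate(self):
        # 12-node toy: two dense blocks bridged weakly; G1 splits the blocks
        n = 12
        A = np.full((n, n), 0.01)
        A[:6, :6] = 1.0
        A[6:, 6:] = 1.0
        np.fill_diagonal(A, 1.0)
        g = gr.diffusion_map_embed(A, 3)
        signs = np.sign(g.g1)
        assert len(set(signs[:6])) == 1 and len(set(signs[6:])) == 1
        assert signs[0] != signs[6]

    def test_permutation_equivariance(self, rng):
        R = population_hierarchy_correlation(30)
        A = gr.cosine_affinity(gr.sparsify(R, 0.8))
        perm = rng.permutation(30)
        g1 = gr.diffusion_map_embed(A, 3)
        g2 = gr.diffusion_map_embed(A[np.ix_(perm, perm)], 3)
        for j in range(3):
            a, b = g1.coordinates[perm, j], g2.coordinates[:, j]
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))

    def test_complete_graph_flagged_degenerate(self):
        g = gr.diffusion_map_embed(np.ones((8, 8)), 3)
        assert g.degenerate

    def test_disconnected_graph_rejected(self):
        A = np.eye(6)
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        with pytest.raises(gr.DisconnectedGraphError, match="2 components"):
            gr.diffusion_map_embed(A, 2)

    def test_scale_invariance_of_affinity(self):
        R = population_hierarchy_correlation(25)
        A = gr.cosine_affinity(gr.sparsify(R, 0.8))
        g1 = gr.diffusion_map_embed(A, 2)
        g2 = gr.diffusion_map_embed(3.7 * A, 2)
        assert np.allclose(g1.coordinates, g2.coordinates, atol=1e-8)

    def test_recovers_latent_hierarchy_order(self):
        R = population_hierarchy_correlation(60)
        g = embed_pipeline(R)
        rho = spearmanr(g.g1, np.linspace(-1, 1, 60)).statistic
        assert abs(rho) > 0.95


class TestTemplateAndAlignment:
    def test_template_of_single_matrix_matches_direct(self):
        R = population_hierarchy_correlation(30)
        t = gr.compute_template([R], 5)
        d = embed_pipeline(R, 5)
        assert np.allclose(t.coordinates, d.coordinates, atol=1e-10)

    def test_template_mean_of_two(self):
        R1 = population_hierarchy_correlation(30, 0.5)
        R2 = population_hierarchy_correlation(30, 1.0)
        t = gr.compute_template([R1, R2], 4)
        direct = embed_pipeline((R1 + R2) / 2, 4)
        assert np.allclose(t.coordinates, direct.coordinates, atol=1e-10)

    def test_rotated_copy_recovered(self, rng):
        template = embed_pipeline(population_hierarchy_correlation(40), 5)
        Q = special_ortho_group.rvs(5, random_state=1)
        rotated = gr.GradientSet(
            coordinates=(template.coordinates
                         - template.coordinates.mean(0)) @ Q,
            eigenvalues=template.eigenvalues)
        aligned = gr.procrustes_align(rotated, template)
        centered = template.coordinates - template.coordinates.mean(0)
        assert np.allclose(aligned.coordinates, centered, atol=1e-8)

    def test_self_alignment_identity_zero_disparity(self):
        t = embed_pipeline(population_hierarchy_correlation(30), 4)
        aligned = gr.procrustes_align(t, t)
        assert aligned.disparity == pytest.approx(0.0, abs=1e-8)

    def test_disparity_monotone_in_noise(self, rng):
        t = embed_pipeline(population_hierarchy_correlation(40), 4)
        disparities = []
        for sd in (0.001, 0.01, 0.05, 0.2, 1.0):
            noisy = gr.GradientSet(
                coordinates=t.coordinates + sd * rng.standard_normal(
                    t.coordinates.shape),
                eigenvalues=t.eigenvalues)
            disparities.append(gr.procrustes_align(noisy, t).disparity)
        assert all(np.diff(disparities) > 0)

    def test_aligned_components_positively_correlated_with_template(self, rng):
        t = embed_pipeline(population_hierarchy_correlation(40), 4)
        noisy = gr.GradientSet(
            coordinates=-t.coordinates + 0.1 * rng.standard_normal(
                t.coordinates.shape),
            eigenvalues=t.eigenvalues)
        aligned = gr.procrustes_align(noisy, t)
        for j in range(4):
            assert np.corrcoef(aligned.coordinates[:, j],
                               t.coordinates[:, j])[0, 1] >= 0


class TestSummaries:
    def test_network_average(self):
        g = gr.GradientSet(coordinates=np.array([[0.2], [0.4], [1.0]]),
                           eigenvalues=np.array([0.5]))
        nets = {1: "default", 2: "default", 3: "visual"}
        out = gr.network_average(g, nets)
        assert out["default"][0] == pytest.approx(0.3)
        assert out["visual"][0] == pytest.approx(1.0)

    def test_dispersion_homogeneity(self, rng):
        coords = rng.standard_normal((20, 3))
        g = gr.GradientSet(coordinates=coords, eigenvalues=np.array([3., 2., 1.]))
        h = gr.GradientSet(coordinates=0.5 * coords,
                           eigenvalues=np.array([3., 2., 1.]))
        r1, s1 = gr.gradient_dispersion(g, 1)
        r2, s2 = gr.gradient_dispersion(h, 1)
        assert r2 == pytest.approx(0.5 * r1)
        assert s2 == pytest.approx(0.5 * s1)

    def test_constant_component_zero_dispersion(self):
        g = gr.GradientSet(coordinates=np.ones((10, 2)),
                           eigenvalues=np.array([2.0, 1.0]))
        assert gr.gradient_dispersion(g, 1) == (0.0, 0.0)
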