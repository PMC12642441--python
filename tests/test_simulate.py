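"""Generator contracts: determinism, ground-truth bookkeeping, and the
planted-effect constructions each downstream stage relies on."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from medstates import reho as rh
from medstates import simulate as sim
from medstates.gradients import (cosine_affinity, diffusion_map_embed,
                                 gradient_dispersion, sparsify)
from medstates.io import STATES


def small_spec(**kw):
    defaults = dict(n_participants=3, grid=(6, 6, 6), parcel_grid=(3, 1, 1),
                    t_per_segment=24, seed=11)
    defaults.update(kw)
    return sim.SimulationSpec(**defaults)


class TestSpecValidation:
    def test_bad_compression(self):
        with pytest.raises(ValueError):
            small_spec(gradient_compression={"J1": 0.0})

    def test_bad_missing_rate(self):
        with pytest.raises(ValueError):
            small_spec(missing_rate=0.9)

    def test_degenerate_grid(self):
        with pytest.raises(ValueError):
            small_spec(grid=(4, 6, 6))


class TestRehoGenerator:
    def test_seed_determinism(self):
        a = sim.generate_reho_dataset(small_spec())[0]
        b = sim.generate_reho_dataset(small_spec())[0]
        key = next(iter(a))
        assert np.array_equal(a[key].data, b[key].data)
        c = sim.generate_reho_dataset(small_spec(seed=12))[0]
        assert not np.array_equal(a[key].data, c[key].data)

    def test_full_mixing_gives_reho_one(self):
        spec = small_spec(base_weight_logit=40.0,
                          trend_map={"anterior": (0, 0, 0),
                                     "midline": (0, 0, 0),
                                     "posterior": (0, 0, 0)})
        images, parc, _, _ = sim.generate_reho_dataset(spec)
        img = images[("sub01", "counting")]
        result = rh.compute_reho(img)
        labels = parc.labels
        interior = np.zeros(labels.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        # interior voxels of parcel interiors share one series exactly
        for pid in parc.parcel_ids:
            sel = (labels == pid) & interior
            core = sel & ~_touches_other_parcel(labels, pid)
            if core.any():
                assert np.allclose(result.values[core], 1.0, atol=1e-12)

    def test_ground_truth_signs_recorded(self):
        _, parc, _, truth = sim.generate_reho_dataset(small_spec())
        for pid, group in truth.parcel_groups.items():
            assert np.sign(truth.parcel_trends[pid][0]) == \
                {"anterior": -1, "midline": 0, "posterior": 1}[group]

    def test_zero_mixing_mean_reho_matches_independence_oracle(self, rng):
        # brute-force oracle: E[W] for 27 independent series of length T
        T = 40
        oracle = np.mean([
            rh.kendalls_w(rng.standard_normal((27, T))) for _ in range(400)])
        spec = small_spec(base_weight_logit=-40.0, t_per_segment=T,
                          trend_map={g: (0, 0, 0) for g in
                                     ("anterior", "midline", "posterior")})
        images, _, _, _ = sim.generate_reho_dataset(spec)
        result = rh.compute_reho(images[("sub01", "counting")])
        interior = np.full(result.values.shape, False)
        interior[1:-1, 1:-1, 1:-1] = True
        got = np.nanmean(result.values[interior])
        assert got == pytest.approx(oracle, abs=0.01)

    def test_mixing_weight_monotone_in_linear_coefficient(self):
        W1, _, _ = sim.mixing_weights(small_spec(
            trend_map={"posterior": (0.5, 0, 0)}))
        W2, _, _ = sim.mixing_weights(small_spec(
            trend_map={"posterior": (1.5, 0, 0)}))
        # larger planted slope -> larger weight spread across states
        assert (W2.max(axis=1) - W2.min(axis=1)).max() > \
            (W1.max(axis=1) - W1.min(axis=1)).max()


def _touches_other_parcel(labels, pid):
    from scipy.ndimage import binary_dilation
    other = (labels != pid)
    return binary_dilation(other, np.ones((3, 3, 3), bool))


class TestGradientGenerator:
    def test_same_generator_for_unit_compression(self):
        spec = small_spec(n_parcels_gradient=40, t_per_segment=200)
        series, _, truth = sim.generate_gradient_dataset(spec)
        assert all(a == 1.0 for a in truth.hierarchy_mixing.values())

    def test_noiseless_matrix_compression_ratio(self):
        # the calibration contract, checked on the population matrices
        spec = small_spec(n_parcels_gradient=60,
                          gradient_compression={s: 0.5 for s in STATES})
        _, _, truth = sim.generate_gradient_dataset(spec)
        K = sim.population_hierarchy_correlation(60, spec.hierarchy_lengthscale)
        rng = np.random.default_rng(spec.seed_tree("gradients/perm"))
        perm = rng.permutation(60)

        def emb_range(R):
            g = diffusion_map_embed(cosine_affinity(sparsify(R, 0.9)), 10)
            return gradient_dispersion(g, 1)[0]

        a = truth.hierarchy_mixing["J1"]
        R_state = sim._flattened_correlation(K, perm, a)
        assert emb_range(R_state) / emb_range(K) == pytest.approx(0.5, abs=0.05)

    def test_two_block_structure_separates(self):
        g = np.array([-1.0] * 10 + [1.0] * 10)
        R = sim.population_hierarchy_correlation(20, 0.5, coordinates=g)
        emb = diffusion_map_embed(cosine_affinity(sparsify(R, 0.5)), 2)
        signs = np.sign(emb.g1)
        assert len(set(signs[:10])) == 1 and signs[0] != signs[10]

    def test_latent_order_recovered_from_series(self):
        spec = small_spec(n_parcels_gradient=40, t_per_segment=400)
        series, _, truth = sim.generate_gradient_dataset(spec)
        from medstates.gradients import ParcelSeries, functional_connectivity
        R = functional_connectivity(ParcelSeries(series[("sub01", "counting")]))
        emb = diffusion_map_embed(cosine_affinity(sparsify(R, 0.9)), 5)
        rho = spearmanr(emb.g1, truth.latent_coordinates).statistic
        assert abs(rho) > 0.9


class TestMeshAndModes:
    @pytest.mark.parametrize("sub,verts", [(1, 42), (2, 162)])
    def test_icosphere_vertex_count(self, sub, verts):
        assert len(sim.generate_mesh("icosphere", sub).vertices) == verts

    def test_single_mode_recovery(self, sphere2_basis):
        *_, basis = sphere2_basis
        schedule = np.zeros((5, 8))
        schedule[3, :] = 1.0
        data, truth = sim.generate_mode_timeseries(basis, schedule,
                                                   noise_sd=0.0, seed=0)
        from medstates.eigenmodes import project_timeseries, spectra
        s = spectra(project_timeseries(data["J1"], basis), basis)
        mean_power = s.power.mean(axis=1)
        assert mean_power[3] > 0.5
        assert np.abs(np.delete(mean_power[:5], 3)).max() < 1e-8

    def test_u_shaped_schedule_recovered_as_positive_quadratic(self):
        from medstates.trends import orthogonal_poly_codes
        a = sim.DEFAULT_MODE_AMPLITUDES
        codes = orthogonal_poly_codes(8, 2)
        beta = codes.T @ np.log10(a)
        assert beta[1] > 0  # planted U-shape has positive quadratic trend

    def test_noise_only_flat_power(self, sphere2_basis):
        *_, basis = sphere2_basis
        schedule = np.zeros((5, 8))
        data, _ = sim.generate_mode_timeseries(basis, schedule, noise_sd=1.0,
                                               seed=1, t_per_segment=200)
        from medstates.eigenmodes import project_timeseries
        means = [np.abs(project_timeseries(data[s], basis).coefficients).mean()
                 for s in STATES]
        assert np.std(means) / np.mean(means) < 0.1


class TestBehaviorGenerator:
    def _brain(self, rng, n=40, p=6):
        return rng.standard_normal((n, p))

    def test_perfect_coupling_latent_r_one(self, rng):
        from medstates.brain_behavior import plsc_fit
        spec = small_spec(latent_correlation=1.0, noise_sd=0.0,
                          missing_rate=0.0)
        X = self._brain(rng)
        tables, truth = sim.generate_behavior_tables(spec, X,
                                                     discretize=False)
        fit = plsc_fit(X, tables["phenomenology"].to_numpy(float))
        assert fit.latent_r[0] == pytest.approx(1.0, abs=1e-6)

    def test_missing_count_near_expectation(self, rng):
        spec = small_spec(missing_rate=0.1)
        tables, _ = sim.generate_behavior_tables(
            spec, self._brain(rng, n=20), n_columns={"phenomenology": 12})
        n_missing = tables["phenomenology"].isna().sum().sum()
        assert 10 <= n_missing <= 40  # ~24 expected at 10% of 240 cells

    def test_phenomenology_integer_likert_range(self, rng):
        spec = small_spec(missing_rate=0.0)
        tables, _ = sim.generate_behavior_tables(spec, self._brain(rng))
        vals = tables["phenomenology"].to_numpy(float)
        assert np.all(vals >= 1) and np.all(vals <= 10)
        assert np.allclose(vals, np.rint(vals))

    def test_row_misalignment_rejected(self, rng):
        spec = small_spec()
        with pytest.raises(ValueError):
            sim.generate_behavior_tables(spec, self._brain(rng, n=10),
                                         row_keys=pd.DataFrame({"k": [1, 2]}))


class TestTermLibrary:
    def test_size_and_planted_first(self, rng):
        target = rng.standard_normal(400)
        lib, truth = sim.generate_term_library(
            123, 400, planted=("planted", target, 0.9), seed=0)
        assert len(lib) == 123
        assert truth.planted_term == "planted"

    def test_r_target_validation(self, rng):
        with pytest.raises(ValueError):
            sim.generate_term_library(5, 100,
                                      planted=("x", rng.standard_normal(100),
                                               1.5), seed=0)

    def test_determinism(self, rng):
        t = rng.standard_normal(100)
        a, _ = sim.generate_term_library(5, 100, planted=("x", t, 0.7), seed=3)
        b, _ = sim.generate_term_library(5, 100, planted=("x", t, 0.7), seed=3)
        assert np.array_equal(a.maps, b.maps)
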