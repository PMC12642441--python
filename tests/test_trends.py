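"""Mixed-model state trends: orthogonal codes, REML engine (cross-checked
against statsmodels), iterative degree reduction, contrasts, and FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi

from medstates import trends as tr
from medstates.trends import _reml_random_intercept


class TestOrthogonalCodes:
    def test_n4_linear_contrast(self):
        codes = tr.orthogonal_poly_codes(4, 1)
        expected = np.array([-3, -1, 1, 3]) / np.sqrt(20)
        assert np.allclose(codes.ravel(), expected, atol=1e-12)

    @pytest.mark.parametrize("n,deg", [(4, 3), (8, 3), (10, 5)])
    def test_columns_orthonormal_zero_sum(self, n, deg):
        codes = tr.orthogonal_poly_codes(n, deg)
        assert np.allclose(codes.T @ codes, np.eye(deg), atol=1e-12)
        assert np.allclose(codes.sum(axis=0), 0.0, atol=1e-12)

    def test_degree_must_be_below_levels(self):
        with pytest.raises(ValueError):
            tr.orthogonal_poly_codes(4, 4)


class TestRemlEngine:
    def _sim(self, rng, n_part=15, n_s=8, beta=(2.0, -1.2, 0.0), sd_u=0.8,
             sd_e=0.5):
        codes = tr.orthogonal_poly_codes(n_s, 3)
        u = sd_u * rng.standard_normal(n_part)
        y = (codes[:, :3] @ np.array(beta))[None, :] + u[:, None] \
            + sd_e * rng.standard_normal((n_part, n_s))
        lev = np.tile(np.arange(n_s), n_part)
        part = np.repeat(np.arange(n_part), n_s)
        X = np.column_stack([np.ones(y.size), codes[lev, :3]])
        return X, y.ravel(), part

    def test_matches_statsmodels_mixedlm(self, rng):
        X, y, part = self._sim(rng)
        beta, cov, s_u2, s_e2 = _reml_random_intercept(X, y, part)
        ref = smapi.MixedLM(y, X, groups=part).fit(reml=True)
        assert np.allclose(beta, ref.fe_params, atol=1e-5)
        assert np.allclose(np.sqrt(np.diag(cov)), ref.bse_fe, atol=1e-4)
        assert s_u2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                     abs=1e-3)
        assert s_e2 == pytest.approx(ref.scale, abs=1e-3)

    def test_zero_group_variance_equals_ols(self, rng):
        X, y, part = self._sim(rng, sd_u=0.0, sd_e=1.0)
        beta, *_ = _reml_random_intercept(X, y, part)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, beta_ols, atol=1e-6)


class TestTrendFit:
    def test_exact_linear_recovery_drops_higher_degrees(self, rng):
        codes = tr.orthogonal_poly_codes(8, 1)
        offsets = rng.standard_normal(10)
        Y = 2.0 * codes[:, 0][None, :] + offsets[:, None]
        res = tr.fit_trend_lmm(Y, max_degree=3)
        assert res.retained_degree == 1
        assert res.beta[0] == pytest.approx(2.0, abs=1e-8)

    def test_planted_quadratic_sign_recovered(self, rng):
        codes = tr.orthogonal_poly_codes(8, 2)
        hits = 0
        for _ in range(50):
            Y = (-1.0 * codes[:, 1])[None, :] \
                + 0.5 * rng.standard_normal((20, 8)) \
                + rng.standard_normal(20)[:, None]
            res = tr.fit_trend_lmm(Y, max_degree=3)
            if res.retained_degree >= 2 and res.beta[1] < 0:
                hits += 1
        assert hits >= 47

    def test_null_rejection_rate_near_alpha(self, rng):
        # fraction of metrics with a significant linear term ~ alpha
        sig = sum(tr.fit_trend_lmm(rng.standard_normal((12, 8))).p[0] < 0.05
                  for _ in range(300))
        assert 0.02 < sig / 300 < 0.09  # binomial 95% band around 0.05

    def test_affine_state_relabeling_leaves_t_unchanged(self, rng):
        # orthonormal codes make t statistics invariant to affine level maps,
        # which is what polynomial contrasts over an ordered factor encode
        Y = rng.standard_normal((10, 8)) + np.linspace(0, 1, 8)
        t1 = tr.fit_trend_lmm(Y, max_degree=2).t
        t2 = tr.fit_trend_lmm(Y[:, ::-1], max_degree=2).t
        assert np.allclose(np.abs(t1), np.abs(t2), atol=1e-6)

    def test_long_dataframe_input(self, rng):
        df = pd.DataFrame({
            "participant": np.repeat(np.arange(6), 8),
            "state": np.tile(np.arange(1, 9), 6),
            "value": rng.standard_normal(48),
        })
        res = tr.fit_trend_lmm(df)
        assert res.retained_degree in (1, 2, 3)


class TestAveragingAndControls:
    def test_session_mean(self):
        rows = pd.DataFrame({
            "participant": ["a", "a", "b"],
            "condition": ["J1", "J1", "J1"],
            "metric": ["m", "m", "m"],
            "session": [1, 2, 1],
            "value": [3.0, 5.0, 7.0],
        })
        out = tr.average_sessions(rows)
        assert out.loc[out["participant"] == "a", "value"].item() == 4.0
        assert out.loc[out["participant"] == "b", "value"].item() == 7.0

    def test_composite_control_mean(self):
        rows = pd.DataFrame({
            "participant": ["a", "a"],
            "condition": ["counting", "memory"],
            "metric": ["m", "m"],
            "value": [1.0, 3.0],
        })
        out = tr.composite_control(rows)
        comp = out[out["condition"] == "control"]
        assert comp["value"].item() == 2.0
        assert set(out["condition"]) == {"counting", "memory", "control"}

    def test_single_control_passes_with_warning(self):
        rows = pd.DataFrame({
            "participant": ["a"],
            "condition": ["counting"],
            "metric": ["m"],
            "value": [1.5],
        })
        with pytest.warns(UserWarning):
            out = tr.composite_control(rows)
        assert out[out["condition"] == "control"]["value"].item() == 1.5


class TestContrasts:
    def _table(self, rng, shift=None, n_part=12, sd=0.5):
        conds = ["control"] + [f"J{i}" for i in range(1, 9)]
        rows = []
        for p in range(n_part):
            base = rng.standard_normal()
            for c in conds:
                delta = (shift or {}).get(c, 0.0)
                rows.append({"participant": p, "condition": c,
                             "value": base + delta + sd * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_equal_means_no_significant_contrast(self, rng):
        res = tr.fit_condition_contrasts(self._table(rng))
        assert np.all(res.q_within > 0.05) or np.abs(res.estimates).max() < 0.5

    def test_planted_shift_detected_in_right_states(self, rng):
        hits = 0
        for _ in range(30):
            res = tr.fit_condition_contrasts(
                self._table(rng, shift={"J7": 1.0, "J8": 1.0}))
            idx = {c: i for i, c in enumerate(res.contrast_conditions)}
            ok = (res.q_within[idx["J7"]] < 0.05
                  and res.q_within[idx["J8"]] < 0.05
                  and all(res.q_within[idx[f"J{k}"]] > 0.05
                          for k in range(1, 7)))
            hits += ok
        assert hits >= 27

    def test_balanced_emm_equals_raw_means(self, rng):
        table = self._table(rng)
        res = tr.fit_condition_contrasts(table)
        raw = table.groupby("condition")["value"].mean()
        for c, emm in zip(res.conditions, res.emmeans):
            assert emm == pytest.approx(raw[c], abs=1e-8)

    def test_control_vs_control_identical_zero(self, rng):
        vals = rng.standard_normal(10)
        table = pd.DataFrame({
            "participant": np.tile(np.arange(10), 2),
            "condition": ["counting"] * 10 + ["memory"] * 10,
            "value": np.concatenate([vals, vals]),
        })
        out = tr.control_vs_control(table)
        assert out["estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_control_difference_detected(self, rng):
        detected = 0
        for _ in range(20):
            base = rng.standard_normal(15)
            table = pd.DataFrame({
                "participant": np.tile(np.arange(15), 2),
                "condition": ["counting"] * 15 + ["memory"] * 15,
                "value": np.concatenate([
                    base + 0.5 * rng.standard_normal(15),
                    base + 1.0 + 0.5 * rng.standard_normal(15)]),
            })
            detected += tr.control_vs_control(table)["p"] < 0.05
        assert detected >= 18


class TestFdr:
    def test_hand_bh_example(self):
        q = tr.fdr_adjust(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(q, [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert tr.fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(tr.fdr_adjust(np.ones(5)), 1.0)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.random(50)
        q = tr.fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_nan_passthrough(self):
        q = tr.fdr_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            tr.fdr_adjust(np.array([0.5, 1.2]))
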