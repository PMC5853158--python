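"""Estimator correctness: closed-form examples, independent oracles and
equivariance properties."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

import gliomamr as g
from conftest import make_instruments

LN2 = math.log(2)


def _inst(x, sx, y, sy):
    return [
        g.HarmonisedInstrument(f"s{i}", xi, sxi, yi, syi)
        for i, (xi, sxi, yi, syi) in enumerate(zip(x, sx, y, sy))
    ]


class TestWaldRatio:
    def test_direct_arithmetic(self):
        r = g.wald_ratio(g.HarmonisedInstrument("s", 0.5, 0.1, 0.25, 0.1))
        assert r.theta == 0.5
        assert r.se_theta == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        r = g.wald_ratio(g.HarmonisedInstrument("s", 0.5, 0.1, 0.0, 0.1))
        assert r.theta == 0.0

    def test_fixture_row_rs1837253(self, harmonised):
        inst = next(i for i in harmonised["asthma_hayfever"] if i.snp_id == "rs1837253")
        r = g.wald_ratio(inst)
        assert r.theta == pytest.approx(-0.2600065, abs=1e-6)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            g.wald_ratio(g.HarmonisedInstrument("s", 0.0, 0.1, 0.1, 0.1))

    def test_second_order_se_is_larger(self):
        i = g.HarmonisedInstrument("s", 0.5, 0.1, 0.25, 0.1)
        assert g.wald_ratio(i, second_order=True).se_theta > g.wald_ratio(i).se_theta


class TestIvw:
    def test_exact_proportional_data(self):
        est = g.ivw(_inst([0.5, 1.0], [0.1, 0.1], [0.25, 0.5], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.5, abs=1e-15)
        assert est.se == pytest.approx(math.sqrt(0.008), abs=1e-15)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            g.ivw(_inst([0.5], [0.1], [0.25], [0.1]))

    def test_equals_origin_wls(self, harmonised):
        """IVW must equal weighted least squares of Y on X through the origin
        with weights sigma_Y^-2 (independent statsmodels route)."""
        for inst in harmonised.values():
            x = np.array([i.x for i in inst])
            y = np.array([i.y for i in inst])
            sy = np.array([i.sigma_y for i in inst])
            fit = sm.WLS(y, x[:, None], weights=sy**-2).fit()
            est = g.ivw(inst)
            assert est.beta == pytest.approx(float(fit.params[0]), rel=1e-10)

    def test_equals_fixed_effect_meta_of_ratios(self, harmonised):
        """IVW must equal a fixed-effect inverse-variance meta-analysis of
        the Wald ratios with first-order SEs."""
        for inst in harmonised.values():
            ratios = [g.wald_ratio(i) for i in inst]
            w = np.array([r.se_theta**-2 for r in ratios])
            t = np.array([r.theta for r in ratios])
            pooled = np.sum(w * t) / np.sum(w)
            pooled_se = math.sqrt(1 / np.sum(w))
            est = g.ivw(inst)
            assert est.beta == pytest.approx(pooled, rel=1e-10)
            assert est.se == pytest.approx(pooled_se, rel=1e-10)


class TestMle:
    def test_zero_noise_recovery(self):
        x = np.array([0.2, 0.3, 0.4, 0.5])
        beta = 0.7
        inst = _inst(x, [0.05] * 4, beta * x, [0.05] * 4)
        est = g.mle(inst)
        assert est.beta == pytest.approx(beta, abs=1e-8)

    def test_ivw_limit_as_exposure_se_vanishes(self, synth):
        tiny = [
            g.HarmonisedInstrument(i.snp_id, i.x, 1e-6 * i.sigma_y, i.y, i.sigma_y)
            for i in synth
        ]
        assert g.mle(tiny).beta == pytest.approx(g.ivw(tiny).beta, abs=1e-4)

    def test_invalid_rho_rejected(self, synth):
        with pytest.raises(ValueError):
            g.mle(synth, rho=1.0)

    def test_rho_zero_entry_of_sensitivity_equals_plain_mle(self, synth):
        tab = g.rho_sensitivity(synth, [-0.1, 0.0, 0.1])
        plain = g.mle(synth)
        row = tab[tab.rho == 0.0].iloc[0]
        assert row.beta == pytest.approx(plain.beta, abs=1e-12)
        assert list(tab.rho) == sorted(tab.rho)

    def test_sensitivity_p_symmetric_on_symmetric_toy_data(self):
        # with symmetric X/Y configuration the p-curve is symmetric in rho
        x = np.array([0.3, 0.3, -0.3, -0.3])
        y = np.array([0.1, -0.1, 0.1, -0.1])
        inst = _inst(x, [0.05] * 4, y, [0.05] * 4)
        tab = g.rho_sensitivity(inst, [-0.2, 0.2])
        assert tab.p_value.iloc[0] == pytest.approx(tab.p_value.iloc[1], rel=1e-6)

    def test_empty_grid_rejected(self, synth):
        with pytest.raises(ValueError):
            g.rho_sensitivity(synth, [])


class TestWeightedMedian:
    def test_equal_weights_is_sample_median(self):
        inst = _inst([1, 1, 1], [0.1] * 3, [0.1, 0.2, 0.9], [0.1] * 3)
        est = g.weighted_median(inst, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_weight_pull_matches_percentile_oracle(self):
        # weights (0.9, 0.05, 0.05) on ratios (0.1, 0.2, 0.9): interpolated
        # weighted 50th percentile evaluated directly gives 0.110526...
        sy = 1 / np.sqrt(np.array([0.9, 0.05, 0.05]))
        inst = _inst([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.9], sy)
        est = g.weighted_median(inst, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.11052631578947368, abs=1e-12)

    def test_bootstrap_reproducible_for_fixed_seed(self, synth):
        a = g.weighted_median(synth, n_boot=200, seed=7)
        b = g.weighted_median(synth, n_boot=200, seed=7)
        c = g.weighted_median(synth, n_boot=200, seed=8)
        assert a.se == b.se
        assert a.se != c.se
        assert a.beta == c.beta  # point estimate independent of the seed

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            g.weighted_median(_inst([1, 1], [0.1] * 2, [0.1, 0.2], [0.1] * 2))


class TestModeBased:
    def test_point_mass(self):
        inst = _inst([1, 1, 1], [0.1] * 3, [0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
        est = g.mode_based(inst, n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.4, abs=1e-9)

    def test_majority_cluster_matches_grid_oracle(self, rng):
        thetas = np.concatenate([rng.normal(0.0, 0.02, 8), [1.0, 1.05]])
        inst = _inst(np.ones(10), [0.01] * 10, thetas, [0.1] * 10)
        est = g.mode_based(inst, n_boot=20, seed=1)
        # independent fine-grid argmax of the same weighted kernel density
        w = np.full(10, (0.1 / 1.0) ** -2)
        w = w / w.sum()
        sd = np.std(thetas, ddof=1)
        mad = 1.4826022185056018 * np.median(np.abs(thetas - np.median(thetas)))
        h = 0.9 * min(sd, mad) * 10 ** (-0.2)
        grid = np.linspace(thetas.min() - 3 * h, thetas.max() + 3 * h, 200001)
        dens = (np.exp(-0.5 * ((grid[:, None] - thetas) / h) ** 2) @ w)
        oracle = grid[np.argmax(dens)]
        assert abs(est.beta - oracle) < 1e-4
        assert abs(est.beta) < 0.1  # inside the majority cluster

    def test_phi_validation(self, synth):
        with pytest.raises(ValueError):
            g.mode_based(synth, phi=0.0)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            g.mode_based(_inst([1, 1], [0.1] * 2, [0.1, 0.2], [0.1] * 2))


class TestEgger:
    def test_exact_linear_fit(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        c, beta = 0.05, 0.6
        inst = _inst(x, [0.02] * 4, c + beta * x, [0.05] * 4)
        res = g.egger(inst)
        assert res.intercept.beta == pytest.approx(c, abs=1e-10)
        assert res.slope.beta == pytest.approx(beta, abs=1e-10)

    def test_zero_intercept_constraint_reproduces_ivw(self, synth):
        x = np.array([i.x for i in synth])
        y = np.array([i.y for i in synth])
        sy = np.array([i.sigma_y for i in synth])
        sign = np.where(x < 0, -1, 1)
        fit = sm.WLS(y * sign, (x * sign)[:, None], weights=sy**-2).fit()
        assert float(fit.params[0]) == pytest.approx(g.ivw(synth).beta, rel=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            g.egger(_inst([1, 1], [0.1] * 2, [0.1, 0.2], [0.1] * 2))


class TestPerDoubling:
    def test_null_maps_to_or_one(self):
        est = g.MREstimate("ivw", 0.0, 0.1, 1.0, 5)
        assert g.per_doubling(est).odds_ratio == 1.0

    def test_unit_beta_maps_to_or_two(self):
        est = g.MREstimate("ivw", 1.0, 0.1, 0.001, 5)
        assert g.per_doubling(est).odds_ratio == pytest.approx(2.0, abs=1e-12)

    def test_closed_form_example(self):
        # beta -0.06 maps to OR 0.959 per doubling; CI bounds scale by ln 2,
        # so a raw bound of -0.105 maps to 0.930 and -0.001 to 0.999
        se = (0.105 - 0.001) / (2 * 1.959963984540054)
        est = g.MREstimate("ivw", -0.06, se, 0.05, 5)
        conv = g.per_doubling(est)
        assert conv.odds_ratio == pytest.approx(0.95926, abs=5e-4)
        assert conv.ci_lower == pytest.approx(est.ci_lower * LN2, rel=1e-12)
        assert conv.ci_upper == pytest.approx(est.ci_upper * LN2, rel=1e-12)
        assert math.exp(-0.105 * LN2) == pytest.approx(0.930, abs=1e-3)
        assert math.exp(-0.001 * LN2) == pytest.approx(0.999, abs=1e-3)

    def test_idempotent_and_preserves_p(self):
        est = g.MREstimate("ivw", -0.1, 0.03, 0.02, 5)
        once = g.per_doubling(est)
        assert g.per_doubling(once) == once
        assert once.p_value == est.p_value


ALL_METHODS = ("ivw", "mle", "wme", "mbe", "egger")


def _estimate(method, inst):
    if method == "ivw":
        return g.ivw(inst)
    if method == "mle":
        return g.mle(inst)
    if method == "wme":
        return g.weighted_median(inst, n_boot=100, seed=3)
    if method == "mbe":
        return g.mode_based(inst, n_boot=100, seed=3)
    return g.egger(inst).slope


class TestEquivariance:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_sign_equivariance(self, synth, method):
        """Negating every Y negates beta; deterministic SEs are unchanged."""
        flipped = [
            g.HarmonisedInstrument(i.snp_id, i.x, i.sigma_x, -i.y, i.sigma_y)
            for i in synth
        ]
        a = _estimate(method, synth)
        b = _estimate(method, flipped)
        assert b.beta == pytest.approx(-a.beta, rel=1e-6, abs=1e-9)
        if method in ("ivw", "mle", "egger"):
            assert b.se == pytest.approx(a.se, rel=1e-6)
            assert b.p_value == pytest.approx(a.p_value, rel=1e-6, abs=1e-12)
        else:  # bootstrap SEs: different draws, same distribution
            assert b.se == pytest.approx(a.se, rel=0.3)

    @pytest.mark.parametrize("method", ALL_METHODS)
    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_equivariance(self, synth, method, c):
        """Multiplying all X by c > 0 divides the causal estimate by c."""
        scaled = [
            g.HarmonisedInstrument(i.snp_id, c * i.x, c * i.sigma_x, i.y, i.sigma_y)
            for i in synth
        ]
        a = _estimate(method, synth)
        b = _estimate(method, scaled)
        assert b.beta == pytest.approx(a.beta / c, rel=1e-5, abs=1e-8)


class TestParameterRecovery:
    def test_all_methods_recover_truth_over_replicates(self):
        """On instruments simulated with a known causal slope and independent
        normal noise, every estimator's mean over 200 replicates must lie
        within 3 Monte-Carlo SEs of the truth."""
        rng = np.random.default_rng(2024)
        truth = 0.25
        results = {m: [] for m in ALL_METHODS}
        for _ in range(200):
            inst = make_instruments(rng, k=15, beta=truth)
            for m in ALL_METHODS:
                if m == "wme":
                    est = g.weighted_median(inst, n_boot=10, seed=1)
                elif m == "mbe":
                    est = g.mode_based(inst, n_boot=10, seed=1)
                else:
                    est = _estimate(m, inst)
                results[m].append(est.beta)
        for m, vals in results.items():
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - truth) < 3 * mc_se, (m, vals.mean(), mc_se)
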