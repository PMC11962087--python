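"""Unit and property tests for the error-rate theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from lpbarcode import (
    DiscretePalette,
    JointBarcodeDistribution,
    NoiseModel,
    SpectralDistribution,
    TaggingMixture,
)
from lpbarcode import theory
from lpbarcode.theory import (
    approx_unique_barcodes,
    count_unique_barcodes,
    duplicate_rate_continuous,
    duplicate_rate_discrete,
    duplicate_loss,
    effective_barcodes,
    max_pool_size,
    min_unique_barcodes,
    mixture_error_rates,
    n_distinguishable_colors,
    noise_error,
    optimize_delta,
    solve_delta_for_noise,
    total_error,
)


class TestDiscreteCounting:
    @pytest.mark.parametrize("l,m,expected", [(100, 3, 161700), (5, 5, 1),
                                              (10, 1, 10)])
    def test_binomial_count(self, l, m, expected):
        assert count_unique_barcodes(DiscretePalette(l, m)) == expected

    def test_approximation(self):
        assert approx_unique_barcodes(DiscretePalette(100, 3)) == pytest.approx(
            166666.67, rel=1e-6)

    def test_l_smaller_than_m_rejected(self):
        with pytest.raises(ValueError):
            count_unique_barcodes(DiscretePalette(2, 3))

    def test_color_count_from_wavelength_binning(self):
        assert n_distinguishable_colors(1150.0, 1650.0, 1.0) == 500


class TestDuplicateRateDiscrete:
    def test_single_cell_never_duplicates(self):
        assert duplicate_rate_discrete(10**6, 1) == 0.0

    def test_one_barcode_two_cells(self):
        assert duplicate_rate_discrete(1, 2) == 1.0

    def test_reference_value(self):
        # 1 - (1 - 1e-6)^9999
        assert duplicate_rate_discrete(10**6, 10**4) == pytest.approx(
            0.0099492, rel=1e-4)

    def test_approx_form(self):
        assert duplicate_rate_discrete(10**6, 10**4, exact=False) == \
            pytest.approx(0.01)


class TestMinUniqueBarcodes:
    def test_planning_approximation(self):
        assert min_unique_barcodes(10**4, 0.01) == 10**6

    def test_exact_form_solution(self):
        b = min_unique_barcodes(10**4, 0.01, exact=True)
        assert 9.9e5 < b < 1.0e6
        # plugging the returned B back yields a rate within tolerance
        assert duplicate_rate_discrete(b, 10**4) <= 0.01
        assert duplicate_rate_discrete(b - 1, 10**4) > 0.01

    def test_loose_tolerance_needs_almost_no_barcodes(self):
        # at N=2 the exact rate is 1/B, so even B=2 meets a generous budget
        assert min_unique_barcodes(2, 0.99, exact=True) == 2
        assert duplicate_rate_discrete(2, 2) <= 0.99

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            min_unique_barcodes(10**4, 1.0)


class TestEffectiveBarcodes:
    @pytest.mark.parametrize("delta_big,delta,m,expected", [
        (100.0, 0.5, 3, 166666.67),
        (100.0, 0.5, 1, 100.0),
        (300.0, 0.5, 3, 4.5e6),
    ])
    def test_formula(self, delta_big, delta, m, expected):
        dist = SpectralDistribution.uniform(delta_big)
        assert effective_barcodes(dist, delta, m) == pytest.approx(expected,
                                                                   rel=1e-6)

    def test_non_uniform_unsupported(self):
        g = SpectralDistribution.gaussian(sigma=10.0)
        with pytest.raises(ValueError):
            effective_barcodes(g, 0.5, 3)


class TestDuplicateRateContinuous:
    def test_uniform_closed_form(self, joint_uniform100):
        rate, se = duplicate_rate_continuous(joint_uniform100, 3, 0.5, 10**4)
        b_eff = effective_barcodes(joint_uniform100.base, 0.5, 3)
        expected = 1.0 - (1.0 - 1.0 / b_eff) ** 9999
        assert se == 0.0
        assert rate == pytest.approx(expected, rel=1e-12)
        assert rate == pytest.approx(0.0583, rel=2e-3)

    def test_single_cell(self, joint_gauss100):
        assert duplicate_rate_continuous(joint_gauss100, 3, 0.5, 1, seed=0) \
            == (0.0, 0.0)

    def test_mc_path_matches_closed_form_for_uniform(self, joint_uniform100):
        # the integrand is constant under a uniform density, so the
        # Monte-Carlo average reproduces the closed form to float precision
        exact, _ = duplicate_rate_continuous(joint_uniform100, 3, 0.5, 10**4)
        mc, se = duplicate_rate_continuous(joint_uniform100, 3, 0.5, 10**4,
                                           seed=1, force_mc=True)
        assert mc == pytest.approx(exact, rel=1e-12)

    def test_monotone_in_n_and_delta(self, joint_uniform100):
        r1, _ = duplicate_rate_continuous(joint_uniform100, 3, 0.5, 10**3)
        r2, _ = duplicate_rate_continuous(joint_uniform100, 3, 0.5, 10**4)
        r3, _ = duplicate_rate_continuous(joint_uniform100, 3, 1.0, 10**4)
        assert r1 <= r2 <= r3

    def test_invalid_inputs(self, joint_uniform100):
        with pytest.raises(ValueError):
            duplicate_rate_continuous(joint_uniform100, 3, -0.5, 10)
        with pytest.raises(ValueError):
            duplicate_rate_continuous(joint_uniform100, 3, 0.5, 0)

    def test_dual_mode_theory_matches_pool_counting(self, uniform100,
                                                    pool_from_matrix):
        # the dual-mode density and its sampler must be mutually consistent:
        # the integral prediction has to match empirical Chebyshev counting
        from lpbarcode import simulator

        dual = JointBarcodeDistribution(base=uniform100, f_dm=0.3)
        pred, se_mc = duplicate_rate_continuous(dual, 2, 0.5, 1000, seed=5)
        rng = np.random.default_rng(77)
        fracs = []
        for _ in range(20):
            pool = pool_from_matrix(dual.sample_barcodes(2, 1000, rng))
            fracs.append(
                simulator.count_duplicates(pool, 0.5).pooled_fraction)
        emp = np.mean(fracs)
        se = math.hypot(np.std(fracs, ddof=1) / math.sqrt(len(fracs)), se_mc)
        assert abs(pred - emp) <= 3 * se

    def test_dual_mode_density_normalized(self, uniform100):
        joint = JointBarcodeDistribution(base=uniform100, f_dm=0.3)
        lo, hi = 880.0, 1085.0
        e = np.arange(lo, hi, 0.25)
        e1, e2 = np.meshgrid(e, e, indexing="ij")
        pts = np.stack([e1.ravel(), e2.ravel()], axis=1)
        vals = joint.pdf_sorted(pts).reshape(e1.shape)
        vals[e2 <= e1] = 0.0  # density lives on the sorted region
        integral = vals.sum() * 0.25 ** 2
        assert integral == pytest.approx(1.0, abs=0.02)


class TestNoiseError:
    def test_gaussian_reference_value(self, gaussian_noise01):
        # 1 - erf(0.5 / (0.1 sqrt(2)))^3
        assert noise_error(gaussian_noise01, 0.5, 3) == pytest.approx(
            1.72e-6, rel=0.05)

    def test_wide_gate_no_error(self, gaussian_noise01):
        assert noise_error(gaussian_noise01, 1e3, 3) == pytest.approx(0.0,
                                                                      abs=1e-15)

    def test_generalized_beta2_equals_gaussian(self):
        alpha = 0.2
        gen = NoiseModel.generalized(alpha=alpha, beta=2.0)
        gau = NoiseModel.gaussian(alpha / math.sqrt(2.0))
        for delta in np.geomspace(1e-3, 2.0, 25):
            assert noise_error(gen, delta, 1) == pytest.approx(
                noise_error(gau, delta, 1), abs=1e-10)

    def test_monotone_in_delta_and_m(self, gaussian_noise01):
        deltas = np.linspace(0.01, 1.0, 20)
        vals = [noise_error(gaussian_noise01, d, 3) for d in deltas]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert noise_error(gaussian_noise01, 0.2, 4) >= \
            noise_error(gaussian_noise01, 0.2, 3)


class TestTotalError:
    @pytest.mark.parametrize("a,b,expected", [(0.0, 0.3, 0.3), (1.0, 0.3, 1.0),
                                              (0.5, 0.5, 0.75)])
    def test_values(self, a, b, expected):
        assert total_error(a, b) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_bounded(self, a, b):
        t = total_error(a, b)
        assert 0.0 <= t <= 1.0
        assert t == pytest.approx(total_error(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_error(-0.1, 0.5)


class TestOptimizeDelta:
    def test_minimizer_property(self, joint_uniform100, gaussian_noise01):
        d_opt, e_min = optimize_delta(joint_uniform100, gaussian_noise01,
                                      3, 10**4)

        def tot(d):
            dup, _ = duplicate_rate_continuous(joint_uniform100, 3, d, 10**4)
            return total_error(dup, noise_error(gaussian_noise01, d, 3))

        assert e_min <= tot(2 * d_opt) + 1e-15
        assert e_min <= tot(d_opt / 2) + 1e-15

    def test_matches_fine_grid_scan(self, joint_uniform100, gaussian_noise01):
        # independent oracle: dense scan of the closed-form total error
        N, m, sigma = 10**5, 3, 0.1
        deltas = np.geomspace(1e-3, 50.0, 5000)
        b_eff = (100.0 / (2.0 * deltas)) ** m / math.factorial(m)
        dup = 1.0 - (1.0 - np.minimum(1.0 / b_eff, 1.0)) ** (N - 1)
        noi = 1.0 - special.erf(deltas / (sigma * math.sqrt(2))) ** m
        tot = dup + noi - dup * noi
        d_opt, e_min = optimize_delta(joint_uniform100, gaussian_noise01, m, N)
        assert e_min <= tot.min() + 1e-12
        assert d_opt == pytest.approx(deltas[np.argmin(tot)], rel=0.02)

    def test_delta_opt_shrinks_with_pool_size(self, joint_uniform100,
                                              gaussian_noise01):
        ds = [optimize_delta(joint_uniform100, gaussian_noise01, 3, n)[0]
              for n in (10**3, 10**4, 10**5)]
        assert ds[0] >= ds[1] >= ds[2]

    def test_degenerate_noise_warns(self, joint_uniform100):
        with pytest.warns(RuntimeWarning):
            d_opt, _ = optimize_delta(joint_uniform100,
                                      NoiseModel.gaussian(0.0), 3, 10**4)
        assert d_opt == pytest.approx(1e-3)


class TestMaxPoolSize:
    def test_bisection_contract(self, joint_uniform100, gaussian_noise01):
        n_max = max_pool_size(joint_uniform100, gaussian_noise01, 3, 0.01)

        def grid_eps_min(n):
            # replicates the documented search grid with independent formulas
            deltas = np.geomspace(1e-3, 50.0, 200)
            b_eff = (100.0 / (2.0 * deltas)) ** 3 / 6.0
            dup = 1.0 - (1.0 - np.minimum(1.0 / b_eff, 1.0)) ** (n - 1)
            noi = 1.0 - special.erf(deltas / (0.1 * math.sqrt(2))) ** 3
            return float((dup + noi - dup * noi).min())

        assert grid_eps_min(n_max) <= 0.01 < grid_eps_min(n_max + 1)

    def test_returns_zero_when_hopeless(self, joint_uniform100):
        heavy = NoiseModel.gaussian(40.0)  # noise floor alone exceeds eps0
        assert max_pool_size(joint_uniform100, heavy, 3, 0.01) == 0


class TestTaggingMixture:
    def test_poisson_weights(self):
        tag = TaggingMixture("poisson", lam=3.0)
        assert tag.untagged_fraction == pytest.approx(math.exp(-3.0), rel=1e-9)
        ms, ws = tag.weights()
        assert ms[0] == 1
        assert ws.sum() == pytest.approx(1.0, abs=1e-5)

    def test_include_untagged_raw_masses(self):
        tag = TaggingMixture("poisson", lam=3.0, include_untagged=True)
        _, ws = tag.weights()
        assert ws.sum() == pytest.approx(1.0 - math.exp(-3.0), abs=1e-5)

    def test_invalid(self):
        with pytest.raises(ValueError):
            TaggingMixture("poisson", lam=-1.0)


class TestMixtureErrors:
    def test_fixed_mode_degenerates_to_single_m(self, joint_uniform100,
                                                gaussian_noise01):
        tag = TaggingMixture("fixed", m=3)
        table, totals = mixture_error_rates(tag, joint_uniform100,
                                            gaussian_noise01, 0.5, 10**4)
        direct, _ = duplicate_rate_continuous(joint_uniform100, 3, 0.5, 10**4)
        assert len(table) == 1
        assert totals["eps_dup"] == pytest.approx(direct, rel=1e-9)
        assert totals["eps_noise"] == pytest.approx(
            noise_error(gaussian_noise01, 0.5, 3), rel=1e-9)

    def test_low_multiplicities_dominate(self, joint_uniform100,
                                         gaussian_noise01):
        tag = TaggingMixture("poisson", lam=3.0)
        table, _ = mixture_error_rates(tag, joint_uniform100, gaussian_noise01,
                                       0.5, 10**5)
        contrib = table["weight"] * table["eps_dup"]
        low = contrib[table["m"] <= 3].sum()
        assert low > 0.8 * contrib.sum()


class TestDuplicateLoss:
    def test_noise_budget_is_met_exactly(self, gaussian_noise01):
        tag = TaggingMixture("poisson", lam=3.0)
        delta = solve_delta_for_noise(tag, gaussian_noise01, 0.01)
        ms, ws = tag.weights()
        weighted = sum(w * noise_error(gaussian_noise01, delta, int(m))
                       for m, w in zip(ms, ws))
        assert weighted == pytest.approx(0.01, rel=1e-6)

    def test_loss_monotone_in_n(self, joint_uniform100, gaussian_noise01):
        tag = TaggingMixture("poisson", lam=3.0)
        losses = [duplicate_loss(tag, joint_uniform100, gaussian_noise01,
                                 n, 0.01)[0] for n in (10**3, 10**4, 10**5)]
        assert losses[0] <= losses[1] <= losses[2]

    def test_higher_tagging_ratio_reduces_loss(self, gaussian_noise01):
        joint = JointBarcodeDistribution(
            base=SpectralDistribution.uniform(100.0))
        l3, _ = duplicate_loss(TaggingMixture("poisson", lam=3.0), joint,
                               gaussian_noise01, 10**5, 0.01)
        l6, _ = duplicate_loss(TaggingMixture("poisson", lam=6.0), joint,
                               gaussian_noise01, 10**5, 0.01)
        assert l6 < l3

    def test_loss_matches_pool_simulation(self):
        # cross-check the weighted theory against direct duplicate counting
        from lpbarcode import simulator

        joint = JointBarcodeDistribution(
            base=SpectralDistribution.uniform(300.0))
        noise = NoiseModel.generalized(alpha=0.047, beta=1.28)
        tag = TaggingMixture("poisson", lam=6.0)
        delta = solve_delta_for_noise(tag, noise, 0.01)
        n_req = 20_000
        n_tagged_mean = n_req * (1.0 - tag.untagged_fraction)
        fracs = []
        for s in range(8):
            pool = simulator.sample_pool(joint, tag, n_req, seed=900 + s)
            rep = simulator.count_duplicates(pool, delta)
            fracs.append(rep.n_duplicates / len(pool))
        emp = np.mean(fracs)
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        _, totals = mixture_error_rates(tag, joint, noise, delta,
                                        int(n_tagged_mean))
        assert abs(totals["eps_dup"] - emp) <= 3 * se + 1e-4
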