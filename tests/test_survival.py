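"""SMK survival: protraction factor, compound-Poisson convolution, mixtures."""

import numpy as np
import pytest
from scipy.stats import poisson

from smkbnct.survival import (HeterogeneityModel, SMKParams,
                              compound_poisson_pd, g_factor, survival_group,
                              survival_population, survival_single)
from smkbnct.synth import toy_pd


class TestGFactor:
    def test_acute_limit(self):
        assert g_factor(4.33, 0.0) == pytest.approx(1.0)
        assert g_factor(4.33, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_nine_hour_reference_value(self):
        # gamma0 = 4.33 /h, T = 9 h: G ~ 0.05 for the longest exposure
        assert g_factor(4.33, 9.0) == pytest.approx(0.05, abs=0.002)

    def test_large_argument_asymptote(self):
        # G -> 2/(gamma0 T) for gamma0 T >> 1
        assert g_factor(10.0, 10.0) == pytest.approx(2.0 / 100.0, rel=0.02)

    def test_monotone_decreasing_and_bounded(self):
        ts = np.linspace(0.0, 20.0, 50)
        gs = [g_factor(4.33, t) for t in ts]
        assert np.all(np.diff(gs) < 0)
        assert all(0 < g <= 1 for g in gs)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            g_factor(4.33, -1.0)


class TestSurvivalSingle:
    def test_zero_dose(self, params):
        assert survival_single(0.0, params, zdD=5.0, G=1.0) == 1.0

    def test_hand_evaluation(self, params):
        # alpha = 0.0422 + 0.00822*2; S = exp(-alpha*2 - 0.00822*4) ~ e^-0.150
        got = survival_single(2.0, params, zdD=2.0, G=1.0)
        expected = np.exp(-((0.0422 + 0.00822 * 2.0) * 2.0 + 0.00822 * 4.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(np.exp(-0.150), abs=2e-4)

    def test_g_zero_linear_limit(self, params):
        z = 3.0
        got = survival_single(z, params, zdD=1.0, G=0.0)
        alpha = params.alpha0 + params.beta0 * 1.0
        assert got == pytest.approx(np.exp(-alpha * z), rel=1e-12)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            survival_single(-1.0, params, zdD=1.0)
        with pytest.raises(ValueError):
            survival_single(1.0, params, zdD=1.0, G=1.5)


class TestCompoundPoisson:
    def test_point_mass_analytic_oracle(self):
        # f_1 = delta(a): f_n is Poisson masses at k*a with P(0) = e^-lambda
        a, z_mean = 0.5, 1.5
        pd = compound_poisson_pd(toy_pd("delta", z0=a), z_mean, n_grid=2**13)
        # the atom position is grid-snapped; lambda adjusts so the mean stays
        # exact -- compare against Poisson masses at that effective lambda
        lam = pd.meta["lambda"]
        assert lam == pytest.approx(z_mean / a, rel=2e-3)
        z, p = pd.mids, pd.probabilities
        dz = z[1] - z[0]
        for k in range(8):
            window = np.abs(z - k * a) <= (3 + k) * dz
            assert p[window].sum() == pytest.approx(poisson.pmf(k, lam),
                                                    abs=1e-6)

    def test_zero_mean_is_point_mass_at_zero(self):
        pd = compound_poisson_pd(toy_pd("delta", z0=1.0), 0.0)
        assert pd.z_F < 1e-9

    def test_mean_identity(self):
        # first moment of f_n equals the requested mean nucleus dose
        f1 = toy_pd("exponential", mean=0.3)
        for z_mean in (0.05, 1.0, 20.0):
            pd = compound_poisson_pd(f1, z_mean, n_grid=2**13)
            assert pd.z_F == pytest.approx(z_mean, rel=5e-3)

    def test_variance_cumulant_formula(self):
        # var = lambda * second moment of f_1
        f1 = toy_pd("exponential", mean=0.3)
        z_mean = 3.0
        lam = z_mean / f1.z_F
        pd = compound_poisson_pd(f1, z_mean, n_grid=2**14)
        var = pd.moment(2) - pd.moment(1) ** 2
        assert var == pytest.approx(lam * f1.moment(2), rel=0.01)

    @pytest.mark.parametrize("z_mean", [0.6, 40.0])  # lambda ~ 2 and ~ 130
    def test_ks_against_bruteforce_sampler(self, z_mean):
        f1 = toy_pd("two_point", z1=0.1, z2=0.4, p1=0.3)
        pd = compound_poisson_pd(f1, z_mean, n_grid=2**14)
        # the brute-force oracle draws k ~ Poisson and sums k single events;
        # it uses the same grid-snapped atom positions so the comparison
        # probes the convolution, not the (separately tested) discretization
        dz = pd.mids[1] - pd.mids[0]
        lam = pd.meta["lambda"]
        vals = np.round(np.array([0.1, 0.4]) / dz) * dz
        probs = np.array([0.3, 0.7])
        rng = np.random.default_rng(17)
        n = 100_000
        k = rng.poisson(lam, size=n)
        draws = rng.choice(vals, size=int(k.sum()), p=probs)
        samples = np.zeros(n)
        np.add.at(samples, np.repeat(np.arange(n), k), draws)
        # grid quantization displaces mass by at most one cell, so bracket the
        # right-continuous model CDF one grid step either side of each sample
        cdf = np.concatenate([[0.0], np.cumsum(pd.probabilities)])
        dz = pd.mids[1] - pd.mids[0]

        def model_cdf(z):
            idx = np.searchsorted(pd.mids, z, side="right")
            return cdf[idx]

        samples.sort()
        emp = np.arange(1, n + 1) / n
        upper = model_cdf(samples + dz)
        lower = model_cdf(samples - dz)
        ks = max(np.max(emp - upper, initial=0.0),
                 np.max(lower - emp, initial=0.0))
        assert ks < 0.01


class TestSurvivalGroup:
    def test_zero_dose(self, params):
        assert survival_group(0.8, 0.0, toy_pd("delta", z0=0.3), params, 2.0) == 1.0

    def test_deterministic_dose_limit(self, params):
        # degenerate f_1 with lambda >= 1e4 reproduces the single-cell form
        dose, kappa, zdD = 4.0, 0.9, 3.0
        f1 = toy_pd("delta", z0=kappa * dose / 1e4)
        s_group = survival_group(kappa, dose, f1, params, zdD, n_grid=2**15)
        s_cell = survival_single(kappa * dose, params, zdD)
        assert s_group == pytest.approx(s_cell, rel=1e-3)

    def test_heterogeneity_raises_survival(self, params):
        # broad event spectrum vs delta at the same mean: Jensen-type ordering
        dose = 10.0
        broad = toy_pd("exponential", mean=0.5)
        narrow = toy_pd("delta", z0=0.5)
        s_broad = survival_group(1.0, dose, broad, params, 5.0)
        s_narrow = survival_group(1.0, dose, narrow, params, 5.0)
        assert s_broad > s_narrow

    def test_monotone_in_dose(self, params):
        f1 = toy_pd("exponential", mean=0.3)
        doses = np.linspace(0, 15, 16)
        sf = [survival_group(0.8, d, f1, params, 4.0) for d in doses]
        assert np.all(np.diff(sf) < 0)
        assert all(0 < s <= 1 for s in sf)


class TestSurvivalPopulation:
    def _group_fn(self, params, f1, zdD, kappa0=0.8):
        def group(x, dose):
            return survival_group(kappa0 * x, dose, f1, params, zdD,
                                  n_grid=2**12)
        return group

    def test_sigma_zero_reduces_to_group(self, params):
        f1 = toy_pd("exponential", mean=0.4)
        group = self._group_fn(params, f1, 5.0)
        for form in ("none", "gaussian", "double_peak"):
            het = HeterogeneityModel(form, 0.0)
            assert survival_population(6.0, het, group) == \
                pytest.approx(group(1.0, 6.0), rel=1e-12)

    def test_survival_increases_with_sigma(self, params):
        f1 = toy_pd("exponential", mean=0.4)
        group = self._group_fn(params, f1, 5.0)
        dose = 12.0
        s = [survival_population(dose, HeterogeneityModel("gaussian", sg), group)
             for sg in (0.0, 0.3, 0.6)]
        assert s[0] < s[1] < s[2]

    def test_gaussian_and_double_peak_agree(self, params):
        # same sigma, agreement within a few percent in log-survival
        f1 = toy_pd("exponential", mean=0.4)
        group = self._group_fn(params, f1, 5.0)
        for sigma in (0.2, 0.4):
            s_g = survival_population(10.0, HeterogeneityModel("gaussian", sigma),
                                      group)
            s_d = survival_population(10.0,
                                      HeterogeneityModel("double_peak", sigma),
                                      group)
            assert np.log(s_g) == pytest.approx(np.log(s_d), rel=0.05)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            HeterogeneityModel("gaussian", -0.1)
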