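"""PD container, domain chord surrogate and the two mixing rules."""

import numpy as np
import pytest

from smkbnct import physics
from smkbnct.microdose import (ComponentMix, DomainSpec, SpecificEnergyPD,
                               TrackSegments, default_z_bins, dose_mean_zd,
                               domain_pd_from_tracks, mix_compartment_pds,
                               mix_component_pds, sample_mu_chords)
from smkbnct.synth import toy_pd
from smkbnct.transport import CompartmentWeights

MEV_TO_J = 1.602176634e-13


class TestMoments:
    def test_delta(self):
        pd = toy_pd("delta", z0=2.0)
        assert dose_mean_zd(pd) == pytest.approx(2.0, rel=1e-5)
        assert pd.z_F == pytest.approx(2.0, rel=1e-5)

    def test_two_point(self):
        # half mass at 1 and 3 Gy: z_D = (1+9)/2 / ((1+3)/2) = 2.5
        pd = toy_pd("two_point", z1=1.0, z2=3.0)
        assert dose_mean_zd(pd) == pytest.approx(2.5, rel=1e-5)

    def test_exponential(self):
        pd = toy_pd("exponential", mean=0.7)
        assert pd.z_F == pytest.approx(0.7, rel=5e-3)
        assert dose_mean_zd(pd) == pytest.approx(1.4, rel=5e-3)

    def test_normalization_invariant(self):
        pd = toy_pd("exponential", mean=1.0)
        assert np.sum(pd.probabilities) == pytest.approx(1.0, abs=1e-9)


class TestChordSurrogate:
    def test_mu_randomness_chord_moments(self):
        # E[l] = 4r/3 and E[l^2]/E[l] = 3r/2 under mu-randomness
        r = 0.24
        chords = sample_mu_chords(np.random.default_rng(0), 400_000, r)
        assert chords.max() <= 2 * r
        assert chords.mean() == pytest.approx(4 * r / 3, rel=5e-3)
        assert np.mean(chords**2) / np.mean(chords) == \
            pytest.approx(1.5 * r, rel=5e-3)

    def test_constant_let_dose_mean(self):
        # constant-LET track: z_dD = LET * E[l^2]/E[l] / m = 3 L r / (2 m)
        spec = DomainSpec(0.2)
        let = 50.0  # keV/um, proton-like plateau treated as constant
        rng = np.random.default_rng(1)
        chords = sample_mu_chords(rng, 500_000, spec.radius)
        z = let * chords * 1e-3 * MEV_TO_J / spec.mass_kg
        oracle = np.mean(z**2) / np.mean(z)
        analytic = 1.5 * let * 1e-3 * spec.radius * MEV_TO_J / spec.mass_kg
        assert oracle == pytest.approx(analytic, rel=5e-3)

    def test_domain_pd_vs_bruteforce_oracle(self):
        # monoenergetic alpha through r_d = 0.24 um domains
        spec = DomainSpec(0.24)
        segs = TrackSegments(np.array([0], dtype=np.int8), np.array([1.47]),
                             np.array([1.0]), ("alpha",), n_histories=1)
        pd = domain_pd_from_tracks(segs, spec, n_samples=150_000, rng=2)
        rng = np.random.default_rng(3)
        chords = sample_mu_chords(rng, 300_000, spec.radius)
        dep = physics.deposit_on_segment("alpha", 1.47, chords)
        z = dep * MEV_TO_J / spec.mass_kg
        oracle_zd = np.mean(z**2) / np.mean(z)
        assert pd.z_D == pytest.approx(oracle_zd, rel=0.05)

    def test_empty_track_set_raises(self):
        segs = TrackSegments(np.array([], dtype=np.int8), np.array([]),
                             np.array([]), ("alpha",))
        with pytest.raises(ValueError):
            domain_pd_from_tracks(segs, DomainSpec(0.24), n_samples=10)


class TestRebin:
    def test_moments_preserved(self):
        pd = toy_pd("exponential", mean=0.5)
        re = pd.rebin(np.geomspace(5e-6, 25.0, 300))
        assert re.z_F == pytest.approx(pd.z_F, rel=5e-3)
        assert re.z_D == pytest.approx(pd.z_D, rel=5e-3)

    def test_mass_conserved(self):
        pd = toy_pd("two_point", z1=0.5, z2=2.0)
        re = pd.rebin(np.geomspace(1e-3, 10.0, 500))
        assert np.sum(re.probabilities) == pytest.approx(1.0, abs=1e-6)


class TestCompartmentMixing:
    def _pds(self):
        return {"cytoplasm": toy_pd("exponential", mean=0.3),
                "extracellular": toy_pd("exponential", mean=0.1)}

    def test_single_weight_returns_member(self):
        pds = self._pds()
        w = CompartmentWeights(c=1.0)
        mixed = mix_compartment_pds(pds, w)
        assert mixed.z_F == pytest.approx(pds["cytoplasm"].z_F, rel=1e-9)

    def test_identical_members_unchanged(self):
        pd0 = toy_pd("exponential", mean=0.2)
        w = CompartmentWeights(c=0.5, e=0.5)
        mixed = mix_compartment_pds({"cytoplasm": pd0, "extracellular": pd0}, w)
        assert mixed.z_F == pytest.approx(pd0.z_F, rel=1e-3)
        assert mixed.z_D == pytest.approx(pd0.z_D, rel=1e-3)

    def test_first_moment_is_frequency_weighted_mean(self):
        pds = self._pds()
        pds["cytoplasm"].event_rate = 0.4
        pds["extracellular"].event_rate = 0.1
        w = CompartmentWeights(c=0.7, e=0.3)
        mixed = mix_compartment_pds(pds, w)
        wts = np.array([0.7 * 0.4, 0.3 * 0.1])
        wts = wts / wts.sum()
        oracle = wts[0] * pds["cytoplasm"].z_F + wts[1] * pds["extracellular"].z_F
        assert mixed.z_F == pytest.approx(oracle, rel=1e-3)

    def test_missing_pd_raises(self):
        with pytest.raises(ValueError):
            mix_compartment_pds({"cytoplasm": toy_pd("delta", z0=1.0)},
                                CompartmentWeights(c=0.5, e=0.5))


class TestComponentMixing:
    def test_single_component_passthrough(self):
        pd_g = toy_pd("exponential", mean=0.01)
        mix = ComponentMix({"photon": {"kerma": 2.0, "domain_pd": pd_g}})
        out = mix_component_pds(mix, site="domain")
        assert out.z_F == pytest.approx(pd_g.z_F, rel=1e-9)

    def test_equal_lambdas_identical_pds(self):
        pd0 = toy_pd("exponential", mean=0.05)
        mix = ComponentMix({
            "boron": {"kerma": 1.0, "domain_pd": pd0},
            "photon": {"kerma": 1.0, "domain_pd": pd0}})
        out = mix_component_pds(mix, site="domain")
        assert out.z_D == pytest.approx(pd0.z_D, rel=1e-3)

    def test_mixed_dose_mean_between_members(self):
        pd_b = toy_pd("exponential", mean=0.4)
        pd_g = toy_pd("exponential", mean=0.02)
        mix = ComponentMix({
            "boron": {"kerma": 3.0, "domain_pd": pd_b},
            "photon": {"kerma": 1.0, "domain_pd": pd_g}})
        out = mix_component_pds(mix, site="domain")
        assert pd_g.z_D < out.z_D < pd_b.z_D

    def test_all_zero_lambda_raises(self):
        mix = ComponentMix({"photon": {"kerma": 0.0,
                                       "domain_pd": toy_pd("delta", z0=1)}})
        with pytest.raises(ValueError):
            mix_component_pds(mix)


class TestPDValidation:
    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            SpecificEnergyPD(np.array([0.0, 1.0, 2.0]), np.array([1.0, -0.5]))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            SpecificEnergyPD.from_samples(np.array([]))

    def test_default_bins_span(self):
        bins = default_z_bins()
        assert len(bins) == 401 and bins[0] == pytest.approx(1e-4)
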