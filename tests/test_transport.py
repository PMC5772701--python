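"""Capture-reaction channels, lattice transport and the kappa conversions."""

import numpy as np
import pytest

from smkbnct.geometry import CellLattice
from smkbnct.transport import (CompartmentWeights, EmissionChannel,
                               NucleusDoseCoefficients, SpectrumSource,
                               boron_channels, boron_weights, kappa_B,
                               kappa_total, nitrogen_channel,
                               simulate_component_pd)


class TestChannels:
    def test_boron_branching(self):
        chans = boron_channels()
        assert sum(c.branch_probability for c in chans) == pytest.approx(1.0)
        main = max(chans, key=lambda c: c.branch_probability)
        assert main.branch_probability == pytest.approx(0.937)
        energies = dict(main.fragments)
        assert energies["alpha"] == pytest.approx(1.47, abs=0.01)
        assert energies["li7"] == pytest.approx(0.84, abs=0.01)

    def test_excited_channel_momentum_split(self):
        # E_Li = Q m_alpha / (m_alpha + m_Li) with Q = 2.31 MeV
        q = 2.312
        e_li = q * 4.0015 / (4.0015 + 7.016)
        chans = boron_channels()
        got = dict(chans[0].fragments)["li7"]
        assert got == pytest.approx(e_li, rel=5e-3)

    def test_ground_state_total(self):
        ground = boron_channels()[1]
        assert sum(e for _, e in ground.fragments) == pytest.approx(2.79, abs=0.01)

    def test_nitrogen_kinematics(self):
        (chan,) = nitrogen_channel()
        frag = dict(chan.fragments)
        # carbon recoil energy: Q m_p / (m_p + m_C) = 0.626*1.008/15.011
        assert frag["carbon"] == pytest.approx(0.042, rel=0.01)
        assert frag["proton"] + frag["carbon"] == pytest.approx(0.626, rel=0.01)
        p_p = frag["proton"] * 1.0073
        p_c = frag["carbon"] * 14.0032
        assert abs(p_p - p_c) / p_p < 0.01

    def test_momentum_violation_rejected(self):
        with pytest.raises(ValueError):
            EmissionChannel(1.0, (("alpha", 1.47), ("li7", 0.40)))


class TestBoronWeights:
    def test_bpa(self, lattice):
        w = boron_weights("BPA", lattice=lattice)
        assert w.c == pytest.approx(0.78, abs=0.01)
        assert w.e == pytest.approx(0.22, abs=0.01)
        assert w.n == w.s == 0.0

    def test_bsh(self, lattice):
        w = boron_weights("BSH", lattice=lattice)
        assert w.s == pytest.approx(0.48, abs=0.01)
        assert w.e == pytest.approx(0.52, abs=0.01)

    def test_unit_ratio_ideal(self, lattice):
        # R = 1 intracellular share equals the volume fraction
        w = boron_weights("BPA", intra_extra_ratio=1.0, lattice=lattice)
        assert w.c == pytest.approx(0.5236, abs=1e-3)

    def test_negative_ratio_rejected(self, lattice):
        with pytest.raises(ValueError):
            boron_weights("BPA", intra_extra_ratio=-1.0, lattice=lattice)

    def test_weights_normalized(self):
        with pytest.raises(ValueError):
            CompartmentWeights(c=0.5, e=0.4)


class TestKappa:
    def test_uniform_weights_give_unity(self, offset_sim, lattice):
        coeffs, _ = offset_sim
        w = boron_weights("ideal", lattice=lattice)
        assert kappa_B(coeffs, w) == pytest.approx(1.0, abs=0.03)

    def test_proximity_ordering(self, offset_sim):
        coeffs, _ = offset_sim
        assert coeffs.m_n > coeffs.m_c > coeffs.m_s > coeffs.m_e

    def test_linearity_in_weights(self, offset_sim):
        coeffs, _ = offset_sim
        w1 = CompartmentWeights(c=1.0)
        w2 = CompartmentWeights(e=1.0)
        mix = CompartmentWeights(c=0.3, e=0.7)
        assert kappa_B(coeffs, mix) == pytest.approx(
            0.3 * kappa_B(coeffs, w1) + 0.7 * kappa_B(coeffs, w2), rel=1e-9)

    def test_concentration_factor_scaling(self, offset_sim):
        coeffs, _ = offset_sim
        w = CompartmentWeights(c=0.78, e=0.22)
        k1, k2 = kappa_B(coeffs, w, x=1.0), kappa_B(coeffs, w, x=2.0)
        # extracellular term is not scaled
        extra = 0.22 * coeffs.m_e / coeffs.m_uniform
        assert k2 - k1 == pytest.approx(k1 - extra, rel=1e-9)

    def test_kappa_total(self):
        assert kappa_total(1.0, {"boron": 2.0, "photon": 1.0}) == 1.0
        assert kappa_total(0.78, {"boron": 1.0}) == pytest.approx(0.78)
        assert kappa_total(0.5, {"boron": 1.0, "photon": 1.0}) == \
            pytest.approx(0.75)
        with pytest.raises(ValueError):
            kappa_total(0.8, {"boron": 0.0})

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            NucleusDoseCoefficients(m_n=0.1, m_c=0.5, m_s=0.2, m_e=0.3,
                                    m_uniform=0.3)


class TestTransport:
    def test_uniform_source_near_kerma_equilibrium(self, offset_sim):
        # volume-uniform boron sources: mean nucleus dose == kerma dose
        # (charged-particle equilibrium in the lattice interior).  The mean
        # energy per history over the cube mass must match the nucleus dose.
        _, res = offset_sim
        r = res["uniform"]
        e_per_hist = 0.937 * (1.4723 + 0.8397) + 0.063 * (1.7766 + 1.0132)
        cube_mass = (10e-6) ** 3 * 1000.0
        kerma = e_per_hist * 1.602176634e-13 / cube_mass
        assert r.m_coeff == pytest.approx(kerma, rel=0.02)

    def test_seeded_runs_bit_reproducible(self, lattice):
        from smkbnct.transport import boron_channels
        r1 = simulate_component_pd(lattice, "cytoplasm", 5_000, seed=11,
                                   channels=boron_channels())
        r2 = simulate_component_pd(lattice, "cytoplasm", 5_000, seed=11,
                                   channels=boron_channels())
        assert np.array_equal(r1.pd.density, r2.pd.density)
        assert r1.m_coeff == r2.m_coeff and r1.max_zn == r2.max_zn

    def test_single_full_stop_specific_energy(self, lattice):
        # 0.84 MeV Li fully stopped in a nucleus: z = E / 1.131e-13 kg = 1.19 Gy
        z = 0.84 * 1.602176634e-13 / lattice.nucleus_mass_kg
        assert z == pytest.approx(1.19, abs=0.01)

    def test_unreachable_source_errors(self, lattice):
        # 1 keV carbon recoils (range ~ nm) from the extracellular gap can
        # never reach a nucleus
        spec = SpectrumSource(["carbon"], np.array([0.001]), np.array([1.0]))
        with pytest.raises(RuntimeError):
            simulate_component_pd(lattice, "extracellular", 2_000, seed=3,
                                  spectrum=spec)

    def test_pd_moment_consistency(self, offset_sim):
        # events per history times z_F equals the m coefficient
        _, res = offset_sim
        r = res["cytoplasm"]
        assert r.pd.event_rate * r.pd.z_F == pytest.approx(r.m_coeff, rel=0.01)

    def test_li_cutoff_orders_compartment_spectra(self, offset_sim):
        # Li ions from the cell surface reach but cannot cross the nucleus
        # (range ~ 4 um), so small events dominate there, while intranuclear
        # sources deposit both fragments and sit mostly above ~0.6 Gy
        _, res = offset_sim
        frac = {k: res[k].pd.probabilities[res[k].pd.mids < 0.6].sum()
                for k in ("surface", "cytoplasm", "nucleus")}
        assert frac["surface"] > frac["cytoplasm"] > frac["nucleus"]
        assert frac["nucleus"] < 0.2
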