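"""Spectra, HVL, fluence, arc sampling of the virtual point source."""

import numpy as np
import pytest
from scipy import stats

from kvdose import materials as M
from kvdose import source_model as sm
from tests.conftest import make_mono_source


def kramers(kvp):
    e = np.arange(5.0, kvp + 1.0)
    return sm.EnergySpectrum(e, (kvp - e) / e)


class TestEnergySpectrum:
    def test_normalization_and_validation(self):
        s = kramers(100.0)
        assert s.weights.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            sm.EnergySpectrum(np.array([50.0]), np.array([-1.0]))
        with pytest.raises(ValueError):
            sm.EnergySpectrum(np.array([50.0]), np.array([0.0]))


class TestAttenuate:
    def test_zero_thickness_is_identity(self):
        s = kramers(100.0)
        out = sm.attenuate_spectrum(s, M.ALUMINUM, 0.0)
        assert np.allclose(out.weights, s.weights, rtol=1e-14)

    def test_delta_spectrum_closed_form(self):
        s = sm.EnergySpectrum(np.array([60.0]), np.array([1.0]))
        mu = M.mixture_mu(M.ALUMINUM, 60.0).linear
        out = sm.attenuate_spectrum(s, M.ALUMINUM, 0.2)
        # renormalized delta stays a delta; unnormalized fraction is exp(-mu t)
        assert out.weights[0] == pytest.approx(1.0)
        two = sm.attenuate_spectrum(s, M.ALUMINUM, 0.4)
        assert np.exp(-mu * 0.4) == pytest.approx(np.exp(-mu * 0.2) ** 2, rel=1e-12)

    def test_semigroup_two_layers(self):
        s = kramers(120.0)
        once = sm.attenuate_spectrum(sm.attenuate_spectrum(s, M.ALUMINUM, 0.1),
                                     M.ALUMINUM, 0.1)
        twice = sm.attenuate_spectrum(s, M.ALUMINUM, 0.2)
        assert np.allclose(once.weights, twice.weights, rtol=1e-12)

    def test_hardening_raises_mean_energy(self):
        s = kramers(120.0)
        means = [sm.attenuate_spectrum(s, M.ALUMINUM, t).mean_energy
                 for t in np.linspace(0.0, 1.0, 8)]
        assert np.all(np.diff(means) > 0)

    def test_negative_thickness(self):
        with pytest.raises(ValueError):
            sm.attenuate_spectrum(kramers(80.0), M.ALUMINUM, -0.1)


class TestHvl:
    def test_monoenergetic_closed_form(self):
        s = sm.EnergySpectrum(np.array([60.0]), np.array([1.0]))
        mu = M.mixture_mu(M.ALUMINUM, 60.0).linear
        assert sm.hvl_al(s) == pytest.approx(10.0 * np.log(2) / mu, rel=1e-3)

    def test_matches_brute_force_scan(self):
        """Root-find agrees with a 0.01 mm brute-force transmission scan."""
        s = sm.attenuate_spectrum(kramers(120.0), M.ALUMINUM, 0.3)
        mu = M.mixture_mu(M.ALUMINUM, s.energies).linear
        kerma = M.kerma_per_fluence(M.AIR, s.energies)
        kw = s.weights * kerma
        ts = np.arange(0.0, 20.0, 0.01)
        trans = (kw[None, :] * np.exp(-mu[None, :] * ts[:, None] / 10)).sum(1) / kw.sum()
        brute = ts[np.argmin(np.abs(trans - 0.5))]
        assert sm.hvl_al(s) == pytest.approx(brute, abs=0.01)

    def test_hardened_spectrum_has_larger_hvl(self):
        s = kramers(120.0)
        hard = sm.attenuate_spectrum(s, M.ALUMINUM, 0.2)
        assert sm.hvl_al(hard) >= sm.hvl_al(s)


class TestSampling:
    def test_zero_arc_is_configuration_error(self):
        with pytest.raises(sm.ConfigurationError):
            make_mono_source(arc_deg=0.0)

    def test_arc_angles_uniform(self):
        src = make_mono_source(arc_deg=360.0)
        rng = np.random.default_rng(0)
        *_, gantry = sm.sample_photons(src, 100_000, rng)
        u = (gantry - src.arc_start_deg) / 360.0
        ks = stats.kstest(u, "uniform")
        assert ks.statistic < 1.63 / np.sqrt(len(u))  # 1% critical value
        # mean within 3 standard errors of the arc midpoint
        se = 360.0 / np.sqrt(12 * len(u))
        assert abs(gantry.mean() - (src.arc_start_deg + 180.0)) < 3 * se

    def test_flat_fluence_targets_uniform_and_energy_delta(self):
        src = make_mono_source(60.0, arc_deg=1e-6 + 0.5)
        rng = np.random.default_rng(1)
        pos, dirs, e, w, g = sm.sample_photons(src, 40_000, rng)
        assert np.all(e == 60.0)
        assert np.all(w == 1.0)
        # reconstruct plane intersection points: with gantry ~ 0 the plane is y=0
        t = -pos[:, 1] / dirs[:, 1]
        x = pos[:, 0] + t * dirs[:, 0]
        z = pos[:, 2] + t * dirs[:, 2]
        counts, *_ = np.histogram2d(x, z, bins=4,
                                    range=[[-5, 5], [-5, 5]])
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, 15)

    def test_origin_at_sad(self):
        src = make_mono_source(arc_deg=360.0)
        rng = np.random.default_rng(2)
        pos, *_ = sm.sample_photons(src, 1000, rng)
        assert np.allclose(np.linalg.norm(pos, axis=1), src.sad, atol=1e-9)

    def test_energy_sampling_matches_spectrum(self):
        spec = sm.EnergySpectrum(np.array([30.0, 60.0, 90.0]),
                                 np.array([0.2, 0.5, 0.3]))
        src = sm.VirtualPointSource(
            kvp=100.0, spectrum_map=sm.SpectrumMap.uniform(spec, 30.0),
            fluence=sm.PlanarFluence.flat(), blades=(5.0, 5.0, 5.0, 5.0),
            arc_deg=360.0, mas=1.0)
        rng = np.random.default_rng(3)
        *_, e, _, _ = sm.sample_photons(src, 100_000, rng)
        n = len(e)
        for energy, p in zip(spec.energies, spec.weights):
            k = (e == energy).sum()
            assert abs(k - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_single_photon_state(self):
        src = make_mono_source()
        ph = sm.sample_photon(src, np.random.default_rng(4))
        assert np.linalg.norm(ph.direction) == pytest.approx(1.0, abs=1e-12)
        assert ph.weight == 1.0 and ph.energy == 60.0


class TestFluenceWeight:
    def test_outside_asymmetric_blade_is_zero(self):
        src = make_mono_source(blades=(6.8, 23.5, 10.3, 10.3))
        assert sm.fluence_weight(src, 24.0, 0.0) == 0.0
        assert sm.fluence_weight(src, -7.0, 0.0) == 0.0
        assert sm.fluence_weight(src, 23.0, 0.0) > 0.0

    def test_axis_normalization(self):
        src = make_mono_source()
        assert sm.fluence_weight(src, 0.0, 0.0) == pytest.approx(1.0)

    def test_mirror_symmetry_for_symmetric_input(self):
        grid = np.linspace(-14.0, 14.0, 29)
        vals = 1.0 / (1.0 + (grid / 10.0) ** 2)
        fl = sm.PlanarFluence(grid, vals, grid, np.ones_like(grid))
        spec = sm.EnergySpectrum(np.array([60.0]), np.array([1.0]))
        src = sm.VirtualPointSource(
            kvp=100.0, spectrum_map=sm.SpectrumMap.uniform(spec, 14.0),
            fluence=fl, blades=(13.6, 13.6, 9.2, 9.2), arc_deg=200.0,
            arc_start_deg=-100.0, mas=1.0)
        for x in (3.0, 7.5, 12.0):
            assert sm.fluence_weight(src, x, 2.0) == pytest.approx(
                sm.fluence_weight(src, -x, 2.0), rel=1e-12)


def test_source_serialization_round_trip(pelvis_source):
    d = sm.source_to_dict(pelvis_source)
    back = sm.source_from_dict(d)
    assert back.kvp == pelvis_source.kvp
    assert back.blades == pelvis_source.blades
    assert np.allclose(back.spectrum_map.weight_matrix,
                       pelvis_source.spectrum_map.weight_matrix)
    x = 3.7
    assert back.fluence_weight(x, 1.2) == pytest.approx(
        pelvis_source.fluence_weight(x, 1.2), rel=1e-12)


def test_protocol_presets_match_technique_table():
    p = sm.PROTOCOLS
    assert p["pelvis"].kvp == 125 and p["pelvis"].mas == 580
    assert p["pelvis"].blades == (6.8, 23.5, 10.3, 10.3)
    assert p["thorax"].kvp == 110 and p["thorax"].arc_deg == 360
    assert p["head"].kvp == 100 and p["head"].arc_deg == 200
    assert p["head"].blades == (13.6, 13.6, 9.2, 9.2)
    assert p["pelvis_spotlight"].mas == 720
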