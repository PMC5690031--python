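"""Transport engine: ray tracing, primary, biased scatter, oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from kvdose import materials as M
from kvdose import phantoms_io as ph
from kvdose import transport as tr
from kvdose.transport import _kernels as K
from tests.conftest import make_mono_source

MEC2 = 510.998950


class TestTraceOpticalLength:
    def test_ray_missing_grid_is_zero(self, water_cube, water_scheme):
        tau = tr.trace_optical_length(water_cube, water_scheme,
                                      (-100, 50, 0), (100, 50, 0), 60.0)
        assert tau == 0.0

    def test_uniform_path_closed_form(self, coarse_cylinder, acrylic_scheme):
        mu = M.mixture_mu(M.ACRYLIC, 60.0).linear
        tau = tr.trace_optical_length(coarse_cylinder, acrylic_scheme,
                                      (-5.0, 0.0, 0.0), (5.0, 0.0, 0.0), 60.0)
        assert tau == pytest.approx(mu * 10.0, rel=1e-9)

    def test_symmetry_under_endpoint_swap(self, coarse_cylinder, acrylic_scheme):
        a, b = (-9.0, 2.5, 1.0), (6.0, -3.0, -4.0)
        t1 = tr.trace_optical_length(coarse_cylinder, acrylic_scheme, a, b, 80.0)
        t2 = tr.trace_optical_length(coarse_cylinder, acrylic_scheme, b, a, 80.0)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_non_finite_endpoints(self, water_cube, water_scheme):
        with pytest.raises(ValueError):
            tr.trace_optical_length(water_cube, water_scheme,
                                    (np.nan, 0, 0), (0, 0, 0), 60.0)


class TestPrimary:
    def test_inverse_square(self, water_cube, mist_scheme):
        """Attenuation-free medium: dose follows 1/r^2 from the focal spot."""
        src = make_mono_source(60.0, arc_deg=1e-6)
        # source at (0, -100, 0); on-axis POIs at 88 cm and 112 cm
        d_near = tr.primary_dose(src, water_cube, mist_scheme, (0.0, -12.0, 0.0))
        d_far = tr.primary_dose(src, water_cube, mist_scheme, (0.0, 12.0, 0.0))
        assert d_near / d_far == pytest.approx((112.0 / 88.0) ** 2, rel=1e-9)

    def test_slab_attenuation_closed_form(self, water_cube, water_scheme,
                                          mist_scheme):
        src = make_mono_source(60.0, arc_deg=1e-6)
        poi = (0.0, 10.0, 0.0)
        with_slab = tr.primary_dose(src, water_cube, water_scheme, poi)
        free = tr.primary_dose(src, water_cube, mist_scheme, poi)
        mu = M.mixture_mu(M.WATER, 60.0).linear
        # beam enters at y=-16: 26 cm of water to the POI
        assert with_slab / free == pytest.approx(np.exp(-mu * 26.0), rel=1e-9)

    def test_poi_outside_collimation_gets_zero(self, water_cube, mist_scheme):
        src = make_mono_source(60.0, blades=(2.0, 2.0, 2.0, 2.0), arc_deg=1.0)
        assert tr.primary_dose(src, water_cube, mist_scheme,
                               (10.0, 0.0, 0.0)) == 0.0

    def test_poi_outside_phantom_raises(self, water_cube, water_scheme):
        src = make_mono_source()
        with pytest.raises(ValueError):
            tr.primary_dose(src, water_cube, water_scheme, (100.0, 0.0, 0.0))


class TestScatterPopulation:
    def test_vacuum_phantom_empty_population(self, water_cube, vacuum_scheme):
        src = make_mono_source()
        pop = tr.generate_scatter_population(src, water_cube, vacuum_scheme,
                                             2000, seed=1)
        assert len(pop) == 0

    def test_weights_and_generations(self, water_cube, water_scheme):
        src = make_mono_source()
        pop = tr.generate_scatter_population(src, water_cube, water_scheme,
                                             5000, seed=2)
        assert len(pop) > 0
        assert np.all(pop.weights <= 1.0 + 1e-12)
        assert np.all(pop.weights > 0)
        assert np.all(pop.generations >= 1)

    def test_first_interaction_depth_distribution(self, water_cube,
                                                  water_scheme):
        """Forced-interaction sites follow the truncated exponential."""
        src = make_mono_source(60.0, blades=(0.05, 0.05, 0.05, 0.05),
                               arc_deg=1e-3)
        pop = tr.generate_scatter_population(src, water_cube, water_scheme,
                                             40_000, seed=3)
        depth = pop.positions[pop.generations == 1, 1] + 16.0  # entry at y=-16
        mu = M.mixture_mu(M.WATER, 60.0).linear
        edges = np.linspace(0.0, 10.0, 11)
        counts, _ = np.histogram(depth, bins=edges)
        cdf = (1 - np.exp(-mu * edges)) / (1 - np.exp(-mu * 32.0))
        p = np.diff(cdf)
        n = len(depth)
        chi2 = np.sum((counts - n * p) ** 2 / (n * p))
        assert chi2 < stats.chi2.ppf(0.999, len(p) - 1)


def _kn_single_voxel_oracle(poi_x=5.0, energy=60.0):
    """Closed-form first-scatter dose at a lateral point from one water voxel.

    Pencil beam along +y through a 1 cm water voxel at the origin; the
    phantom elsewhere is water mist (no attenuation, water kerma).  Returns
    dose per unit (mas x output-calibrated) normalization, i.e. the same
    quantity compute_dose reports, via 1-D quadrature.
    """
    mu_t = M.mixture_mu(M.WATER, energy).linear
    mu_c = M.mixture_mu(M.WATER, energy, "coherent").linear
    mu_i = M.mixture_mu(M.WATER, energy, "incoherent").linear
    k = energy / MEC2
    sig = K._kn_sigma_re2(k)

    def exit_len(t, cost_dir):
        # distance from (0, t, 0) to the voxel x-face along the ray to the POI
        d = np.sqrt(poi_x**2 + t**2)
        return 0.5 / (poi_x / d)

    def integrand(t):
        d2 = poi_x**2 + t**2
        d = np.sqrt(d2)
        cost = -t / d
        le = exit_len(t, cost)
        # coherent branch: Thomson shape, energy unchanged
        coh = mu_c * (3.0 / (16.0 * np.pi)) * (1.0 + cost**2) \
            * np.exp(-mu_t * le) * M.kerma_per_fluence(M.WATER, energy) * 100
        # incoherent branch: Klein-Nishina toward the POI
        r = 1.0 / (1.0 + k * (1.0 - cost))
        e_out = energy * r
        pdf = 0.5 * r * r * (r + 1.0 / r - (1.0 - cost**2)) / sig
        mu_out = M.mixture_mu(M.WATER, e_out).linear
        inc = mu_i * pdf * np.exp(-mu_out * le) \
            * M.kerma_per_fluence(M.WATER, e_out) * 100
        return np.exp(-mu_t * (t + 0.5)) * (coh + inc) / d2

    val, _ = quad(integrand, -0.5, 0.5, limit=200)
    return val


class TestScatterDoseOracles:
    def _single_voxel_setup(self):
        hu = np.zeros((11, 11, 11), dtype=np.int16)  # mist everywhere
        hu[5, 5, 5] = 100                            # one water voxel
        mist = M.Material("mist2", dict(M.WATER.composition), 1e-12)
        scheme = M.SegmentationScheme("one_voxel", (
            (-1024, 50, mist), (50, 10000, M.WATER)))
        vol = ph.VoxelPhantom(hu, (10.0, 10.0, 10.0), (-5.0, -5.0, -5.0))
        src = make_mono_source(60.0, blades=(0.05, 0.05, 0.05, 0.05),
                               arc_deg=1e-3, mas=1.0, output=1.0)
        return vol, scheme, src

    def test_single_scatter_matches_klein_nishina_closed_form(self):
        vol, scheme, src = self._single_voxel_setup()
        poi = (5.0, 0.0, 0.0)
        res = tr.compute_dose(src, vol, scheme, [poi], n_photons=80_000,
                              seed=11)[0]
        phi0 = src.output_cgy_per_mas / (
            M.kerma_per_fluence(M.AIR, 60.0) * 100)
        n0 = src.mas * phi0 * 0.1 * 0.1  # flat fluence over the pencil field
        oracle = n0 * _kn_single_voxel_oracle()
        sigma = res.rel_uncertainty * res.total
        assert res.first_scatter == pytest.approx(
            oracle, abs=3 * sigma + 0.02 * oracle)

    def test_zero_density_phantom_zero_scatter(self, water_cube,
                                               vacuum_scheme):
        src = make_mono_source()
        pop = tr.generate_scatter_population(src, water_cube, vacuum_scheme,
                                             1000, seed=4)
        first, mult, sig = tr.scatter_dose((0, 0, 0), pop, water_cube,
                                           vacuum_scheme)
        assert (first, mult, sig) == (0.0, 0.0, 0.0)

    def test_doubling_weights_doubles_components(self, water_cube,
                                                 water_scheme):
        src = make_mono_source()
        pop = tr.generate_scatter_population(src, water_cube, water_scheme,
                                             4000, seed=5)
        f1, m1, _ = tr.scatter_dose((0, 0, 0), pop, water_cube, water_scheme)
        pop2 = dataclasses.replace(pop, weights=2.0 * pop.weights)
        f2, m2, _ = tr.scatter_dose((0, 0, 0), pop2, water_cube, water_scheme)
        assert f2 == 2.0 * f1 and m2 == 2.0 * m1


class TestComputeDose:
    def test_total_is_sum_of_components(self, water_cube, water_scheme,
                                        mono60_source):
        res = tr.compute_dose(mono60_source, water_cube, water_scheme,
                              [(0, 0, 0), (0, 5, 0)], 20_000, seed=6)
        for r in res:
            assert r.total == r.primary + r.first_scatter + r.multiple_scatter

    def test_doubling_mas_doubles_every_component(self, water_cube,
                                                  water_scheme, mono60_source):
        r1 = tr.compute_dose(mono60_source, water_cube, water_scheme,
                             [(0, 0, 0)], 20_000, seed=7)[0]
        src2 = dataclasses.replace(mono60_source, mas=2 * mono60_source.mas)
        r2 = tr.compute_dose(src2, water_cube, water_scheme,
                             [(0, 0, 0)], 20_000, seed=7)[0]
        assert r2.primary == 2.0 * r1.primary
        assert r2.first_scatter == 2.0 * r1.first_scatter
        assert r2.multiple_scatter == 2.0 * r1.multiple_scatter

    def test_full_arc_left_right_symmetry(self, coarse_cylinder,
                                          acrylic_scheme):
        src = make_mono_source(60.0, blades=(10.0, 10.0, 10.0, 10.0),
                               arc_deg=360.0)
        res = tr.compute_dose(src, coarse_cylinder, acrylic_scheme,
                              [(4.5, 0, 0), (-4.5, 0, 0)], 120_000, seed=8)
        a, b = res
        comb = np.hypot(a.rel_uncertainty * a.total,
                        b.rel_uncertainty * b.total)
        assert abs(a.total - b.total) < 3 * comb

    def test_fixed_seed_bit_identical(self, water_cube, water_scheme,
                                      mono60_source):
        r1 = tr.compute_dose(mono60_source, water_cube, water_scheme,
                             [(0, 0, 0)], 30_000, seed=9)[0]
        r2 = tr.compute_dose(mono60_source, water_cube, water_scheme,
                             [(0, 0, 0)], 30_000, seed=9)[0]
        assert r1 == r2

    def test_uncertainty_scales_as_inverse_sqrt_n(self, water_cube,
                                                  water_scheme, mono60_source):
        rels = []
        for n in (10_000, 100_000, 1_000_000):
            r = tr.compute_dose(mono60_source, water_cube, water_scheme,
                                [(0, 0, 0)], n, seed=10)[0]
            rels.append(r.rel_uncertainty)
        for lo, hi in ((0, 1), (1, 2)):
            ratio = rels[lo] / rels[hi]
            assert np.sqrt(10) / 1.3 < ratio < np.sqrt(10) * 1.3


class TestAnalogOracleEquivalence:
    def test_biased_engine_matches_analog_mc(self, water_cube, water_scheme):
        """32^3 homogeneous cube, stationary beam: two independent engines."""
        src = make_mono_source(60.0, arc_deg=1.0)
        pois = [(0.0, 0.0, 0.0), (0.0, 5.0, 0.0), (2.0, -2.0, 0.0),
                (0.0, -8.0, 0.0), (3.0, 3.0, 3.0)]
        res = tr.compute_dose(src, water_cube, water_scheme, pois,
                              200_000, seed=12)
        for i, (p, r) in enumerate(zip(pois, res)):
            dose_a, sig_a = tr.analog_reference_dose(
                src, water_cube, water_scheme, p, radius_cm=0.5,
                n_photons=600_000, seed=100 + i)
            comb = np.hypot(sig_a, r.rel_uncertainty * r.total)
            assert abs(r.total - dose_a) < 3.0 * comb, (p, r.total, dose_a)


@pytest.fixture(scope="module")
def fine_mist():
    hu = np.zeros((64, 64, 21), dtype=np.int16)
    return ph.VoxelPhantom(hu, (0.81, 0.81, 3.0),
                           ph._centered_origin((64, 64, 21), (0.81, 0.81, 3.0)))


class TestVolumeAverage:
    def test_uniformish_field_mean_matches_point(self, fine_mist, mist_scheme):
        src = make_mono_source(60.0, arc_deg=1.0)
        mean, sd, results = tr.volume_average_dose(
            src, fine_mist, mist_scheme, (0.0, 0.0, 0.0), n_photons=5000,
            seed=13)
        assert len(results) > 5  # detector-sized lattice at this pitch
        point = tr.compute_dose(src, fine_mist, mist_scheme, [(0.0, 0.0, 0.0)],
                                5000, seed=13)[0].total
        assert mean == pytest.approx(point, rel=1e-3)
        assert sd < 0.01 * mean

    def test_region_outside_phantom_raises(self, fine_mist, mist_scheme,
                                           mono60_source):
        # detector lattice extends past the +y face even though the center
        # voxel itself is inside
        with pytest.raises(ValueError):
            tr.volume_average_dose(mono60_source, fine_mist, mist_scheme,
                                   (0.0, 2.45, 0.0), n_photons=1000)
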