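"""TLD calibration, CTDIw, comparison statistics, DTA, conversion factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kvdose import analysis_calibration as ac
from kvdose import materials as M
from kvdose import phantoms_io as ph
from kvdose import source_characterization as sc


class TestTldFit:
    def test_noiseless_fit_is_exact(self):
        q = np.array([1.0, 2.0, 3.0, 4.0])
        cal = ac.tld_fit(q, 2.0 * q + 0.1)
        assert cal.m == pytest.approx(2.0, abs=1e-12)
        assert cal.b == pytest.approx(0.1, abs=1e-12)
        assert cal.dm == pytest.approx(0.0, abs=1e-9)
        assert cal.db == pytest.approx(0.0, abs=1e-9)

    def test_constant_dose_shift_moves_intercept_only(self):
        q = np.array([1.0, 2.0, 3.0, 5.0])
        d = 1.7 * q + 0.2
        c1 = ac.tld_fit(q, d)
        c2 = ac.tld_fit(q, d + 0.5)
        assert c2.m == pytest.approx(c1.m, rel=1e-12)
        assert c2.b == pytest.approx(c1.b + 0.5, rel=1e-9)

    def test_identical_charges_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            ac.tld_fit([2.0, 2.0, 2.0], [1.0, 1.1, 0.9])

    def test_fit_errors_match_bootstrap(self):
        """Standard errors agree with a brute-force bootstrap within 20%."""
        rng = np.random.default_rng(42)
        q = np.linspace(0.5, 5.0, 100)
        d = 2.0 * q + 0.1 + rng.normal(0, 0.2, q.size)
        cal = ac.tld_fit(q, d)
        ms, bs = [], []
        for _ in range(600):
            idx = rng.integers(0, q.size, q.size)
            c = np.polyfit(q[idx], d[idx], 1)
            ms.append(c[0])
            bs.append(c[1])
        assert cal.dm == pytest.approx(np.std(ms), rel=0.2)
        assert cal.db == pytest.approx(np.std(bs), rel=0.2)


class TestTldDose:
    def test_zero_charge_boundary(self):
        cal = ac.TLDCalibration(2.0, 0.1, 0.05, 0.02, 0.05)
        d, dd = ac.tld_dose(cal, 0.0)
        assert (d, dd) == (0.1, 0.02)

    def test_linear_uncertainty_combination(self):
        cal = ac.TLDCalibration(2.0, 0.1, 0.1, 0.02, 0.05)
        d, dd = ac.tld_dose(cal, 1.0)
        assert d == pytest.approx(2.1)
        assert dd == pytest.approx(1.0 * 0.1 + 2.0 * 0.05 * 1.0 + 0.02)

    def test_uncertainty_monotone_in_charge(self):
        cal = ac.TLDCalibration(2.0, 0.1, 0.1, 0.02, 0.05)
        dds = [ac.tld_dose(cal, q)[1] for q in (0.0, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(dds) > 0)


class TestCtdiw:
    def test_constant_doses(self):
        assert ac.ctdiw(2.5, [2.5] * 4) == pytest.approx(2.5)

    def test_standard_weighting(self):
        assert ac.ctdiw(1.0, [2.0, 2.0, 2.0, 2.0]) == pytest.approx(5.0 / 3.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.permutations([0.8, 1.3, 2.1, 0.5]))
    def test_periphery_permutation_invariance(self, periph):
        assert ac.ctdiw(1.0, list(periph)) == pytest.approx(
            ac.ctdiw(1.0, [0.8, 1.3, 2.1, 0.5]), rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            ac.ctdiw(1.0, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ac.ctdiw(-1.0, [1.0, 1.0, 1.0, 1.0])


class TestCompare:
    def test_identical_inputs(self):
        m = [(1.0, 0.1), (2.0, 0.2)]
        rep = ac.compare(m, m)
        assert rep.mean == 0.0 and rep.sd == 0.0
        assert rep.n_pass == rep.n_total == 2

    def test_disjoint_intervals_fail(self):
        rep = ac.compare([(1.0, 0.1)], [(1.25, 0.1)])
        assert rep.n_pass == 0
        assert rep.percent_diff[0] == pytest.approx(25.0)

    def test_hand_computed_five_point_fixture(self):
        measured = [(1.0, 0.05), (2.0, 0.1), (0.5, 0.02), (4.0, 0.2), (1.6, 0.1)]
        computed = [(1.1, 0.05), (1.9, 0.1), (0.52, 0.02), (4.2, 0.2), (1.6, 0.1)]
        rep = ac.compare(measured, computed)
        diffs = np.array([10.0, -5.0, 4.0, 5.0, 0.0])
        assert np.allclose(rep.percent_diff, diffs)
        assert rep.mean == pytest.approx(diffs.mean())
        assert rep.sd == pytest.approx(diffs.std(ddof=1))

    def test_sign_convention_on_swap(self):
        """Swapping inputs flips the sign of every local difference."""
        m = [(1.0, 0.1), (2.5, 0.1)]
        c = [(1.2, 0.1), (2.0, 0.1)]
        r1 = ac.compare(m, c)
        r2 = ac.compare(c, m)
        assert np.all(np.sign(r1.percent_diff) == -np.sign(r2.percent_diff))
        assert np.array_equal(r1.passed, r2.passed)

    def test_zero_measured_dose(self):
        with pytest.raises(ValueError):
            ac.compare([(0.0, 0.1)], [(1.0, 0.1)])


class TestDta:
    def test_identical_profiles(self):
        x = np.linspace(0, 10, 21)
        y = np.exp(-0.3 * x)
        out = ac.dta(np.column_stack([x[2:-2], y[2:-2]]), (x, y))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_shifted_profile_gives_shift(self):
        x = np.linspace(0.0, 20.0, 201)
        y = 100.0 - 3.0 * x  # monotone
        pts = np.column_stack([x[50:150:20], np.interp(x[50:150:20] + 2.0, x, y)])
        out = ac.dta(pts, (x, y))
        assert np.allclose(out, 2.0, atol=0.02)

    def test_matches_brute_force_grid(self):
        x = np.linspace(0.0, 10.0, 101)
        y = np.sin(x / 3.0) + 2.0
        pts = np.array([[4.0, 2.4], [7.0, 2.9]])
        out = ac.dta(pts, (x, y), resolution_mm=0.001)
        dense = np.arange(0, 10, 0.0002)
        yd = np.interp(dense, x, y)
        for (x0, d0), got in zip(pts, out):
            brute = np.min(np.abs(dense[np.abs(yd - d0) < 5e-5] - x0))
            assert got == pytest.approx(brute, abs=0.005)

    def test_unattained_dose_is_inf_and_empty_raises(self):
        x = np.linspace(0, 10, 11)
        out = ac.dta([[5.0, 99.0]], (x, np.ones_like(x)))
        assert np.isinf(out[0])
        with pytest.raises(ValueError):
            ac.dta(np.empty((0, 2)), (x, np.ones_like(x)))


@pytest.fixture(scope="module")
def thorax_setup():
    vol = ph.make_anatomy_fixture("thorax")
    scheme = M.get_scheme("thorax")
    src = sc.characterized_protocol_source("thorax")
    return vol, scheme, src


class TestLungToTissueFactor:
    def test_identity_substitution_is_exactly_one(self, thorax_setup):
        vol, scheme, src = thorax_setup
        f = ac.lung_to_tissue_factor(src, vol, scheme, (78, 128, 20),
                                     n_photons=1000, seed=1,
                                     substitute="rando_lung")
        assert f == 1.0

    def test_non_lung_voxel_raises(self, thorax_setup):
        vol, scheme, src = thorax_setup
        with pytest.raises(ValueError):
            ac.lung_to_tissue_factor(src, vol, scheme, (128, 128, 20))

    def test_factor_bracketed_by_kerma_ratio(self, thorax_setup):
        """The factor is a spectrum-weighted kerma ratio: it must lie near
        the lung/tissue kerma-factor band (transport through the substituted
        voxel itself adds only a small last-leg correction)."""
        vol, scheme, src = thorax_setup
        f = ac.lung_to_tissue_factor(src, vol, scheme, (92, 150, 20),
                                     n_photons=120_000, seed=6)
        eg = np.arange(10.0, 111.0)
        ratio = (M.kerma_per_fluence(M.RANDO_LUNG, eg)
                 / M.kerma_per_fluence(M.RANDO_TISSUE, eg))
        assert ratio.min() - 0.03 < f < ratio.max() + 0.03
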