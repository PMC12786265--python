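"""Bessel-expansion transforms, the direct-summation oracle, form factors."""

import math

import numpy as np
import pytest

import fiberdiff as fd
from fiberdiff.diffraction import (
    ReciprocalGrid,
    read_pattern_hdf5,
    read_pattern_text,
    write_pattern_hdf5,
    write_pattern_text,
)

from conftest import random_sites


class TestSphereFormFactor:
    def test_normalisation_at_zero(self):
        assert fd.sphere_form_factor(0.0, 5.0) == pytest.approx(1.0)

    def test_closed_form_at_x_pi(self):
        """x = pi (q = 1/(2 rs)) gives 3/pi^2."""
        rs = 4.0
        q = 1.0 / (2 * rs)
        assert fd.sphere_form_factor(q, rs) == pytest.approx(3.0 / math.pi**2, rel=1e-12)

    def test_first_zero_of_47_grain_ladder(self):
        """rs = 6.20 Å vanishes at the 8.67 Å Bragg spacing."""
        assert abs(fd.sphere_form_factor(1.0 / 8.67, 6.20)) < 1e-3

    def test_small_argument_series_is_continuous(self):
        rs = 3.0
        q = np.array([0.0, 1e-7, 1e-5, 1e-3])
        phi = fd.sphere_form_factor(q, rs)
        assert np.all(np.diff(phi) <= 0)
        assert phi[0] == 1.0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            fd.sphere_form_factor(0.1, 0.0)


class TestFormFactorFirstZero:
    def test_inversion_identity(self):
        """rs = x*/(2 pi) Å has its first zero at exactly 1 Å spacing."""
        from fiberdiff.diffraction import _first_zero_x

        rs = _first_zero_x() / (2 * math.pi)
        assert fd.form_factor_first_zero(rs) == pytest.approx(1.0, rel=1e-12)

    def test_spacing_proportional_to_radius(self):
        assert fd.form_factor_first_zero(10.0) == pytest.approx(
            10.0 * fd.form_factor_first_zero(1.0), rel=1e-12
        )


class TestHelixAmplitude:
    def test_on_axis_site_reduces_to_lattice_sum(self):
        """r0 = 0 keeps only n = 0: amplitude = sum_m exp(2 pi i Z z_m)."""
        z_m = np.array([0.0, 27.36, 54.72, 82.08])
        Z = 0.017
        amp = fd.helix_amplitude(0.0, 0.0, fd.ACTIN_DPSI0, z_m, [0.05], 1.1, [Z], n_max=12)
        expected = np.exp(2j * np.pi * Z * z_m).sum()
        assert amp[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_lattice_peak_magnitude_is_m_max(self):
        """At R = 0, Z = 1/p0 all monomer phases align."""
        p0, m_max = 27.36, 17
        z_m = np.arange(m_max) * p0
        amp = fd.helix_amplitude(16.2, 0.7, fd.ACTIN_DPSI0, z_m, [0.0], 0.0, [1 / p0], n_max=10)
        assert abs(amp[0, 0]) == pytest.approx(m_max, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_monomer_equals_plane_wave(self, seed):
        """Jacobi–Anger: one monomer's Bessel sum is the direct exponential."""
        rng = np.random.default_rng(seed)
        r0 = rng.uniform(1, 30)
        psi1 = rng.uniform(0, 2 * np.pi)
        z1 = rng.uniform(-10, 10)
        R, Psi, Z = rng.uniform(0, 0.12), rng.uniform(0, 2 * np.pi), rng.uniform(-0.1, 0.1)
        n_max = fd.bessel_order_cap(R, r0)
        amp = fd.helix_amplitude(r0, psi1, fd.ACTIN_DPSI0, np.array([z1]), [R], Psi, [Z], n_max)
        direct = np.exp(2j * np.pi * (R * r0 * np.cos(Psi - psi1) + Z * z1))
        assert amp[0, 0] == pytest.approx(direct, rel=1e-9)


class TestFilamentAmplitude:
    def test_empty_site_set_gives_zero(self):
        sites = fd.ScattererSet(r0=[], psi1=[], z1=[], rs=[], weight=[])
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=5))
        amp = fd.filament_amplitude(fil, [0.01], 0.0, [0.01], n_max=5)
        assert amp.shape == (1, 1) and amp[0, 0] == 0

    def test_forward_scattering_sum(self):
        sites = random_sites(3, n_sites=4)
        m_max = 6
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=m_max))
        amp = fd.filament_amplitude(fil, [0.0], 0.9, [0.0])
        assert amp[0, 0] == pytest.approx(sites.weight.sum() * m_max, rel=1e-10)


class TestOracleEquivalence:
    GRID = ReciprocalGrid(
        R_values=np.linspace(0.0, 0.12, 15),
        Z_values=np.linspace(-0.12, 0.12, 17),
        psi_values=np.linspace(0, 2 * np.pi, 6, endpoint=False),
    )

    @pytest.mark.parametrize("seed", range(5))
    def test_relaxed_filaments(self, seed):
        sites = random_sites(seed)
        rng = np.random.default_rng(seed + 100)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=int(rng.integers(1, 9))))
        fast = fd.cylindrically_averaged_intensity(fil, self.GRID)
        slow = fd.direct_sum_intensity(fil, self.GRID)
        rel = np.abs(fast.intensity - slow.intensity).max() / slow.intensity.max()
        assert rel < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_nonuniformly_strained_filaments(self, seed):
        """The Bessel path handles segment-wise spacing changes exactly."""
        sites = random_sites(seed, n_sites=3)
        m_max = 8
        relaxed = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=m_max))
        prof = fd.build_strain_profile(
            [3 * fd.ACTIN_P0, 6 * fd.ACTIN_P0], [200.0, 400.0], m_max=m_max
        )
        fil = fd.apply_deformation(relaxed, prof)
        fast = fd.cylindrically_averaged_intensity(fil, self.GRID)
        slow = fd.direct_sum_intensity(fil, self.GRID)
        rel = np.abs(fast.intensity - slow.intensity).max() / slow.intensity.max()
        assert rel < 1e-6

    def test_size_cap_error_suggests_fast_path(self):
        sites = random_sites(0, n_sites=5)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=364))
        with pytest.raises(ValueError, match="cylindrically_averaged_intensity"):
            fd.direct_sum_intensity(fil, self.GRID, max_terms=100)


class TestPatternProperties:
    def test_friedel_symmetry(self):
        sites = random_sites(7, n_sites=3)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=10))
        Z = np.linspace(-0.1, 0.1, 41)  # symmetric about 0
        grid = ReciprocalGrid(np.linspace(0, 0.06, 10), Z, np.linspace(0, 2 * np.pi, 18, endpoint=False))
        pat = fd.cylindrically_averaged_intensity(fil, grid)
        assert np.allclose(pat.intensity, pat.intensity[:, ::-1], rtol=1e-8)

    def test_intensity_nonnegative(self):
        sites = random_sites(9, n_sites=2)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=6))
        pat = fd.cylindrically_averaged_intensity(fil, self_grid())
        assert np.all(pat.intensity >= 0)

    def test_selection_rule_13_6(self):
        """Off-meridional intensity sits on layer lines Z = l/(13 p0) with
        l = 6n + 13m; between-line intensity is < 1e-3 of the line maximum."""
        p0 = fd.ACTIN_P0
        sites = fd.ScattererSet(r0=[16.2], psi1=[0.0], z1=[0.0], rs=[3.0], weight=[10.0])
        fil = fd.build_relaxed_filament(sites, fd.HelixParams.actin(m_max=13 * 8))
        repeat = 13 * p0
        z_on = 6 / repeat  # l = 6 layer line (59 Å)
        z_off = 6.5 / repeat  # midway between l = 6 and l = 7
        grid = ReciprocalGrid(
            np.array([0.02]), np.array([z_off, z_on]), np.linspace(0, 2 * np.pi, 18, endpoint=False)
        )
        pat = fd.cylindrically_averaged_intensity(fil, grid)
        assert pat.intensity[0, 0] < 1e-3 * pat.intensity[0, 1]

    def test_uniform_strain_is_axial_rescaling(self):
        """Strained pattern = relaxed pattern at Z*(1+delta), point scatterers."""
        sites = random_sites(11, n_sites=3)
        m_max, delta = 30, 0.003
        relaxed = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=m_max))
        strained = fd.apply_deformation(relaxed, fd.uniform_strain_profile(delta, m_max=m_max))
        Z = np.linspace(0.0, 0.08, 60)
        psis = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        R = np.linspace(0.0, 0.05, 12)
        g_strained = ReciprocalGrid(R, Z, psis)
        g_rescaled = ReciprocalGrid(R, Z * (1 + delta), psis)
        i_strained = fd.cylindrically_averaged_intensity(strained, g_strained, form_factor=False)
        i_rescaled = fd.cylindrically_averaged_intensity(relaxed, g_rescaled, form_factor=False)
        rel = np.abs(i_strained.intensity - i_rescaled.intensity).max() / i_rescaled.intensity.max()
        assert rel < 1e-10

    def test_first_radial_maximum_moves_inward_with_larger_r0(self):
        """On the |n| = 1 layer line the first maximum tracks J1: larger helix
        radius puts it at smaller R."""
        positions = []
        R = np.linspace(1e-4, 0.05, 400)
        for r0 in (10.0, 16.2, 30.0):
            sites = fd.ScattererSet(r0=[r0], psi1=[0.0], z1=[0.0], rs=[3.0], weight=[10.0])
            fil = fd.build_relaxed_filament(sites, fd.HelixParams.actin(m_max=26))
            z6 = 1.0 / fd.HelixParams.actin().pitch  # 6th layer line (59 Å)
            grid = ReciprocalGrid(R, np.array([z6]), np.linspace(0, 2 * np.pi, 6, endpoint=False))
            pat = fd.cylindrically_averaged_intensity(fil, grid)
            positions.append(R[np.argmax(pat.intensity[:, 0])])
        assert positions[0] > positions[1] > positions[2]


def self_grid():
    return ReciprocalGrid(
        R_values=np.linspace(0, 0.08, 9),
        Z_values=np.linspace(-0.08, 0.08, 11),
        psi_values=np.linspace(0, 2 * np.pi, 4, endpoint=False),
    )


class TestLorentz:
    def test_multiplies_by_R(self):
        sites = random_sites(2, n_sites=2)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=4))
        grid = ReciprocalGrid(np.array([0.0, 0.1]), np.array([0.0]), np.array([0.0]))
        pat = fd.cylindrically_averaged_intensity(fil, grid)
        cor = fd.lorentz_correct(pat)
        assert cor.intensity[0, 0] == 0.0  # R = 0 column
        assert cor.intensity[1, 0] == pytest.approx(0.1 * pat.intensity[1, 0])

    def test_double_application_raises(self):
        sites = random_sites(2, n_sites=2)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=4))
        pat = fd.cylindrically_averaged_intensity(fil, self_grid())
        cor = fd.lorentz_correct(pat)
        with pytest.raises(ValueError, match="already applied"):
            fd.lorentz_correct(cor)

    def test_raw_pattern_untouched(self):
        sites = random_sites(2, n_sites=2)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=4))
        pat = fd.cylindrically_averaged_intensity(fil, self_grid())
        before = pat.intensity.copy()
        fd.lorentz_correct(pat)
        np.testing.assert_array_equal(pat.intensity, before)


class TestPatternIO:
    def _pattern(self):
        sites = random_sites(4, n_sites=2)
        fil = fd.build_relaxed_filament(sites, fd.HelixParams(m_max=5))
        return fd.cylindrically_averaged_intensity(fil, self_grid())

    def test_text_round_trip(self, tmp_path):
        pat = self._pattern()
        path = tmp_path / "pattern.txt"
        write_pattern_text(pat, path)
        back = read_pattern_text(path)
        np.testing.assert_allclose(back.intensity, pat.intensity, rtol=1e-9)
        np.testing.assert_allclose(back.R, pat.R, rtol=1e-7)
        assert back.lorentz_applied is False

    def test_hdf5_round_trip(self, tmp_path):
        pat = fd.lorentz_correct(self._pattern())
        path = tmp_path / "pattern.h5"
        write_pattern_hdf5(pat, path)
        back = read_pattern_hdf5(path)
        np.testing.assert_allclose(back.intensity, pat.intensity)
        assert back.lorentz_applied is True
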