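"""Scattering-factor mathematics: radial transforms, harmonics, Gaussian
and Slater factors, multipolar deformation terms, Mott-Bethe conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import spherical_jn

from conftest import random_rotation
from taamkit.bank import GaussianTable
from taamkit.constants import MOTT_BETHE_CONSTANT
from taamkit.form_factors import (ValidityWarning, gaussian_ff, mott_bethe,
                                  multipolar_ff, spherical_slater_ff)
from taamkit.harmonics import N_LM, d_lm, lm_index, real_sph_harm
from taamkit.radial import slater_fourier_bessel, slater_norm
from taamkit.tables import builtin_table, slater_shell_set


def quadrature_jl(n, zeta, l, H):
    norm = slater_norm(n, zeta)
    val, _ = quad(lambda r: 4 * np.pi * r**2 * norm * r**n * np.exp(-zeta * r)
                  * spherical_jn(l, H * r), 0, np.inf,
                  limit=400, epsabs=1e-13, epsrel=1e-13)
    return val


class TestRadialTransforms:
    def test_closed_form_example(self):
        # n = 0: <j0>(H) = zeta^4 / (zeta^2 + H^2)^2, so 1/4 at H = zeta
        assert slater_fourier_bessel(0, 3.0, 0, 3.0) == pytest.approx(0.25, abs=1e-12)

    def test_origin_limits(self):
        for n, zeta in [(0, 1.0), (4, 7.5), (8, 2.2)]:
            assert slater_fourier_bessel(n, zeta, 0, 0.0) == pytest.approx(1.0)
        for l in range(1, 5):
            assert slater_fourier_bessel(l + 2, 5.0, l, 0.0) == 0.0

    def test_n_below_l_is_domain_error(self):
        with pytest.raises(ValueError, match="n="):
            slater_fourier_bessel(1, 3.0, 2, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(l=st.integers(0, 4), dn=st.integers(0, 4),
           zeta=st.floats(1.0, 10.0), H=st.floats(0.0, 25.0))
    def test_matches_adaptive_quadrature_over_box(self, l, dn, zeta, H):
        n = l + dn
        oracle = quadrature_jl(n, zeta, l, H)
        value = slater_fourier_bessel(n, zeta, l, H)
        assert value == pytest.approx(oracle, rel=1e-8, abs=1e-9)

    def test_series_and_recursion_branches_agree(self):
        # straddle the internal switchover with a dense H scan
        for l, n, zeta in [(4, 6, 3.0), (2, 3, 8.0), (0, 1, 1.0)]:
            H = np.linspace(0.01, 1.2 * zeta, 200)
            vals = slater_fourier_bessel(n, zeta, l, H)
            assert np.all(np.isfinite(vals))
            # compare a few points on each side against quadrature
            for h in (0.1 * zeta, 0.19 * zeta, 0.21 * zeta, 0.5 * zeta):
                assert slater_fourier_bessel(n, zeta, l, h) == pytest.approx(
                    quadrature_jl(n, zeta, l, h), rel=1e-8, abs=1e-10)


class TestHarmonics:
    def test_density_normalization_integrates_to_two(self):
        """For l >= 1 the density-normalized |d_lm| integrates to 2 over
        the sphere (independent Monte Carlo check)."""
        rng = np.random.default_rng(0)
        u = rng.normal(size=(200_000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        for l, m in [(1, 0), (2, 2), (3, -1), (4, 4)]:
            mc = 4 * np.pi * np.mean(np.abs(d_lm(l, m, u)))
            assert mc == pytest.approx(2.0, rel=0.02)

    def test_d00_is_one(self):
        u = np.array([[0.0, 0.0, 1.0], [0.6, 0.8, 0.0]])
        assert np.allclose(d_lm(0, 0, u), 1.0)

    def test_orthonormal_basis(self):
        """The underlying real harmonics are orthonormal on the sphere."""
        nodes, w = np.polynomial.legendre.leggauss(60)
        nphi = 120
        phi = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
        st_ = np.sqrt(1 - nodes**2)
        u = np.stack([st_[:, None] * np.cos(phi), st_[:, None] * np.sin(phi),
                      np.broadcast_to(nodes[:, None], (60, nphi))], axis=-1)
        pairs = [(1, 0), (1, 1), (2, 0), (2, -2), (3, 3), (4, 0)]
        for i, (l1, m1) in enumerate(pairs):
            y1 = real_sph_harm(l1, m1, u)
            for l2, m2 in pairs[i:]:
                y2 = real_sph_harm(l2, m2, u)
                val = np.sum(y1 * y2 * w[:, None]) * 2 * np.pi / nphi
                assert val == pytest.approx(
                    1.0 if (l1, m1) == (l2, m2) else 0.0, abs=1e-10)

    def test_parity(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(50, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        for l in range(5):
            for m in range(-l, l + 1):
                assert np.allclose(d_lm(l, m, -u), (-1.0) ** l * d_lm(l, m, u))


class TestGaussianFF:
    def test_closed_forms(self):
        t = GaussianTable("four-gauss-const", 2.0)
        t.add(6, [2.0], [0.0], 0.0)
        assert gaussian_ff(6, 1.3, t) == pytest.approx(2.0)
        t2 = GaussianTable("four-gauss-const", 2.0)
        t2.add(6, [1.0], [1.0], 0.0)
        assert gaussian_ff(6, 1.0, t2) == pytest.approx(np.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("z", [1, 6, 7, 8, 16, 26, 53])
    def test_xray_tables_sum_to_z_at_origin(self, z):
        for dialect in ("four-gauss-const", "five-gauss"):
            f0 = gaussian_ff(z, 0.0, builtin_table(dialect))
            assert f0 == pytest.approx(z, abs=0.02)

    def test_validity_warning_past_smax(self):
        with pytest.warns(ValidityWarning):
            gaussian_ff(6, 3.0, builtin_table("four-gauss-const"))

    def test_missing_element_is_lookup_error(self):
        with pytest.raises(KeyError):
            gaussian_ff(99, 0.1, builtin_table("four-gauss-const"))


class TestSphericalSlater:
    def test_origin_value_is_electron_count(self):
        sh = slater_shell_set(8)
        assert spherical_slater_ff(sh, sh.n_valence, 1.0, 0.0) == pytest.approx(8.0)
        assert spherical_slater_ff(sh, 5.5, 0.9, 0.0) == pytest.approx(
            sh.n_core + 5.5)

    def test_zero_valence_is_pure_core(self):
        sh = slater_shell_set(6)
        s = np.linspace(0, 2, 20)
        from taamkit.form_factors import _shell_sum
        assert np.allclose(spherical_slater_ff(sh, 0.0, 1.0, s),
                           _shell_sum(sh.core, s))

    def test_contracted_density_scatters_higher_at_high_s(self):
        """kappa > 1 contracts the valence density in real space, pushing
        scattering power to higher angle (checked at s = 0.4 Å⁻¹, inside
        the positive-decaying lobe of the carbon valence transform)."""
        sh = slater_shell_set(6)
        f_contracted = spherical_slater_ff(sh, 4.0, 1.2, 0.4)
        f_neutral = spherical_slater_ff(sh, 4.0, 1.0, 0.4)
        assert f_contracted > f_neutral

    def test_matches_iam_gaussian_roughly(self):
        """Synthetic Slater atoms track the Gaussian IAM curve at low
        angle (sanity of the synthetic shell model, loose)."""
        for z in (6, 7, 8):
            sh = slater_shell_set(z)
            for s in (0.1, 0.3, 0.5):
                f_s = spherical_slater_ff(sh, sh.n_valence, 1.0, s)
                f_g = gaussian_ff(z, s, builtin_table("four-gauss-const"))
                assert f_s == pytest.approx(f_g, rel=0.25)


def brute_force_multipolar(entry, frame, g_cart, nr=140, nt=50, nphi=100):
    """3D numerical Fourier transform of the entry's real-space density
    on a radial x angular product grid (independent of the analytic
    plane-wave-expansion code path)."""
    zeta_min = min(min(a for _, _, a in entry.core_valence_model.core
                       + entry.core_valence_model.valence),
                   entry.kappa_prime * entry.radial.zeta)
    rmax = 40.0 / zeta_min
    xr, wr = np.polynomial.legendre.leggauss(nr)
    r = 0.5 * rmax * (xr + 1)
    wr = wr * 0.5 * rmax
    ct, wt = np.polynomial.legendre.leggauss(nt)
    stheta = np.sqrt(1 - ct**2)
    phi = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
    x = r[:, None, None] * stheta[None, :, None] * np.cos(phi)[None, None, :]
    y = r[:, None, None] * stheta[None, :, None] * np.sin(phi)[None, None, :]
    z = r[:, None, None] * ct[None, :, None] * np.ones(nphi)[None, None, :]
    xyz = np.stack([x, y, z], axis=-1)
    rr = np.linalg.norm(xyz, axis=-1)
    u = xyz / np.maximum(rr[..., None], 1e-300)
    sh = entry.core_valence_model
    dens = np.zeros_like(rr)
    for occ, n, al in sh.core:
        dens += occ * slater_norm(n, al) * rr**n * np.exp(-al * rr)
    for occ, n, al in sh.valence:
        a2 = entry.kappa * al
        dens += (entry.p_val / sh.n_valence) * occ * slater_norm(n, a2) \
            * rr**n * np.exp(-a2 * rr)
    for l in range(5):
        zt = entry.kappa_prime * entry.radial.zeta
        n = entry.radial.n_l[l]
        rad = slater_norm(n, zt) * rr**n * np.exp(-zt * rr)
        for m in range(-l, l + 1):
            p = entry.p_lm[lm_index(l, m)]
            if p:
                dens += p * rad * d_lm(l, m, u)
    weight = wr[:, None, None] * wt[None, :, None] * (2 * np.pi / nphi) \
        * r[:, None, None] ** 2
    g_loc = frame.T @ np.asarray(g_cart)
    phase = np.exp(2j * np.pi * (xyz @ g_loc))
    return complex(np.sum(dens * weight * phase))


class TestMultipolar:
    def test_spherical_limit_equals_slater_path(self, bank):
        import dataclasses
        entry = bank.entries[0]
        neutral = dataclasses.replace(entry, p_lm=tuple([0.0] * N_LM),
                                      kappa=1.0, kappa_prime=1.0)
        rng = np.random.default_rng(0)
        g = rng.normal(size=(1000, 3)) * 0.8
        s = np.linalg.norm(g, axis=1) / 2
        f_m = multipolar_ff(neutral, np.eye(3), g)
        f_s = spherical_slater_ff(entry.core_valence_model, entry.p_val, 1.0, s)
        assert np.allclose(f_m.real, f_s, rtol=1e-14, atol=1e-14)
        assert np.allclose(f_m.imag, 0.0, atol=1e-14)

    def test_hermitian_symmetry(self, bank):
        rng = np.random.default_rng(2)
        frame = random_rotation(rng)
        for entry in bank.entries[:4]:
            g = rng.normal(size=(20, 3)) * 0.7
            assert np.allclose(multipolar_ff(entry, frame, -g),
                               np.conj(multipolar_ff(entry, frame, g)),
                               atol=1e-13)

    def test_rotation_invariance(self, bank):
        """Rotating frame and scattering vector together leaves the form
        factor unchanged."""
        rng = np.random.default_rng(3)
        entry = bank.entries[3]
        frame = random_rotation(rng)
        g = rng.normal(size=(30, 3)) * 0.9
        f0 = multipolar_ff(entry, frame, g)
        rot = random_rotation(rng)
        f1 = multipolar_ff(entry, rot @ frame, g @ rot.T)
        assert np.allclose(f0, f1, atol=1e-10)

    def test_agrees_with_brute_force_fourier_transform(self, bank):
        rng = np.random.default_rng(4)
        for entry in (bank.entries[3], bank.entries[9]):  # C_carbonyl, H
            frame = random_rotation(rng)
            for _ in range(5):
                g = rng.normal(size=3)
                g *= rng.uniform(0.2, 1.6) / np.linalg.norm(g)
                f_num = brute_force_multipolar(entry, frame, g)
                f_an = multipolar_ff(entry, frame, g)
                assert abs(f_an - f_num) / abs(f_num) < 1e-4

    def test_missing_frame_is_contract_violation(self, bank):
        with pytest.raises(ValueError, match="frame"):
            multipolar_ff(bank.entries[0], None, np.array([0.1, 0.2, 0.3]))


class TestMottBethe:
    def test_fx_equal_z_gives_zero(self):
        assert mott_bethe(6.0, 6, 0.7) == 0.0

    def test_single_gaussian_closed_form(self):
        z, b1 = 6, 8.0
        s = 0.5
        fx = z * np.exp(-b1 * s**2)
        expected = MOTT_BETHE_CONSTANT * z * (1 - np.exp(-b1 * s**2)) / s**2
        assert mott_bethe(fx, z, s) == pytest.approx(expected, rel=1e-12)

    def test_origin_limit_matches_taylor(self):
        z, b1 = 6, 8.0
        limit = mott_bethe(float(z), z, 0.0,
                           gaussian_coeffs=([z], [b1], 0.0))
        assert limit == pytest.approx(MOTT_BETHE_CONSTANT * z * b1, rel=1e-12)
        s_small = 1e-4
        fx = z * np.exp(-b1 * s_small**2)
        assert mott_bethe(fx, z, s_small) == pytest.approx(limit, rel=1e-6)

    def test_charged_atom_diverges_at_origin(self):
        with pytest.raises(ZeroDivisionError, match="divergent"):
            mott_bethe(5.0, 6, 0.0, gaussian_coeffs=([5.0], [4.0], 0.0))

    @pytest.mark.parametrize("z", [6, 8, 16])
    def test_xray_tables_approximate_electron_tables(self, z):
        """Mott-Bethe applied to the X-ray Gaussian table tracks the
        embedded electron dialects within their fit validity (loose:
        the parameterizations are independent fits)."""
        s = np.linspace(0.15, 1.8, 30)
        fx = gaussian_ff(z, s, builtin_table("four-gauss-const"))
        fe_mb = mott_bethe(fx, z, s)
        for dialect in ("electron-6", "electron-2"):
            fe_tab = gaussian_ff(z, s, builtin_table(dialect))
            assert np.max(np.abs(fe_tab - fe_mb) / np.abs(fe_mb)) < 0.05
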