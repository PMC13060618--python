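"""Direct-summation structure factors, Debye-Waller factors, gradients."""

import tracemalloc

import gemmi
import numpy as np
import pytest

from conftest import typed
from taamkit.fixtures import FixtureRecipe, make_ls_target, make_structure
from taamkit.form_factors import gaussian_ff
from taamkit.model_io import (AtomSite, CrystalStructure, generate_reflections,
                              u_cart_to_u_star)
from taamkit.structure_factors import (debye_waller, direct_summation_sf,
                                       fft_iam_sf, per_reflection_sf_gradients,
                                       sf_gradients)
from taamkit.tables import builtin_table


def single_atom(frac=(0.0, 0.0, 0.0), b=0.0, occ=1.0, z=6, a=10.0):
    cell = gemmi.UnitCell(a, a, a, 90, 90, 90)
    ident = [(np.eye(3, dtype=int), np.zeros(3))]
    site = AtomSite("X", z, np.array(frac), occupancy=occ, b_iso=b)
    return CrystalStructure(cell, ident, [site])


class TestDebyeWaller:
    def test_b_zero_is_one(self):
        st = single_atom()
        assert debye_waller(0.0, [1, 2, 3], 0.4, st.cell) == 1.0

    def test_isotropic_closed_form(self):
        st = single_atom()
        assert debye_waller(10.0, [1, 0, 0], 0.5, st.cell) \
            == pytest.approx(np.exp(-2.5), rel=1e-12)

    def test_isotropic_tensor_reproduces_b(self):
        """U = u*I in Cartesian coordinates equals B = 8 pi^2 u."""
        cell = gemmi.UnitCell(9, 11, 8, 85, 95, 102)
        u = 0.02
        b = 8 * np.pi**2 * u
        for hkl in ([1, 0, 0], [2, -1, 3], [0, 1, 1]):
            g = np.array(cell.orth.mat.tolist())
            s = 0.5 / cell.calculate_d(hkl)
            dw_iso = debye_waller(b, hkl, s, cell)
            dw_tensor = debye_waller(u * np.eye(3), hkl, s, cell)
            assert dw_tensor == pytest.approx(dw_iso, rel=1e-10)


class TestDirectSummation:
    def test_single_atom_at_origin_real_positive(self):
        st = single_atom()
        miller = generate_reflections(st, 2.0)
        sf = direct_summation_sf(st, None, miller, "xray", "iam")
        table = builtin_table("four-gauss-const")
        assert np.allclose(sf.f.imag, 0.0, atol=1e-12)
        assert np.allclose(sf.f.real, gaussian_ff(6, miller.s, table))

    def test_atom_at_half_x_flips_sign_of_100(self):
        st = single_atom(frac=(0.5, 0.0, 0.0))
        miller = generate_reflections(st, 2.0)
        sf = direct_summation_sf(st, None, miller, "xray", "iam")
        i = np.flatnonzero((miller.hkl == [1, 0, 0]).all(axis=1))[0]
        f_free = gaussian_ff(6, miller.s[i], builtin_table("four-gauss-const"))
        assert sf.f[i] == pytest.approx(-f_free, rel=1e-12)

    def test_f000_is_total_electron_count(self, structures):
        st = structures["random-P1"]
        miller = generate_reflections(st, 8.0, include_origin=True)
        sf = direct_summation_sf(st, None, miller, "xray", "iam")
        i = np.flatnonzero((miller.hkl == 0).all(axis=1))[0]
        expected = sum(s.occupancy * s.element for s in st.sites)
        # the Gaussian tables reproduce Z to their printed rounding only
        assert sf.f[i].real == pytest.approx(expected, rel=1e-3)

    def test_friedel_symmetry_both_modes(self, structures, bank):
        st = structures["triclinic-mixed"]
        _, a = typed(st, bank)
        miller = generate_reflections(st, 1.5)
        neg = miller.__class__(-miller.hkl, miller.s, miller.d)
        for mode, asn in (("iam", None), ("taam", a)):
            fp = direct_summation_sf(st, asn, miller, "xray", mode, bank=bank)
            fm = direct_summation_sf(st, asn, neg, "xray", mode, bank=bank)
            assert np.allclose(fm.f, np.conj(fp.f), rtol=1e-12, atol=1e-12)

    def test_p21_asu_equals_p1_expansion(self, structures, bank):
        st = structures["chiral-P21"]
        _, a = typed(st, bank)
        miller = generate_reflections(st, 1.5)
        f_sym = direct_summation_sf(st, a, miller, "xray", "taam", bank=bank)
        p1 = st.expand_to_p1()
        _, a1 = typed(p1, bank)
        f_p1 = direct_summation_sf(p1, a1, miller, "xray", "taam", bank=bank)
        assert np.allclose(f_sym.f, f_p1.f, atol=1e-10 * np.abs(f_sym.f).max())

    def test_occupancy_linearity(self, structures):
        st = structures["random-P1"]
        miller = generate_reflections(st, 2.5)
        f1 = direct_summation_sf(st, None, miller, "xray", "iam").f
        doubled = CrystalStructure(st.cell, st.ops, [
            AtomSite(s.label, s.element, s.frac_xyz.copy(),
                     min(1.0, 2 * s.occupancy) if s.occupancy <= 0.5 else s.occupancy,
                     s.b_iso) for s in st.sites], st.spacegroup)
        # affine check instead: halving all occupancies halves F
        halved = CrystalStructure(st.cell, st.ops, [
            AtomSite(s.label, s.element, s.frac_xyz.copy(), 0.5 * s.occupancy,
                     s.b_iso) for s in st.sites], st.spacegroup)
        f_half = direct_summation_sf(halved, None, miller, "xray", "iam").f
        assert np.allclose(f_half, 0.5 * f1, rtol=1e-12)

    def test_translation_multiplies_by_phase(self, structures):
        st = structures["random-P1"]
        miller = generate_reflections(st, 2.5)
        f0 = direct_summation_sf(st, None, miller, "xray", "iam").f
        t = np.array([0.11, -0.23, 0.07])
        moved = CrystalStructure(st.cell, st.ops, [
            AtomSite(s.label, s.element, s.frac_xyz + t, s.occupancy, s.b_iso)
            for s in st.sites], st.spacegroup)
        f1 = direct_summation_sf(moved, None, miller, "xray", "iam").f
        phase = np.exp(2j * np.pi * (miller.hkl @ t))
        assert np.allclose(f1, f0 * phase, rtol=1e-10)

    def test_taam_on_all_gaussian_assignment_equals_iam(self, structures, bank):
        """An assignment forced entirely to the Gaussian level reproduces
        IAM mode bit for bit."""
        from taamkit.atom_typing import AtomTypeRecord, TypeAssignment

        st = structures["random-P1"]
        forced = TypeAssignment([AtomTypeRecord("gaussian-iam", reason="forced")
                                 for _ in st.sites])
        miller = generate_reflections(st, 2.0)
        for radiation in ("xray",):
            f_taam = direct_summation_sf(st, forced, miller, radiation, "taam",
                                         bank=bank).f
            f_iam = direct_summation_sf(st, None, miller, radiation, "iam").f
            assert np.array_equal(f_taam, f_iam)

    def test_matches_fft_oracle_on_random_structure(self, structures):
        st = structures["random-P1"]
        miller = generate_reflections(st, 1.2)
        f_direct = direct_summation_sf(st, None, miller, "xray", "iam")
        f_fft = fft_iam_sf(st, miller, "xray")
        rel = np.abs(np.abs(f_fft.f) - np.abs(f_direct.f)) / np.abs(f_direct.f)
        dphase = np.degrees(np.abs(np.angle(f_fft.f / f_direct.f)))
        assert rel.max() < 1e-3
        assert dphase.max() < 0.1


def ls_setup(structures, bank, radiation, perturb_seed=1):
    st0 = structures["triclinic-mixed"]
    _, asn = typed(st0, bank)
    miller = generate_reflections(st0, 1.1)
    sf_true = direct_summation_sf(st0, asn, miller, radiation, "taam", bank=bank)
    f_obs, target, dtdf = make_ls_target(sf_true, 0.0, 0)
    rng = np.random.default_rng(perturb_seed)
    pert = rng.normal(0.0, 0.004, (len(st0.sites), 3))

    def build(extra=None):
        st = make_structure(FixtureRecipe("triclinic-mixed", 0))
        for site, dp in zip(st.sites, pert):
            site.frac_xyz = site.frac_xyz + dp
        if extra:
            extra(st)
        return st

    return build, asn, miller, target, dtdf


class TestGradients:
    def test_zero_at_the_minimum(self, structures, bank):
        st = structures["triclinic-mixed"]
        _, asn = typed(st, bank)
        miller = generate_reflections(st, 1.3)
        sf = direct_summation_sf(st, asn, miller, "xray", "taam", bank=bank)
        _, _, dtdf = make_ls_target(sf, 0.0, 0)
        g = sf_gradients(st, asn, miller, "xray", "taam", dtdf(sf.f), bank=bank)
        scale = np.sum(np.abs(sf.f) ** 2)
        assert np.max(np.abs(g.xyz)) < 1e-8 * scale
        assert np.max(np.abs(g.occ)) < 1e-8 * scale

    @pytest.mark.parametrize("radiation", ["xray", "electron"])
    def test_xyz_b_occ_match_finite_differences(self, structures, bank, radiation):
        build, asn, miller, target, dtdf = ls_setup(structures, bank, radiation)
        st = build()

        def T(structure):
            return target(direct_summation_sf(structure, asn, miller,
                                              radiation, "taam", bank=bank).f)

        sf = direct_summation_sf(st, asn, miller, radiation, "taam", bank=bank)
        g = sf_gradients(st, asn, miller, radiation, "taam", dtdf(sf.f),
                         bank=bank)
        h = 1e-5
        for j in range(len(st.sites)):
            for ax in range(3):
                stp = build()
                stp.sites[j].frac_xyz[ax] += h
                tp = T(stp)
                stp.sites[j].frac_xyz[ax] -= 2 * h
                tm = T(stp)
                fd = (tp - tm) / (2 * h)
                assert g.xyz[j, ax] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        hb = 1e-4
        for j in (0, 1, 4):  # isotropic atoms
            stp = build()
            stp.sites[j].b_iso += hb
            tp = T(stp)
            stp.sites[j].b_iso -= 2 * hb
            tm = T(stp)
            fd = (tp - tm) / (2 * hb)
            assert g.adp[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        ho = 1e-5
        for j in (2, 4):
            stp = build()
            stp.sites[j].occupancy += ho
            tp = T(stp)
            stp.sites[j].occupancy -= 2 * ho
            tm = T(stp)
            fd = (tp - tm) / (2 * ho)
            assert g.occ[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_aniso_u_star_matches_finite_differences(self, structures, bank):
        build, asn, miller, target, dtdf = ls_setup(structures, bank, "xray")
        st = build()
        orth = st.orth

        def T(structure):
            return target(direct_summation_sf(structure, asn, miller, "xray",
                                              "taam", bank=bank).f)

        sf = direct_summation_sf(st, asn, miller, "xray", "taam", bank=bank)
        g = sf_gradients(st, asn, miller, "xray", "taam", dtdf(sf.f), bank=bank)
        j = 3  # the anisotropic iron
        u_star0 = u_cart_to_u_star(st.sites[j].u_cart, st.cell)
        pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        for k, (p, q) in enumerate(pairs):
            def fd_at(h):
                us = u_star0.copy()
                us[p, q] += h
                us[q, p] = us[p, q]
                stp = build()
                stp.sites[j].u_cart = orth @ us @ orth.T
                tp = T(stp)
                us[p, q] -= 2 * h
                us[q, p] = us[p, q]
                stp.sites[j].u_cart = orth @ us @ orth.T
                tm = T(stp)
                return (tp - tm) / (2 * h)

            h = 1e-3 * np.trace(u_star0) / 3
            fd = (4 * fd_at(h / 2) - fd_at(h)) / 3  # Richardson, O(h^4)
            assert g.adp[j][k] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_contraction_identity(self, structures, bank):
        """Contracting the explicit dF/dp table with dT/dF reproduces the
        accumulated target gradients to 1e-10."""
        build, asn, miller, target, dtdf = ls_setup(structures, bank, "xray")
        st = build()
        sf = direct_summation_sf(st, asn, miller, "xray", "taam", bank=bank)
        dtdf_vec = dtdf(sf.f)
        g = sf_gradients(st, asn, miller, "xray", "taam", dtdf_vec, bank=bank)
        table = per_reflection_sf_gradients(st, asn, miller, "xray", "taam",
                                            bank=bank)
        cg = np.conj(dtdf_vec)
        scale = max(np.max(np.abs(g.xyz)), 1.0)
        for j, site in enumerate(st.sites):
            for ax, name in enumerate("xyz"):
                contracted = np.sum(cg * table[(j, name)]).real
                assert abs(contracted - g.xyz[j, ax]) < 1e-10 * scale
            contracted_occ = np.sum(cg * table[(j, "occ")]).real
            assert abs(contracted_occ - g.occ[j]) < 1e-10 * scale

    def test_single_atom_positional_gradient_closed_form(self):
        """P1, one atom: dF/dx at h = (1,0,0) is 2 pi i f DW e^{2 pi i x}."""
        st = single_atom(frac=(0.137, 0.0, 0.0), b=3.0)
        miller = generate_reflections(st, 5.0)
        i = np.flatnonzero((miller.hkl == [1, 0, 0]).all(axis=1))[0]
        table = per_reflection_sf_gradients(st, None, miller, "xray", "iam")
        s = miller.s[i]
        f = gaussian_ff(6, s, builtin_table("four-gauss-const"))
        expected = 2j * np.pi * f * np.exp(-3.0 * s**2) \
            * np.exp(2j * np.pi * 0.137)
        assert table[(0, "x")][i] == pytest.approx(expected, rel=1e-12)

    def test_lone_atom_occupancy_gradient_closed_form(self):
        """T = |F(h0)|^2 for one atom at occ = 1: dT/docc = 2 |F|^2."""
        st = single_atom(frac=(0.1, 0.2, 0.3), b=2.0)
        miller = generate_reflections(st, 5.0)
        sf = direct_summation_sf(st, None, miller, "xray", "iam")
        i = 2
        dtdf = np.zeros(len(miller), dtype=complex)
        dtdf[i] = 2.0 * sf.f[i]  # dT/dF of |F|^2 in the Re[conj(g) dF] convention
        g = sf_gradients(st, None, miller, "xray", "iam", dtdf)
        assert g.occ[0] == pytest.approx(2.0 * abs(sf.f[i]) ** 2, rel=1e-12)

    def test_guard_against_huge_tables(self, structures):
        st = structures["random-P1"]
        miller = generate_reflections(st, 1.2)
        with pytest.raises(MemoryError, match="limit"):
            per_reflection_sf_gradients(st, None, miller, "xray", "iam",
                                        max_entries=1000)

    def test_nonfinite_target_gradient_rejected(self, structures):
        st = structures["random-P1"]
        miller = generate_reflections(st, 2.5)
        bad = np.full(len(miller), np.nan, dtype=complex)
        with pytest.raises(ValueError, match="finite"):
            sf_gradients(st, None, miller, "xray", "iam", bad)

    def test_memory_stays_proportional_to_parameters(self, structures, bank):
        """The accumulated-gradient path never materializes the
        reflections x parameters array (coarse tracemalloc bound)."""
        st = structures["triclinic-mixed"]
        _, asn = typed(st, bank)
        miller = generate_reflections(st, 0.8)
        sf = direct_summation_sf(st, asn, miller, "xray", "taam", bank=bank)
        _, _, dtdf = make_ls_target(sf, 0.0, 0)
        dtdf_vec = dtdf(sf.f)
        n_params = 10 * len(st.sites)
        full_table_bytes = 16 * n_params * len(miller)
        tracemalloc.start()
        sf_gradients(st, asn, miller, "xray", "taam", dtdf_vec, bank=bank)
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        # a handful of per-reflection temporaries is fine; the full
        # parameters x reflections table is not
        assert peak < 0.5 * full_table_bytes
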