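"""Direct-summation structure factors and analytic parameter gradients.

F(h) = sum_ops sum_atoms occ_j f_j(h R_s) DW_j(h R_s) exp(2 pi i h (R_s x_j + t_s))

The atomic factor f_j follows the atom's assigned representation
(multipolar / spherical Slater / Gaussian IAM) and the radiation; for
electron scattering in TAAM mode the X-ray factor is converted through
the Mott-Bethe relation per reflection.  Cost scales as reflections x
atoms x symmetry operators.

Two gradient paths are provided, mirroring refinement practice: target
gradients dT/dp accumulated on the fly from caller-supplied dT/dF
(memory proportional to parameters only), and an explicit per-reflection
dF/dp table for small problems (guarded, since reflections x parameters
tables grow to hundreds of gigabytes for macromolecules).

Positional gradients are per fractional coordinate (the 2 pi i h
convention); ``grad_frac_to_cart`` converts to per-Å.  Anisotropic ADP
gradients are for the six unique components of the reciprocal-frame
tensor U* (DW = exp(-2 pi^2 h^T U* h)).  Occupancies of atoms on special
positions are taken at face value: no multiplicity correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atom_typing import TypeAssignment
from .bank import Bank
from .constants import MOTT_BETHE_CONSTANT
from .form_factors import gaussian_ff, multipolar_ff, spherical_slater_ff
from .model_io import (CrystalStructure, MillerSet, StructureFactorSet,
                       u_cart_to_u_star)
from .tables import builtin_table

__all__ = [
    "direct_summation_sf",
    "debye_waller",
    "sf_gradients",
    "per_reflection_sf_gradients",
    "ParameterGradients",
    "fft_iam_sf",
    "grad_frac_to_cart",
    "default_dialect",
]

_U_STAR_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def default_dialect(radiation: str) -> str:
    """Default Gaussian dialect per radiation (the 6 Å⁻¹ electron fit and
    the four-Gaussian-plus-constant X-ray table)."""
    return "electron-6" if radiation == "electron" else "four-gauss-const"


def debye_waller(adp, hkl, s, cell) -> np.ndarray:
    """Debye-Waller attenuation in (0, 1].

    *adp* is an isotropic B in Å² (DW = exp(-B s^2)) or a Cartesian U
    tensor in Å² (DW = exp(-2 pi^2 h^T U* h) with U* the reciprocal-frame
    tensor).
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if np.ndim(adp) == 0:
        out = np.exp(-float(adp) * s**2)
    else:
        u_star = u_cart_to_u_star(np.asarray(adp, dtype=float), cell)
        out = np.exp(-2.0 * np.pi**2 * np.einsum("ni,ij,nj->n", hkl, u_star, hkl))
    return out if out.size > 1 else float(out[0])


def _slater_r2_moment(shells, p_val, kappa) -> float:
    """Second radial moment Int r^2 rho d^3r of the spherical model (Å²)."""
    m = 0.0
    for occ, n, alpha in shells.core:
        m += occ * (n + 3) * (n + 4) / alpha**2
    if shells.n_valence > 0:
        for occ, n, alpha in shells.valence:
            m += (p_val / shells.n_valence) * occ * (n + 3) * (n + 4) / (kappa * alpha) ** 2
    return m


class _FormFactorProvider:
    """Per-atom scattering factors f_j(h') for rotated indices h'.

    Caches the direction-independent factors (Gaussian, spherical
    Slater) per atom on the unique |s| grid; multipolar factors are
    evaluated per symmetry operator since they depend on the scattering
    direction.
    """

    def __init__(self, structure: CrystalStructure, assignment: TypeAssignment | None,
                 radiation: str, mode: str, table_dialect: str | None = None,
                 bank: Bank | None = None, use_mott_bethe_for_iam: bool = False):
        if mode not in ("taam", "iam"):
            raise ValueError(f"mode must be 'taam' or 'iam', got {mode!r}")
        if radiation not in ("xray", "electron"):
            raise ValueError(f"radiation must be 'xray' or 'electron', got {radiation!r}")
        if mode == "taam" and assignment is None:
            raise ValueError("taam mode needs a TypeAssignment")
        self.structure = structure
        self.assignment = assignment
        self.radiation = radiation
        self.mode = mode
        self.mb_iam = use_mott_bethe_for_iam
        if table_dialect is None:
            table_dialect = default_dialect("xray" if use_mott_bethe_for_iam
                                            else radiation)
        self.dialect = table_dialect
        self.table = self._resolve_table(bank, table_dialect)
        # the plain-IAM leg inside TAAM+electron converts from X-rays too
        self.xray_table = self._resolve_table(bank, default_dialect("xray"))
        from .tables import slater_shell_set
        self._slater_shells = (bank.slater if bank else {})
        self._builtin_slater = slater_shell_set

    def _resolve_table(self, bank, dialect):
        if bank is not None and dialect in bank.gaussian:
            bank_table = bank.gaussian[dialect]
            builtin = builtin_table(dialect)

            class _Merged:
                dialect_ = dialect

                def __init__(self):
                    self.dialect = dialect
                    self.validity_smax = builtin.validity_smax

                def get(self, z):
                    try:
                        return bank_table.get(z)
                    except KeyError:
                        return builtin.get(z)

            return _Merged()
        return builtin_table(dialect)

    def _shells_for(self, z):
        if z in self._slater_shells:
            return self._slater_shells[z]
        return self._builtin_slater(z)

    def _fx(self, j: int, hkl_rot: np.ndarray, s: np.ndarray,
            g_rot: np.ndarray) -> np.ndarray:
        """X-ray-scale factor for atom j at rotated reflections."""
        site = self.structure.sites[j]
        rec = self.assignment[j] if self.assignment is not None else None
        if self.mode == "iam" or rec.level == "gaussian-iam":
            table = self.xray_table if (self.radiation == "electron"
                                        and (self.mode == "taam" or self.mb_iam)) \
                else self.table
            return gaussian_ff(site.element, s, table).astype(complex)
        if rec.level == "spherical-slater":
            shells = self._shells_for(site.element)
            return spherical_slater_ff(shells, shells.n_valence, 1.0, s).astype(complex)
        return multipolar_ff(rec.entry, rec.frame, g_rot)

    def __call__(self, j: int, hkl_rot: np.ndarray, s: np.ndarray,
                 g_rot: np.ndarray) -> np.ndarray:
        site = self.structure.sites[j]
        z = site.element
        rec = self.assignment[j] if self.assignment is not None else None
        electron_direct = (self.radiation == "electron"
                           and self.mode == "iam" and not self.mb_iam)
        if electron_direct:
            return gaussian_ff(z, s, self.table).astype(complex)
        fx = self._fx(j, hkl_rot, s, g_rot)
        if self.radiation == "xray":
            return fx
        # Mott-Bethe conversion, with the analytic neutral limit at s = 0
        out = np.empty_like(fx)
        nz = s > 0
        out[nz] = MOTT_BETHE_CONSTANT * (z - fx[nz]) / s[nz] ** 2
        if np.any(~nz):
            out[~nz] = self._electron_origin(j, z, rec)
        return out

    def _electron_origin(self, j, z, rec) -> float:
        site = self.structure.sites[j]
        if self.mode == "iam" or (rec is not None and rec.level == "gaussian-iam"):
            a, b, c = self.xray_table.get(z)
            if abs(np.sum(a) + c - z) > 1e-3:
                raise ZeroDivisionError(
                    f"divergent electron F(000) for charged atom {site.label}")
            return MOTT_BETHE_CONSTANT * float(np.dot(a, b))
        if rec.level == "spherical-slater":
            shells = self._shells_for(z)
            m2 = _slater_r2_moment(shells, shells.n_valence, 1.0)
            return MOTT_BETHE_CONSTANT * (8.0 * np.pi**2 / 3.0) * m2
        entry = rec.entry
        q = entry.p_core + entry.p_val + entry.p_lm[0]
        if abs(q - z) > 1e-6:
            raise ZeroDivisionError(
                f"divergent electron F(000) for charged atom {site.label} "
                f"(model holds {q:.4f} electrons, Z = {z})")
        m2 = _slater_r2_moment(entry.core_valence_model, entry.p_val, entry.kappa)
        # l = 0 deformation second moment, if populated
        if entry.p_lm[0] != 0.0:
            n0 = entry.radial.n_l[0]
            zeta0 = entry.kappa_prime * entry.radial.zeta
            m2 += entry.p_lm[0] * (n0 + 3) * (n0 + 4) / zeta0**2
        return MOTT_BETHE_CONSTANT * (8.0 * np.pi**2 / 3.0) * m2


def _sym_terms(structure: CrystalStructure, miller: MillerSet):
    """Rotated indices, Cartesian g, and translation phases per operator."""
    hkl = miller.hkl.astype(float)
    for R, t in structure.ops:
        h_rot = hkl @ R  # (h^T R) per reflection
        g_rot = structure.g_cart(h_rot)
        tphase = np.exp(2j * np.pi * (hkl @ np.asarray(t, dtype=float)))
        yield h_rot, g_rot, tphase


def direct_summation_sf(structure: CrystalStructure,
                        assignment: TypeAssignment | None,
                        miller: MillerSet, radiation: str = "xray",
                        mode: str = "taam", *, table_dialect: str | None = None,
                        bank: Bank | None = None,
                        use_mott_bethe_for_iam: bool = False) -> StructureFactorSet:
    """Structure factors by explicit summation over atoms and operators."""
    provider = _FormFactorProvider(structure, assignment, radiation, mode,
                                   table_dialect, bank, use_mott_bethe_for_iam)
    f_total = np.zeros(len(miller), dtype=complex)
    s = miller.s
    for h_rot, g_rot, tphase in _sym_terms(structure, miller):
        for j, site in enumerate(structure.sites):
            fj = provider(j, h_rot, s, g_rot)
            if site.has_aniso:
                u_star = u_cart_to_u_star(site.u_cart, structure.cell)
                dw = np.exp(-2.0 * np.pi**2 *
                            np.einsum("ni,ij,nj->n", h_rot, u_star, h_rot))
            else:
                dw = np.exp(-(site.b_iso or 0.0) * s**2)
            phase = np.exp(2j * np.pi * (h_rot @ site.frac_xyz)) * tphase
            f_total += site.occupancy * fj * dw * phase
    return StructureFactorSet(miller, f_total, radiation, mode)


# ---------------------------------------------------------------------------
# gradients


@dataclass
class ParameterGradients:
    """Target gradients per atom; arrays sized by parameters only."""

    xyz: np.ndarray | None  # (n_atoms, 3), per fractional coordinate
    adp: list | None  # per atom: scalar dT/dB or (6,) dT/dU* [11,22,33,12,13,23]
    occ: np.ndarray | None  # (n_atoms,)


def grad_frac_to_cart(grad_xyz: np.ndarray, structure: CrystalStructure) -> np.ndarray:
    """Convert per-fractional-coordinate gradients to per-Å (chain rule
    through x_cart = O x_frac)."""
    o_inv = np.linalg.inv(structure.orth)
    return grad_xyz @ o_inv


def _atom_terms(structure, provider, miller, j):
    """Yield (h_rot, term) contributions of atom j for every operator,
    where term = occ * f * DW * phase (the atom's summand)."""
    site = structure.sites[j]
    s = miller.s
    if site.has_aniso:
        u_star = u_cart_to_u_star(site.u_cart, structure.cell)
    for h_rot, g_rot, tphase in _sym_terms(structure, miller):
        fj = provider(j, h_rot, s, g_rot)
        if site.has_aniso:
            dw = np.exp(-2.0 * np.pi**2 *
                        np.einsum("ni,ij,nj->n", h_rot, u_star, h_rot))
        else:
            dw = np.exp(-(site.b_iso or 0.0) * s**2)
        phase = np.exp(2j * np.pi * (h_rot @ site.frac_xyz)) * tphase
        yield h_rot, site.occupancy * fj * dw * phase


def sf_gradients(structure: CrystalStructure, assignment: TypeAssignment | None,
                 miller: MillerSet, radiation: str, mode: str,
                 dtarget_dF: np.ndarray, *, select=("xyz", "adp", "occ"),
                 table_dialect: str | None = None, bank: Bank | None = None,
                 use_mott_bethe_for_iam: bool = False) -> ParameterGradients:
    """Accumulate target gradients dT/dp = sum_h Re[conj(dT/dF) dF/dp].

    *dtarget_dF* is the caller's complex dT/dF per reflection, in the
    convention dT = sum_h Re[conj(dT/dF_h) dF_h].  The reflections x
    parameters array is never materialized.
    """
    dtarget_dF = np.asarray(dtarget_dF)
    if len(dtarget_dF) != len(miller):
        raise ValueError("dT/dF length does not match the reflection set")
    if not np.all(np.isfinite(dtarget_dF)):
        raise ValueError("non-finite dT/dF input")
    provider = _FormFactorProvider(structure, assignment, radiation, mode,
                                   table_dialect, bank, use_mott_bethe_for_iam)
    n = len(structure.sites)
    want_xyz = "xyz" in select
    want_adp = "adp" in select
    want_occ = "occ" in select
    g_xyz = np.zeros((n, 3)) if want_xyz else None
    g_adp = [None] * n if want_adp else None
    g_occ = np.zeros(n) if want_occ else None
    s2 = miller.s**2
    cg = np.conj(dtarget_dF)
    for j, site in enumerate(structure.sites):
        if want_adp:
            g_adp[j] = np.zeros(6) if site.has_aniso else 0.0
        for h_rot, term in _atom_terms(structure, provider, miller, j):
            base = cg * term
            if want_xyz:
                g_xyz[j] += ((base * 2j * np.pi) @ h_rot).real
            if want_occ:
                g_occ[j] += float(np.sum(base).real) / site.occupancy \
                    if site.occupancy != 0 else 0.0
            if want_adp:
                if site.has_aniso:
                    for k, (p, q) in enumerate(_U_STAR_PAIRS):
                        mult = 1.0 if p == q else 2.0
                        g_adp[j][k] += float(np.sum(
                            base * (-2.0 * np.pi**2 * mult
                                    * h_rot[:, p] * h_rot[:, q])).real)
                else:
                    g_adp[j] += float(np.sum(base * (-s2)).real)
    return ParameterGradients(g_xyz, g_adp, g_occ)


def per_reflection_sf_gradients(structure: CrystalStructure,
                                assignment: TypeAssignment | None,
                                miller: MillerSet, radiation: str, mode: str,
                                *, select=("xyz", "adp", "occ"),
                                table_dialect: str | None = None,
                                bank: Bank | None = None,
                                max_entries: int = 10_000_000,
                                use_mott_bethe_for_iam: bool = False) -> dict:
    """Explicit complex dF/dp tables, keyed ``(atom_index, parameter)``.

    Parameters are ``'x'|'y'|'z'``, ``'b'`` or ``'u11'...'u23'``, and
    ``'occ'``.  Refuses (resource error) when reflections x parameters
    exceeds *max_entries* — for macromolecular problems this table is
    the hundreds-of-gigabytes object the accumulated path avoids.
    """
    n_params = 0
    for site in structure.sites:
        n_params += (3 if "xyz" in select else 0)
        n_params += ((6 if site.has_aniso else 1) if "adp" in select else 0)
        n_params += (1 if "occ" in select else 0)
    if n_params * len(miller) > max_entries:
        raise MemoryError(
            f"per-reflection gradient table would hold "
            f"{n_params * len(miller):,} complex entries "
            f"(limit {max_entries:,}); use sf_gradients instead"
        )
    provider = _FormFactorProvider(structure, assignment, radiation, mode,
                                   table_dialect, bank, use_mott_bethe_for_iam)
    out: dict = {}
    s2 = miller.s**2
    names_u = ["u11", "u22", "u33", "u12", "u13", "u23"]
    for j, site in enumerate(structure.sites):
        acc: dict = {}
        if "xyz" in select:
            for name in "xyz":
                acc[name] = np.zeros(len(miller), dtype=complex)
        if "adp" in select:
            if site.has_aniso:
                for name in names_u:
                    acc[name] = np.zeros(len(miller), dtype=complex)
            else:
                acc["b"] = np.zeros(len(miller), dtype=complex)
        if "occ" in select:
            acc["occ"] = np.zeros(len(miller), dtype=complex)
        for h_rot, term in _atom_terms(structure, provider, miller, j):
            if "xyz" in select:
                for axis, name in enumerate("xyz"):
                    acc[name] += term * 2j * np.pi * h_rot[:, axis]
            if "adp" in select:
                if site.has_aniso:
                    for k, (p, q) in enumerate(_U_STAR_PAIRS):
                        mult = 1.0 if p == q else 2.0
                        acc[names_u[k]] += term * (
                            -2.0 * np.pi**2 * mult * h_rot[:, p] * h_rot[:, q])
                else:
                    acc["b"] += term * (-s2)
            if "occ" in select:
                acc["occ"] += term / site.occupancy if site.occupancy else 0.0
        for name, arr in acc.items():
            out[(j, name)] = arr
    return out


# ---------------------------------------------------------------------------
# FFT-based Gaussian IAM (independent algorithm, used as a cross-check)


def _smooth_size(n: int) -> int:
    """Smallest 2,3,5-smooth integer >= n."""
    m = n
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


def fft_iam_sf(structure: CrystalStructure, miller: MillerSet,
               radiation: str = "xray", table_dialect: str | None = None,
               oversampling: float = 6.0) -> StructureFactorSet:
    """Gaussian-IAM structure factors via real-space sampling + FFT.

    Samples each atom's Gaussian density (thermally smeared by its
    isotropic B; the table's constant term rides on the pure B Gaussian)
    on a fractional grid and reads F(h) off the FFT.  P1, isotropic
    ADPs, B > 0 only — this is the classical FFT route that exists for
    Gaussian densities and serves as an independent algorithm against
    direct summation.
    """
    if len(structure.ops) != 1:
        raise ValueError("fft_iam_sf supports P1 only")
    table = builtin_table(table_dialect or default_dialect(radiation))
    cell = structure.cell
    d_min = float(np.min(miller.d[np.isfinite(miller.d)]))
    spacing = d_min / oversampling
    p = cell.parameters
    dims = []
    hmax = np.max(np.abs(miller.hkl), axis=0) if len(miller) else np.zeros(3)
    for i in range(3):
        n = max(int(np.ceil(p[i] / spacing)), int(2 * hmax[i] + 3), 4)
        dims.append(_smooth_size(n))
    rho = np.zeros(dims)
    orth = structure.orth
    grids = [np.arange(dims[i]) / dims[i] for i in range(3)]
    for site in structure.sites:
        if site.has_aniso:
            raise ValueError("fft_iam_sf supports isotropic ADPs only")
        b_iso = site.b_iso or 0.0
        if b_iso <= 0.5:
            raise ValueError("fft_iam_sf needs B > 0.5 Å² (constant term "
                             "is folded into the thermal Gaussian)")
        a, b, c = table.get(site.element)
        terms = list(zip(np.append(a, c), np.append(b, 0.0)))
        b_tot_max = max(bb for _, bb in terms) + b_iso
        r_cut = np.sqrt(b_tot_max * 23.0 / (4 * np.pi**2))
        # fractional half-widths of the cutoff box
        inv = np.linalg.inv(orth)
        half = np.array([r_cut * np.linalg.norm(inv[i]) for i in range(3)])
        lo = np.floor((site.frac_xyz - half) * dims).astype(int)
        hi = np.ceil((site.frac_xyz + half) * dims).astype(int)
        idx = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
        fr = [idx[i] / dims[i] for i in range(3)]
        fx, fy, fz = np.meshgrid(*fr, indexing="ij")
        d_frac = np.stack([fx, fy, fz], axis=-1) - site.frac_xyz
        d_cart = d_frac @ orth.T
        r2 = np.sum(d_cart**2, axis=-1)
        dens = np.zeros_like(r2)
        for aa, bb in terms:
            bt = bb + b_iso
            dens += aa * (4.0 * np.pi / bt) ** 1.5 * np.exp(-4.0 * np.pi**2 * r2 / bt)
        dens *= site.occupancy
        ix = [np.mod(idx[i], dims[i]) for i in range(3)]
        np.add.at(rho, np.ix_(ix[0], ix[1], ix[2]), dens)
    f_grid = np.fft.ifftn(rho) * cell.volume
    f = np.array([f_grid[tuple(np.mod(h, dims))] for h in miller.hkl])
    return StructureFactorSet(miller, f, radiation, "iam")
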