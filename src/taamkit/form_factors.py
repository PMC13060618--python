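"""Atomic scattering factors: Gaussian IAM, spherical Slater, multipolar.

Conventions
-----------
* ``s`` is sin(theta)/lambda in Å⁻¹; all Gaussian ``b`` coefficients act
  on ``s**2``.  The Fourier-Bessel argument is ``H = 4*pi*s``.
* kappa scaling is applied to the radial exponents (``zeta -> kappa *
  zeta`` contracts the density); because the radial terms are
  density-normalized this is algebraically identical to evaluating the
  unscaled transform at ``s / kappa``.
* The multipolar form factor is the analytic Fourier transform of

      rho(r) = rho_core(r) + P_val * kappa^3 * rho_val(kappa r)
             + sum_lm P_lm * R_l(kappa' ; r) * d_lm(Omega)

  evaluated in the atom's local frame:

      f(g) = f_core + P_val f_val + sum_l i^l <j_l>(H) sum_m P_lm d_lm(u)

  with u the unit scattering direction in local coordinates.  All l >= 1
  terms vanish at s = 0.
* Electron scattering uses the Mott-Bethe relation
  f_e(s) = C * (Z - f_x(s)) / s^2, C = m_e e^2 / (8 pi eps0 h^2)
  = 0.0239337 Å⁻¹, so electron form factors are in Å.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bank import GaussianTable, MultipolarEntry, SlaterShellSet
from .constants import MOTT_BETHE_CONSTANT
from .harmonics import d_lm, lm_index
from .radial import slater_fourier_bessel

__all__ = [
    "gaussian_ff",
    "spherical_slater_ff",
    "multipolar_ff",
    "mott_bethe",
    "slater_fourier_bessel",
    "ValidityWarning",
]


class ValidityWarning(UserWarning):
    """A Gaussian table was evaluated beyond its fitted s range."""


def gaussian_ff(element: int, s, table: GaussianTable):
    """Sum-of-Gaussians form factor f(s) = sum a_i exp(-b_i s^2) + c.

    Electrons for X-ray dialects, Å for electron dialects.  Evaluation
    past the table's validity bound records a :class:`ValidityWarning`.
    """
    a, b, c = table.get(element)
    s = np.asarray(s, dtype=float)
    if np.any(s > table.validity_smax):
        warnings.warn(
            f"{table.dialect} table for Z={element} evaluated at "
            f"s > {table.validity_smax} Å⁻¹ (outside fit validity)",
            ValidityWarning,
            stacklevel=2,
        )
    out = (a[..., :] * np.exp(-b[..., :] * s[..., None] ** 2)).sum(axis=-1) + c
    return float(out) if out.ndim == 0 else out


def _shell_sum(terms, s, scale: float = 1.0):
    """Transform of a normalized Slater shell sum; exponents scaled by *scale*."""
    H = 4.0 * np.pi * np.asarray(s, dtype=float)
    out = np.zeros_like(H)
    for occ, n, alpha in terms:
        out = out + occ * slater_fourier_bessel(n, scale * alpha, 0, H)
    return out


def spherical_slater_ff(shells: SlaterShellSet, p_val: float, kappa: float, s):
    """Spherical Hansen-Coppens factor: core + kappa-scaled valence.

    f(s) = f_core(s) + (p_val / N_val) * f_val(s; zeta -> kappa zeta), so
    f(0) = p_core + p_val exactly.
    """
    out = _shell_sum(shells.core, s)
    if p_val != 0.0 and shells.n_valence > 0:
        out = out + (p_val / shells.n_valence) * _shell_sum(shells.valence, s, kappa)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def multipolar_ff(entry: MultipolarEntry, frame: np.ndarray, g_cart):
    """Hansen-Coppens multipolar form factor at Cartesian scattering vectors.

    Parameters
    ----------
    entry : MultipolarEntry
        Bank parameters (populations, kappas, radial functions).
    frame : (3, 3) array
        Local-frame rotation; columns are the local x, y, z axes in
        crystal-Cartesian coordinates.
    g_cart : (..., 3) array
        Cartesian reciprocal vectors in Å⁻¹ (|g| = 2 s).

    Returns a complex array (Hermitian in g -> -g).
    """
    if frame is None:
        raise ValueError(f"multipolar type {entry.type_id} needs a local frame")
    g = np.atleast_2d(np.asarray(g_cart, dtype=float))
    gnorm = np.linalg.norm(g, axis=-1)
    s = gnorm / 2.0
    f = spherical_slater_ff(entry.core_valence_model, entry.p_val, entry.kappa,
                            s).astype(complex)

    p = np.asarray(entry.p_lm)
    H = 4.0 * np.pi * s
    nonzero = gnorm > 0
    u_local = np.zeros_like(g)
    if np.any(nonzero):
        u = g[nonzero] / gnorm[nonzero, None]
        u_local[nonzero] = u @ frame  # frame columns are local axes => u . axis_k
    for l in range(5):
        ml = [m for m in range(-l, l + 1) if p[lm_index(l, m)] != 0.0]
        if not ml:
            continue
        radial = np.zeros_like(H)
        radial[nonzero] = slater_fourier_bessel(
            entry.radial.n_l[l], entry.kappa_prime * entry.radial.zeta, l, H[nonzero]
        )
        if l == 0:
            radial[~nonzero] = 1.0
        ang = np.zeros_like(H)
        for m in ml:
            vals = np.zeros_like(H)
            vals[nonzero] = d_lm(l, m, u_local[nonzero])
            if l == 0:
                vals[~nonzero] = 1.0
            ang += p[lm_index(l, m)] * vals
        f = f + (1j**l) * radial * ang
    if np.asarray(g_cart).ndim == 1:
        return complex(f[0])
    return f


def mott_bethe(f_x, z: int, s, *, gaussian_coeffs=None):
    """Convert X-ray form factor(s) to electron scattering (Å).

    f_e(s) = C (Z - f_x(s)) / s^2.  At s = 0 the expression is finite
    only for a neutral atom; for Gaussian f_x the analytic limit
    C * sum_i a_i b_i is used when *gaussian_coeffs* = (a, b, c) is
    supplied, otherwise s = 0 raises.  A net-charged atom (f_x(0) != Z)
    diverges at the origin and raises a ``ZeroDivisionError``.
    """
    s = np.asarray(s, dtype=float)
    f_x = np.asarray(f_x, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    f_x = np.broadcast_to(np.atleast_1d(f_x), s.shape).copy()
    out = np.empty_like(s)
    origin = s == 0
    nz = ~origin
    out[nz] = MOTT_BETHE_CONSTANT * (z - f_x[nz]) / s[nz] ** 2
    if np.any(origin):
        if gaussian_coeffs is None:
            raise ValueError(
                "s = 0 needs an analytic limit: pass gaussian_coeffs=(a, b, c)"
            )
        a, b, c = gaussian_coeffs
        if abs(np.sum(a) + c - z) > 1e-3:
            raise ZeroDivisionError(
                f"divergent F(000): atom with net charge {z - np.sum(a) - c:+.3f}"
            )
        out[origin] = MOTT_BETHE_CONSTANT * float(np.dot(a, b))
    if scalar:
        return float(out[0])
    return out
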