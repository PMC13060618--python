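"""Density-normalized real spherical harmonics d_lm for l = 0..4.

The multipole deformation terms of the Hansen-Coppens model use real
spherical harmonics normalized as *density* functions: for l >= 1 the
integral of |d_lm| over the sphere equals 2, so a population P_lm = 1
shifts one electron from the function's negative lobe to its positive
lobe; d_00 is the constant 1, so a monopole population adds exactly P_00
electrons when paired with a density-normalized radial function.

Rather than transcribing tables of normalization constants, the constants
are computed here once by numerical integration of |Y_lm| on a product
Gauss-Legendre / uniform-phi grid and cached, which makes the convention
self-verifying.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["real_sph_harm", "density_normalization", "d_lm", "lm_index", "N_LM"]

#: total number of (l, m) slots for l = 0..4
N_LM = 25


def lm_index(l: int, m: int) -> int:
    """Flat index of (l, m) in the canonical ordering l=0..4, m=-l..l."""
    if not 0 <= l <= 4 or abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m})")
    return l * l + (m + l)


def real_sph_harm(l: int, m: int, u: np.ndarray) -> np.ndarray:
    """Orthonormal real spherical harmonic Y_lm at unit vectors *u*.

    *u* has shape (..., 3).  Uses the standard real combinations of the
    complex harmonics (Condon-Shortley phase removed): m > 0 are the
    cosine-type, m < 0 the sine-type combinations.
    """
    u = np.asarray(u, dtype=float)
    z = np.clip(u[..., 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.arctan2(u[..., 1], u[..., 0])
    if m == 0:
        return sph_harm_y(l, 0, theta, phi).real
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    return np.sqrt(2.0) * (-1.0) ** m * y.imag


@lru_cache(maxsize=None)
def density_normalization(l: int, m: int) -> float:
    """Constant c_lm with d_lm = c_lm * Y_lm (orthonormal Y_lm).

    c_00 = sqrt(4*pi) (so d_00 = 1); for l >= 1, c_lm = 2 / Int |Y_lm| dOmega.
    """
    if l == 0:
        return float(np.sqrt(4.0 * np.pi))
    # Gauss-Legendre in cos(theta) x uniform in phi
    nodes, weights = np.polynomial.legendre.leggauss(120)
    nphi = 240
    phi = (np.arange(nphi) + 0.5) * (2.0 * np.pi / nphi)
    ct = nodes[:, None]
    st = np.sqrt(1.0 - ct**2)
    u = np.stack(
        [
            np.broadcast_to(st * np.cos(phi)[None, :], (120, nphi)),
            np.broadcast_to(st * np.sin(phi)[None, :], (120, nphi)),
            np.broadcast_to(ct, (120, nphi)),
        ],
        axis=-1,
    )
    vals = np.abs(real_sph_harm(l, m, u))
    integral = float(np.sum(vals * weights[:, None]) * (2.0 * np.pi / nphi))
    return 2.0 / integral


def d_lm(l: int, m: int, u: np.ndarray) -> np.ndarray:
    """Density-normalized real spherical harmonic at unit vectors *u*."""
    return density_normalization(l, m) * real_sph_harm(l, m, u)
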