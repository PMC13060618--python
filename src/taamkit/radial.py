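"""Fourier-Bessel transforms of Slater-type radial density functions.

The building block of the Hansen-Coppens model is a density-normalized
Slater-type function

    R(r) = N * r**n * exp(-zeta * r),    4*pi * Int r^2 R(r) dr = 1,

whose order-``l`` Fourier-Bessel transform

    <j_l>(H) = 4*pi * Int_0^inf r^2 R(r) j_l(H r) dr

is needed at H = 4*pi*s = 2*pi*|g| for every scattering vector.  The
integrals have closed forms built from the elementary moments

    Int_0^inf r^m exp(-a r) exp(i H r) dr = m! / (a - iH)**(m+1),

combined through the downward spherical-Bessel recurrence

    I_l(m) = (2l-1)/H * I_{l-1}(m-1) - I_{l-2}(m),

where I_l(m) = Int r^m exp(-a r) j_l(H r) dr.  The recurrence loses
precision when H*r is small over the integrand's support, so a power
series in (H/zeta) replaces it there.  No numerical quadrature is used in
this module; quadrature serves only as an independent oracle in the tests.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["slater_fourier_bessel", "slater_norm"]

_SERIES_SWITCH = 0.2  # use the power series for H/zeta below this ratio
_SERIES_TERMS = 40


def slater_norm(n: int, zeta: float) -> float:
    """Normalization N with 4*pi*Int r^(n+2) N exp(-zeta r) dr = 1."""
    if zeta <= 0:
        raise ValueError(f"zeta must be positive, got {zeta}")
    return zeta ** (n + 3) / (4.0 * np.pi * factorial(n + 2))


def _moment(m: int, a: float, H: np.ndarray) -> np.ndarray:
    """m! / (a - iH)^(m+1) as a complex array."""
    return factorial(m) * (a - 1j * H) ** (-(m + 1))


def _bessel_integral(m: int, l: int, a: float, H: np.ndarray) -> np.ndarray:
    """Int_0^inf r^m exp(-a r) j_l(H r) dr for H > 0 elementwise."""
    if l == 0:
        return _moment(m - 1, a, H).imag / H
    if l == -1:
        return _moment(m - 1, a, H).real / H
    return ((2 * l - 1) / H) * _bessel_integral(m - 1, l - 1, a, H) - _bessel_integral(
        m, l - 2, a, H
    )


def _series(n: int, l: int, x: np.ndarray) -> np.ndarray:
    """<j_l> as a power series in x = H/zeta (small-x branch).

    <j_l> = sum_k (-1)^k x^(l+2k) (n+l+2k+2)! / ((n+2)! 2^k k! (2l+2k+1)!!)
    """
    out = np.zeros_like(x)
    term = np.ones_like(x)
    # k = 0 prefactor
    pref = factorial(n + l + 2) / factorial(n + 2)
    dfac = 1.0
    for j in range(1, 2 * l + 2, 2):
        dfac *= j
    term = pref / dfac * x**l
    out = term.copy()
    num = n + l + 2
    for k in range(1, _SERIES_TERMS):
        term = term * (-(x**2)) * (num + 1) * (num + 2) / (2 * k * (2 * l + 2 * k + 1))
        num += 2
        out += term
        if np.all(np.abs(term) < 1e-17 * (1.0 + np.abs(out))):
            break
    return out


def slater_fourier_bessel(n: int, zeta: float, l: int, H) -> np.ndarray | float:
    """<j_l>(H) for the normalized density N r^n exp(-zeta r).

    Parameters
    ----------
    n : int
        Non-negative power of r in the density; must satisfy ``n >= l``.
    zeta : float
        Positive radial exponent in Å⁻¹ (density convention, i.e. the
        exponent of the *density*, not of an orbital).
    l : int
        Multipole order, 0..4.
    H : float or array
        Scattering argument 4*pi*sin(theta)/lambda in Å⁻¹.

    Returns
    -------
    <j_l>(H), with <j_0>(0) = 1 and <j_l>(0) = 0 for l >= 1.
    """
    if not 0 <= l <= 4:
        raise ValueError(f"l must be in 0..4, got {l}")
    if n < l:
        raise ValueError(f"radial power n={n} must be >= l={l}")
    if zeta <= 0:
        raise ValueError(f"zeta must be positive, got {zeta}")
    Harr = np.asarray(H, dtype=float)
    scalar = Harr.ndim == 0
    Harr = np.atleast_1d(Harr)
    if np.any(Harr < 0):
        raise ValueError("H must be non-negative")

    out = np.empty_like(Harr)
    x = Harr / zeta
    small = x < _SERIES_SWITCH
    if np.any(small):
        out[small] = _series(n, l, x[small])
    if np.any(~small):
        Hi = Harr[~small]
        norm = factorial(n + 2) / zeta ** (n + 3)  # Int r^(n+2) e^(-zeta r) dr
        out[~small] = _bessel_integral(n + 2, l, zeta, Hi) / norm
    return float(out[0]) if scalar else out
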