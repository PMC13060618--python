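"""Built-in scattering tables.

Four Gaussian dialects are exposed:

``four-gauss-const``
    The International Tables four-Gaussian-plus-constant X-ray
    parameterization, taken from gemmi's embedded IT92 coefficients
    (fit validity up to s = sin(theta)/lambda = 2 Å⁻¹).
``five-gauss``
    A five-Gaussian X-ray dialect.  The coefficients are refit here, per
    element on first use, against the four-Gaussian-plus-constant curve
    over its validity range; the dialect exists so both common Gaussian
    layouts (with and without the constant) are exercised end to end.
``electron-6``
    The International Tables five-Gaussian electron-scattering
    parameterization valid up to 6 Å⁻¹, from gemmi's embedded
    coefficients.  Units are Å.
``electron-2``
    A five-Gaussian electron dialect valid up to 2 Å⁻¹, refit per
    element against the Mott-Bethe transform of the X-ray table over
    (0, 2] Å⁻¹.

Spherical core/valence fallback densities are synthesized per element
(Z <= 36) from Slater's screening rules; they are a synthetic stand-in
with the correct electron counts and realistic shell structure, not
Hartree-Fock tabulations.
"""

from __future__ import annotations

from functools import lru_cache

import gemmi
import numpy as np
from scipy.optimize import least_squares

from .bank import GaussianTable, SlaterShellSet
from .constants import BOHR_ANGSTROM, MOTT_BETHE_CONSTANT

__all__ = ["builtin_table", "slater_shell_set", "has_gaussian_coefficients"]


def _it92(z: int):
    coef = gemmi.Element(z).it92
    if coef is None:
        raise KeyError(f"no IT92 X-ray Gaussian coefficients for Z={z}")
    return np.array(coef.a), np.array(coef.b), float(coef.c)


def _c4322(z: int):
    coef = gemmi.Element(z).c4322
    if coef is None:
        raise KeyError(f"no electron Gaussian coefficients for Z={z}")
    return np.array(coef.a), np.array(coef.b), 0.0


def has_gaussian_coefficients(z: int) -> bool:
    """True if the built-in tables can represent element *z* at all."""
    return gemmi.Element(z).it92 is not None


def _fit_five_gauss(s, f, b0):
    """Fit f(s) ~ sum_i a_i exp(-b_i s^2) with b_i >= 0, deterministic start."""

    def resid(p):
        a, b = p[:5], p[5:]
        return (a[None, :] * np.exp(-b[None, :] * s[:, None] ** 2)).sum(axis=1) - f

    p0 = np.concatenate([np.full(5, f[0] / 5.0), b0])
    sol = least_squares(resid, p0, bounds=(np.concatenate([np.full(5, -np.inf),
                                                           np.zeros(5)]),
                                           np.full(10, np.inf)),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return sol.x[:5], sol.x[5:]


class _LazyTable(GaussianTable):
    """GaussianTable that fills per-element coefficients on first access."""

    def __init__(self, dialect, smax, provider):
        super().__init__(dialect, smax, {})
        self._provider = provider

    def get(self, z: int):
        if z not in self.coeffs:
            a, b, c = self._provider(z)
            self.add(z, a, b, c)
        return self.coeffs[z]


def _five_gauss_provider(z: int):
    a4, b4, c4 = _it92(z)
    s = np.linspace(0.0, 2.0, 400)
    f = (a4[None, :] * np.exp(-b4[None, :] * s[:, None] ** 2)).sum(axis=1) + c4
    a, b = _fit_five_gauss(s, f, b0=np.array([0.1, 1.0, 5.0, 20.0, 60.0]))
    return a, b, 0.0


def _electron2_provider(z: int):
    a4, b4, c4 = _it92(z)
    s = np.linspace(0.02, 2.0, 400)
    fx = (a4[None, :] * np.exp(-b4[None, :] * s[:, None] ** 2)).sum(axis=1) + c4
    fe = MOTT_BETHE_CONSTANT * (z - fx) / s**2
    a, b = _fit_five_gauss(s, fe, b0=np.array([0.2, 1.5, 6.0, 20.0, 50.0]))
    return a, b, 0.0


@lru_cache(maxsize=None)
def builtin_table(dialect: str) -> GaussianTable:
    """The built-in :class:`GaussianTable` for *dialect* (lazy, cached)."""
    if dialect == "four-gauss-const":
        return _LazyTable(dialect, 2.0, _it92)
    if dialect == "five-gauss":
        return _LazyTable(dialect, 2.0, _five_gauss_provider)
    if dialect == "electron-6":
        return _LazyTable(dialect, 6.0, _c4322)
    if dialect == "electron-2":
        return _LazyTable(dialect, 2.0, _electron2_provider)
    raise KeyError(f"unknown Gaussian dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Slater's-rules shell sets

# aufbau order with principal quantum number, subshell and capacity
_AUFBAU = [(1, "s", 2), (2, "s", 2), (2, "p", 6), (3, "s", 2), (3, "p", 6),
           (4, "s", 2), (3, "d", 10), (4, "p", 6)]
# Slater screening groups: (1s)(2s2p)(3s3p)(3d)(4s4p)
_GROUP_OF = {(1, "s"): 0, (2, "s"): 1, (2, "p"): 1, (3, "s"): 2, (3, "p"): 2,
             (3, "d"): 3, (4, "s"): 4, (4, "p"): 4}
_GROUP_N = [1, 2, 3, 3, 4]  # principal quantum number per group
_N_EFF = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7}


def _configuration(z: int) -> list[float]:
    """Electrons per Slater group for the aufbau ground configuration."""
    occ = [0.0] * 5
    left = z
    for n, l, cap in _AUFBAU:
        take = min(cap, left)
        occ[_GROUP_OF[(n, l)]] += take
        left -= take
        if left == 0:
            break
    return occ


@lru_cache(maxsize=None)
def slater_shell_set(z: int) -> SlaterShellSet:
    """Synthetic spherical atom density for element *z* (Z <= 36).

    Each occupied Slater group (1s)(2s2p)(3s3p)(3d)(4s4p) contributes one
    density-normalized term occ * N * r^(2(n-1)) * exp(-2 zeta r / a0)
    with zeta = (Z - sigma)/n* from Slater's screening rules.  The
    outermost principal shell is the valence group; everything deeper is
    core.  Total electron count is exactly Z.
    """
    if not 1 <= z <= 36:
        raise KeyError(f"Slater shell sets cover 1 <= Z <= 36, got {z}")
    occ = _configuration(z)
    n_max = max(_GROUP_N[g] for g in range(5) if occ[g] > 0)
    core, valence = [], []
    for g in range(5):
        if occ[g] == 0:
            continue
        n = _GROUP_N[g]
        # Slater's rules: same group 0.35 (0.30 in 1s); for s/p electrons
        # n-1 shields 0.85 and deeper shells 1.00; for d all inner 1.00.
        sigma = 0.30 * (occ[g] - 1) if g == 0 else 0.35 * (occ[g] - 1)
        if g == 3:  # 3d
            sigma += sum(occ[gg] for gg in (0, 1, 2))
        else:
            for gg in range(5):
                if gg == g or occ[gg] == 0:
                    continue
                ng = _GROUP_N[gg]
                if ng == n - 1:
                    sigma += 0.85 * occ[gg]
                elif ng <= n - 2:
                    sigma += 1.00 * occ[gg]
        zeta = max(z - sigma, 0.5) / _N_EFF[n]
        alpha = 2.0 * zeta / BOHR_ANGSTROM  # density exponent, Å⁻¹
        term = (round(occ[g], 6), 2 * (n - 1), round(alpha, 6))
        (valence if n == n_max else core).append(term)
    shells = SlaterShellSet(z, tuple(core), tuple(valence))
    shells.validate()
    return shells
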