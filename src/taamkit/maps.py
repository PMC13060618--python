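"""Fourier synthesis of density / potential maps and deformation maps.

rho(x) = (1/V) sum_h F(h) exp(-2 pi i h . x)

with the Friedel mates of the stored unique set reconstituted before the
transform, so the synthesized map is real (the residual imaginary part
is checked and discarded).  X-ray structure factors (electrons) give
electron density in e Å⁻³; electron structure factors (Å) give
electrostatic potential in Å⁻² (Å/Å³).

Deformation maps are synthesized from the difference between aspherical
(TAAM) and spherical (IAM) structure factors, optionally after a single
least-squares scale between the two legs.  F(000) is excluded from both
legs by default: the electron-scattering origin term diverges for net
charges, and its neutral-limit value can be enabled explicitly.
"""

from __future__ import annotations

import warnings

import numpy as np

from .atom_typing import TypeAssignment, type_coverage_report
from .bank import Bank
from .model_io import (CrystalStructure, MillerSet, RealSpaceMap,
                       StructureFactorSet, generate_reflections)
from .structure_factors import _smooth_size, direct_summation_sf

__all__ = [
    "MapSpec",
    "fourier_map",
    "rmsd_contour_levels",
    "deformation_map",
    "scale_factor",
]

from dataclasses import dataclass


@dataclass
class MapSpec:
    """Gridding rule: spacing <= d_min / oversampling, FFT-friendly sizes."""

    d_min: float
    oversampling: float = 3.0

    def __post_init__(self):
        if self.oversampling < 2.0:
            raise ValueError("oversampling must be >= 2")

    def grid_dimensions(self, cell, hkl=None) -> tuple[int, int, int]:
        p = cell.parameters
        spacing = self.d_min / self.oversampling
        hmax = (np.max(np.abs(hkl), axis=0) if hkl is not None and len(hkl)
                else np.zeros(3))
        return tuple(
            _smooth_size(max(int(np.ceil(p[i] / spacing)),
                             int(2 * hmax[i] + 2), 2))
            for i in range(3)
        )


def _quantity(radiation: str) -> str:
    return "electrostatic-potential" if radiation == "electron" else "electron-density"


def fourier_map(sf: StructureFactorSet, spec: MapSpec,
                cell=None) -> RealSpaceMap:
    """Synthesize a real-space map from a unique structure-factor set."""
    if cell is None:
        raise ValueError("fourier_map needs the unit cell")
    dims = spec.grid_dimensions(cell, sf.miller.hkl)
    grid = np.zeros(dims, dtype=complex)
    has_origin = False
    for h, F in zip(sf.miller.hkl, sf.f):
        idx = tuple(np.mod(h, dims))
        grid[idx] += F
        if np.any(h):
            grid[tuple(np.mod(-h, dims))] += np.conj(F)
        else:
            has_origin = True
    volume = cell.volume
    rho = np.fft.fftn(grid) / volume
    imag_max = float(np.max(np.abs(rho.imag))) if rho.size else 0.0
    scale = max(float(np.max(np.abs(rho.real))), 1e-30)
    if imag_max > 1e-10 * scale:
        warnings.warn(f"map has residual imaginary part {imag_max:.2e}",
                      stacklevel=2)
    out = RealSpaceMap(values=rho.real.copy(), cell=cell,
                       quantity=_quantity(sf.radiation))
    out.metadata["f000_included"] = has_origin
    if not has_origin:
        out.metadata["mean"] = "zero (F(000) absent)"
    return out


def rmsd_contour_levels(map_a: RealSpaceMap, map_b: RealSpaceMap,
                        k: float = 1.5) -> tuple[float, float, float]:
    """Contour levels k * rmsd for two maps and their midpoint.

    Returns (level_a, level_b, midpoint) on the absolute scale of the
    maps' physical units; the midpoint is the recommended common level
    when overlaying the two maps.
    """
    level_a = k * map_a.rmsd()
    level_b = k * map_b.rmsd()
    return level_a, level_b, 0.5 * (level_a + level_b)


def scale_factor(f_ref: np.ndarray, f_scaled: np.ndarray) -> float:
    """Least-squares scalar k minimizing sum |f_ref - k * f_scaled|^2."""
    denom = float(np.sum(np.abs(f_scaled) ** 2))
    if denom == 0.0:
        return 1.0
    return float(np.sum(np.conj(f_scaled) * f_ref).real / denom)


def deformation_map(structure: CrystalStructure, assignment: TypeAssignment,
                    bank: Bank, d_min: float, radiation: str = "xray",
                    scaling: bool = False, *, spec: MapSpec | None = None,
                    iam_dialect: str | None = None,
                    miller: MillerSet | None = None,
                    return_sf: bool = False):
    """TAAM-minus-IAM Fourier deformation map.

    Delta F(h) = F_taam(h) - k F_iam(h), with k = 1 when *scaling* is
    off and the least-squares scalar otherwise.  The IAM leg uses the
    default Gaussian dialect for the radiation.  A warning is issued
    when multipolar coverage is below 100%.
    """
    report = type_coverage_report(assignment)
    if report["multipolar_coverage"] < 1.0:
        warnings.warn(
            f"multipolar coverage is "
            f"{100 * report['multipolar_coverage']:.1f}%; the deformation "
            "map mixes representation levels",
            stacklevel=2,
        )
    if miller is None:
        miller = generate_reflections(structure, d_min)
    f_taam = direct_summation_sf(structure, assignment, miller, radiation,
                                 "taam", bank=bank)
    f_iam = direct_summation_sf(structure, None, miller, radiation, "iam",
                                table_dialect=iam_dialect)
    k = scale_factor(f_taam.f, f_iam.f) if scaling else 1.0
    delta = StructureFactorSet(miller, f_taam.f - k * f_iam.f, radiation,
                               "taam")
    spec = spec or MapSpec(d_min=d_min)
    out = fourier_map(delta, spec, structure.cell)
    out.metadata["scale_factor"] = k
    out.metadata["radiation"] = radiation
    if return_sf:
        return out, f_taam, f_iam
    return out
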