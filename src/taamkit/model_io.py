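"""Atomic models, reflection sets, structure-factor and map I/O.

Coordinates are fractional internally; Cartesian conversions use the
standard orthogonalization with the a axis along x (gemmi's convention).
Anisotropic displacement tensors win over isotropic B when both are
present.  Phases are stored in degrees in [-180, 180).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "CrystalStructure",
    "MillerSet",
    "StructureFactorSet",
    "RealSpaceMap",
    "read_structure",
    "generate_reflections",
    "write_structure_factors",
    "read_structure_factors",
    "write_map",
    "read_map",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class AtomSite:
    """One atom in the asymmetric unit."""

    label: str
    element: int
    frac_xyz: np.ndarray  # (3,) fractional
    occupancy: float = 1.0
    b_iso: float | None = None  # Å²
    u_cart: np.ndarray | None = None  # (3,3) Å², Cartesian crystal frame
    altloc: str = ""
    is_water: bool = False
    charge: int = 0
    residue: str = ""
    seqid: int | None = None

    def __post_init__(self):
        self.frac_xyz = np.asarray(self.frac_xyz, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.label}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.b_iso is not None and self.b_iso < 0:
            raise ValueError(f"atom {self.label}: negative isotropic B")
        if self.u_cart is not None:
            self.u_cart = np.asarray(self.u_cart, dtype=float)
            w = np.linalg.eigvalsh(0.5 * (self.u_cart + self.u_cart.T))
            if w.min() < -1e-8:
                warnings.warn(
                    f"atom {self.label}: anisotropic U is not positive "
                    f"semi-definite (min eigenvalue {w.min():.2e})",
                    stacklevel=2,
                )

    @property
    def has_aniso(self) -> bool:
        return self.u_cart is not None

    @property
    def b_equivalent(self) -> float:
        """Isotropic-equivalent B (Å²); aniso tensor wins when present."""
        if self.u_cart is not None:
            return 8.0 * np.pi**2 * float(np.trace(self.u_cart)) / 3.0
        return float(self.b_iso or 0.0)


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operators + asymmetric-unit sites."""

    cell: gemmi.UnitCell
    ops: list[tuple[np.ndarray, np.ndarray]]  # (3x3 int rotation, 3 translation)
    sites: list[AtomSite]
    spacegroup: str = "P 1"

    def __post_init__(self):
        p = self.cell.parameters
        if min(p[:3]) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0.0 < ang < 180.0 for ang in p[3:]):
            raise ValueError("cell angles must lie in (0, 180) degrees")
        if len(self.ops) <= 48 and not self._closed():
            raise ValueError(
                f"symmetry operator set of {self.spacegroup!r} is not closed "
                "under composition"
            )

    def _closed(self) -> bool:
        key = lambda R, t: (tuple(R.ravel()), tuple(np.round(t % 1.0, 9)))
        ops = {key(R, t) for R, t in self.ops}
        for R1, t1 in self.ops:
            for R2, t2 in self.ops:
                if key(R1 @ R2, R1 @ t2 + t1) not in ops:
                    return False
        return True

    @property
    def orth(self) -> np.ndarray:
        """Fractional-to-Cartesian matrix (a along x)."""
        return np.array(self.cell.orth.mat.tolist())

    @property
    def frac_to_recip_cart(self) -> np.ndarray:
        """Matrix B with g_cart = B @ hkl (Å⁻¹)."""
        return np.linalg.inv(self.orth).T

    @property
    def volume(self) -> float:
        return self.cell.volume

    def g_cart(self, hkl: np.ndarray) -> np.ndarray:
        """Cartesian reciprocal vectors for integer triples (n, 3)."""
        return np.asarray(hkl, dtype=float) @ self.frac_to_recip_cart.T

    def cart_xyz(self, i: int) -> np.ndarray:
        return self.orth @ self.sites[i].frac_xyz

    def expand_to_p1(self) -> "CrystalStructure":
        """All symmetry copies as an explicit P1 model (no dedup of special
        positions; fixtures avoid them)."""
        new_sites = []
        for s in self.sites:
            for k, (R, t) in enumerate(self.ops):
                xs = (R @ s.frac_xyz + t) % 1.0
                lab = s.label if k == 0 else f"{s.label}_{k}"
                new_sites.append(replace(s, label=lab, frac_xyz=xs,
                                         u_cart=None if s.u_cart is None
                                         else s.u_cart.copy()))
        ident = [(np.eye(3, dtype=int), np.zeros(3))]
        return CrystalStructure(self.cell, ident, new_sites, "P 1")


@dataclass
class MillerSet:
    """Unique reflection indices with resolution data (s = 1/(2 d))."""

    hkl: np.ndarray  # (n, 3) int
    s: np.ndarray  # sin(theta)/lambda, Å⁻¹
    d: np.ndarray  # Å (inf for the origin)

    def __len__(self):
        return len(self.hkl)


@dataclass
class StructureFactorSet:
    """Complex structure factors on a MillerSet."""

    miller: MillerSet
    f: np.ndarray  # complex
    radiation: str = "xray"  # or "electron"
    mode: str = "iam"  # or "taam"

    def __post_init__(self):
        if len(self.f) != len(self.miller):
            raise ValueError("structure-factor array length mismatch")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("non-finite structure factors")


@dataclass
class RealSpaceMap:
    """Values on a periodic fractional grid over one unit cell.

    ``quantity`` records the physical meaning: electron density in
    e Å⁻³ for X-rays, electrostatic potential in Å⁻² for electrons
    (electron structure factors carry Å, so Å/Å³ = Å⁻²).
    """

    values: np.ndarray  # (n1, n2, n3)
    cell: gemmi.UnitCell
    quantity: str = "electron-density"  # or "electrostatic-potential"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3D with >= 2 points per axis")

    @property
    def shape(self):
        return self.values.shape

    def rmsd(self) -> float:
        """Root-mean-square deviation of values about their mean."""
        return float(np.sqrt(np.mean((self.values - self.values.mean()) ** 2)))


# ---------------------------------------------------------------------------
# reading models


def _ops_from_gemmi(gops) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for op in gops:
        R = np.array(op.rot, dtype=float) / op.DEN
        t = np.array(op.tran, dtype=float) / op.DEN
        out.append((R.astype(int), t))
    return out


def _macromolecular(path: str, fmt) -> CrystalStructure:
    st = gemmi.read_structure(str(path), format=fmt)
    if st.cell.volume <= 0 or st.cell.parameters[:3] == (1.0, 1.0, 1.0):
        raise ValueError(f"{path}: missing or invalid unit cell")
    sg = gemmi.SpaceGroup(st.spacegroup_hm) if st.spacegroup_hm else gemmi.SpaceGroup("P 1")
    ops = _ops_from_gemmi(sg.operations())
    sites = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    el = atom.element
                    if el.atomic_number == 0:
                        raise ValueError(
                            f"{path}: unknown element for atom {atom.name!r} "
                            f"in residue {res.name}"
                        )
                    frac = st.cell.fractionalize(atom.pos)
                    u_cart = None
                    if atom.aniso.nonzero():
                        # PDB ANISOU / mmCIF anisotrop tensors are Cartesian U
                        u = atom.aniso
                        u_cart = np.array([[u.u11, u.u12, u.u13],
                                           [u.u12, u.u22, u.u23],
                                           [u.u13, u.u23, u.u33]])
                    sites.append(AtomSite(
                        label=f"{chain.name}/{res.name}{res.seqid.num}/{atom.name}",
                        element=el.atomic_number,
                        frac_xyz=np.array([frac.x, frac.y, frac.z]),
                        occupancy=atom.occ,
                        b_iso=atom.b_iso,
                        u_cart=u_cart,
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        is_water=res.name in _WATER_NAMES,
                        charge=atom.charge,
                        residue=res.name,
                        seqid=res.seqid.num,
                    ))
        break  # first model only
    return CrystalStructure(st.cell, ops, sites,
                            st.spacegroup_hm or "P 1")


def _small_molecule(path: str) -> CrystalStructure:
    sm = gemmi.read_small_structure(str(path))
    if sm.cell.volume <= 0:
        raise ValueError(f"{path}: missing or invalid unit cell")
    sg = sm.find_spacegroup() or gemmi.SpaceGroup("P 1")
    ops = _ops_from_gemmi(sg.operations())
    sites = []
    for site in sm.sites:
        el = site.element
        if el.atomic_number == 0:
            raise ValueError(f"{path}: unknown element for site {site.label!r}")
        u_cart = None
        b_iso = site.u_iso * 8 * np.pi**2 if site.u_iso else 0.0
        aniso = site.aniso
        if aniso.nonzero():
            u_star = _ucif_to_ustar(np.array(
                [[aniso.u11, aniso.u12, aniso.u13],
                 [aniso.u12, aniso.u22, aniso.u23],
                 [aniso.u13, aniso.u23, aniso.u33]]), sm.cell)
            u_cart = _ustar_to_ucart(u_star, sm.cell)
        sites.append(AtomSite(
            label=site.label,
            element=el.atomic_number,
            frac_xyz=np.array([site.fract.x, site.fract.y, site.fract.z]),
            occupancy=site.occ if site.occ > 0 else 1.0,
            b_iso=b_iso,
            u_cart=u_cart,
            charge=int(site.charge),
        ))
    return CrystalStructure(sm.cell, ops, sites, sm.spacegroup_hm or "P 1")


def read_structure(path, format: str | None = None) -> CrystalStructure:
    """Read a PDB, mmCIF or small-molecule CIF model.

    *format* is one of ``pdb``, ``mmcif``, ``cif-small-molecule``; when
    omitted it is guessed from the extension (``.pdb``/``.ent`` ->
    pdb, ``.cif`` -> mmCIF first, small-molecule CIF as fallback).
    Charged element labels are normalized to the neutral element with
    the formal charge kept on the site.
    """
    path = str(path)
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "pdb" if suffix in (".pdb", ".ent") else "mmcif"
    if format == "pdb":
        return _macromolecular(path, gemmi.CoorFormat.Pdb)
    if format == "mmcif":
        try:
            st = _macromolecular(path, gemmi.CoorFormat.Mmcif)
            if st.sites:
                return st
        except (RuntimeError, ValueError):
            pass
        return _small_molecule(path)
    if format == "cif-small-molecule":
        return _small_molecule(path)
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# ADP basis changes


def _ucif_to_ustar(u_cif: np.ndarray, cell: gemmi.UnitCell) -> np.ndarray:
    """U_cif (dimensionless CIF convention) -> U* (reciprocal-frame, Å⁻²)."""
    r = cell.reciprocal().parameters
    n = np.diag(r[:3])
    return n @ u_cif @ n


def _ustar_to_ucart(u_star: np.ndarray, cell: gemmi.UnitCell) -> np.ndarray:
    """U* -> Cartesian U (Å²): U_cart = O U* O^T with O the orth matrix."""
    o = np.array(cell.orth.mat.tolist())
    return o @ u_star @ o.T


def u_cart_to_u_star(u_cart: np.ndarray, cell: gemmi.UnitCell) -> np.ndarray:
    o_inv = np.linalg.inv(np.array(cell.orth.mat.tolist()))
    return o_inv @ u_cart @ o_inv.T


# ---------------------------------------------------------------------------
# reflections


def generate_reflections(structure: CrystalStructure, d_min: float,
                         include_origin: bool = False) -> MillerSet:
    """All unique reflections with d >= d_min (one per Friedel pair).

    The Friedel representative is the lexicographically larger of
    (h, k, l) and (-h, -k, -l); (0, 0, 0) is excluded unless
    *include_origin*.
    """
    if d_min <= 0:
        raise ValueError(f"d_min must be positive, got {d_min}")
    cell = structure.cell
    # bounding box: |h_i| <= a_i / d_min is safe since 1/d >= h_i / a_i' with
    # a_i' the axis length; use the conservative direct axis lengths
    p = cell.parameters
    hmax = [int(np.floor(p[i] / d_min)) + 1 for i in range(3)]
    rng = [np.arange(-m, m + 1) for m in hmax]
    H, K, L = np.meshgrid(*rng, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    g = structure.g_cart(hkl)
    inv_d = np.linalg.norm(g, axis=1)
    with np.errstate(divide="ignore"):
        d = np.where(inv_d > 0, 1.0 / np.where(inv_d > 0, inv_d, 1.0), np.inf)
    keep = d >= d_min
    if not include_origin:
        keep &= inv_d > 0
    hkl = hkl[keep]
    # Friedel representative: lexicographically larger of h and -h
    rep = []
    for h in hkl:
        neg = tuple(-h)
        if tuple(h) >= neg:
            rep.append(True)
        else:
            rep.append(False)
    hkl = hkl[np.array(rep, dtype=bool)] if len(hkl) else hkl
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0])) if len(hkl) else []
    hkl = hkl[order] if len(hkl) else hkl.reshape(0, 3)
    g = structure.g_cart(hkl)
    inv_d = np.linalg.norm(g, axis=1)
    with np.errstate(divide="ignore"):
        d = np.where(inv_d > 0, 1.0 / np.where(inv_d > 0, inv_d, 1.0), np.inf)
    return MillerSet(hkl=hkl.astype(int), s=inv_d / 2.0, d=d)


# ---------------------------------------------------------------------------
# structure-factor files


def write_structure_factors(sf: StructureFactorSet, path, format: str = "hkl-text"):
    """Write structure factors as plain text (``hkl-text``) or CIF (``cif-sf``).

    Amplitudes and phases (degrees, [-180, 180)) round-trip to 6
    significant digits.
    """
    amp = np.abs(sf.f)
    phase = np.degrees(np.angle(sf.f))
    phase = ((phase + 180.0) % 360.0) - 180.0
    if format == "hkl-text":
        with open(path, "w") as fh:
            fh.write(f"# taamkit structure factors  radiation={sf.radiation} "
                     f"mode={sf.mode}\n")
            fh.write("#   h   k   l          |F|      phase_deg\n")
            for (h, k, l), a, p in zip(sf.miller.hkl, amp, phase):
                fh.write(f"{h:5d}{k:5d}{l:5d} {a:16.8e} {p:14.8f}\n")
    elif format == "cif-sf":
        doc = gemmi.cif.Document()
        block = doc.add_new_block("structure_factors")
        block.set_pair("_taamkit.radiation", sf.radiation)
        block.set_pair("_taamkit.mode", sf.mode)
        loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                           "F_calc", "phase_calc"])
        for (h, k, l), a, p in zip(sf.miller.hkl, amp, phase):
            loop.add_row([str(h), str(k), str(l), f"{a:.8e}", f"{p:.8f}"])
        doc.write_file(str(path))
    else:
        raise ValueError(f"unknown structure-factor format {format!r}")


def read_structure_factors(path, cell: gemmi.UnitCell | None = None,
                           format: str = "hkl-text") -> StructureFactorSet:
    """Read files produced by :func:`write_structure_factors`."""
    rows = []
    radiation, mode = "xray", "iam"
    if format == "hkl-text":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "radiation=" in line:
                        for tok in line.split():
                            if tok.startswith("radiation="):
                                radiation = tok.split("=")[1]
                            if tok.startswith("mode="):
                                mode = tok.split("=")[1]
                    continue
                toks = line.split()
                if toks:
                    rows.append([float(t) for t in toks])
    elif format == "cif-sf":
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        radiation = block.find_pair("_taamkit.radiation")[1]
        mode = block.find_pair("_taamkit.mode")[1]
        table = block.find("_refln.", ["index_h", "index_k", "index_l",
                                       "F_calc", "phase_calc"])
        for row in table:
            rows.append([float(row[i]) for i in range(5)])
    else:
        raise ValueError(f"unknown structure-factor format {format!r}")
    if rows:
        arr = np.array(rows)
        hkl = arr[:, :3].astype(int)
        f = arr[:, 3] * np.exp(1j * np.radians(arr[:, 4]))
    else:
        hkl = np.zeros((0, 3), dtype=int)
        f = np.zeros(0, dtype=complex)
    if cell is not None and len(hkl):
        inv_d = np.array([1.0 / cell.calculate_d(list(map(int, h))) if any(h) else 0.0
                          for h in hkl])
    else:
        inv_d = np.zeros(len(hkl))
    with np.errstate(divide="ignore"):
        d = np.where(inv_d > 0, 1.0 / np.where(inv_d > 0, inv_d, 1.0), np.inf)
    return StructureFactorSet(MillerSet(hkl, inv_d / 2.0, d), f, radiation, mode)


# ---------------------------------------------------------------------------
# maps


def write_map(map_: RealSpaceMap, path) -> None:
    """Write a CCP4/MRC mode-2 (float32) map covering the unit cell."""
    grid = gemmi.FloatGrid(*map_.shape)
    grid.set_unit_cell(map_.cell)
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    arr = np.array(grid, copy=False)
    arr[...] = map_.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(mode=2)
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> RealSpaceMap:
    ccp4 = gemmi.read_ccp4_map(str(path))
    values = np.array(ccp4.grid, copy=True)
    return RealSpaceMap(values=values, cell=ccp4.grid.unit_cell)
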