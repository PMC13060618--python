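"""Deterministic toy crystals, molecules and targets for exercising the
whole pipeline without external data.

Small rigid molecules (methane, water, benzene) are hand-built from
ideal geometry; conformationally non-trivial ones (pentane, decalin, a
capped dipeptide) are embedded with RDKit's seeded ETKDG so bond lengths
and angles are chemically sensible.  Every recipe is a pure function of
(name, seed): the same pair regenerates identical structures, and
coordinates are rounded to 6 decimals before use so written fixture
files are byte-stable.

The recipe list deliberately covers every representation level and
fallback path: full multipolar coverage (methane, water, benzene,
peptide), hydrogen-free water (no-H demotion), altloc overlap and clash
(forced Gaussian IAM), a Z > 36 element (Gaussian-only), and a mixed
triclinic cell exercising all three levels plus anisotropic ADPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .model_io import AtomSite, CrystalStructure, StructureFactorSet

__all__ = ["FixtureRecipe", "RECIPES", "make_structure", "make_ls_target",
           "write_fixture_files"]


@dataclass(frozen=True)
class FixtureRecipe:
    name: str
    seed: int = 0
    noise: float = 0.0  # Å, added to Cartesian coordinates (seeded)


def _tetrahedron(bond: float) -> np.ndarray:
    d = bond / np.sqrt(3.0)
    return np.array([[d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]])


def _methane():
    coords = np.vstack([[0.0, 0.0, 0.0], _tetrahedron(1.09)])
    return ["C", "H", "H", "H", "H"], coords, {}


def _water():
    ang = np.radians(104.5)
    r = 0.9572
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r, 0.0, 0.0],
        [r * np.cos(ang), r * np.sin(ang), 0.0],
    ])
    return ["O", "H", "H"], coords, {"is_water": True}


def _water_no_h():
    return ["O"], np.zeros((1, 3)), {"is_water": True}


def _benzene():
    rc, rh = 1.39, 2.47  # ring radii for C and H (C-H 1.08)
    syms, coords = [], []
    for i in range(6):
        a = np.pi / 3 * i
        syms.append("C")
        coords.append([rc * np.cos(a), rc * np.sin(a), 0.0])
    for i in range(6):
        a = np.pi / 3 * i
        syms.append("H")
        coords.append([rh * np.cos(a), rh * np.sin(a), 0.0])
    return syms, np.array(coords), {}


def _rdkit_embed(smiles: str, seed: int):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed + 1
    AllChem.EmbedMolecule(mol, params)
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    conf = mol.GetConformer()
    syms = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    return syms, coords, {}


def _random_p1(seed: int, n: int = 20):
    rng = np.random.default_rng(seed)
    box = 12.0
    coords = []
    while len(coords) < n:
        cand = rng.uniform(1.0, box - 1.0, size=3)
        ok = True
        for c in coords:
            diff = cand - c
            diff -= box * np.round(diff / box)
            if np.linalg.norm(diff) < 1.2:
                ok = False
                break
        if ok:
            coords.append(cand)
    syms = [str(rng.choice(["C", "N", "O"])) for _ in range(n)]
    b = rng.uniform(4.0, 15.0, size=n)
    occ = rng.uniform(0.6, 1.0, size=n)
    return syms, np.array(coords), {"box": box, "b_iso": b, "occupancy": occ}


_P21_OPS = [(np.eye(3, dtype=int), np.zeros(3)),
            (np.diag([-1, 1, -1]).astype(int), np.array([0.0, 0.5, 0.0]))]


def make_structure(recipe: FixtureRecipe) -> CrystalStructure:
    """Build the CrystalStructure for a recipe (see RECIPES)."""
    name, seed = recipe.name, recipe.seed
    rng = np.random.default_rng(seed)
    extra: dict = {}
    ops = [(np.eye(3, dtype=int), np.zeros(3))]
    sg = "P 1"
    if name == "methane":
        syms, coords, extra = _methane()
    elif name == "water":
        syms, coords, extra = _water()
    elif name == "water-no-h":
        syms, coords, extra = _water_no_h()
    elif name == "benzene":
        syms, coords, extra = _benzene()
    elif name == "pentane":
        syms, coords, extra = _rdkit_embed("CCCCC", seed)
    elif name == "decalin":
        syms, coords, extra = _rdkit_embed("C1CCC2CCCCC2C1", seed)
    elif name == "peptide":
        # capped alanine: two secondary amide groups, a peptide-like unit
        # whose every environment exists in the fixture bank
        syms, coords, extra = _rdkit_embed("CC(=O)NC(C)C(=O)NC(C)C", seed)
    elif name == "random-P1":
        syms, coords, extra = _random_p1(seed)
    elif name == "triclinic-mixed":
        # water (multipolar) + Fe (spherical-slater) + I (gaussian-iam)
        syms, coords, extra = _water()
        extra = {}
        syms += ["Fe", "I"]
        coords = np.vstack([coords, [[3.5, 1.0, 2.0], [1.0, 3.8, 3.2]]])
    elif name == "chiral-P21":
        # one chiral centre: C bonded to H, N, O, S
        d = _tetrahedron(1.0)
        coords = np.vstack([[0.0, 0.0, 0.0],
                            d * np.array([[1.09, 1.47, 1.42, 1.81]]).T / 1.0])
        syms = ["C", "H", "N", "O", "S"]
        ops = [(R.copy(), t.copy()) for R, t in _P21_OPS]
        sg = "P 1 21 1"
    elif name == "altloc-overlap":
        syms = ["C", "C", "O", "H"]
        coords = np.array([[0.0, 0.0, 0.0], [0.25, 0.0, 0.0],
                           [1.40, 0.2, 0.1], [2.0, 0.9, 0.4]])
        extra = {"altloc": ["A", "B", "", ""]}
    elif name == "clash":
        syms = ["C", "C", "O"]
        coords = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [1.8, 0.5, 0.2]])
    else:
        raise KeyError(f"unknown fixture recipe {recipe.name!r}")

    coords = np.asarray(coords, dtype=float)
    if recipe.noise > 0:
        coords = coords + rng.normal(0.0, recipe.noise, coords.shape)

    if "box" in extra:
        box = extra["box"]
        cell = gemmi.UnitCell(box, box, box, 90, 90, 90)
        frac = coords / box
    elif name == "triclinic-mixed":
        cell = gemmi.UnitCell(7.3, 8.1, 8.8, 83.0, 97.0, 105.0)
        orth = np.array(cell.orth.mat.tolist())
        frac = coords @ np.linalg.inv(orth).T + 0.18
    else:
        span = coords.max(axis=0) - coords.min(axis=0)
        pad = 8.0
        lengths = np.round(span + pad, 2)
        if sg != "P 1":
            lengths = lengths + [0.0, 2.0, 0.0]  # room for the screw mate
        cell = gemmi.UnitCell(*lengths, 90, 90, 90)
        frac = (coords - coords.min(axis=0) + pad / 2) / lengths

    frac = np.round(frac, 6)
    n = len(syms)
    b_arr = np.broadcast_to(
        np.asarray(extra.get("b_iso",
                             np.where(np.array(syms) == "H", 8.0, 5.0))), (n,))
    occupancy = extra.get("occupancy", np.ones(n))
    altlocs = extra.get("altloc", [""] * n)
    sites = []
    for i, sym in enumerate(syms):
        sites.append(AtomSite(
            label=f"{sym}{i + 1}",
            element=gemmi.Element(sym).atomic_number,
            frac_xyz=frac[i],
            occupancy=float(np.round(occupancy[i], 6)),
            b_iso=float(np.round(b_arr[i], 6)),
            altloc=altlocs[i],
            is_water=extra.get("is_water", False),
            residue="HOH" if extra.get("is_water") else "LIG",
            seqid=1,
        ))
    if name == "triclinic-mixed":
        # give the iron an anisotropic tensor (positive definite, Å²)
        u = np.diag([0.05, 0.08, 0.06])
        u[0, 1] = u[1, 0] = 0.015
        sites[3].u_cart = u
        sites[3].b_iso = None
        sites[4].occupancy = 0.8
    return CrystalStructure(cell, ops, sites, sg)


RECIPES = ("methane", "water", "water-no-h", "benzene", "pentane", "decalin",
           "peptide", "random-P1", "triclinic-mixed", "chiral-P21",
           "altloc-overlap", "clash")


def _to_gemmi(structure: CrystalStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = structure.cell
    st.spacegroup_hm = structure.spacegroup
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    residues: dict = {}
    for site in structure.sites:
        key = (site.residue or "LIG", site.seqid or 1)
        if key not in residues:
            res = gemmi.Residue()
            res.name = key[0]
            res.seqid = gemmi.SeqId(key[1], " ")
            residues[key] = res
        atom = gemmi.Atom()
        atom.name = site.label[:4]
        atom.element = gemmi.Element(site.element)
        atom.pos = structure.cell.orthogonalize(gemmi.Fractional(*site.frac_xyz))
        atom.occ = site.occupancy
        atom.b_iso = site.b_equivalent
        if site.u_cart is not None:
            u = site.u_cart
            atom.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2],
                                       u[0, 1], u[0, 2], u[1, 2])
        if site.altloc:
            atom.altloc = site.altloc
        residues[key].add_atom(atom)
    for res in residues.values():
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_fixture_files(recipe: FixtureRecipe, directory) -> dict:
    """Materialize a recipe as PDB and mmCIF files; returns the paths."""
    from pathlib import Path

    structure = make_structure(recipe)
    st = _to_gemmi(structure)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pdb = directory / f"{recipe.name}-{recipe.seed}.pdb"
    cif = directory / f"{recipe.name}-{recipe.seed}.cif"
    st.write_pdb(str(pdb))
    st.make_mmcif_document().write_file(str(cif))
    return {"pdb": pdb, "mmcif": cif, "structure": structure}


# ---------------------------------------------------------------------------
# least-squares demo target


def make_ls_target(sf_true: StructureFactorSet, noise_sd: float = 0.0,
                   seed: int = 0):
    """Observed amplitudes + dT/dF provider for the least-squares target
    T = sum_h (|F_calc(h)| - |F_obs(h)|)^2.

    Returns ``(f_obs, target, dtarget_dF)``: *target* maps complex
    F_calc to the scalar T; *dtarget_dF* maps F_calc to the complex
    gradient 2 (|F_calc| - |F_obs|) F_calc / |F_calc| in the convention
    dT = sum_h Re[conj(dT/dF) dF].
    """
    rng = np.random.default_rng(seed)
    f_obs = np.abs(sf_true.f) + rng.normal(0.0, noise_sd, len(sf_true.f))
    f_obs = np.abs(f_obs)

    def target(f_calc: np.ndarray) -> float:
        return float(np.sum((np.abs(f_calc) - f_obs) ** 2))

    def dtarget_dF(f_calc: np.ndarray) -> np.ndarray:
        amp = np.abs(f_calc)
        safe = np.where(amp > 0, amp, 1.0)
        return 2.0 * (amp - f_obs) * f_calc / safe

    return f_obs, target, dtarget_dF
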