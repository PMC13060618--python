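"""Chemistry-aware atom typing.

Bonding connectivity is perceived from geometry alone (covalent radii +
tolerance, periodic images included), rings come from a minimum cycle
basis, and planarity from the best-fit plane of an atom and its bonded
neighbours.  Each atom is then assigned one of three representation
levels:

``multipolar``
    a bank entry matched the atom's environment and a local frame could
    be built;
``spherical-slater``
    no multipolar parameters, but a core + spherical-valence Slater
    model exists (built in for Z <= 36);
``gaussian-iam``
    the plain Gaussian independent-atom fallback (also forced for atoms
    involved in altloc overlaps or clashes, whose connectivity cannot be
    trusted).

Typing is a pure function of coordinates, elements and the bank.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bank import Bank, MultipolarEntry
from .constants import (DEFAULT_BOND_TOLERANCE, DEFAULT_PLANARITY_THRESHOLD,
                        OVERLAP_DISTANCE, covalent_radius, element_symbol)
from .model_io import CrystalStructure

__all__ = [
    "BondGraph",
    "TypeAssignment",
    "AtomTypeRecord",
    "FrameDegeneracyError",
    "build_bond_graph",
    "perceive_rings",
    "planarity",
    "assign_atom_types",
    "build_local_frame",
    "type_coverage_report",
]

LEVELS = ("multipolar", "spherical-slater", "gaussian-iam")


class FrameDegeneracyError(ValueError):
    """Local frame could not be built (missing or collinear references)."""


@dataclass
class BondGraph:
    """Geometric bonding connectivity over asymmetric-unit atom indices.

    Edge attributes: ``distance`` (Å) and ``vec`` (Cartesian vector from
    the lower to the higher index, minimum image).  ``clashes`` records
    same-conformer pairs closer than the overlap distance; ``overlaps``
    records distinct-altloc pairs that were made mutually invisible.
    """

    graph: nx.Graph
    clashes: set[tuple[int, int]] = field(default_factory=set)
    overlaps: set[tuple[int, int]] = field(default_factory=set)

    def neighbors(self, i: int) -> list[int]:
        return list(self.graph.neighbors(i))

    def vec(self, i: int, j: int) -> np.ndarray:
        """Cartesian vector from atom i to (the bonded image of) atom j."""
        data = self.graph.edges[i, j]
        v = data["vec"]
        return v if i < j else -v

    def distance(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["distance"]


def _min_image_vectors(structure: CrystalStructure):
    """Pairwise minimum-image Cartesian vector and distance arrays.

    Considers all symmetry mates and the 3x3x3 block of lattice
    translations, which covers bonding across cell borders for any
    sensible cell.  Returns (vec[i, j, 3], dist[i, j]) from atom i to the
    nearest image of atom j (i != j).
    """
    n = len(structure.sites)
    frac = np.array([s.frac_xyz for s in structure.sites])
    orth = structure.orth
    shifts = np.array(np.meshgrid(*[[-1, 0, 1]] * 3, indexing="ij")).reshape(3, -1).T
    best_d = np.full((n, n), np.inf)
    best_v = np.zeros((n, n, 3))
    cart_i = frac @ orth.T
    for R, t in structure.ops:
        base = frac @ R.T + t
        for sh in shifts:
            cart_j = (base + sh) @ orth.T
            diff = cart_j[None, :, :] - cart_i[:, None, :]
            d = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(d, np.where(np.diag(d) < 1e-6, np.inf, np.diag(d)))
            better = d < best_d
            best_d = np.where(better, d, best_d)
            best_v = np.where(better[:, :, None], diff, best_v)
    return best_v, best_d


def build_bond_graph(structure: CrystalStructure, radii: dict | None = None,
                     tolerance: float = DEFAULT_BOND_TOLERANCE) -> BondGraph:
    """Perceive bonds: d(i, j) <= r_i + r_j + tolerance and d >= 0.4 Å.

    Hydrogens are monovalent: each keeps only the bond to its nearest
    heavy atom (ties broken by lower atom index).  Pairs closer than
    0.4 Å are clashes (same conformer, warning recorded) or altloc
    overlaps (distinct altlocs, mutually invisible to bonding).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    sites = structure.sites
    n = len(sites)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    bg = BondGraph(graph=g)
    if n == 0:
        return bg
    vec, dist = _min_image_vectors(structure)

    def radius(site):
        if radii is not None:
            key = element_symbol(site.element)
            if key in radii:
                return radii[key]
        return covalent_radius(site.element)

    r = np.array([radius(s) for s in sites])
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if not np.isfinite(d):
                continue
            if d < OVERLAP_DISTANCE:
                ai, aj = sites[i].altloc, sites[j].altloc
                if ai and aj and ai != aj:
                    bg.overlaps.add((i, j))
                else:
                    bg.clashes.add((i, j))
                    warnings.warn(
                        f"clash: atoms {sites[i].label} and {sites[j].label} "
                        f"are {d:.2f} Å apart",
                        stacklevel=2,
                    )
                continue
            if d <= r[i] + r[j] + tolerance:
                g.add_edge(i, j, distance=float(d), vec=vec[i, j].copy())

    # hydrogen monovalence: keep only the nearest heavy-atom bond
    for i in range(n):
        if sites[i].element != 1:
            continue
        nbrs = list(g.neighbors(i))
        heavy = [j for j in nbrs if sites[j].element != 1]
        keep = (min(heavy, key=lambda j: (g.edges[i, j]["distance"], j))
                if heavy else None)
        for j in nbrs:
            if j != keep:
                g.remove_edge(i, j)
    return bg


def perceive_rings(bond_graph: BondGraph,
                   max_size: int = 8) -> dict[int, list[int]]:
    """Ring sizes (3..max_size) per atom, from a minimum cycle basis."""
    rings: dict[int, list[int]] = {i: [] for i in bond_graph.graph.nodes}
    for cycle in nx.minimum_cycle_basis(bond_graph.graph):
        if 3 <= len(cycle) <= max_size:
            for i in cycle:
                rings[i].append(len(cycle))
    for lst in rings.values():
        lst.sort()
    return rings


def planarity(atom: int, bond_graph: BondGraph, structure: CrystalStructure,
              threshold: float = DEFAULT_PLANARITY_THRESHOLD) -> bool:
    """True iff atom + bonded neighbours fit a plane to < threshold RMS.

    Atoms with fewer than three neighbours are reported non-planar
    (the property is not applicable, which match rules treat as a
    non-planar trigger).
    """
    nbrs = bond_graph.neighbors(atom)
    if len(nbrs) < 3:
        return False
    pts = np.vstack([[0.0, 0.0, 0.0]] + [bond_graph.vec(atom, j) for j in nbrs])
    pts = pts - pts.mean(axis=0)
    _, svals, _ = np.linalg.svd(pts, full_matrices=False)
    rms = svals[-1] / np.sqrt(len(pts))
    return bool(rms < threshold)


def _canonical_neighbors(atom: int, bond_graph: BondGraph,
                         structure: CrystalStructure,
                         exclude: int | None = None) -> list[int]:
    """Neighbours ordered by descending Z, then bond length, then index."""
    nbrs = [j for j in bond_graph.neighbors(atom) if j != exclude]
    return sorted(nbrs, key=lambda j: (-structure.sites[j].element,
                                       bond_graph.distance(atom, j), j))


def build_local_frame(atom: int, entry: MultipolarEntry, bond_graph: BondGraph,
                      structure: CrystalStructure) -> np.ndarray:
    """Right-handed orthonormal local frame from the entry's recipe.

    Z is along the first reference direction, X is the Gram-Schmidt
    complement of the second, Y = Z x X.  Columns of the returned matrix
    are the local axes in crystal-Cartesian coordinates.  Raises
    :class:`FrameDegeneracyError` when a reference atom is missing or
    the two directions are collinear.
    """
    nbrs = _canonical_neighbors(atom, bond_graph, structure)

    def resolve(ref: str) -> np.ndarray:
        i1, i2, sign = entry.frame_recipe.parse_ref(ref)
        if i1 >= len(nbrs):
            raise FrameDegeneracyError(
                f"atom {structure.sites[atom].label}: frame reference {ref} "
                f"needs neighbour {i1 + 1}, found {len(nbrs)}"
            )
        j = nbrs[i1]
        v = bond_graph.vec(atom, j)
        if i2 is not None:
            second = _canonical_neighbors(j, bond_graph, structure, exclude=atom)
            if i2 >= len(second):
                raise FrameDegeneracyError(
                    f"atom {structure.sites[atom].label}: frame reference "
                    f"{ref} needs a further neighbour of "
                    f"{structure.sites[j].label}"
                )
            v = v + bond_graph.vec(j, second[i2])
        return sign * v

    zv = resolve(entry.frame_recipe.z_ref)
    xv = resolve(entry.frame_recipe.x_ref)
    nz = np.linalg.norm(zv)
    if nz < 1e-8:
        raise FrameDegeneracyError("zero-length Z reference")
    ez = zv / nz
    xperp = xv - np.dot(xv, ez) * ez
    nx_ = np.linalg.norm(xperp)
    if nx_ < 1e-6 * max(np.linalg.norm(xv), 1.0):
        raise FrameDegeneracyError(
            f"atom {structure.sites[atom].label}: Z and X references collinear"
        )
    ex = xperp / nx_
    ey = np.cross(ez, ex)
    return np.column_stack([ex, ey, ez])


@dataclass
class AtomTypeRecord:
    level: str
    type_id: str | None = None
    frame: np.ndarray | None = None
    reason: str = ""
    entry: MultipolarEntry | None = None


@dataclass
class TypeAssignment:
    """Per-atom representation levels with provenance."""

    records: list[AtomTypeRecord]

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i) -> AtomTypeRecord:
        return self.records[i]

    def count(self, level: str) -> int:
        return sum(1 for r in self.records if r.level == level)

    @property
    def coverage(self) -> float:
        """Fraction of atoms with a full multipolar representation."""
        if not self.records:
            return 0.0
        return self.count("multipolar") / len(self.records)


def _rule_matches(rule, atom, nbr_symbols, is_planar, ring_sizes, bond_graph,
                  structure) -> bool:
    if tuple(sorted(nbr_symbols)) != rule.neighbors:
        return False
    if rule.planar is not None and is_planar != rule.planar:
        return False
    if rule.ring_size is not None and rule.ring_size not in ring_sizes:
        return False
    for elt, required in rule.second:
        found = False
        for j in bond_graph.neighbors(atom):
            if element_symbol(structure.sites[j].element) != elt:
                continue
            others = sorted(element_symbol(structure.sites[k].element)
                            for k in bond_graph.neighbors(j) if k != atom)
            if tuple(others) == required:
                found = True
                break
        if not found:
            return False
    return True


def assign_atom_types(structure: CrystalStructure, bond_graph: BondGraph,
                      bank: Bank,
                      planarity_threshold: float = DEFAULT_PLANARITY_THRESHOLD
                      ) -> TypeAssignment:
    """Assign each atom a representation level (see module docstring).

    Matching is most-specific-first: candidate entries are ordered by
    descending constraint count, ties broken by bank order.  Raises if
    an atom ends at the Gaussian level but no Gaussian coefficients
    exist for its element in the bank or the built-in tables.
    """
    from .tables import has_gaussian_coefficients, slater_shell_set

    rings = perceive_rings(bond_graph)
    compromised = {i for pair in bond_graph.clashes for i in pair}
    compromised |= {i for pair in bond_graph.overlaps for i in pair}

    records = []
    for i, site in enumerate(structure.sites):
        z = site.element

        def gaussian_ok() -> bool:
            if has_gaussian_coefficients(z):
                return True
            return any(z in t.coeffs for t in bank.gaussian.values())

        def slater_available():
            if z in bank.slater:
                return bank.slater[z]
            if z <= 36:
                return slater_shell_set(z)
            return None

        def fallback(reason: str) -> AtomTypeRecord:
            shells = slater_available()
            if shells is not None:
                return AtomTypeRecord("spherical-slater", reason=reason)
            if not gaussian_ok():
                raise ValueError(
                    f"atom {site.label}: element {element_symbol(z)} has no "
                    "Gaussian coefficients in any table"
                )
            if z > 36:
                reason = (reason + "; " if reason else "") + "Z>36-no-slater"
            return AtomTypeRecord("gaussian-iam", reason=reason)

        if i in compromised:
            if not gaussian_ok():
                raise ValueError(
                    f"atom {site.label}: element {element_symbol(z)} has no "
                    "Gaussian coefficients in any table"
                )
            reason = ("altloc-overlap"
                      if any(i in p for p in bond_graph.overlaps) else "clash")
            records.append(AtomTypeRecord("gaussian-iam", reason=reason))
            continue

        nbr_symbols = [element_symbol(structure.sites[j].element)
                       for j in bond_graph.neighbors(i)]
        candidates = [(idx, e) for idx, e in enumerate(bank.entries)
                      if e.element == z]
        is_planar = planarity(i, bond_graph, structure, planarity_threshold)
        candidates.sort(key=lambda t: (-t[1].match_rule.specificity(), t[0]))
        matched = None
        for _, e in candidates:
            if _rule_matches(e.match_rule, i, nbr_symbols, is_planar,
                             rings[i], bond_graph, structure):
                matched = e
                break
        if matched is None:
            reason = "no-matching-type"
            if "H" not in nbr_symbols and any(
                    e.match_rule.requires_hydrogen for _, e in candidates):
                reason = "no-H-neighbour"
            records.append(fallback(reason))
            continue
        try:
            frame = build_local_frame(i, matched, bond_graph, structure)
        except FrameDegeneracyError:
            records.append(fallback("incomplete-environment"))
            continue
        records.append(AtomTypeRecord("multipolar", matched.type_id, frame,
                                      "", matched))
    return TypeAssignment(records)


def type_coverage_report(assignment: TypeAssignment, as_json: bool = False):
    """Per-level counts, multipolar percentage and per-atom reasons.

    Returns a dict (or its JSON string).  Percentages sum to 100 over
    the three levels; an empty assignment reports zero counts without
    dividing by zero.
    """
    n = len(assignment)
    counts = {level: assignment.count(level) for level in LEVELS}
    pct = {level: (100.0 * c / n if n else 0.0) for level, c in counts.items()}
    report = {
        "n_atoms": n,
        "counts": counts,
        "percent": pct,
        "multipolar_coverage": assignment.coverage,
        "reasons": [
            {"index": i, "level": r.level, "type_id": r.type_id,
             "reason": r.reason}
            for i, r in enumerate(assignment.records)
        ],
    }
    if as_json:
        return json.dumps(report, indent=2)
    return report


def format_coverage_report(report: dict) -> str:
    """Plain-text rendering of :func:`type_coverage_report` output."""
    lines = [f"atoms: {report['n_atoms']}"]
    for level in LEVELS:
        lines.append(f"  {level:18s} {report['counts'][level]:6d} "
                     f"({report['percent'][level]:6.2f}%)")
    lines.append(f"multipolar coverage: {100 * report['multipolar_coverage']:.2f}%")
    flagged = [r for r in report["reasons"] if r["reason"]]
    if flagged:
        lines.append("demotions:")
        for r in flagged:
            lines.append(f"  atom {r['index']}: {r['level']} ({r['reason']})")
    return "\n".join(lines)
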