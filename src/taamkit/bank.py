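"""Multipolar parameter banks: schema, parsing, validation, fixture bank.

A bank is a dictionary of transferable atom types.  Each entry couples a
chemistry matching rule (element, first-neighbour multiset, optional
planarity / ring / second-shell constraints) with the Hansen-Coppens
parameters of that environment (core and valence populations, kappa and
kappa-prime contraction scalars, multipole populations P_lm up to
hexadecapoles, a Slater radial function) and a recipe for the local
coordinate frame in which the P_lm are defined.  Banks of this kind
(UBDB/MATTS, ELMAM2, Invariom families) have no standard serialization;
the line-oriented text schema documented in ``docs/bank_format.md`` is
normative for this package.

A bank file may additionally carry spherical Slater shell sets (for the
core + spherical-valence fallback representation) and Gaussian scattering
tables (for the plain IAM fallback).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_ANGSTROM, atomic_number, element_symbol
from .harmonics import N_LM, lm_index

__all__ = [
    "RadialFunction",
    "SlaterShellSet",
    "GaussianTable",
    "MatchRule",
    "FrameRecipe",
    "MultipolarEntry",
    "Bank",
    "BankParseError",
    "BankValidationError",
    "load_bank",
    "loads_bank",
    "write_bank",
    "dumps_bank",
    "make_fixture_bank",
    "count_refinable_parameters",
]

FORMAT_VERSION = 1

DIALECTS = ("four-gauss-const", "five-gauss", "electron-2", "electron-6")


class BankParseError(ValueError):
    """Malformed bank file; message names the line and field."""


class BankValidationError(ValueError):
    """A parsed entry violates a type invariant."""


@dataclass(frozen=True)
class RadialFunction:
    """Slater radial deformation functions R_l(r) = N r^(n_l) exp(-zeta r).

    ``zeta`` is stored in Å⁻¹ on the density scale (exponent of the
    density itself).  Bank files may declare bohr⁻¹ with a unit flag; the
    value is converted on load.
    """

    n_l: tuple[int, int, int, int, int]
    zeta: float

    def __post_init__(self):
        if self.zeta <= 0:
            raise BankValidationError(f"zeta must be positive, got {self.zeta}")
        if len(self.n_l) != 5:
            raise BankValidationError("n_l needs one power per l = 0..4")
        for l, n in enumerate(self.n_l):
            if n < l:
                raise BankValidationError(f"n_l[{l}]={n} violates n >= l")


@dataclass(frozen=True)
class SlaterShellSet:
    """Spherical core/valence density as sums of normalized Slater terms.

    Each triple is (electron count, power n, exponent alpha in Å⁻¹) of a
    density-normalized term occ * N * r^n * exp(-alpha r).
    """

    element: int
    core: tuple[tuple[float, int, float], ...]
    valence: tuple[tuple[float, int, float], ...]

    @property
    def n_core(self) -> float:
        return sum(t[0] for t in self.core)

    @property
    def n_valence(self) -> float:
        return sum(t[0] for t in self.valence)

    def validate(self) -> None:
        for occ, n, alpha in self.core + self.valence:
            if alpha <= 0 or n < 0 or occ < 0:
                raise BankValidationError(
                    f"invalid slater term (occ={occ}, n={n}, alpha={alpha}) "
                    f"for element {element_symbol(self.element)}"
                )
        total = self.n_core + self.n_valence
        if abs(total - self.element) > 1e-6:
            raise BankValidationError(
                f"slater shells for {element_symbol(self.element)} integrate to "
                f"{total:.8f} electrons, expected Z = {self.element}"
            )


@dataclass
class GaussianTable:
    """Sum-of-Gaussians scattering table f(s) = sum a_i exp(-b_i s^2) + c.

    X-ray dialects are in electrons, electron dialects in Å.  Evaluation
    beyond ``validity_smax`` emits a warning (never an error).
    """

    dialect: str
    validity_smax: float
    coeffs: dict[int, tuple[np.ndarray, np.ndarray, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise BankValidationError(f"unknown Gaussian dialect {self.dialect!r}")
        for z, (a, b, c) in self.coeffs.items():
            self._check(z, a, b)

    @staticmethod
    def _check(z, a, b):
        if len(a) != len(b):
            raise BankValidationError(f"element Z={z}: a/b length mismatch")
        if np.any(np.asarray(b) < 0):
            raise BankValidationError(f"element Z={z}: negative Gaussian width b")

    def add(self, z: int, a, b, c: float) -> None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        self._check(z, a, b)
        self.coeffs[z] = (a, b, float(c))

    def get(self, z: int):
        try:
            return self.coeffs[z]
        except KeyError:
            raise KeyError(
                f"no {self.dialect} Gaussian coefficients for Z={z}"
            ) from None

    @property
    def is_electron(self) -> bool:
        return self.dialect.startswith("electron")


@dataclass(frozen=True)
class MatchRule:
    """Chemical-environment pattern for one transferable atom type.

    The grammar reaches first neighbours (exact element multiset),
    optional planarity and smallest-ring-size flags, and optional
    second-shell constraints of the form "some first neighbour of element
    E has exactly this multiset of further neighbours".  Environments
    that depend on atoms beyond the second shell cannot be expressed.
    """

    element: int
    neighbors: tuple[str, ...]  # sorted element symbols
    planar: bool | None = None
    ring_size: int | None = None
    second: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def specificity(self) -> int:
        n = 1 + len(self.neighbors)
        if self.planar is not None:
            n += 1
        if self.ring_size is not None:
            n += 1
        n += len(self.second)
        return n

    @property
    def requires_hydrogen(self) -> bool:
        return "H" in self.neighbors


_FRAME_REF = re.compile(r"^-?N([1-9]\d*)(?:\.([1-9]\d*))?$")


@dataclass(frozen=True)
class FrameRecipe:
    """Local-frame construction: Z along *z_ref*, X Gram-Schmidt of *x_ref*.

    References index the canonically ordered neighbour list (descending
    atomic number, then increasing bond length): ``N2`` is the second
    first-shell neighbour, ``N1.2`` the second further neighbour of
    neighbour 1 (needed for terminal atoms, whose only first-shell
    direction defines Z).  A leading ``-`` flips the direction.
    """

    z_ref: str
    x_ref: str

    def __post_init__(self):
        for ref in (self.z_ref, self.x_ref):
            if not _FRAME_REF.match(ref):
                raise BankValidationError(f"bad frame reference {ref!r}")

    @staticmethod
    def parse_ref(ref: str) -> tuple[int, int | None, int]:
        """(first-shell index, second-shell index or None, sign), 0-based."""
        m = _FRAME_REF.match(ref)
        sign = -1 if ref.startswith("-") else 1
        sub = m.group(2)
        return int(m.group(1)) - 1, (int(sub) - 1 if sub else None), sign


@dataclass(frozen=True)
class MultipolarEntry:
    """One bank atom type: matching rule + Hansen-Coppens parameters."""

    type_id: str
    match_rule: MatchRule
    frame_recipe: FrameRecipe
    p_core: float
    p_val: float
    kappa: float
    kappa_prime: float
    p_lm: tuple[float, ...]  # 25 populations, (l, m) canonical order
    radial: RadialFunction
    core_valence_model: SlaterShellSet

    def __post_init__(self):
        if self.p_core + self.p_val < 0:
            raise BankValidationError(
                f"{self.type_id}: p_core + p_val must be non-negative"
            )
        if self.kappa <= 0:
            raise BankValidationError(f"{self.type_id}: kappa must be positive")
        if self.kappa_prime <= 0:
            raise BankValidationError(f"{self.type_id}: kappa_prime must be positive")
        if len(self.p_lm) != N_LM:
            raise BankValidationError(
                f"{self.type_id}: p_lm has {len(self.p_lm)} slots, expected {N_LM}"
            )

    @property
    def element(self) -> int:
        return self.match_rule.element


@dataclass
class Bank:
    """A parsed parameter bank."""

    entries: list[MultipolarEntry] = field(default_factory=list)
    slater: dict[int, SlaterShellSet] = field(default_factory=dict)
    gaussian: dict[str, GaussianTable] = field(default_factory=dict)

    def entries_for(self, z: int) -> list[MultipolarEntry]:
        return [e for e in self.entries if e.element == z]


# ---------------------------------------------------------------------------
# parsing


def _tokens(line: str) -> list[str]:
    return line.split("#", 1)[0].split()


def loads_bank(text: str, name: str = "<string>") -> Bank:
    """Parse a bank from text.  See ``load_bank``."""
    bank = Bank()
    lines = text.splitlines()
    i = 0
    seen_ids: set[str] = set()

    def err(lineno, field_, msg):
        raise BankParseError(f"{name}:{lineno}: field {field_!r}: {msg}")

    # collect blocks
    blocks: list[tuple[int, str, list[str], list[tuple[int, list[str]]]]] = []
    while i < len(lines):
        toks = _tokens(lines[i])
        if not toks:
            i += 1
            continue
        head = toks[0].lower()
        if head == "bank-format":
            if len(toks) != 2 or not toks[1].isdigit():
                err(i + 1, "bank-format", "expected 'bank-format <int>'")
            i += 1
            continue
        if head in ("type", "slater", "gauss"):
            start = i + 1
            body: list[tuple[int, list[str]]] = []
            i += 1
            closed = False
            while i < len(lines):
                btoks = _tokens(lines[i])
                if btoks and btoks[0].lower() == "end":
                    closed = True
                    i += 1
                    break
                if btoks:
                    body.append((i + 1, btoks))
                i += 1
            if not closed:
                err(start, head, "block never closed with 'end'")
            blocks.append((start, head, toks[1:], body))
            continue
        err(i + 1, head, "unknown directive at top level")

    for start, kind, args, body in blocks:
        if kind == "slater":
            bank_slater = _parse_slater(start, args, body, err)
            bank.slater[bank_slater.element] = bank_slater
        elif kind == "gauss":
            _parse_gauss(start, args, body, bank, err)

    for start, kind, args, body in blocks:
        if kind != "type":
            continue
        entry = _parse_type(start, args, body, bank, err)
        if entry.type_id in seen_ids:
            err(start, "type", f"duplicate type_id {entry.type_id!r}")
        seen_ids.add(entry.type_id)
        bank.entries.append(entry)
    return bank


def _parse_slater(start, args, body, err) -> SlaterShellSet:
    if len(args) != 1:
        err(start, "slater", "expected 'slater <element>'")
    try:
        z = atomic_number(args[0])
    except KeyError as e:
        err(start, "slater", str(e))
    core, valence = [], []
    for lineno, toks in body:
        if toks[0].lower() not in ("core", "valence") or len(toks) != 4:
            err(lineno, "slater-shell", "expected 'core|valence <occ> <n> <alpha>'")
        try:
            occ, n, alpha = float(toks[1]), int(toks[2]), float(toks[3])
        except ValueError as e:
            err(lineno, "slater-shell", str(e))
        (core if toks[0].lower() == "core" else valence).append((occ, n, alpha))
    shells = SlaterShellSet(z, tuple(core), tuple(valence))
    try:
        shells.validate()
    except BankValidationError as e:
        err(start, "slater", str(e))
    return shells


def _parse_gauss(start, args, body, bank, err) -> None:
    if len(args) != 3:
        err(start, "gauss", "expected 'gauss <element> <dialect> <smax>'")
    try:
        z = atomic_number(args[0])
    except KeyError as e:
        err(start, "gauss", str(e))
    dialect, smax = args[1], float(args[2])
    a = b = None
    c = 0.0
    for lineno, toks in body:
        key = toks[0].lower()
        try:
            if key == "a":
                a = [float(t) for t in toks[1:]]
            elif key == "b":
                b = [float(t) for t in toks[1:]]
            elif key == "c":
                c = float(toks[1])
            else:
                err(lineno, key, "unknown gauss field")
        except ValueError as e:
            err(lineno, key, str(e))
    if a is None or b is None:
        err(start, "gauss", "missing 'a' or 'b' coefficients")
    table = bank.gaussian.get(dialect)
    if table is None:
        try:
            table = GaussianTable(dialect, smax)
        except BankValidationError as e:
            err(start, "gauss", str(e))
        bank.gaussian[dialect] = table
    try:
        table.add(z, a, b, c)
    except BankValidationError as e:
        err(start, "gauss", str(e))


def _parse_type(start, args, body, bank, err) -> MultipolarEntry:
    if len(args) != 1:
        err(start, "type", "expected 'type <type_id>'")
    type_id = args[0]
    fields: dict = {
        "planar": None,
        "ring": None,
        "second": [],
        "plm": np.zeros(N_LM),
        "zeta_unit": "angstrom",
    }
    for lineno, toks in body:
        key = toks[0].lower()
        try:
            if key == "element":
                fields["element"] = atomic_number(toks[1])
            elif key == "neighbors":
                fields["neighbors"] = tuple(sorted(t.capitalize() for t in toks[1:]))
            elif key == "planar":
                fields["planar"] = {"yes": True, "no": False}[toks[1].lower()]
            elif key == "ring":
                fields["ring"] = int(toks[1])
            elif key == "second":
                fields["second"].append(
                    (toks[1].capitalize(), tuple(sorted(t.capitalize() for t in toks[2:])))
                )
            elif key == "frame":
                if len(toks) != 5 or toks[1].upper() != "Z" or toks[3].upper() != "X":
                    raise ValueError("expected 'frame Z <ref> X <ref>'")
                fields["frame"] = FrameRecipe(toks[2].upper(), toks[4].upper())
            elif key in ("pcore", "pval", "kappa", "kappa_prime", "zeta"):
                fields[key] = float(toks[1])
            elif key == "zeta_unit":
                if toks[1] not in ("angstrom", "bohr"):
                    raise ValueError("zeta_unit must be 'angstrom' or 'bohr'")
                fields["zeta_unit"] = toks[1]
            elif key == "nl":
                fields["nl"] = tuple(int(t) for t in toks[1:])
            elif key == "plm":
                l, m, v = int(toks[1]), int(toks[2]), float(toks[3])
                fields["plm"][lm_index(l, m)] = v
            elif key == "plm_dense":
                vals = [float(t) for t in toks[1:]]
                if len(vals) != N_LM:
                    raise BankValidationError(
                        f"plm_dense has {len(vals)} values, expected {N_LM}"
                    )
                fields["plm"] = np.array(vals)
            else:
                raise ValueError(f"unknown type field {key!r}")
        except BankValidationError as e:
            err(lineno, key, str(e))
        except (ValueError, KeyError, IndexError) as e:
            err(lineno, key, str(e))

    for req in ("element", "neighbors", "frame", "pcore", "pval", "kappa",
                "kappa_prime", "zeta", "nl"):
        if req not in fields:
            err(start, req, f"type {type_id!r} is missing required field")
    z = fields["element"]
    if z not in bank.slater:
        err(start, "element",
            f"type {type_id!r} needs a 'slater {element_symbol(z)}' block")
    zeta = fields["zeta"]
    if fields["zeta_unit"] == "bohr":
        zeta = zeta / BOHR_ANGSTROM
    try:
        rule = MatchRule(z, fields["neighbors"], fields["planar"], fields["ring"],
                         tuple(fields["second"]))
        radial = RadialFunction(fields["nl"], zeta)
        entry = MultipolarEntry(
            type_id=type_id,
            match_rule=rule,
            frame_recipe=fields["frame"],
            p_core=fields["pcore"],
            p_val=fields["pval"],
            kappa=fields["kappa"],
            kappa_prime=fields["kappa_prime"],
            p_lm=tuple(float(v) for v in fields["plm"]),
            radial=radial,
            core_valence_model=bank.slater[z],
        )
    except BankValidationError as e:
        err(start, "type", str(e))
    return entry


def load_bank(path) -> Bank:
    """Load and validate a bank file.

    Raises :class:`BankParseError` (naming line and field) on malformed
    input and :class:`BankValidationError` on invariant violations.
    """
    with open(path) as fh:
        return loads_bank(fh.read(), name=str(path))


# ---------------------------------------------------------------------------
# writing


def dumps_bank(bank: Bank) -> str:
    """Serialize a bank to the text schema (round-trips through load)."""
    out = io.StringIO()
    out.write(f"bank-format {FORMAT_VERSION}\n\n")
    for z in sorted(bank.slater):
        s = bank.slater[z]
        out.write(f"slater {element_symbol(z)}\n")
        for occ, n, alpha in s.core:
            out.write(f"  core {occ:.6f} {n} {alpha:.6f}\n")
        for occ, n, alpha in s.valence:
            out.write(f"  valence {occ:.6f} {n} {alpha:.6f}\n")
        out.write("end\n\n")
    for dialect in sorted(bank.gaussian):
        table = bank.gaussian[dialect]
        for z in sorted(table.coeffs):
            a, b, c = table.coeffs[z]
            out.write(f"gauss {element_symbol(z)} {dialect} {table.validity_smax:.6f}\n")
            out.write("  a " + " ".join(f"{v:.6f}" for v in a) + "\n")
            out.write("  b " + " ".join(f"{v:.6f}" for v in b) + "\n")
            out.write(f"  c {c:.6f}\n")
            out.write("end\n\n")
    for e in bank.entries:
        r = e.match_rule
        out.write(f"type {e.type_id}\n")
        out.write(f"  element {element_symbol(e.element)}\n")
        out.write("  neighbors " + " ".join(r.neighbors) + "\n")
        if r.planar is not None:
            out.write(f"  planar {'yes' if r.planar else 'no'}\n")
        if r.ring_size is not None:
            out.write(f"  ring {r.ring_size}\n")
        for elt, rest in r.second:
            out.write(f"  second {elt} " + " ".join(rest) + "\n")
        out.write(f"  frame Z {e.frame_recipe.z_ref} X {e.frame_recipe.x_ref}\n")
        out.write(f"  pcore {e.p_core:.6f}\n")
        out.write(f"  pval {e.p_val:.6f}\n")
        out.write(f"  kappa {e.kappa:.6f}\n")
        out.write(f"  kappa_prime {e.kappa_prime:.6f}\n")
        out.write(f"  zeta {e.radial.zeta:.6f}\n")
        out.write("  nl " + " ".join(str(n) for n in e.radial.n_l) + "\n")
        for l in range(5):
            for m in range(-l, l + 1):
                v = e.p_lm[lm_index(l, m)]
                if v != 0.0:
                    out.write(f"  plm {l} {m} {v:.6f}\n")
        out.write("end\n\n")
    return out.getvalue()


def write_bank(bank: Bank, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_bank(bank))


# ---------------------------------------------------------------------------
# parameter counting


def count_refinable_parameters(model_kind: str, adp_kind: str, l_max: int = 4) -> int:
    """Number of refinable parameters per atom.

    Both model kinds refine positions, displacement parameters and the
    occupancy (3 + 6 + 1 = 10 with anisotropic ADPs; 3 + 1 + 1 = 5 with an
    isotropic B).  The full multipolar model additionally refines P_val,
    kappa, kappa-prime (only meaningful when deformation terms are
    present, l_max >= 1) and the (2l+1) multipole populations for each
    l = 1..l_max — through hexadecapoles this reaches 37 per atom.
    ``l_max`` is ignored for ``model_kind='iam'``.
    """
    if model_kind not in ("iam", "multipolar"):
        raise ValueError(f"model_kind must be 'iam' or 'multipolar', got {model_kind!r}")
    if adp_kind not in ("iso", "aniso"):
        raise ValueError(f"adp_kind must be 'iso' or 'aniso', got {adp_kind!r}")
    if model_kind == "multipolar" and not 0 <= l_max <= 4:
        raise ValueError(f"l_max must be in 0..4, got {l_max}")
    n = 3 + (6 if adp_kind == "aniso" else 1) + 1
    if model_kind == "multipolar":
        n += 1 + 1  # P_val, kappa
        if l_max >= 1:
            n += 1  # kappa-prime
        n += sum(2 * l + 1 for l in range(1, l_max + 1))
    return n


# ---------------------------------------------------------------------------
# fixture bank


def make_fixture_bank(seed: int = 0) -> Bank:
    """Deterministic toy bank covering {C, N, O, H, S} environments.

    Writes 12 entries matching methane-like, water-like, peptide-like and
    aromatic environments, Slater shell sets for the involved elements,
    and one Gaussian-only heavy element (iodine, Z = 53) so the plain-IAM
    fallback path is exercised.  Multipole populations are drawn from a
    seeded generator within physically plausible bounds (|P_lm| <= 1,
    kappa within [0.8, 1.2]); they are synthetic, not literature values.
    """
    from .tables import builtin_table, slater_shell_set  # local: avoids cycle

    rng = np.random.default_rng(seed)
    bank = Bank()
    for sym in ("H", "C", "N", "O", "S"):
        z = atomic_number(sym)
        bank.slater[z] = slater_shell_set(z)

    iodine = builtin_table("four-gauss-const").get(53)
    table = GaussianTable("four-gauss-const", 2.0)
    table.add(53, *iodine)
    bank.gaussian["four-gauss-const"] = table

    def plm(spec: dict[tuple[int, int], float]) -> np.ndarray:
        arr = np.zeros(N_LM)
        for (l, m), v in spec.items():
            # seeded +-10% jitter keeps entries distinct across seeds while
            # staying physically plausible
            arr[lm_index(l, m)] = round(v * (1.0 + 0.1 * rng.uniform(-1, 1)), 6)
        return arr

    def entry(type_id, elt, neighbors, frame, pval, kappa, kappa_prime, zeta, nl,
              plm_spec, planar=None, ring=None, second=()):
        z = atomic_number(elt)
        shells = bank.slater[z]
        return MultipolarEntry(
            type_id=type_id,
            match_rule=MatchRule(z, tuple(sorted(neighbors)), planar, ring,
                                 tuple(second)),
            frame_recipe=FrameRecipe(*frame),
            p_core=shells.n_core,
            p_val=pval,
            kappa=round(kappa, 6),
            kappa_prime=round(kappa_prime, 6),
            p_lm=tuple(plm(plm_spec)),
            radial=RadialFunction(tuple(nl), zeta),
            core_valence_model=shells,
        )

    k = lambda lo=0.95, hi=1.1: rng.uniform(lo, hi)
    # density-scale zeta values ~ 2 * orbital exponents, in Å⁻¹
    zC, zN, zO, zS, zH = 6.2, 7.2, 8.4, 7.0, 4.3
    bank.entries = [
        entry("C_methyl", "C", ("C", "H", "H", "H"), ("N1", "N2"),
              4.1, k(), k(0.85, 1.0), zC, (2, 2, 2, 3, 4),
              {(3, 2): 0.30, (1, 0): 0.02}),
        entry("C_sp3_CH4", "C", ("H", "H", "H", "H"), ("N1", "N2"),
              4.2, k(), k(0.85, 1.0), zC, (2, 2, 2, 3, 4),
              {(3, 2): 0.35, (4, 0): 0.05}),
        entry("C_alpha", "C", ("C", "C", "H", "N"), ("N1", "N2"),
              4.0, k(), k(0.85, 1.0), zC, (2, 2, 2, 3, 4),
              {(1, 0): 0.05, (3, 2): 0.25}),
        entry("C_carbonyl", "C", ("C", "N", "O"), ("N1", "N2"),
              3.8, k(), k(0.85, 1.0), zC, (2, 2, 2, 3, 4),
              {(1, 1): 0.08, (2, 0): -0.20, (3, 3): 0.25}, planar=True),
        entry("C_aromatic", "C", ("C", "C", "H"), ("N1", "N2"),
              4.0, k(), k(0.85, 1.0), zC, (2, 2, 2, 3, 4),
              {(2, 0): -0.25, (3, 3): 0.30}, planar=True, ring=6),
        entry("N_amide", "N", ("C", "C", "H"), ("N1", "N2"),
              5.2, k(), k(0.85, 1.0), zN, (2, 2, 2, 3, 4),
              {(1, 0): 0.10, (2, 0): -0.15}, planar=True),
        entry("O_carbonyl", "O", ("C",), ("N1", "N1.1"),
              6.3, k(), k(0.85, 1.0), zO, (1, 2, 2, 3, 4),
              {(1, 0): -0.06, (2, 0): -0.10}, second=[("C", ("C", "N"))]),
        entry("O_water", "O", ("H", "H"), ("N1", "N2"),
              6.2, k(), k(0.85, 1.0), zO, (1, 2, 2, 3, 4),
              {(1, 0): -0.10, (2, -2): -0.08}),
        entry("S_thiol", "S", ("C", "H"), ("N1", "N2"),
              6.1, k(), k(0.85, 1.0), zS, (2, 2, 2, 3, 4),
              {(1, 0): -0.05, (2, 0): -0.08}),
        entry("H_carbon", "H", ("C",), ("N1", "N1.1"),
              0.85, k(1.1, 1.2), k(1.1, 1.3), zH, (0, 1, 2, 3, 4),
              {(1, 0): 0.12}),
        entry("H_oxygen", "H", ("O",), ("N1", "N1.1"),
              0.70, k(1.1, 1.2), k(1.1, 1.3), zH, (0, 1, 2, 3, 4),
              {(1, 0): 0.15}),
        entry("H_nitrogen", "H", ("N",), ("N1", "N1.1"),
              0.75, k(1.1, 1.2), k(1.1, 1.3), zH, (0, 1, 2, 3, 4),
              {(1, 0): 0.14}),
    ]
    return bank
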