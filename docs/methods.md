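# Methods

## Scattering model

taamkit evaluates atomic scattering factors at three levels and sums
them into structure factors by direct summation.

**Hansen–Coppens multipolar atoms.**  The atomic electron density is

    rho(r) = rho_core(r) + P_val kappa^3 rho_val(kappa r)
           + sum_{l=0..4} sum_m P_lm R_l(kappa' zeta; r) d_lm(theta, phi)

with density-normalized Slater radial functions
`R_l(r) = N r^{n_l} exp(-kappa' zeta r)` and density-normalized real
spherical harmonics `d_lm` defined in a per-atom local frame.  Its
analytic Fourier transform is

    f(g) = f_core(H) + P_val f_val(H; kappa)
         + sum_l i^l <j_l>(H) sum_m P_lm d_lm(u),

where `H = 4 pi s`, `u` is the unit scattering direction expressed in
the local frame, and `<j_l>` is the order-l Fourier–Bessel transform of
the normalized radial function.  `<j_l>` is evaluated in closed form
from the elementary moments `Int r^m e^{-ar} e^{iHr} dr = m!/(a-iH)^{m+1}`
via the spherical-Bessel recurrence; because the recurrence cancels
catastrophically when `H/zeta` is small, a power series in `H/zeta`
takes over below `H/zeta = 0.2` (both branches agree with adaptive
quadrature to better than 1e-8 over `n in [l, l+4]`, `zeta in [1, 10]`,
`H in [0, 25]`).

Two algebraically equivalent kappa conventions exist (scaling the
argument or the exponents); taamkit scales the exponents
(`zeta -> kappa zeta`), which for density-normalized terms is identical
to evaluating the unscaled transform at `s/kappa`.

The `d_lm` are *density*-normalized: `d_00 = 1` and
`Int |d_lm| dOmega = 2` for `l >= 1`, so a unit population moves one
electron between lobes.  The normalization constants are computed once
by numerical integration of `|Y_lm|` on a Gauss–Legendre grid and
cached, rather than transcribed from tables — the convention is thereby
self-verifying (the test suite checks the integrals independently by
Monte Carlo).

**Spherical Slater fallback.**  Atoms without multipolar parameters but
with `Z <= 36` get a core + kappa-scalable spherical valence model.
The shipped shell sets are *synthetic*: they are generated from
Slater's screening rules (groups (1s)(2s2p)(3s3p)(3d)(4s4p), standard
shielding increments, `n* = 3.7` for `n = 4`), with the density power
fixed at `2(n-1)` and the exponent `2 zeta / a0`.  They integrate to
exactly Z electrons and track the Gaussian IAM curves to a few percent
at low angle, which is what the fallback needs; they are not
Hartree–Fock reference densities, and users with real coefficients can
supply them through the bank schema.

**Gaussian IAM.**  Four dialects: the four-Gaussian-plus-constant
X-ray table and the five-Gaussian electron table (valid to 6 Å⁻¹) are
taken from gemmi's embedded International-Tables coefficients.  The
`five-gauss` X-ray dialect and the `electron-2` dialect (valid to
2 Å⁻¹) are refit in-package, per element on first use, by bounded
least squares against the four-Gaussian curve and against the
Mott–Bethe transform of it, respectively; the fits are deterministic
(fixed starting widths) and exist so both common coefficient layouts
and both electron validity ranges are exercised.

**Electron scattering.**  X-ray factors convert through the Mott–Bethe
relation `f_e(s) = C (Z - f_x(s)) / s^2` with
`C = m_e e^2/(8 pi eps0 h^2) = 0.0239337 Å⁻¹` (CODATA 2018, frozen to
six significant digits).  Electron form factors are in Å, so Fourier
electrostatic-potential maps carry Å/Å³ = Å⁻².  At `s = 0` the
analytic neutral-atom limit is used (`C sum a_i b_i` for Gaussians,
`C (8 pi^2/3) <r^2>` for Slater densities); a net-charged atom raises
an explicit divergent-F(000) error.

## Atom typing

Bonds: `d <= r_i + r_j + tolerance` with published single-bond covalent
radii, default tolerance 0.40 Å, a 0.4 Å lower cutoff, and periodic /
symmetry images included.  Hydrogens are pruned to their nearest heavy
atom (ties to the lower index).  Pairs closer than 0.4 Å are altloc
overlaps (distinct altlocs — mutually invisible to bonding) or clashes
(warning recorded); atoms in either situation are forced to the
Gaussian level because their perceived environment cannot be trusted.
Rings come from a networkx minimum cycle basis (sizes 3–8); planarity
is an RMS best-fit-plane test over the atom and its bonded neighbours
with a 0.10 Å default threshold (not applicable below three
neighbours, which match rules treat as non-planar).  Both thresholds
are package defaults, chosen as round values in the range used by
common structure-perception tools, and are user-overridable.

Matching is most-specific-first (constraint count, ties by bank order).
A matched atom still needs a local frame; missing or collinear frame
references demote it to the spherical level with reason
`incomplete-environment`.  Typing is a pure function of coordinates,
elements and the bank.  The coverage report lists per-level counts and
per-atom demotion reasons; the multipolar percentage is the number a
user should check first.

## Structure factors and gradients

    F(h) = sum_s sum_j occ_j f_j(h R_s) DW_j(h R_s)
           exp(2 pi i h (R_s x_j + t_s))

summed over explicit symmetry operators (no symmetry-reduced summation;
occupancies of special positions are taken at face value, with no
multiplicity correction).  Debye–Waller: `exp(-B s^2)` isotropic,
`exp(-2 pi^2 h^T U* h)` anisotropic with `U*` the reciprocal-frame
tensor derived from the Cartesian `U`.  Multipolar atoms use the
rotated reflection direction per operator, so symmetry mates scatter
anisotropically in the correct orientations.

Gradients come in the two forms refinement programs need: accumulated
target gradients `dT/dp = sum_h Re[conj(dT/dF) dF/dp]` with memory
proportional to the parameter count only (the caller supplies `dT/dF`
in the convention `dT = sum_h Re[conj(dT/dF) dF]`), and an explicit
per-reflection `dF/dp` table guarded at 1e7 entries, since that table
is the object that grows to hundreds of gigabytes for macromolecular
problems.  Positional gradients are per fractional coordinate (the
`2 pi i h` form); `grad_frac_to_cart` converts to per-Å.  Anisotropic
ADP gradients address the six unique `U*` components.  Local frames
are held fixed under differentiation (standard TAAM refinement
practice — the finite-difference oracle in the tests perturbs
coordinates under the same frozen assignment).

An independent FFT-based Gaussian-IAM path (real-space sampling of the
thermally smeared Gaussians, oversampling 6 grid points per resolution
element, constant term folded into the thermal factor — hence its
`B > 0.5 Å²` requirement) exists as the classical fast algorithm for
the Gaussian special case and serves as the cross-check oracle for
direct summation.

## Maps

Fourier synthesis `rho(x) = (1/V) sum_h F(h) exp(-2 pi i h x)` with
Friedel mates reconstituted; grids are the smallest 2,3,5-smooth sizes
satisfying spacing `<= d_min/3` (and Nyquist for the reflection list).
Deformation maps subtract an IAM synthesis from the TAAM one,
optionally after one global least-squares scale
`k = Re(sum conj(F_iam) F_taam)/sum |F_iam|^2` (a single scalar; no
resolution binning).  The IAM leg defaults to the
four-Gaussian-plus-constant table for X-rays and the 6 Å⁻¹ electron
table for electrons.  F(000) is excluded from both legs by default
because the electron origin term diverges for net charges.  Contour
helpers implement the k·rmsd rule (default k = 1.5) and the midpoint
of the two maps' levels for overlays.

## Synthetic data

The fixture generators produce small rigid molecules from ideal
geometry (methane, water, benzene) and conformationally non-trivial
ones via seeded RDKit ETKDG embedding plus MMFF relaxation (pentane,
decalin, a doubly amide-capped alanine); a 20-atom random P1 cell, a
mixed triclinic cell (water + Fe + I — all three representation
levels, isotropic and anisotropic ADPs, partial occupancy), a chiral
P2₁ pair, and deliberate altloc-overlap / clash / hydrogen-free-water
pathologies.  The fixture bank holds 12 invented but physically
plausible types (|P_lm| <= 1, kappa in [0.8, 1.2], charge transfer of
a few tenths of an electron) covering C, N, O, H, S environments plus
a Gaussian-only iodine.  What these fixtures do *not* emulate:
experimental noise and incompleteness, bulk solvent, real bank
parameter values, disorder beyond a single overlapping pair, and
macromolecular scale.  Passing tests therefore demonstrate
mathematical correctness of the model, typing and gradient machinery —
not agreement with any experimental data set.

## Numerical choices and limitations

* Radial-transform series/recursion switch at `H/zeta = 0.2`; both
  branches agree to ~1e-9 relative at the seam.
* Frame Gram–Schmidt degeneracy threshold 1e-6 (relative); frames are
  orthonormal to 1e-10.
* Reflection uniqueness keeps the lexicographically larger member of
  each Friedel pair; no space-group-specific merging is performed.
* The FFT cross-check supports P1, isotropic B > 0.5 Å² only.
* The bond-graph stores one minimum-image vector per bond; reverse
  directions assume the identity image, which holds for the molecular
  fixtures (whole molecules in the asymmetric unit) but would need op
  bookkeeping for polymeric bonding across symmetry mates.
* Problem sizes in the test and acceptance runs (cells of 3–28 atoms,
  up to ~2000 reflections, quadrature grids of ~1e6 points) were chosen
  so every oracle comparison is itself converged well below the
  tolerance it checks.
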