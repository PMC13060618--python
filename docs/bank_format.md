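# Bank file format (version 1)

This document is normative for the text serialization of multipolar
parameter banks used by taamkit.  Transferable-atom banks in the field
(the UBDB/MATTS, ELMAM2 and Invariom families) each use their own
private serializations; taamkit defines its own, line-oriented and
versioned.

General rules: `#` starts a comment; blank lines are ignored; the file
opens with `bank-format 1`; three block types exist, each closed by a
line `end`.  Parse errors name the line and the offending field.

## `slater <element>`

Spherical core/valence reference density as density-normalized Slater
terms.  Each body line is

    core|valence <electrons> <n> <alpha>

meaning a term `occ * N * r^n * exp(-alpha r)` with `N` fixed by
`4 pi Int r^2 N r^n exp(-alpha r) dr = 1`; `alpha` is in Å⁻¹ on the
density scale.  The summed electron counts of core plus valence must
equal Z (the neutral reference atom) to 1e-6.

## `gauss <element> <dialect> <smax>`

Per-element sum-of-Gaussians scattering coefficients,
`f(s) = sum_i a_i exp(-b_i s^2) + c` with `s = sin(theta)/lambda` in
Å⁻¹.  Dialects: `four-gauss-const`, `five-gauss` (X-ray, electrons),
`electron-2`, `electron-6` (electron scattering, Å).  `smax` is the fit
validity bound; evaluation beyond it warns.  Body lines: `a ...`,
`b ...` (equal length, `b_i >= 0`), optional `c <const>`.

## `type <type_id>`

One transferable atom type.  `type_id`s must be unique within a file.

| field           | meaning |
|-----------------|---------|
| `element E`     | central element (a `slater E` block must exist) |
| `neighbors ...` | exact multiset of first-shell element symbols |
| `planar yes/no` | optional; compared against the best-fit-plane test |
| `ring N`        | optional; atom must lie in an N-membered ring |
| `second E S...` | optional, repeatable; some first neighbour of element E has exactly the multiset S of further neighbours |
| `frame Z r X r` | local-frame recipe (below) |
| `pcore/pval`    | core and spherical-valence populations (electrons) |
| `kappa`         | valence contraction-expansion scalar (> 0) |
| `kappa_prime`   | deformation contraction-expansion scalar (> 0), shared across l = 1..4 |
| `zeta`          | deformation radial exponent, Å⁻¹ density scale (`zeta_unit bohr` converts) |
| `nl n0..n4`     | radial powers per multipole order l = 0..4, `n_l >= l` |
| `plm l m v`     | sparse multipole population entries |
| `plm_dense v×25`| alternative dense form; exactly 25 values |

Frame references: `N1`, `N2`, ... index the canonically ordered
neighbour list (descending atomic number, then increasing bond length,
then atom index); `N1.2` is the second further neighbour of neighbour 1
(needed for terminal atoms such as hydrogens and carbonyl oxygens); a
leading `-` flips the direction.  Z lies along the first reference; X is
the Gram-Schmidt complement of the second; Y completes a right-handed
frame.  Collinear references make the frame degenerate and demote the
atom at assignment time.

The matching grammar deliberately stops at second neighbours plus the
planarity/ring flags; environments distinguished only by more distant
atoms cannot be expressed and fall back to the spherical representation.
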