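# taamkit

Aspherical and independent-atom scattering-factor calculations for
crystallography and electron diffraction: Hansen–Coppens multipolar
atoms with bank-based transferable parameters (TAAM), spherical Slater
and Gaussian fallbacks, direct-summation structure factors with
analytic parameter gradients, Mott–Bethe conversion to electron
scattering, and Fourier map synthesis including TAAM−IAM deformation
maps.

## Who this is for

The independent atom model (IAM) treats every atom as a neutral,
spherical, chemically inert scatterer.  That approximation breaks down
at sub-ångström resolution for X-rays and is structurally inadequate
for electron diffraction and cryoEM, where the electrostatic potential
is sensitive to charge transfer at any resolution.  The transferable
aspherical atom model (TAAM) replaces each atomic density with a
Hansen–Coppens multipolar expansion

    rho(r) = rho_core + P_val kappa^3 rho_val(kappa r)
           + sum_lm P_lm R_l(kappa' zeta; r) d_lm(theta, phi)

whose parameters are looked up in a bank indexed by the atom's local
chemical environment, keeping the refinable parameter count identical
to IAM (10 per atom with anisotropic ADPs, against 37 if the
multipoles through hexadecapoles were refined).  taamkit implements
the full pipeline — chemistry-aware atom typing with a documented
fallback hierarchy, form factors, structure factors and gradients,
maps — as a self-contained library + CLI for method developers and for
anyone who wants aspherical scattering without assembling a chain of
refinement packages.  It ships a small synthetic fixture bank and toy
crystal generators, so everything runs and is testable offline; real
bank coefficients can be supplied in the documented text schema
(`docs/bank_format.md`).

## Worked example

Materialize a toy water crystal and the fixture bank, check the
typing, and compute TAAM electron structure factors:

    $ taamkit fixtures bank --seed 0
    $ taamkit fixtures water
    $ taamkit type-report water-0.pdb --bank fixture-bank-0.txt
    atoms: 3
      multipolar              3 (100.00%)
      spherical-slater        0 (  0.00%)
      gaussian-iam            0 (  0.00%)
    multipolar coverage: 100.00%

Every atom matched a bank type (O_water and two H_oxygen), so the
model is fully multipolar — the coverage percentage is the first thing
to check before trusting any TAAM result; demoted atoms are listed
with machine-readable reasons (`no-H-neighbour`, `altloc-overlap`,
`Z>36-no-slater`, ...).

    $ taamkit sf water-0.pdb --bank fixture-bank-0.txt \
          --mode taam --radiation electron --d-min 1.0 --out water-e.hkl
    multipolar coverage: 100.0%
    $ head -4 water-e.hkl
    # taamkit structure factors  radiation=electron mode=taam
    #   h   k   l          |F|      phase_deg
        0    0    1   4.27681378e+00  -180.00000000
        0    0    2   2.18082627e+00     0.00000000

The amplitudes are electron scattering factors in Å (X-ray factors
converted per reflection through the Mott–Bethe relation
f_e = C (Z − f_x)/s²); phases are degrees in [−180, 180).  A JSON run
manifest (`water-e.hkl.manifest.json`) records the resolved mode,
radiation, table dialect and coverage.

A TAAM−IAM deformation map with the 1.5-rmsd midpoint contour
suggestion:

    $ taamkit defmap water-0.pdb --bank fixture-bank-0.txt \
          --radiation xray --d-min 0.9 --out water-def.ccp4
    $ cat water-def.ccp4.json
    {
      "taam_level_1_5_rmsd": 0.32126198849726995,
      "iam_level_1_5_rmsd": 0.2982220444029895,
      "midpoint_level": 0.3097420164501297,
      "scale_factor": 1.0,
      "quantity": "electron-density"
    }

The CCP4/MRC map holds the Fourier synthesis of F_taam − F_iam in
e Å⁻³ (Å⁻² for `--radiation electron`); the sidecar suggests a common
absolute contour level — the midpoint of the two maps' 1.5-rmsd
levels — for overlaying TAAM and IAM maps on one scale.
`--scaling` inserts a least-squares scalar between the legs first.

The same functionality is a library: `read_structure`,
`build_bond_graph` / `assign_atom_types`, `direct_summation_sf`,
`sf_gradients`, `fourier_map`, `deformation_map`.

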