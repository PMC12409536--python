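# Methods

## The energy model

All workflows operate on the component triple (E_0, E_OS, E_SS): the
restricted Hartree–Fock total energy and the opposite-spin / same-spin
parts of the MP2 correlation energy. For a closed-shell reference with
canonical spatial orbitals (i, j occupied; a, b virtual),

    E_OS = Σ_ijab (ia|jb)² / Δ_ijab
    E_SS = Σ_ijab (ia|jb) [(ia|jb) − (ib|ja)] / Δ_ijab
    Δ_ijab = ε_i + ε_j − ε_a − ε_b.

E_OS + E_SS is the full MP2 correlation energy by construction, and
both parts are non-positive for a gapped ground state. The scaled
total energy E(C_OS, C_SS) = E_0 + C_OS·E_OS + C_SS·E_SS is affine in
the coefficients; every downstream quantity (interaction energies,
stacking decompositions, dissociation curves, calibration objectives)
inherits that affinity, which is exploited throughout: curves can be
rescaled to new coefficients without recomputation, and calibration
needs no quantum chemistry after the per-system component deltas are
assembled.

Two independent routes compute the spin split: the spatial-orbital
fast path above, and a brute-force spin-orbital oracle that builds the
antisymmetrized integral tensor explicitly and classifies every
occupied pair by spin. The oracle is guarded to ≤ 30 spin orbitals and
exists purely for validation; the test suite requires agreement to
1e-10 hartree.

## The built-in engine

The engine is deliberately small and self-contained:

- **Integrals** — McMurchie–Davidson Hermite recursions over contracted
  Cartesian Gaussians, with the Boys function evaluated through the
  regularized incomplete gamma function (series fallback below
  x = 1e-7, downward recursion in the order). The same machinery
  yields overlap, kinetic, nuclear-attraction and two-/three-/
  four-center repulsion integrals; three- and two-center variants are
  obtained by pairing a shell with a zero-exponent unit "shell".
- **Orbital bases** — STO-3G for H–Ne, generated at import time from
  the classic three-Gaussian Slater-fit constants and per-element
  Slater exponents (values agree with the Basis Set Exchange
  tabulation to all printed digits), and 6-31G for H and He. The
  6-31G set exists because a minimal basis leaves He with no virtual
  orbitals, so correlated rare-gas fixtures need a split valence.
  Arbitrary basis *names* on externally computed component tables are
  recorded verbatim and never interpreted.
- **SCF** — restricted Hartree–Fock with a core-Hamiltonian guess,
  DIIS (least-squares solve of the error-overlap system, which turns
  singular near convergence; extrapolation is skipped when the weights
  degenerate), canonical orthogonalization dropping overlap
  eigenvalues below 1e-10 of the largest (needed for counterpoise
  runs, where ghost functions overlap real ones), and convergence at
  1e-10 hartree / 1e-8 RMS density. Canonical orbitals are taken from
  the *unextrapolated* Fock operator of the converged density — DIIS
  extrapolation noise otherwise contaminates orbital energies at the
  1e-3 level even when the energy is converged.
- **Ghost atoms** contribute basis functions but no electrons or
  nuclear charge; they are the counterpoise mechanism and are spelled
  `@El` in XYZ text.

MP2 denominators with |Δ| < 1e-8 hartree raise a degeneracy error
rather than being damped; perturbation theory is simply invalid there.

Frozen core is on by default, with He cores for Li–Ne and Ne cores for
Na–Ar. Note that the published calibrations do not state their
frozen-core convention; the flag is explicit on `BasisSpec`.

Unit boundaries: geometry is Å at the API and bohr inside the engine
(1 bohr = 0.529177210903 Å); energies are hartree internally and
converted to kcal/mol (627.5094740631) only where interaction energies
are reported.

## RI density fitting

The RI correlation step factorizes (ia|jb) ≈ Σ_P B_ia^P B_jb^P with
B = (ia|Q) [J^{-1/2}]_QP over an auxiliary basis, J_PQ = (P|Q). The
metric inverse square root is formed by eigendecomposition, dropping
eigenvalues below 1e-10 of the largest (even-tempered sets are
intentionally redundant).

Auxiliary sets are generated even-tempered from the orbital basis on
each atom ("autoaux" style): a geometric ladder of single-Gaussian
exponents spanning [min α, 2·max α], with angular momenta up to
2·l_max plus one extra channel — off-center orbital products carry
higher multipoles than any on-center product, and without that channel
the fit error stalls near 1e-4 hartree on polyatomics. Steep exponents
are trimmed from the l > 0 channels (only compact s-type core products
need them). Three densities are provided:

| name | ratio β | extra l channel | role |
|---|---|---|---|
| autoaux-coarse | 3.2 | no | economy / convergence studies |
| autoaux-medium | 2.2 | yes | matched default |
| autoaux-fine | 1.5 | yes | tight reference |

On the water fixture the correlation-energy fit error decreases
monotonically through this ladder and is below 1e-4 hartree from the
medium set on; the test suite asserts both properties for E_OS and
E_SS separately.

## Supermolecule and stacking conventions

Interaction energies use frozen in-complex monomer geometries by
default; a relaxed-monomer mode accepts separately supplied monomer
components and results carry the mode label. Counterpoise correction
(monomers in the full dimer basis) is available but off by default in
every pipeline: the BWI-style calibration is performed on uncorrected
interaction energies and absorbs basis-set superposition effects into
the coefficients. Note the correction itself is always non-negative —
ghost functions can only stabilize a monomer — so CP reduces the
*magnitude* of E_int only where the interaction is attractive; at
repulsive geometries it makes E_int more positive.

Stacked tetramers index monomers 1–4 with (1,2) and (3,4) the intact
Watson–Crick pairs. The two-body stacking energy sums the four
cross-pair interactions ΔE_1,3 + ΔE_2,4 + ΔE_1,4 + ΔE_2,3 (intra-pair
terms never enter); the four-body version is E_1,2,3,4 − E_1,2 −
E_3,4. For a strictly pairwise-additive energy function the two agree
identically — the test suite checks this to 1e-10 kcal/mol on toy
assemblies. The driver plans the required sub-calculations (4 monomers
+ 6 pairs + optional tetramer) from a single 4-fragment geometry.

## Dissociation scans

Separation scaling is rigid-body: fragment 0 is held fixed and
fragment 1 translated along the center-of-mass vector so the COM
distance scales by the requested factor. The reference points are not
dictated by the physics; COM is the least arbitrary choice and is used
consistently. Preset factor ladders span 0.90–2.00 (hydrogen-bonded)
and 0.70–2.00 (stacked aromatics, to sample the repulsive wall), step
0.10 by default, endpoints included exactly. Monomer energies are
computed once per scan (rigid monomers have factor-independent
internal energies). The curve minimum is located by a quadratic fit
through the three lowest points, falling back to the grid minimum at
an edge or under degenerate curvature. SCF failure at a point flags it
and the scan continues.

## Calibration

Fitting works entirely in kcal/mol on per-system deltas
(ΔE0, ΔE_OS, ΔE_SS) = dimer − monomers. The MAD objective is a sum of
absolute affine functions of (C_OS, C_SS) — convex and piecewise
linear — and is minimized exactly as a linear program (scipy HiGHS)
with slack variables per residual. Default bounds are [0, 2.5]²:
no published preset is negative, and the known double-zeta optimum
sits *on* the C_OS = 0 boundary, so boundary activity is always
reported. Because LP solvers only reach their own tolerance (~1e-8),
the solution is polished onto the exact optimal vertex: the
zero-residual lines nearest the LP point are intersected pairwise and
with the bound edges, and the best candidate is kept. Near-ties
(within 1e-9 kcal/mol) resolve to the lexicographically smallest pair,
and the bounding box of the near-optimal set is reported — shallow
valleys with many near-optimal coefficient pairs are the norm for
these surfaces, not an edge case. Collinearity of the (ΔE_OS, ΔE_SS)
columns (Gram-matrix condition number above 1e10) sets a
non-uniqueness flag; the fit is still returned.

The dense grid scan evaluates MAD, Max(MAD) and RMSD on a 0.01-step
lattice over the bounds (the precision to which such coefficients are
conventionally printed), chunked to bound memory, and doubles as an
independent argmin oracle for the LP in the tests.

## Synthetic calibration data

The generator emulates only the *structure* of a weak-interaction
benchmark: ΔE0 ~ N(+2, 2) kcal/mol, ΔE_OS = −|N(3, 1)|,
ΔE_SS = −|N(1.5, 0.5)|, and E_ref from the planted affine model plus
Gaussian noise. These magnitudes are kcal-scale scaffolding chosen
once, not physical claims; real benchmark sets have correlated,
system-class-dependent deltas, heavier tails and reference-level
systematics that the generator does not model. Passing recovery tests
therefore demonstrates the correctness of the fitting machinery, not
transferability of any fitted coefficients to real chemistry. All
sampling flows through one explicitly passed seeded generator.

## Problem sizes and numerical checks in the shipped tests

Fixtures are intentionally tiny: H2O/STO-3G (7 basis functions) for
oracle and RI checks, He/H2 in 6-31G/STO-3G for two-electron limits
and scans, n = 60–200 synthetic systems for calibration. The whole
suite runs in well under a minute on one core. Key tolerances: oracle
agreement 1e-10 Eh, decomposition identity 1e-12 Eh, RI matched-set
error 1e-4 Eh, noiseless coefficient recovery ±0.01 with MAD ≤ 1e-8,
noisy (σ = 0.2, n = 200, fixed seed) recovery ±0.05.

## Known limitations

- Closed-shell (RHF/MP2) only; multiplicity ≠ 1 is rejected.
- Built-in orbital bases are minimal/double-zeta for light elements;
  the engine targets validation-scale fixtures, not production
  basis-set work. Heavier elements or larger bases enter via
  externally computed component tables.
- No SCF-level RI (RI-JK) or grid-based exchange; such components are
  supported only as externally supplied tables with their basis
  strings recorded verbatim.
- No three-body or higher many-body terms beyond the two formulas
  above; no error-propagation model for the multi-step decompositions.
- The LAD fit treats all systems with equal weight; no per-family
  weighting or cross-validation.
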