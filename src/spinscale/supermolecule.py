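"""Supermolecule interaction energies and many-body stacking decompositions.

The interaction energy of a complex is the scaled total energy of the
dimer minus those of its monomers,

    E_int = E(dimer) - E(monomer 1) - E(monomer 2),

reported in kcal/mol.  Because the scaled energy is affine in the
coefficients, E_int(C) = dE0 + C_OS*dE_OS + C_SS*dE_SS with
dimer-minus-monomer component deltas — the identity the calibration
module exploits.

For stacked tetramers (two stacked Watson-Crick pairs, monomers indexed
1..4 with 1,2 the first pair and 3,4 the second) the two-body stacking
energy sums the four cross-pair interactions,

    dE_stack = dE_13 + dE_24 + dE_14 + dE_23,    dE_XY = E_XY - E_X - E_Y,

and the four-body stacking energy compares the full tetramer with the
two intact pairs:

    dE_4stack = E_1234 - E_12 - E_34.

Monomer energies default to the frozen in-complex fragment geometries;
a relaxed-monomer mode accepts separately optimized monomer energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .basis import BasisSpec
from .chem_model import DimerSystem
from .constants import HARTREE_TO_KCALMOL
from .mp2 import EnergyComponents, mp2_components_canonical, mp2_components_ri
from .scaling import ScalingCoefficients, scaled_energy
from .scf import SCFSettings, compute_scf

CROSS_PAIRS = ((1, 3), (2, 4), (1, 4), (2, 3))
WC_PAIRS = ((1, 2), (3, 4))


class ConsistencyError(ValueError):
    """Component sets of one record mix method tags."""


class CompletenessError(KeyError):
    """A required sub-assembly is missing from a stack decomposition."""


@dataclass(frozen=True)
class InteractionRecord:
    """Component triples for one dimer system, plus an optional reference."""

    system_id: str
    dimer: EnergyComponents
    monomer1: EnergyComponents
    monomer2: EnergyComponents
    E_ref: float | None = None
    mode: str = "frozen-monomer"


def interaction_energy(
    rec: InteractionRecord, c: ScalingCoefficients, allow_mixed: bool = False
) -> float:
    """Scaled supermolecule interaction energy, kcal/mol."""
    tags = {rec.dimer.method_tag, rec.monomer1.method_tag, rec.monomer2.method_tag}
    if len(tags) > 1 and not allow_mixed:
        raise ConsistencyError(
            f"mixed method tags {sorted(tags)} in {rec.system_id!r}; "
            "pass allow_mixed=True to override"
        )
    e = (
        scaled_energy(rec.dimer, c)
        - scaled_energy(rec.monomer1, c)
        - scaled_energy(rec.monomer2, c)
    )
    return e * HARTREE_TO_KCALMOL


def compute_components(
    mol, basis: BasisSpec, settings: SCFSettings | None = None
) -> EnergyComponents:
    """SCF + spin-component MP2 for one molecule (RI when an auxiliary
    basis is named, canonical otherwise)."""
    scf = compute_scf(mol, basis, settings)
    if basis.aux_basis_corr:
        return mp2_components_ri(scf, basis)
    return mp2_components_canonical(scf, basis.frozen_core)


def compute_interaction_record(
    dimer: DimerSystem,
    basis: BasisSpec,
    settings: SCFSettings | None = None,
) -> InteractionRecord:
    """Full pipeline for a dimer: components for the complex and for both
    frozen in-complex monomers."""
    return InteractionRecord(
        system_id=dimer.label or "dimer",
        dimer=compute_components(dimer.geometry, basis, settings),
        monomer1=compute_components(dimer.monomer(0), basis, settings),
        monomer2=compute_components(dimer.monomer(1), basis, settings),
    )


def counterpoise_interaction_energy(
    dimer: DimerSystem,
    basis: BasisSpec,
    c: ScalingCoefficients,
    settings: SCFSettings | None = None,
) -> float:
    """Counterpoise-corrected interaction energy, kcal/mol.

    Monomers are evaluated in the full dimer basis, with the partner's
    atoms retained as ghost centers.  Off by default everywhere else:
    the BWI calibration was performed on uncorrected interaction
    energies and absorbs basis-set superposition effects empirically.
    """
    e_dimer = scaled_energy(compute_components(dimer.geometry, basis, settings), c)
    e_m1 = scaled_energy(
        compute_components(dimer.monomer(0, ghost_partner=True), basis, settings), c
    )
    e_m2 = scaled_energy(
        compute_components(dimer.monomer(1, ghost_partner=True), basis, settings), c
    )
    return (e_dimer - e_m1 - e_m2) * HARTREE_TO_KCALMOL


def _norm_pair(x: int, y: int) -> tuple[int, int]:
    if x == y:
        raise ValueError(f"a pair needs two distinct monomers, got ({x}, {y})")
    if not (1 <= x <= 4 and 1 <= y <= 4):
        raise ValueError(f"monomer indices must be 1..4, got ({x}, {y})")
    return (min(x, y), max(x, y))


@dataclass(frozen=True)
class StackAssembly:
    """Indexed tetramer: monomers 1,2 form the first Watson-Crick pair,
    3,4 the second.  ``pair_energies`` keys are sorted index pairs."""

    tetramer: EnergyComponents | None
    pair_energies: dict[tuple[int, int], EnergyComponents] = field(default_factory=dict)
    monomers: dict[int, EnergyComponents] = field(default_factory=dict)
    label: str = ""

    def pair(self, x: int, y: int) -> EnergyComponents:
        key = _norm_pair(x, y)
        if key not in self.pair_energies:
            raise CompletenessError(f"missing sub-assembly E_{key[0]},{key[1]}")
        return self.pair_energies[key]

    def monomer(self, i: int) -> EnergyComponents:
        if i not in self.monomers:
            raise CompletenessError(f"missing monomer E_{i}")
        return self.monomers[i]


def compute_stack_assembly(
    mol,
    basis: BasisSpec,
    settings: SCFSettings | None = None,
    include_tetramer: bool = True,
) -> StackAssembly:
    """Plan and run the component calculations a stacking decomposition
    needs on a 4-fragment geometry: the four monomers, the four cross
    pairs, the two intact pairs, and (optionally) the tetramer.

    Sub-geometries keep their frozen in-complex coordinates.  Fragments
    are 0-based in the geometry and 1-based in the assembly indexing.
    """
    if mol.n_fragments != 4:
        raise ValueError(f"stack decomposition needs 4 fragments, got {mol.n_fragments}")

    def sub(fragment_ids):
        atoms, frags = [], []
        for atom, f in zip(mol.atoms, mol.fragment_of):
            if f + 1 in fragment_ids:
                atoms.append(atom)
                frags.append(0)
        from .chem_model import Molecule

        return Molecule(tuple(atoms), charge=0, multiplicity=1)

    monomers = {
        i: compute_components(sub({i}), basis, settings) for i in range(1, 5)
    }
    pair_energies = {
        p: compute_components(sub(set(p)), basis, settings)
        for p in (*CROSS_PAIRS, *WC_PAIRS)
    }
    pair_energies = {(min(p), max(p)): v for p, v in pair_energies.items()}
    tetramer = compute_components(mol, basis, settings) if include_tetramer else None
    return StackAssembly(tetramer, pair_energies, monomers)


def pair_interaction(
    assembly: StackAssembly, x: int, y: int, c: ScalingCoefficients
) -> float:
    """dE_XY = E_XY - E_X - E_Y, kcal/mol."""
    e = (
        scaled_energy(assembly.pair(x, y), c)
        - scaled_energy(assembly.monomer(x), c)
        - scaled_energy(assembly.monomer(y), c)
    )
    return e * HARTREE_TO_KCALMOL


def stack_two_body(assembly: StackAssembly, c: ScalingCoefficients) -> float:
    """Two-body stacking energy: the sum of the four cross-pair
    interactions between the stacked Watson-Crick pairs, kcal/mol."""
    return sum(pair_interaction(assembly, x, y, c) for x, y in CROSS_PAIRS)


def stack_four_body(assembly: StackAssembly, c: ScalingCoefficients) -> float:
    """Four-body stacking energy: tetramer minus the two intact pairs,
    kcal/mol."""
    if assembly.tetramer is None:
        raise CompletenessError("missing tetramer components E_1,2,3,4")
    e = scaled_energy(assembly.tetramer, c)
    for x, y in WC_PAIRS:
        e -= scaled_energy(assembly.pair(x, y), c)
    return e * HARTREE_TO_KCALMOL
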