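"""Interaction energies and the two-/four-body stacking decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinscale import BasisSpec, builtin_molecule
from spinscale.constants import HARTREE_TO_KCALMOL
from spinscale.mp2 import EnergyComponents
from spinscale.scaling import ScalingCoefficients, preset
from spinscale.supermolecule import (
    CompletenessError,
    ConsistencyError,
    CROSS_PAIRS,
    InteractionRecord,
    StackAssembly,
    compute_interaction_record,
    counterpoise_interaction_energy,
    interaction_energy,
    pair_interaction,
    stack_four_body,
    stack_two_body,
)

C00 = ScalingCoefficients(0.0, 0.0)


def test_noninteracting_limit_is_zero():
    m1 = EnergyComponents(-1.5, -0.2, -0.05)
    m2 = EnergyComponents(-2.5, -0.3, -0.07)
    rec = InteractionRecord("s", m1 + m2, m1, m2)
    assert interaction_energy(rec, preset("mp2")) == pytest.approx(0.0, abs=1e-12)


def test_hand_arithmetic_with_unit_conversion():
    rec = InteractionRecord(
        "s",
        EnergyComponents(-2.000000, 0.0, 0.0),
        EnergyComponents(-0.999, 0.0, 0.0),
        EnergyComponents(-1.000, 0.0, 0.0),
    )
    assert interaction_energy(rec, C00) == pytest.approx(
        -0.001 * HARTREE_TO_KCALMOL, abs=1e-10
    )
    assert interaction_energy(rec, C00) == pytest.approx(-0.6275, abs=1e-4)


def test_mixed_method_tags_rejected_unless_overridden():
    a = EnergyComponents(-1.0, -0.1, -0.02, method_tag="canonical")
    b = EnergyComponents(-1.0, -0.1, -0.02, method_tag="ri")
    rec = InteractionRecord("s", a, b, b)
    with pytest.raises(ConsistencyError):
        interaction_energy(rec, C00)
    assert interaction_energy(rec, C00, allow_mixed=True) == pytest.approx(
        HARTREE_TO_KCALMOL, abs=1e-9
    )


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.floats(-5, 5, allow_nan=False), min_size=9, max_size=9),
    st.floats(0, 2.5), st.floats(0, 2.5),
)
def test_linearity_in_coefficients(vals, cos, css):
    """E_int(c) == dE0 + C_OS*dE_OS + C_SS*dE_SS with dimer-minus-monomer deltas."""
    d, m1, m2 = (EnergyComponents(*vals[i:i + 3]) for i in (0, 3, 6))
    rec = InteractionRecord("s", d, m1, m2)
    c = ScalingCoefficients(cos, css)
    delta = d - m1 - m2
    direct = (delta.E0 + cos * delta.E_OS + css * delta.E_SS) * HARTREE_TO_KCALMOL
    assert interaction_energy(rec, c) == pytest.approx(direct, abs=1e-9)


def test_monomer_relabeling_symmetry():
    d = EnergyComponents(-3.0, -0.4, -0.1)
    m1 = EnergyComponents(-1.0, -0.15, -0.03)
    m2 = EnergyComponents(-1.9, -0.22, -0.06)
    c = preset("bwi-dz")
    assert interaction_energy(InteractionRecord("a", d, m1, m2), c) == pytest.approx(
        interaction_energy(InteractionRecord("a", d, m2, m1), c), abs=1e-12
    )


def test_long_range_dimer_pipeline():
    dim = builtin_molecule("he_he", 20.0)
    rec = compute_interaction_record(dim, BasisSpec("6-31g", frozen_core=False))
    assert abs(interaction_energy(rec, preset("mp2"))) <= 1e-4


def test_counterpoise_correction_positive_near_contact():
    """Ghost functions only stabilize the monomers, so the counterpoise
    correction (CP minus plain) is non-negative."""
    spec = BasisSpec("6-31g", frozen_core=False)
    dim = builtin_molecule("he_he", 2.2)
    c = preset("mp2")
    plain = interaction_energy(compute_interaction_record(dim, spec), c)
    cp = counterpoise_interaction_energy(dim, spec, c)
    assert cp >= plain - 1e-10


def test_counterpoise_matches_plain_at_long_range():
    spec = BasisSpec("6-31g", frozen_core=False)
    dim = builtin_molecule("he_he", 50.0)
    c = preset("mp2")
    plain = interaction_energy(compute_interaction_record(dim, spec), c)
    cp = counterpoise_interaction_energy(dim, spec, c)
    assert cp == pytest.approx(plain, abs=1e-4)


# ---------- stacking decomposition ----------

def _pairwise_additive_assembly(rng):
    """Toy model: monomer energies random; every pair energy is exactly the
    sum of its monomers plus a pair-specific interaction; the tetramer is
    the sum of monomers plus all six pairwise interactions."""
    mono = {i: EnergyComponents(*rng.normal(-2, 0.5, 3)) for i in range(1, 5)}
    pair_int = {}
    for x in range(1, 5):
        for y in range(x + 1, 5):
            pair_int[(x, y)] = EnergyComponents(*rng.normal(-0.01, 0.005, 3))
    pairs = {
        (x, y): mono[x] + mono[y] + pair_int[(x, y)] for (x, y) in pair_int
    }
    tetra = EnergyComponents(0.0, 0.0, 0.0)
    for m in mono.values():
        tetra = tetra + m
    for pi in pair_int.values():
        tetra = tetra + pi
    return StackAssembly(tetra, pairs, mono), pair_int


def test_noninteracting_assembly_decomposes_to_zero():
    rng = np.random.default_rng(0)
    mono = {i: EnergyComponents(*rng.normal(-2, 0.5, 3)) for i in range(1, 5)}
    pairs = {
        (x, y): mono[x] + mono[y]
        for x in range(1, 5) for y in range(x + 1, 5)
    }
    tetra = mono[1] + mono[2] + mono[3] + mono[4]
    asm = StackAssembly(tetra, pairs, mono)
    c = preset("bwi-dz")
    assert stack_two_body(asm, c) == pytest.approx(0.0, abs=1e-9)
    assert stack_four_body(asm, c) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_pairwise_additive_model_two_body_equals_four_body(seed):
    asm, _ = _pairwise_additive_assembly(np.random.default_rng(seed))
    c = preset("bwi-dz")
    assert stack_two_body(asm, c) == pytest.approx(stack_four_body(asm, c), abs=1e-10)


def test_two_body_equals_bruteforce_cross_pair_sum():
    asm, pair_int = _pairwise_additive_assembly(np.random.default_rng(9))
    c = preset("scs")
    brute = sum(
        (pair_int[(min(x, y), max(x, y))].E0
         + c.C_OS * pair_int[(min(x, y), max(x, y))].E_OS
         + c.C_SS * pair_int[(min(x, y), max(x, y))].E_SS) * HARTREE_TO_KCALMOL
        for x, y in CROSS_PAIRS
    )
    assert stack_two_body(asm, c) == pytest.approx(brute, abs=1e-10)


def test_two_body_ignores_intra_pair_energies():
    asm, _ = _pairwise_additive_assembly(np.random.default_rng(4))
    c = preset("mp2")
    full = stack_two_body(asm, c)
    stripped = StackAssembly(
        asm.tetramer,
        {k: v for k, v in asm.pair_energies.items() if k not in ((1, 2), (3, 4))},
        asm.monomers,
    )
    assert stack_two_body(stripped, c) == pytest.approx(full, abs=1e-12)


def test_pair_relabeling_symmetry():
    """Swapping the two Watson-Crick pairs (1,2)<->(3,4) leaves both
    decompositions unchanged."""
    asm, _ = _pairwise_additive_assembly(np.random.default_rng(5))
    remap = {1: 3, 2: 4, 3: 1, 4: 2}
    swapped = StackAssembly(
        asm.tetramer,
        {tuple(sorted((remap[x], remap[y]))): v for (x, y), v in asm.pair_energies.items()},
        {remap[i]: v for i, v in asm.monomers.items()},
    )
    c = preset("bwi-tz")
    assert stack_two_body(swapped, c) == pytest.approx(stack_two_body(asm, c), abs=1e-10)
    assert stack_four_body(swapped, c) == pytest.approx(stack_four_body(asm, c), abs=1e-10)


def test_four_body_hand_arithmetic():
    mono = {i: EnergyComponents(-1.0, 0.0, 0.0) for i in range(1, 5)}
    pairs = {
        (1, 2): EnergyComponents(-2.05, 0.0, 0.0),
        (3, 4): EnergyComponents(-2.04, 0.0, 0.0),
    }
    asm = StackAssembly(EnergyComponents(-4.10, 0.0, 0.0), pairs, mono)
    assert stack_four_body(asm, C00) == pytest.approx(
        -0.01 * HARTREE_TO_KCALMOL, abs=1e-9
    )


def test_completeness_and_domain_errors():
    mono = {i: EnergyComponents(-1.0, -0.1, -0.02) for i in range(1, 5)}
    asm = StackAssembly(EnergyComponents(-4.0, -0.4, -0.08), {}, mono)
    c = preset("mp2")
    with pytest.raises(CompletenessError, match="E_1,3"):
        stack_two_body(asm, c)
    with pytest.raises(CompletenessError):
        stack_four_body(asm, c)
    with pytest.raises(ValueError, match="distinct"):
        pair_interaction(asm, 2, 2, c)


def test_pair_interaction_matches_interaction_record():
    asm, _ = _pairwise_additive_assembly(np.random.default_rng(6))
    c = preset("mp2")
    rec = InteractionRecord("p13", asm.pair(1, 3), asm.monomer(1), asm.monomer(3))
    assert pair_interaction(asm, 1, 3, c) == pytest.approx(
        interaction_energy(rec, c), abs=1e-12
    )
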