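"""Shared fixtures: converged SCF solutions are expensive enough to share."""

import pytest

from spinscale import BasisSpec, builtin_molecule, compute_scf
from spinscale.mp2 import mp2_components_canonical


@pytest.fixture(scope="session")
def h2o_scf():
    return compute_scf(builtin_molecule("h2o"), BasisSpec("sto-3g"))


@pytest.fixture(scope="session")
def h2o_mp2(h2o_scf):
    return mp2_components_canonical(h2o_scf, frozen_core=True)


@pytest.fixture(scope="session")
def he_scf_dz():
    return compute_scf(builtin_molecule("he"), BasisSpec("6-31g", frozen_core=False))


@pytest.fixture(scope="session")
def h2_scf():
    return compute_scf(builtin_molecule("h2"), BasisSpec("sto-3g"))
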