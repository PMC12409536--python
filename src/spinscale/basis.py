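"""Basis sets for the built-in engine.

Orbital basis: STO-3G, generated from the classic three-Gaussian
least-squares fits to Slater 1s/2s/2p orbitals with the standard
per-element Slater exponents (public reference data; values agree with
the Basis Set Exchange tabulation to all printed digits).  A minimal
basis is all the acceptance fixtures need; arbitrary basis-set *names*
are still carried verbatim on externally supplied component tables.

Auxiliary basis for the RI correlation fit: even-tempered expansions
derived from the orbital basis on each atom ("autoaux" style), at three
densities — ``autoaux-coarse``, ``autoaux-medium``, ``autoaux-fine``.
Density fitting only needs the auxiliary set to span the space of
orbital-product densities, so a geometric progression of exponents
covering [min(α), 2·max(α)] with angular momenta up to 2·l_max does the
job; the fit error decreases systematically as the progression tightens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem_model import Molecule
from .constants import ANGSTROM_TO_BOHR, ATOMIC_NUMBERS
from .integrals import Shell

# Three-Gaussian Slater-fit constants for zeta = 1 (Hehre-Stewart-Pople).
_STO3G_1S_ALPHA = (2.227660584, 0.405771156, 0.1098175104)
_STO3G_1S_COEF = (0.154328967, 0.535328142, 0.444634542)
_STO3G_2SP_ALPHA = (0.994203, 0.231031, 0.0751386)
_STO3G_2S_COEF = (-0.09996723, 0.39951283, 0.70011547)
_STO3G_2P_COEF = (0.15591627, 0.60768372, 0.39195739)

# Slater exponents (zeta_1s, zeta_2sp) per element.
_STO3G_ZETA = {
    "H": (1.24,), "He": (1.69,),
    "Li": (2.69, 0.80), "Be": (3.68, 1.15), "B": (4.68, 1.50),
    "C": (5.67, 1.72), "N": (6.67, 1.95), "O": (7.66, 2.25),
    "F": (8.65, 2.55), "Ne": (9.64, 2.88),
}


# 6-31G split-valence for the lightest elements: a minimal basis leaves He
# with no virtual orbitals, so correlated rare-gas fixtures need this.
_631G = {
    "H": [
        (0, (18.7311370, 2.8253937, 0.6401217), (0.03349460, 0.23472695, 0.81375733)),
        (0, (0.1612778,), (1.0,)),
    ],
    "He": [
        (0, (38.4216340, 5.7780300, 1.2417740), (0.0237660, 0.1546790, 0.4696300)),
        (0, (0.2979640,), (1.0,)),
    ],
}


class BasisError(ValueError):
    """Unknown basis name or element not covered by a built-in basis."""


@dataclass(frozen=True)
class BasisSpec:
    """Names the orbital basis and, for RI runs, the correlation-fit
    auxiliary basis; ``frozen_core`` selects the correlation window."""

    orbital_basis: str = "sto-3g"
    aux_basis_corr: str | None = None
    frozen_core: bool = True

    def __post_init__(self) -> None:
        if not self.orbital_basis:
            raise BasisError("orbital_basis must be non-empty")


def _orbital_shells(element: str, name: str) -> list[tuple[int, tuple, tuple]]:
    if name == "sto-3g":
        return _sto3g_shells(element)
    if name == "6-31g":
        if element not in _631G:
            raise BasisError(f"built-in 6-31G covers H and He only, not {element!r}")
        return _631G[element]
    raise BasisError(f"unknown built-in orbital basis {name!r}")


def _sto3g_shells(element: str) -> list[tuple[int, tuple, tuple]]:
    if element not in _STO3G_ZETA:
        raise BasisError(f"no built-in STO-3G parameters for element {element!r}")
    zetas = _STO3G_ZETA[element]
    z1 = zetas[0] ** 2
    shells = [(0, tuple(a * z1 for a in _STO3G_1S_ALPHA), _STO3G_1S_COEF)]
    if len(zetas) > 1:
        z2 = zetas[1] ** 2
        sp_alpha = tuple(a * z2 for a in _STO3G_2SP_ALPHA)
        shells.append((0, sp_alpha, _STO3G_2S_COEF))
        shells.append((1, sp_alpha, _STO3G_2P_COEF))
    return shells


# name -> (even-tempered ratio, extra angular channels beyond 2*l_max)
_AUX_BETA = {"autoaux-coarse": (3.2, 0), "autoaux-medium": (2.2, 1), "autoaux-fine": (1.5, 1)}


def _autoaux_shells(
    element: str, beta: float, orbital_basis: str = "sto-3g", extra_l: int = 1
) -> list[tuple[int, tuple, tuple]]:
    """Even-tempered auxiliary shells spanning the orbital-product space."""
    orb = _orbital_shells(element, orbital_basis)
    exps = np.concatenate([np.asarray(a) for _, a, _ in orb])
    lmax_orb = max(l for l, _, _ in orb)
    lo, hi = float(exps.min()), 2.0 * float(exps.max())
    n = int(math.ceil(math.log(hi / lo) / math.log(beta))) + 1
    grid = lo * beta ** np.arange(n)
    shells = []
    valence = [np.asarray(a) for l, a, _ in orb if l > 0]
    cap_high = 2.0 * float(np.concatenate(valence).max()) if valence else hi / 4.0
    # channels beyond 2*l_max: off-center (two-center) orbital products
    # carry higher multipoles than any on-center product does
    for l_aux in range(2 * lmax_orb + 1 + extra_l):
        # steep functions only matter for the compact (core) s-type products;
        # trim them from the higher-angular-momentum auxiliary channels
        cap = hi if l_aux == 0 else cap_high
        for a in grid:
            if a <= cap * 1.0001:
                shells.append((l_aux, (float(a),), (1.0,)))
    return shells


def build_shells(
    mol: Molecule, basis_name: str, orbital_basis: str = "sto-3g"
) -> list[Shell]:
    """Instantiate contracted shells for every atom (ghosts included).

    ``orbital_basis`` is consulted only when ``basis_name`` is one of the
    autoaux auxiliary sets, whose exponents derive from the orbital basis.
    """
    name = basis_name.lower()
    shells: list[Shell] = []
    for i, atom in enumerate(mol.atoms):
        center = np.asarray(atom.position) * ANGSTROM_TO_BOHR
        if name in _AUX_BETA:
            beta, extra_l = _AUX_BETA[name]
            per_atom = _autoaux_shells(atom.element, beta, orbital_basis.lower(), extra_l)
        else:
            try:
                per_atom = _orbital_shells(atom.element, name)
            except BasisError:
                raise BasisError(
                    f"unknown built-in basis {basis_name!r} for element "
                    f"{atom.element!r}; available: sto-3g, 6-31g (H/He), "
                    f"{', '.join(_AUX_BETA)}"
                ) from None
        for l, alphas, coefs in per_atom:
            shells.append(Shell.contracted(l, center, alphas, coefs, atom_index=i))
    return shells


def n_basis_functions(shells: list[Shell]) -> int:
    return sum(sh.n_components for sh in shells)


def n_core_orbitals(mol: Molecule) -> int:
    from .constants import CORE_ORBITALS

    return sum(
        CORE_ORBITALS[ATOMIC_NUMBERS[a.element]] for a in mol.atoms if not a.ghost
    )
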