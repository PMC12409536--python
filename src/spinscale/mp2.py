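"""Spin-component-resolved MP2 correlation energies.

For a closed-shell reference the second-order correlation energy splits
exactly into opposite-spin and same-spin parts,

    E_OS = sum_ijab (ia|jb)^2 / D_ijab
    E_SS = sum_ijab (ia|jb) [ (ia|jb) - (ib|ja) ] / D_ijab
    D_ijab = eps_i + eps_j - eps_a - eps_b,

with i,j doubly occupied and a,b virtual spatial orbitals.  E_OS + E_SS
is the full MP2 correlation energy by construction; both parts are
non-positive for a gapped ground state.  The RI variant replaces the MO
integrals by their density-fitted factorization
(ia|jb) ~= sum_P B_ia^P B_jb^P over an auxiliary basis.

A brute-force spin-orbital oracle (explicit antisymmetrized integrals,
pair-by-pair summation) is provided for validation on tiny systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, build_shells, n_core_orbitals
from .integrals import eri_2center, eri_3center
from .scf import SCFResult, assemble_eri

DEGENERACY_THRESHOLD = 1e-8


class DegeneracyError(ArithmeticError):
    """A near-zero MP2 denominator; perturbation theory breaks down."""


class RIConditioningError(np.linalg.LinAlgError):
    """Auxiliary Coulomb metric too ill-conditioned to invert."""


@dataclass(frozen=True)
class EnergyComponents:
    """The (E0, E_OS, E_SS) triple the scaled-energy model operates on."""

    E0: float
    E_OS: float
    E_SS: float
    method_tag: str = "canonical"

    def __post_init__(self) -> None:
        for name in ("E0", "E_OS", "E_SS"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @property
    def correlation(self) -> float:
        return self.E_OS + self.E_SS

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            self.E0 + other.E0, self.E_OS + other.E_OS, self.E_SS + other.E_SS,
            method_tag=self.method_tag,
        )

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            self.E0 - other.E0, self.E_OS - other.E_OS, self.E_SS - other.E_SS,
            method_tag=self.method_tag,
        )


def _correlation_window(scf: SCFResult, frozen_core: bool):
    n_frozen = n_core_orbitals(scf.molecule) if frozen_core else 0
    occ = slice(n_frozen, scf.n_occ)
    virt = slice(scf.n_occ, scf.n_mo)
    if scf.n_mo == scf.n_occ:
        raise ValueError("no virtual orbitals; MP2 undefined")
    if scf.n_occ - n_frozen < 1:
        raise ValueError("frozen core leaves no correlated occupied orbitals")
    return n_frozen, occ, virt


def _spin_components_from_ovov(ovov: np.ndarray, eps_o: np.ndarray, eps_v: np.ndarray):
    denom = (
        eps_o[:, None, None, None]
        + eps_o[None, None, :, None]
        - eps_v[None, :, None, None]
        - eps_v[None, None, None, :]
    )
    if np.any(np.abs(denom) < DEGENERACY_THRESHOLD):
        raise DegeneracyError(
            f"MP2 denominator below {DEGENERACY_THRESHOLD:g} hartree; "
            "near-degenerate reference"
        )
    exch = ovov.transpose(0, 3, 2, 1)  # (ib|ja)
    e_os = float(np.sum(ovov * ovov / denom))
    e_ss = float(np.sum(ovov * (ovov - exch) / denom))
    return e_os, e_ss


def mp2_components_canonical(scf: SCFResult, frozen_core: bool = True) -> EnergyComponents:
    """Canonical (exact four-index) spin-component MP2."""
    _, occ, virt = _correlation_window(scf, frozen_core)
    C = scf.mo_coefficients
    eri_ao = assemble_eri(scf.shells)
    Co, Cv = C[:, occ], C[:, virt]
    ovov = np.einsum(
        "pqrs,pi,qa,rj,sb->iajb", eri_ao, Co, Cv, Co, Cv, optimize=True
    )
    e_os, e_ss = _spin_components_from_ovov(
        ovov, scf.orbital_energies[occ], scf.orbital_energies[virt]
    )
    return EnergyComponents(scf.E0, e_os, e_ss, method_tag="canonical")


def ri_b_tensor(scf: SCFResult, basis: BasisSpec, frozen_core: bool = True):
    """Fitted three-index factors B_ia^P with (ia|jb) ~= B_ia . B_jb."""
    if not basis.aux_basis_corr:
        raise ValueError("RI-MP2 requires BasisSpec.aux_basis_corr")
    _, occ, virt = _correlation_window(scf, frozen_core)
    aux_shells = build_shells(
        scf.molecule, basis.aux_basis_corr, orbital_basis=basis.orbital_basis
    )
    orb_shells = scf.shells
    nbf = sum(sh.n_components for sh in orb_shells)
    naux = sum(sh.n_components for sh in aux_shells)
    offs = np.cumsum([0] + [sh.n_components for sh in orb_shells])
    aoffs = np.cumsum([0] + [sh.n_components for sh in aux_shells])

    three = np.empty((nbf, nbf, naux))
    for i, sa in enumerate(orb_shells):
        for j, sb in enumerate(orb_shells):
            if j < i:
                continue
            for k, sp in enumerate(aux_shells):
                block = eri_3center(sa, sb, sp)
                three[offs[i]:offs[i + 1], offs[j]:offs[j + 1], aoffs[k]:aoffs[k + 1]] = block
                if j > i:
                    three[offs[j]:offs[j + 1], offs[i]:offs[i + 1], aoffs[k]:aoffs[k + 1]] = (
                        block.transpose(1, 0, 2)
                    )
    metric = np.empty((naux, naux))
    for k, sp in enumerate(aux_shells):
        for l, sq in enumerate(aux_shells):
            if l < k:
                continue
            block = eri_2center(sp, sq)
            metric[aoffs[k]:aoffs[k + 1], aoffs[l]:aoffs[l + 1]] = block
            if l > k:
                metric[aoffs[l]:aoffs[l + 1], aoffs[k]:aoffs[k + 1]] = block.T

    sval, svec = np.linalg.eigh(metric)
    smax = float(sval.max())
    keep = sval > 1e-10 * smax
    if not np.any(keep):
        raise RIConditioningError(
            f"auxiliary metric singular (condition number {smax / abs(sval.min()):.3e})"
        )
    jm12 = svec[:, keep] / np.sqrt(sval[keep])

    C = scf.mo_coefficients
    Co, Cv = C[:, occ], C[:, virt]
    iap = np.einsum("pqP,pi,qa->iaP", three, Co, Cv, optimize=True)
    return np.einsum("iaP,PQ->iaQ", iap, jm12, optimize=True)


def mp2_components_ri(scf: SCFResult, basis: BasisSpec) -> EnergyComponents:
    """Density-fitted (RI) spin-component MP2."""
    B = ri_b_tensor(scf, basis, basis.frozen_core)
    _, occ, virt = _correlation_window(scf, basis.frozen_core)
    ovov = np.einsum("iaP,jbP->iajb", B, B, optimize=True)
    e_os, e_ss = _spin_components_from_ovov(
        ovov, scf.orbital_energies[occ], scf.orbital_energies[virt]
    )
    return EnergyComponents(scf.E0, e_os, e_ss, method_tag="ri")


ORACLE_MAX_SPIN_ORBITALS = 30


def mp2_components_spinorbital_oracle(
    scf: SCFResult, frozen_core: bool = True
) -> EnergyComponents:
    """Brute-force spin-orbital MP2, classifying each occupied pair by spin.

    Builds the full antisymmetrized spin-orbital integral tensor and sums
    E(2) = 1/4 sum |<ij||ab>|^2 / D pair by pair.  Exponential in nothing
    but brutally O(N^8) in memory/time, hence the hard size guard; this
    exists to validate the spatial-orbital fast path, not to be used.
    """
    n_frozen, occ, virt = _correlation_window(scf, frozen_core)
    n_act = scf.n_mo - n_frozen
    if 2 * n_act > ORACLE_MAX_SPIN_ORBITALS:
        raise ValueError(
            f"oracle limited to {ORACLE_MAX_SPIN_ORBITALS} spin orbitals, got {2 * n_act}"
        )
    C = scf.mo_coefficients[:, n_frozen:]
    eps = scf.orbital_energies[n_frozen:]
    eri_ao = assemble_eri(scf.shells)
    mo_eri = np.einsum(
        "pqrs,pi,qj,rk,sl->ijkl", eri_ao, C, C, C, C, optimize=True
    )  # chemists' (ij|kl)

    nso = 2 * n_act
    so_spatial = np.arange(nso) // 2
    so_spin = np.arange(nso) % 2
    eps_so = eps[so_spatial]
    n_occ_so = 2 * (scf.n_occ - n_frozen)

    # physicists' <pq|rs> = (pr|qs) * spin deltas; antisymmetrize
    spat = so_spatial
    spin = so_spin
    dpr = (spin[:, None] == spin[None, :]).astype(float)
    phys = (
        mo_eri[np.ix_(spat, spat, spat, spat)].transpose(0, 2, 1, 3)
        * dpr[:, None, :, None]  # delta(spin_p, spin_r)
        * dpr[None, :, None, :]  # delta(spin_q, spin_s)
    )
    anti = phys - phys.transpose(0, 1, 3, 2)

    e_os = 0.0
    e_ss = 0.0
    total_check = 0.0
    for i in range(n_occ_so):
        for j in range(n_occ_so):
            same = spin[i] == spin[j]
            for a in range(n_occ_so, nso):
                for b in range(n_occ_so, nso):
                    d = eps_so[i] + eps_so[j] - eps_so[a] - eps_so[b]
                    term = 0.25 * anti[i, j, a, b] ** 2 / d
                    total_check += term
                    if same:
                        e_ss += term
                    else:
                        e_os += term
    assert abs(total_check - (e_os + e_ss)) < 1e-12
    return EnergyComponents(scf.E0, float(e_os), float(e_ss), method_tag="oracle")
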