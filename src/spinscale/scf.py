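"""Restricted Hartree-Fock for closed-shell molecules.

Core-Hamiltonian guess, DIIS acceleration, canonical orthogonalization
(near-linear-dependent combinations are projected out, which matters for
counterpoise runs where ghost basis functions overlap the real ones).
Ghost atoms contribute basis functions but neither electrons nor nuclear
charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec, build_shells
from .chem_model import Molecule
from .constants import ANGSTROM_TO_BOHR
from .integrals import (
    Shell,
    eri_shell_quartet,
    nuclear_attraction_shells,
    overlap_kinetic_shells,
)


class SCFConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class SCFSettings:
    max_iterations: int = 200
    energy_tol: float = 1e-10
    density_tol: float = 1e-8
    lindep_tol: float = 1e-10


@dataclass
class SCFResult:
    """Converged RHF solution: total energy, canonical MOs and occupancy."""

    E0: float
    orbital_energies: np.ndarray
    mo_coefficients: np.ndarray  # AO x MO
    n_occ: int
    converged: bool
    molecule: Molecule = None
    shells: list[Shell] = field(default_factory=list)
    basis: BasisSpec = None
    nuclear_repulsion: float = 0.0

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def n_virtual(self) -> int:
        return self.n_mo - self.n_occ


def _assemble_one_electron(shells: list[Shell], charges, centers):
    nbf = sum(sh.n_components for sh in shells)
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    offs = np.cumsum([0] + [sh.n_components for sh in shells])
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j < i:
                continue
            s, t = overlap_kinetic_shells(sa, sb)
            v = nuclear_attraction_shells(sa, sb, charges, centers)
            sl = (slice(offs[i], offs[i + 1]), slice(offs[j], offs[j + 1]))
            S[sl], T[sl], V[sl] = s, t, v
            if j > i:
                S[sl[1], sl[0]] = s.T
                T[sl[1], sl[0]] = t.T
                V[sl[1], sl[0]] = v.T
    return S, T, V


def assemble_eri(shells: list[Shell]) -> np.ndarray:
    """Full (μν|λσ) tensor.  Fine for the small fixtures this engine targets."""
    nbf = sum(sh.n_components for sh in shells)
    offs = np.cumsum([0] + [sh.n_components for sh in shells])
    eri = np.empty((nbf, nbf, nbf, nbf))
    npairs = len(shells)
    for i in range(npairs):
        for j in range(i + 1):
            for k in range(npairs):
                for l in range(k + 1):
                    if (k, l) > (i, j):
                        continue
                    block = eri_shell_quartet(shells[i], shells[j], shells[k], shells[l])
                    si = slice(offs[i], offs[i + 1])
                    sj = slice(offs[j], offs[j + 1])
                    sk = slice(offs[k], offs[k + 1])
                    sl = slice(offs[l], offs[l + 1])
                    eri[si, sj, sk, sl] = block
                    eri[sj, si, sk, sl] = block.transpose(1, 0, 2, 3)
                    eri[si, sj, sl, sk] = block.transpose(0, 1, 3, 2)
                    eri[sj, si, sl, sk] = block.transpose(1, 0, 3, 2)
                    eri[sk, sl, si, sj] = block.transpose(2, 3, 0, 1)
                    eri[sl, sk, si, sj] = block.transpose(3, 2, 0, 1)
                    eri[sk, sl, sj, si] = block.transpose(2, 3, 1, 0)
                    eri[sl, sk, sj, si] = block.transpose(3, 2, 1, 0)
    return eri


def nuclear_repulsion(mol: Molecule) -> float:
    """Point-charge repulsion in hartree; ghosts carry no charge."""
    atoms = [a for a in mol.atoms if not a.ghost]
    e = 0.0
    for i in range(len(atoms)):
        for j in range(i):
            rij = (
                np.linalg.norm(
                    np.asarray(atoms[i].position) - np.asarray(atoms[j].position)
                )
                * ANGSTROM_TO_BOHR
            )
            e += atoms[i].atomic_number * atoms[j].atomic_number / rij
    return e


def compute_scf(
    mol: Molecule, basis: BasisSpec, settings: SCFSettings | None = None
) -> SCFResult:
    """Solve restricted Hartree-Fock for a closed-shell molecule."""
    settings = settings or SCFSettings()
    if mol.multiplicity != 1:
        raise ValueError(
            f"built-in engine is closed-shell only (multiplicity 1), got {mol.multiplicity}"
        )
    nelec = mol.n_electrons
    if nelec % 2 != 0 or nelec <= 0:
        raise ValueError(f"closed-shell RHF needs a positive even electron count, got {nelec}")
    n_occ = nelec // 2

    shells = build_shells(mol, basis.orbital_basis)
    charges = [a.atomic_number for a in mol.atoms if not a.ghost]
    centers = [np.asarray(a.position) * ANGSTROM_TO_BOHR for a in mol.atoms if not a.ghost]
    S, T, V = _assemble_one_electron(shells, charges, centers)
    hcore = T + V
    eri = assemble_eri(shells)
    enuc = nuclear_repulsion(mol)

    # canonical orthogonalization
    sval, svec = np.linalg.eigh(S)
    keep = sval > settings.lindep_tol * sval.max()
    X = svec[:, keep] / np.sqrt(sval[keep])

    def fock(D):
        J = np.einsum("pqrs,rs->pq", eri, D)
        K = np.einsum("prqs,rs->pq", eri, D)
        return hcore + J - 0.5 * K

    def diag(F):
        Fp = X.T @ F @ X
        eps, Cp = np.linalg.eigh(Fp)
        return eps, X @ Cp

    eps, C = diag(hcore)
    D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    e_old = 0.0
    trace: list[float] = []
    diis_F: list[np.ndarray] = []
    diis_err: list[np.ndarray] = []
    converged = False
    for _ in range(settings.max_iterations):
        F = fock(D)
        err = F @ D @ S - S @ D @ F
        diis_F.append(F)
        diis_err.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.vdot(diis_err[i], diis_err[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            # lstsq: the error-overlap system turns singular near convergence
            w = np.linalg.lstsq(B, rhs, rcond=1e-14)[0][:m]
            if abs(w.sum() - 1.0) < 0.1:
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
        eps, C = diag(F)
        D_new = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        e_elec = 0.5 * np.einsum("pq,pq->", D_new, hcore + fock(D_new))
        e_tot = e_elec + enuc
        trace.append(float(e_tot))
        d_rms = np.sqrt(np.mean((D_new - D) ** 2))
        if abs(e_tot - e_old) < settings.energy_tol and d_rms < settings.density_tol:
            converged = True
            D = D_new
            break
        D, e_old = D_new, e_tot
    if not converged:
        raise SCFConvergenceError(
            f"SCF failed to converge in {settings.max_iterations} iterations", trace
        )
    if C.shape[1] < n_occ:
        raise RuntimeError("linear dependence removed too many orbitals")
    # canonical orbitals of the *unextrapolated* Fock at the converged density
    eps, C = diag(fock(D))
    return SCFResult(
        E0=float(e_tot),
        orbital_energies=eps,
        mo_coefficients=C,
        n_occ=n_occ,
        converged=True,
        molecule=mol,
        shells=shells,
        basis=basis,
        nuclear_repulsion=enuc,
    )
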