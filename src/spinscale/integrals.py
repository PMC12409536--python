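"""Gaussian integrals over contracted Cartesian shells.

McMurchie–Davidson scheme: charge distributions of primitive pairs are
expanded in Hermite Gaussians (coefficients ``E``), and Coulomb kernels
between Hermite Gaussians reduce to the Boys function through the
``R_tuv`` auxiliary integrals.  One machinery serves overlap, kinetic,
nuclear-attraction and two-/three-/four-center repulsion integrals; the
three- and two-center variants back the RI (density-fitting) correlation
step.

Everything here works in atomic units (bohr, hartree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaln


def boys(nmax: int, x: float) -> np.ndarray:
    """Boys function F_n(x) for n = 0..nmax (downward recursion)."""
    out = np.empty(nmax + 1)
    if x < 1e-7:
        # short Taylor series; exact at x = 0
        for n in range(nmax + 1):
            out[n] = (
                1.0 / (2 * n + 1)
                - x / (2 * n + 3)
                + x * x / (2 * (2 * n + 5))
                - x**3 / (6 * (2 * n + 7))
            )
        return out
    a = nmax + 0.5
    # F_n(x) = Γ(n+1/2) γreg(n+1/2, x) / (2 x^(n+1/2))
    out[nmax] = np.exp(gammaln(a)) * gammainc(a, x) / (2.0 * x**a)
    ex = np.exp(-x)
    for n in range(nmax, 0, -1):
        out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)
    return out


def hermite_expansion(la: int, lb: int, a: float, b: float, ab: float) -> np.ndarray:
    """E[i, j, t] coefficients for one Cartesian direction.

    ``ab`` is A_x - B_x.  Includes the Gaussian-product prefactor
    exp(-a b/(a+b) ab^2); valid for b = 0 (single-Gaussian expansion).
    """
    p = a + b
    mu = a * b / p
    E = np.zeros((la + 1, lb + 1, la + lb + 1))
    E[0, 0, 0] = np.exp(-mu * ab * ab)
    pa = -(b / p) * ab  # X_PA = P_x - A_x
    pb = (a / p) * ab  # X_PB = P_x - B_x
    one_2p = 1.0 / (2.0 * p)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                src = E[i - 1, 0]
                x = pa
            else:
                src = E[i, j - 1]
                x = pb
            for t in range(i + j + 1):
                val = x * src[t]
                if t > 0:
                    val += one_2p * src[t - 1]
                if t + 1 <= i + j - 1:
                    val += (t + 1) * src[t + 1]
                E[i, j, t] = val
    return E


def hermite_coulomb(L: int, p: float, pc: np.ndarray, T: float) -> np.ndarray:
    """R[t, u, v] Hermite Coulomb integrals with t+u+v <= L."""
    F = boys(L, T)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))  # [n, t, u, v]
    for n in range(L + 1):
        R[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for total in range(1, L + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                v = total - t - u
                # raise the first nonzero index
                if t > 0:
                    for n in range(L - total + 1):
                        val = pc[0] * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                        R[n, t, u, v] = val
                elif u > 0:
                    for n in range(L - total + 1):
                        val = pc[1] * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                        R[n, t, u, v] = val
                else:
                    for n in range(L - total + 1):
                        val = pc[2] * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                        R[n, t, u, v] = val
    return R[0]


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian powers (lx, ly, lz) with lx+ly+lz = l, canonical order."""
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def primitive_norm(a: float, lx: int, ly: int, lz: int) -> float:
    l = lx + ly + lz
    dd = double_factorial(2 * lx - 1) * double_factorial(2 * ly - 1) * double_factorial(2 * lz - 1)
    return (2.0 * a / np.pi) ** 0.75 * (4.0 * a) ** (l / 2.0) / np.sqrt(dd)


@dataclass
class Shell:
    """A contracted Cartesian shell on one center.

    ``coefs`` are contraction coefficients including primitive and
    contracted normalization for the (l,0,0) component; ``comp_scale``
    carries the per-component renormalization ratio.
    """

    l: int
    center: np.ndarray  # bohr
    exps: np.ndarray
    coefs: np.ndarray
    atom_index: int = -1

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.components = cartesian_components(self.l)
        dfl = double_factorial(2 * self.l - 1)
        self.comp_scale = np.array(
            [
                np.sqrt(
                    dfl
                    / (
                        double_factorial(2 * lx - 1)
                        * double_factorial(2 * ly - 1)
                        * double_factorial(2 * lz - 1)
                    )
                )
                for lx, ly, lz in self.components
            ]
        )

    @property
    def n_components(self) -> int:
        return len(self.components)

    @classmethod
    def contracted(cls, l: int, center, exps, raw_coefs, atom_index: int = -1) -> "Shell":
        """Build a normalized contracted shell from raw contraction coefficients."""
        exps = np.asarray(exps, dtype=float)
        raw = np.asarray(raw_coefs, dtype=float)
        c = raw * np.array([primitive_norm(a, l, 0, 0) for a in exps])
        # contracted self-overlap of the (l,0,0) component
        pmat = exps[:, None] + exps[None, :]
        s = (np.pi / pmat) ** 1.5 * double_factorial(2 * l - 1) / (2.0 * pmat) ** l
        norm = (c @ s @ c) ** -0.5
        return cls(l=l, center=center, exps=exps, coefs=c * norm, atom_index=atom_index)


def _unit_shell(center) -> Shell:
    """Zero-exponent s 'shell' representing the constant 1 (for 2c/3c ERIs)."""
    sh = Shell.__new__(Shell)
    sh.l = 0
    sh.center = np.asarray(center, dtype=float)
    sh.exps = np.array([0.0])
    sh.coefs = np.array([1.0])
    sh.atom_index = -1
    sh.components = [(0, 0, 0)]
    sh.comp_scale = np.array([1.0])
    return sh


def _pair_hermite(sha: Shell, shb: Shell):
    """Per primitive pair: (p, P, E3) with E3[comp_a, comp_b, t, u, v]."""
    AB = sha.center - shb.center
    la, lb = sha.l, shb.l
    out = []
    for ka, a in enumerate(sha.exps):
        for kb, b in enumerate(shb.exps):
            p = a + b
            P = (a * sha.center + b * shb.center) / p
            Ex = hermite_expansion(la, lb, a, b, AB[0])
            Ey = hermite_expansion(la, lb, a, b, AB[1])
            Ez = hermite_expansion(la, lb, a, b, AB[2])
            cc = sha.coefs[ka] * shb.coefs[kb]
            E3 = np.zeros((sha.n_components, shb.n_components, la + lb + 1, la + lb + 1, la + lb + 1))
            for ia, (ax, ay, az) in enumerate(sha.components):
                for ib, (bx, by, bz) in enumerate(shb.components):
                    E3[ia, ib] = cc * np.einsum(
                        "t,u,v->tuv", Ex[ax, bx], Ey[ay, by], Ez[az, bz]
                    )
            out.append((p, P, E3))
    return out


def overlap_kinetic_shells(sha: Shell, shb: Shell):
    """Overlap and kinetic blocks between two shells."""
    la, lb = sha.l, shb.l
    AB = sha.center - shb.center
    S = np.zeros((sha.n_components, shb.n_components))
    T = np.zeros_like(S)
    for ka, a in enumerate(sha.exps):
        for kb, b in enumerate(shb.exps):
            p = a + b
            # direction-resolved overlaps up to lb+2 for the kinetic part
            Ex = hermite_expansion(la, lb + 2, a, b, AB[0])
            Ey = hermite_expansion(la, lb + 2, a, b, AB[1])
            Ez = hermite_expansion(la, lb + 2, a, b, AB[2])
            fac = (np.pi / p) ** 0.5
            cc = sha.coefs[ka] * shb.coefs[kb]

            def s1(E, i, j):
                return E[i, j, 0] * fac

            for ia, (ax, ay, az) in enumerate(sha.components):
                for ib, (bx, by, bz) in enumerate(shb.components):
                    sx, sy, sz = s1(Ex, ax, bx), s1(Ey, ay, by), s1(Ez, az, bz)
                    S[ia, ib] += cc * sx * sy * sz

                    def tk(E, i, j):
                        val = b * (2 * j + 1) * s1(E, i, j) - 2.0 * b * b * s1(E, i, j + 2)
                        if j >= 2:
                            val -= 0.5 * j * (j - 1) * s1(E, i, j - 2)
                        return val

                    T[ia, ib] += cc * (
                        tk(Ex, ax, bx) * sy * sz
                        + sx * tk(Ey, ay, by) * sz
                        + sx * sy * tk(Ez, az, bz)
                    )
    S *= sha.comp_scale[:, None] * shb.comp_scale[None, :]
    T *= sha.comp_scale[:, None] * shb.comp_scale[None, :]
    return S, T


def nuclear_attraction_shells(sha: Shell, shb: Shell, charges, centers) -> np.ndarray:
    """Nuclear-attraction block -sum_C Z_C <a|1/r_C|b>."""
    la, lb = sha.l, shb.l
    L = la + lb
    V = np.zeros((sha.n_components, shb.n_components))
    for p, P, E3 in _pair_hermite(sha, shb):
        for Z, C in zip(charges, centers):
            pc = P - C
            T = p * float(pc @ pc)
            R = hermite_coulomb(L, p, pc, T)
            V -= Z * (2.0 * np.pi / p) * np.einsum("abtuv,tuv->ab", E3, R[: L + 1, : L + 1, : L + 1])
    return V * (sha.comp_scale[:, None] * shb.comp_scale[None, :])


def eri_shell_quartet(sa: Shell, sb: Shell, sc: Shell, sd: Shell) -> np.ndarray:
    """(ab|cd) block in chemists' notation, shape (na, nb, nc, nd)."""
    Lb = sa.l + sb.l
    Lk = sc.l + sd.l
    L = Lb + Lk
    bra = _pair_hermite(sa, sb)
    ket = _pair_hermite(sc, sd)
    out = np.zeros((sa.n_components, sb.n_components, sc.n_components, sd.n_components))
    # (-1)^(t+u+v) parity for the ket Hermite indices
    sign = np.fromfunction(
        lambda t, u, v: (-1.0) ** (t + u + v), (Lk + 1, Lk + 1, Lk + 1)
    )
    for p, P, Eb in bra:
        for q, Q, Ek in ket:
            alpha = p * q / (p + q)
            pq = P - Q
            T = alpha * float(pq @ pq)
            R = hermite_coulomb(L, alpha, pq, T)
            pref = 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))
            Eks = Ek * sign[None, None]
            # fold R over the ket indices: K[c,d,t,u,v]
            K = np.zeros((sc.n_components, sd.n_components, Lb + 1, Lb + 1, Lb + 1))
            for tt in range(Lk + 1):
                for uu in range(Lk + 1 - tt):
                    for vv in range(Lk + 1 - tt - uu):
                        K += (
                            Eks[:, :, tt, uu, vv][:, :, None, None, None]
                            * R[tt : tt + Lb + 1, uu : uu + Lb + 1, vv : vv + Lb + 1]
                        )
            out += pref * np.einsum("abtuv,cdtuv->abcd", Eb, K)
    scale = (
        sa.comp_scale[:, None, None, None]
        * sb.comp_scale[None, :, None, None]
        * sc.comp_scale[None, None, :, None]
        * sd.comp_scale[None, None, None, :]
    )
    return out * scale


def eri_3center(sa: Shell, sb: Shell, sp: Shell) -> np.ndarray:
    """(ab|P) with a unit dummy ket partner, shape (na, nb, nP)."""
    unit = _unit_shell(sp.center)
    return eri_shell_quartet(sa, sb, sp, unit)[:, :, :, 0]


def eri_2center(sp: Shell, sq: Shell) -> np.ndarray:
    """(P|Q) Coulomb metric block."""
    unit_p = _unit_shell(sp.center)
    unit_q = _unit_shell(sq.center)
    return eri_shell_quartet(sp, unit_p, sq, unit_q)[:, 0, :, 0]
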