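"""Dissociation curves over rigidly scaled intermolecular separations.

The equilibrium center-of-mass separation of a dimer is multiplied by a
ladder of factors (hydrogen-bonded preset 0.90-2.00; stacked-aromatic
preset 0.70-2.00, which also samples the short-range repulsive wall);
monomers stay internally rigid.  Because monomer internal energies are
factor-independent they are computed once per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisSpec
from .chem_model import DimerSystem, scale_separation
from .constants import HARTREE_TO_KCALMOL
from .mp2 import EnergyComponents
from .scaling import ScalingCoefficients, scaled_energy
from .scf import SCFConvergenceError, SCFSettings
from .supermolecule import compute_components

FACTOR_PRESETS = {"hbond": (0.90, 2.00), "stacked": (0.70, 2.00)}


def default_factors(kind: str = "hbond", step: float = 0.10) -> tuple[float, ...]:
    """The preset factor ladder, endpoints included exactly."""
    if kind not in FACTOR_PRESETS:
        raise ValueError(f"unknown scan preset {kind!r}; choose from {sorted(FACTOR_PRESETS)}")
    lo, hi = FACTOR_PRESETS[kind]
    n = int(round((hi - lo) / step))
    vals = [round(lo + i * step, 10) for i in range(n + 1)]
    if vals[-1] != hi:
        vals.append(hi)
    return tuple(vals)


@dataclass(frozen=True)
class ScanSpec:
    dimer: DimerSystem
    factors: tuple[float, ...]
    basis: BasisSpec
    coefficients: ScalingCoefficients
    settings: SCFSettings | None = None

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.factors)
        object.__setattr__(self, "factors", f)
        if not f:
            raise ValueError("factor list is empty")
        if any(x <= 0 for x in f):
            raise ValueError("all separation factors must be positive")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("factors must be strictly increasing")


@dataclass(frozen=True)
class ScanPoint:
    factor: float
    E_int: float | None  # kcal/mol; None for failed points
    dimer: EnergyComponents | None
    monomer1: EnergyComponents
    monomer2: EnergyComponents
    failed: bool = False


@dataclass
class ScanResult:
    points: list[ScanPoint]
    coefficients: ScalingCoefficients
    minimum_factor: float | None = None
    failures: list[float] = field(default_factory=list)

    def energies(self) -> np.ndarray:
        return np.array([p.E_int if p.E_int is not None else np.nan for p in self.points])

    def rescaled(self, c: ScalingCoefficients) -> np.ndarray:
        """Recombine the stored components under different coefficients —
        no recomputation needed, the curve is affine in (C_OS, C_SS)."""
        out = []
        for p in self.points:
            if p.failed:
                out.append(np.nan)
                continue
            e = (
                scaled_energy(p.dimer, c)
                - scaled_energy(p.monomer1, c)
                - scaled_energy(p.monomer2, c)
            )
            out.append(e * HARTREE_TO_KCALMOL)
        return np.array(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"factor": p.factor, "E_int_kcalmol": p.E_int, "failed": p.failed}
            for role, comp in (
                ("dimer", p.dimer), ("monomer1", p.monomer1), ("monomer2", p.monomer2)
            ):
                if comp is not None:
                    row[f"{role}_E0"] = comp.E0
                    row[f"{role}_EOS"] = comp.E_OS
                    row[f"{role}_ESS"] = comp.E_SS
            rows.append(row)
        return pd.DataFrame(rows)


def _interpolated_minimum(factors: np.ndarray, energies: np.ndarray) -> float | None:
    """Quadratic fit through the three lowest points; falls back to the
    grid minimum at the scan edge or on degenerate curvature."""
    ok = np.isfinite(energies)
    if ok.sum() < 3:
        return float(factors[ok][np.argmin(energies[ok])]) if ok.any() else None
    f, e = factors[ok], energies[ok]
    i = int(np.argmin(e))
    if i == 0 or i == len(f) - 1:
        return float(f[i])
    x = f[i - 1 : i + 2]
    y = e[i - 1 : i + 2]
    a, b, _ = np.polyfit(x, y, 2)
    if a <= 0:
        return float(f[i])
    return float(-b / (2 * a))


def scan(spec: ScanSpec) -> ScanResult:
    """Run the dissociation scan; SCF failures flag the point and the scan
    continues."""
    m1 = compute_components(spec.dimer.monomer(0), spec.basis, spec.settings)
    m2 = compute_components(spec.dimer.monomer(1), spec.basis, spec.settings)
    e_mono = scaled_energy(m1, spec.coefficients) + scaled_energy(m2, spec.coefficients)
    points: list[ScanPoint] = []
    failures: list[float] = []
    for f in spec.factors:
        geom = scale_separation(spec.dimer, f)
        try:
            d = compute_components(geom.geometry, spec.basis, spec.settings)
        except SCFConvergenceError:
            points.append(ScanPoint(f, None, None, m1, m2, failed=True))
            failures.append(f)
            continue
        e_int = (scaled_energy(d, spec.coefficients) - e_mono) * HARTREE_TO_KCALMOL
        points.append(ScanPoint(f, e_int, d, m1, m2))
    result = ScanResult(points, spec.coefficients, failures=failures)
    result.minimum_factor = _interpolated_minimum(
        np.array(spec.factors), result.energies()
    )
    return result
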