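"""Built-in toy geometries and a synthetic calibration-data generator.

The embedded molecules are independently constructed small systems with
textbook-ish bond lengths — convenient, converged-SCF fixtures, not
literature benchmark geometries.  The synthetic generator emulates the
*structure* of a weak-interaction calibration set: per-system component
deltas (dE0, dE_OS, dE_SS) with kcal-scale magnitudes and reference
energies from a planted linear model plus Gaussian noise.  It makes no
claim of physical realism; it exists so the calibration machinery can
be exercised and validated against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationDataset, CalibrationRecord
from .chem_model import Atom, DimerSystem, Molecule
from .scaling import ScalingCoefficients

def _mol(atom_specs, fragments=None) -> Molecule:
    atoms = tuple(Atom(sym, xyz) for sym, xyz in atom_specs)
    return Molecule(atoms, fragment_of=tuple(fragments) if fragments else ())


_MONOMERS = {
    "he": [("He", (0.0, 0.0, 0.0))],
    "ne": [("Ne", (0.0, 0.0, 0.0))],
    "h2": [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.74))],
    "hf": [("F", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.92))],
    "h2o": [
        ("O", (0.0, 0.0, 0.1173)),
        ("H", (0.0, 0.7572, -0.4692)),
        ("H", (0.0, -0.7572, -0.4692)),
    ],
    "nh3": [
        ("N", (0.0, 0.0, 0.0)),
        ("H", (0.9377, 0.0, -0.3816)),
        ("H", (-0.4689, 0.8121, -0.3816)),
        ("H", (-0.4689, -0.8121, -0.3816)),
    ],
}


class FixtureLookupError(KeyError):
    pass


def builtin_molecule(name: str, separation: float | None = None):
    """Fetch an embedded geometry by name.

    Monomers: he, ne, h2, hf, h2o, nh3.  Dimers (returned as
    :class:`DimerSystem`): he_he, ne_ne, h2o_h2o, hf_nh3; rare-gas pairs
    take an optional center-of-mass ``separation`` in Å (default 3.0).
    """
    key = name.strip().lower()
    if key in _MONOMERS:
        return _mol(_MONOMERS[key])
    if key in ("he_he", "ne_ne"):
        el = "He" if key == "he_he" else "Ne"
        d = 3.0 if separation is None else float(separation)
        if d <= 0:
            raise ValueError(f"separation must be positive, got {d}")
        geom = _mol(
            [(el, (0.0, 0.0, 0.0)), (el, (0.0, 0.0, d))], fragments=(0, 1)
        )
        return DimerSystem(geom, label=f"{key}@{d:g}")
    if key == "h2o_h2o":
        # near-linear hydrogen bond, O...O about 2.98 A; constructed
        donor = [
            ("O", (0.0, 0.0, 0.0)),
            ("H", (0.9572, 0.0, 0.0)),
            ("H", (-0.2399, 0.9272, 0.0)),
        ]
        acceptor = [
            ("O", (2.98, 0.0, 0.0)),
            ("H", (3.2727, 0.7553, -0.4692)),
            ("H", (3.2727, 0.7553, 0.4692)),
        ]
        geom = _mol(donor + acceptor, fragments=(0, 0, 0, 1, 1, 1))
        return DimerSystem(geom, label="h2o_h2o")
    if key == "hf_nh3":
        hf = [("F", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.92))]
        nh3 = [
            ("N", (0.0, 0.0, 2.65)),
            ("H", (0.9377, 0.0, 3.0316)),
            ("H", (-0.4689, 0.8121, 3.0316)),
            ("H", (-0.4689, -0.8121, 3.0316)),
        ]
        geom = _mol(hf + nh3, fragments=(0, 0, 1, 1, 1, 1))
        return DimerSystem(geom, label="hf_nh3")
    raise FixtureLookupError(
        f"unknown fixture {name!r}; monomers: {', '.join(sorted(_MONOMERS))}; "
        "dimers: he_he, ne_ne, h2o_h2o, hf_nh3"
    )


@dataclass(frozen=True)
class DeltaDistributions:
    """Sampling parameters for the component deltas, kcal/mol.

    dE0 is Gaussian (repulsive on average at equilibrium geometries);
    dE_OS and dE_SS are negative magnitudes (stabilizing correlation).
    Defaults are arbitrary test scaffolding at kcal-scale magnitudes.
    """

    dE0_mean: float = 2.0
    dE0_sd: float = 2.0
    dEOS_mag_mean: float = 3.0
    dEOS_mag_sd: float = 1.0
    dESS_mag_mean: float = 1.5
    dESS_mag_sd: float = 0.5

    def __post_init__(self) -> None:
        for f in ("dE0_sd", "dEOS_mag_sd", "dESS_mag_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class SynthSpec:
    n_systems: int
    true_coefficients: ScalingCoefficients
    noise_sd: float = 0.0
    deltas: DeltaDistributions = field(default_factory=DeltaDistributions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_systems < 1:
            raise ValueError("n_systems must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_calibration_dataset(spec: SynthSpec) -> CalibrationDataset:
    """Sample a dataset whose references obey the planted linear model
    E_ref = dE0 + C_OS*dE_OS + C_SS*dE_SS + N(0, noise_sd)."""
    rng = np.random.default_rng(spec.seed)
    d = spec.deltas
    n = spec.n_systems
    dE0 = rng.normal(d.dE0_mean, d.dE0_sd, n)
    dEOS = -np.abs(rng.normal(d.dEOS_mag_mean, d.dEOS_mag_sd, n))
    dESS = -np.abs(rng.normal(d.dESS_mag_mean, d.dESS_mag_sd, n))
    eps = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    c = spec.true_coefficients
    eref = dE0 + c.C_OS * dEOS + c.C_SS * dESS + eps
    return CalibrationDataset(
        tuple(
            CalibrationRecord(f"synth-{i:04d}", float(dE0[i]), float(dEOS[i]),
                              float(dESS[i]), float(eref[i]))
            for i in range(n)
        )
    )
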