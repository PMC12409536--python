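"""Geometry and fragment data model.

Molecules are ordered lists of atoms with an optional fragment assignment
(one integer per atom, contiguous from 0).  Coordinates are Å throughout
this module; the integral engine converts to bohr at its boundary.

Ghost atoms carry basis functions but no electrons or nuclear charge; they
are the mechanism behind counterpoise corrections.  In XYZ text a ghost
atom is written with an ``@`` prefix on the element symbol (``@He``), a
convention this package documents and round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASSES, ATOMIC_NUMBERS

GHOST_PREFIX = "@"


class XYZFormatError(ValueError):
    """Malformed XYZ text; the message names the offending line."""


class FragmentError(ValueError):
    """Fragment assignment missing, non-contiguous, or of the wrong shape."""


@dataclass(frozen=True)
class Atom:
    """A point nucleus (or ghost basis center) with a position in Å."""

    element: str
    position: tuple[float, float, float]
    ghost: bool = False

    def __post_init__(self) -> None:
        if self.element not in ATOMIC_NUMBERS:
            raise ValueError(f"unknown element symbol {self.element!r}")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for {self.element}")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))

    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBERS[self.element]

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass(frozen=True)
class Molecule:
    """An ordered collection of atoms with charge, spin multiplicity and
    per-atom fragment labels.

    All built-in workflows are closed-shell (multiplicity 1).  ``fragment_of``
    maps atom index -> fragment index; indices must be contiguous from 0.
    """

    atoms: tuple[Atom, ...]
    charge: int = 0
    multiplicity: int = 1
    fragment_of: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        object.__setattr__(self, "atoms", atoms)
        if not any(not a.ghost for a in atoms):
            raise ValueError("molecule must contain at least one non-ghost atom")
        frags = tuple(self.fragment_of) if self.fragment_of else tuple([0] * len(atoms))
        object.__setattr__(self, "fragment_of", frags)
        if len(frags) != len(atoms):
            raise FragmentError(
                f"fragment_of has {len(frags)} entries for {len(atoms)} atoms"
            )
        seen = sorted(set(frags))
        if seen != list(range(len(seen))):
            raise FragmentError(f"fragment indices not contiguous from 0: {seen}")

    @property
    def n_fragments(self) -> int:
        return max(self.fragment_of) + 1

    @property
    def n_electrons(self) -> int:
        return sum(a.atomic_number for a in self.atoms if not a.ghost) - self.charge

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def fragment_indices(self, k: int) -> list[int]:
        return [i for i, f in enumerate(self.fragment_of) if f == k]

    def fragment(self, k: int, ghost_rest: bool = False) -> "Molecule":
        """Extract fragment ``k`` as a standalone molecule.

        With ``ghost_rest`` the other fragments are retained as ghost
        centers (the counterpoise construction); atom order is preserved.
        """
        if k < 0 or k >= self.n_fragments:
            raise FragmentError(f"no fragment {k} in a {self.n_fragments}-fragment molecule")
        atoms = []
        for atom, f in zip(self.atoms, self.fragment_of):
            if f == k:
                atoms.append(atom)
            elif ghost_rest:
                atoms.append(replace(atom, ghost=True))
        return Molecule(tuple(atoms), charge=self.charge, multiplicity=self.multiplicity)

    def center_of_mass(self, fragment: int | None = None) -> np.ndarray:
        """Mass-weighted center (Å); ghosts are massless by construction."""
        idx = (
            range(len(self.atoms))
            if fragment is None
            else self.fragment_indices(fragment)
        )
        pts, masses = [], []
        for i in idx:
            if self.atoms[i].ghost:
                continue
            pts.append(self.atoms[i].position)
            masses.append(self.atoms[i].mass)
        m = np.asarray(masses)
        return (np.asarray(pts) * m[:, None]).sum(axis=0) / m.sum()

    def translated(self, shift, only_fragment: int | None = None) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        atoms = []
        for i, atom in enumerate(self.atoms):
            if only_fragment is None or self.fragment_of[i] == only_fragment:
                atoms.append(replace(atom, position=tuple(np.asarray(atom.position) + shift)))
            else:
                atoms.append(atom)
        return Molecule(tuple(atoms), self.charge, self.multiplicity, self.fragment_of)

    def with_fragments(self, ranges: list[tuple[int, int]]) -> "Molecule":
        """Assign fragments from 0-based inclusive atom-index ranges."""
        frags = [-1] * len(self.atoms)
        for k, (lo, hi) in enumerate(ranges):
            for i in range(lo, hi + 1):
                if i < 0 or i >= len(self.atoms):
                    raise FragmentError(f"atom index {i} out of range in fragment {k}")
                if frags[i] != -1:
                    raise FragmentError(f"atom {i} assigned to two fragments")
                frags[i] = k
        if -1 in frags:
            raise FragmentError(f"atom {frags.index(-1)} not covered by any fragment range")
        return Molecule(self.atoms, self.charge, self.multiplicity, tuple(frags))


@dataclass(frozen=True)
class DimerSystem:
    """A two-fragment complex; the unit of supermolecule interaction energies."""

    geometry: Molecule
    label: str = ""

    def __post_init__(self) -> None:
        if self.geometry.n_fragments != 2:
            raise FragmentError(
                f"DimerSystem needs exactly 2 fragments, got {self.geometry.n_fragments}"
            )
        for k in (0, 1):
            if not self.geometry.fragment_indices(k):
                raise FragmentError(f"fragment {k} is empty")

    def monomer(self, k: int, ghost_partner: bool = False) -> Molecule:
        return self.geometry.fragment(k, ghost_rest=ghost_partner)

    def separation(self) -> float:
        """Center-of-mass distance between the two fragments, Å."""
        return float(
            np.linalg.norm(
                self.geometry.center_of_mass(0) - self.geometry.center_of_mass(1)
            )
        )


def parse_fragment_ranges(specs: list[str]) -> list[tuple[int, int]]:
    """Parse CLI-style fragment specs like ``0-5`` (0-based inclusive)."""
    out = []
    for s in specs:
        lo, _, hi = s.partition("-")
        try:
            out.append((int(lo), int(hi if hi else lo)))
        except ValueError as exc:
            raise FragmentError(f"bad fragment range {s!r}") from exc
    return out


def read_xyz(text: str, charge: int = 0, multiplicity: int = 1) -> Molecule:
    """Parse XYZ-format text into a Molecule (coordinates in Å).

    Line 1 is the atom count, line 2 a free comment; each atom line is
    ``symbol x y z``.  ``@``-prefixed symbols mark ghost centers.  Fragment
    assignment is supplied separately (see :meth:`Molecule.with_fragments`).
    """
    lines = text.splitlines()
    if not lines:
        raise XYZFormatError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZFormatError(f"line 1: expected an atom count, got {lines[0]!r}") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise XYZFormatError(f"header declares {n} atoms but only {len(body)} atom lines found")
    atoms = []
    for lineno, ln in enumerate(body[:n], start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"line {lineno}: expected 'symbol x y z', got {ln!r}")
        sym = parts[0]
        ghost = sym.startswith(GHOST_PREFIX)
        if ghost:
            sym = sym[len(GHOST_PREFIX):]
        sym = sym.capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise XYZFormatError(f"line {lineno}: unknown element symbol {parts[0]!r}")
        try:
            xyz = tuple(float(p) for p in parts[1:4])
        except ValueError as exc:
            raise XYZFormatError(f"line {lineno}: unparseable coordinate in {ln!r}") from exc
        atoms.append(Atom(sym, xyz, ghost=ghost))
    return Molecule(tuple(atoms), charge=charge, multiplicity=multiplicity)


def write_xyz(mol: Molecule, comment: str = "") -> str:
    """Serialize to XYZ text (15 decimal places; lossless round-trip)."""
    lines = [str(len(mol.atoms)), comment]
    for atom in mol.atoms:
        sym = (GHOST_PREFIX + atom.element) if atom.ghost else atom.element
        x, y, z = atom.position
        lines.append(f"{sym:<4s} {x:20.15f} {y:20.15f} {z:20.15f}")
    return "\n".join(lines) + "\n"


def scale_separation(dimer: DimerSystem, factor: float) -> DimerSystem:
    """Rigidly scale the intermolecular separation of a dimer.

    Fragment 0 is held fixed; fragment 1 is translated along the
    center-of-mass vector so that the COM distance becomes ``factor``
    times its current value.  Monomer internal geometry is untouched.
    """
    if not factor > 0:
        raise ValueError(f"separation factor must be positive, got {factor}")
    mol = dimer.geometry
    com0 = mol.center_of_mass(0)
    com1 = mol.center_of_mass(1)
    shift = (factor - 1.0) * (com1 - com0)
    return DimerSystem(mol.translated(shift, only_fragment=1), label=dimer.label)
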