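"""Component-table I/O.

A component table is a plain CSV carrying per-system Hartree-Fock and
spin-component correlation energies that were computed elsewhere (any
program, any basis — e.g. grid-exchange accelerated SCF variants this
package does not implement), plus optional reference interaction
energies.  Schema:

    system_id, role, E0_hartree, EOS_hartree, ESS_hartree, Eref_kcalmol

``role`` is one of ``dimer``, ``monomer1``, ``monomer2`` or
``fragment:k`` (k >= 1); ``Eref_kcalmol`` may be non-empty only on
dimer/assembly rows.  Optional columns ``method_tag`` and ``basis`` are
recorded verbatim and never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mp2 import EnergyComponents

REQUIRED_COLUMNS = ["system_id", "role", "E0_hartree", "EOS_hartree", "ESS_hartree"]
_ROLES = {"dimer", "monomer1", "monomer2"}


class ComponentTableError(ValueError):
    """Schema violation; the message names the offending row or system."""


@dataclass(frozen=True)
class ComponentRow:
    system_id: str
    role: str
    components: EnergyComponents
    E_ref: float | None = None
    basis: str | None = None


def _check_role(role: str, row_label: str) -> None:
    if role in _ROLES:
        return
    if role.startswith("fragment:"):
        try:
            k = int(role.split(":", 1)[1])
        except ValueError:
            k = -1
        if k >= 1:
            return
    raise ComponentTableError(f"row {row_label}: unrecognized role {role!r}")


def load_component_table(path) -> list[ComponentRow]:
    """Read and validate a component-table CSV."""
    df = pd.read_csv(
        path, dtype={"system_id": str, "role": str}, float_precision="round_trip"
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ComponentTableError(f"missing required column(s): {', '.join(missing)}")
    rows: list[ComponentRow] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        label = f"{idx + 2}"  # 1-based with header
        sid, role = str(row["system_id"]), str(row["role"])
        _check_role(role, label)
        if (sid, role) in seen:
            raise ComponentTableError(f"row {label}: duplicate (system_id, role) = ({sid}, {role})")
        seen.add((sid, role))
        vals = {}
        for col in ("E0_hartree", "EOS_hartree", "ESS_hartree"):
            v = row[col]
            if not np.isfinite(pd.to_numeric(v, errors="coerce")):
                raise ComponentTableError(f"row {label}: non-numeric {col} = {v!r}")
            vals[col] = float(v)
        eref = None
        if "Eref_kcalmol" in df.columns and pd.notna(row["Eref_kcalmol"]):
            eref = float(pd.to_numeric(row["Eref_kcalmol"], errors="coerce"))
            if not np.isfinite(eref):
                raise ComponentTableError(f"row {label}: non-numeric Eref_kcalmol")
            if role.startswith("monomer") or role.startswith("fragment:"):
                raise ComponentTableError(
                    f"row {label}: Eref_kcalmol only allowed on dimer/assembly rows"
                )
        tag = str(row["method_tag"]) if "method_tag" in df.columns and pd.notna(row.get("method_tag")) else "external"
        rows.append(
            ComponentRow(
                system_id=sid,
                role=role,
                components=EnergyComponents(
                    vals["E0_hartree"], vals["EOS_hartree"], vals["ESS_hartree"], method_tag=tag
                ),
                E_ref=eref,
                basis=str(row["basis"]) if "basis" in df.columns and pd.notna(row.get("basis")) else None,
            )
        )
    return rows


def write_component_table(rows: list[ComponentRow], path) -> None:
    """Full-precision serialization (round-trips exactly through repr)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "system_id": r.system_id,
                "role": r.role,
                "E0_hartree": repr(r.components.E0),
                "EOS_hartree": repr(r.components.E_OS),
                "ESS_hartree": repr(r.components.E_SS),
                "Eref_kcalmol": "" if r.E_ref is None else repr(r.E_ref),
                "method_tag": r.components.method_tag,
                "basis": r.basis or "",
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def group_interaction_systems(rows: list[ComponentRow]):
    """Group rows into complete (dimer, monomer1, monomer2) triples.

    Returns ``{system_id: {role: ComponentRow}}``; raises naming every
    incomplete system.
    """
    by_sys: dict[str, dict[str, ComponentRow]] = {}
    for r in rows:
        by_sys.setdefault(r.system_id, {})[r.role] = r
    incomplete = [
        sid
        for sid, roles in by_sys.items()
        if not {"dimer", "monomer1", "monomer2"} <= set(roles)
    ]
    if incomplete:
        raise ComponentTableError(
            f"incomplete systems (need dimer+monomer1+monomer2): {', '.join(sorted(incomplete))}"
        )
    return by_sys
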