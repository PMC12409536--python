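"""Calibration of the spin-component scaling coefficients.

Because the scaled interaction energy is affine in (C_OS, C_SS),

    E_int(C) = dE0 + C_OS * dE_OS + C_SS * dE_SS    (all kcal/mol),

the mean absolute deviation from reference energies,

    MAD(C) = (1/n) sum_i | E_int,i(C) - E_ref,i |,

is a convex piecewise-linear surface over the coefficient plane.  Its
minimizer is found exactly by least-absolute-deviation linear
programming (scipy HiGHS); a dense grid scan of MAD / Max(MAD) / RMSD
over the plane reproduces the familiar heat-map view of the same
surface.  Optima frequently sit on the C_OS = 0 boundary and inside a
broad shallow valley, so the fit reports boundary activity and the
bounding box of the near-optimal set, and breaks exact ties by the
lexicographically smallest coefficient pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .scaling import ScalingCoefficients
from .supermolecule import InteractionRecord, interaction_energy

DEFAULT_BOUNDS = ((0.0, 2.5), (0.0, 2.5))
DEFAULT_GRID_STEP = 0.01
TIE_TOL = 1e-9
COLLINEARITY_COND = 1e10


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-system deltas (dimer minus monomers) and the reference energy."""

    system_id: str
    dE0: float
    dEOS: float
    dESS: float
    E_ref: float

    def __post_init__(self) -> None:
        for f in ("dE0", "dEOS", "dESS", "E_ref"):
            if not np.isfinite(getattr(self, f)):
                raise CalibrationError(f"{self.system_id}: non-finite {f}")

    def predict(self, c: ScalingCoefficients) -> float:
        return self.dE0 + c.C_OS * self.dEOS + c.C_SS * self.dESS


@dataclass(frozen=True)
class CalibrationDataset:
    records: tuple[CalibrationRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.system_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CalibrationError(f"duplicate system_id(s): {', '.join(dupes)}")

    @property
    def n(self) -> int:
        return len(self.records)

    def arrays(self):
        """(dE0, dEOS, dESS, E_ref) as float arrays."""
        r = self.records
        return (
            np.array([x.dE0 for x in r]),
            np.array([x.dEOS for x in r]),
            np.array([x.dESS for x in r]),
            np.array([x.E_ref for x in r]),
        )

    def predictions(self, c: ScalingCoefficients) -> np.ndarray:
        d0, dos, dss, _ = self.arrays()
        return d0 + c.C_OS * dos + c.C_SS * dss

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {"system_id": r.system_id, "dE0": repr(r.dE0), "dEOS": repr(r.dEOS),
                 "dESS": repr(r.dESS), "Eref": repr(r.E_ref)}
                for r in self.records
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        need = {"system_id", "dE0", "dEOS", "dESS", "Eref"}
        if not need <= set(df.columns):
            raise CalibrationError(f"delta CSV needs columns {sorted(need)}")
        return cls(
            tuple(
                CalibrationRecord(str(r.system_id), float(r.dE0), float(r.dEOS),
                                  float(r.dESS), float(r.Eref))
                for r in df.itertuples()
            )
        )


def assemble_dataset(records: list[InteractionRecord]) -> CalibrationDataset:
    """Precompute per-system component deltas in kcal/mol.

    After this step no quantum computation is needed during fitting:
    E_int(C) is reconstructed exactly from the three deltas.
    """
    from .constants import HARTREE_TO_KCALMOL

    missing = [r.system_id for r in records if r.E_ref is None]
    if missing:
        raise CalibrationError(f"records without E_ref: {', '.join(missing)}")
    out = []
    for r in records:
        d = r.dimer - r.monomer1 - r.monomer2
        out.append(
            CalibrationRecord(
                r.system_id,
                d.E0 * HARTREE_TO_KCALMOL,
                d.E_OS * HARTREE_TO_KCALMOL,
                d.E_SS * HARTREE_TO_KCALMOL,
                float(r.E_ref),
            )
        )
    return CalibrationDataset(tuple(out))


def metrics(predicted, reference) -> tuple[float, float, float]:
    """(MAD, Max(MAD), RMSD) of predicted vs reference, kcal/mol."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and reference must be equal-length non-empty vectors")
    d = np.abs(p - r)
    return float(d.mean()), float(d.max()), float(np.sqrt(np.mean(d * d)))


@dataclass
class FitResult:
    coefficients: ScalingCoefficients
    mad: float
    max_mad: float
    rmsd: float
    surface: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def grid_scan(
    ds: CalibrationDataset,
    cos_range: tuple[float, float] = (0.0, 2.5),
    css_range: tuple[float, float] = (0.0, 2.5),
    step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """All three metrics on a dense (C_OS, C_SS) grid, long format.

    Columns: C_OS, C_SS, mad, max_mad, rmsd — ready for heat-map plotting.
    """
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    for lo, hi in (cos_range, css_range):
        if not hi > lo:
            raise ValueError(f"degenerate range ({lo}, {hi})")
    cos_vals = np.arange(cos_range[0], cos_range[1] + step / 2, step)
    css_vals = np.arange(css_range[0], css_range[1] + step / 2, step)
    d0, dos, dss, ref = ds.arrays()
    base = d0 - ref
    frames = []
    for css in css_vals:  # chunk over one axis to bound memory
        resid = base[None, :] + np.outer(cos_vals, dos) + css * dss[None, :]
        a = np.abs(resid)
        frames.append(
            pd.DataFrame(
                {
                    "C_OS": cos_vals,
                    "C_SS": css,
                    "mad": a.mean(axis=1),
                    "max_mad": a.max(axis=1),
                    "rmsd": np.sqrt((a * a).mean(axis=1)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _polish_candidates(A, b, bounds, c_lp, n_lines: int = 16) -> np.ndarray:
    """Exact vertex candidates near an approximate LAD solution.

    Takes the lines of smallest |residual| at the LP point and intersects
    them pairwise, with every bound edge, and collects the box corners.
    """
    resid = np.abs(b + A @ c_lp)
    idx = np.argsort(resid)[: min(n_lines, len(b))]
    (c0_lo, c0_hi), (c1_lo, c1_hi) = bounds
    pts = [c_lp.copy()]
    for ii, i in enumerate(idx):
        ai, bi = A[i], -b[i]
        # line x bound edges
        for j, (lo, hi) in enumerate(bounds):
            other = 1 - j
            if abs(ai[other]) > 1e-14:
                for edge in (lo, hi):
                    val = (bi - ai[j] * edge) / ai[other]
                    pt = np.empty(2)
                    pt[j], pt[other] = edge, val
                    pts.append(pt)
        # line x line
        for k in idx[ii + 1 :]:
            M = np.array([ai, A[k]])
            det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
            if abs(det) > 1e-12 * max(1.0, np.abs(M).max() ** 2):
                pts.append(np.linalg.solve(M, np.array([bi, -b[k]])))
    pts.extend(
        np.array([x, y]) for x in (c0_lo, c0_hi) for y in (c1_lo, c1_hi)
    )
    cand = np.array(pts)
    inside = (
        (cand[:, 0] >= c0_lo - 1e-12) & (cand[:, 0] <= c0_hi + 1e-12)
        & (cand[:, 1] >= c1_lo - 1e-12) & (cand[:, 1] <= c1_hi + 1e-12)
    )
    cand = np.clip(
        cand[inside], [c0_lo, c1_lo], [c0_hi, c1_hi]
    )
    return cand


def _lad_lp(A, b, bounds, extra_A=None, extra_b=None, objective=None):
    """Shared LP core: minimize objective over (c, t) with |A c + b| <= t."""
    n = A.shape[0]
    A_ub = np.zeros((2 * n, 2 + n))
    A_ub[:n, :2] = A
    A_ub[:n, 2:] = -np.eye(n)
    A_ub[n:, :2] = -A
    A_ub[n:, 2:] = -np.eye(n)
    b_ub = np.concatenate([-b, b])
    if extra_A is not None:
        A_ub = np.vstack([A_ub, extra_A])
        b_ub = np.concatenate([b_ub, extra_b])
    if objective is None:
        objective = np.concatenate([[0.0, 0.0], np.full(n, 1.0 / n)])
    lp_bounds = [bounds[0], bounds[1]] + [(0, None)] * n
    res = linprog(objective, A_ub=A_ub, b_ub=b_ub, bounds=lp_bounds, method="highs")
    if not res.success:
        raise CalibrationError(f"LP solver failed: {res.message}")
    return res


def fit_coefficients(
    ds: CalibrationDataset,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    with_surface: bool = False,
    grid_step: float = DEFAULT_GRID_STEP,
) -> FitResult:
    """Minimize MAD over (C_OS, C_SS) by exact LAD linear programming.

    Ties on flat regions are broken toward the lexicographically smallest
    pair; diagnostics report collinearity of the delta columns, which
    bounds are active, and the bounding box of the near-optimal set
    (MAD within 1e-9 of the optimum).
    """
    if ds.n < 2:
        raise CalibrationError(f"need at least 2 records to fit, got {ds.n}")
    d0, dos, dss, ref = ds.arrays()
    A = np.column_stack([dos, dss])
    b = d0 - ref
    n = ds.n

    gram = A.T @ A
    sv = np.linalg.svd(gram, compute_uv=False)
    collinear = bool(sv[-1] <= 0 or sv[0] / max(sv[-1], 1e-300) > COLLINEARITY_COND)

    res = _lad_lp(A, b, bounds)
    mad_opt = float(res.fun)

    # Vertex polish: a bounded LAD optimum lies at an intersection of
    # zero-residual lines and/or active bounds, which the LP only hits to
    # solver tolerance.  Rebuild the nearby vertices exactly and keep the
    # best; near-ties resolve toward the lexicographically smallest pair.
    c_lp = np.array([res.x[0], res.x[1]])
    cand = _polish_candidates(A, b, bounds, c_lp)
    mads = np.abs(b[None, :] + cand @ A.T).mean(axis=1)
    best = mads.min()
    near = cand[mads <= best + TIE_TOL]
    c_best = near[np.lexsort((near[:, 1], near[:, 0]))][0]
    if best <= mad_opt + TIE_TOL:
        mad_opt = float(best)
        res.x[:2] = c_best

    cos_opt = float(np.clip(res.x[0], *bounds[0]))
    css_opt = float(np.clip(res.x[1], *bounds[1]))
    coeffs = ScalingCoefficients(cos_opt, css_opt)

    # bounding box of the near-optimal set
    mad_row = np.concatenate([[0.0, 0.0], np.full(n, 1.0 / n)])[None, :]
    cap = np.array([mad_opt + TIE_TOL])
    box = {}
    for j, name in ((0, "C_OS"), (1, "C_SS")):
        for sgn, side in ((1.0, "min"), (-1.0, "max")):
            obj = np.zeros(2 + n)
            obj[j] = sgn
            r = _lad_lp(A, b, bounds, extra_A=mad_row, extra_b=cap, objective=obj)
            box[f"{name}_{side}"] = float(sgn * r.fun)

    pred = ds.predictions(coeffs)
    mad, max_mad, rmsd = metrics(pred, ref)
    eps = 1e-9
    diagnostics = {
        "collinear": collinear,
        "boundary_active": {
            "C_OS_lower": abs(cos_opt - bounds[0][0]) < eps,
            "C_OS_upper": abs(cos_opt - bounds[0][1]) < eps,
            "C_SS_lower": abs(css_opt - bounds[1][0]) < eps,
            "C_SS_upper": abs(css_opt - bounds[1][1]) < eps,
        },
        "near_optimal_box": box,
        "lp_mad": mad_opt,
    }
    surface = (
        grid_scan(ds, (bounds[0][0], bounds[0][1]), (bounds[1][0], bounds[1][1]), grid_step)
        if with_surface
        else None
    )
    return FitResult(coeffs, mad, max_mad, rmsd, surface, diagnostics)
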