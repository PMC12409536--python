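"""Coefficient calibration: metrics, grid surfaces, LAD fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinscale import (
    BasisSpec,
    CalibrationDataset,
    CalibrationRecord,
    ScalingCoefficients,
    SynthSpec,
    assemble_dataset,
    builtin_molecule,
    compute_interaction_record,
    fit_coefficients,
    grid_scan,
    interaction_energy,
    metrics,
    preset,
    preset_names,
    synth_calibration_dataset,
)
from spinscale.calibration import CalibrationError
from spinscale.supermolecule import InteractionRecord
from spinscale.mp2 import EnergyComponents


def test_metrics_hand_arithmetic():
    mad, mx, rmsd = metrics([0.0, 1.0, -2.0], [0.0, 0.0, 0.0])
    assert (mad, mx) == (1.0, 2.0)
    assert rmsd == pytest.approx(np.sqrt(5.0 / 3.0), abs=1e-14)
    assert metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0, 0.0)
    assert metrics([0.5], [0.0]) == (0.5, 0.5, 0.5)


def test_metrics_domain_errors():
    with pytest.raises(ValueError):
        metrics([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        metrics([], [])


def test_assemble_dataset_identity():
    """E_int reconstructed from deltas equals the direct evaluation."""
    rng = np.random.default_rng(11)
    recs = []
    for i in range(6):
        d, m1, m2 = (EnergyComponents(*rng.normal(-1, 0.3, 3)) for _ in range(3))
        recs.append(InteractionRecord(f"s{i}", d, m1, m2, E_ref=float(rng.normal())))
    ds = assemble_dataset(recs)
    c = ScalingCoefficients(1.0, 1.0)
    for rec, cal in zip(recs, ds.records):
        assert cal.predict(c) == pytest.approx(
            interaction_energy(rec, c), abs=1e-10
        )


def test_assemble_dataset_engine_consistency():
    """Deltas built from a real engine run reproduce the pipeline E_int."""
    dim = builtin_molecule("he_he", 2.5)
    rec = compute_interaction_record(dim, BasisSpec("6-31g", frozen_core=False))
    rec = InteractionRecord(rec.system_id, rec.dimer, rec.monomer1, rec.monomer2, -0.02)
    ds = assemble_dataset([rec])
    for name in ("mp2", "scs", "bwi-dz"):
        c = preset(name)
        assert ds.records[0].predict(c) == pytest.approx(
            interaction_energy(rec, c), abs=1e-10
        )


def test_assemble_dataset_requires_references():
    d = EnergyComponents(-1.0, -0.1, -0.02)
    rec = InteractionRecord("noref", d, d, d)
    with pytest.raises(CalibrationError, match="noref"):
        assemble_dataset([rec])


def test_duplicate_system_ids_rejected():
    r = CalibrationRecord("dup", 1.0, -1.0, -0.5, 0.2)
    with pytest.raises(CalibrationError, match="dup"):
        CalibrationDataset((r, r))


def test_grid_identity_point_and_fit_refinement():
    ds = synth_calibration_dataset(
        SynthSpec(40, ScalingCoefficients(0.8, 1.1), 0.3, seed=21)
    )
    surface = grid_scan(ds, (0.0, 2.5), (0.0, 2.5), 0.05)
    at_11 = surface.loc[
        (np.isclose(surface.C_OS, 1.0)) & (np.isclose(surface.C_SS, 1.0))
    ].iloc[0]
    _, _, _, ref = ds.arrays()
    direct = metrics(ds.predictions(preset("mp2")), ref)
    assert at_11["mad"] == pytest.approx(direct[0], abs=1e-12)
    assert at_11["max_mad"] == pytest.approx(direct[1], abs=1e-12)
    assert at_11["rmsd"] == pytest.approx(direct[2], abs=1e-12)
    # the continuous optimum can only improve on the best grid cell
    fit = fit_coefficients(ds)
    assert surface["mad"].min() >= fit.mad - 1e-12


def test_grid_scan_degenerate_range_rejected():
    ds = synth_calibration_dataset(SynthSpec(5, ScalingCoefficients(1, 1), 0, seed=0))
    with pytest.raises(ValueError):
        grid_scan(ds, (1.0, 1.0), (0.0, 2.5), 0.1)
    with pytest.raises(ValueError):
        grid_scan(ds, (0.0, 2.5), (0.0, 2.5), -0.1)


@pytest.mark.parametrize("planted", [(0.0, 1.5), (1.2, 0.33)])
def test_noiseless_recovery_with_grid_oracle(planted):
    ds = synth_calibration_dataset(
        SynthSpec(60, ScalingCoefficients(*planted), 0.0, seed=7)
    )
    fit = fit_coefficients(ds)
    assert fit.coefficients.C_OS == pytest.approx(planted[0], abs=0.01)
    assert fit.coefficients.C_SS == pytest.approx(planted[1], abs=0.01)
    assert fit.mad <= 1e-8
    # independent dense-grid argmin lands in the same cell
    surface = grid_scan(ds, (0.0, 2.5), (0.0, 2.5), 0.01)
    best = surface.loc[surface["mad"].idxmin()]
    assert best["C_OS"] == pytest.approx(planted[0], abs=0.011)
    assert best["C_SS"] == pytest.approx(planted[1], abs=0.011)


def test_noisy_recovery_within_tolerance():
    ds = synth_calibration_dataset(
        SynthSpec(200, ScalingCoefficients(0.0, 1.5), 0.2, seed=42)
    )
    fit = fit_coefficients(ds)
    assert fit.coefficients.C_OS == pytest.approx(0.0, abs=0.05)
    assert fit.coefficients.C_SS == pytest.approx(1.5, abs=0.05)


def test_boundary_activity_reported():
    ds = synth_calibration_dataset(
        SynthSpec(80, ScalingCoefficients(0.0, 1.5), 0.0, seed=13)
    )
    fit = fit_coefficients(ds)
    assert fit.diagnostics["boundary_active"]["C_OS_lower"]
    assert not fit.diagnostics["boundary_active"]["C_SS_upper"]
    box = fit.diagnostics["near_optimal_box"]
    assert box["C_OS_min"] <= fit.coefficients.C_OS <= box["C_OS_max"] + 1e-9


def test_collinear_design_flagged_but_fit_returned():
    recs = tuple(
        CalibrationRecord(f"s{i}", float(i), -(i + 1.0), -2.0 * (i + 1.0), 0.5)
        for i in range(10)
    )
    fit = fit_coefficients(CalibrationDataset(recs))
    assert fit.diagnostics["collinear"]
    assert np.isfinite(fit.mad)


def test_small_dataset_rejected():
    ds = CalibrationDataset((CalibrationRecord("one", 1.0, -1.0, -0.5, 0.0),))
    with pytest.raises(CalibrationError, match="at least 2"):
        fit_coefficients(ds)


def test_fit_beats_every_preset():
    rng = np.random.default_rng(3)
    for trial in range(10):
        ds = synth_calibration_dataset(
            SynthSpec(
                30,
                ScalingCoefficients(rng.uniform(0, 2), rng.uniform(0, 2)),
                0.3,
                seed=500 + trial,
            )
        )
        fit = fit_coefficients(ds)
        _, _, _, ref = ds.arrays()
        for name in preset_names():
            assert fit.mad <= metrics(ds.predictions(preset(name)), ref)[0] + 1e-10


@settings(max_examples=40, deadline=None)
@given(
    st.integers(0, 10_000),
    st.floats(0, 2.5), st.floats(0, 2.5),
    st.floats(0, 2.5), st.floats(0, 2.5),
    st.floats(0, 1),
)
def test_mad_objective_is_convex(seed, a0, a1, b0, b1, t):
    ds = synth_calibration_dataset(
        SynthSpec(25, ScalingCoefficients(1.0, 1.0), 0.5, seed=seed)
    )
    _, _, _, ref = ds.arrays()

    def mad(cos, css):
        return metrics(ds.predictions(ScalingCoefficients(cos, css)), ref)[0]

    mid = (t * a0 + (1 - t) * b0, t * a1 + (1 - t) * b1)
    assert mad(*mid) <= t * mad(a0, a1) + (1 - t) * mad(b0, b1) + 1e-9


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.1, 50))
def test_scale_equivariance(seed, k):
    """Scaling all deltas and references by k > 0 keeps the argmin and
    scales every metric by k."""
    ds = synth_calibration_dataset(
        SynthSpec(30, ScalingCoefficients(0.7, 1.2), 0.25, seed=seed)
    )
    scaled = CalibrationDataset(
        tuple(
            CalibrationRecord(r.system_id, k * r.dE0, k * r.dEOS, k * r.dESS, k * r.E_ref)
            for r in ds.records
        )
    )
    f1, f2 = fit_coefficients(ds), fit_coefficients(scaled)
    assert f2.coefficients.C_OS == pytest.approx(f1.coefficients.C_OS, abs=1e-6)
    assert f2.coefficients.C_SS == pytest.approx(f1.coefficients.C_SS, abs=1e-6)
    assert f2.mad == pytest.approx(k * f1.mad, rel=1e-6, abs=1e-9)
    assert f2.rmsd == pytest.approx(k * f1.rmsd, rel=1e-6, abs=1e-9)


def test_csv_round_trip(tmp_path):
    ds = synth_calibration_dataset(SynthSpec(15, ScalingCoefficients(0, 1.5), 0.1, seed=2))
    p = tmp_path / "deltas.csv"
    ds.to_csv(p)
    back = CalibrationDataset.from_csv(p)
    for a, b in zip(ds.records, back.records):
        assert (a.dE0, a.dEOS, a.dESS, a.E_ref) == (b.dE0, b.dEOS, b.dESS, b.E_ref)
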