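"""Stopped-flow kinetics: exponential fits, k_obs model, rate-constant maths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoaffinity.kinetics import (
    AssociationSeries,
    DisplacementSeries,
    KineticTrace,
    compute_kd,
    fit_association,
    fit_single_exponential,
    format_sig,
    kobs_reversible,
    koff_from_displacement,
    round_sig,
)
from paleoaffinity.synthetic import (
    simulate_association_series,
    simulate_displacement_series,
    simulate_trace,
)


# ---------------------------------------------------------------------------
# single-exponential traces

def test_noiseless_exponential_recovered_exactly():
    t = np.linspace(0.01, 1.0, 100)
    trace = KineticTrace(t, 1.0 + 2.0 * np.exp(-5.0 * t), 1.0, 5.0)
    fit = fit_single_exponential(trace)
    assert fit.k_obs == pytest.approx(5.0, abs=1e-8)
    assert fit.amplitude == pytest.approx(2.0, abs=1e-8)
    assert fit.offset == pytest.approx(1.0, abs=1e-8)
    assert not fit.no_signal


def test_noisy_trace_recovered_within_three_sigma():
    trace = simulate_trace(k_obs=50.0, amplitude=1.0, noise_frac=0.02, seed=123)
    fit = fit_single_exponential(trace)
    assert abs(fit.k_obs - 50.0) < 3 * fit.k_obs_err
    assert not fit.no_signal


def test_constant_trace_flags_no_signal():
    rng = np.random.default_rng(0)
    t = np.linspace(0.001, 1.0, 100)
    trace = KineticTrace(t, 5.0 + rng.normal(0, 0.01, t.size), 1.0, 5.0)
    fit = fit_single_exponential(trace)
    assert fit.no_signal


def test_trace_validation():
    with pytest.raises(ValueError):
        KineticTrace(np.arange(5), np.arange(5), 1.0, 1.0)          # too short
    t = np.arange(12, dtype=float)
    t[5] = t[4]
    with pytest.raises(ValueError):
        KineticTrace(t, np.ones(12), 1.0, 1.0)                      # non-monotone
    with pytest.raises(ValueError):
        KineticTrace(np.arange(12), np.ones(12), -1.0, 1.0)         # bad conc


# ---------------------------------------------------------------------------
# k_obs for reversible binding

def test_kobs_zero_ligand_is_pseudo_first_order_line():
    assert kobs_reversible(2.0, 0.0, 25.0, 0.28) == pytest.approx(25.0 * 2.0 + 0.28)


def test_kobs_worked_value_equimolar():
    # A0 = B0 = 1 uM, k_on = 25 1/(uM s), k_off = 0.28 1/s
    expected = np.sqrt(0.28**2 + 4 * 25 * 0.28 * 1.0)
    assert kobs_reversible(1.0, 1.0, 25.0, 0.28) == pytest.approx(expected)
    assert expected == pytest.approx(5.30, abs=0.005)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.floats(0.01, 50.0), st.floats(0.01, 50.0),
    st.floats(0.1, 100.0), st.floats(0.01, 100.0),
)
def test_kobs_symmetric_and_monotone_in_excess_ligand(A0, B0, kon, koff):
    """k_obs is symmetric in the two totals and, once the ligand is at least
    equimolar (the association-experiment regime), strictly increasing in it.
    (Below equimolarity k_obs can pass through a minimum at B0 = A0 - K_D,
    so monotonicity only holds on the excess-ligand side.)"""
    assert kobs_reversible(A0, B0, kon, koff) == pytest.approx(
        kobs_reversible(B0, A0, kon, koff), rel=1e-12
    )
    B_lo = max(A0, B0)
    assert kobs_reversible(A0, B_lo * 1.5, kon, koff) > kobs_reversible(A0, B_lo, kon, koff)


def test_kobs_collapses_to_linear_in_excess():
    # ligand 2000x over protein: relative error vs k_on[B] + k_off < 1e-3
    A0, B0, kon, koff = 0.0005, 1.0, 20.0, 2.0
    linear = kon * B0 + koff
    assert abs(kobs_reversible(A0, B0, kon, koff) - linear) / linear < 1e-3


def test_kobs_rejects_negative_inputs():
    with pytest.raises(ValueError):
        kobs_reversible(-1.0, 1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# association series

def test_association_noiseless_round_trip():
    series = simulate_association_series(21.0, 1.7, protein_total=1.0, noise_frac=0.0)
    (kon, _), (koff, _) = fit_association(series)
    assert kon == pytest.approx(21.0, rel=1e-6)
    assert koff == pytest.approx(1.7, rel=1e-6)


def test_association_pseudo_first_order_limit_is_line():
    # protein a million-fold below ligand: the reversible fit and a plain
    # straight-line fit coincide (slope = k_on, intercept = k_off)
    series = simulate_association_series(
        21.0, 1.7, protein_total=1e-8, noise_frac=0.0
    )
    (kon, _), (koff, _) = fit_association(series)
    conc = np.array([c for c, _, _ in series.points])
    kobs = np.array([k for _, k, _ in series.points])
    slope, icept = np.polyfit(conc, kobs, 1)
    assert kon == pytest.approx(slope, rel=1e-6)
    assert koff == pytest.approx(icept, rel=1e-6)


def test_association_replicate_study_recovers_kon():
    """Mean recovered k_on over noisy replicates lands within 1% of truth and
    the fitted sigma covers the truth at roughly the nominal 68% rate."""
    kons, covered = [], 0
    n = 100
    for rep in range(n):
        series = simulate_association_series(21.0, 1.7, noise_frac=0.02, seed=1000 + rep)
        (kon, err), _ = fit_association(series)
        kons.append(kon)
        covered += abs(kon - 21.0) <= err
    assert abs(np.mean(kons) / 21.0 - 1) < 0.01
    assert 0.5 <= covered / n <= 0.85


def test_association_series_validation():
    with pytest.raises(ValueError, match="distinct"):
        AssociationSeries(1.0, [(1.0, 20.0, 0.1)] * 4)
    s = AssociationSeries(1.0, [(0.5, 10.0, 0.1), (2.0, 40.0, 0.1),
                                (5.0, 100.0, 0.1), (12.0, 240.0, 0.1)])
    assert s.warnings  # outside the nominal 1-10 uM regime


# ---------------------------------------------------------------------------
# displacement series

def test_flat_displacement_series_reports_plateau():
    series = DisplacementSeries((1.0, 1.0), [(10.0, 0.29, 0.0), (15.0, 0.28, 0.0),
                                             (20.0, 0.28, 0.0)])
    fit = koff_from_displacement(series)
    assert fit.k_off == pytest.approx(0.28, abs=0.01)
    assert not fit.extrapolated


def test_hyperbolic_displacement_recovers_plateau_within_five_percent():
    series = simulate_displacement_series(
        3.7, k_half=1.5, displacer_concs=np.linspace(2.0, 20.0, 8),
        noise_frac=0.02, seed=4,
    )
    fit = koff_from_displacement(series)
    assert abs(fit.k_off / 3.7 - 1) < 0.05


def test_non_plateauing_series_flagged_as_extrapolation():
    points = [(float(d), 0.5 + 0.1 * d, 0.0) for d in range(10, 22, 2)]
    series = DisplacementSeries((1.0, 1.0), points)
    fit = koff_from_displacement(series)
    assert fit.extrapolated
    assert any("extrapolation" in w for w in series.warnings)


def test_plateau_mean_cross_check_mode():
    series = simulate_displacement_series(3.7, noise_frac=0.0)
    fit = koff_from_displacement(series, mode="plateau_mean")
    assert fit.k_off == pytest.approx(3.7, rel=0.05)


# ---------------------------------------------------------------------------
# K_D arithmetic

def test_kd_identity_and_quadrature_propagation():
    est = compute_kd(1.0, 0.0, 1.0, 0.0)
    assert est.K_D == 1.0 and est.K_D_err == 0.0
    est = compute_kd(20.0, 2.0, 5.0, 0.5)
    assert est.K_D == 5.0 / 20.0
    rel = np.sqrt((2.0 / 20.0) ** 2 + (0.5 / 5.0) ** 2)
    assert est.K_D_err == pytest.approx(est.K_D * rel)


def test_kd_rejects_nonpositive_rates():
    with pytest.raises(ValueError):
        compute_kd(0.0, 0.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        compute_kd(1.0, 0.0, -1.0, 0.0)


@pytest.mark.parametrize("x,n,expected", [
    (0.0112, 2, "0.011"),
    (0.10101, 2, "0.10"),
    (0.145, 3, "0.145"),
    (0.18, 3, "0.180"),
    (0.19892, 2, "0.20"),
    (2.069, 2, "2.1"),
])
def test_significant_figure_formatting(x, n, expected):
    assert format_sig(x, n) == expected
    assert round_sig(x, n) == float(expected)
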