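import numpy as np
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from meiodecay.decay import (LoessFit, calibrate_time, calibration_from_width,
                             chromosome_signal, estimate_relative_rate,
                             half_life, loess_fit, run_decay_analysis,
                             steepest_descent)
from meiodecay.errors import AnalysisError, NoDescentError
from meiodecay.synthetic import density_quantiles, expected_profile

from conftest import make_matrix


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def test_loess_reproduces_linear_function():
    t = np.linspace(0, 1, 100)
    fit = loess_fit(t, 2 * t + 1, span=0.3)
    assert np.abs(fit.fitted - (2 * fit.grid + 1)).max() < 1e-6


def test_loess_constant_data_gives_constant_fit():
    t = np.linspace(0, 1, 50)
    fit = loess_fit(t, np.full(50, 3.5), span=0.4)
    assert np.abs(fit.fitted - 3.5).max() < 1e-12


def test_loess_dense_sine_oracle():
    t = np.linspace(0, 1, 500)
    y = np.sin(2 * np.pi * t)
    fit = loess_fit(t, y, span=0.1, grid=t)
    assert np.abs(fit.fitted - y).max() < 0.01


def test_loess_agrees_with_statsmodels_lowess():
    """Independent cross-check of the local-linear tricube smoother."""
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(0, 1, 400))
    y = np.sin(2 * np.pi * t) + rng.normal(0, 0.2, 400)
    grid = np.linspace(0.1, 0.9, 41)
    ours = loess_fit(t, y, span=0.3, grid=grid).fitted
    ref = sm_lowess(y, t, frac=0.3, it=0, xvals=grid)
    assert np.abs(ours - ref).max() < 0.02


def test_loess_rejects_too_few_points():
    with pytest.raises(AnalysisError, match=">= 20"):
        loess_fit(np.linspace(0, 1, 10), np.zeros(10))


def test_loess_rejects_tiny_span():
    t = np.linspace(0, 1, 30)
    with pytest.raises(AnalysisError, match="< 3 points"):
        loess_fit(t, t, span=0.01)


def test_loess_handles_long_tie_runs():
    # cells projected onto a shared curve vertex produce duplicate t values
    t = np.sort(np.concatenate([np.full(150, 0.4), np.linspace(0, 1, 150)]))
    y = np.where((t > 0.3) & (t < 0.5), 10.0, 0.0)
    fit = loess_fit(t, y, span=0.1, grid=np.linspace(0, 1, 101))
    assert fit.fitted.max() > 5


# ---------------------------------------------------------------------------
# Steepest descent
# ---------------------------------------------------------------------------

def test_steepest_descent_linear_ties_break_left():
    grid = np.linspace(0, 1, 101)
    fit = LoessFit(grid=grid, fitted=1 - grid, span=0.3)
    t_star, slope, value = steepest_descent(fit, 0.0, 1.0)
    assert t_star == 0.0  # ties toward smaller t
    assert slope == pytest.approx(1.0)
    assert value == pytest.approx(1.0)


def test_steepest_descent_logistic_oracle():
    """Closed form: the logistic 1/(1+exp((t-1/2)/s)) has its steepest
    descent at t=1/2 with slope 1/(4s)."""
    s = 0.02
    grid = np.linspace(0, 1, 501)
    fit = LoessFit(grid=grid, fitted=1 / (1 + np.exp((grid - 0.5) / s)),
                   span=0.3)
    t_star, slope, _value = steepest_descent(fit, 0.0, 1.0)
    step = grid[1] - grid[0]
    assert abs(t_star - 0.5) <= step
    assert slope == pytest.approx(1 / (4 * s), rel=0.01)


def test_steepest_descent_increasing_curve_errors():
    grid = np.linspace(0, 1, 51)
    fit = LoessFit(grid=grid, fitted=grid ** 2, span=0.3)
    with pytest.raises(NoDescentError):
        steepest_descent(fit, 0.0, 1.0)


def test_steepest_descent_restricted_interval():
    grid = np.linspace(0, 1, 201)
    fitted = np.where(grid < 0.5, 1 - grid, 1.5 - 2 * grid)
    fit = LoessFit(grid=grid, fitted=fitted, span=0.3)
    t_star, slope, _ = steepest_descent(fit, 0.0, 0.4)
    assert t_star <= 0.4 and slope == pytest.approx(1.0, rel=0.05)


# ---------------------------------------------------------------------------
# Chromosome signal
# ---------------------------------------------------------------------------

def test_signal_constant_totals_are_one():
    counts = np.zeros((4, 2), dtype=int)
    counts[:, 0] = 10
    matrix = make_matrix(counts, chromosomes=["Y", "1"])
    sig = chromosome_signal(matrix, np.linspace(0, 1, 4), "Y")
    assert np.allclose(sig.values, 1.0)


def test_signal_mean_centering_arithmetic():
    counts = np.array([[5, 1], [15, 1]])
    matrix = make_matrix(counts, chromosomes=["Y", "1"])
    sig = chromosome_signal(matrix, np.array([0.2, 0.8]), "Y")
    assert np.allclose(sig.values, [0.5, 1.5])


def test_signal_mean_is_exactly_one(default_dataset):
    matrix, truth = default_dataset
    for c in ("Y", "X", "autosomes"):
        sig = chromosome_signal(matrix, truth.pseudotime, c)
        assert sig.values.mean() == pytest.approx(1.0, abs=1e-12)


def test_signal_errors_without_class_counts():
    matrix = make_matrix(np.ones((3, 2), dtype=int), chromosomes=["1", "2"])
    with pytest.raises(AnalysisError):
        chromosome_signal(matrix, np.linspace(0, 1, 3), "Y")


def test_signal_excludes_mt_and_other_from_autosomes():
    counts = np.array([[2, 100, 100], [4, 100, 100]])
    matrix = make_matrix(counts, chromosomes=["3", "MT", "other"])
    sig = chromosome_signal(matrix, np.array([0.1, 0.9]), "autosomes")
    assert np.allclose(sig.values, [2 / 3, 4 / 3])


def test_signal_scale_invariance(default_dataset, marker_panel_symbols):
    """Multiplying all Y counts by a constant leaves signal and rate alone."""
    matrix, truth = default_dataset
    sig1 = chromosome_signal(matrix, truth.pseudotime, "Y",
                             exclude_symbols=marker_panel_symbols)
    scaled = make_scaled_y(matrix, 10)
    sig2 = chromosome_signal(scaled, truth.pseudotime, "Y",
                             exclude_symbols=marker_panel_symbols)
    assert np.allclose(sig1.values, sig2.values)
    r1 = estimate_relative_rate(sig1.pseudotime, sig1.values, (0.95, 1.0))
    r2 = estimate_relative_rate(sig2.pseudotime, sig2.values, (0.95, 1.0))
    assert r1["rate"] == pytest.approx(r2["rate"], rel=1e-9)


def make_scaled_y(matrix, factor):
    counts = matrix.counts.toarray()
    ymask = matrix.class_mask("Y")
    counts[:, ymask] *= factor
    return make_matrix(counts,
                       chromosomes=matrix.genes["chromosome"].tolist(),
                       symbols=matrix.genes["symbol"].tolist())


# ---------------------------------------------------------------------------
# Calibration and half-life
# ---------------------------------------------------------------------------

def test_calibration_from_width_unit_case():
    assert calibration_from_width(0.01, 100.0) == pytest.approx(100.0)


def test_calibrate_time_noiseless_window_recovery(default_config,
                                                  default_model):
    t = density_quantiles(2550)
    cal = calibrate_time(default_model.expected_profile("Tnp1L", t), t,
                         stage_duration_h=default_config.stage_duration_h)
    assert cal.hours_per_001 == pytest.approx(200.67, rel=0.10)


def test_calibrate_time_requires_detected_marker():
    t = np.linspace(0, 1, 100)
    with pytest.raises(AnalysisError):
        calibrate_time(np.zeros(100), t)


def test_half_life_unit_and_paper_inversion():
    # a rate that halves the signal over 0.01 units maps to hours_per_001
    assert half_life(50.0, 200.67) == pytest.approx(200.67)
    # inverting the printed Y half-life through the printed formula
    assert half_life(1337.8, 200.67) == pytest.approx(7.50, abs=0.005)


def test_half_life_requires_positive_rate():
    with pytest.raises(AnalysisError):
        half_life(0.0, 200.67)


def test_half_life_inverse_proportionality():
    rates = np.array([10.0, 20.0, 80.0])
    values = [half_life(r, 200.67) for r in rates]
    assert values[0] / values[1] == pytest.approx(2.0)
    assert values[0] / values[2] == pytest.approx(8.0)


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def test_run_decay_analysis_without_postmeiotic_cells(default_dataset,
                                                      marker_panel_symbols):
    """With the trajectory truncated before the decay phase, every class
    raises a no-descent style error."""
    matrix, truth = default_dataset
    t = truth.pseudotime.copy()
    t[t > 0.9] = np.nan  # no post-meiotic cells
    with pytest.raises(AnalysisError):
        run_decay_analysis(matrix, t, exclude_symbols=marker_panel_symbols)
    sig = chromosome_signal(matrix, t, "Y",
                            exclude_symbols=marker_panel_symbols)
    with pytest.raises(NoDescentError):
        estimate_relative_rate(sig.pseudotime, sig.values, (0.95, 1.0))


def test_run_decay_analysis_reports_all_classes(default_dataset,
                                                marker_panel_symbols):
    matrix, truth = default_dataset
    estimates, calibration = run_decay_analysis(
        matrix, truth.pseudotime, exclude_symbols=marker_panel_symbols)
    assert set(estimates) == {"Y", "X", "autosomes"}
    for est in estimates.values():
        assert est.slope >= 0 and est.half_life_h > 0
        assert est.raw_relative_rate > 0
    assert calibration.hours_per_001 > 0
    # the estimate and the formula agree exactly
    for est in estimates.values():
        assert est.half_life_h == pytest.approx(
            half_life(est.relative_rate, calibration.hours_per_001))
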