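import numpy as np
import pytest

from meiodecay.errors import ConfigurationError
from meiodecay.synthetic import (CHROM_CLASSES, SimulationConfig,
                                 density_quantiles, expected_profile,
                                 generate_dataset)


def test_seeded_determinism():
    cfg = SimulationConfig(n_cells=300, seed=1)
    m1, t1 = generate_dataset(cfg)
    m2, t2 = generate_dataset(cfg)
    assert (m1.counts != m2.counts).nnz == 0
    assert np.array_equal(t1.pseudotime, t2.pseudotime, equal_nan=True)
    assert np.array_equal(t1.labels, t2.labels)


@pytest.mark.parametrize("field, value", [
    ("n_cells", 10),
    ("rare_fractions", (0.5, 0.5, 0.2)),
    ("rare_fractions", (0.0, 0.001, 0.001)),
    ("meiosis_window", (0.95, 0.90)),
    ("tnp1_window_width", 0.0),
    ("decay_half_lives_h", (7.5, -1.0, 24.7)),
    ("stage_duration_h", -5.0),
    ("msci_factor", 0.0),
    ("decay_floor", 1.0),
    ("nb_dispersion", 0.0),
])
def test_invalid_config_names_field(field, value):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**{field: value})


def test_rare_population_counts_within_binomial_bound(default_dataset,
                                                      default_config):
    _matrix, truth = default_dataset
    n = default_config.n_cells
    for pop, frac in zip(("spermatogonia", "sertoli", "leydig"),
                         default_config.rare_fractions):
        count = int((truth.labels == pop).sum())
        expected = n * frac
        assert abs(count - expected) <= 3 * np.sqrt(expected)
        assert count >= 3


def test_germ_pseudotimes_cover_unit_interval(default_dataset):
    _matrix, truth = default_dataset
    t = truth.pseudotime[np.isfinite(truth.pseudotime)]
    assert t.min() == 0.0 and t.max() == 1.0


def test_truth_half_life_is_exactly_half_over_lambda(default_dataset):
    _matrix, truth = default_dataset
    for c in CHROM_CLASSES:
        assert truth.half_life_h[c] == 0.5 / truth.lambda_per_h[c]


def test_counts_match_expected_class_magnitudes(default_dataset, default_model,
                                                default_config):
    """Sampled class totals of mid-trajectory cells track the model means."""
    matrix, truth = default_dataset
    mid = np.isfinite(truth.pseudotime) & (truth.pseudotime > 0.3) \
        & (truth.pseudotime < 0.7)
    for c in CHROM_CLASSES:
        observed = np.asarray(
            matrix.counts[mid][:, matrix.class_mask(c)].sum(axis=1)).mean()
        expected = default_model.expected_class_total(
            truth.pseudotime[mid], c).mean()
        assert observed == pytest.approx(expected, rel=0.15)


def test_tnp1_profile_zero_outside_window(default_config, default_model):
    lo, hi = default_model.tnp1_window
    prof = expected_profile(default_config, "Tnp1L",
                            [0.0, lo - 1e-6, hi + 1e-6, 1.0])
    assert np.all(prof == 0)
    inside = expected_profile(default_config, "Tnp1L", [(lo + hi) / 2])
    assert inside[0] > 0
    assert hi - lo == pytest.approx(default_config.tnp1_window_width)


def test_msci_suppresses_y_genes_inside_meiosis_window(default_config):
    lo, hi = default_config.meiosis_window
    before, inside = expected_profile(
        default_config, "YG000", [lo - 0.01, (lo + hi) / 2])
    assert inside < before  # suppressed relative to just before the window


def test_y_gene_decays_at_configured_rate(default_config):
    """Past onset the Y mean follows exp(-lambda * dt * hours_per_unit).

    The per-gene smooth modulation is divided out by comparing against a
    configuration whose half-lives are effectively infinite; the gene
    panel draws depend only on the seed, so the two models share genes.
    """
    import dataclasses
    no_decay = dataclasses.replace(
        default_config, decay_half_lives_h=(1e9, 1e9, 1e9))
    onset = default_config.prm1_onset
    ts = [onset, onset + 0.0004, onset + 0.002]
    with_decay = expected_profile(default_config, "YG003", ts)
    without = expected_profile(no_decay, "YG003", ts)
    factors = with_decay / without
    k = default_config.decay_rate_per_unit("Y")
    f = default_config.decay_floor
    expected = f + (1 - f) * np.exp(-k * (np.asarray(ts) - onset))
    assert factors == pytest.approx(expected, rel=1e-6)


def test_unknown_gene_raises_lookup_error(default_config):
    with pytest.raises(KeyError):
        expected_profile(default_config, "NotAGene", [0.5])


def test_expected_class_signal_non_increasing_after_onset(default_config,
                                                          default_model):
    grid = np.linspace(default_config.prm1_onset, 1.0, 400)
    for c in CHROM_CLASSES:
        total = default_model.expected_class_total(grid, c)
        # non-increasing up to the small smooth per-gene modulation drift
        assert np.all(np.diff(total) <= 1e-4 * total[:-1])


def test_noiseless_steepest_relative_slope_matches_planted_rate(
        default_config, default_model):
    """Closed-form oracle: on a fine grid the mean-centered Y signal's
    slope/value at the steepest descent equals lambda_Y x hours_per_unit."""
    t = np.linspace(0.95, 1.0, 20001)
    total = default_model.expected_class_total(
        t, "Y", exclude_symbols=("Tnp1L",))
    signal = total / total.mean()
    deriv = np.gradient(signal, t)
    f = default_config.decay_floor
    floor = signal.min()
    i = int(np.argmin(deriv))
    rel = -deriv[i] / (signal[i] - floor)
    assert rel == pytest.approx(default_config.decay_rate_per_unit("Y"),
                                rel=0.02)


def test_density_quantiles_monotone_and_spanning():
    q = density_quantiles(1000)
    assert np.all(np.diff(q) >= 0)
    assert 0 <= q[0] < 0.01 and 0.99 < q[-1] <= 1
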