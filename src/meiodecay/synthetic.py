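"""Spermatogenesis-like count-matrix simulator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a continuum of germ cells along a latent pseudotime ``t in [0,1]``,
stage-windowed marker programs, meiotic sex chromosome inactivation (MSCI)
as a multiplicative dip of X/Y expression inside the meiosis window,
post-meiotic exponential transcript decay with chromosome-class-specific
half-lives expressed in real hours, a Tnp1-like calibration marker active
in a narrow late window, three rare somatic/stem populations with exclusive
marker programs, and negative-binomial sampling with per-cell library-size
variation.

The latent axis is laid out like the published trajectory: meiosis around
0.925-0.95, protamine onset at 0.986, and the Tnp1-like window (width
0.009) spanning the decay region.  Real time maps onto pseudotime through
``hours_per_unit = stage_duration_h / tnp1_window_width`` (180.6 h for the
window by default, i.e. 200.67 h per 0.01 units), so a class with estimand
half-life ``T`` decays at ``lambda = 0.5/T`` per hour, equivalently
``k = lambda * hours_per_unit`` per pseudotime unit.  Germ-cell pseudotimes
are drawn from a stage-weighted density mirroring adult testis composition
(spermatids are the large majority of germ cells), which concentrates cells
in the late region exactly where the decay must be resolved.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .io import CountMatrix, MarkerTable, default_marker_fixture_path, read_marker_table

CHROM_CLASSES = ("Y", "X", "autosomes")

#: Germ-cell stage composition along pseudotime: (t_lo, t_hi, weight).
#: Weights follow adult testis histology: spermatogonia a few percent,
#: spermatocytes ~a quarter, spermatids the large majority.
STAGE_DENSITY = (
    (0.000, 0.100, 0.04),   # spermatogonia / early spermatocytes
    (0.100, 0.925, 0.24),   # meiotic prophase
    (0.925, 0.950, 0.04),   # meiotic divisions
    (0.950, 0.986, 0.38),   # round spermatids
    (0.986, 1.000, 0.30),   # elongating / condensing spermatids
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic spermatogenesis dataset.

    ``decay_half_lives_h`` are the *estimand* half-lives (0.5/lambda, the
    linear halving rule) in hours, ordered (Y, X, autosomes).
    ``gene_panel`` counts (autosomal, X, Y, marker) genes.
    """

    n_cells: int = 2550
    gene_panel: tuple[int, int, int, int] = (1800, 60, 12, 40)
    rare_fractions: tuple[float, float, float] = (0.0023, 0.0023, 0.0020)
    meiosis_window: tuple[float, float] = (0.925, 0.950)
    prm1_onset: float = 0.986
    decay_half_lives_h: tuple[float, float, float] = (7.5, 26.0, 24.7)
    tnp1_window_width: float = 0.009
    stage_duration_h: float = 180.6
    msci_factor: float = 0.15
    decay_floor: float = 0.08
    nb_dispersion: float = 4.0
    libsize_lognorm: tuple[float, float] = (0.0, 0.30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 50:
            raise ConfigurationError("n_cells must be >= 50")
        if len(self.gene_panel) != 4 or any(g < 1 for g in self.gene_panel):
            raise ConfigurationError("gene_panel needs 4 positive gene counts")
        if any(not (0.0 < f < 1.0) for f in self.rare_fractions):
            raise ConfigurationError("rare_fractions must each lie in (0, 1)")
        if sum(self.rare_fractions) >= 1.0:
            raise ConfigurationError("rare_fractions must sum to < 1")
        lo, hi = self.meiosis_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(
                "meiosis_window must satisfy 0 <= lower < upper <= 1")
        if not (0.0 < self.prm1_onset < 1.0):
            raise ConfigurationError("prm1_onset must lie in (0, 1)")
        if self.tnp1_window_width <= 0:
            raise ConfigurationError("tnp1_window_width must be > 0")
        if any(h <= 0 for h in self.decay_half_lives_h):
            raise ConfigurationError("decay_half_lives_h must be positive")
        if self.stage_duration_h <= 0:
            raise ConfigurationError("stage_duration_h must be > 0")
        if not (0.0 < self.msci_factor <= 1.0):
            raise ConfigurationError("msci_factor must lie in (0, 1]")
        if not (0.0 <= self.decay_floor < 1.0):
            raise ConfigurationError("decay_floor must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.libsize_lognorm[1] < 0:
            raise ConfigurationError("libsize_lognorm sigma must be >= 0")

    @property
    def hours_per_unit(self) -> float:
        """Real hours represented by one pseudotime unit in the late region."""
        return self.stage_duration_h / self.tnp1_window_width

    @property
    def half_lives(self) -> dict[str, float]:
        return dict(zip(CHROM_CLASSES, self.decay_half_lives_h))

    def decay_rate_per_hour(self, chrom_class: str) -> float:
        """Relative decay rate lambda such that 0.5/lambda is the half-life."""
        return 0.5 / self.half_lives[chrom_class]

    def decay_rate_per_unit(self, chrom_class: str) -> float:
        return self.decay_rate_per_hour(chrom_class) * self.hours_per_unit


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the simulator for recovery tests."""

    pseudotime: np.ndarray          # NaN for cells outside the germ trajectory
    labels: np.ndarray              # germ | spermatogonia | sertoli | leydig
    hours_per_unit: float
    lambda_per_h: dict[str, float]
    half_life_h: dict[str, float]   # estimand 0.5/lambda, exactly
    rate_per_unit: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hours_per_unit": self.hours_per_unit,
            "lambda_per_h": self.lambda_per_h,
            "half_life_h": self.half_life_h,
            "rate_per_unit": self.rate_per_unit,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "pseudotime": self.pseudotime,
            "label": self.labels,
        }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression model: the deterministic generative mean
# ---------------------------------------------------------------------------

# Marker panel: (symbol, stage, kind, window or None).
# kind "germ" = windowed along the trajectory; "shared" = windowed early AND
# expressed by the spermatogonia population; "sg"/"sertoli"/"leydig" =
# exclusive to that rare population; "tnp1"/"prm" are the calibration marker
# and the onset-anchored condensing program (window filled in from config).
_MARKER_PANEL = [
    ("Stra8L", "spermatogonia", "shared", (0.00, 0.06), 20.0),
    ("Crabp1L", "spermatogonia", "shared", (0.00, 0.08), 20.0),
    ("Hist1h1aL", "spermatogonia", "shared", (0.00, 0.12), 20.0),
    ("DazlL", "spermatogonia", "shared", (0.00, 0.10), 20.0),
    ("Gfra1L", "spermatogonia", "sg", None, 300.0),
    ("Zbtb16L", "spermatogonia", "sg", None, 300.0),
    ("Id4L", "spermatogonia", "sg", None, 300.0),
    ("Lin28aL", "spermatogonia", "sg", None, 300.0),
    ("Sycp3L", "spermatocyte", "germ", (0.08, 0.55), 25.0),
    ("Hormad1L", "spermatocyte", "germ", (0.12, 0.70), 25.0),
    ("Piwil1L", "spermatocyte", "germ", (0.25, 0.93), 25.0),
    ("Spo11L", "spermatocyte", "germ", (0.10, 0.50), 25.0),
    ("Mlh3L", "spermatocyte", "germ", (0.50, 0.95), 25.0),
    ("Sycp1L", "spermatocyte", "germ", (0.15, 0.80), 25.0),
    ("Acrv1L", "round spermatid", "germ", (0.950, 0.988), 25.0),
    ("Spaca1L", "round spermatid", "germ", (0.955, 0.990), 25.0),
    ("Izumo1L", "round spermatid", "germ", (0.952, 0.985), 25.0),
    ("Tssk1L", "round spermatid", "germ", (0.948, 0.975), 25.0),
    ("Tex21L", "round spermatid", "germ", (0.958, 0.992), 25.0),
    ("GapdhsL", "round spermatid", "germ", (0.960, 0.995), 25.0),
    ("Tnp2L", "elongating spermatid", "germ", (0.982, 0.996), 60.0),
    ("Odf1L", "elongating spermatid", "germ", (0.975, 0.995), 60.0),
    ("Oaz3L", "elongating spermatid", "germ", (0.978, 0.998), 60.0),
    ("Akap4L", "elongating spermatid", "germ", (0.972, 0.993), 60.0),
    ("Tnp1L", "elongating spermatid", "tnp1", None, 80.0),
    ("Prm1L", "condensing spermatid", "prm", 0.000, 150.0),
    ("Prm2L", "condensing spermatid", "prm", 0.002, 150.0),
    ("SmcpL", "condensing spermatid", "prm", 0.004, 80.0),
    ("Wt1L", "Sertoli", "sertoli", None, 300.0),
    ("Rhox5L", "Sertoli", "sertoli", None, 300.0),
    ("KitlL", "Sertoli", "sertoli", None, 300.0),
    ("Sox8L", "Sertoli", "sertoli", None, 300.0),
    ("AmhL", "Sertoli", "sertoli", None, 300.0),
    ("CtslL", "Sertoli", "sertoli", None, 300.0),
    ("Cyp17a1L", "Leydig", "leydig", None, 300.0),
    ("Hsd3b6L", "Leydig", "leydig", None, 300.0),
    ("Hsd17b11L", "Leydig", "leydig", None, 300.0),
    ("Vcam1L", "Leydig", "leydig", None, 300.0),
    ("StarL", "Leydig", "leydig", None, 300.0),
    ("Insl3L", "Leydig", "leydig", None, 300.0),
]

#: Expected total counts per germ cell, per gene class, at mid-trajectory
#: before decay (autosomes, X, Y).  X is a few percent of the autosomal
#: output and Y is weak, matching the relative magnitudes seen in testis
#: single-cell data.
_CLASS_TOTALS = {"autosomes": 24000.0, "X": 1500.0, "Y": 280.0}

_RAMP_FRAC = 0.2


def _trapezoid(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal bump with support exactly (lo, hi); plateau height 1.

    Ramps occupy ``_RAMP_FRAC`` of the window on each side.  A window
    reaching t=1 keeps its plateau to the end (no falling ramp).
    """
    t = np.asarray(t, dtype=float)
    r = _RAMP_FRAC * (hi - lo)
    up = np.clip((t - lo) / r, 0.0, 1.0)
    if hi >= 1.0:
        down = 1.0
    else:
        down = np.clip((hi - t) / r, 0.0, 1.0)
    return np.where((t > lo) & (t < hi) | ((hi >= 1.0) & (t >= hi)),
                    np.minimum(up, down) if hi < 1.0 else up, 0.0)


class ExpressionModel:
    """Deterministic generative mean for every gene, given a config.

    Built from ``config.seed`` alone, so :func:`expected_profile` returns
    exactly the mean used by :func:`generate_dataset`.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        n_auto, n_x, n_y, n_marker = config.gene_panel
        if n_marker < len(_MARKER_PANEL):
            raise ConfigurationError(
                f"gene_panel marker count must be >= {len(_MARKER_PANEL)}")
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))

        records = []
        for i in range(n_auto):
            records.append((f"AUTO{i:04d}", f"Auto{i:04d}", str(i % 19 + 1), "base", "autosomes"))
        for i in range(n_x):
            records.append((f"XG{i:03d}", f"Xg{i:03d}", "X", "base", "X"))
        for i in range(n_y):
            records.append((f"YG{i:03d}", f"Yg{i:03d}", "Y", "base", "Y"))
        self._marker_rows = []
        for j in range(n_marker):
            if j < len(_MARKER_PANEL):
                sym, stage, kind, window, level = _MARKER_PANEL[j]
            else:  # spare marker slots: silent filler genes
                sym, stage, kind, window, level = f"MrkPad{j}", "spermatocyte", "pad", None, 0.0
            records.append((f"MRK{j:03d}", sym, str(j % 19 + 1), "marker", "autosomes"))
            self._marker_rows.append((sym, stage, kind, window, level))
        self.genes = pd.DataFrame(
            records, columns=["gene_id", "symbol", "chromosome", "kind", "chrom_class"])

        n_base = n_auto + n_x + n_y
        base_raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_base)
        self.base = np.zeros(n_base)
        cls = self.genes["chrom_class"].to_numpy()[:n_base]
        for name, total in _CLASS_TOTALS.items():
            mask = cls == name
            self.base[mask] = base_raw[mask] / base_raw[mask].sum() * total
        # smooth per-gene modulation: log-linear trend + one Gaussian bump,
        # giving the trajectory a continuously turning direction so the
        # ordering is identifiable everywhere
        self.trend = rng.normal(0.0, 0.8, size=n_base)
        self.bump_amp = rng.normal(0.0, 0.8, size=n_base)
        self.bump_center = rng.uniform(0.0, 1.0, size=n_base)
        self.bump_width = np.exp(rng.uniform(np.log(0.02), np.log(0.35), size=n_base))
        # somatic populations carry their own genome-wide expression
        # programs (lognormal modulation of the base means), as real
        # Sertoli/Leydig/stem transcriptomes differ globally, not only in
        # a handful of named markers
        self.somatic_mod = {
            pop: rng.lognormal(0.0, 2.5, size=n_base)
            for pop in ("spermatogonia", "sertoli", "leydig")
        }
        self.n_base = n_base
        self.n_genes = n_base + n_marker

        w = config.tnp1_window_width
        self.tnp1_window = (config.prm1_onset + 0.0005,
                            config.prm1_onset + 0.0005 + w)
        self._symbol_index = {s: self.n_base + j
                              for j, (s, *_rest) in enumerate(self._marker_rows)}
        self._symbol_index.update(
            {gid: i for i, gid in enumerate(self.genes["gene_id"])})

    # -- germ trajectory ----------------------------------------------------

    def _marker_mean(self, t: np.ndarray) -> np.ndarray:
        cfg = self.config
        t = np.asarray(t, dtype=float)
        out = np.zeros((t.size, len(self._marker_rows)))
        # marker genes sit on autosomes, so the post-onset class decay
        # applies to them too; only the calibration clock gene escapes it
        # (its window must stay visible against the collapsing background,
        # the way Tnp1 is actively transcribed through the decay phase)
        f = cfg.decay_floor
        decay = f + (1.0 - f) * np.exp(
            -cfg.decay_rate_per_unit("autosomes")
            * np.clip(t - cfg.prm1_onset, 0.0, None))
        for j, (_sym, _stage, kind, window, level) in enumerate(self._marker_rows):
            if kind in ("germ", "shared"):
                out[:, j] = level * _trapezoid(t, *window) * decay
            elif kind == "tnp1":
                out[:, j] = level * _trapezoid(t, *self.tnp1_window)
            elif kind == "prm":
                onset = cfg.prm1_onset + window  # window holds the stagger
                out[:, j] = level * _trapezoid(t, onset, 1.0) * decay
            # sg / sertoli / leydig / pad: zero along the germ trajectory
        return out

    def _base_mean(self, t: np.ndarray) -> np.ndarray:
        cfg = self.config
        t = np.asarray(t, dtype=float)[:, None]
        log_mod = (self.trend[None, :] * (t - 0.5)
                   + self.bump_amp[None, :]
                   * np.exp(-0.5 * ((t - self.bump_center[None, :])
                                    / self.bump_width[None, :]) ** 2))
        mu = self.base[None, :] * np.exp(log_mod)
        cls = self.genes["chrom_class"].to_numpy()[: self.n_base]
        lo, hi = cfg.meiosis_window
        in_msci = ((t >= lo) & (t < hi)).astype(float)
        sex = np.isin(cls, ["X", "Y"])[None, :]
        mu = mu * np.where(sex & (in_msci > 0), cfg.msci_factor, 1.0)
        dt = np.clip(t - cfg.prm1_onset, 0.0, None)
        # a small stable residual pool escapes degradation, as in real
        # spermatids; the decaying component still follows exp(-k dt)
        f = cfg.decay_floor
        for name in CHROM_CLASSES:
            k = cfg.decay_rate_per_unit(name)
            mu[:, cls == name] *= f + (1.0 - f) * np.exp(-k * dt)
        return mu

    def germ_means(self, t: np.ndarray) -> np.ndarray:
        """Expected counts (cells x genes) for germ cells at pseudotimes t."""
        return np.concatenate([self._base_mean(t), self._marker_mean(t)], axis=1)

    def somatic_means(self, population: str) -> np.ndarray:
        """Expected counts for one cell of a rare population."""
        mu = np.zeros(self.n_genes)
        prof = self.base * self.somatic_mod[population]
        # distinct lineage program with a germ-like total RNA output
        mu[: self.n_base] = prof * self.base.sum() / prof.sum()
        for j, (_sym, _stage, kind, window, level) in enumerate(self._marker_rows):
            col = self.n_base + j
            if population == "spermatogonia" and kind in ("sg", "shared"):
                mu[col] = level
            elif population == "sertoli" and kind == "sertoli":
                mu[col] = level
            elif population == "leydig" and kind == "leydig":
                mu[col] = level
        return mu

    # -- oracle access ------------------------------------------------------

    def expected_profile(self, gene: str, t) -> np.ndarray:
        """Generative mean of one gene along the germ trajectory.

        ``gene`` may be a gene id or a marker symbol; ``t`` a scalar or
        array in [0, 1].
        """
        if gene not in self._symbol_index:
            raise KeyError(f"unknown gene {gene!r}")
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any((t < 0) | (t > 1)):
            raise ValueError("t must lie in [0, 1]")
        col = self._symbol_index[gene]
        return self.germ_means(t)[:, col]

    def expected_class_total(self, t, chrom_class: str,
                             exclude_symbols: tuple[str, ...] = ()) -> np.ndarray:
        """Noiseless per-cell class totals (sum of generative means)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        means = self.germ_means(t)
        mask = (self.genes["chrom_class"] == chrom_class).to_numpy()
        if exclude_symbols:
            mask = mask & ~self.genes["symbol"].isin(exclude_symbols).to_numpy()
        return means[:, mask].sum(axis=1)

    def marker_table(self) -> MarkerTable:
        rows = [(sym, stage, "synthetic panel")
                for sym, stage, kind, _w, _l in self._marker_rows
                if kind != "pad"]
        return MarkerTable(table=pd.DataFrame(
            rows, columns=["symbol", "stage", "source"]))


@functools.lru_cache(maxsize=8)
def _model_for(config: SimulationConfig) -> ExpressionModel:
    return ExpressionModel(config)


def expected_profile(config: SimulationConfig, gene: str, t) -> np.ndarray:
    """Module-level oracle: the generative mean used by generate_dataset."""
    return _model_for(config).expected_profile(gene, t)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def density_quantiles(n: int) -> np.ndarray:
    """Deterministic pseudotime design: quantiles of the stage density.

    Used as the cell layout for noiseless-limit oracles, where sampling
    noise would defeat the purpose.
    """
    bounds = np.array([s[:2] for s in STAGE_DENSITY])
    weights = np.array([s[2] for s in STAGE_DENSITY], dtype=float)
    weights /= weights.sum()
    cum = np.concatenate([[0.0], np.cumsum(weights)])
    u = (np.arange(n) + 0.5) / n
    comp = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(weights) - 1)
    frac = (u - cum[comp]) / weights[comp]
    return bounds[comp, 0] + frac * (bounds[comp, 1] - bounds[comp, 0])


def _sample_pseudotimes(n: int, rng: np.random.Generator) -> np.ndarray:
    bounds = np.array([s[:2] for s in STAGE_DENSITY])
    weights = np.array([s[2] for s in STAGE_DENSITY])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    t = rng.uniform(bounds[comp, 0], bounds[comp, 1])
    if n >= 2:  # pin the extremes so the trajectory spans [0, 1] exactly
        t[np.argmin(t)] = 0.0
        t[np.argmax(t)] = 1.0
    return t


def generate_dataset(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic dataset and its ground truth.

    Counts are negative-binomially distributed around the generative mean
    scaled by a per-cell lognormal library factor; ``nb_dispersion=inf``
    gives the Poisson limit.
    """
    model = _model_for(config)
    rng_cells = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    rng_counts = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))

    n = config.n_cells
    # binomial capture of each rare population, conditioned on at least 3
    # cells being captured (the documented populations were all captured;
    # 3 is the minimum the rank-sum marker test is defined for)
    def _capture(fraction: float) -> int:
        while True:
            k = int(rng_cells.binomial(n, fraction))
            if k >= 3:
                return k

    n_sg = _capture(config.rare_fractions[0])
    n_sert = _capture(config.rare_fractions[1])
    n_ley = _capture(config.rare_fractions[2])
    n_germ = n - n_sg - n_sert - n_ley

    t_germ = _sample_pseudotimes(n_germ, rng_cells)
    labels = np.array(["germ"] * n_germ + ["spermatogonia"] * n_sg
                      + ["sertoli"] * n_sert + ["leydig"] * n_ley)
    pseudotime = np.full(n, np.nan)
    pseudotime[:n_germ] = t_germ

    mu = np.empty((n, model.n_genes))
    mu[:n_germ] = model.germ_means(t_germ)
    row = n_germ
    for pop, count in (("spermatogonia", n_sg), ("sertoli", n_sert), ("leydig", n_ley)):
        mu[row:row + count] = model.somatic_means(pop)[None, :]
        row += count

    mean_log, sigma_log = config.libsize_lognorm
    lib = rng_counts.lognormal(mean_log, sigma_log, size=n) if sigma_log > 0 \
        else np.full(n, math.exp(mean_log))
    mu *= lib[:, None]

    if math.isinf(config.nb_dispersion):
        counts = rng_counts.poisson(mu)
    else:
        lam = rng_counts.gamma(config.nb_dispersion, mu / config.nb_dispersion)
        counts = rng_counts.poisson(lam)

    # shuffle so cell order carries no information
    perm = rng_cells.permutation(n)
    counts = counts[perm]
    pseudotime = pseudotime[perm]
    labels = labels[perm]

    matrix = CountMatrix(
        barcodes=[f"CELL{i:06d}" for i in range(n)],
        genes=model.genes[["gene_id", "symbol", "chromosome"]].copy(),
        counts=sp.csr_matrix(counts),
    )
    truth = SyntheticTruth(
        pseudotime=pseudotime,
        labels=labels,
        hours_per_unit=config.hours_per_unit,
        lambda_per_h={c: config.decay_rate_per_hour(c) for c in CHROM_CLASSES},
        half_life_h={c: 0.5 / config.decay_rate_per_hour(c) for c in CHROM_CLASSES},
        rate_per_unit={c: config.decay_rate_per_unit(c) for c in CHROM_CLASSES},
        seed=config.seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Marker-filter fixture
# ---------------------------------------------------------------------------

def marker_fixture(n_cells: int = 40) -> tuple[CountMatrix, MarkerTable]:
    """Deterministic fixture mirroring the published marker-count funnel.

    Returns a 233-row marker table (the packaged synthetic stand-in) and a
    count matrix in which exactly 224 of the symbols are annotated and the
    expression-filter rule (mean >= 0.1 over all cells, expressed in >= 3
    cells) retains exactly 214 of them.
    """
    table = read_marker_table(default_marker_fixture_path())
    symbols = table.symbols()
    annotated = symbols[:224]          # last 9 symbols stay unannotated
    fail_mean = set(annotated[-10:-5])  # too weak: 3 cells of 1 < 0.1 mean
    fail_cells = set(annotated[-5:])    # abundant but in only 2 cells

    rng = np.random.default_rng(20260924)
    cols = []
    for sym in annotated:
        col = np.zeros(n_cells, dtype=np.int64)
        if sym in fail_mean:
            col[rng.choice(n_cells, 3, replace=False)] = 1
        elif sym in fail_cells:
            col[rng.choice(n_cells, 2, replace=False)] = 30
        else:
            # at least mean 0.1 and >= 3 expressing cells; a few sit exactly
            # on the boundary (4 cells of 1 over 40 cells)
            k = int(rng.integers(4, 12))
            col[rng.choice(n_cells, k, replace=False)] = rng.integers(1, 5, size=k)
            col[np.argmax(col)] = max(col.max(), int(np.ceil(0.1 * n_cells)) - k + 1)
        cols.append(col)
    counts = np.stack(cols, axis=1)
    genes = pd.DataFrame({
        "gene_id": [f"FIX{i:03d}" for i in range(len(annotated))],
        "symbol": annotated,
        "chromosome": [str(i % 19 + 1) for i in range(len(annotated))],
    })
    matrix = CountMatrix(
        barcodes=[f"FIXCELL{i:03d}" for i in range(n_cells)],
        genes=genes,
        counts=sp.csr_matrix(counts),
    )
    return matrix, table
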