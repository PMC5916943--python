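# meiodecay

Chromosome-level transcript decay and RNA half-life estimation along the
mouse spermatogenesis trajectory, from single-cell RNA-seq.

During spermiogenesis, transcription ceases as histones are exchanged for
protamines, and the transcript pool laid down beforehand decays. Because
the X and Y chromosomes were silenced once already during meiosis (meiotic
sex chromosome inactivation), the stability of their post-meiotic
transcripts is a question of its own — and it can be read off whole-testis
single-cell data as chromosome-class read-share trajectories. This package
implements that analysis end to end for anyone who wants to apply it to
10x-style testis data or study its statistical behavior:

* marker-based annotation of K-means clusters (including the rare
  spermatogonia, Sertoli and Leydig populations, each a handful of cells
  in ~2550),
* principal-curve pseudotime scaled to [0, 1],
* the half-life estimator at its core: per chromosome class
  `c ∈ {Y, X, autosomes}`, the mean-centered class signal
  `S_c(i)/⟨S_c⟩` is LOESS-smoothed against pseudotime `t`; at the point
  of steepest descent `t*` the relative decay rate is
  `r = |dŜ/dt| / Ŝ(t*)` (per pseudotime unit); a stage-restricted
  calibration marker (a *Tnp1* analogue) whose window of width `w`
  represents 180.6 h of the seminiferous epithelial cycle converts
  pseudotime to hours (`hours_per_001 = 180.6 × 0.01/w`, 200.67 h per
  0.01 units at the default width); and the half-life follows the linear
  halving rule

  ```
  T½ = (0.5 / r) × (hours_per_001 / 0.01)
  ```

  which equals `0.5/λ` for exponential decay at rate `λ` per hour
  (deliberately not `ln 2/λ`),
* a synthetic-data generator that plants all of this — trajectory, MSCI
  dip, decay kinetics, calibration window, rare populations — with known
  ground truth, so every stage is testable without any download.

See `docs/methods.md` for the model, the numerical design of the rate
estimator, and what the simulator does and does not emulate.

## Worked example

```python
from meiodecay import (SimulationConfig, generate_dataset,
                       run_decay_analysis)
from meiodecay.synthetic import _model_for

config = SimulationConfig(seed=0)          # 2550 cells, planted half-lives
matrix, truth = generate_dataset(config)   # Y 7.5 h, X 26 h, autosomes 24.7 h
markers = _model_for(config).marker_table()

estimates, calibration = run_decay_analysis(
    matrix, truth.pseudotime, exclude_symbols=tuple(markers.symbols()))
print(f"hours per 0.01 pseudotime: {calibration.hours_per_001:.1f}")
for name, est in estimates.items():
    print(f"{name:10s} t*={est.t_star:.4f}  rate={est.relative_rate:7.1f}/unit"
          f"  half-life={est.half_life_h:5.1f} h")
```

Output:

```
hours per 0.01 pseudotime: 213.0
Y          t*=0.9866  rate= 1277.8/unit  half-life=  8.3 h
X          t*=0.9878  rate=  370.9/unit  half-life= 28.7 h
autosomes  t*=0.9872  rate=  381.4/unit  half-life= 27.9 h
```

The planted half-lives are 7.5, 26 and 24.7 h: one seeded simulation
recovers each within its sampling error, with the Y transcripts decaying
about 3× faster than X and autosomal ones. `truth.pseudotime` supplies the
planted ordering, isolating the decay estimator; the full self-contained
pipeline (which infers its own pseudotime) is one call:

```
meiodecay run-all --seed 0 --out out/
```

which writes counts, cluster labels, cell-type assignments, dot-plot
statistics, rare-population marker tables, pseudotime, decay estimates and
a consolidated `report.json`. The other subcommands
(`simulate`, `convert`, `validate`, `cluster`, `annotate`, `pseudotime`,
`decay`) expose the stages individually.

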