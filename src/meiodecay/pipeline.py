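"""End-to-end orchestration: simulate/load -> cluster -> annotate ->
pseudotime -> decay, with a machine-readable report.

A single YAML config drives all stages; the global ``seed`` fixes every
source of randomness, so rerunning the same config reproduces the report
bit for bit (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import decay as dc
from . import markers as mk
from . import pseudotime as ps
from . import synthetic as syn
from .errors import AnalysisError, ConfigurationError
from .io import read_marker_table, read_mtx_counts, write_mtx_counts

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "meiodecay_out",
    "simulate": {},          # SimulationConfig overrides; or use "input"
    "input": None,           # {"directory":..., "markers":..., "annotation":...}
    "cluster": {"k": 9, "n_components": 10},
    "pseudotime": {"span": 0.1},
    "decay": {"stage_duration_h": 180.6, "calibration_marker": "Tnp1L"},
}


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Merge the default config, a YAML file and CLI overrides (in order)."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config file must contain a mapping")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if isinstance(val, dict) and isinstance(config.get(key), dict):
            config[key].update(val)
        else:
            config[key] = val
    return config


@dataclasses.dataclass
class PipelineReport:
    """Everything the pipeline computed, in JSON-serializable form."""

    config: dict
    stages: dict                 # stage -> {"status", "runtime_s"}
    cell_types: dict             # cluster id -> cell type
    cluster_sizes: dict
    marker_counts: dict          # input / annotated / retained
    pseudotime_converged: bool
    decay: dict                  # class -> DecayEstimate fields
    calibration: dict
    warnings: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=_jsonable))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineReport":
        return cls(**json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: dict | str | Path) -> PipelineReport:
    """Execute all stages; write stage outputs and the report to output_dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("output_dir", "meiodecay_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    warnings: list[str] = []

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                stages[name] = {
                    "status": "failed" if exc_type else "ok",
                    "runtime_s": round(time.time() - self.t0, 3),
                }
                return False
        return _T()

    # --- load or simulate -------------------------------------------------
    truth = None
    with timed("input"):
        if config.get("input"):
            section = config["input"]
            matrix = read_mtx_counts(section["directory"],
                                     annotation=section.get("annotation"))
            marker_table = read_marker_table(section["markers"])
        else:
            sim_kwargs = dict(config.get("simulate") or {})
            sim_kwargs.setdefault("seed", seed)
            for key in ("gene_panel", "rare_fractions", "meiosis_window",
                        "decay_half_lives_h", "libsize_lognorm"):
                if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_config = syn.SimulationConfig(**sim_kwargs)
            matrix, truth = syn.generate_dataset(sim_config)
            marker_table = syn._model_for(sim_config).marker_table()
            write_mtx_counts(matrix, outdir / "counts")
            truth.to_json(outdir / "truth.json")
            truth.to_tsv(outdir / "truth.tsv")

    # --- normalize / embed / cluster --------------------------------------
    with timed("cluster"):
        ccfg = config.get("cluster", {})
        normalized = cl.normalize_log(matrix)
        embedding = cl.embed_pca(
            normalized, n_components=int(ccfg.get("n_components", 10)),
            seed=seed)
        labels = cl.kmeans_cluster(embedding, k=int(ccfg.get("k", 9)),
                                   seed=seed)
        pd.DataFrame({
            "barcode": np.asarray(matrix.barcodes)[normalized.kept],
            "cluster": labels,
        }).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    # --- annotate ----------------------------------------------------------
    with timed("annotate"):
        filt = mk.filter_markers(matrix, marker_table)
        stats = mk.dotplot_stats(matrix, labels, filt.retained,
                                 normalized=normalized)
        assignments = mk.assign_cell_types(stats, marker_table)
        cell_types = assignments["cell_type"].to_dict()
        stats.table.to_csv(outdir / "dotplot.tsv", sep="\t", index=False)
        assignments.to_csv(outdir / "cell_types.tsv", sep="\t")
        if assignments["low_confidence"].any():
            warnings.append("low-confidence cell-type assignments present")

    # --- rare-population markers -------------------------------------------
    with timed("rare_markers"):
        de_tables = []
        for cluster_id, cell_type in cell_types.items():
            if cell_type in ("spermatogonia", "Sertoli", "Leydig"):
                size = int((labels == cluster_id).sum())
                if size < 3 or size > 0.05 * labels.size:
                    continue
                de = cl.rare_population_markers(
                    matrix, labels, cluster_id, normalized=normalized)
                de["cluster"] = cluster_id
                de["cell_type"] = cell_type
                de_tables.append(de[de["marker"]])
        if de_tables:
            pd.concat(de_tables).to_csv(
                outdir / "rare_population_markers.tsv", sep="\t", index=False)

    # --- pseudotime ---------------------------------------------------------
    with timed("pseudotime"):
        germ_mask = ps.select_germ_cells(labels, cell_types)
        symbols = matrix.genes["symbol"].to_numpy()
        marker = next((m for m in ps.EARLY_MARKER_CANDIDATES
                       if m in symbols), None)
        if marker is None:
            raise AnalysisError(
                "no early orientation marker found; expected one of "
                + ", ".join(ps.EARLY_MARKER_CANDIDATES))
        early = normalized.values[:, int(np.flatnonzero(symbols == marker)[0])]
        pcfg = config.get("pseudotime", {})
        assignment = ps.assign_pseudotime(
            embedding.coords, germ_mask, early, orientation_marker=marker,
            span=float(pcfg.get("span", 0.1)))
        if not assignment.converged:
            warnings.append("principal curve did not fully converge; "
                            "best iterate used")
        pd.DataFrame({
            "barcode": np.asarray(matrix.barcodes)[normalized.kept],
            "pseudotime": assignment.t,
        }).to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)

    # --- decay --------------------------------------------------------------
    with timed("decay"):
        dcfg = config.get("decay", {})
        # the normalized/kept cells define the label/pseudotime frame; map
        # the assignment back onto the full matrix
        t_full = np.full(matrix.n_cells, np.nan)
        inc_full = np.zeros(matrix.n_cells, dtype=bool)
        kept_idx = np.flatnonzero(normalized.kept)
        t_full[kept_idx] = assignment.t
        inc_full[kept_idx] = assignment.included
        estimates, calibration = dc.run_decay_analysis(
            matrix, t_full,
            stage_duration_h=float(dcfg.get("stage_duration_h", 180.6)),
            calibration_marker=dcfg.get("calibration_marker", "Tnp1L"),
            exclude_symbols=tuple(marker_table.symbols()),
        )
        pd.DataFrame([dataclasses.asdict(e) for e in estimates.values()]
                     ).to_csv(outdir / "decay.tsv", sep="\t", index=False)
        Path(outdir / "calibration.json").write_text(
            json.dumps(dataclasses.asdict(calibration), indent=2))

    report = PipelineReport(
        config=config,
        stages=stages,
        cell_types={str(k): v for k, v in cell_types.items()},
        cluster_sizes={str(k): int(v)
                       for k, v in zip(*np.unique(labels, return_counts=True))},
        marker_counts={"input": filt.counts[0], "annotated": filt.counts[1],
                       "retained": filt.counts[2]},
        pseudotime_converged=bool(assignment.converged),
        decay={name: dataclasses.asdict(est)
               for name, est in estimates.items()},
        calibration=dataclasses.asdict(calibration),
        warnings=warnings,
    )
    report.to_json(outdir / "report.json")
    return report


def summarize_markers(report: PipelineReport) -> tuple[int, int, int]:
    """The marker funnel (input, annotated, retained) from a report."""
    if "annotate" not in report.stages or \
            report.stages["annotate"]["status"] != "ok":
        raise AnalysisError("annotate stage did not complete")
    counts = report.marker_counts
    return (int(counts["input"]), int(counts["annotated"]),
            int(counts["retained"]))
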