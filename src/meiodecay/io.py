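"""Readers and writers for the standard formats the pipeline touches.

Count matrices travel as 10x-style directories (MatrixMarket ``matrix.mtx``
plus ``barcodes.tsv`` and ``features.tsv``), optionally gzip-compressed.
Literature stage markers travel as a TSV of (gene symbol, stage label,
source note).  In memory, counts are held as a :class:`CountMatrix`:
a sparse non-negative integer matrix oriented cells x genes, with a
chromosome label per gene.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Chromosome vocabulary for mouse; anything else is mapped to "other".
MOUSE_CHROMOSOMES = tuple(str(i) for i in range(1, 20)) + ("X", "Y", "MT")

#: Stage vocabulary for the marker table.
STAGE_VOCABULARY = (
    "spermatogonia",
    "spermatocyte",
    "round spermatid",
    "elongating spermatid",
    "condensing spermatid",
    "Sertoli",
    "Leydig",
)

#: Germ-cell stages, in trajectory order (somatic types excluded).
GERM_STAGES = STAGE_VOCABULARY[:5]


@dataclass
class CountMatrix:
    """Cells x genes unique-molecule counts with per-gene chromosome labels.

    Attributes
    ----------
    barcodes : list of str
        One barcode per cell; must be unique.
    genes : pandas.DataFrame
        Columns ``gene_id``, ``symbol``, ``chromosome``; one row per gene.
    counts : scipy.sparse.csr_matrix
        Non-negative integers, shape ``(n_cells, n_genes)``.
    """

    barcodes: list[str]
    genes: pd.DataFrame
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        missing = {"gene_id", "symbol", "chromosome"} - set(self.genes.columns)
        if missing:
            raise FormatError(f"gene table missing columns: {sorted(missing)}")
        chrom = self.genes["chromosome"].astype(str)
        bad = ~chrom.isin(MOUSE_CHROMOSOMES + ("other",))
        if bad.any():
            self.genes = self.genes.copy()
            self.genes["chromosome"] = chrom.where(~bad, "other")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def class_mask(self, chrom_class: str) -> np.ndarray:
        """Boolean gene mask for a chromosome class.

        ``autosomes`` covers chromosomes 1-19; MT and unplaced contigs
        ("other") belong to no class.
        """
        chrom = self.genes["chromosome"].astype(str).to_numpy()
        if chrom_class == "autosomes":
            return np.isin(chrom, [str(i) for i in range(1, 20)])
        if chrom_class in ("X", "Y"):
            return chrom == chrom_class
        raise ValueError(f"unknown chromosome class {chrom_class!r}")


@dataclass
class MarkerTable:
    """Literature stage markers: rows of (symbol, stage, source note)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["symbol", "stage", "source"]))

    def __post_init__(self) -> None:
        t = self.table
        missing = {"symbol", "stage"} - set(t.columns)
        if missing:
            raise FormatError(f"marker table missing columns: {sorted(missing)}")
        if "source" not in t.columns:
            t = t.assign(source="")
        bad = sorted(set(t["stage"]) - set(STAGE_VOCABULARY))
        if bad:
            raise FormatError(
                f"unknown stage labels {bad}; allowed: {list(STAGE_VOCABULARY)}"
            )
        dup = t.duplicated(subset=["symbol", "stage"])
        if dup.any():
            raise FormatError(
                "duplicate (symbol, stage) rows: "
                + ", ".join(t.loc[dup, "symbol"].unique())
            )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def symbols(self) -> list[str]:
        return self.table["symbol"].tolist()

    def stage_of(self) -> dict[str, str]:
        return dict(zip(self.table["symbol"], self.table["stage"]))


def _find(directory: Path, name: str) -> Path:
    for candidate in (directory / name, directory / f"{name}.gz"):
        if candidate.exists():
            return candidate
    raise IOError(f"{name}(.gz) not found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_mtx_counts(directory: str | Path,
                    annotation: str | Path | None = None) -> CountMatrix:
    """Read a 10x-style directory into a :class:`CountMatrix`.

    The on-disk matrix may be genes x cells (cellranger convention) or
    cells x genes; orientation is normalized using the TSV lengths.  A
    two-column ``features.tsv`` (no chromosome) loads with chromosome
    "other" and a warning; alternatively an ``annotation`` TSV mapping
    gene id to chromosome supplies the labels.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    barcodes_path = _find(directory, "barcodes.tsv")
    features_path = _find(directory, "features.tsv")

    try:
        with _open_text(mtx_path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # malformed MTX (e.g. truncated entries)
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc

    with _open_text(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(features_path) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]

    n_feat, n_bc = len(feat_rows), len(barcodes)
    if mat.shape == (n_feat, n_bc) and mat.shape != (n_bc, n_feat):
        mat = mat.T  # genes x cells on disk
    elif mat.shape == (n_bc, n_feat):
        pass  # already cells x genes
    elif mat.shape == (n_feat, n_bc):
        mat = mat.T  # square case: adopt the 10x convention
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_feat} features x "
            f"{n_bc} barcodes nor its transpose"
        )

    ncol = min(len(r) for r in feat_rows)
    genes = pd.DataFrame({
        "gene_id": [r[0] for r in feat_rows],
        "symbol": [r[1] if ncol >= 2 else r[0] for r in feat_rows],
    })
    if ncol >= 3 and any(r[2] for r in feat_rows):
        genes["chromosome"] = [r[2] for r in feat_rows]
    elif annotation is not None:
        ann = pd.read_csv(annotation, sep="\t", dtype=str)
        if not {"gene_id", "chromosome"} <= set(ann.columns):
            raise FormatError(
                "annotation TSV needs columns gene_id and chromosome")
        lookup = dict(zip(ann["gene_id"], ann["chromosome"]))
        genes["chromosome"] = [lookup.get(g, "other") for g in genes["gene_id"]]
    else:
        logger.warning(
            "features.tsv has no chromosome column and no annotation table "
            "was given; labelling all genes 'other'")
        genes["chromosome"] = "other"

    counts = sp.csr_matrix(mat)
    counts.data = np.rint(counts.data).astype(np.int64)
    return CountMatrix(barcodes=barcodes, genes=genes, counts=counts)


def write_mtx_counts(matrix: CountMatrix, directory: str | Path) -> None:
    """Write a :class:`CountMatrix` as matrix.mtx + barcodes.tsv + features.tsv.

    The matrix is stored genes x cells with 1-based indices, matching the
    cellranger convention; :func:`read_mtx_counts` restores orientation.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"),
        sp.coo_matrix(matrix.counts.T),
        field="integer",
    )
    with open(directory / "barcodes.tsv", "w") as fh:
        for bc in matrix.barcodes:
            fh.write(f"{bc}\n")
    with open(directory / "features.tsv", "w") as fh:
        for row in matrix.genes.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{row.symbol}\t{row.chromosome}\n")


def read_marker_table(path: str | Path) -> MarkerTable:
    """Read a marker TSV with header columns symbol, stage[, source]."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return MarkerTable(table=table)


def default_marker_fixture_path() -> Path:
    """Path of the packaged 233-row synthetic marker fixture.

    The fixture is a synthetic stand-in mirroring the size and stage
    structure of the published marker compilation, not a reproduction of
    its curated content.
    """
    return Path(resources.files("meiodecay") / "data" / "marker_fixture_synthetic.tsv")
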