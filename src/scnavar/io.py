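"""Count-matrix loading, gene annotation, filtering and log transform.

Counts are held cells x genes in a :class:`CountMatrix` together with a
genome-ordered gene annotation table. On-disk coordinates are 1-based
inclusive; internal gene indices are plain 0-based positions along the
ordered genome.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Chromosome sort order used everywhere. Y and MT are excluded by default
#: because expression-based copy-number inference on them is unreliable.
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end"]


class ParseError(ValueError):
    """Malformed input file."""


class EmptyAfterFilterError(ValueError):
    """No cells or genes survive the preprocessing filters."""


def _chrom_rank(chroms: pd.Series, order: tuple[str, ...]) -> np.ndarray:
    rank = {c: i for i, c in enumerate(order)}
    return chroms.map(rank).to_numpy()


@dataclass
class CountMatrix:
    """Cells x genes expression matrix with per-gene genomic annotation.

    values : dense float array, cells on rows.
    cell_ids : unique barcodes, one per row.
    genes : DataFrame with at least gene_id; after annotation also chrom,
        start, end (1-based inclusive), sorted by (chromosome order, start).
    layer : "raw" counts or "log" (log2(count + 1)).
    """

    values: np.ndarray
    cell_ids: list[str]
    genes: pd.DataFrame
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match row count")
        if len(self.genes) != self.values.shape[1]:
            raise ValueError("gene table length does not match column count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = pd.Series(self.cell_ids).value_counts()
            raise ValueError(
                f"duplicate cell barcodes: {list(dupes[dupes > 1].index[:5])}"
            )
        if self.layer not in ("raw", "log"):
            raise ValueError("layer must be 'raw' or 'log'")
        if self.layer == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw counts must be non-negative")
        self.genes = self.genes.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def chromosome_bounds(self) -> list[tuple[int, int]]:
        """[start, end) gene-index spans of each chromosome block."""
        if "chrom" not in self.genes:
            return [(0, self.n_genes)]
        bounds = []
        chrom = self.genes["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                bounds.append((start, i))
                start = i
        return bounds


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _read_sidecar_ids(path: Path, column: int = 0) -> list[str]:
    return [line.split("\t")[column] for line in _read_lines(path)]


def _find(dirpath: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (dirpath / name, dirpath / (name + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} found in {dirpath}")


def load_counts(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Load a raw count matrix from MTX+sidecars, a 10x directory, or TSV.

    MTX orientation (genes x cells vs cells x genes) is resolved from the
    sidecar row/column label files; dense TSV is genes on rows with a
    header row of cell barcodes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tenx_dir":
        if not path.is_dir():
            raise ParseError(f"{path} is not a directory")
        mtx = _find(path, ["matrix.mtx"])
        genes_f = _find(path, ["features.tsv", "genes.tsv"])
        barcodes_f = _find(path, ["barcodes.tsv"])
        return _load_mtx(mtx, genes_f, barcodes_f)
    if format == "mtx":
        genes_f = _find(path.parent, ["genes.tsv", "features.tsv"])
        barcodes_f = _find(path.parent, ["barcodes.tsv"])
        return _load_mtx(path, genes_f, barcodes_f)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _load_mtx(mtx: Path, genes_f: Path, barcodes_f: Path) -> CountMatrix:
    try:
        mat = scipy.io.mmread(str(mtx))
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"cannot parse MatrixMarket file {mtx}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat).toarray()
    gene_ids = _read_sidecar_ids(genes_f)
    barcodes = _read_sidecar_ids(barcodes_f)
    if mat.shape == (len(gene_ids), len(barcodes)):
        mat = mat.T
    elif mat.shape != (len(barcodes), len(gene_ids)):
        raise ParseError(
            f"matrix shape {mat.shape} matches neither (genes={len(gene_ids)},"
            f" cells={len(barcodes)}) nor its transpose"
        )
    genes = pd.DataFrame({"gene_id": gene_ids})
    return CountMatrix(mat, barcodes, genes, layer="raw")


def _load_tsv(path: Path) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty or unreadable TSV {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"TSV {path} has no data rows/columns")
    genes = pd.DataFrame({"gene_id": df.index.astype(str)})
    return CountMatrix(df.to_numpy(dtype=float).T, list(df.columns.astype(str)), genes)


# ---------------------------------------------------------------------------
# packaged resources


def _resource(name: str):
    return resources.files("scnavar.resources").joinpath(name)


def load_gene_annotation(path: str | Path | None = None) -> pd.DataFrame:
    """Gene coordinate table (gene_id, chrom, start, end[, band]).

    With no path, returns the packaged synthetic example annotation (a
    synthetic stand-in useful for demos; real analyses should pass a
    genome-build-specific table).
    """
    if path is None:
        with resources.as_file(_resource("synthetic_gene_annotation.tsv")) as p:
            ann = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"annotation missing columns {missing}")
    bad = ann["start"] > ann["end"]
    if bad.any():
        raise ParseError(f"annotation rows with start > end: {bad.sum()}")
    return ann.drop_duplicates("gene_id", keep="first")


def load_cell_cycle_genes() -> set[str]:
    """Packaged cell-cycle pathway member genes (symbols, one per line)."""
    return set(_resource("cell_cycle_genes.txt").read_text().split())


def load_signatures(directory: str | Path | None = None) -> dict[str, set[str]]:
    """Stromal/immune signature gene sets; filename stem = signature name."""
    if directory is None:
        sig_dir = _resource("signatures")
        return {
            p.name.removesuffix(".txt"): set(p.read_text().split())
            for p in sig_dir.iterdir()
            if p.name.endswith(".txt")
        }
    directory = Path(directory)
    return {p.stem: set(p.read_text().split()) for p in directory.glob("*.txt")}


# ---------------------------------------------------------------------------
# filtering / transform


def filter_and_annotate(
    cm: CountMatrix,
    ann: pd.DataFrame,
    cc_genes: set[str] | None = None,
    min_genes_per_cell: int = 200,
    min_cell_fraction_per_gene: float = 0.01,
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
) -> CountMatrix:
    """Apply the preprocessing filters and order genes along the genome.

    Cells with fewer than ``min_genes_per_cell`` detected genes (count > 0)
    are removed first; then genes expressed in fewer than
    ``min_cell_fraction_per_gene`` of the remaining cells, genes without a
    coordinate, genes on excluded chromosomes and cell-cycle genes are
    dropped. Surviving genes are sorted by (chromosome order, start).
    """
    if cm.layer != "raw":
        raise ValueError("filter_and_annotate expects raw counts")
    cc_genes = cc_genes or set()

    detected = (cm.values > 0).sum(axis=1)
    keep_cells = detected >= min_genes_per_cell
    if not keep_cells.any():
        raise EmptyAfterFilterError("no cells pass the detected-gene filter")
    values = cm.values[keep_cells]
    cell_ids = [c for c, k in zip(cm.cell_ids, keep_cells) if k]

    frac = (values > 0).mean(axis=0)
    keep_genes = frac >= min_cell_fraction_per_gene

    ann_idx = ann.set_index("gene_id")
    gene_ids = cm.genes["gene_id"]
    annotated = gene_ids.isin(ann_idx.index).to_numpy()
    not_cc = ~gene_ids.isin(cc_genes).to_numpy()
    keep_genes &= annotated & not_cc

    genes = cm.genes[keep_genes].copy()
    values = values[:, keep_genes]
    coords = ann_idx.loc[genes["gene_id"], ["chrom", "start", "end"]]
    genes[["chrom", "start", "end"]] = coords.to_numpy()
    genes["chrom"] = genes["chrom"].astype(str)
    on_chrom = genes["chrom"].isin(chromosomes).to_numpy()
    genes = genes[on_chrom]
    values = values[:, on_chrom]
    if genes.empty:
        raise EmptyAfterFilterError("no genes survive annotation/filters")

    order = np.lexsort(
        (genes["start"].to_numpy(), _chrom_rank(genes["chrom"], chromosomes))
    )
    genes = genes.iloc[order].reset_index(drop=True)
    genes[["start", "end"]] = genes[["start", "end"]].astype(int)
    return CountMatrix(values[:, order], cell_ids, genes, layer="raw")


def log_transform(cm: CountMatrix) -> CountMatrix:
    """log2(count + 1), elementwise; zeros stay zero."""
    if cm.layer == "log":
        warnings.warn("matrix already log-transformed; returning unchanged")
        return cm
    return CountMatrix(np.log2(cm.values + 1.0), list(cm.cell_ids), cm.genes.copy(), layer="log")
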