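"""Synthetic benchmark generator: sparse counts, planted CNAs, dropout.

The generator emulates the study conditions of the published benchmark:

* a highly sparse base count matrix (negative-binomial counts with
  log-normal per-gene means, calibrated so ~94% of entries are zero);
* planted clonal/subclonal alterations: an aneuploid subset of cells
  (30-90% of the sample), 1-10 alterations of 50-1000 genes each, with a
  multiplicative magnitude rho ~ U(0, alpha) applied as x*(1+rho) for
  amplifications and x/(1+rho) for deletions (rounded back to integers);
* optional logistic dropout noise: gene g's non-zero counts are zeroed
  with probability p_g = 1 / (1 + exp(-k (x0 - log mu_g))), so lowly
  expressed genes drop out more.

Scenario I plants only clonal alterations; scenario II assigns each
aneuploid cell to one of two subclones, with the first ceil(n/3)
alterations truncal (both subclones) and the rest alternating between
subclones, so clonal, shared-by-none and subclone-specific events all
exist by construction. The planted truth (breakpoints, labels, copy-ratio
tracks) is serializable to JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .io import CountMatrix

#: base-count calibration. Genes are a two-component population, as in real
#: transcriptomes: a silent majority and an expressed minority with
#: log-normal means and moderate negative-binomial overdispersion. The
#: fractions/means are calibrated so the overall zero fraction is in the
#: ~0.92-0.94 range typical of droplet scRNA-seq.
FRAC_EXPRESSED = 0.13
EXPRESSED_LOGNORMAL = (1.0, 1.2)
SILENT_LOGNORMAL = (-5.5, 1.5)
NB_DISPERSION = 0.5


@dataclass
class SyntheticSpec:
    """Study conditions for one generated matrix."""

    n_cells: int = 500
    n_genes: int = 5000
    aneuploid_fraction: float = 0.6
    n_alterations: int = 5
    alteration_len_range: tuple[int, int] = (50, 1000)
    alpha: float = 4.0
    scenario: str = "I"  # "I" clonal only, "II" two subclones
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.aneuploid_fraction <= 1.0:
            raise ValueError("aneuploid_fraction must be in (0, 1]")
        if not 1 <= self.n_alterations <= 10:
            raise ValueError("n_alterations must be in [1, 10]")
        lo, hi = self.alteration_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid alteration_len_range")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.scenario not in ("I", "II"):
            raise ValueError("scenario must be 'I' or 'II'")


@dataclass
class PlantedAlteration:
    start: int          # gene index, inclusive
    end: int            # gene index, exclusive
    kind: str           # "amp" or "del"
    rho: float
    subclones: tuple[int, ...]  # (0, 1) = truncal; (0,) / (1,) = specific

    @property
    def ratio(self) -> float:
        return (1 + self.rho) if self.kind == "amp" else 1 / (1 + self.rho)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated matrix."""

    breakpoints: list[int]
    cell_labels: list[str]            # "malignant" / "normal" per cell
    clone_labels: list[int]           # subclone id per cell (-1 = normal)
    alterations: list[PlantedAlteration]
    copy_ratio_track: dict[int, list[float]]  # per-clone per-gene multiplier

    def to_json(self, path: str | Path) -> None:
        payload = {
            "breakpoints": self.breakpoints,
            "cell_labels": self.cell_labels,
            "clone_labels": self.clone_labels,
            "alterations": [
                {"start": a.start, "end": a.end, "kind": a.kind,
                 "rho": a.rho, "subclones": list(a.subclones)}
                for a in self.alterations
            ],
            "copy_ratio_track": {str(k): v for k, v in
                                 self.copy_ratio_track.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            breakpoints=list(d["breakpoints"]),
            cell_labels=list(d["cell_labels"]),
            clone_labels=list(d["clone_labels"]),
            alterations=[
                PlantedAlteration(a["start"], a["end"], a["kind"], a["rho"],
                                  tuple(a["subclones"]))
                for a in d["alterations"]
            ],
            copy_ratio_track={int(k): list(v) for k, v in
                              d["copy_ratio_track"].items()},
        )


@dataclass
class DropoutConfig:
    """Logistic dropout: midpoint x0 (log scale), shape k, RNG seed."""

    x0: float = 0.0
    k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


def synthetic_gene_table(n_genes: int, n_chromosomes: int | None = None
                         ) -> pd.DataFrame:
    """Genome-ordered synthetic annotation for generated matrices.

    The synthetic genome is scaled with the matrix: by default one
    chromosome per ~1000 genes (so benchmark alterations of up to 1000
    genes fit inside a chromosome), gene starts 100 kb apart.
    """
    if n_chromosomes is None:
        n_chromosomes = max(1, n_genes // 1000)
    per = int(math.ceil(n_genes / n_chromosomes))
    rows = []
    g = 0
    for c in range(1, n_chromosomes + 1):
        for i in range(per):
            if g >= n_genes:
                break
            start = 100_000 * (i + 1)
            rows.append((f"G{g:05d}", str(c), start, start + 20_000))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def generate_base_counts(n_cells: int, n_genes: int, seed: int = 0,
                         n_chromosomes: int | None = None) -> CountMatrix:
    """Sparse negative-binomial base matrix (all cells diploid).

    Per-gene means are log-normal; NB dispersion is shared. The default
    calibration yields ~94% zeros at typical sizes.
    """
    if n_cells < 1 or n_genes < 1:
        raise ValueError("n_cells and n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    expressed = rng.random(n_genes) < FRAC_EXPRESSED
    mu = np.where(
        expressed,
        rng.lognormal(*EXPRESSED_LOGNORMAL, size=n_genes),
        rng.lognormal(*SILENT_LOGNORMAL, size=n_genes),
    )
    r = NB_DISPERSION
    # NB as Gamma-Poisson: lambda ~ Gamma(r, mu/r), x ~ Poisson(lambda)
    lam = rng.gamma(r, mu[None, :] / r, size=(n_cells, n_genes))
    counts = rng.poisson(lam).astype(float)
    genes = synthetic_gene_table(n_genes, n_chromosomes)
    cells = [f"cell_{i:04d}" for i in range(n_cells)]
    return CountMatrix(counts, cells, genes, layer="raw")


def _draw_alterations(spec: SyntheticSpec, chrom_spans: list[tuple[int, int]],
                      rng: np.random.Generator) -> list[PlantedAlteration]:
    lo, hi = spec.alteration_len_range
    alterations: list[PlantedAlteration] = []
    n_truncal = math.ceil(spec.n_alterations / 3)
    for i in range(spec.n_alterations):
        for attempt in range(100):
            length = int(rng.integers(lo, hi + 1))
            center = int(rng.integers(0, spec.n_genes))
            start = max(0, center - length // 2)
            end = start + length
            span = next(((s, e) for s, e in chrom_spans
                         if s <= center < e), None)
            if span is None or start < span[0] or end > span[1]:
                continue
            if any(a.start < end and start < a.end for a in alterations):
                continue
            break
        else:
            raise RuntimeError(
                "could not place non-overlapping alterations in 100 attempts")
        kind = "amp" if rng.random() < 0.5 else "del"
        rho = float(rng.uniform(0.0, spec.alpha))
        if spec.scenario == "I":
            subclones: tuple[int, ...] = (0,)
        elif i < n_truncal:
            subclones = (0, 1)
        else:
            subclones = ((i - n_truncal) % 2,)
        alterations.append(PlantedAlteration(start, end, kind, rho, subclones))
    return alterations


def plant_alterations(cm: CountMatrix, spec: SyntheticSpec
                      ) -> tuple[CountMatrix, SyntheticTruth]:
    """Plant clonal/subclonal CNAs into a diploid base matrix."""
    rng = np.random.default_rng(spec.seed + 1)
    m, n = cm.values.shape
    if n != spec.n_genes:
        raise ValueError("spec.n_genes does not match the matrix")
    chrom_spans = cm.chromosome_bounds()
    alterations = _draw_alterations(spec, chrom_spans, rng)

    n_aneuploid = max(1, int(round(spec.aneuploid_fraction * m)))
    aneuploid = rng.choice(m, size=n_aneuploid, replace=False)
    clone_labels = np.full(m, -1, dtype=int)
    if spec.scenario == "II":
        half = rng.permutation(n_aneuploid)
        clone_labels[aneuploid[half[: n_aneuploid // 2]]] = 0
        clone_labels[aneuploid[half[n_aneuploid // 2:]]] = 1
    else:
        clone_labels[aneuploid] = 0

    n_clones = 2 if spec.scenario == "II" else 1
    tracks = {c: np.ones(n) for c in range(n_clones)}
    values = cm.values.copy()
    for alt in alterations:
        for clone in alt.subclones:
            if clone >= n_clones:
                continue
            tracks[clone][alt.start:alt.end] *= alt.ratio
            rows = np.where(clone_labels == clone)[0]
            values[np.ix_(rows, np.arange(alt.start, alt.end))] = np.round(
                values[np.ix_(rows, np.arange(alt.start, alt.end))] * alt.ratio)

    # a breakpoint flush with a chromosome end produces no observable step
    chrom_ends = {b for span in chrom_spans for b in span}
    breakpoints = sorted(
        ({a.start for a in alterations} | {a.end for a in alterations})
        - chrom_ends
    )
    truth = SyntheticTruth(
        breakpoints=breakpoints,
        cell_labels=["malignant" if clone_labels[i] >= 0 else "normal"
                     for i in range(m)],
        clone_labels=clone_labels.tolist(),
        alterations=alterations,
        copy_ratio_track={c: t.tolist() for c, t in tracks.items()},
    )
    out = CountMatrix(values, list(cm.cell_ids), cm.genes.copy(), layer="raw")
    return out, truth


def original_gene_indices(genes) -> np.ndarray:
    """Original gene-axis positions encoded in synthetic gene ids (G00042)."""
    return np.array([int("".join(ch for ch in g if ch.isdigit()))
                     for g in genes["gene_id"]], dtype=int)


def dropout_probabilities(cm: CountMatrix, cfg: DropoutConfig) -> np.ndarray:
    """Per-gene zero-replacement probability of the logistic dropout model."""
    mu = cm.values.mean(axis=0)
    return 1.0 / (1.0 + np.exp(-cfg.k * (cfg.x0 - np.log(mu + 1e-8))))


def add_dropout(cm: CountMatrix, cfg: DropoutConfig) -> CountMatrix:
    """Zero out non-zero counts with gene-wise logistic probabilities."""
    if cm.layer != "raw":
        raise ValueError("add_dropout expects raw counts")
    rng = np.random.default_rng(cfg.seed)
    p = dropout_probabilities(cm, cfg)
    drop = rng.random(cm.values.shape) < p[None, :]
    values = np.where(drop & (cm.values > 0), 0.0, cm.values)
    return CountMatrix(values, list(cm.cell_ids), cm.genes.copy(), layer="raw")


def upshift_signature(cm: CountMatrix, rows: np.ndarray, genes: set[str],
                      factor: float = 4.0) -> CountMatrix:
    """Scale signature-gene counts of selected cells (immune-like normals).

    Used to make the generated normal cells detectable by the confident
    non-malignant seeding, emulating the immune compartments of real
    samples.
    """
    mask = cm.genes["gene_id"].isin(genes).to_numpy()
    values = cm.values.copy()
    values[np.ix_(rows, np.where(mask)[0])] = np.round(
        values[np.ix_(rows, np.where(mask)[0])] * factor)
    return CountMatrix(values, list(cm.cell_ids), cm.genes.copy(), layer="raw")


def simulate_dataset(spec: SyntheticSpec,
                     dropout: DropoutConfig | None = None
                     ) -> tuple[CountMatrix, SyntheticTruth]:
    """Base counts + planted alterations (+ optional dropout) in one call."""
    cm = generate_base_counts(spec.n_cells, spec.n_genes, spec.seed)
    cm, truth = plant_alterations(cm, spec)
    if dropout is not None:
        cm = add_dropout(cm, dropout)
    return cm, truth


def write_mtx(cm: CountMatrix, directory: str | Path) -> None:
    """MTX + genes.tsv + barcodes.tsv sidecars (genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(cm.values.T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    cm.genes["gene_id"].to_csv(directory / "genes.tsv", sep="\t",
                               index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t",
                                  index=False, header=False)


def load_benchmark_matrix(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Load an externally published benchmark matrix (MTX or dense TSV)."""
    from .io import load_counts

    return load_counts(path, format=format)
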