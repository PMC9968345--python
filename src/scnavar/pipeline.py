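"""End-to-end workflow orchestration and the synthetic benchmark driver.

``run_pipeline`` chains the stages: preprocess -> confident-normal seeding
-> relative matrix (median baseline, or synthetic baseline for pure
samples) -> edge-preserving smoothing -> joint segmentation (beta = 0.5)
-> malignant/non-malignant classification -> CNA re-baselining -> subclone
clustering -> per-clone re-segmentation (beta = 3.0) -> mixture-model CNV
calling -> alteration characterization -> clone tree. All randomness is
drawn from named sub-seeds of the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as bl
from . import classify as cls
from . import clones as cl
from . import cnv_call as cc
from . import io as io_mod
from . import segment as sg
from . import simulate as sim
from . import smooth as sm
from .config import PipelineConfig, SegConfig
from .evaluate import score_breakpoints

logger = logging.getLogger("scnavar")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineResult:
    """In-memory outputs of one run (also serialized by ``run_pipeline``)."""

    cell_ids: list[str]
    genes: pd.DataFrame
    confident_normals: set[str]
    labels: np.ndarray                   # malignant / non_malignant per cell
    segmentation: sg.Segmentation
    cna: np.ndarray                      # final (re-baselined) CNA matrix
    clones: list[cl.Clone] = field(default_factory=list)
    clone_labels: dict[str, int] = field(default_factory=dict)
    alterations: list[cl.Alteration] = field(default_factory=list)
    newick: str = ""
    manifest: dict = field(default_factory=dict)

    @property
    def malignant_mask(self) -> np.ndarray:
        return np.asarray([lab == cls.MALIGNANT for lab in self.labels])


def run_pipeline(
    cm: io_mod.CountMatrix,
    config: PipelineConfig | None = None,
    annotation: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    signatures: dict[str, set] | None = None,
    preprocessed: bool = False,
    confident_normals: set[str] | None = None,
) -> PipelineResult:
    """Run the full workflow on a raw count matrix.

    ``preprocessed=True`` skips filtering/annotation (the matrix must
    already be genome-ordered with coordinates). ``confident_normals``
    overrides the signature-based seeding (useful for benchmarks with
    known diploid cells).
    """
    config = config or PipelineConfig()
    t0 = time.time()
    stage_times: dict[str, float] = {}

    def tick(name: str) -> None:
        stage_times[name] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.2fs", name, stage_times[name])

    # A: preproc
    if not preprocessed:
        ann = annotation if annotation is not None else io_mod.load_gene_annotation()
        cm = io_mod.filter_and_annotate(
            cm, ann, io_mod.load_cell_cycle_genes(),
            config.min_genes_per_cell, config.min_cell_fraction_per_gene)
    logcm = io_mod.log_transform(cm)
    tick("preprocess")

    # B: confident normals + relative matrix
    if confident_normals is None:
        sigs = signatures if signatures is not None else io_mod.load_signatures()
        confident_normals = bl.identify_confident_normals(
            logcm, sigs, config.p_threshold, config.nes_threshold,
            config.max_confident_normals)
    if confident_normals:
        rm = bl.compute_relative_matrix(
            logcm, confident_normals, config.baseline_statistic)
    else:
        logger.warning("no confident normal cells found; synthetic baseline")
        rm = bl.synthetic_baseline(logcm, seed=derive_seed(config.seed, "baseline"))
    tick("baseline")

    # C: smoothing. Two tracks share one breakpoint structure: breakpoints
    # are found on the per-gene standardized signal (each gene contributes
    # comparable evidence) while segment means are reported on the plain
    # log-ratio scale.
    if config.standardize_genes:
        rm_struct = bl.standardize_genes(rm, logcm, config.gene_sd_floor)
    else:
        rm_struct = rm
    smoothed_struct = sm.edge_preserving_smooth(rm_struct, config.smoothing)
    smoothed = sm.edge_preserving_smooth(rm, config.smoothing)
    tick("smooth")

    # D: joint segmentation
    bounds = smoothed.chromosome_bounds()
    seg = sg.joint_segment(smoothed_struct.values, bounds, config.segmentation)
    cna = sg.build_cna_matrix(smoothed.values, seg)
    tick("segment")

    # E: classification + re-baselining
    seeds = np.array([c in confident_normals for c in logcm.cell_ids])
    clf = cls.MalignantCellClassifier().fit(cna, confident_normals=seeds)
    labels = clf.labels_
    cna = cls.rebaseline_cna(cna, labels)
    # gene-level rebaselined smoothed log-ratios, for clone-level calling
    normal_rows = np.asarray([lab == cls.NON_MALIGNANT for lab in labels])
    rel_final = smoothed.values.copy()
    if normal_rows.any():
        rel_final -= smoothed.values[normal_rows].mean(axis=0)
    tick("classify")

    result = PipelineResult(
        cell_ids=list(logcm.cell_ids),
        genes=logcm.genes,
        confident_normals=set(confident_normals),
        labels=labels,
        segmentation=seg,
        cna=cna,
    )

    # F-H: clonal deconvolution on the malignant cells
    mal = result.malignant_mask
    mal_cells = [c for c, m in zip(result.cell_ids, mal) if m]
    clone_cfg = config.clones
    if mal.sum() >= 2 * clone_cfg.min_clone_size:
        comm = cl.cluster_subclones(
            cna[mal], clone_cfg.k_neighbors, clone_cfg.resolution,
            derive_seed(config.seed, "louvain"))
        clones = []
        for cid in np.unique(comm):
            cells = [mal_cells[i] for i in np.where(comm == cid)[0]]
            if len(cells) < clone_cfg.min_clone_size:
                logger.warning("clone %d dropped (%d cells)", cid, len(cells))
                continue
            clones.append(cl.Clone(int(cid), cells))
        row_of = {c: i for i, c in enumerate(result.cell_ids)}
        model = None
        for clone in clones:
            rows = [row_of[c] for c in clone.cells]
            clone.segmentation = cl.resegment_clone(
                smoothed_struct.values[rows], bounds,
                SegConfig(beta=clone_cfg.beta_clonal))
            if model is None:
                model = cc.TruncatedNormalMixture(config.mixture)
                pooled = sg.segment_means(rel_final[mal], clone.segmentation)
                model.fit(pooled.ravel())
            clone.calls = cc.call_segment_states(
                rel_final[rows], clone.segmentation, result.genes, model)
        if clones:
            cell_index = {c: i for i, c in enumerate(mal_cells)}
            alterations, kept = cl.characterize_clones(
                clones, cna[mal], cell_index, clone_cfg)
            result.clones = kept
            result.alterations = alterations
            result.clone_labels = {
                cell: clone.clone_id for clone in kept for cell in clone.cells}
            result.newick = cl.build_clone_tree(kept) if kept else ""
    tick("clones")

    result.manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_cells": len(result.cell_ids),
        "n_genes": len(result.genes),
        "n_confident_normals": len(result.confident_normals),
        "n_malignant": int(mal.sum()),
        "n_clones": len(result.clones),
        "n_breakpoints": len(seg.breakpoints),
        "stage_seconds": stage_times,
    }
    if out_dir is not None:
        _write_outputs(result, smoothed.values, out_dir)
    return result


def _write_outputs(result: PipelineResult, smoothed: np.ndarray,
                   out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "cell_id": result.cell_ids,
        "label": list(result.labels),
        "cluster_id": [result.clone_labels.get(c, -1) for c in result.cell_ids],
        "was_confident_seed": [c in result.confident_normals
                               for c in result.cell_ids],
    }).to_csv(out / "classification.tsv", sep="\t", index=False)
    sg.write_seg(result.segmentation, smoothed, result.cell_ids,
                 result.genes, out / "segments.seg")
    sg.write_breakpoints(result.segmentation, result.genes,
                         out / "breakpoints.tsv")
    if result.clone_labels:
        pd.DataFrame(sorted(result.clone_labels.items()),
                     columns=["cell_id", "clone_id"]).to_csv(
            out / "clones.tsv", sep="\t", index=False)
    if result.alterations:
        pd.DataFrame([
            {"chrom": a.chrom, "start": a.start_bp, "end": a.end_bp,
             "state": a.state, "category": a.category,
             "clone_ids": ",".join(map(str, sorted(a.clone_ids)))}
            for a in result.alterations
        ]).to_csv(out / "alterations.tsv", sep="\t", index=False)
    if result.newick:
        (out / "clone_tree.nwk").write_text(result.newick + "\n")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def run_benchmark(grid: list[dict], out_path: str | Path | None = None,
                  tolerance: int = 20) -> dict:
    """Generate matrices per grid entry, run the pipeline, aggregate scores.

    Each grid entry maps to :class:`~scnavar.simulate.SyntheticSpec`
    fields plus ``n_matrices``. The report holds per-matrix breakpoint and
    classification F1 plus their means.
    """
    report: dict = {"runs": [], "tolerance": tolerance}
    for entry in grid:
        entry = dict(entry)
        n_matrices = int(entry.pop("n_matrices", 1))
        base_seed = int(entry.pop("seed", 0))
        scores = []
        for i in range(n_matrices):
            spec = sim.SyntheticSpec(**entry, seed=base_seed + i)
            scores.append(benchmark_one(spec, tolerance)[0])
        agg = {
            "spec": {**entry, "n_matrices": n_matrices, "seed": base_seed},
            "per_matrix": scores,
            "mean_breakpoint_f1": float(np.mean(
                [s["breakpoint_f1"] for s in scores])) if scores else None,
            "mean_classification_f1": float(np.mean(
                [s["classification_f1"] for s in scores])) if scores else None,
        }
        report["runs"].append(agg)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report


def benchmark_one(spec: sim.SyntheticSpec, tolerance: int = 20,
                  n_seed_normals: int = 30,
                  config: PipelineConfig | None = None,
                  dropout: sim.DropoutConfig | None = None) -> tuple[dict, PipelineResult, sim.SyntheticTruth]:
    """One synthetic matrix end to end: breakpoint + classification scores.

    The full pipeline is run, including the 1%-of-cells gene filter (the
    detected-gene cell filter is scaled to the synthetic panel size);
    predicted breakpoints are mapped back to the original gene axis before
    scoring against the planted truth. A handful of known diploid cells
    seed the baseline — the benchmark analogue of confident immune cells
    in real samples.
    """
    cm, truth = sim.simulate_dataset(spec, dropout)
    normal_ids = [c for c, lab in zip(cm.cell_ids, truth.cell_labels)
                  if lab == "normal"]
    rng = np.random.default_rng(derive_seed(spec.seed, "seed-normals"))
    k = min(n_seed_normals, len(normal_ids))
    seeds = set(rng.choice(normal_ids, size=k, replace=False)) if k else set()
    if config is None:
        config = PipelineConfig(seed=spec.seed)
        # detected-gene threshold scaled to the synthetic panel size
        config.min_genes_per_cell = max(1, spec.n_genes // 100)
    result = run_pipeline(cm, config, annotation=cm.genes,
                          confident_normals=seeds)
    # map breakpoints from the filtered gene axis back to planted coordinates
    orig = sim.original_gene_indices(result.genes)
    pred = [int(orig[min(b, len(orig) - 1)])
            for b in result.segmentation.interior_breakpoints]
    sc = score_breakpoints(pred, truth.breakpoints, tolerance)
    truth_label = dict(zip(cm.cell_ids, truth.cell_labels))
    truth_mal = np.array([truth_label[c] == "malignant"
                          for c in result.cell_ids])
    pred_mal = result.malignant_mask
    tp = int((truth_mal & pred_mal).sum())
    fp = int((~truth_mal & pred_mal).sum())
    fn = int((truth_mal & ~pred_mal).sum())
    cls_f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    scores = {
        "seed": spec.seed,
        "breakpoint_f1": sc.f1,
        "breakpoint_precision": sc.precision,
        "breakpoint_recall": sc.recall,
        "classification_f1": cls_f1,
        "n_clones": len(result.clones),
    }
    return scores, result, truth
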