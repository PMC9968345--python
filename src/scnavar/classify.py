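"""Malignant vs non-malignant cell classification from the CNA matrix.

Cells are clustered into two groups (Ward hierarchical clustering on the
intermediate CNA matrix); the cluster containing the majority of the
confident normal seeds is labelled non-malignant and the other malignant.
With no confident seeds the sample is assumed pure: every cell is
malignant. The final CNA matrix is re-baselined by subtracting the
per-gene mean of the identified normal cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator

MALIGNANT = "malignant"
NON_MALIGNANT = "non_malignant"


@dataclass
class CellClassification:
    cell_id: str
    label: str
    cluster_id: int
    was_confident_seed: bool


class MalignantCellClassifier(BaseEstimator):
    """Two-group aneuploidy classifier over CNA-matrix rows.

    Parameters
    ----------
    linkage, metric : hierarchical-clustering settings (Ward/Euclidean).

    Attributes (after ``fit``)
    --------------------------
    labels_ : array of {"malignant", "non_malignant"} per cell
    cluster_ids_ : two-group cluster assignment (0/1)
    normal_cluster_ : id of the non-malignant cluster, or None (pure sample)
    """

    def __init__(self, linkage: str = "ward", metric: str = "euclidean"):
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None, confident_normals: np.ndarray | None = None):
        """``confident_normals`` is a boolean mask over rows (seed cells)."""
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
        seeds = (
            np.zeros(m, dtype=bool)
            if confident_normals is None
            else np.asarray(confident_normals, dtype=bool)
        )
        if m < 2:
            self.cluster_ids_ = np.zeros(m, dtype=int)
        else:
            Z = sch.linkage(X, method=self.linkage, metric=self.metric)
            self.cluster_ids_ = sch.fcluster(Z, t=2, criterion="maxclust") - 1
        if not seeds.any():
            warnings.warn(
                "no confident normal cells: assuming a pure tumor sample"
            )
            self.normal_cluster_ = None
            self.labels_ = np.full(m, MALIGNANT, dtype=object)
            return self
        counts = [int(seeds[self.cluster_ids_ == k].sum()) for k in (0, 1)]
        if counts[0] != counts[1]:
            normal = int(np.argmax(counts))
        else:
            # tie: the cluster closer to baseline (lower mean |CNA|) is normal
            mags = [
                float(np.abs(X[self.cluster_ids_ == k]).mean()) for k in (0, 1)
            ]
            normal = int(np.argmin(mags))
        self.normal_cluster_ = normal
        self.labels_ = np.where(
            self.cluster_ids_ == normal, NON_MALIGNANT, MALIGNANT
        ).astype(object)
        return self

    def fit_predict(self, X, y=None, confident_normals=None):
        return self.fit(X, confident_normals=confident_normals).labels_


def classify_cells(
    cna: np.ndarray, cell_ids: list[str], confident_normals: set[str]
) -> list[CellClassification]:
    """Functional wrapper; order of the result follows ``cell_ids``."""
    seeds = np.array([c in confident_normals for c in cell_ids], dtype=bool)
    clf = MalignantCellClassifier().fit(cna, confident_normals=seeds)
    return [
        CellClassification(c, clf.labels_[i], int(clf.cluster_ids_[i]), bool(seeds[i]))
        for i, c in enumerate(cell_ids)
    ]


def rebaseline_cna(
    cna: np.ndarray, labels: np.ndarray | list[str]
) -> np.ndarray:
    """Subtract the per-gene mean of non-malignant rows from every row."""
    cna = np.asarray(cna, dtype=float)
    mask = np.asarray([lab == NON_MALIGNANT for lab in labels], dtype=bool)
    if not mask.any():
        return cna.copy()
    return cna - cna[mask].mean(axis=0)
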