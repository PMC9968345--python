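"""Clonal substructure deconvolution of the malignant cells.

Malignant cells are clustered on their CNA-matrix rows with Louvain
community detection over a shared nearest-neighbor (SNN) graph; each
community is a candidate subclone and is re-segmented with a coarser
stopping constant (beta = 3.0 by default). Segment calls are reduced to
alterations (non-neutral runs, merging same-state segments closer than
10 Mb), alterations are matched across clones (boundary within 10 Mb and
size difference under 40%, same state) and labelled clonal (all clones),
shared (a subset) or specific (one clone). Clones with no specific
alteration are dissolved into their best-correlated surviving clone. A
clone tree is built by neighbor joining on Manhattan distances between
consensus state vectors, rooted at an all-neutral pseudo-clone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

from .cnv_call import NEUTRAL, SegmentCall
from .config import CloneConfig, SegConfig
from .segment import Segmentation, joint_segment


@dataclass
class Clone:
    clone_id: int
    cells: list[str]
    segmentation: Segmentation | None = None
    calls: list[SegmentCall] = field(default_factory=list)


@dataclass
class Alteration:
    chrom: str
    start_bp: int
    end_bp: int
    state: int
    clone_ids: set[int] = field(default_factory=set)
    category: str = ""

    @property
    def size(self) -> int:
        return self.end_bp - self.start_bp

    def __post_init__(self) -> None:
        if self.state == NEUTRAL:
            raise ValueError("an alteration cannot be copy-neutral")


class SubcloneClusterer(ClusterMixin, BaseEstimator):
    """Louvain communities on an SNN graph of CNA-matrix rows.

    Edges connect mutual k-nearest neighbours weighted by the Jaccard
    overlap of their neighbour sets; Louvain is run with a fixed seed so
    results are deterministic.

    Attributes (after ``fit``)
    --------------------------
    labels_ : community index per row (0-based, by decreasing size)
    """

    def __init__(self, k_neighbors: int = 10, resolution: float = 1.0,
                 seed: int = 0):
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
        k = min(self.k_neighbors, m - 1)
        # degenerate input: identical rows carry no partition information
        if k < 1 or np.allclose(X, X[0]):
            self.labels_ = np.zeros(m, dtype=int)
            return self
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        neigh = [set(row[1:]) for row in idx]
        g = nx.Graph()
        g.add_nodes_from(range(m))
        for i in range(m):
            for j in neigh[i]:
                if i < j:
                    inter = len(neigh[i] & neigh[j])
                    union = len(neigh[i] | neigh[j])
                    w = inter / union if union else 0.0
                    if w > 0:
                        g.add_edge(i, int(j), weight=w)
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=self.resolution, seed=self.seed)
        comms = sorted(comms, key=lambda c: (-len(c), min(c)))
        labels = np.zeros(m, dtype=int)
        for lab, comm in enumerate(comms):
            for node in comm:
                labels[node] = lab
        self.labels_ = labels
        return self


def cluster_subclones(cna_tumor: np.ndarray, k_neighbors: int = 10,
                      resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Community label per malignant cell (deterministic given seed)."""
    return SubcloneClusterer(k_neighbors, resolution, seed).fit(cna_tumor).labels_


def resegment_clone(smoothed_rows: np.ndarray,
                    chrom_bounds: list[tuple[int, int]],
                    cfg: SegConfig | None = None) -> Segmentation:
    """Re-run joint segmentation on one clone's cells with coarser beta."""
    cfg = cfg or SegConfig(beta=3.0)
    return joint_segment(smoothed_rows, chrom_bounds, cfg)


def merge_adjacent_alterations(calls: list[SegmentCall],
                               clone_id: int = 0,
                               merge_gap_bp: int = 10_000_000) -> list[Alteration]:
    """Collapse consecutive same-state non-neutral segments closer than 10 Mb."""
    alterations: list[Alteration] = []
    current: Alteration | None = None
    for call in calls:
        if call.consensus_state == NEUTRAL:
            continue
        if (current is not None
                and call.chrom == current.chrom
                and call.consensus_state == current.state
                and call.start_bp - current.end_bp < merge_gap_bp):
            current.end_bp = max(current.end_bp, call.end_bp)
            continue
        current = Alteration(call.chrom, call.start_bp, call.end_bp,
                             call.consensus_state, {clone_id})
        alterations.append(current)
    return alterations


def match_alterations(a: Alteration, b: Alteration,
                      distance_bp: int = 10_000_000,
                      size_frac: float = 0.40) -> bool:
    """Same alteration in two clones?

    True iff same chromosome and state, a start or end boundary within
    ``distance_bp``, and a relative size difference below ``size_frac``.
    """
    if a.chrom != b.chrom or a.state != b.state:
        return False
    boundary_close = (abs(a.start_bp - b.start_bp) < distance_bp
                      or abs(a.end_bp - b.end_bp) < distance_bp)
    size_close = (abs(a.size - b.size) / max(a.size, b.size)) < size_frac
    return boundary_close and size_close


def _group_alterations(per_clone: dict[int, list[Alteration]],
                       cfg: CloneConfig) -> list[Alteration]:
    """Single-linkage transitive closure of pairwise matches across clones."""
    flat = [(cid, alt) for cid, alts in per_clone.items() for alt in alts]
    n = len(flat)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, ai = flat[i]
            cj, aj = flat[j]
            if ci != cj and match_alterations(
                    ai, aj, cfg.match_distance_bp, cfg.match_size_frac):
                g.add_edge(i, j)
    n_clones = len(per_clone)
    groups: list[Alteration] = []
    for comp in nx.connected_components(g):
        members = [flat[i] for i in sorted(comp)]
        clone_ids = {cid for cid, _ in members}
        rep = Alteration(
            chrom=members[0][1].chrom,
            start_bp=min(a.start_bp for _, a in members),
            end_bp=max(a.end_bp for _, a in members),
            state=members[0][1].state,
            clone_ids=clone_ids,
        )
        if len(clone_ids) == n_clones:
            rep.category = "clonal"
        elif len(clone_ids) == 1:
            rep.category = "specific"
        else:
            rep.category = "shared"
        groups.append(rep)
    groups.sort(key=lambda a: (a.chrom, a.start_bp))
    return groups


def characterize_clones(
    clones: list[Clone],
    cna_tumor: np.ndarray,
    cell_index: dict[str, int],
    cfg: CloneConfig | None = None,
) -> tuple[list[Alteration], list[Clone]]:
    """Label alterations clonal/shared/specific; dissolve redundant clones.

    Clones with zero specific alterations are dissolved one at a time
    (smallest first) and their cells reassigned to the surviving clone
    whose mean CNA profile correlates best; categories are recomputed
    after each dissolution. A single clone trivially has all its
    alterations clonal.
    """
    cfg = cfg or CloneConfig()
    clones = [c for c in clones if c.cells]
    if not clones:
        return [], []
    while True:
        per_clone = {
            c.clone_id: merge_adjacent_alterations(
                c.calls, c.clone_id, cfg.merge_gap_bp)
            for c in clones
        }
        groups = _group_alterations(per_clone, cfg)
        if len(clones) <= 1:
            return groups, clones
        has_specific = {
            c.clone_id: any(c.clone_id in g.clone_ids and g.category == "specific"
                            for g in groups)
            for c in clones
        }
        weak = [c for c in clones if not has_specific[c.clone_id]]
        if not weak:
            return groups, clones
        victim = min(weak, key=lambda c: (len(c.cells), c.clone_id))
        survivors = [c for c in clones if c.clone_id != victim.clone_id]
        if not survivors:
            return groups, clones
        profiles = {
            c.clone_id: cna_tumor[[cell_index[x] for x in c.cells]].mean(axis=0)
            for c in survivors
        }
        for cell in victim.cells:
            row = cna_tumor[cell_index[cell]]
            best = max(
                survivors,
                key=lambda c: _safe_corr(row, profiles[c.clone_id]),
            )
            best.cells.append(cell)
        clones = survivors


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def clone_state_vectors(clones: list[Clone]) -> dict[int, np.ndarray]:
    """Per-clone gene-level consensus state vector (neutral = 2)."""
    vectors = {}
    for clone in clones:
        if clone.segmentation is None:
            continue
        n = clone.segmentation.breakpoints[-1]
        vec = np.full(n, NEUTRAL, dtype=float)
        for call, region in zip(clone.calls, clone.segmentation.regions):
            vec[region.start:region.end] = call.consensus_state
        vectors[clone.clone_id] = vec
    return vectors


def build_clone_tree(clones: list[Clone]) -> str:
    """Newick clone tree: neighbor joining on Manhattan state distances.

    The tree includes an all-neutral pseudo-clone ("diploid") as the
    outgroup/root. With a single clone a one-leaf tree is returned.
    """
    if not clones:
        raise ValueError("no clones")
    vectors = clone_state_vectors(clones)
    ids = sorted(vectors)
    if len(ids) == 1:
        return f"(clone_{ids[0]}:0.0,diploid:0.0);"
    names = [f"clone_{i}" for i in ids] + ["diploid"]
    n = len(vectors[ids[0]])
    mats = [vectors[i] for i in ids] + [np.full(n, NEUTRAL, dtype=float)]
    dist = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = float(np.abs(mats[i] - mats[j]).sum())
            dist[i, j] = dist[j, i] = d
    if len(names) < 3:  # pragma: no cover - unreachable (>=2 clones + root)
        return f"({names[0]}:0.0,{names[1]}:{dist[0, 1]});"
    tree = nj(DistanceMatrix(dist, ids=names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rooted = tree.root_at(tree.find("diploid").parent)
    return _to_newick(rooted)


def _to_newick(tree) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
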