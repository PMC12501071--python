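"""Recurrent gene-module (meta-program) discovery across tumors.

The procedure has four steps, run on log-normalized steroid-cell expression:

1. Per tumor, PCA on centered (unscaled) genes x cells; for each of the
   first 10 components emit two candidate modules — the top 50 genes by
   positive loading and the top 50 by negative loading.  Tumors with fewer
   than 250 cells are skipped.
2. Compute pairwise Sørensen indexes 2|A∩B|/(|A|+|B|) between candidate
   modules and discard modules associated (index >= 0.4) with fewer than
   2 other modules.
3. Cluster the filtered similarity matrix (average linkage on 1 - Sørensen)
   and cut the dendrogram to obtain clusters of modules spanning >= 3
   distinct source tumors.
4. Within each cluster keep the genes contributed by >= 50% of the
   cluster's tumors; these are the consensus (recurrent) modules.

Cells are then scored per consensus module with expression-bin-matched
control genes and labeled with the maximal-score module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.decomposition import PCA

from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModule",
    "ConsensusModule",
    "extract_candidate_modules",
    "sorensen_index",
    "similarity_matrix",
    "filter_nonrecurrent",
    "cluster_modules",
    "derive_consensus_genes",
    "discover_consensus_modules",
    "score_cells",
]


@dataclass
class GeneModule:
    """One signed candidate module from one tumor's PCA component."""

    id: str
    source_tumor: str
    component_index: int      # 1-based
    sign: str                 # "+" or "-"
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.id}: duplicate genes")


@dataclass
class ConsensusModule:
    """A recurrent module: member candidate modules from >= min_tumors tumors
    and the genes found in >= 50% of those tumors."""

    id: str
    member_ids: list[str]
    tumors: list[str]
    genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# step (i): per-tumor candidate modules
# ---------------------------------------------------------------------------

def extract_candidate_modules(nm: NormalizedMatrix, tumor: str,
                              n_components: int = 10, top_k: int = 50,
                              min_cells: int = 250) -> list[GeneModule]:
    """PCA one tumor's cells and emit two signed top-k modules per component.

    ``nm`` must already be restricted to the tumor's steroid cells (or carry
    only that tumor; cells are selected by the ``sample`` metadata column).
    Zero-variance genes are excluded before the decomposition.  Ties in the
    loading ranking break by gene id, lexicographically.
    """
    mask = (nm.sample_of == tumor).to_numpy()
    n_cells = int(mask.sum())
    if n_cells < min_cells:
        logger.info("tumor %s skipped: limited number of steroid cells "
                    "(<%d): %d", tumor, min_cells, n_cells)
        return []
    X = nm.values[:, mask].T                      # cells x genes
    var = X.var(axis=0)
    keep = var > 0
    X = X[:, keep]
    gene_ids = nm.gene_ids[keep]
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X - X.mean(axis=0, keepdims=True))
    modules: list[GeneModule] = []
    for c in range(n_comp):
        loadings = pca.components_[c]
        for sign, order_key in (("+", -loadings), ("-", loadings)):
            # stable two-key sort: loading first, gene id to break ties
            idx = np.lexsort((gene_ids.astype(str), order_key))[:top_k]
            modules.append(GeneModule(
                id=f"{tumor}|PC{c + 1}{sign}",
                source_tumor=tumor,
                component_index=c + 1,
                sign=sign,
                genes=list(gene_ids[idx]),
            ))
    return modules


# ---------------------------------------------------------------------------
# step (ii): Sørensen similarity and neighbor filtering
# ---------------------------------------------------------------------------

def sorensen_index(a, b) -> float:
    """Sørensen (Dice) index 2|A∩B| / (|A|+|B|), in [0, 1]."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Sørensen index undefined for empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def similarity_matrix(modules: list[GeneModule]) -> pd.DataFrame:
    """Symmetric module x module Sørensen matrix (diagonal 1)."""
    ids = [m.id for m in modules]
    sets = [set(m.genes) for m in modules]
    n = len(modules)
    S = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        s = 2.0 * len(sets[i] & sets[j]) / (len(sets[i]) + len(sets[j]))
        S[i, j] = S[j, i] = s
    return pd.DataFrame(S, index=ids, columns=ids)


def filter_nonrecurrent(sim: pd.DataFrame, sim_threshold: float = 0.4,
                        min_neighbors: int = 2) -> pd.DataFrame:
    """Keep modules with >= min_neighbors other modules at similarity >=
    sim_threshold.  Applied in a single pass (not iterated)."""
    S = sim.to_numpy().copy()
    np.fill_diagonal(S, 0.0)
    n_neighbors = (S >= sim_threshold).sum(axis=1)
    keep = n_neighbors >= min_neighbors
    kept = list(sim.index[keep])
    logger.info("filter_nonrecurrent: kept %d/%d modules", len(kept), len(sim))
    return sim.loc[kept, kept]


# ---------------------------------------------------------------------------
# step (iii): clustering into recurrent modules
# ---------------------------------------------------------------------------

def _tumor_of(module_id: str) -> str:
    return module_id.split("|")[0]


def cluster_modules(sim_filtered: pd.DataFrame, min_tumors: int = 3,
                    tumor_of=None) -> list[ConsensusModule]:
    """Average-linkage clustering on 1 - Sørensen; keep clusters spanning
    >= min_tumors distinct source tumors.

    Partitions are scanned from finest (every module its own cluster) to
    coarsest; the retained partition is the one maximizing the number of
    clusters that span >= min_tumors tumors, ties resolved toward the finer
    cut.  Clusters failing the tumor criterion at that cut are dropped, not
    merged further.  Deterministic given the input.
    """
    if tumor_of is None:
        tumor_of = _tumor_of
    ids = list(sim_filtered.index)
    if len(ids) == 0:
        return []
    tumors = np.array([tumor_of(i) for i in ids])
    if len(ids) == 1:
        return []
    D = 1.0 - sim_filtered.to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = sch.linkage(ssd.squareform(D, checks=False), method="average")

    best: tuple[int, int] | None = None   # (n_good, n_clusters)
    best_labels = None
    for n_clusters in range(len(ids), 0, -1):
        labels = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
        n_good = sum(
            1 for lab in np.unique(labels)
            if len(set(tumors[labels == lab])) >= min_tumors)
        if best is None or n_good > best[0]:
            best = (n_good, n_clusters)
            best_labels = labels
    if best is None or best[0] == 0:
        logger.info("cluster_modules: no cluster spans >= %d tumors",
                    min_tumors)
        return []
    labels = best_labels
    clusters = []
    for lab in np.unique(labels):
        members = [ids[i] for i in np.flatnonzero(labels == lab)]
        tu = sorted({str(t) for t in tumors[labels == lab]})
        if len(tu) < min_tumors:
            continue
        clusters.append(ConsensusModule(
            id=f"CM{len(clusters) + 1}", member_ids=members, tumors=tu))
    logger.info("cluster_modules: %d recurrent clusters at %d-cluster cut",
                len(clusters), best[1])
    return clusters


# ---------------------------------------------------------------------------
# step (iv): consensus genes
# ---------------------------------------------------------------------------

def derive_consensus_genes(cluster: ConsensusModule,
                           modules: list[GeneModule],
                           recurrence_fraction: float = 0.5,
                           tumor_of=None) -> ConsensusModule:
    """Keep genes contributed by >= recurrence_fraction of the cluster's
    tumors (inclusive).  A gene present in both signed modules of one tumor
    counts that tumor once."""
    if tumor_of is None:
        tumor_of = _tumor_of
    by_id = {m.id: m for m in modules}
    gene_tumors: dict[str, set[str]] = {}
    for mid in cluster.member_ids:
        m = by_id[mid]
        for g in m.genes:
            gene_tumors.setdefault(g, set()).add(m.source_tumor)
    n_tumors = len(cluster.tumors)
    genes = sorted(g for g, tu in gene_tumors.items()
                   if len(tu) / n_tumors >= recurrence_fraction)
    if not genes:
        logger.warning("cluster %s: empty consensus gene list; dropped",
                       cluster.id)
    return ConsensusModule(id=cluster.id, member_ids=cluster.member_ids,
                           tumors=cluster.tumors, genes=genes)


def discover_consensus_modules(nm: NormalizedMatrix,
                               n_components: int = 10, top_k: int = 50,
                               min_cells: int = 250,
                               sim_threshold: float = 0.4,
                               min_neighbors: int = 2, min_tumors: int = 3,
                               recurrence_fraction: float = 0.5,
                               ) -> tuple[list[ConsensusModule],
                                          list[GeneModule], pd.DataFrame]:
    """Run steps (i)-(iv) end to end over all tumors in ``nm``.

    Returns (consensus modules with genes, all candidate modules, the full
    similarity matrix).
    """
    candidates: list[GeneModule] = []
    for tumor in sorted(pd.unique(nm.sample_of)):
        candidates.extend(extract_candidate_modules(
            nm, tumor, n_components=n_components, top_k=top_k,
            min_cells=min_cells))
    if not candidates:
        return [], [], pd.DataFrame()
    sim = similarity_matrix(candidates)
    sim_f = filter_nonrecurrent(sim, sim_threshold, min_neighbors)
    clusters = cluster_modules(sim_f, min_tumors=min_tumors)
    consensus = [derive_consensus_genes(c, candidates, recurrence_fraction)
                 for c in clusters]
    consensus = [c for c in consensus if c.genes]
    return consensus, candidates, sim


# ---------------------------------------------------------------------------
# per-cell module scoring and labeling
# ---------------------------------------------------------------------------

def score_cells(nm: NormalizedMatrix, consensus: list[ConsensusModule],
                n_bins: int = 25, n_ctrl: int = 50,
                seed: int = 0) -> pd.DataFrame:
    """Score each consensus module in each cell and label cells by argmax.

    Score = mean normalized expression of the module's genes minus the mean
    of expression-bin-matched control genes (``n_ctrl`` controls per module
    gene, drawn from the gene's mean-expression bin with the given seed).
    Ties in the argmax break toward the lexicographically smallest module id.
    """
    if not consensus:
        raise ValueError("no consensus modules to score")
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    mean_expr = nm.values.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(np.arange(nm.n_genes) * n_bins // nm.n_genes,
                             n_bins - 1)
    bin_members = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    scores = {}
    for cm in sorted(consensus, key=lambda c: c.id):
        idx = [gene_index[g] for g in cm.genes if g in gene_index]
        missing = len(cm.genes) - len(idx)
        if missing:
            logger.warning("module %s: %d genes absent from matrix", cm.id,
                           missing)
        if not idx:
            raise ValueError(f"module {cm.id}: no genes present in matrix")
        ctrl_idx: list[np.ndarray] = []
        for gi in idx:
            pool = bin_members[bins[gi]]
            ctrl_idx.append(rng.choice(pool, size=n_ctrl,
                                       replace=len(pool) < n_ctrl))
        ctrl = np.concatenate(ctrl_idx)
        scores[cm.id] = (nm.values[idx].mean(axis=0)
                         - nm.values[ctrl].mean(axis=0))

    table = pd.DataFrame(scores, index=nm.barcodes)
    # argmax with lexicographic tie-break: columns already sorted by id
    table["label"] = table.idxmax(axis=1)
    n_ties = int((table.drop(columns="label").to_numpy()
                  == table.drop(columns="label").max(axis=1)
                  .to_numpy()[:, None]).sum(axis=1).max())
    if n_ties > 1:
        logger.info("score_cells: ties observed in argmax labeling")
    return table
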