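"""Bulk-transcriptome signature scoring and cell-fraction deconvolution.

Gene modules are scored per bulk sample with single-sample GSEA (the
rank-weighted running-sum statistic, exponent 0.25).  Microenvironment cell
fractions are estimated by non-negative least squares of each bulk profile
on a single-cell-derived signature matrix (population mean profiles over
marker genes; populations with fewer than 50 cells are excluded), with
coefficients renormalized onto the simplex.  A split-validation protocol
holds out cells, forms a pseudobulk from them and checks that deconvolved
fractions track the true held-out proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.stats

from .io import BulkCohort, CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["SignatureMatrix", "ssgsea", "ssgsea_table",
           "build_signature_matrix", "deconvolve", "split_validate"]


@dataclass
class SignatureMatrix:
    """Genes x populations mean reference profile with cell counts used."""

    profiles: pd.DataFrame         # genes x populations, non-negative
    cell_counts: pd.Series         # population -> n cells

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("signature profiles must be non-negative")

    @property
    def populations(self) -> list[str]:
        return list(self.profiles.columns)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea(expr: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment of ``gene_set`` in one expression profile.

    Genes are ranked by expression, descending, with average ranks for ties.
    Walking down the ranking, the in-set cumulative weight (rank^alpha,
    normalized) is compared to the out-set cumulative count (normalized);
    the score is the sum of the differences over all positions.  When the
    gene set covers every gene the statistic degenerates to 0.
    """
    genes = np.asarray(expr.index, dtype=object)
    in_set = np.isin(genes, list(set(gene_set)))
    if not in_set.any():
        raise ValueError("gene set does not intersect the expressed genes")
    values = expr.to_numpy(dtype=float)
    # rank 1 = lowest expression; average ranks on ties; weight by rank^alpha
    ranks = scipy.stats.rankdata(values, method="average")
    order = np.lexsort((genes.astype(str), -ranks))   # descending rank
    in_ord = in_set[order]
    r_ord = ranks[order]

    n = len(genes)
    n_in = int(in_set.sum())
    if n_in == n:
        return 0.0
    w = np.where(in_ord, np.abs(r_ord) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ord) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_table(cohort: BulkCohort, gene_sets: dict[str, list[str]],
                 alpha: float = 0.25,
                 normalize_range: bool = False) -> pd.DataFrame:
    """Samples x gene-sets ssGSEA score table for a bulk cohort.

    ``normalize_range`` optionally rescales each column by the overall range
    of scores across samples and sets (off by default).
    """
    rows = {}
    for sample in cohort.expr.index:
        profile = cohort.expr.loc[sample]
        rows[sample] = {name: ssgsea(profile, gs, alpha=alpha)
                        for name, gs in gene_sets.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.loc[cohort.expr.index, list(gene_sets)]
    if normalize_range:
        rng = table.to_numpy().max() - table.to_numpy().min()
        if rng > 0:
            table = table / rng
    return table


# ---------------------------------------------------------------------------
# signature matrix and deconvolution
# ---------------------------------------------------------------------------

def _depth_normalized(counts: np.ndarray) -> np.ndarray:
    depth = counts.sum(axis=0, keepdims=True).astype(float)
    depth[depth == 0] = 1.0
    return counts / depth * float(np.median(depth))


def build_signature_matrix(cm: CountMatrix, labels: pd.Series | np.ndarray,
                           marker_genes=None,
                           min_cells_signature: int = 50) -> SignatureMatrix:
    """Population mean profiles over marker genes.

    ``labels`` assigns a population to every cell; ``marker_genes`` is the
    gene space (typically the union of cluster markers from
    :func:`snatlas.qc.detect_markers`); when omitted, all genes are used.
    Populations with fewer than ``min_cells_signature`` cells are excluded.
    Near-duplicate (collinear) columns trigger a condition-number warning.
    """
    labels = pd.Series(np.asarray(labels), index=cm.barcodes)
    dense = cm.counts.toarray().astype(float)
    norm = _depth_normalized(dense)
    if marker_genes is not None:
        gene_index = {g: i for i, g in enumerate(cm.gene_ids)}
        idx = [gene_index[g] for g in marker_genes if g in gene_index]
        genes = [g for g in marker_genes if g in gene_index]
    else:
        idx = list(range(cm.n_genes))
        genes = list(cm.gene_ids)
    cols = {}
    counts = {}
    for pop in sorted(map(str, pd.unique(labels.dropna()))):
        mask = (labels.astype(str) == pop).to_numpy()
        n = int(mask.sum())
        if n < min_cells_signature:
            logger.info("signature %s excluded: %d cells < %d", pop, n,
                        min_cells_signature)
            continue
        cols[pop] = norm[np.ix_(idx, np.flatnonzero(mask))].mean(axis=1)
        counts[pop] = n
    if not cols:
        raise ValueError("no population passes the minimum cell count")
    profiles = pd.DataFrame(cols, index=genes)
    if profiles.shape[1] >= 2:
        cond = np.linalg.cond(profiles.to_numpy())
        if cond > 1e6:
            logger.warning("signature matrix nearly collinear "
                           "(condition number %.2g)", cond)
    return SignatureMatrix(profiles=profiles, cell_counts=pd.Series(counts))


def deconvolve(bulk: BulkCohort | pd.DataFrame, sig: SignatureMatrix,
               min_overlap: int = 50) -> pd.DataFrame:
    """Non-negative least squares cell fractions per bulk sample.

    Coefficients are renormalized to sum to one; the per-sample residual
    norm (relative to the bulk vector norm) is reported in a ``_residual``
    column.  Requires >= ``min_overlap`` shared genes.
    """
    expr = bulk.expr if isinstance(bulk, BulkCohort) else bulk
    if len(sig.populations) < 2:
        raise ValueError("deconvolution needs >= 2 populations")
    shared = [g for g in sig.profiles.index if g in set(expr.columns)]
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} genes shared between bulk and signature "
            f"(floor {min_overlap})")
    A = sig.profiles.loc[shared].to_numpy()
    out = np.zeros((expr.shape[0], len(sig.populations)))
    resid = np.zeros(expr.shape[0])
    B = expr[shared].to_numpy(dtype=float)
    for i in range(B.shape[0]):
        coef, rnorm = scipy.optimize.nnls(A, B[i])
        total = coef.sum()
        out[i] = coef / total if total > 0 else 1.0 / len(coef)
        bnorm = np.linalg.norm(B[i])
        resid[i] = rnorm / bnorm if bnorm > 0 else 0.0
    table = pd.DataFrame(out, index=expr.index, columns=sig.populations)
    table["_residual"] = resid
    return table


# ---------------------------------------------------------------------------
# split validation
# ---------------------------------------------------------------------------

def split_validate(cm: CountMatrix, labels: pd.Series | np.ndarray,
                   sig_builder=None, seed: int = 0,
                   large_population: int = 2000,
                   train_draw: int = 1000) -> dict:
    """Hold-out validation of deconvolution against pseudobulk truth.

    Per population, ``train_draw`` cells are sampled for training when the
    population exceeds ``large_population`` cells, otherwise 50% of its
    cells; the signature matrix is built from the training cells and a
    pseudobulk (summed counts, depth-normalized) is formed from the held-out
    cells.  Returns the Pearson r between deconvolved and true held-out
    proportions, plus the per-population tables.
    """
    labels = pd.Series(np.asarray(labels), index=cm.barcodes)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    train_sizes = {}
    for pop in sorted(map(str, pd.unique(labels.dropna()))):
        idx = np.flatnonzero((labels.astype(str) == pop).to_numpy())
        n = len(idx)
        n_train = train_draw if n > large_population else n // 2
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_idx.extend(chosen.tolist())
        test_idx.extend(sorted(set(idx) - set(chosen.tolist())))
        train_sizes[pop] = n_train
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)

    cm_train = cm.subset_cells(np.asarray(train_idx))
    if sig_builder is None:
        sig = build_signature_matrix(cm_train,
                                     labels.iloc[train_idx].to_numpy())
    else:
        sig = sig_builder(cm_train, labels.iloc[train_idx].to_numpy())

    test_labels = labels.iloc[test_idx].astype(str)
    true_frac = (test_labels.value_counts(normalize=True)
                 .reindex(sig.populations).fillna(0.0))
    pseudo = np.asarray(cm.counts[:, test_idx].sum(axis=1)).ravel().astype(float)
    pseudo = pseudo / pseudo.sum() * 1e4
    bulk = pd.DataFrame([pseudo], index=["pseudobulk"], columns=cm.gene_ids)
    est = deconvolve(bulk, sig).drop(columns="_residual").iloc[0]

    r = float(np.corrcoef(true_frac.to_numpy(), est.to_numpy())[0, 1])
    return {
        "pearson_r": r,
        "true_proportions": true_frac,
        "estimated_proportions": est,
        "train_sizes": train_sizes,
    }
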