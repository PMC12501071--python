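"""Nucleus-level quality filtering, log normalization and marker detection.

Filtering keeps nuclei with a detected-gene count inside [min_genes,
max_genes] (removal is strict: <500 or >8000 detected genes, or a
mitochondrial fraction strictly above 5%).  Normalization scales each cell
to the median sequencing depth and applies log1p; this variance-reasonable
log-scale matrix is what module discovery and scoring consume.  Markers are
called per cluster versus the rest with a Wilcoxon rank-sum test on raw
counts, Bonferroni-corrected, keeping positive differences with
log2 fold-change > 0.25 expressed in >10% of cells in at least one group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "filter_nuclei", "normalize", "detect_markers"]


@dataclass
class NormalizedMatrix:
    """Log-normalized genes x cells matrix with its scaling metadata.

    ``values`` holds log1p(median-depth-scaled counts) as a dense array;
    ``size_factors`` are per-cell depth / median depth; ``gene_mean_counts``
    records the per-gene mean of the *raw* counts (needed by the CNV caller's
    low-expression filter).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    metadata: pd.DataFrame
    size_factors: np.ndarray
    gene_mean_counts: np.ndarray
    gene_pos: pd.DataFrame | None = None
    median_depth: float = float("nan")
    log_base: str = "e"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def sample_of(self) -> pd.Series:
        return self.metadata["sample"]

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[idx],
            metadata=self.metadata.iloc[idx],
            size_factors=self.size_factors[idx],
            gene_mean_counts=self.gene_mean_counts,
            gene_pos=self.gene_pos,
            median_depth=self.median_depth,
        )


def filter_nuclei(cm: CountMatrix, min_genes: int = 500, max_genes: int = 8000,
                  max_mito: float = 0.05,
                  mito_prefix: str = "MT-") -> CountMatrix:
    """Remove low-quality nuclei.

    A nucleus is removed if it has fewer than ``min_genes`` detected genes
    (count > 0), more than ``max_genes`` detected genes, or a mitochondrial
    transcript fraction strictly greater than ``max_mito``.  Cells exactly at
    a gene-count bound are kept.
    """
    counts = cm.counts
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in cm.gene_ids])
    depth = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() \
        else np.zeros_like(depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(depth > 0, mito / depth, 0.0)

    low = detected < min_genes
    high = detected > max_genes
    mito_bad = mito_frac > max_mito
    keep = ~(low | high | mito_bad)
    logger.info("filter_nuclei: removed %d (<%d genes), %d (>%d genes), "
                "%d (mito>%s); kept %d/%d",
                int(low.sum()), min_genes, int(high.sum()), max_genes,
                int(mito_bad.sum()), max_mito, int(keep.sum()), cm.n_cells)
    if not keep.any():
        raise ValueError("all cells removed by QC filtering")
    return cm.subset_cells(keep)


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Median-depth scaling followed by log1p.

    Each cell is scaled so its total count equals the median depth of the
    dataset, then log1p-transformed.  Deterministic; equal-depth datasets
    reduce to values = log1p(counts).
    """
    counts = cm.counts
    depth = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if np.any(depth == 0):
        raise ValueError("cells with zero total counts; run filter_nuclei first")
    median_depth = float(np.median(depth))
    sf = depth / median_depth
    dense = counts.toarray().astype(float)
    values = np.log1p(dense / sf[np.newaxis, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=cm.gene_ids,
        barcodes=cm.barcodes,
        metadata=cm.metadata,
        size_factors=sf,
        gene_mean_counts=dense.mean(axis=1),
        gene_pos=cm.gene_pos,
        median_depth=median_depth,
    )


def detect_markers(nm: NormalizedMatrix, labels: pd.Series | np.ndarray,
                   raw_counts: np.ndarray | sp.spmatrix | None = None,
                   min_log2fc: float = 0.25, min_frac: float = 0.10,
                   only_positive: bool = True,
                   min_cells_per_label: int = 3) -> pd.DataFrame:
    """Per-cluster marker genes versus all other cells.

    The rank-sum test runs on raw counts; effect-size and expression-fraction
    filters use the normalized matrix.  log2 fold-change follows the
    convention log2(mean(expm1(x_in)) + 1) - log2(mean(expm1(x_out)) + 1).
    Bonferroni multiplies raw p by the total number of genes in the matrix.

    Returns a tidy frame with columns cluster, gene, log2fc, frac_in,
    frac_out, p, p_adj sorted by (cluster, p_adj, gene).
    """
    labels = pd.Series(np.asarray(labels), index=nm.barcodes)
    uniq = [lab for lab in pd.unique(labels) if pd.notna(lab)]
    if len(uniq) < 2:
        raise ValueError("marker detection needs >=2 labels")
    if raw_counts is None:
        # recover raw scale from the normalized values and size factors
        raw = np.expm1(nm.values) * nm.size_factors[np.newaxis, :]
    else:
        raw = raw_counts.toarray() if sp.issparse(raw_counts) else \
            np.asarray(raw_counts, dtype=float)

    expr_lin = np.expm1(nm.values)
    rows = []
    for lab in sorted(map(str, uniq)):
        in_mask = (labels.astype(str) == lab).to_numpy()
        n_in = int(in_mask.sum())
        if n_in < min_cells_per_label or (~in_mask).sum() < min_cells_per_label:
            logger.warning("detect_markers: label %r has <%d cells on one "
                           "side; skipped", lab, min_cells_per_label)
            continue
        frac_in = (nm.values[:, in_mask] > 0).mean(axis=1)
        frac_out = (nm.values[:, ~in_mask] > 0).mean(axis=1)
        mean_in = expr_lin[:, in_mask].mean(axis=1)
        mean_out = expr_lin[:, ~in_mask].mean(axis=1)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)

        keep = (np.maximum(frac_in, frac_out) > min_frac) & (log2fc > min_log2fc)
        if only_positive:
            keep &= mean_in > mean_out
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        res = scipy.stats.mannwhitneyu(
            raw[np.ix_(idx, in_mask)], raw[np.ix_(idx, ~in_mask)],
            axis=1, alternative="two-sided")
        for j, gi in enumerate(idx):
            rows.append((lab, nm.gene_ids[gi], float(log2fc[gi]),
                         float(frac_in[gi]), float(frac_out[gi]),
                         float(res.pvalue[j])))

    table = pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "frac_in",
                                        "frac_out", "p"])
    table["p_adj"] = np.minimum(table["p"] * nm.n_genes, 1.0)
    return table.sort_values(["cluster", "p_adj", "gene"],
                             kind="stable").reset_index(drop=True)
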