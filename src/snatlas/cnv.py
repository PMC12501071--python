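"""Windowed copy-number inference from expression, against a normal reference.

The signal for each cell is the mean, over a 100-gene genomic sliding
window, of the cell's log-normalized expression minus the reference-cell
mean for the same genes, then centered by the cell's median window signal
(so a focal gain does not masquerade as a genome-wide loss after depth
normalization).  Genes with mean raw count < 0.1 across all cells are
dropped before windowing; windows slide by one gene and never span a
chromosome boundary.  Denoising flattens query signal within 1.5 pooled
reference standard deviations of the reference mean.  A window is called a
gain/loss when the (denoised) query signal falls outside the empirical 99%
interval of the reference signal for that window, and a cell is flagged
malignant when more than 3% of its windows are altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["CnvProfile", "window_smooth", "denoise", "call_windows",
           "call_malignant", "run_cnv_pipeline"]

LOSS, NEUTRAL, GAIN = -1, 0, 1


@dataclass
class CnvProfile:
    """Per-cell windowed CNV signal, calls and malignancy verdicts.

    ``signal`` is cells x windows; ``reference_mask`` marks the reference
    (normal) cells among the rows.  ``calls`` uses -1/0/+1 for
    loss/neutral/gain.  ``altered_fraction`` is the per-cell fraction of
    non-neutral windows; ``malignant`` applies the >3%-of-windows rule.
    """

    windows: pd.DataFrame            # columns: chrom, start_gene, end_gene
    barcodes: np.ndarray
    reference_mask: np.ndarray
    signal: np.ndarray
    raw_signal: np.ndarray | None = None
    calls: np.ndarray | None = None
    altered_fraction: np.ndarray | None = None
    malignant: np.ndarray | None = None
    reference_stats: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.signal.shape[1]

    def verdicts(self) -> pd.DataFrame:
        return pd.DataFrame({
            "altered_fraction": self.altered_fraction,
            "malignant": self.malignant,
            "reference": self.reference_mask,
        }, index=self.barcodes)


def window_smooth(nm: NormalizedMatrix, reference_cells,
                  window: int = 100,
                  min_mean_count: float = 0.1) -> CnvProfile:
    """Compute the smoothed windowed log-ratio signal for every cell.

    ``reference_cells`` is a boolean mask or an array of barcodes naming the
    normal population.  Chromosomes with fewer than ``window`` genes are
    skipped with a warning.
    """
    if nm.gene_pos is None:
        raise ValueError("gene positions required for CNV inference")
    ref_mask = _as_mask(reference_cells, nm.barcodes)
    if not ref_mask.any():
        raise ValueError("reference cell set is empty")

    expressed = nm.gene_mean_counts >= min_mean_count
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("window_smooth: dropped %d genes with mean count < %s",
                    n_dropped, min_mean_count)

    gp = nm.gene_pos
    keep_ids = [g for g, ok in zip(nm.gene_ids, expressed)
                if ok and g in gp.index]
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    pos = gp.loc[keep_ids].copy()
    pos["_gene_idx"] = [gene_index[g] for g in keep_ids]
    pos = pos.sort_values(["chrom", "start", "end"], kind="stable")

    ref_mean = nm.values[:, ref_mask].mean(axis=1)
    centered = nm.values - ref_mean[:, np.newaxis]

    win_rows = []
    sig_cols = []
    for chrom, sub in pos.groupby("chrom", sort=True):
        gidx = sub["_gene_idx"].to_numpy()
        if len(gidx) < window:
            logger.warning("chromosome %s has %d genes < window %d; skipped",
                           chrom, len(gidx), window)
            continue
        block = centered[gidx]                       # genes x cells
        csum = np.vstack([np.zeros((1, block.shape[1])),
                          np.cumsum(block, axis=0)])
        means = (csum[window:] - csum[:-window]) / window
        for w in range(means.shape[0]):
            win_rows.append((chrom, int(gidx[w]), int(gidx[w + window - 1])))
        sig_cols.append(means)
    if not sig_cols:
        raise ValueError("no chromosome has enough genes for a window")
    signal = np.vstack(sig_cols).T                   # cells x windows
    # center each cell by its median window signal: depth normalization makes
    # a focal gain depress every other window otherwise
    signal = signal - np.median(signal, axis=1, keepdims=True)
    windows = pd.DataFrame(win_rows, columns=["chrom", "start_gene",
                                              "end_gene"])
    return CnvProfile(windows=windows, barcodes=nm.barcodes,
                      reference_mask=ref_mask, signal=signal,
                      raw_signal=signal.copy())


def denoise(profile: CnvProfile, k_sd: float = 1.5) -> CnvProfile:
    """Flatten query signal within mu +/- k_sd*sigma of the pooled reference.

    mu and sigma pool the reference cells' signal over all windows (the
    cited tool's default).  Reference rows are left untouched so the calling
    interval keeps its spread.  Idempotent.
    """
    ref = profile.signal[profile.reference_mask]
    mu = float(ref.mean())
    sd = float(ref.std())
    out = profile.signal.copy()
    q = ~profile.reference_mask
    inside = np.abs(out[q] - mu) <= k_sd * sd
    block = out[q]
    block[inside] = mu
    out[q] = block
    profile.signal = out
    profile.reference_stats.update({"mu": mu, "sd": sd, "k_sd": k_sd})
    return profile


def call_windows(profile: CnvProfile, ci_level: float = 0.99) -> CnvProfile:
    """Call loss/neutral/gain per window from the reference empirical CI.

    The interval per window is the [ (1-ci)/2, 1-(1-ci)/2 ] empirical
    quantile range of the *unsmoothed-by-denoising* reference signal; query
    signal below/above it is a loss/gain.
    """
    ref_signal = (profile.raw_signal if profile.raw_signal is not None
                  else profile.signal)[profile.reference_mask]
    if ref_signal.shape[0] < 50:
        logger.warning("call_windows: only %d reference cells; quantiles "
                       "may be unstable", ref_signal.shape[0])
    tail = (1.0 - ci_level) / 2.0
    # outer order statistics, so the empirical interval holds >= ci_level mass
    lo = np.quantile(ref_signal, tail, axis=0, method="lower")
    hi = np.quantile(ref_signal, 1.0 - tail, axis=0, method="higher")
    calls = np.zeros_like(profile.signal, dtype=np.int8)
    calls[profile.signal < lo[np.newaxis, :]] = LOSS
    calls[profile.signal > hi[np.newaxis, :]] = GAIN
    profile.calls = calls
    profile.reference_stats.update({"ci_lo": lo, "ci_hi": hi,
                                    "ci_level": ci_level})
    return profile


def call_malignant(profile: CnvProfile,
                   genome_fraction: float = 0.03) -> CnvProfile:
    """Flag cells with altered_fraction strictly greater than the threshold.

    The altered fraction is measured in window space (fraction of
    non-neutral windows), the native resolution of the method.
    """
    if profile.calls is None:
        raise ValueError("run call_windows before call_malignant")
    altered = (profile.calls != NEUTRAL).mean(axis=1)
    profile.altered_fraction = altered
    profile.malignant = altered > genome_fraction
    return profile


def run_cnv_pipeline(nm: NormalizedMatrix, reference_cells,
                     window: int = 100, min_mean_count: float = 0.1,
                     k_sd: float = 1.5, ci_level: float = 0.99,
                     genome_fraction: float = 0.03) -> CnvProfile:
    """window_smooth -> denoise -> call_windows -> call_malignant."""
    profile = window_smooth(nm, reference_cells, window=window,
                            min_mean_count=min_mean_count)
    profile = denoise(profile, k_sd=k_sd)
    profile = call_windows(profile, ci_level=ci_level)
    return call_malignant(profile, genome_fraction=genome_fraction)


def _as_mask(cells, barcodes: np.ndarray) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        if len(cells) != len(barcodes):
            raise ValueError("boolean mask length mismatch")
        return cells
    wanted = set(cells.tolist())
    return np.array([b in wanted for b in barcodes])
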