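"""Ecotype construction: Z-scored signature columns grouped by consensus
partition clustering, with summed per-sample ecotype scores.

Signature scores are standardized within each bulk dataset (so cohorts
measured on different platforms can be pooled), capped at +/-3, and the
signatures are clustered by a subsampled consensus scheme: for each k from
2 to max_k, samples are repeatedly subsampled and the signatures clustered
(average linkage on 1 - Pearson correlation); the co-clustering frequency
matrix defines consensus, and the retained k maximizes mean within-cluster
minus mean between-cluster consensus.  An ecotype's per-sample score is the
sum of its member signatures' capped Z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

logger = logging.getLogger(__name__)

__all__ = ["EcotypeModel", "zscore_cap", "consensus_partition",
           "ecotype_scores"]


@dataclass
class EcotypeModel:
    """Signature -> ecotype assignment with the consensus evidence."""

    assignment: pd.Series          # signature -> ecotype label ("E1"...)
    k: int
    consensus: pd.DataFrame        # signatures x signatures co-clustering
    k_statistics: pd.DataFrame     # per-k within/between consensus

    @property
    def ecotypes(self) -> list[str]:
        return sorted(self.assignment.unique())

    def members(self, ecotype: str) -> list[str]:
        return list(self.assignment.index[self.assignment == ecotype])


def zscore_cap(scores: pd.DataFrame, dataset_of: pd.Series,
               zcap: float = 3.0) -> pd.DataFrame:
    """Standardize each signature within each dataset, then clamp to +/-zcap.

    Constant columns within a dataset map to zeros with a warning.  Clamp
    counts are logged.
    """
    dataset_of = dataset_of.loc[scores.index]
    out = scores.copy().astype(float)
    for ds, idx in scores.groupby(dataset_of).groups.items():
        if len(idx) < 3:
            raise ValueError(f"dataset {ds} has <3 samples")
        block = scores.loc[idx]
        mu = block.mean()
        sd = block.std(ddof=1)
        constant = sd == 0
        if constant.any():
            logger.warning("dataset %s: %d constant signature columns set "
                           "to 0", ds, int(constant.sum()))
        sd = sd.replace(0.0, np.inf)
        out.loc[idx] = (block - mu) / sd
    n_clamped = int((out.to_numpy() < -zcap).sum()
                    + (out.to_numpy() > zcap).sum())
    if n_clamped:
        logger.info("zscore_cap: clamped %d values to +/-%s", n_clamped, zcap)
    return out.clip(-zcap, zcap)


def _cluster_signatures(X: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage clustering of signature rows at 1 - Pearson distance."""
    C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = sch.linkage(ssd.squareform(np.maximum(D, 0.0), checks=False),
                    method="average")
    return sch.fcluster(Z, t=k, criterion="maxclust")


def consensus_partition(z: pd.DataFrame, max_k: int = 10,
                        n_resamples: int = 100, subsample_frac: float = 0.8,
                        seed: int = 0) -> EcotypeModel:
    """Group signature columns into ecotypes by subsampled consensus.

    ``z`` is samples x signatures (capped Z-scores).  Signatures are the
    objects clustered; samples are the features subsampled.  For each k in
    2..max_k the mean co-clustering frequency over resamples is summarized
    as mean within-cluster consensus minus mean between-cluster consensus
    (clusters taken from re-clustering the consensus matrix at k); the k
    maximizing this gap is retained.  Deterministic given the seed.
    """
    n_sig = z.shape[1]
    if n_sig < 4:
        raise ValueError("consensus partition needs >= 4 signatures")
    if z.shape[0] < 20:
        raise ValueError("consensus partition needs >= 20 samples")
    if max_k >= n_sig:
        raise ValueError("max_k must be < number of signatures")
    rng = np.random.default_rng(seed)
    X_full = z.to_numpy().T                     # signatures x samples
    n_samples = z.shape[0]
    n_sub = max(2, int(round(subsample_frac * n_samples)))

    subsamples = [rng.choice(n_samples, size=n_sub, replace=False)
                  for _ in range(n_resamples)]
    stats = []
    best = None
    for k in range(2, max_k + 1):
        co = np.zeros((n_sig, n_sig))
        for sub in subsamples:
            labels = _cluster_signatures(X_full[:, sub], k)
            co += labels[:, None] == labels[None, :]
        co /= n_resamples
        # cluster the consensus matrix itself at k to score the partition
        Dc = 1.0 - co
        np.fill_diagonal(Dc, 0.0)
        Z = sch.linkage(ssd.squareform((Dc + Dc.T) / 2.0, checks=False),
                        method="average")
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(n_sig, dtype=bool)
        within = co[same & off].mean() if (same & off).any() else 0.0
        between = co[~same].mean() if (~same).any() else 0.0
        gap = within - between
        stats.append((k, within, between, gap))
        # >= prefers the finest partition among equally consistent ones
        if best is None or gap >= best[0]:
            best = (gap, k, labels, co)

    _, k, labels, co = best
    order = {}
    assignment = []
    for lab in labels:
        if lab not in order:
            order[lab] = f"E{len(order) + 1}"
        assignment.append(order[lab])
    model = EcotypeModel(
        assignment=pd.Series(assignment, index=z.columns),
        k=k,
        consensus=pd.DataFrame(co, index=z.columns, columns=z.columns),
        k_statistics=pd.DataFrame(stats, columns=["k", "within", "between",
                                                  "gap"]).set_index("k"),
    )
    logger.info("consensus_partition: retained k=%d (gap %.3f)", k, best[0])
    return model


def ecotype_scores(z: pd.DataFrame, model: EcotypeModel) -> pd.DataFrame:
    """Per-sample ecotype scores: sum of member signatures' capped Z-scores."""
    out = {}
    for eco in model.ecotypes:
        members = model.members(eco)
        out[eco] = z[members].sum(axis=1)
    return pd.DataFrame(out, index=z.index)
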