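"""Synthetic multi-tumor single-nucleus data, CNV-bearing cells and bulk cohorts.

Every downstream stage of the pipeline (module discovery, CNV calling,
deconvolution, ecotypes, survival) is validated against data generated here,
where the planted structure is known exactly.  Counts follow a negative
binomial model: per-gene baseline means are drawn log-normally, module or
cell-type structure shifts the log-mean, and a fixed dispersion governs
overdispersion.  Module activity per cell is a two-component (on/off)
mixture, which makes "top-k genes per principal component" recovery
well-posed.  Bulk cohorts are convex mixtures of cell-population signatures
with multiplicative log-normal noise; survival times are exponential with a
log-hazard linear in standardized planted ecotype scores, censored by an
independent exponential clock tuned to roughly 40% censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import BulkCohort, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedModule",
    "CnvEvent",
    "SimulationConfig",
    "GroundTruth",
    "generate_multi_tumor_dataset",
    "generate_cnv_cells",
    "generate_bulk_cohort",
    "planted_score_table",
    "random_signature_matrix",
    "default_multi_tumor_config",
    "default_ecotype_blocks",
]


@dataclass
class PlantedModule:
    """A planted expression program: ``size`` genes, active (on/off per cell)
    in the listed carrier tumors with the given log-scale effect."""

    size: int
    carriers: tuple[int, ...]
    effect: float = 2.0
    p_on: float = 0.5


@dataclass
class CnvEvent:
    """A planted copy-number event spanning ``span`` consecutive genes of one
    chromosome; carrier cells have NB means multiplied by ``fold``."""

    chrom: str
    start_gene: int          # offset within the chromosome, 0-based
    span: int
    fold: float
    carrier_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic generators.

    Sizes mirror a desk-scale version of a multi-tumor single-nucleus atlas:
    6 tumors x 800 steroid cells x 2,000 genes with three shared programs and
    one private program per tumor; 5 chromosomes of 440 genes each for CNV
    cells; bulk cohorts of 200 samples over 12 signatures in 4 ecotype blocks.
    """

    n_tumors: int = 6
    cells_per_tumor: int = 800
    n_genes: int = 2000
    planted_modules: list[PlantedModule] = field(default_factory=list)
    n_celltypes: int = 4
    microenv_cells_per_tumor: int = 0
    celltype_centroid_separation: float = 2.0
    celltype_marker_genes: int = 60
    nb_dispersion: float = 0.3
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.0
    # CNV generation; the genome must be large relative to the smoothing
    # window (many independent window-lengths), as a real transcriptome is —
    # otherwise a single noise excursion already covers >3% of windows
    n_chromosomes: int = 10
    genes_per_chromosome: int = 720
    n_reference_cells: int = 400
    n_query_cells: int = 300
    cnv_events: list[CnvEvent] = field(default_factory=list)
    # bulk cohort
    cohort_n: int = 200
    ecotype_blocks: list[tuple[int, ...]] = field(default_factory=list)
    within_block_r: float = 0.8
    planted_log_hazard: list[float] = field(default_factory=list)
    noise_sd: float = 0.1
    baseline_hazard: float = np.log(2) / 1000.0   # median survival ~1000 days
    censoring_rate_ratio: float = 2.0 / 3.0       # censor clock vs hazard -> ~40%
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.planted_modules:
            if m.size > self.n_genes:
                raise ValueError("module gene set exceeds n_genes")
            if any(c >= self.n_tumors or c < 0 for c in m.carriers):
                raise ValueError("carrier tumors must index existing tumors")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within-block correlation must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted truth aligned one-to-one with generated barcodes/samples."""

    module_genes: dict[str, list[str]] = field(default_factory=dict)
    module_activity: pd.DataFrame | None = None      # cells x modules (0/1)
    shared_module_ids: list[str] = field(default_factory=list)
    private_module_ids: list[str] = field(default_factory=list)
    cnv_carrier: pd.Series | None = None             # barcode -> bool
    altered_gene_spans: list[tuple[str, int, int]] = field(default_factory=list)
    proportions: pd.DataFrame | None = None          # samples x populations
    signature_activity: pd.DataFrame | None = None   # samples x signatures
    block_of: pd.Series | None = None                # signature -> block id
    ecotype_scores: pd.DataFrame | None = None       # samples x blocks (std.)
    log_hazard: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared NB machinery
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial draw parameterized by mean and dispersion
    (var = mean + dispersion * mean^2)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _baseline_log_means(rng: np.random.Generator,
                        cfg: SimulationConfig) -> np.ndarray:
    return rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)


# ---------------------------------------------------------------------------
# multi-tumor dataset with planted programs
# ---------------------------------------------------------------------------

def default_multi_tumor_config(seed: int = 0) -> SimulationConfig:
    """The standard multi-tumor scenario: 3 programs shared by 4/6 tumors and
    one private program per tumor, 50 genes each.

    Effect sizes differ across programs (2.5/2.0/1.6 shared, 1.2 private
    log-units): co-active programs of identical strength make the per-tumor
    covariance rotationally degenerate, which no PCA-based recovery can
    disentangle, and real programs differ in strength anyway.
    """
    shared = [
        PlantedModule(size=50, carriers=(0, 1, 2, 3), effect=2.5),
        PlantedModule(size=50, carriers=(1, 2, 3, 4), effect=2.0),
        PlantedModule(size=50, carriers=(2, 3, 4, 5), effect=1.6),
    ]
    private = [PlantedModule(size=50, carriers=(t,), effect=1.2)
               for t in range(6)]
    return SimulationConfig(planted_modules=shared + private, seed=seed)


def generate_multi_tumor_dataset(
        cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate per-tumor steroid-cell count matrices with planted programs.

    Module gene sets are disjoint blocks of the gene space (module m gets
    genes ``[m*size, (m+1)*size)``), so recovered gene lists can be compared
    to the truth without ambiguity.  Optionally appends microenvironment
    cells of ``n_celltypes`` types with separated centroids.
    """
    rng = np.random.default_rng(cfg.seed)
    base_log = _baseline_log_means(rng, cfg)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)

    modules = cfg.planted_modules
    total = sum(m.size for m in modules)
    if total > cfg.n_genes:
        raise ValueError("planted modules exceed the gene space")
    gene_sets: dict[str, list[str]] = {}
    offset = 0
    mod_ids = []
    for i, m in enumerate(modules):
        mid = f"M{i}"
        gene_sets[mid] = list(genes[offset:offset + m.size])
        mod_ids.append(mid)
        offset += m.size

    blocks: list[np.ndarray] = []
    barcodes: list[str] = []
    samples: list[str] = []
    celltypes: list[str] = []
    activities: list[np.ndarray] = []

    for t in range(cfg.n_tumors):
        n = cfg.cells_per_tumor
        act = np.zeros((n, len(modules)))
        log_mu = np.tile(base_log, (n, 1))
        off = 0
        for i, m in enumerate(modules):
            if t in m.carriers and m.effect != 0:
                on = rng.random(n) < m.p_on
                act[:, i] = on.astype(float)
                log_mu[np.ix_(on, np.arange(off, off + m.size))] += m.effect
            off += m.size
        blocks.append(_nb_sample(rng, np.exp(log_mu), cfg.nb_dispersion))
        barcodes += [f"T{t}_C{j}" for j in range(n)]
        samples += [f"T{t}"] * n
        celltypes += ["steroid"] * n
        activities.append(act)

    if cfg.microenv_cells_per_tumor > 0:
        centroids = _celltype_centroids(rng, cfg, base_log)
        # uneven population sizes, as in real microenvironments
        weights = np.linspace(2.0, 1.0, cfg.n_celltypes)
        weights /= weights.sum()
        for t in range(cfg.n_tumors):
            for ct in range(cfg.n_celltypes):
                per_type = max(1, int(round(
                    weights[ct] * cfg.microenv_cells_per_tumor)))
                mu = np.exp(np.tile(centroids[ct], (per_type, 1)))
                blocks.append(_nb_sample(rng, mu, cfg.nb_dispersion))
                barcodes += [f"T{t}_CT{ct}_C{j}" for j in range(per_type)]
                samples += [f"T{t}"] * per_type
                celltypes += [f"CT{ct}"] * per_type
                activities.append(np.zeros((per_type, len(modules))))

    counts = np.vstack(blocks).T  # genes x cells
    meta = pd.DataFrame({"sample": samples, "celltype": celltypes},
                        index=pd.Index(barcodes, name="barcode"))
    cm = CountMatrix(counts=sp.csr_matrix(counts), gene_ids=genes,
                     barcodes=np.asarray(barcodes, dtype=object),
                     metadata=meta)
    activity = pd.DataFrame(np.vstack(activities), index=barcodes,
                            columns=mod_ids)
    gt = GroundTruth(
        module_genes=gene_sets,
        module_activity=activity,
        shared_module_ids=[mid for mid, m in zip(mod_ids, modules)
                           if len(m.carriers) > 1],
        private_module_ids=[mid for mid, m in zip(mod_ids, modules)
                            if len(m.carriers) == 1],
    )
    logger.info("generated %d tumors, %d cells, %d genes, %d planted modules",
                cfg.n_tumors, cm.n_cells, cfg.n_genes, len(modules))
    return cm, gt


def _celltype_centroids(rng: np.random.Generator, cfg: SimulationConfig,
                        base_log: np.ndarray) -> np.ndarray:
    """Each cell type up-shifts a private block of marker genes at the end of
    the gene space by the centroid separation (log-units)."""
    k, g = cfg.n_celltypes, cfg.celltype_marker_genes
    if k * g > cfg.n_genes:
        raise ValueError("cell-type marker blocks exceed the gene space")
    centroids = np.tile(base_log, (k, 1))
    for ct in range(k):
        lo = cfg.n_genes - (ct + 1) * g
        centroids[ct, lo:lo + g] += cfg.celltype_centroid_separation
    return centroids


# ---------------------------------------------------------------------------
# CNV cells
# ---------------------------------------------------------------------------

def generate_cnv_cells(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Reference plus query cells with planted chromosomal gains/losses.

    Gene positions tile ``n_chromosomes`` chromosomes with
    ``genes_per_chromosome`` genes each.  Carrier query cells have NB means
    multiplied by the event fold-change across the event's gene span before
    sampling.  Reference cells (celltype ``reference``) carry no events.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_chromosomes * cfg.genes_per_chromosome
    base_log = rng.normal(-0.5, 0.8, n_genes)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    chroms = np.repeat([f"chr{c + 1}" for c in range(cfg.n_chromosomes)],
                       cfg.genes_per_chromosome)
    within = np.tile(np.arange(cfg.genes_per_chromosome), cfg.n_chromosomes)
    gene_pos = pd.DataFrame({
        "chrom": chroms,
        "start": within * 10_000 + 1,
        "end": within * 10_000 + 5_000,
    }, index=pd.Index(genes, name="gene"))

    fold = np.ones(n_genes)
    spans: list[tuple[str, int, int]] = []
    chrom_offset = {f"chr{c + 1}": c * cfg.genes_per_chromosome
                    for c in range(cfg.n_chromosomes)}
    for ev in cfg.cnv_events:
        lo = chrom_offset[ev.chrom] + ev.start_gene
        hi = lo + ev.span
        if ev.start_gene + ev.span > cfg.genes_per_chromosome:
            raise ValueError("event span exceeds its chromosome")
        fold[lo:hi] *= ev.fold
        spans.append((ev.chrom, lo, hi))

    carrier_frac = cfg.cnv_events[0].carrier_fraction if cfg.cnv_events else 0.0
    n_ref, n_query = cfg.n_reference_cells, cfg.n_query_cells
    carrier = np.zeros(n_ref + n_query, dtype=bool)
    n_carriers = int(round(carrier_frac * n_query))
    carrier[n_ref:n_ref + n_carriers] = True

    mu = np.tile(np.exp(base_log), (n_ref + n_query, 1))
    mu[carrier] *= fold
    counts = _nb_sample(rng, mu, cfg.nb_dispersion).T
    barcodes = ([f"REF_C{j}" for j in range(n_ref)]
                + [f"Q_C{j}" for j in range(n_query)])
    meta = pd.DataFrame({
        "sample": ["normal"] * n_ref + ["tumor"] * n_query,
        "celltype": ["reference"] * n_ref + ["query"] * n_query,
    }, index=pd.Index(barcodes, name="barcode"))
    cm = CountMatrix(counts=sp.csr_matrix(counts), gene_ids=genes,
                     barcodes=np.asarray(barcodes, dtype=object),
                     metadata=meta, gene_pos=gene_pos)
    gt = GroundTruth(
        cnv_carrier=pd.Series(carrier, index=barcodes),
        altered_gene_spans=spans,
    )
    return cm, gt


# ---------------------------------------------------------------------------
# bulk cohorts with planted ecotype blocks and hazards
# ---------------------------------------------------------------------------

def default_ecotype_blocks(n_signatures: int = 12,
                           n_blocks: int = 4) -> list[tuple[int, ...]]:
    per = n_signatures // n_blocks
    return [tuple(range(b * per, (b + 1) * per)) for b in range(n_blocks)]


def planted_score_table(n_samples: int, blocks: list[tuple[int, ...]],
                        within_r: float, rng: np.random.Generator,
                        sig_names: list[str] | None = None,
                        ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Samples x signatures activity table with planted correlation blocks.

    Signature j in block b is ``sqrt(r)*u_b + sqrt(1-r)*eps_j`` with the
    block latent u_b ~ N(0,1) per sample, giving within-block correlation r
    and zero between blocks.  Returns (activities, block_of, block latents).
    """
    n_sig = sum(len(b) for b in blocks)
    if sig_names is None:
        sig_names = [f"S{j}" for j in range(n_sig)]
    u = rng.normal(size=(n_samples, len(blocks)))
    x = np.empty((n_samples, n_sig))
    block_of = pd.Series(index=sig_names, dtype=object)
    for b, members in enumerate(blocks):
        for j in members:
            eps = rng.normal(size=n_samples)
            x[:, j] = np.sqrt(within_r) * u[:, b] + np.sqrt(1 - within_r) * eps
            block_of.iloc[j] = f"B{b}"
    samples = [f"S{i:04d}" for i in range(n_samples)]
    activities = pd.DataFrame(x, index=samples, columns=sig_names)
    latents = pd.DataFrame(u, index=samples,
                           columns=[f"B{b}" for b in range(len(blocks))])
    return activities, block_of, latents


def random_signature_matrix(n_genes: int, populations: list[str],
                            rng: np.random.Generator,
                            marker_frac: float = 0.05,
                            marker_boost: float = 8.0) -> pd.DataFrame:
    """Non-negative genes x populations reference with distinct marker blocks."""
    base = rng.lognormal(0.0, 0.5, size=(n_genes, len(populations)))
    n_mark = max(1, int(marker_frac * n_genes))
    for j in range(len(populations)):
        lo = j * n_mark
        base[lo:lo + n_mark, j] *= marker_boost
    genes = [f"G{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(base, index=genes, columns=populations)


def generate_bulk_cohort(cfg: SimulationConfig,
                         signature_matrix: pd.DataFrame,
                         proportions: pd.DataFrame | None = None,
                         ) -> tuple[BulkCohort, GroundTruth]:
    """Bulk cohort = proportions x signatures + log-normal noise, with
    survival driven by planted ecotype scores.

    If ``proportions`` is not given, per-sample population proportions are a
    softmax of the planted signature activities (one activity column per
    signature-matrix population), so ecotype structure propagates into the
    mixture.  Survival: exponential event times with log-hazard
    ``sum_b beta_b * z_b`` over standardized block latents, independent
    exponential censoring, three ``dataset_id`` strata assigned round-robin.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = list(signature_matrix.columns)
    blocks = cfg.ecotype_blocks or default_ecotype_blocks(len(pops))
    if sum(len(b) for b in blocks) != len(pops):
        raise ValueError("ecotype blocks must cover the signature populations")
    activities, block_of, latents = planted_score_table(
        cfg.cohort_n, blocks, cfg.within_block_r, rng, sig_names=pops)
    samples = list(activities.index)

    if proportions is None:
        w = np.exp(0.5 * activities.to_numpy())
        p = w / w.sum(axis=1, keepdims=True)
        proportions = pd.DataFrame(p, index=samples, columns=pops)
    else:
        proportions = proportions.copy()
        samples = list(proportions.index)
    if not np.allclose(proportions.sum(axis=1), 1.0):
        raise ValueError("proportions rows must sum to 1")

    clean = proportions.to_numpy() @ signature_matrix.to_numpy().T
    if cfg.noise_sd > 0:
        clean = clean * rng.lognormal(0.0, cfg.noise_sd, size=clean.shape)
    expr = pd.DataFrame(clean, index=samples,
                        columns=list(signature_matrix.index))

    z = (latents - latents.mean()) / latents.std(ddof=1)
    z = z.loc[samples] if set(samples) <= set(z.index) else z
    betas = list(cfg.planted_log_hazard) or [0.0] * len(blocks)
    if len(betas) != len(blocks):
        raise ValueError("planted_log_hazard must have one entry per block")
    lin = z.to_numpy() @ np.asarray(betas)

    clinical = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for endpoint, hazard_scale in (("os", 1.0), ("dfs", 1.3)):
        h = cfg.baseline_hazard * hazard_scale * np.exp(lin)
        t_event = rng.exponential(1.0 / h)
        t_cens = rng.exponential(
            1.0 / (cfg.censoring_rate_ratio * cfg.baseline_hazard * hazard_scale),
            size=len(samples))
        clinical[f"time_{endpoint}"] = np.minimum(t_event, t_cens)
        clinical[f"event_{endpoint}"] = (t_event <= t_cens).astype(int)
    clinical["stage"] = rng.choice(["I", "II", "III", "IV"], size=len(samples),
                                   p=[0.2, 0.35, 0.3, 0.15])
    clinical["dataset_id"] = [f"D{i % 3 + 1}" for i in range(len(samples))]

    cohort = BulkCohort(expr=expr, clinical=clinical)
    gt = GroundTruth(
        proportions=proportions,
        signature_activity=activities,
        block_of=block_of,
        ecotype_scores=z,
        log_hazard={f"B{b}": beta for b, beta in enumerate(betas)},
    )
    return cohort, gt
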