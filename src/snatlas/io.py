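"""Readers and writers for on-disk formats, run configuration and core containers.

On-disk layout follows 10x Genomics conventions: a Matrix Market coordinate
integer matrix (genes x cells) next to one-id-per-line ``features.tsv`` /
``barcodes.tsv`` files, plus a per-cell metadata TSV keyed by barcode.
Bulk cohorts are a samples x genes expression TSV joined with a clinical TSV.
Gene sets travel as GMT. All in-memory indices are 0-based; Matrix Market
files are 1-based; gene coordinates are 1-based inclusive bp.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "BulkCohort",
    "RunConfig",
    "GeneSet",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_cohort",
    "write_cohort",
]

REQUIRED_CLINICAL_COLUMNS = ("time_dfs", "event_dfs", "time_os", "event_os",
                             "stage", "dataset_id")
STAGES = ("I", "II", "III", "IV")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x cells integer count matrix with per-cell annotations.

    Parameters
    ----------
    counts
        Sparse CSR matrix of non-negative integers, shape (n_genes, n_cells).
    gene_ids
        Ordered, unique gene identifiers.
    barcodes
        Ordered, unique cell barcodes.
    metadata
        Per-cell table indexed by barcode.  Must contain a ``sample`` column;
        a ``celltype`` column defaults to ``"unknown"``.  Extra columns are
        carried through untouched.
    gene_pos
        Optional per-gene genomic coordinates indexed by gene id with columns
        ``chrom``, ``start``, ``end`` (1-based inclusive bp).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    metadata: pd.DataFrame
    gene_pos: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"dimension mismatch: {len(self.gene_ids)} gene ids for "
                f"{n_genes} matrix rows")
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"dimension mismatch: {len(self.barcodes)} barcodes for "
                f"{n_cells} matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate ids in gene list")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("duplicate ids in barcode list")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        self.counts.data = self.counts.data.astype(np.int64)
        if "sample" not in self.metadata.columns:
            raise ValueError("metadata must provide a 'sample' column")
        missing = set(self.barcodes) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing {len(missing)} barcodes")
        self.metadata = self.metadata.loc[list(self.barcodes)].copy()
        if "celltype" not in self.metadata.columns:
            self.metadata["celltype"] = "unknown"
        if self.gene_pos is not None:
            gp = self.gene_pos
            if not {"chrom", "start", "end"} <= set(gp.columns):
                raise ValueError("gene_pos needs chrom/start/end columns")
            if (gp["start"] > gp["end"]).any():
                raise ValueError("gene_pos start must be <= end")
            if (gp["chrom"].astype(str) == "").any():
                raise ValueError("gene_pos chromosome must be non-empty")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_of(self) -> pd.Series:
        return self.metadata["sample"]

    @property
    def celltype_of(self) -> pd.Series:
        return self.metadata["celltype"]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a copy restricted to the selected cells (boolean or index)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx].tocsr(),
            gene_ids=self.gene_ids.copy(),
            barcodes=self.barcodes[idx],
            metadata=self.metadata.iloc[idx].copy(),
            gene_pos=None if self.gene_pos is None else self.gene_pos.copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        genes = self.gene_ids[idx]
        gp = None
        if self.gene_pos is not None:
            gp = self.gene_pos.loc[[g for g in genes if g in self.gene_pos.index]]
        return CountMatrix(
            counts=self.counts[idx, :].tocsr(),
            gene_ids=genes,
            barcodes=self.barcodes.copy(),
            metadata=self.metadata.copy(),
            gene_pos=gp,
        )


@dataclass
class BulkCohort:
    """Bulk expression cohort with survival annotations.

    ``expr`` is samples x genes (non-negative reals); ``clinical`` is indexed
    by sample id and carries ``time_dfs``/``event_dfs``/``time_os``/``event_os``
    (times in days, may be missing), ``stage`` (I-IV) and ``dataset_id``.
    """

    expr: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            raise ValueError("duplicate sample ids in expression table")
        if not self.expr.index.equals(self.clinical.index):
            self.clinical = self.clinical.loc[self.expr.index]
        if "dataset_id" not in self.clinical.columns:
            raise ValueError("clinical table must provide dataset_id")
        for col in ("event_dfs", "event_os"):
            if col in self.clinical.columns:
                vals = self.clinical[col].dropna()
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"{col} must be 0/1")
        for col in ("time_dfs", "time_os"):
            if col in self.clinical.columns:
                vals = self.clinical[col].dropna()
                if (vals < 0).any():
                    raise ValueError(f"{col} must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.expr.shape[0]


@dataclass
class GeneSet:
    """A named, ordered gene set (GMT record)."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        dupes = 0
        for g in self.genes:
            if g in seen:
                dupes += 1
            else:
                seen[g] = None
        if dupes:
            logger.warning("gene set %s: removed %d duplicate genes",
                           self.name, dupes)
        self.genes = list(seen)


@dataclass
class RunConfig:
    """All tunable pipeline parameters, with the published defaults.

    Serializes losslessly to/from YAML.  Thresholds are grouped by stage:
    nucleus QC, marker detection, module discovery, CNV calling, bulk
    signatures, ecotypes and survival testing.
    """

    # nucleus QC
    min_genes: int = 500
    max_genes: int = 8000
    max_mito: float = 0.05
    mito_prefix: str = "MT-"
    # marker detection
    min_log2fc: float = 0.25
    min_frac: float = 0.10
    # module discovery
    n_components: int = 10
    top_k: int = 50
    sim_threshold: float = 0.4
    min_neighbors: int = 2
    min_tumors: int = 3
    min_cell_count: int = 250
    recurrence_fraction: float = 0.5
    n_bins: int = 25
    n_ctrl: int = 50
    # CNV calling
    window: int = 100
    min_mean_count: float = 0.1
    denoise_sd: float = 1.5
    ci_level: float = 0.99
    genome_fraction: float = 0.03
    # bulk signatures
    min_cells_signature: int = 50
    ssgsea_alpha: float = 0.25
    # ecotypes
    zcap: float = 3.0
    max_k: int = 10
    n_resamples: int = 100
    subsample_frac: float = 0.8
    # survival
    alpha: float = 0.05
    # plumbing
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def log_resolved(self) -> None:
        logger.info("resolved run configuration: %s", dataclasses.asdict(self))


# ---------------------------------------------------------------------------
# counts triplet I/O
# ---------------------------------------------------------------------------

def _read_id_file(path: str | Path, what: str) -> np.ndarray:
    # features.tsv may carry extra columns (10x style); the id is column 0
    ids = [line.split("\t")[0] for line in
           Path(path).read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in {what} file {path}")
    return np.asarray(ids, dtype=object)


def read_counts(matrix_path: str | Path, genes_path: str | Path,
                barcodes_path: str | Path, metadata_path: str | Path,
                gene_pos_path: str | Path | None = None) -> CountMatrix:
    """Load a 10x-style triplet plus per-cell metadata into a CountMatrix.

    The matrix file is Matrix Market coordinate (genes as rows); metadata is
    a TSV keyed by a ``barcode`` column.  ``gene_pos_path`` optionally points
    to a BED-like TSV (chrom, start, end, gene id).
    """
    for p in (matrix_path, genes_path, barcodes_path, metadata_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(str(matrix_path))
    if not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat.data != np.round(mat.data)):
            raise ValueError("matrix contains non-integer entries")
    genes = _read_id_file(genes_path, "gene")
    barcodes = _read_id_file(barcodes_path, "barcode")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"barcode": str})
    if "barcode" not in meta.columns:
        raise ValueError("metadata must have a 'barcode' column")
    meta = meta.set_index("barcode")
    gene_pos = None
    if gene_pos_path is not None:
        gene_pos = read_gene_positions(gene_pos_path)
    cm = CountMatrix(counts=sp.csr_matrix(mat), gene_ids=genes,
                     barcodes=barcodes, metadata=meta, gene_pos=gene_pos)
    logger.info("read %d genes x %d cells from %s", cm.n_genes, cm.n_cells,
                matrix_path)
    return cm


def write_counts(cm: CountMatrix, out_dir: str | Path) -> None:
    """Write the 10x-style triplet plus metadata (and gene positions) to a dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), cm.counts.tocoo(), field="integer")
    (out / "features.tsv").write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(map(str, cm.barcodes)) + "\n")
    cm.metadata.rename_axis("barcode").reset_index().to_csv(
        out / "metadata.tsv", sep="\t", index=False)
    if cm.gene_pos is not None:
        write_gene_positions(cm.gene_pos, out / "gene_positions.tsv")


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    """BED-like TSV (chrom, start, end, gene) -> DataFrame indexed by gene."""
    gp = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"])
    return gp.set_index("gene")[["chrom", "start", "end"]]


def write_gene_positions(gene_pos: pd.DataFrame, path: str | Path) -> None:
    gene_pos.reset_index()[["chrom", "start", "end",
                            gene_pos.index.name or "index"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line has <3 tab-separated fields")
        sets.append(GeneSet(name=fields[0], description=fields[1],
                            genes=list(fields[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------

def read_cohort(expr_path: str | Path, clinical_path: str | Path) -> BulkCohort:
    """Inner-join a samples x genes expression TSV with a clinical TSV."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    clinical = pd.read_csv(clinical_path, sep="\t", index_col=0)
    shared = expr.index.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("no shared sample ids between expression and clinical")
    logger.info("cohort join: %d expression x %d clinical -> %d shared samples",
                len(expr), len(clinical), len(shared))
    return BulkCohort(expr=expr.loc[shared], clinical=clinical.loc[shared])


def write_cohort(cohort: BulkCohort, expr_path: str | Path,
                 clinical_path: str | Path) -> None:
    cohort.expr.rename_axis("sample").to_csv(expr_path, sep="\t")
    cohort.clinical.rename_axis("sample").to_csv(clinical_path, sep="\t")
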