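"""Count-matrix ingestion and cell-level quality control.

Reads the three common on-disk layouts (10x MTX triplet, H5AD, dense CSV) into
an :class:`~scpix.containers.ExpressionMatrix`, computes the standard per-cell
QC metrics (genes detected ``nFeature_RNA``, total UMI ``nCount_RNA``, percent
mitochondrial UMI ``percent.mt``) and filters low-quality cells: droplets with
very few detected genes, putative doublets with abnormally many, and dying
cells dominated by mitochondrial transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, QCMetrics, ValidationError

# Default thresholds: detected-gene window 300-4000 (inclusive) and at most
# 15% mitochondrial UMI; nCount bounds exist but are off by default.
MIN_FEATURES = 300
MAX_FEATURES = 4000
MAX_PCT_MT = 15.0


class InputError(FileNotFoundError):
    """A required input file is missing."""


def _read_mtx10x(path: Path) -> ExpressionMatrix:
    """Read a 10x-style triplet directory: matrix.mtx + barcodes.tsv + features.tsv.

    On disk the matrix is genes x cells (10x convention); it is transposed so
    cells are rows. ``genes.tsv`` is accepted as a legacy alias of
    ``features.tsv``.
    """
    mtx = path / "matrix.mtx"
    barcodes = path / "barcodes.tsv"
    features = path / "features.tsv"
    if not features.exists() and (path / "genes.tsv").exists():
        features = path / "genes.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise InputError(f"missing 10x triplet member: {f}")
    m = spio.mmread(mtx)
    X = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=np.float64).T
    cell_ids = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).to_numpy()
    feat = pd.read_csv(features, header=None, sep="\t")
    # features.tsv columns: id, symbol[, type]; use the symbol when present
    gene_col = 1 if feat.shape[1] > 1 else 0
    gene_ids = feat[gene_col].astype(str).to_numpy()
    return ExpressionMatrix(X, cell_ids, gene_ids, layer_tag="counts")


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata as ad

    return ExpressionMatrix.from_anndata(ad.read_h5ad(path))


def _read_csv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        cell_ids=df.index.astype(str).to_numpy(),
        gene_ids=df.columns.astype(str).to_numpy(),
        layer_tag="counts",
    )


_READERS = {"mtx10x": _read_mtx10x, "h5ad": _read_h5ad, "csv": _read_csv}


def load_counts(path, format: str) -> ExpressionMatrix:
    """Load a raw UMI count matrix; cells are rows regardless of on-disk layout.

    Raises
    ------
    InputError
        If ``path`` (or a triplet member) does not exist.
    ValidationError
        On duplicate barcodes/genes or non-integer count values.
    """
    path = Path(path)
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    return _READERS[format](path)


def compute_qc(em: ExpressionMatrix, mt_prefix: str = "MT-",
               case_insensitive: bool = True) -> QCMetrics:
    """Per-cell QC metrics from a counts layer.

    ``percent.mt`` is 100 x (UMI in genes whose name starts with ``mt_prefix``)
    / total UMI; all-zero cells get 0 by convention.
    """
    if em.layer_tag != "counts":
        raise ValidationError("compute_qc expects a counts layer")
    genes = np.asarray([str(g) for g in em.gene_ids])
    if case_insensitive:
        is_mt = np.char.startswith(np.char.upper(genes), mt_prefix.upper())
    else:
        is_mt = np.char.startswith(genes, mt_prefix)
    if not is_mt.any():
        warnings.warn(
            f"no gene name starts with {mt_prefix!r}; percent.mt will be all zero",
            stacklevel=2,
        )
    n_feature = (em.values > 0).sum(axis=1)
    n_count = em.values.sum(axis=1)
    mt_count = em.values[:, is_mt].sum(axis=1) if is_mt.any() else np.zeros(em.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mt = np.where(n_count > 0, 100.0 * mt_count / n_count, 0.0)
    return QCMetrics(n_feature=n_feature, n_count=n_count, pct_mt=pct_mt)


@dataclass
class FilterReport:
    """How many cells each QC rule removed (a cell may violate several)."""

    n_input: int
    n_kept: int
    removed_low_features: int
    removed_high_features: int
    removed_high_mt: int
    removed_low_counts: int = 0
    removed_high_counts: int = 0


def filter_cells(
    em: ExpressionMatrix,
    qc: QCMetrics,
    min_features: int = MIN_FEATURES,
    max_features: int = MAX_FEATURES,
    max_pct_mt: float = MAX_PCT_MT,
    min_counts: Optional[float] = None,
    max_counts: Optional[float] = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep cells with ``min_features <= nFeature <= max_features`` and
    ``percent.mt <= max_pct_mt`` (all bounds inclusive); row order preserved.

    ``min_counts``/``max_counts`` add optional nCount_RNA bounds (off by
    default). Raises if every cell is removed.
    """
    if len(qc.n_feature) != em.n_cells:
        raise ValidationError("QC metrics not aligned to matrix rows")
    low = qc.n_feature < min_features
    high = qc.n_feature > max_features
    mt = qc.pct_mt > max_pct_mt
    low_c = np.zeros(em.n_cells, bool) if min_counts is None else qc.n_count < min_counts
    high_c = np.zeros(em.n_cells, bool) if max_counts is None else qc.n_count > max_counts
    keep = ~(low | high | mt | low_c | high_c)
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review thresholds "
            f"(min_features={min_features}, max_features={max_features}, "
            f"max_pct_mt={max_pct_mt})"
        )
    report = FilterReport(
        n_input=em.n_cells,
        n_kept=int(keep.sum()),
        removed_low_features=int(low.sum()),
        removed_high_features=int(high.sum()),
        removed_high_mt=int(mt.sum()),
        removed_low_counts=int(low_c.sum()),
        removed_high_counts=int(high_c.sum()),
    )
    return em.subset_cells(keep), report
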