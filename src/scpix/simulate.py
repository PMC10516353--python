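"""Synthetic scRNA-seq counts with fully known structure.

The generator emulates, with planted ground truth, the features of real UMI
data the pipeline must handle: negative-binomial counts with log-normal
per-cell depth, per-type marker genes (mean multiplied by ``marker_fold``),
multiplicative per-batch effects on a subset of genes, mitochondrial genes
(``MT-`` prefix), low-quality cells violating QC thresholds (too few detected
genes, or excessive mitochondrial fraction), and an optional novel cell type
present only in the query. Every draw is reproducible from the seed, and the
returned truth tables record exactly what was planted.

It does NOT emulate gene-gene correlation beyond type structure, zero
inflation beyond the NB's own, or cell-cycle / ambient-RNA artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

NOVEL_TYPE_NAME = "novel"


@dataclass
class SimSpec:
    """Stated world of one simulation; defaults follow the standard fixture."""

    n_types: int = 5
    cells_per_type: int = 400
    query_cells_per_type: int = 200
    n_genes: int = 1000
    n_markers_per_type: int = 5
    marker_fold: float = 8.0
    base_mean: float = 1.5
    dispersion: float = 2.0  # NB shape theta; variance = mu + mu^2/theta
    depth_variation: float = 0.25  # sigma of log-normal depth factor
    batch_factor: float = 2.0  # multiplicative effect on affected genes
    batch_gene_frac: float = 0.2  # fraction of genes carrying the batch effect
    frac_qc_violators: float = 0.05
    novel_type: bool = True
    novel_cells: int = 100
    mt_genes: int = 10
    seed: int = 0
    # novel cells suppress reference markers by this factor (out-of-distribution)
    novel_suppression: float = 0.125

    def __post_init__(self) -> None:
        needed = self.n_markers_per_type * (self.n_types + int(self.novel_type))
        if needed > self.n_genes - self.mt_genes:
            raise ValueError(
                f"{needed} disjoint marker genes requested but only "
                f"{self.n_genes - self.mt_genes} non-mitochondrial genes available"
            )
        if not 0 <= self.frac_qc_violators < 0.5:
            raise ValueError("frac_qc_violators must be in [0, 0.5)")


@dataclass
class SimTruth:
    """Everything that was planted: per-cell labels/flags and gene-level keys."""

    reference: pd.DataFrame  # barcode, cell_type, batch, is_violator, is_novel
    query: pd.DataFrame
    markers: Dict[str, List[str]]  # type -> planted marker genes (disjoint)
    batch_genes: List[str]  # genes carrying the multiplicative batch factor
    mt_genes: List[str]


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB via gamma-Poisson mixture: mean ``mean``, shape ``theta``."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam).astype(np.float64)


def _plant_low_feature(rng: np.random.Generator, row: np.ndarray, keep: int | None = None) -> np.ndarray:
    """Zero all but ~10% of genes so nFeature falls far below the QC floor."""
    out = np.zeros_like(row)
    if keep is None:
        keep = max(1, len(row) // 10)
    idx = rng.choice(len(row), size=keep, replace=False)
    out[idx] = row[idx]
    if out.sum() == 0:  # keep the cell nonempty
        out[idx[0]] = 1.0
    return out


def _plant_high_mt(row: np.ndarray, mt_mask: np.ndarray,
                   rng: np.random.Generator, mt_over_rest: float = 0.4) -> np.ndarray:
    """Shift mass into MT- genes so percent.mt lands near 100*r/(1+r) (~28.6%)."""
    out = row.copy()
    rest = out[~mt_mask].sum()
    if rest == 0:
        out[~mt_mask] = 1.0
        rest = out[~mt_mask].sum()
    target_mt = max(int(np.ceil(mt_over_rest * rest)), 1)
    mt_idx = np.flatnonzero(mt_mask)
    alloc = rng.multinomial(target_mt, np.full(len(mt_idx), 1.0 / len(mt_idx)))
    out[mt_idx] = alloc
    return out


def _simulate_block(
    rng: np.random.Generator,
    types: List[str],
    cells_per_type: Dict[str, int],
    gene_means: Dict[str, np.ndarray],
    spec: SimSpec,
    batch_multiplier: Optional[np.ndarray],
    mt_mask: np.ndarray,
    prefix: str,
    violator_pool: Optional[List[str]] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    rows, meta = [], []
    for t in types:
        for _ in range(cells_per_type[t]):
            meta.append(t)
    labels = np.array(meta, dtype=object)
    order = rng.permutation(len(labels))
    labels = labels[order]
    depth = np.exp(rng.normal(0.0, spec.depth_variation, size=len(labels)))
    X = np.zeros((len(labels), spec.n_genes))
    for i, t in enumerate(labels):
        mean = depth[i] * gene_means[t]
        if batch_multiplier is not None:
            mean = mean * batch_multiplier
        X[i] = _nb_draws(rng, mean, spec.dispersion)

    # plant QC violators among eligible (non-novel) cells: half low-feature,
    # half high-mitochondrial; the count is deterministic, placement random
    eligible = np.flatnonzero(
        np.isin(labels, violator_pool if violator_pool is not None else types)
    )
    n_viol = int(round(spec.frac_qc_violators * len(labels)))
    n_viol = min(n_viol, len(eligible))
    viol_idx = rng.choice(eligible, size=n_viol, replace=False)
    is_violator = np.zeros(len(labels), dtype=bool)
    is_violator[viol_idx] = True
    for j, i in enumerate(viol_idx):
        if j % 2 == 0:
            X[i] = _plant_low_feature(rng, X[i])
        else:
            X[i] = _plant_high_mt(X[i], mt_mask, rng)

    truth = pd.DataFrame(
        {
            "barcode": [f"{prefix}{i:05d}" for i in range(len(labels))],
            "cell_type": labels.astype(str),
            "batch": prefix.rstrip("_"),
            "is_violator": is_violator,
            "is_novel": labels.astype(str) == NOVEL_TYPE_NAME,
            "depth_factor": depth,
        }
    )
    return X, truth


def simulate_counts(spec: SimSpec) -> Tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Draw a (reference, query, truth) triple from the stated world.

    The reference holds ``n_types x cells_per_type`` cells in batch ``ref``;
    the query holds ``n_types x query_cells_per_type`` known cells plus (if
    enabled) ``novel_cells`` cells of a type absent from the reference, in
    batch ``query`` with the multiplicative batch factor applied to a random
    ``batch_gene_frac`` of genes. QC violators are planted only among
    known-type cells.
    """
    rng = np.random.default_rng(spec.seed)
    n_named = spec.n_genes - spec.mt_genes
    gene_ids = np.array(
        [f"G{i:04d}" for i in range(n_named)] + [f"MT-{i + 1}" for i in range(spec.mt_genes)],
        dtype=object,
    )
    mt_mask = np.char.startswith(gene_ids.astype(str), "MT-")

    types = [f"type{chr(ord('A') + i)}" for i in range(spec.n_types)]
    marker_pool = rng.permutation(n_named)
    markers: Dict[str, List[str]] = {}
    cursor = 0
    all_types = types + ([NOVEL_TYPE_NAME] if spec.novel_type else [])
    for t in all_types:
        idx = marker_pool[cursor : cursor + spec.n_markers_per_type]
        markers[t] = [str(gene_ids[j]) for j in idx]
        cursor += spec.n_markers_per_type

    ref_marker_cols = [
        int(np.flatnonzero(gene_ids == g)[0]) for t in types for g in markers[t]
    ]

    gene_means: Dict[str, np.ndarray] = {}
    for t in all_types:
        mean = np.full(spec.n_genes, spec.base_mean)
        cols = [int(np.flatnonzero(gene_ids == g)[0]) for g in markers[t]]
        mean[cols] *= spec.marker_fold
        if t == NOVEL_TYPE_NAME:
            mean[ref_marker_cols] *= spec.novel_suppression
        gene_means[t] = mean

    batch_genes_idx = rng.choice(
        spec.n_genes, size=int(round(spec.batch_gene_frac * spec.n_genes)), replace=False
    )
    batch_multiplier = np.ones(spec.n_genes)
    batch_multiplier[batch_genes_idx] = spec.batch_factor

    Xr, truth_ref = _simulate_block(
        rng, types, {t: spec.cells_per_type for t in types}, gene_means, spec,
        batch_multiplier=None, mt_mask=mt_mask, prefix="ref_",
    )
    q_types = list(types)
    q_counts = {t: spec.query_cells_per_type for t in types}
    if spec.novel_type:
        q_types.append(NOVEL_TYPE_NAME)
        q_counts[NOVEL_TYPE_NAME] = spec.novel_cells
    Xq, truth_q = _simulate_block(
        rng, q_types, q_counts, gene_means, spec,
        batch_multiplier=batch_multiplier, mt_mask=mt_mask, prefix="query_",
        violator_pool=types,
    )

    reference = ExpressionMatrix(
        values=Xr,
        cell_ids=truth_ref["barcode"].to_numpy(dtype=object),
        gene_ids=gene_ids,
        batch=truth_ref["batch"].to_numpy(dtype=object),
        cell_type=truth_ref["cell_type"].to_numpy(dtype=object),
        layer_tag="counts",
    )
    query = ExpressionMatrix(
        values=Xq,
        cell_ids=truth_q["barcode"].to_numpy(dtype=object),
        gene_ids=gene_ids,
        batch=truth_q["batch"].to_numpy(dtype=object),
        cell_type=truth_q["cell_type"].to_numpy(dtype=object),
        layer_tag="counts",
    )
    truth = SimTruth(
        reference=truth_ref,
        query=truth_q,
        markers=markers,
        batch_genes=[str(g) for g in gene_ids[np.sort(batch_genes_idx)]],
        mt_genes=[str(g) for g in gene_ids[mt_mask]],
    )
    return reference, query, truth


STANDARD_SEED = 20230731


def standard_fixture() -> Tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """The canonical test world: 5 types x 400 reference cells, a query of
    5 x 200 known + 100 novel cells, 1000 genes (10 MT-), 5 markers per type
    at fold 8, batch factor 2.0 on 20% of genes, 5% planted QC violators."""
    return simulate_counts(SimSpec(seed=STANDARD_SEED))


def write_dataset(
    em: ExpressionMatrix, out_dir, format: str = "mtx10x", name: str = "counts"
) -> Path:
    """Serialize a counts matrix in a supported on-disk layout; returns the path
    to hand to :func:`scpix.ingest.load_counts`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "mtx10x":
        from scipy import io as spio
        from scipy import sparse

        tri = out_dir / name
        tri.mkdir(exist_ok=True)
        spio.mmwrite(tri / "matrix.mtx", sparse.csr_matrix(em.values.T.astype(int)))
        pd.Series(em.cell_ids.astype(str)).to_csv(
            tri / "barcodes.tsv", index=False, header=False
        )
        pd.DataFrame(
            {
                "id": em.gene_ids.astype(str),
                "symbol": em.gene_ids.astype(str),
                "type": "Gene Expression",
            }
        ).to_csv(tri / "features.tsv", sep="\t", index=False, header=False)
        return tri
    if format == "h5ad":
        path = out_dir / f"{name}.h5ad"
        em.to_anndata().write_h5ad(path)
        return path
    if format == "csv":
        path = out_dir / f"{name}.csv"
        pd.DataFrame(
            em.values, index=em.cell_ids.astype(str), columns=em.gene_ids.astype(str)
        ).to_csv(path)
        return path
    raise ValueError(f"unknown format {format!r}")


def write_truth(truth: SimTruth, out_dir) -> Path:
    """Write the per-cell truth TSV (barcode, type, flags, batch) for both
    reference and query cells."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "truth.tsv"
    pd.concat([truth.reference, truth.query], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
    return path
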