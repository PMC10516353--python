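"""Depth normalization, HVG selection, batch correction and [0,1] scaling.

Normalization removes the per-cell sequencing-depth trend with analytic
regularized Pearson residuals under a negative-binomial error model: for gene
g and cell c with depth d_c, the expected count is mu_cg = d_c * p_g where
p_g is the gene's share of total counts, and the residual is

    r_cg = (x_cg - mu_cg) / sqrt(mu_cg + mu_cg**2 / theta_g)

with a per-gene dispersion theta_g estimated by method of moments. Residuals
are clipped to +/- sqrt(n_cells). Under pure depth-proportional Poisson noise
the residuals have mean ~0 and variance ~1, which is the tested contract.

Batch correction is per-gene location/scale matching: each query batch is
affinely transformed so every gene's mean and standard deviation match the
reference. Scaling maps each gene independently to [0,1] using min/max fitted
on the reference, with query values clipped into the reference range so the
image intensity scale is fixed by the training distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

THETA_MIN = 0.01
THETA_MAX = 1e8  # effectively Poisson


def _pearson_residuals(X: np.ndarray, clip: float, theta_min: float) -> np.ndarray:
    depth = X.sum(axis=1, keepdims=True)
    p = X.sum(axis=0) / depth.sum()
    mu = depth * p  # (cells, genes)
    # Method-of-moments dispersion: NB variance mu + mu^2/theta, so the
    # pooled excess over Poisson identifies theta per gene.
    excess = ((X - mu) ** 2 - mu).sum(axis=0)
    mu2 = (mu**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(excess > 0, mu2 / excess, THETA_MAX)
    theta = np.clip(theta, theta_min, THETA_MAX)
    var = mu + mu**2 / theta
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(var > 0, (X - mu) / np.sqrt(var), 0.0)
    return np.clip(r, -clip, clip)


def normalize_counts(
    em: ExpressionMatrix,
    method: str = "pearson_residual",
    clip: float | None = None,
    theta_min: float = THETA_MIN,
) -> ExpressionMatrix:
    """Depth-normalize a counts layer.

    ``pearson_residual`` (default) computes clipped NB Pearson residuals;
    ``log_cpm`` computes log1p(1e4 * x / depth). Cells with zero depth must be
    removed by QC first.
    """
    if em.layer_tag != "counts":
        raise ValidationError("normalize_counts expects a counts layer")
    X = em.values
    depth = X.sum(axis=1)
    if (depth == 0).any():
        raise ValueError(
            f"{int((depth == 0).sum())} cells have zero total counts; "
            "run QC filtering before normalization"
        )
    if method == "pearson_residual":
        if clip is None:
            clip = float(np.sqrt(em.n_cells))
        out = _pearson_residuals(X, clip=clip, theta_min=theta_min)
    elif method == "log_cpm":
        out = np.log1p(1e4 * X / depth[:, None])
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return em.with_values(out, layer_tag="normalized")


def select_hvg(em: ExpressionMatrix, n_genes: int) -> ExpressionMatrix:
    """Keep the ``n_genes`` genes with the largest residual variance.

    Ties at the cutoff are broken toward the lexicographically smaller gene
    name; the retained genes keep their original column order.
    """
    if em.layer_tag != "normalized":
        raise ValidationError("select_hvg expects a normalized layer")
    if n_genes >= em.n_genes:
        if n_genes > em.n_genes:
            warnings.warn(
                f"requested {n_genes} HVGs but only {em.n_genes} genes present; "
                "keeping all",
                stacklevel=2,
            )
        return em
    var = em.values.var(axis=0)
    order = sorted(range(em.n_genes), key=lambda i: (-var[i], str(em.gene_ids[i])))
    chosen = np.zeros(em.n_genes, dtype=bool)
    chosen[order[:n_genes]] = True
    return em.subset_genes(chosen)


def align_query_genes(
    reference_genes: np.ndarray, query: ExpressionMatrix, min_overlap: float = 0.5
) -> tuple[ExpressionMatrix, dict]:
    """Reindex the query to the reference gene order.

    Genes missing from the query become all-zero columns; extra query genes
    are dropped. Errors out below ``min_overlap`` matched fraction (a likely
    species or annotation mismatch).
    """
    reference_genes = np.asarray(reference_genes, dtype=object)
    pos = {str(g): j for j, g in enumerate(query.gene_ids)}
    idx = np.array([pos.get(str(g), -1) for g in reference_genes])
    matched = int((idx >= 0).sum())
    if matched < min_overlap * len(reference_genes):
        raise ValueError(
            f"only {matched}/{len(reference_genes)} reference genes found in query "
            f"(<{min_overlap:.0%}); check species/annotation"
        )
    out = np.zeros((query.n_cells, len(reference_genes)))
    present = idx >= 0
    out[:, present] = query.values[:, idx[present]]
    report = {
        "matched": matched,
        "missing": int(len(reference_genes) - matched),
        "dropped": int(query.n_genes - matched),
    }
    aligned = ExpressionMatrix(
        values=out,
        cell_ids=query.cell_ids,
        gene_ids=reference_genes,
        batch=query.batch,
        cell_type=query.cell_type,
        layer_tag=query.layer_tag,
    )
    return aligned, report


def correct_batch(
    reference: ExpressionMatrix, query: ExpressionMatrix
) -> ExpressionMatrix:
    """Location/scale batch correction of the query onto the reference.

    Each query batch (per its ``batch`` labels, or the whole query if absent)
    is transformed gene-wise so its mean and SD match the reference's.
    Zero-variance query genes are shifted only. The reference is never
    modified.
    """
    for em, name in ((reference, "reference"), (query, "query")):
        if em.layer_tag != "normalized":
            raise ValidationError(f"correct_batch expects normalized {name}")
    if query.n_cells < 2:
        raise ValueError("need at least 2 query cells to estimate batch scale")
    if list(map(str, reference.gene_ids)) != list(map(str, query.gene_ids)):
        raise ValueError("gene order mismatch; run align_query_genes first")
    ref_mean = reference.values.mean(axis=0)
    ref_sd = reference.values.std(axis=0)
    out = query.values.copy()
    groups = (
        [np.ones(query.n_cells, dtype=bool)]
        if query.batch is None
        else [query.batch == b for b in pd.unique(query.batch)]
    )
    for mask in groups:
        block = out[mask]
        q_mean = block.mean(axis=0)
        q_sd = block.std(axis=0)
        scale = np.where(q_sd > 0, ref_sd / np.where(q_sd > 0, q_sd, 1.0), 1.0)
        out[mask] = (block - q_mean) * scale + ref_mean
    return query.with_values(out, layer_tag="normalized")


@dataclass
class GeneScaling:
    """Per-gene min/max fitted on the reference, applied to any aligned matrix."""

    gene_ids: np.ndarray
    per_gene_min: np.ndarray
    per_gene_max: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.per_gene_min = np.asarray(self.per_gene_min, dtype=np.float64)
        self.per_gene_max = np.asarray(self.per_gene_max, dtype=np.float64)
        if (self.per_gene_min > self.per_gene_max).any():
            raise ValidationError("per-gene min exceeds max")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene": self.gene_ids, "min": self.per_gene_min, "max": self.per_gene_max}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneScaling":
        df = pd.read_csv(Path(path), sep="\t")
        return cls(
            gene_ids=df["gene"].to_numpy(dtype=object),
            per_gene_min=df["min"].to_numpy(),
            per_gene_max=df["max"].to_numpy(),
        )


def fit_scaling(reference: ExpressionMatrix) -> GeneScaling:
    """Record each gene's min and max over reference cells."""
    if reference.layer_tag != "normalized":
        raise ValidationError("fit_scaling expects a normalized reference")
    if reference.n_cells == 0 or reference.n_genes == 0:
        raise ValueError("cannot fit scaling on an empty matrix")
    return GeneScaling(
        gene_ids=reference.gene_ids,
        per_gene_min=reference.values.min(axis=0),
        per_gene_max=reference.values.max(axis=0),
    )


def apply_scaling(em: ExpressionMatrix, s: GeneScaling) -> ExpressionMatrix:
    """Map each gene to [0,1] via (v - min)/(max - min), clipped.

    Constant reference genes (max == min) map to 0 for any input value.
    """
    if list(map(str, em.gene_ids)) != list(map(str, s.gene_ids)):
        raise ValueError("gene order mismatch between matrix and scaling")
    span = s.per_gene_max - s.per_gene_min
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, (em.values - s.per_gene_min) / np.where(span > 0, span, 1.0), 0.0)
    return em.with_values(np.clip(scaled, 0.0, 1.0), layer_tag="scaled")
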