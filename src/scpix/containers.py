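"""Tabular containers shared by every pipeline stage.

The pipeline's currency is an :class:`ExpressionMatrix`: a dense cells x genes
matrix plus barcodes, gene names, optional batch and cell-type labels, and a
``layer_tag`` recording which transformation the values carry (raw ``counts``,
depth-``normalized`` residuals, or per-gene min/max ``scaled`` values in [0,1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

LAYER_TAGS = ("counts", "normalized", "scaled")


class ValidationError(ValueError):
    """Input data violates a structural contract (duplicates, shape, dtype)."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with aligned metadata.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` float array. Raw UMI counts carry
        integer-valued floats; later layers are real-valued.
    cell_ids, gene_ids
        Unique barcode / gene-name strings, one per row / column.
    batch
        Optional per-cell categorical batch label.
    cell_type
        Optional per-cell type label (present on labeled references and on
        synthetic truth).
    layer_tag
        One of ``counts``, ``normalized``, ``scaled``.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch: Optional[np.ndarray] = None
    cell_type: Optional[np.ndarray] = None
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cells x genes matrix")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} barcodes for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene names for {n_genes} matrix columns"
            )
        for name, ids in (("cell_ids", self.cell_ids), ("gene_ids", self.gene_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
            if len(dupes):
                raise ValidationError(
                    f"duplicate {name}: {list(map(str, dupes[:5]))}"
                    + (" ..." if len(dupes) > 5 else "")
                )
        if self.layer_tag not in LAYER_TAGS:
            raise ValidationError(f"layer_tag must be one of {LAYER_TAGS}")
        if self.layer_tag == "counts":
            if (self.values < 0).any():
                raise ValidationError("counts layer contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts layer contains non-integer values")
        for name, lab in (("batch", self.batch), ("cell_type", self.cell_type)):
            if lab is not None:
                lab = np.asarray(lab, dtype=object)
                if len(lab) != n_cells:
                    raise ValidationError(f"{name} labels misaligned with cells")
                setattr(self, name, lab)

    # -- convenience -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """Row subset (boolean mask or integer index), metadata kept aligned."""
        return ExpressionMatrix(
            values=self.values[index],
            cell_ids=self.cell_ids[index],
            gene_ids=self.gene_ids,
            batch=None if self.batch is None else self.batch[index],
            cell_type=None if self.cell_type is None else self.cell_type[index],
            layer_tag=self.layer_tag,
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[:, index],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[index],
            batch=self.batch,
            cell_type=self.cell_type,
            layer_tag=self.layer_tag,
        )

    def with_values(self, values: np.ndarray, layer_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids,
            batch=self.batch,
            cell_type=self.cell_type,
            layer_tag=layer_tag,
        )

    def to_anndata(self):
        """Export to :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="barcode"))
        if self.batch is not None:
            obs["batch"] = self.batch.astype(str)
        if self.cell_type is not None:
            obs["cell_type"] = self.cell_type.astype(str)
        var = pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene"))
        adata = ad.AnnData(X=self.values.copy(), obs=obs, var=var)
        adata.uns["layer_tag"] = self.layer_tag
        return adata

    @classmethod
    def from_anndata(cls, adata, layer_tag: Optional[str] = None) -> "ExpressionMatrix":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        return cls(
            values=np.asarray(X, dtype=np.float64),
            cell_ids=np.asarray(adata.obs_names, dtype=object),
            gene_ids=np.asarray(adata.var_names, dtype=object),
            batch=(
                np.asarray(adata.obs["batch"], dtype=object)
                if "batch" in adata.obs
                else None
            ),
            cell_type=(
                np.asarray(adata.obs["cell_type"], dtype=object)
                if "cell_type" in adata.obs
                else None
            ),
            layer_tag=layer_tag or adata.uns.get("layer_tag", "counts"),
        )


@dataclass
class QCMetrics:
    """Per-cell quality metrics: genes detected, total UMI, percent mitochondrial."""

    n_feature: np.ndarray
    n_count: np.ndarray
    pct_mt: np.ndarray

    def __post_init__(self) -> None:
        self.n_feature = np.asarray(self.n_feature)
        self.n_count = np.asarray(self.n_count)
        self.pct_mt = np.asarray(self.pct_mt, dtype=np.float64)
        if not (len(self.n_feature) == len(self.n_count) == len(self.pct_mt)):
            raise ValidationError("QC metric arrays misaligned")

    def to_frame(self, cell_ids: Sequence[str] | None = None) -> pd.DataFrame:
        idx = None if cell_ids is None else pd.Index(cell_ids, name="barcode")
        return pd.DataFrame(
            {
                "nFeature_RNA": self.n_feature,
                "nCount_RNA": self.n_count,
                "percent.mt": self.pct_mt,
            },
            index=idx,
        )
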