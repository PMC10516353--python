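"""Class-activation maps and pixel-to-gene marker extraction.

For each cell type, a gradient-weighted class activation map (Grad-CAM) is
computed on the last convolutional block: channel weights are the spatially
averaged gradients of the class logit, the map is the rectified weighted sum
of activations, bilinearly upsampled to the image frame and averaged over the
class's cells. Because every pixel is owned by known genes (the feature map
is invertible), pixel relevance projects directly onto genes, and the top of
the resulting ranking recovers the type's marker genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .classifier import TrainedModel
from .mapping import FeatureMap, ImageStack

MAX_CELLS_PER_CLASS = 256


@dataclass
class GeneRelevance:
    class_name: str
    cam: np.ndarray  # (P, P), >= 0, max 1 when nonzero
    gene_scores: np.ndarray
    ranked_genes: np.ndarray


def compute_cam(
    model: TrainedModel,
    images: ImageStack,
    class_name: str,
    batch_size: int = 64,
    score: str = "logit",
) -> np.ndarray:
    """Average Grad-CAM over the given cells for ``class_name``.

    Channel weights are the spatially averaged gradients of the class score
    (the raw logit by default; softmax probability via
    ``score="probability"``); the map is the rectified weighted activation
    sum, bilinearly upsampled and averaged over cells. Returns a (P, P)
    non-negative grid, max-normalized to 1 when any value is positive.
    """
    if class_name not in model.class_names:
        raise ValueError(f"class {class_name!r} not in model classes")
    class_idx = model.class_names.index(class_name)
    P = images.pixel_size
    acc = np.zeros((P, P))
    for s in range(0, images.n_cells, batch_size):
        batch = images.pixels[s : s + batch_size]
        act, grad = model.net.feature_gradients(batch, class_idx, score=score)
        weights = grad.mean(axis=(2, 3))  # (N, C)
        cam = np.einsum("nc,nchw->nhw", weights, act)
        cam = np.maximum(cam, 0.0)
        zoom = (1, P / cam.shape[1], P / cam.shape[2])
        # grid_mode treats activation cells as pixel blocks, keeping the
        # upsampled map aligned with the gene pixel grid
        acc += ndimage.zoom(
            cam, zoom, order=1, grid_mode=True, mode="grid-constant"
        ).sum(axis=0)
    acc /= images.n_cells
    m = acc.max()
    if m > 0:
        acc /= m
    return acc


def gene_relevance(cam: np.ndarray, fmap: FeatureMap) -> np.ndarray:
    """Per-gene scores: each gene reads the CAM value at its own pixel."""
    cam = np.asarray(cam, dtype=float)
    if cam.shape != (fmap.pixel_size, fmap.pixel_size):
        raise ValueError(
            f"CAM shape {cam.shape} does not match pixel grid "
            f"({fmap.pixel_size}x{fmap.pixel_size})"
        )
    return cam[fmap.pixel_of_gene[:, 0], fmap.pixel_of_gene[:, 1]]


def gene_relevance_pooled(cam: np.ndarray, fmap: FeatureMap) -> np.ndarray:
    """Radius-1 mean-pooled variant of :func:`gene_relevance`."""
    pooled = ndimage.uniform_filter(np.asarray(cam, dtype=float), size=3, mode="constant")
    return pooled[fmap.pixel_of_gene[:, 0], fmap.pixel_of_gene[:, 1]]


def rank_genes(scores: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Gene names by descending score; ties fall back to lexicographic order."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], str(gene_ids[i])))
    return np.asarray(gene_ids, dtype=object)[order]


def relevance_for_class(
    model: TrainedModel,
    images: ImageStack,
    fmap: FeatureMap,
    class_name: str,
    pooled: bool = False,
) -> GeneRelevance:
    cam = compute_cam(model, images, class_name)
    scores = (gene_relevance_pooled if pooled else gene_relevance)(cam, fmap)
    return GeneRelevance(
        class_name=class_name,
        cam=cam,
        gene_scores=scores,
        ranked_genes=rank_genes(scores, fmap.gene_ids),
    )


def top_markers(
    model: TrainedModel,
    images: ImageStack,
    labels: np.ndarray,
    fmap: FeatureMap,
    k: int = 20,
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Top-``k`` CAM-ranked genes per class.

    ``labels`` assigns each image to a class (predicted or true); classes are
    subsampled to at most 256 cells (seeded) before averaging CAMs. Returns a
    tidy table with columns class, rank, gene, score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels, dtype=object).astype(str)
    rng = np.random.default_rng(seed)
    rows = []
    for class_name in model.class_names:
        idx = np.flatnonzero(labels == class_name)
        if len(idx) == 0:
            warnings.warn(f"no cells labeled {class_name!r}; skipped", stacklevel=2)
            continue
        if len(idx) > MAX_CELLS_PER_CLASS:
            idx = np.sort(rng.choice(idx, MAX_CELLS_PER_CLASS, replace=False))
        sub = ImageStack(
            pixels=images.pixels[idx],
            cell_ids=images.cell_ids[idx],
            map_ref=images.map_ref,
        )
        rel = relevance_for_class(model, sub, fmap, class_name, pooled=pooled)
        score_of = {str(g): s for g, s in zip(fmap.gene_ids, rel.gene_scores)}
        for rank, gene in enumerate(rel.ranked_genes[: min(k, fmap.n_genes)], start=1):
            rows.append(
                {
                    "class": class_name,
                    "rank": rank,
                    "gene": str(gene),
                    "score": float(score_of[str(gene)]),
                }
            )
    return pd.DataFrame(rows, columns=["class", "rank", "gene", "score"])
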