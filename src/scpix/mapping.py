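"""Gene-to-pixel feature mapping: turn expression vectors into images.

Genes — not cells — are the embedded points: each gene's expression profile
across the reference cells is a feature vector, and a 2-D embedding (t-SNE by
default; PCA and UMAP as alternatives) places similar genes near each other.
The minimum-area rectangle enclosing the gene cloud is found with the convex
hull + rotating-calipers construction, the cloud is rotated so that rectangle
is axis-aligned, and coordinates are discretized onto a P x P pixel grid.
Each cell's scaled expression vector then paints one grayscale image: the
pixel of a gene carries that gene's value, genes sharing a pixel are
aggregated (mean by default), and empty pixels stay 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .containers import ExpressionMatrix, ValidationError


def embed_features(
    reference: ExpressionMatrix,
    method: str = "tsne",
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Embed genes into 2-D; deterministic given ``seed``.

    The input matrix is the scaled reference; the embedded points are its
    genes (columns), each described by its values across cells.
    """
    if reference.n_genes < 3:
        raise ValueError("need at least 3 genes to embed")
    X = np.ascontiguousarray(reference.values.T)  # genes x cells
    if method == "tsne":
        if perplexity >= reference.n_genes:
            raise ValueError(
                f"perplexity ({perplexity}) must be < number of genes "
                f"({reference.n_genes}); try {max(2, reference.n_genes // 4)}"
            )
        from sklearn.manifold import TSNE

        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
        )
        return np.asarray(tsne.fit_transform(X), dtype=np.float64)
    if method == "pca":
        from sklearn.decomposition import PCA

        n_comp = min(2, X.shape[1])
        coords = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
        if n_comp < 2:  # single-cell-column degenerate case
            coords = np.column_stack([coords, np.zeros(len(coords))])
        return np.asarray(coords, dtype=np.float64)
    if method == "umap":
        import umap

        um = umap.UMAP(n_components=2, random_state=seed)
        return np.asarray(um.fit_transform(X), dtype=np.float64)
    raise ValueError(f"unknown embedding method {method!r}")


def min_area_rectangle(coords: np.ndarray) -> Tuple[float, float, float, float]:
    """Minimum-area enclosing rectangle of a 2-D point set.

    Returns ``(angle_deg, width, height, area)`` where rotating the points by
    ``-angle_deg`` axis-aligns the optimal rectangle; the angle is normalized
    to [0, 90). Uses the rotating-calipers fact that some side of an optimal
    rectangle is collinear with a convex-hull edge. Degenerate inputs
    (single point, collinear points) yield zero-area rectangles.
    """
    pts = np.asarray(coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("coords must be a non-empty (n, 2) array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return 0.0, 0.0, 0.0, 0.0
    try:
        hull = ConvexHull(uniq)
        hull_pts = uniq[hull.vertices]
    except QhullError:  # collinear
        d = uniq - uniq[0]
        direction = d[np.argmax(np.einsum("ij,ij->i", d, d))]
        angle = float(np.degrees(np.arctan2(direction[1], direction[0]))) % 90.0
        proj = d @ (direction / np.linalg.norm(direction))
        return angle, float(proj.max() - proj.min()), 0.0, 0.0

    edges = np.diff(np.vstack([hull_pts, hull_pts[:1]]), axis=0)
    angles = np.arctan2(edges[:, 1], edges[:, 0]) % (np.pi / 2)
    best = None
    for a in np.unique(angles):
        c, s = np.cos(-a), np.sin(-a)
        rot = hull_pts @ np.array([[c, -s], [s, c]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        area = w * h
        if best is None or area < best[3]:
            best = (float(np.degrees(a) % 90.0), float(w), float(h), float(area))
    return best


@dataclass
class FeatureMap:
    """A fixed, invertible gene -> pixel assignment.

    ``pixel_of_gene[g]`` is the 0-based (row, col) of gene g, with row 0 at
    the image top; ``genes_at_pixel`` is the exact inverse. Rebuilding with
    the same seed and inputs reproduces the map bit-for-bit.
    """

    gene_ids: np.ndarray
    embedding: np.ndarray
    rotation_deg: float
    pixel_size: int
    pixel_of_gene: np.ndarray  # (n_genes, 2) int
    perplexity: float
    seed: int
    method: str = "tsne"
    aggregator: str = "mean"
    genes_at_pixel: Dict[Tuple[int, int], List[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.pixel_of_gene = np.asarray(self.pixel_of_gene, dtype=int)
        P = self.pixel_size
        if ((self.pixel_of_gene < 0) | (self.pixel_of_gene >= P)).any():
            raise ValidationError("pixel assignment outside the grid")
        if not self.genes_at_pixel:
            inv: Dict[Tuple[int, int], List[int]] = {}
            for g, (r, c) in enumerate(self.pixel_of_gene):
                inv.setdefault((int(r), int(c)), []).append(g)
            self.genes_at_pixel = inv

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def collision_summary(self) -> dict:
        sizes = [len(v) for v in self.genes_at_pixel.values()]
        return {
            "pixels_used": len(sizes),
            "pixels_with_collision": int(sum(s > 1 for s in sizes)),
            "max_genes_per_pixel": int(max(sizes)) if sizes else 0,
        }

    def identifier(self) -> str:
        """Stable content hash used to detect map/model skew."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.pixel_of_gene.tobytes())
        h.update("".join(map(str, self.gene_ids)).encode())
        h.update(f"{self.pixel_size}:{self.seed}:{self.method}".encode())
        return h.hexdigest()[:16]

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": [str(g) for g in self.gene_ids],
            "embedding": self.embedding.tolist(),
            "rotation_deg": self.rotation_deg,
            "pixel_size": self.pixel_size,
            "pixel_of_gene": self.pixel_of_gene.tolist(),
            "perplexity": self.perplexity,
            "seed": self.seed,
            "method": self.method,
            "aggregator": self.aggregator,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "FeatureMap":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=np.array(d["gene_ids"], dtype=object),
            embedding=np.array(d["embedding"]),
            rotation_deg=d["rotation_deg"],
            pixel_size=d["pixel_size"],
            pixel_of_gene=np.array(d["pixel_of_gene"]),
            perplexity=d["perplexity"],
            seed=d["seed"],
            method=d.get("method", "tsne"),
            aggregator=d.get("aggregator", "mean"),
        )


def build_feature_map(
    coords: np.ndarray,
    gene_ids: np.ndarray,
    pixel_size: int = 64,
    perplexity: float = 30.0,
    seed: int = 0,
    method: str = "tsne",
    aggregator: str = "mean",
    collision_warn_frac: float = 0.5,
) -> FeatureMap:
    """Discretize a 2-D gene embedding onto a ``pixel_size`` grid.

    The embedding is rotated to axis-align its minimum-area rectangle, each
    axis is scaled independently to [0, P-1], the y axis is flipped so row 0
    is the image top, and coordinates are rounded to the nearest pixel.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if pixel_size < 2:
        raise ValueError("pixel_size must be >= 2")
    if len(coords) != len(gene_ids):
        raise ValueError("one coordinate pair per gene required")
    angle, _, _, _ = min_area_rectangle(coords)
    a = np.radians(-angle)
    c, s = np.cos(a), np.sin(a)
    rot = coords @ np.array([[c, -s], [s, c]]).T
    P = pixel_size
    cols = np.zeros(len(rot), dtype=int)
    rows = np.zeros(len(rot), dtype=int)
    for axis, out in ((0, cols), (1, rows)):
        lo, hi = rot[:, axis].min(), rot[:, axis].max()
        span = hi - lo
        if span == 0:
            out[:] = 0
        else:
            out[:] = np.clip(np.round((rot[:, axis] - lo) / span * (P - 1)), 0, P - 1)
    rows = (P - 1) - rows  # Cartesian y-up -> image row-down
    fmap = FeatureMap(
        gene_ids=np.asarray(gene_ids, dtype=object),
        embedding=coords,
        rotation_deg=float(angle),
        pixel_size=P,
        pixel_of_gene=np.column_stack([rows, cols]),
        perplexity=perplexity,
        seed=seed,
        method=method,
        aggregator=aggregator,
    )
    summary = fmap.collision_summary()
    n_colliding = fmap.n_genes - summary["pixels_used"]
    if fmap.n_genes and n_colliding > collision_warn_frac * fmap.n_genes:
        import warnings

        warnings.warn(
            f"{n_colliding}/{fmap.n_genes} genes share pixels at P={P}; "
            "consider a larger pixel_size",
            stacklevel=2,
        )
    return fmap


@dataclass
class ImageStack:
    """Per-cell single-channel images aligned to a FeatureMap."""

    pixels: np.ndarray  # (cells, P, P) in [0,1]
    cell_ids: np.ndarray
    map_ref: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.pixels.ndim != 3 or self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValidationError("pixels must be (cells, P, P)")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError("image intensities must lie in [0,1]")

    @property
    def n_cells(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_size(self) -> int:
        return self.pixels.shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("pixels", data=self.pixels.astype(np.float32))
            f.create_dataset(
                "cell_ids", data=np.array([str(c) for c in self.cell_ids], dtype="S")
            )
            f.attrs["map_ref"] = self.map_ref

    @classmethod
    def from_hdf5(cls, path) -> "ImageStack":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                pixels=f["pixels"][...].astype(np.float64),
                cell_ids=np.array([b.decode() for b in f["cell_ids"][...]], dtype=object),
                map_ref=str(f.attrs["map_ref"]),
            )

    def to_png_dir(self, path) -> None:
        import imageio.v3 as iio

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for cid, img in zip(self.cell_ids, self.pixels):
            iio.imwrite(out / f"{cid}.png", np.round(255 * img).astype(np.uint8))


def cells_to_images(
    em: ExpressionMatrix, fmap: FeatureMap, aggregator: str | None = None
) -> ImageStack:
    """Paint each cell's scaled expression vector into a P x P image.

    A pixel's intensity is the ``mean`` (default) or ``max`` of the scaled
    values of all genes assigned to it; pixels hosting no gene are exactly 0.
    """
    if em.layer_tag != "scaled":
        raise ValidationError("cells_to_images expects a scaled layer")
    if list(map(str, em.gene_ids)) != list(map(str, fmap.gene_ids)):
        raise ValueError("matrix genes do not match the feature map")
    aggregator = aggregator or fmap.aggregator
    P = fmap.pixel_size
    flat_pix = fmap.pixel_of_gene[:, 0] * P + fmap.pixel_of_gene[:, 1]
    n_cells = em.n_cells
    out = np.zeros((n_cells, P * P))
    if aggregator == "mean":
        np.add.at(out.T, flat_pix, em.values.T)
        counts = np.bincount(flat_pix, minlength=P * P)
        nz = counts > 0
        out[:, nz] /= counts[nz]
    elif aggregator == "max":
        order = np.argsort(flat_pix, kind="stable")
        sorted_pix = flat_pix[order]
        starts = np.flatnonzero(np.r_[True, sorted_pix[1:] != sorted_pix[:-1]])
        maxes = np.maximum.reduceat(em.values[:, order], starts, axis=1)
        out[:, sorted_pix[starts]] = maxes
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return ImageStack(
        pixels=out.reshape(n_cells, P, P),
        cell_ids=em.cell_ids,
        map_ref=fmap.identifier(),
    )


def inverse_lookup(fmap: FeatureMap, row: int, col: int) -> List[str]:
    """Gene names assigned to pixel (row, col); empty list for empty pixels."""
    P = fmap.pixel_size
    if not (0 <= row < P and 0 <= col < P):
        raise ValueError(f"pixel ({row},{col}) outside the {P}x{P} grid")
    return [str(fmap.gene_ids[g]) for g in fmap.genes_at_pixel.get((row, col), [])]
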