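"""Supervised mapping of genes into class-discriminative 2D images.

The transform places each selected gene at a pixel of a small image so that
genes with similar discriminative behaviour land near each other:

1. score every gene with the two-class Fisher criterion
   (mu1 - mu0)^2 / (s1^2 + s0^2), where the variances are population
   variances over the task's two sample groups;
2. bin genes into K equal-count categories by Fisher-score rank;
3. run linear discriminant analysis with *genes as observations* — each
   gene's feature vector is its expression across the training samples and
   its class is its Fisher category — and keep the top two discriminant
   axes as 2D coordinates;
4. tighten the layout by rotating the minimal-area enclosing rectangle of
   the point cloud (rotating-calipers over the convex hull) onto the axes;
5. rasterize onto a fixed pixel grid; genes that collide on a pixel are
   averaged when images are rendered.

Each per-sample image then carries that sample's expression values arranged
by discriminative similarity — the second modality for the fusion
classifier.  The map is a supervised, task-specific artifact: it must be
fitted on training samples only, and `fitted_on_` records provenance so
leakage can be asserted downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import pinvh
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix
from .errors import ConfigError, DegeneracyError

FISHER_EPS = 1e-12
DEFAULT_CATEGORIES = 15
DEFAULT_RESOLUTION = (50, 50)


# ---------------------------------------------------------------------------
# Fisher scoring and categorization
# ---------------------------------------------------------------------------

def fisher_scores(X: np.ndarray, y: np.ndarray, eps: float = FISHER_EPS) -> np.ndarray:
    """Two-class Fisher criterion per gene.

    Parameters
    ----------
    X : (n_samples, n_genes) expression design matrix
    y : (n_samples,) binary labels
    eps : variance-floor guard so equal constant classes give 0, not NaN

    Returns ``(mu1 - mu0)^2 / (var1 + var0 + eps)`` with population
    (ddof=0) class variances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    g0, g1 = X[y == 0], X[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each class needs >= 2 samples for Fisher scoring")
    d = g1.mean(axis=0) - g0.mean(axis=0)
    return d**2 / (g1.var(axis=0) + g0.var(axis=0) + eps)


def categorize(scores: np.ndarray, n_categories: int = DEFAULT_CATEGORIES) -> np.ndarray:
    """Equal-count categories by ascending Fisher-score rank.

    Genes are sorted by score (ties broken by gene index, so the result is
    deterministic) and cut into ``n_categories`` contiguous rank blocks whose
    sizes differ by at most one; when the division is uneven the larger
    blocks go to the lower category numbers.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n_categories < 2:
        raise ConfigError("need at least 2 categories")
    if n < n_categories:
        raise ConfigError(f"{n} genes cannot fill {n_categories} categories")
    order = np.argsort(scores, kind="stable")  # stable = ties by gene index
    base, rem = divmod(n, n_categories)
    sizes = [base + 1 if c < rem else base for c in range(n_categories)]
    cats = np.empty(n, dtype=int)
    start = 0
    for c, size in enumerate(sizes):
        cats[order[start : start + size]] = c
        start += size
    return cats


# ---------------------------------------------------------------------------
# LDA on genes
# ---------------------------------------------------------------------------

def _scatter_matrices(F: np.ndarray, cats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = F.mean(axis=0)
    p = F.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in np.unique(cats):
        Fc = F[cats == c]
        mc = Fc.mean(axis=0)
        D = Fc - mc
        Sw += D.T @ D
        dm = (mc - mu)[:, None]
        Sb += len(Fc) * (dm @ dm.T)
    return Sw, Sb


def lda_project(F: np.ndarray, categories: np.ndarray) -> np.ndarray:
    """Project genes onto the top-2 discriminant axes of their categories.

    ``F`` is genes x features where each gene's features are its expression
    values across the training samples.  Solves the generalized eigenproblem
    of between- vs within-category scatter, using the pseudo-inverse of the
    within-scatter when it is singular (common: the number of genes is of
    the order of the number of sample-features).  Sign convention: on each
    axis the largest-magnitude eigenvector loading is made positive, so the
    output is reproducible bit-for-bit.
    """
    F = np.asarray(F, dtype=float)
    categories = np.asarray(categories)
    if len(np.unique(categories)) < 3:
        raise ConfigError("LDA 2D projection needs at least 3 categories")
    if np.allclose(F, F[0]):
        raise DegeneracyError("all gene feature vectors identical")
    Sw, Sb = _scatter_matrices(F, categories)
    M = pinvh(Sw) @ Sb
    eigvals, eigvecs = np.linalg.eig(M)
    order = np.argsort(eigvals.real)[::-1]
    W = eigvecs[:, order[:2]].real
    # unit-normalize and fix sign for determinism
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return (F - F.mean(axis=0)) @ W


# ---------------------------------------------------------------------------
# minimal enclosing rectangle
# ---------------------------------------------------------------------------

def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return points @ np.array([[c, -s], [s, c]]).T


def min_rectangle_align(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate a point cloud so its minimal-area enclosing rectangle is axis-aligned.

    Uses the rotating-calipers property: the minimal rectangle has one side
    collinear with a convex-hull edge, so only hull-edge orientations need
    checking.  Area ties are broken by the smallest rotation magnitude; the
    applied rotation is normalized into (-45, 45] degrees since rectangle
    orientation is modulo 90 degrees.

    Returns (rotated points, applied rotation angle in radians).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise DegeneracyError("need at least 3 points")
    try:
        hull = ConvexHull(points)
    except QhullError as e:
        raise DegeneracyError(f"degenerate point cloud (collinear/coincident): {e}") from None
    vertices = points[hull.vertices]
    edges = np.roll(vertices, -1, axis=0) - vertices
    best: tuple[float, float] | None = None  # (area, angle)
    for dx, dy in edges:
        theta = np.arctan2(dy, dx) % (np.pi / 2)
        if theta > np.pi / 4:
            theta -= np.pi / 2
        angle = -theta  # rotation that aligns this edge with an axis
        rot = _rotate(vertices, angle)
        span = rot.max(axis=0) - rot.min(axis=0)
        area = float(span[0] * span[1])
        if (
            best is None
            or area < best[0] - 1e-12
            or (abs(area - best[0]) <= 1e-12 and abs(angle) < abs(best[1]))
        ):
            best = (area, angle)
    assert best is not None
    return _rotate(points, best[1]), best[1]


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------

def _half_up(v: np.ndarray) -> np.ndarray:
    """Round half-up (0.5 -> 1), frozen so pixel assignment is reproducible."""
    return np.floor(v + 0.5).astype(int)


@dataclass
class GeneMap:
    """A fitted gene -> pixel mapping at a given resolution."""

    coords_2d: np.ndarray  # (n_genes, 2) post-rotation coordinates
    resolution: tuple[int, int]  # (rows, cols)
    pixel_of_gene: np.ndarray  # (n_genes, 2) int (row, col), 0-based, row 0 = top
    rotation_angle: float
    fitted_on: list[str]  # sample IDs the map was fitted on (provenance)

    @property
    def genes_of_pixel(self) -> dict[tuple[int, int], list[int]]:
        out: dict[tuple[int, int], list[int]] = {}
        for g, (r, c) in enumerate(self.pixel_of_gene):
            out.setdefault((int(r), int(c)), []).append(g)
        return out

    @property
    def n_genes(self) -> int:
        return len(self.pixel_of_gene)

    def to_json(self, path: str | Path, probe_ids: list[str] | None = None) -> None:
        ids = probe_ids or [str(i) for i in range(self.n_genes)]
        obj = {
            "resolution": list(self.resolution),
            "rotation_angle": self.rotation_angle,
            "fitted_on": self.fitted_on,
            "pixel_of_gene": {p: [int(r), int(c)] for p, (r, c) in zip(ids, self.pixel_of_gene)},
            "coords_2d": {p: [float(x), float(y)] for p, (x, y) in zip(ids, self.coords_2d)},
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["GeneMap", list[str]]:
        obj = json.loads(Path(path).read_text())
        ids = list(obj["pixel_of_gene"])
        return (
            cls(
                coords_2d=np.array([obj["coords_2d"][p] for p in ids], dtype=float),
                resolution=tuple(obj["resolution"]),
                pixel_of_gene=np.array([obj["pixel_of_gene"][p] for p in ids], dtype=int),
                rotation_angle=float(obj["rotation_angle"]),
                fitted_on=list(obj["fitted_on"]),
            ),
            ids,
        )


def rasterize(
    coords: np.ndarray,
    resolution: tuple[int, int] = DEFAULT_RESOLUTION,
    rotation_angle: float = 0.0,
    fitted_on: list[str] | None = None,
) -> GeneMap:
    """Snap 2D gene coordinates onto a (rows, cols) pixel grid.

    Each axis is min–max scaled — x to [0, cols-1], y to [0, rows-1] — and
    rounded half-up to the nearest pixel.  Row 0 is the top of the image;
    y increases downward after scaling (pure relabeling of an arbitrary
    LDA axis direction).
    """
    coords = np.asarray(coords, dtype=float)
    rows, cols = resolution
    if rows < 2 or cols < 2:
        raise ConfigError("resolution must be at least 2x2")
    span = coords.max(axis=0) - coords.min(axis=0)
    if span[0] <= 0 or span[1] <= 0:
        raise DegeneracyError("zero coordinate range on an axis; cannot rasterize")
    scaled_x = (coords[:, 0] - coords[:, 0].min()) / span[0] * (cols - 1)
    scaled_y = (coords[:, 1] - coords[:, 1].min()) / span[1] * (rows - 1)
    pixel = np.stack([_half_up(scaled_y), _half_up(scaled_x)], axis=1)
    return GeneMap(
        coords_2d=coords,
        resolution=(rows, cols),
        pixel_of_gene=pixel,
        rotation_angle=rotation_angle,
        fitted_on=list(fitted_on or []),
    )


def render_images(X: np.ndarray, gene_map: GeneMap) -> np.ndarray:
    """Render one image per sample: pixel value = mean expression of its genes.

    ``X`` is samples x genes in the gene order the map was fitted with.
    Pixels with no assigned gene are 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != gene_map.n_genes:
        raise ValueError(
            f"matrix has {X.shape[1]} genes but map was fitted on {gene_map.n_genes}"
        )
    rows, cols = gene_map.resolution
    flat = gene_map.pixel_of_gene[:, 0] * cols + gene_map.pixel_of_gene[:, 1]
    counts = np.bincount(flat, minlength=rows * cols)
    sums = np.zeros((X.shape[0], rows * cols))
    np.add.at(sums.T, flat, X.T)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.where(counts == 0, 1, counts), 0.0)
    return means.reshape(X.shape[0], rows, cols)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class GeneImageMapper(BaseEstimator, TransformerMixin):
    """Fit the full gene-to-image transform; render images for any samples.

    Parameters
    ----------
    n_categories : number of Fisher-rank bins (K); default 15
    resolution : (rows, cols) of the output image; default (50, 50)

    Attributes (after fit)
    ----------------------
    scores_ : per-gene Fisher scores
    categories_ : per-gene category labels in [0, K-1]
    map_ : the fitted :class:`GeneMap` (pixel assignments, rotation, provenance)

    The map is task-specific (it depends on the binary labels), so one
    mapper per pairwise task is fitted; `fitted_on_` lists the training
    sample IDs for leakage checks.
    """

    def __init__(
        self,
        n_categories: int = DEFAULT_CATEGORIES,
        resolution: tuple[int, int] = DEFAULT_RESOLUTION,
    ):
        self.n_categories = n_categories
        self.resolution = resolution

    def fit(self, X: np.ndarray, y: np.ndarray, sample_ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        self.scores_ = fisher_scores(X, y)
        self.categories_ = categorize(self.scores_, self.n_categories)
        raw = lda_project(X.T, self.categories_)
        rotated, angle = min_rectangle_align(raw)
        ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(X))]
        self.map_ = rasterize(rotated, tuple(self.resolution), angle, fitted_on=ids)
        self.fitted_on_ = self.map_.fitted_on
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return render_images(X, self.map_)


def fit_gene_map(
    matrix: ExpressionMatrix,
    n_categories: int = DEFAULT_CATEGORIES,
    resolution: tuple[int, int] = DEFAULT_RESOLUTION,
) -> GeneMap:
    """Fit a gene map on a pairwise-task subset (binary labels attached)."""
    if matrix.binary_labels is None:
        raise ValueError("matrix has no binary labels; run make_pair_subset first")
    mapper = GeneImageMapper(n_categories=n_categories, resolution=resolution)
    mapper.fit(matrix.X, matrix.binary_labels, sample_ids=matrix.sample_ids)
    return mapper.map_
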