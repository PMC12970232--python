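"""Unsupervised dual-feature tumor/normal discrimination.

Two complementary feature views are extracted per image — a gray-level
intensity histogram and an edge summary (Canny densities plus a Sobel
gradient-magnitude histogram) — each standardized, PCA-reduced, and
clustered with K-means (k = 2).  Cluster indices are aligned to ground
truth by the accuracy-maximizing permutation, and the two views are
combined with an OR-toward-tumor rule that can only raise sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "FeatureMatrix",
    "ClusterResult",
    "intensity_features",
    "edge_features",
    "build_feature_matrix",
    "pca_kmeans",
    "align_labels",
    "dual_combine",
    "embed_2d",
    "run_discrimination",
]

VIEWS = ("intensity", "edge")
NORMAL, TUMOR = "normal", "tumor"


def _default_mask(shape) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    return np.hypot(yy - cy, xx - cx) <= min(ny, nx) / 2.0


def intensity_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    bins: int = 64,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Normalized gray-level histogram inside the mask (sums to 1)."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = _default_mask(image.shape)
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    if value_range is None:
        lo, hi = vals.min(), vals.max()
    else:
        lo, hi = value_range
    if hi <= lo:
        hi = lo + 1.0
    hist, _ = np.histogram(vals, bins=bins, range=(lo, hi))
    return hist / hist.sum()


def edge_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    n_annuli: int = 8,
    sobel_bins: int = 16,
    sigma: float = 1.0,
    sobel_range: float | None = None,
) -> np.ndarray:
    """Canny edge densities (overall + radial annuli) and Sobel histogram.

    Canny thresholds are derived per image from the gradient-magnitude
    distribution: high = 90th percentile, low = 0.4 * high.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = _default_mask(image.shape)
    grad = sobel(image)
    high = float(np.percentile(grad[mask], 90))
    # guard: numerically flat images must not trip Canny on rounding noise
    flat = np.ptp(image[mask]) <= 1e-12 * max(1.0, float(np.abs(image).max()))
    if high > 0 and not flat:
        edges = canny(image, sigma=sigma, low_threshold=0.4 * high,
                      high_threshold=high)
    else:
        edges = np.zeros(image.shape, dtype=bool)
    edges &= mask
    overall = edges.sum() / mask.sum()
    ny, nx = image.shape
    yy, xx = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    rmax = r[mask].max()
    annuli = np.empty(n_annuli)
    for k in range(n_annuli):
        ring = mask & (r >= rmax * k / n_annuli) & (r < rmax * (k + 1) / n_annuli)
        annuli[k] = edges[ring].sum() / max(int(ring.sum()), 1)
    gvals = grad[mask]
    hi = sobel_range if sobel_range is not None else float(gvals.max())
    if hi <= 0:
        hist = np.zeros(sobel_bins)
        hist[0] = 1.0
    else:
        hist, _ = np.histogram(gvals, bins=sobel_bins, range=(0, hi))
        hist = hist / hist.sum()
    return np.concatenate([[overall], annuli, hist])


@dataclass
class FeatureMatrix:
    """Standardized per-image features for one view."""

    X: np.ndarray
    view: str
    mean: np.ndarray = field(default=None, repr=False)
    sd: np.ndarray = field(default=None, repr=False)
    pca_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (images x features)")


def build_feature_matrix(
    images,
    view: str,
    mask: np.ndarray | None = None,
    *,
    resize_to: int | None = 128,
) -> FeatureMatrix:
    """Extract one view's features for a dataset and standardize columns.

    Images are resampled to ``resize_to`` squared for cohort uniformity;
    histogram ranges are shared across the dataset so brightness
    differences between images are preserved.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    prepped = []
    for img in images:
        arr = np.asarray(img, dtype=float)
        if resize_to is not None and arr.shape != (resize_to, resize_to):
            arr = resize(arr, (resize_to, resize_to), anti_aliasing=True)
        prepped.append(arr)
    if mask is None and prepped:
        mask = _default_mask(prepped[0].shape)
    if view == "intensity":
        lo = min(float(a[mask].min()) for a in prepped)
        hi = max(float(a[mask].max()) for a in prepped)
        rows = [
            intensity_features(a, mask, value_range=(lo, hi)) for a in prepped
        ]
    else:
        smax = max(float(sobel(a)[mask].max()) for a in prepped)
        rows = [edge_features(a, mask, sobel_range=smax) for a in prepped]
    X = np.vstack(rows)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return FeatureMatrix(X=(X - mean) / sd_safe, view=view, mean=mean, sd=sd)


def pca_kmeans(
    fm: FeatureMatrix, n_components: int = 10, seed: int = 0
) -> np.ndarray:
    """PCA reduction then K-means (k=2, 20 restarts); returns 0/1 labels."""
    n_rows = fm.X.shape[0]
    if n_rows < 2:
        raise ValueError("need at least 2 rows to form 2 clusters")
    k = min(n_components, n_rows - 1, fm.X.shape[1])
    scores = PCA(n_components=k, random_state=seed).fit_transform(fm.X)
    fm.pca_scores = scores
    km = KMeans(n_clusters=2, n_init=20, random_state=seed)
    return km.fit_predict(scores)


def align_labels(pred, truth) -> tuple[np.ndarray, dict]:
    """Map cluster indices to class names by maximizing accuracy.

    Returns the aligned string labels and a metrics dict with accuracy,
    sensitivity (tumor recall), specificity, and confusion counts.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    truth_is_tumor = truth == TUMOR if truth.dtype.kind in "US" else truth.astype(bool)
    best = None
    for tumor_cluster in np.unique(pred):
        pred_is_tumor = pred == tumor_cluster
        acc = float(np.mean(pred_is_tumor == truth_is_tumor))
        if best is None or acc > best[0]:
            best = (acc, pred_is_tumor)
    acc, pred_is_tumor = best
    tp = int(np.sum(pred_is_tumor & truth_is_tumor))
    tn = int(np.sum(~pred_is_tumor & ~truth_is_tumor))
    fp = int(np.sum(pred_is_tumor & ~truth_is_tumor))
    fn = int(np.sum(~pred_is_tumor & truth_is_tumor))
    n_tumor = tp + fn
    n_normal = tn + fp
    metrics = dict(
        accuracy=acc,
        sensitivity=tp / n_tumor if n_tumor else float("nan"),
        specificity=tn / n_normal if n_normal else float("nan"),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )
    labels = np.where(pred_is_tumor, TUMOR, NORMAL)
    return labels, metrics


def dual_combine(labels_a, labels_b, rule: str = "or_tumor") -> np.ndarray:
    """Combine two aligned label vectors.

    ``or_tumor``: tumor iff either view says tumor (never lowers
    sensitivity); ``and_tumor``: tumor iff both views agree on tumor.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must be aligned and of equal length")
    for v in (a, b):
        if not np.isin(v, (NORMAL, TUMOR)).all():
            raise ValueError("labels must be 'normal'/'tumor' (aligned)")
    if rule == "or_tumor":
        out = np.where((a == TUMOR) | (b == TUMOR), TUMOR, NORMAL)
    elif rule == "and_tumor":
        out = np.where((a == TUMOR) & (b == TUMOR), TUMOR, NORMAL)
    else:
        raise ValueError("rule must be 'or_tumor' or 'and_tumor'")
    return out


def embed_2d(fm: FeatureMatrix, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE coordinates for plotting only (no numeric contract)."""
    n = fm.X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 rows for a 2-D embedding")
    perplexity = min(30.0, (n - 1) / 3.0)
    ts = TSNE(
        n_components=2, random_state=seed, init="pca", perplexity=perplexity
    )
    return ts.fit_transform(fm.X)


@dataclass
class ClusterResult:
    """Per-view and combined predictions with alignment-corrected metrics."""

    labels_intensity: np.ndarray
    labels_edge: np.ndarray
    labels_combined: np.ndarray
    metrics_intensity: dict
    metrics_edge: dict
    metrics_combined: dict


def run_discrimination(
    images,
    truth_labels,
    *,
    seed: int = 0,
    rule: str = "or_tumor",
    n_components: int = 10,
    mask: np.ndarray | None = None,
    resize_to: int | None = 128,
) -> ClusterResult:
    """Full dual-view pipeline: features, PCA+K-means, align, combine."""
    truth = np.asarray(truth_labels)
    aligned = {}
    metrics = {}
    for view in VIEWS:
        fm = build_feature_matrix(images, view, mask, resize_to=resize_to)
        raw = pca_kmeans(fm, n_components=n_components, seed=seed)
        aligned[view], metrics[view] = align_labels(raw, truth)
    combined = dual_combine(aligned["intensity"], aligned["edge"], rule)
    # the combined vector is already aligned; compute metrics directly
    truth_is_tumor = truth == TUMOR
    comb_is_tumor = combined == TUMOR
    tp = int(np.sum(comb_is_tumor & truth_is_tumor))
    tn = int(np.sum(~comb_is_tumor & ~truth_is_tumor))
    fp = int(np.sum(comb_is_tumor & ~truth_is_tumor))
    fn = int(np.sum(~comb_is_tumor & truth_is_tumor))
    metrics_combined = dict(
        accuracy=(tp + tn) / len(truth),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )
    return ClusterResult(
        labels_intensity=aligned["intensity"],
        labels_edge=aligned["edge"],
        labels_combined=combined,
        metrics_intensity=metrics["intensity"],
        metrics_edge=metrics["edge"],
        metrics_combined=metrics_combined,
    )
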