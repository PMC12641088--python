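"""Gaussian-mixture clustering of the (slope, dc) plane.

Participants are clustered on the two-dimensional feature point (slope
of the pivotal regression, determination coefficient).  The number of
components is chosen by maximising the mean silhouette value over a
range of candidate K, and each component is summarised by its 95%
confidence ellipse (Mahalanobis radius sqrt(chi2_quantile(0.95; 2))
= 2.45).

Components are relabelled so that cluster 0 is always the component
whose mean lies closest to the intact-response point (1, 1); remaining
components follow by increasing distance from that point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

REFERENCE_POINT = np.array([1.0, 1.0])  # slope 1, dc 1: the standard response


def mahalanobis_radius(confidence: float, dim: int) -> float:
    """Mahalanobis radius enclosing ``confidence`` mass of a Gaussian.

    For a d-dimensional Gaussian the squared Mahalanobis distance is
    chi-square with d degrees of freedom, so the radius is the square
    root of the chi-square quantile; (0.95, 2) -> 2.447.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    return float(np.sqrt(chi2.ppf(confidence, df=dim)))


@dataclass
class ClusterModel:
    """A fitted Gaussian mixture with hard labels and silhouettes."""

    k: int
    means: np.ndarray          # (K, 2)
    covariances: np.ndarray    # (K, 2, 2)
    weights: np.ndarray        # (K,)
    labels: np.ndarray         # (n,) hard assignment in 0..K-1
    posteriors: np.ndarray     # (n, K)
    log_likelihood: float
    seed: int
    mean_silhouette: float = np.nan
    silhouettes: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class ClusterEllipse:
    """Confidence ellipse of one mixture component."""

    center: np.ndarray
    covariance: np.ndarray
    radius: float
    confidence: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        d = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return m2 <= self.radius**2


def fit_gmm(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    tol: float = 1e-6,
) -> ClusterModel:
    """Best-of-restarts EM fit of a K-component full-covariance mixture.

    Hard labels are the maximum-posterior assignment.  The mixture with
    K >= 2 also carries per-point silhouettes on the raw Euclidean
    (slope, dc) plane.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array (n, d)")
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1 and not (k == 1 and n >= 1):
        raise ValueError(f"k={k} too large for n={n} points (need k <= n-1)")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_restarts,
        tol=tol,
        random_state=seed % (2**31),
    ).fit(points)
    order = np.argsort(
        np.linalg.norm(gm.means_ - REFERENCE_POINT[: points.shape[1]], axis=1),
        kind="stable",
    )
    posteriors = gm.predict_proba(points)[:, order]
    labels = np.argmax(posteriors, axis=1)
    model = ClusterModel(
        k=k,
        means=gm.means_[order],
        covariances=gm.covariances_[order],
        weights=gm.weights_[order],
        labels=labels,
        posteriors=posteriors,
        log_likelihood=float(gm.score(points) * n),
        seed=seed,
    )
    if k >= 2 and len(np.unique(labels)) >= 2:
        model.silhouettes = silhouette_values(points, labels)
        model.mean_silhouette = float(model.silhouettes.mean())
    return model


def silhouette_values(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s = (b - a) / max(a, b), Euclidean distance.

    ``a`` is the mean distance to the other members of the point's own
    cluster, ``b`` the smallest mean distance to another cluster.
    Points in singleton clusters get s = 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two clusters")
    dist = cdist(points, points)
    n = points.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton convention: s = 0
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return s


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over all points; 1 means perfect separation."""
    return float(silhouette_values(points, labels).mean())


def select_cluster_count(
    points: np.ndarray,
    k_range=range(2, 7),
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[int, ClusterModel, dict[int, float]]:
    """Choose K by maximum mean silhouette; ties go to the smaller K.

    Returns (best K, its fitted model, the silhouette-vs-K trace).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = np.asarray(points).shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")
    trace: dict[int, float] = {}
    models: dict[int, ClusterModel] = {}
    for k in ks:
        model = fit_gmm(points, k, seed=seed, n_restarts=n_restarts)
        models[k] = model
        trace[k] = model.mean_silhouette
    # NaN silhouette (degenerate hard assignment) never wins
    best_k = max(ks, key=lambda k: (np.nan_to_num(trace[k], nan=-2.0), -k))
    return best_k, models[best_k], trace


def confidence_ellipses(
    model: ClusterModel, confidence: float = 0.95
) -> list[ClusterEllipse]:
    """One confidence ellipse per mixture component."""
    radius = mahalanobis_radius(confidence, model.means.shape[1])
    return [
        ClusterEllipse(model.means[j].copy(), model.covariances[j].copy(),
                       radius, confidence)
        for j in range(model.k)
    ]


def ellipse_overlap(
    e1: ClusterEllipse, e2: ClusterEllipse, grid: int = 400
) -> float:
    """Overlap area fraction of two ellipses by grid integration.

    The fraction is the intersection area divided by the smaller
    ellipse's area, so two identical ellipses overlap with fraction 1.
    """
    centers = np.stack([e1.center, e2.center])
    # half-extents of each ellipse's bounding box along the axes
    exts = np.stack(
        [e.radius * np.sqrt(np.diag(e.covariance)) for e in (e1, e2)]
    )
    lo = (centers - exts).min(axis=0)
    hi = (centers + exts).max(axis=0)
    xs = np.linspace(lo[0], hi[0], grid)
    ys = np.linspace(lo[1], hi[1], grid)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    in1 = e1.contains(pts)
    in2 = e2.contains(pts)
    smaller = min(in1.sum(), in2.sum())
    if smaller == 0:
        return 0.0
    return float((in1 & in2).sum() / smaller)


def ellipse_overlap_report(ellipses: list[ClusterEllipse]) -> list[tuple[int, int, float]]:
    """Pairwise overlap fractions, supporting the 'little overlap' check."""
    out = []
    for i in range(len(ellipses)):
        for j in range(i + 1, len(ellipses)):
            out.append((i, j, ellipse_overlap(ellipses[i], ellipses[j])))
    return out
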