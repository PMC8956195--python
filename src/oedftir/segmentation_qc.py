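"""Epithelium segmentation and spectral quality control.

Two-tiered k-means identifies spectrally similar epithelial sub-regions on
a hyperspectral tile: tier 1 partitions tissue pixels (background is
removed first by a mean-absorbance threshold), tier 2 re-clusters a chosen
subset of tier-1 regions to resolve finer layers (basal / parabasal /
spinous / keratinized).

Quality control rejects anomalous spectra by projecting each image's
spectra onto 5 principal components and discarding those whose Hotelling
T^2 statistic exceeds the F-distribution confidence bound (default 95%).
The small-sample F form of the threshold is used rather than the chi-square
asymptote, so the expected retention rate equals the confidence level
exactly under multivariate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .spectra_core import HyperspectralImage
from .preprocessing import normalize_matrix

__all__ = ["ClusterMap", "QCReport", "kmeans_tier1", "kmeans_tier2", "hotelling_qc",
           "hotelling_threshold"]

#: Pixels whose mean absorbance falls below this fraction of the image
#: median are treated as background before tier-1 clustering.
BACKGROUND_FRACTION = 0.25


@dataclass
class ClusterMap:
    """Per-pixel cluster labels from one k-means tier.

    ``labels`` is an ``(n_rows, n_cols)`` integer grid; clustered pixels
    carry labels in ``[0, k)`` and pixels outside the tier's scope
    (background, or unselected tier-1 regions) carry -1.
    """

    labels: np.ndarray
    tier: int
    k: int
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        in_scope = lab[lab >= 0]
        if in_scope.size and (in_scope.min() < 0 or in_scope.max() >= self.k):
            raise ValueError("cluster labels must lie in [0, k)")

    def pixels_of(self, labels: list[int] | int) -> np.ndarray:
        if np.isscalar(labels):
            labels = [labels]
        return np.isin(self.labels, list(labels))


@dataclass
class QCReport:
    """Outcome of Hotelling T^2 spectral quality control."""

    kept_indices: np.ndarray
    discarded_indices: np.ndarray
    t2_values: np.ndarray
    threshold: float
    confidence: float
    n_components: int

    def __post_init__(self) -> None:
        n = self.t2_values.size
        union = np.sort(np.concatenate([self.kept_indices, self.discarded_indices]))
        if not np.array_equal(union, np.arange(n)):
            raise ValueError("kept and discarded indices must partition the input")

    @property
    def retained_fraction(self) -> float:
        return self.kept_indices.size / self.t2_values.size


def _pixel_matrix(img: HyperspectralImage) -> np.ndarray:
    return img.cube.reshape(-1, img.cube.shape[-1])


def _cluster_features(X: np.ndarray, wn: np.ndarray, derivative: bool, normalize: bool) -> np.ndarray:
    """Spectral features for clustering: optional SG first derivative (to
    suppress scattering baselines) followed by vector normalization (to
    suppress section thickness)."""
    from scipy.signal import savgol_filter

    if derivative and wn.size >= 9:
        X = savgol_filter(X, 9, 2, deriv=1, delta=float(wn[1] - wn[0]), axis=-1, mode="interp")
    if normalize:
        norms = np.sqrt((X**2).sum(axis=1, keepdims=True))
        norms[norms == 0] = 1.0
        X = X / norms
    return X


def _run_kmeans(
    X: np.ndarray, k: int, seed: int, n_restarts: int = 10, n_pcs: int = 10
) -> tuple[np.ndarray, float]:
    # cluster on a PCA-reduced representation: suppresses per-pixel noise
    # that would otherwise blur thin-section (low-SNR) pixels together
    if n_pcs and X.shape[1] > n_pcs and X.shape[0] > n_pcs:
        X = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return labels, float(km.inertia_)


def kmeans_tier1(
    img: HyperspectralImage,
    k1: int = 3,
    seed: int = 0,
    normalize: bool = True,
    derivative: bool = True,
    exclude_background: bool = True,
) -> ClusterMap:
    """First clustering tier: partition tissue pixels into k1 spectral regions.

    Background pixels (mean absolute absorbance below a fraction of the
    image median) are excluded and labelled -1.  By default spectra are
    first-differentiated (suppressing scattering baselines) and
    vector-normalized (suppressing section thickness) so clustering
    responds to spectral shape, then clustered on a 10-component PCA
    reduction.  Deterministic given the seed; 10 k-means++ restarts keep
    the lowest within-cluster sum of squares.
    """
    if k1 < 2:
        raise ValueError(f"k1 must be >= 2, got {k1}")
    X = _pixel_matrix(img)
    # absolute absorbance: robust to scattering baselines of either sign
    mean_abs = np.abs(X).mean(axis=1)
    if exclude_background:
        tissue = mean_abs > BACKGROUND_FRACTION * np.median(mean_abs)
    else:
        tissue = np.ones(X.shape[0], dtype=bool)
    if tissue.sum() < k1:
        raise ValueError(f"fewer tissue pixels ({tissue.sum()}) than clusters ({k1})")
    Xs = _cluster_features(X[tissue], img.axis.values, derivative, normalize)
    labels_flat = np.full(X.shape[0], -1, dtype=np.int64)
    lab, inertia = _run_kmeans(Xs, k1, seed)
    labels_flat[tissue] = lab
    return ClusterMap(labels_flat.reshape(img.cube.shape[:2]), 1, k1, inertia, seed)


def kmeans_tier2(
    img: HyperspectralImage,
    tier1: ClusterMap,
    selected_labels: list[int],
    k2: int = 4,
    seed: int = 0,
    normalize: bool = True,
    derivative: bool = True,
) -> ClusterMap:
    """Second tier: re-cluster the pixels of selected tier-1 regions into k2.

    Pixels outside the selection are labelled -1 (background), so tier-2
    labels never escape the tier-1 selection.
    """
    if not selected_labels:
        raise ValueError("selected_labels must be a non-empty list of tier-1 labels")
    present = set(np.unique(tier1.labels[tier1.labels >= 0]).tolist())
    bad = set(selected_labels) - present
    if bad:
        raise ValueError(f"selected labels {sorted(bad)} not present in tier-1 map")
    sel = tier1.pixels_of(list(selected_labels))
    X = img.cube[sel]
    if X.shape[0] < k2:
        raise ValueError(f"fewer selected pixels ({X.shape[0]}) than clusters ({k2})")
    X = _cluster_features(X, img.axis.values, derivative, normalize)
    lab, inertia = _run_kmeans(X, k2, seed)
    labels = np.full(img.cube.shape[:2], -1, dtype=np.int64)
    labels[sel] = lab
    return ClusterMap(labels, 2, k2, inertia, seed)


def hotelling_threshold(n: int, k: int, confidence: float) -> float:
    """T^2 critical value: k(n-1)(n+1) / (n(n-k)) * F_{k, n-k}(confidence)."""
    if confidence >= 100.0:
        return float("inf")
    f_crit = stats.f.ppf(confidence / 100.0, k, n - k)
    return float(k * (n - 1) * (n + 1) / (n * (n - k)) * f_crit)


def hotelling_qc(
    spectra: np.ndarray, n_components: int = 5, confidence: float = 95.0
) -> QCReport:
    """Reject anomalous spectra by Hotelling's T^2 on a PCA model.

    Spectra are decomposed into ``n_components`` principal components;
    T^2_i = sum_j score_ij^2 / lambda_j measures each spectrum's distance
    from the model centre, and spectra beyond the F-distribution
    ``confidence``-percent bound are discarded.
    """
    X = np.asarray(spectra, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("spectra must be a 2-D (n_spectra, n_wavenumbers) matrix")
    n = X.shape[0]
    if n <= n_components:
        raise ValueError(
            f"need more spectra ({n}) than principal components ({n_components})"
        )
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    lam = pca.explained_variance_  # per-component score variance (ddof=1)
    t2 = np.sum(scores**2 / lam[None, :], axis=1)
    threshold = hotelling_threshold(n, n_components, confidence)
    keep = t2 <= threshold
    return QCReport(
        kept_indices=np.nonzero(keep)[0],
        discarded_indices=np.nonzero(~keep)[0],
        t2_values=t2,
        threshold=threshold,
        confidence=confidence,
        n_components=n_components,
    )
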