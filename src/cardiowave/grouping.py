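"""Grouping strategies for pooled AP populations, and their comparison.

Three routes from a population of averaged AP waveforms to group labels:

1. ``apd80_threshold`` — fit a two-component Gaussian mixture to the
   pooled APD80 distribution and split at the density crossover.
2. ``pca_threshold`` — project (APD30, APD80) onto the first principal
   component and split the scores at a two-Gaussian crossover.
3. ``waveform_spectral`` — build a similarity matrix from the cumulative
   squared error (CSE) between whole waveforms and cluster it spectrally
   (symmetric normalized Laplacian, k-means on the embedded rows).

Comparison machinery: the Davies-Bouldin index in CSE distance (lower is
better clustering), SVM-derived linear boundaries in parameter planes
with the percentage of APs on the wrong side, and Levene's test of equal
variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.svm import SVC

__all__ = [
    "GaussianPairFit",
    "PrincipalComponent",
    "SimilarityMatrix",
    "GroupingResult",
    "BoundaryOverlap",
    "FitFailureError",
    "fit_two_gaussians",
    "pca_axis",
    "threshold_group",
    "waveform_similarity",
    "spectral_cluster",
    "davies_bouldin",
    "svm_overlap",
    "levene_equal_variance",
    "group_population",
]


class FitFailureError(RuntimeError):
    """A statistical fit collapsed (degenerate component, zero variance...)."""


@dataclass
class GaussianPairFit:
    """Two-component Gaussian mixture with its density-crossover threshold.

    The crossover is the point strictly between the two component means
    where the weighted densities are equal; it serves as the group
    threshold for unimodal-or-bimodal parameter distributions.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    crossover_threshold: float


@dataclass
class PrincipalComponent:
    """First principal axis of the mean-centered (APD30, APD80) cloud."""

    loadings: np.ndarray  # unit vector, (apd30, apd80) order
    scores: np.ndarray
    variance_explained_fraction: float
    center: np.ndarray


@dataclass
class SimilarityMatrix:
    """Pairwise waveform similarity S = exp(-CSE / (2 sigma^2)).

    CSE is the cumulative squared error between two aligned waveforms;
    sigma is the median nonzero pairwise sqrt(CSE), making the kernel
    scale-adaptive.  Symmetric with unit diagonal.
    """

    values: np.ndarray
    sigma: float
    cse: np.ndarray


@dataclass
class GroupingResult:
    """Labels from one grouping method plus its Davies-Bouldin index."""

    method: str  # apd80_threshold | pca_threshold | waveform_spectral
    k: int
    labels: np.ndarray
    dbi: float
    details: dict


@dataclass
class BoundaryOverlap:
    """Linear SVM boundary in a 2-D parameter plane and the percentage of
    APs falling on the wrong side of it."""

    parameter_pair: tuple[str, str]
    boundary: np.ndarray  # (a, b, c): a*x + b*y + c = 0 in raw units
    overlap_percent: float


def fit_two_gaussians(values: np.ndarray, seed: int = 0) -> GaussianPairFit:
    """Maximum-likelihood two-Gaussian fit of 1-D data with crossover.

    EM with 10 seeded restarts.  The crossover solves the quadratic
    equality of the weighted log-densities; the root strictly between the
    two means is selected.  Components are ordered by mean.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ValueError("need n >= 20 observations for a mixture fit")
    if np.ptp(x) == 0:
        raise ValueError("data are all equal")
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=10, max_iter=500,
        tol=1e-8, reg_covar=1e-10, random_state=seed,
    ).fit(x)
    order = np.argsort(gmm.means_.ravel())
    means = gmm.means_.ravel()[order]
    sds = np.sqrt(gmm.covariances_.ravel()[order])
    weights = gmm.weights_.ravel()[order]
    if weights.min() < 1e-3 or sds.min() < 1e-9 * max(np.ptp(x), 1.0):
        raise FitFailureError("degenerate mixture component")
    crossover = _gaussian_crossover(means, sds, weights)
    return GaussianPairFit(means=means, sds=sds, weights=weights,
                           crossover_threshold=crossover)


def _gaussian_crossover(means: np.ndarray, sds: np.ndarray, weights: np.ndarray) -> float:
    """Point between the means where the two weighted normal densities are
    equal: root of a quadratic in x (linear when the sds coincide)."""
    (m1, m2), (s1, s2), (w1, w2) = means, sds, weights
    if m1 == m2:
        raise FitFailureError("coincident component means")
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log(w1 / s1) - np.log(w2 / s2))
    lo, hi = min(m1, m2), max(m1, m2)
    if abs(a) < 1e-300:
        root = -c / b
        if not lo < root < hi:
            raise FitFailureError("crossover does not lie between the means")
        return float(root)
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise FitFailureError("no real density crossover")
    roots = (-b + np.array([1.0, -1.0]) * np.sqrt(disc)) / (2 * a)
    between = [r for r in roots if lo < r < hi]
    if not between:
        raise FitFailureError("no crossover strictly between the means")
    return float(between[0])


def pca_axis(apd30: np.ndarray, apd80: np.ndarray) -> PrincipalComponent:
    """First principal component of paired (APD30, APD80) values.

    Eigendecomposition of the 2 x 2 covariance of the mean-centered data
    (unstandardized: both variables are in ms).  The sign is fixed so the
    APD80 loading is positive (APD30 positive if the APD80 loading is
    zero); the equal-eigenvalue tie resolves to (1, 1)/sqrt(2).
    """
    x = np.column_stack([np.asarray(apd30, float), np.asarray(apd80, float)])
    if x.shape[0] < 3:
        raise ValueError("need n >= 3 observations")
    center = x.mean(axis=0)
    xc = x - center
    cov = np.cov(xc, rowvar=False)
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("zero total variance")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if np.isclose(evals[0], evals[1]):
        loadings = np.array([1.0, 1.0]) / np.sqrt(2.0)
        var_frac = 0.5
    else:
        loadings = evecs[:, 1]
        var_frac = float(evals[1] / total)
    if loadings[1] < 0 or (loadings[1] == 0 and loadings[0] < 0):
        loadings = -loadings
    return PrincipalComponent(
        loadings=loadings,
        scores=xc @ loadings,
        variance_explained_fraction=var_frac,
        center=center,
    )


def threshold_group(values: np.ndarray, threshold: float) -> np.ndarray:
    """Two-group labels by thresholding: 0 below, 1 at/above the threshold.

    Warns when all points land on one side (degenerate single group)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = (np.asarray(values, float) >= threshold).astype(int)
    if labels.min() == labels.max():
        warnings.warn("threshold puts every AP in one group", stacklevel=2)
    return labels


def waveform_similarity(aps: np.ndarray, sigma: float | None = None) -> SimilarityMatrix:
    """Similarity matrix over aligned, equal-length, normalized waveforms.

    CSE_ij = sum_t (AP_i(t) - AP_j(t))^2 ;  S_ij = exp(-CSE_ij / (2 sigma^2))

    with sigma defaulting to the median nonzero pairwise sqrt(CSE).
    """
    aps = np.asarray(aps, dtype=float)
    if aps.ndim != 2:
        raise ValueError("aps must be n x L (identical time support)")
    cse = squareform(pdist(aps, metric="sqeuclidean"))
    if sigma is None:
        d = np.sqrt(cse[np.triu_indices_from(cse, k=1)])
        nz = d[d > 0]
        sigma = float(np.median(nz)) if nz.size else 1.0
    s = np.exp(-cse / (2.0 * sigma**2))
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(values=s, sigma=sigma, cse=cse)


def spectral_cluster(similarity: SimilarityMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of a similarity matrix into k groups.

    Symmetric normalized Laplacian L = I - D^{-1/2} S D^{-1/2}; the rows
    of the k leading eigenvectors (smallest eigenvalues), row-normalized,
    are clustered by seeded k-means with restarts.  If the similarity
    graph is disconnected and splits into exactly k components, the
    components themselves are the partition (flagged by a warning).
    """
    s = np.asarray(similarity.values, dtype=float)
    n = s.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError("need more waveforms than groups")
    adj = s.copy()
    np.fill_diagonal(adj, 0.0)
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components((adj > 1e-300).astype(int), directed=False)
    if n_comp > 1:
        warnings.warn(f"similarity graph has {n_comp} disconnected components", stacklevel=2)
        if n_comp == k:
            return comp
    deg = s.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * s * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(lap)
    emb = evecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    return km.fit_predict(emb)


def davies_bouldin(aps: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index of a waveform grouping, in CSE distance.

    Scatter s_i is the mean sqrt(CSE) of group members to the group's
    pointwise-mean waveform; separation d_ij is the sqrt(CSE) between
    group mean waveforms; DBI = (1/k) sum_i max_{j != i} (s_i+s_j)/d_ij.
    Lower values mean tighter and/or better-separated groups.
    """
    aps = np.asarray(aps, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need >= 2 nonempty groups")
    centers = np.stack([aps[labels == g].mean(axis=0) for g in groups])
    scatter = np.array([
        np.mean(np.linalg.norm(aps[labels == g] - centers[i], axis=1))
        for i, g in enumerate(groups)
    ])
    sep = squareform(pdist(centers))
    if np.any(sep[np.triu_indices_from(sep, k=1)] == 0):
        raise ValueError("coincident group mean waveforms")
    k = groups.size
    ratios = (scatter[:, None] + scatter[None, :]) / np.where(sep > 0, sep, np.inf)
    np.fill_diagonal(ratios, -np.inf)
    return float(np.mean(ratios.max(axis=1)))


def svm_overlap(
    params_2d: np.ndarray,
    labels: np.ndarray,
    parameter_pair: tuple[str, str] = ("apd30_ms", "apd80_ms"),
    c: float = 1.0,
) -> BoundaryOverlap:
    """Linear SVM decision boundary between two groups in a parameter plane.

    The soft-margin classifier (fixed penalty C) is trained on
    standardized coordinates; the boundary is mapped back to raw units
    and the overlap is the percentage of APs on the wrong side of it.
    Symmetric under label swap.
    """
    x = np.asarray(params_2d, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("params_2d must be n x 2")
    if np.unique(y).size != 2:
        raise ValueError("need exactly two nonempty groups")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    clf = SVC(kernel="linear", C=c, tol=1e-8).fit(z, y)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    # w . (x - mu)/sd + b = 0  ->  (w/sd) . x + (b - w . mu/sd) = 0
    a_raw = w / sd
    c_raw = b - float(np.dot(w, mu / sd))
    pred = clf.predict(z)
    overlap = 100.0 * float(np.mean(pred != y))
    return BoundaryOverlap(
        parameter_pair=parameter_pair,
        boundary=np.array([a_raw[0], a_raw[1], c_raw]),
        overlap_percent=overlap,
    )


def levene_equal_variance(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Levene's test of equal variances between two samples.

    W statistic on absolute deviations from the group means (one-way
    ANOVA on |x - mean|), p-value from the F distribution.  Used to ask
    whether pacing reduces the across-cluster variability of APD80.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    if za.max() == 0 and zb.max() == 0:
        raise ValueError("zero within-group deviation everywhere")
    w, p = stats.levene(a, b, center="mean")
    return float(w), float(p)


def group_population(
    aps: np.ndarray,
    apd30: np.ndarray,
    apd80: np.ndarray,
    k: int = 2,
    methods: tuple[str, ...] = ("apd80_threshold", "pca_threshold", "waveform_spectral"),
    seed: int = 0,
) -> dict[str, GroupingResult]:
    """Run the requested grouping strategies on one pooled AP population.

    The threshold methods support k = 2 only (a single crossover);
    spectral clustering supports k in {2, 3}.  Every result carries the
    DBI computed on the waveforms under its labels, so the strategies are
    comparable on a common scale.
    """
    out: dict[str, GroupingResult] = {}
    for method in methods:
        if method == "apd80_threshold":
            if k != 2:
                continue
            fit = fit_two_gaussians(apd80, seed=seed)
            labels = threshold_group(apd80, fit.crossover_threshold)
            details = {"crossover": fit.crossover_threshold,
                       "means": fit.means.tolist(), "sds": fit.sds.tolist(),
                       "weights": fit.weights.tolist()}
        elif method == "pca_threshold":
            if k != 2:
                continue
            pc = pca_axis(apd30, apd80)
            fit = fit_two_gaussians(pc.scores, seed=seed)
            labels = threshold_group(pc.scores, fit.crossover_threshold)
            details = {"crossover": fit.crossover_threshold,
                       "loadings": pc.loadings.tolist(),
                       "variance_explained": pc.variance_explained_fraction}
        elif method == "waveform_spectral":
            sim = waveform_similarity(aps)
            labels = spectral_cluster(sim, k=k, seed=seed)
            details = {"sigma": sim.sigma}
        else:
            raise ValueError(f"unknown grouping method {method!r}")
        if np.unique(labels).size < 2:
            dbi = float("nan")
        else:
            dbi = davies_bouldin(aps, labels)
        out[method] = GroupingResult(method=method, k=int(np.unique(labels).size),
                                     labels=labels, dbi=dbi, details=details)
    return out
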