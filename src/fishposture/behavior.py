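"""Behavioral space: trajectory distances, MDS embedding, clustering, density.

Each time-normalized oscillation cycle becomes one point in a behavioral
space built in four steps.  (1) Pairwise trajectory distances weighted by
the eigenshape singular values,

    d_αβ² = Σ_i Σ_k S_kk² [U_k^α(t̃_i) − U_k^β(t̃_i)]²,

which is the Euclidean distance between spine-angle trajectories expressed
through the orthonormal basis.  (2) Classical (Torgerson double-centering)
MDS of the distance matrix, with a dimensionality criterion based on the
maximum relative error between input and embedded squared dissimilarities.
(3) k-means clustering with the gap statistic selecting the cluster count.
(4) An anisotropic Gaussian kernel-density map over embedding dims 1–2.
A classical bend-angle classification (scoot < 40° < turn) is provided for
comparison with the unsupervised clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .spine import InvalidInputError, SpineAngleMatrix
from .trajectory import CycleSegment


class DegenerateEmbeddingError(ValueError):
    """Distance matrix carries no geometry to embed."""


@dataclass
class DistanceMatrix:
    d: np.ndarray  # (N, N) symmetric, zero diagonal
    ids: list[str]


@dataclass
class BehavioralEmbedding:
    coords: np.ndarray  # (N, D_selected)
    max_rel_error: np.ndarray  # error at candidate D = 1..len
    D_selected: int
    eigenvalues: np.ndarray


@dataclass
class ClusterResult:
    k_optimal: int
    labels: np.ndarray  # values in 1..k_optimal
    gap: np.ndarray  # gap(k) for k = 1..k_max
    log_W: np.ndarray


@dataclass
class DensityMap:
    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray  # (len(y_grid), len(x_grid)), integrates to 1
    sigma1: float
    sigma2: float


@dataclass
class BendAngleFeatures:
    bend_angle_deg: float
    head_angle_deg: float
    label: str  # "scoot" or "turn" by the 40 degree rule


def segment_feature_matrix(
    segments: list[CycleSegment], S: np.ndarray
) -> np.ndarray:
    """Flatten segments into S_kk-scaled feature vectors (one row each).

    The Eq-2 trajectory distance is exactly the Euclidean distance between
    these rows, which is the identity the embedding relies on.
    """
    K = S.size
    T = segments[0].grid_points
    if any(s.grid_points != T for s in segments):
        raise InvalidInputError("segments must share the normalized-time grid")
    rows = []
    for seg in segments:
        if seg.U.shape[0] < K:
            raise InvalidInputError("segment has fewer modes than S")
        rows.append((seg.U[:K] * S[:, None]).ravel())
    return np.array(rows)


def pairwise_distance(
    segments: list[CycleSegment], S: np.ndarray
) -> DistanceMatrix:
    """Singular-value-weighted trajectory distance between all cycle pairs."""
    X = segment_feature_matrix(segments, np.asarray(S, dtype=float))
    d = squareform(pdist(X, metric="euclidean"))
    ids = [f"{s.bout_id}/c{s.cycle_index}" for s in segments]
    return DistanceMatrix(d=d, ids=ids)


def embed_mds(dm: DistanceMatrix, D: int = 3, D_max: int | None = None) -> BehavioralEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distances, eigendecomposes, and keeps the
    top-D coordinates (negative eigenvalues truncated at zero).  For each
    candidate dimensionality up to ``D_max`` the maximum relative error
    between input and embedded squared dissimilarities,
    max |d² − d′²| / d′², is recorded as the dimensionality criterion.
    """
    Dsq = dm.d**2
    N = Dsq.shape[0]
    if N < D + 1:
        raise InvalidInputError("need at least D+1 points")
    if not np.any(Dsq):
        raise DegenerateEmbeddingError("all-zero distance matrix")
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ Dsq @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = np.maximum(evals, 0.0)
    D_max = D_max or D
    # maximum error between input and embedded squared dissimilarities,
    # relative to the scale of the reconstructed matrix (a per-pair ratio
    # is unstable for near-duplicate cycles whose d' is ~0)
    errors = []
    iu = np.triu_indices(N, k=1)
    for Dc in range(1, D_max + 1):
        coords_c = evecs[:, :Dc] * np.sqrt(pos[:Dc])
        dsq_hat = squareform(pdist(coords_c)) ** 2
        scale = dsq_hat[iu].max()
        if scale <= 0:
            errors.append(1.0)
            continue
        errors.append(float(np.max(np.abs(Dsq[iu] - dsq_hat[iu])) / scale))
    coords = evecs[:, :D] * np.sqrt(pos[:D])
    return BehavioralEmbedding(
        coords=coords,
        max_rel_error=np.array(errors),
        D_selected=D,
        eigenvalues=evals,
    )


def _within_dispersion(X: np.ndarray, k: int, seed: int) -> float:
    """Pooled within-cluster sum of squares W_k via multi-restart k-means."""
    if k == 1:
        return float(np.sum((X - X.mean(axis=0)) ** 2))
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def cluster_gap(
    coords: np.ndarray,
    k_max: int = 8,
    B_refs: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """Select the cluster count by the gap statistic and label the points.

    gap(k) = mean_b log W_k(reference_b) − log W_k(data), with uniform
    reference datasets drawn over the per-dimension bounding box of the
    data; the optimal k is the global gap maximum.
    """
    if k_max < 2:
        raise InvalidInputError("k_max must be >= 2")
    X = np.asarray(coords, dtype=float)
    N = X.shape[0]
    if N < k_max:
        raise InvalidInputError("need at least k_max points")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = np.arange(1, k_max + 1)
    log_W = np.array([np.log(max(_within_dispersion(X, k, seed), 1e-300)) for k in ks])
    log_W_ref = np.zeros((B_refs, k_max))
    for b in range(B_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        for i, k in enumerate(ks):
            log_W_ref[b, i] = np.log(max(_within_dispersion(ref, k, ref_seed), 1e-300))
    gap = log_W_ref.mean(axis=0) - log_W
    k_opt = int(ks[np.argmax(gap)])
    if k_opt == 1:
        labels = np.ones(N, dtype=int)
    else:
        km = KMeans(n_clusters=k_opt, n_init=20, random_state=seed)
        labels = km.fit_predict(X) + 1
    return ClusterResult(k_optimal=k_opt, labels=labels, gap=gap, log_W=log_W)


def density_map(
    coords: np.ndarray,
    sigma1: float | None = None,
    sigma2: float | None = None,
    grid_size: int = 120,
    pad_sigmas: float = 3.0,
) -> DensityMap:
    """Anisotropic Gaussian kernel density over embedding dims 1–2.

    Defaults for the kernel widths are 1/8 of each dimension's range
    (embedding scale depends on the ensemble); the map is normalized to
    integrate to 1 over the grid.
    """
    X = np.asarray(coords, dtype=float)
    if X.size == 0:
        raise InvalidInputError("no coordinates")
    x, y = X[:, 0], X[:, 1]
    s1 = sigma1 if sigma1 is not None else max(np.ptp(x) / 8.0, 1e-12)
    s2 = sigma2 if sigma2 is not None else max(np.ptp(y) / 8.0, 1e-12)
    if s1 <= 0 or s2 <= 0:
        raise InvalidInputError("kernel widths must be positive")
    xg = np.linspace(x.min() - pad_sigmas * s1, x.max() + pad_sigmas * s1, grid_size)
    yg = np.linspace(y.min() - pad_sigmas * s2, y.max() + pad_sigmas * s2, grid_size)
    XX, YY = np.meshgrid(xg, yg)
    dens = np.zeros_like(XX)
    for xi, yi in zip(x, y):
        dens += np.exp(
            -0.5 * (((XX - xi) / s1) ** 2 + ((YY - yi) / s2) ** 2)
        )
    cell = (xg[1] - xg[0]) * (yg[1] - yg[0])
    dens /= dens.sum() * cell
    return DensityMap(x_grid=xg, y_grid=yg, density=dens, sigma1=s1, sigma2=s2)


def count_local_maxima(dm: DensityMap, min_fraction: float = 0.05) -> int:
    """Strict interior local maxima above ``min_fraction`` of the peak."""
    d = dm.density
    peak = d.max()
    count = 0
    for i in range(1, d.shape[0] - 1):
        for j in range(1, d.shape[1] - 1):
            v = d[i, j]
            if v < min_fraction * peak:
                continue
            patch = d[i - 1 : i + 2, j - 1 : j + 2]
            if v >= patch.max() and (patch < v).sum() == 8:
                count += 1
    return count


def bend_angle_features(
    spine: SpineAngleMatrix,
    cycle_bounds_ms: tuple[float, float],
    turn_threshold_deg: float = 40.0,
) -> BendAngleFeatures:
    """Classical scoot/turn classification of a bout's first cycle.

    The bend angle is the maximum tail-vs-head angle |Δθ(s_{n-1})| over
    cycle 1; the head angle is the net change of the absolute head tangent
    over the bout.  Bouts with bend angle above 40° are classed as turns.
    """
    t0, t1 = cycle_bounds_ms
    mask = (spine.time_ms >= t0) & (spine.time_ms <= t1)
    if not mask.any():
        mask = np.ones(spine.n_frames, dtype=bool)
    bend = float(np.degrees(np.max(np.abs(spine.tail_angle()[mask]))))
    head = float(np.degrees(spine.theta_head[-1] - spine.theta_head[0]))
    label = "turn" if bend > turn_threshold_deg else "scoot"
    return BendAngleFeatures(bend_angle_deg=bend, head_angle_deg=head, label=label)
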