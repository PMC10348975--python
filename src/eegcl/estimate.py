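"""Soft clustering of the feature matrix into conscious/unconscious states.

The normalised N_samples x 7 feature matrix is clustered twice with N = 2:

* Fuzzy c-means (fuzziness m = 2, at most 1000 iterations, objective
  improvement tolerance 1e-5), alternating the centroid update

      c_j = Σ_i μ_ij^m x_i / Σ_i μ_ij^m

  with the membership update

      μ_ij = 1 / Σ_k (‖x_i − c_j‖ / ‖x_i − c_k‖)^(2/(m−1))

  until the objective J_m = Σ_ij μ_ij^m ‖x_i − c_j‖² stops improving.

* A two-component full-covariance Gaussian mixture fitted by EM
  (scikit-learn backend driven one EM step at a time so the log-likelihood
  trace is recorded); posterior probabilities serve as soft memberships.

The cluster whose centroid is higher in the majority of feature coordinates
is labelled *conscious* — all seven features are hypothesised to rise with
the level of consciousness.  The two conscious-membership traces are then
averaged element-wise into the final consciousness level in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .features import FEATURE_NAMES, FeatureMatrix

__all__ = [
    "ClusterResult",
    "ConsciousnessTrace",
    "normalize_features",
    "fcm",
    "gmm_em",
    "label_conscious_cluster",
    "ensemble_average",
    "estimate_consciousness",
]


@dataclass
class ClusterResult:
    """Soft-partition output of one clustering method.

    ``memberships`` has one row per input row (including NaN rows, which
    carry NaN memberships); finite rows sum to 1 across clusters.
    """

    memberships: np.ndarray              # (n_rows, n_clusters)
    centroids: np.ndarray                # (n_clusters, n_features)
    method: str                          # "FCM" | "GMM"
    objective_trace: np.ndarray          # J_m or log-likelihood per iteration
    conscious_index: int | None = None
    m: float | None = None               # FCM fuzziness
    weights: np.ndarray | None = None    # GMM mixing proportions
    covariances: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    def conscious_trace(self, timestamps: np.ndarray) -> "ConsciousnessTrace":
        if self.conscious_index is None:
            raise ValueError("conscious cluster not labelled yet")
        return ConsciousnessTrace(
            p_conscious=self.memberships[:, self.conscious_index].copy(),
            timestamps=np.asarray(timestamps, dtype=float),
        )


@dataclass
class ConsciousnessTrace:
    """Per-window probability of consciousness in [0, 1] (NaN where undefined)."""

    p_conscious: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.p_conscious = np.asarray(self.p_conscious, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.p_conscious.shape != self.timestamps.shape:
            raise ValueError("trace and timestamps must align")

    def __len__(self) -> int:
        return self.p_conscious.size


def normalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale each column to [0, 1] over its finite rows.

    NaN entries are excluded from the min/max and left NaN.  A constant
    column carries no contrast; it is set to 0.5 with a warning so the
    clustering runs on the remaining features.
    """
    values = fm.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        finite = np.isfinite(col)
        if finite.sum() < 2:
            warnings.warn(
                f"column {fm.feature_names[j]!r} has < 2 finite values", stacklevel=2
            )
            continue
        lo, hi = col[finite].min(), col[finite].max()
        if hi == lo:
            warnings.warn(
                f"column {fm.feature_names[j]!r} is constant; set to 0.5", stacklevel=2
            )
            col[finite] = 0.5
        else:
            col[finite] = (col[finite] - lo) / (hi - lo)
    return FeatureMatrix(values=values, timestamps=fm.timestamps.copy(),
                         feature_names=fm.feature_names)


def _fcm_memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Membership update; points coinciding with a centroid get membership 1."""
    d = np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=2)  # (n, N)
    u = np.zeros_like(d)
    zero = d == 0
    zero_rows = zero.any(axis=1)
    if zero_rows.any():
        # convention for the update singularity: full membership to the
        # coincident centroid (split evenly if coincident with several)
        z = zero[zero_rows]
        u[zero_rows] = z / z.sum(axis=1, keepdims=True)
    ok = ~zero_rows
    if ok.any():
        ratio = (d[ok][:, :, None] / d[ok][:, None, :]) ** (2.0 / (m - 1.0))
        u[ok] = 1.0 / ratio.sum(axis=2)
    return u


def _fcm_single(x: np.ndarray, n_clusters: int, m: float, max_iter: int,
                eps: float, rng: np.random.Generator):
    n = x.shape[0]
    u = rng.random((n, n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    trace: list[float] = []
    prev_j = np.inf
    for _ in range(max_iter):
        um = u**m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        u = _fcm_memberships(x, centroids, m)
        d2 = np.sum((x[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        j_m = float(np.sum(u**m * d2))
        trace.append(j_m)
        if abs(prev_j - j_m) < eps:
            break
        prev_j = j_m
    return u, centroids, np.asarray(trace)


def fcm(
    data: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    max_iter: int = 1000,
    eps: float = 1e-5,
    seed: int | None = None,
    n_restarts: int = 5,
) -> ClusterResult:
    """Fuzzy c-means soft clustering.

    Memberships are initialised uniform-random (row-normalised) from
    ``seed``; the best of ``n_restarts`` runs by final objective J_m is
    kept.  Rows containing non-finite values are excluded from fitting and
    returned with NaN memberships.
    """
    if m <= 1:
        raise ValueError(f"fuzziness m must exceed 1, got {m}")
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    valid = np.isfinite(data).all(axis=1)
    x = data[valid]
    if np.unique(x, axis=0).shape[0] < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} distinct finite rows, "
            f"got {np.unique(x, axis=0).shape[0]}"
        )
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        u, centroids, trace = _fcm_single(
            x, n_clusters, m, max_iter, eps, np.random.default_rng(child)
        )
        if best is None or trace[-1] < best[2][-1]:
            best = (u, centroids, trace)
    u, centroids, trace = best
    memberships = np.full((data.shape[0], n_clusters), np.nan)
    memberships[valid] = u
    return ClusterResult(
        memberships=memberships,
        centroids=centroids,
        method="FCM",
        objective_trace=trace,
        m=m,
        valid_mask=valid,
    )


def gmm_em(
    data: np.ndarray,
    n_clusters: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-5,
    seed: int | None = None,
    n_init: int = 5,
    reg_covar: float = 1e-6,
) -> ClusterResult:
    """Full-covariance Gaussian mixture fitted by EM.

    EM is driven one step at a time (warm-started scikit-learn backend) so
    the per-iteration mean log-likelihood is recorded; convergence is an
    absolute improvement below ``tol``.  The best of ``n_init`` seeded
    k-means++-style initialisations by final log-likelihood is kept.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    valid = np.isfinite(data).all(axis=1)
    x = data[valid]
    if x.shape[0] < n_clusters:
        raise ValueError(f"need >= {n_clusters} finite rows, got {x.shape[0]}")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        gm = GaussianMixture(
            n_components=n_clusters,
            covariance_type="full",
            max_iter=1,
            warm_start=True,
            tol=0.0,
            reg_covar=reg_covar,
            init_params="k-means++",
            random_state=int(rng.integers(2**31 - 1)),
        )
        trace: list[float] = []
        prev = -np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(max_iter):
                gm.fit(x)
                ll = float(gm.lower_bound_)
                trace.append(ll)
                if abs(ll - prev) < tol:
                    break
                prev = ll
            else:
                warnings.warn(
                    f"GMM-EM did not converge within {max_iter} iterations",
                    stacklevel=2,
                )
        if best is None or trace[-1] > best[1][-1]:
            best = (gm, trace)
    gm, trace = best
    posteriors = gm.predict_proba(x)
    memberships = np.full((data.shape[0], n_clusters), np.nan)
    memberships[valid] = posteriors
    return ClusterResult(
        memberships=memberships,
        centroids=gm.means_,
        method="GMM",
        objective_trace=np.asarray(trace),
        weights=gm.weights_,
        covariances=gm.covariances_,
        valid_mask=valid,
    )


def label_conscious_cluster(
    result: ClusterResult,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> int:
    """Identify the conscious cluster from the two centroids.

    All seven features are hypothesised to increase with consciousness, so
    the cluster whose centroid is higher in the majority of coordinates is
    conscious.  Ties fall back to the higher SEF95 coordinate, then to the
    higher centroid mean.
    """
    c = result.centroids
    if c.shape[0] != 2:
        raise ValueError("conscious labelling defined for exactly 2 clusters")
    wins0 = int(np.sum(c[0] > c[1]))
    wins1 = int(np.sum(c[1] > c[0]))
    if wins0 != wins1:
        idx = 0 if wins0 > wins1 else 1
    elif "sef95" in feature_names and c[0][feature_names.index("sef95")] != c[1][feature_names.index("sef95")]:
        j = feature_names.index("sef95")
        idx = 0 if c[0][j] > c[1][j] else 1
    else:
        idx = 0 if c[0].mean() >= c[1].mean() else 1
    result.conscious_index = idx
    return idx


def ensemble_average(
    p_fcm: ConsciousnessTrace, p_gmm: ConsciousnessTrace
) -> ConsciousnessTrace:
    """Element-wise mean of the two conscious-membership traces."""
    if len(p_fcm) != len(p_gmm) or not np.allclose(
        p_fcm.timestamps, p_gmm.timestamps, equal_nan=True
    ):
        raise ValueError("traces must be aligned on the same timestamps")
    return ConsciousnessTrace(
        p_conscious=(p_fcm.p_conscious + p_gmm.p_conscious) / 2.0,
        timestamps=p_fcm.timestamps.copy(),
    )


def estimate_consciousness(
    fm: FeatureMatrix,
    seed: int | None = None,
    m: float = 2.0,
    max_iter: int = 1000,
    eps: float = 1e-5,
    n_restarts: int = 5,
) -> tuple[ConsciousnessTrace, ClusterResult, ClusterResult]:
    """Full estimation stage: normalise, cluster twice, label, average.

    Returns the ensemble trace plus the labelled FCM and GMM results.
    """
    norm = normalize_features(fm)
    fcm_res = fcm(norm.values, m=m, max_iter=max_iter, eps=eps,
                  seed=seed, n_restarts=n_restarts)
    gmm_res = gmm_em(norm.values, max_iter=max_iter, tol=eps,
                     seed=None if seed is None else seed + 1,
                     n_init=n_restarts)
    label_conscious_cluster(fcm_res, norm.feature_names)
    label_conscious_cluster(gmm_res, norm.feature_names)
    trace = ensemble_average(
        fcm_res.conscious_trace(norm.timestamps),
        gmm_res.conscious_trace(norm.timestamps),
    )
    return trace, fcm_res, gmm_res
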