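"""Spectral clustering and gap-statistic selection of the cluster count.

The z-scored feature matrix is partitioned by normalized spectral clustering
(radial-basis affinity ``exp(-gamma d^2)``, symmetric-normalized graph
Laplacian, k-means on the row-normalized eigenvector embedding).  The number
of clusters is chosen by the gap statistic: the observed log pooled
intra-cluster dispersion ``log W_k`` is compared against its expectation
under a structureless reference distribution, obtained by sampling uniformly
over the per-column ranges of the data expressed in its right-singular
basis (so the reference inherits the observed covariance orientation).  The
selected k is the smallest with ``G_k > G_{k+1} - S_{k+1}``, where ``S`` is
the bootstrap standard deviation inflated by ``sqrt(1 + 1/B)`` to account
for simulation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "ZScoredFeatures",
    "GapProfile",
    "KSelection",
    "zscore",
    "spectral_cluster",
    "pooled_dispersion",
    "reference_sample",
    "gap_profile",
    "select_k",
    "DEFAULT_K_RANGE",
    "DEFAULT_N_BOOT",
]

DEFAULT_K_RANGE = tuple(range(2, 8))
DEFAULT_N_BOOT = 1000


def _values(Z) -> np.ndarray:
    if isinstance(Z, ZScoredFeatures):
        return Z.values
    if hasattr(Z, "values") and isinstance(getattr(Z, "values"), np.ndarray):
        return np.asarray(Z.values, dtype=float)
    return np.asarray(Z, dtype=float)


@dataclass
class ZScoredFeatures:
    """Column-standardized feature matrix with the inverse transform stored."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    def inverse(self) -> np.ndarray:
        """Map back to the original feature scale."""
        return self.values * self.column_sds + self.column_means


def zscore(F, column_names: Sequence[str] | None = None) -> ZScoredFeatures:
    """Standardize each column to mean 0 and (sample) SD 1.

    Raises ``ValueError`` naming the offending column when a column has zero
    variance (standardization would be undefined).
    """
    X = _values(F)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s <= 1e-12 * max(1.0, abs(mu[j])):
            name = column_names[j] if column_names else f"column {j}"
            raise ValueError(f"zero-variance feature: {name}")
    return ZScoredFeatures(values=(X - mu) / sd, column_means=mu, column_sds=sd)


def spectral_cluster(
    Z,
    k: int,
    gamma: float = 1.0,
    seed: int | None = None,
    n_init: int = 10,
) -> np.ndarray:
    """Normalized spectral clustering with an RBF affinity.

    Affinity ``W_ij = exp(-gamma ||x_i - x_j||^2)``; the first ``k``
    eigenvectors of the symmetric-normalized Laplacian are degree-rescaled,
    row-normalized, and partitioned with k-means (``n_init`` restarts).
    Deterministic given ``seed``.
    """
    X = _values(Z)
    n = len(X)
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    if k == n:
        return np.arange(n)

    d2 = squareform(pdist(X, "sqeuclidean"))
    W = np.exp(-gamma * d2)
    deg = W.sum(axis=1)
    dm = 1.0 / np.sqrt(deg)
    L = -(dm[:, None] * W * dm[None, :])
    np.fill_diagonal(L, 1.0 + np.diag(L))
    _, vecs = scipy.linalg.eigh(L, subset_by_index=(0, k - 1))
    U = dm[:, None] * vecs
    U /= np.maximum(np.linalg.norm(U, axis=1, keepdims=True), 1e-12)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(U)


def pooled_dispersion(Z, labels: np.ndarray) -> float:
    """Pooled intra-cluster dispersion ``W = sum_r D_r / (2 n_r)``.

    ``D_r`` is the sum over *ordered* pairs of squared Euclidean distances
    between the members of cluster ``r``.  Every cluster id in
    ``0..max(labels)`` must be non-empty.
    """
    X = _values(Z)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels length mismatch")
    k = int(labels.max()) + 1
    W = 0.0
    for r in range(k):
        members = X[labels == r]
        if len(members) == 0:
            raise ValueError(f"cluster {r} is empty")
        if len(members) == 1:
            continue
        # pdist sums unordered pairs; ordered-pair sum is twice that
        W += pdist(members, "sqeuclidean").sum() / len(members)
    return float(W)


def reference_sample(Z, rng: np.random.Generator) -> np.ndarray:
    """One reference dataset for the gap statistic (Tibshirani's method b).

    The data are rotated into their right-singular basis, a sample is drawn
    uniformly over each rotated column's observed range, and the sample is
    rotated back to feature space.
    """
    X = _values(Z)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    Xp = X @ vt.T
    U = rng.uniform(Xp.min(axis=0), Xp.max(axis=0), size=Xp.shape)
    return U @ vt


@dataclass
class GapProfile:
    """Per-k gap statistic summary.

    ``gap[k] = e_log_w[k] - log_w[k]`` and ``s = sd * sqrt(1 + 1/B)`` where
    ``sd`` is the bootstrap SD of the reference log dispersions.
    """

    k_values: tuple[int, ...]
    log_w: np.ndarray
    e_log_w: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    n_boot: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "log_w": self.log_w.tolist(),
            "e_log_w": self.e_log_w.tolist(),
            "gap": self.gap.tolist(),
            "s": self.s.tolist(),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


class KSelection(NamedTuple):
    k: int
    elbow_found: bool


def gap_profile(
    Z,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    gamma: float = 1.0,
    n_init: int = 10,
) -> GapProfile:
    """Gap statistic over ``k_range`` with ``n_boot`` reference bootstraps.

    Observed data and every reference sample are clustered with the same
    spectral algorithm at each k.  All randomness (reference draws, k-means
    seeding) derives from ``seed``.
    """
    X = _values(Z)
    ks = tuple(int(k) for k in k_range)
    if len(ks) == 0 or any(b - a != 1 for a, b in zip(ks[:-1], ks[1:])):
        raise ValueError("k_range must be consecutive integers")
    if len(X) < max(ks):
        raise ValueError("more clusters requested than observations")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    rng = np.random.default_rng(seed)
    base = int(rng.integers(2**31 - 10_000))

    log_w = np.array([
        np.log(pooled_dispersion(X, spectral_cluster(X, k, gamma, seed=base + k,
                                                     n_init=n_init)))
        for k in ks
    ])
    ref_log_w = np.empty((n_boot, len(ks)))
    for b in range(n_boot):
        U = reference_sample(X, rng)
        for j, k in enumerate(ks):
            labels = spectral_cluster(U, k, gamma, seed=base + 1000 + b * 10 + k,
                                      n_init=n_init)
            ref_log_w[b, j] = np.log(pooled_dispersion(U, labels))

    e_log_w = ref_log_w.mean(axis=0)
    sd = ref_log_w.std(axis=0)
    return GapProfile(
        k_values=ks,
        log_w=log_w,
        e_log_w=e_log_w,
        gap=e_log_w - log_w,
        s=sd * np.sqrt(1.0 + 1.0 / n_boot),
        n_boot=n_boot,
        seed=seed,
    )


def select_k(profile: GapProfile) -> KSelection:
    """Smallest k with ``G_k > G_{k+1} - S_{k+1}``.

    When no k in the range satisfies the rule the largest k is returned with
    ``elbow_found=False`` (no elbow detected).
    """
    G, S, ks = profile.gap, profile.s, profile.k_values
    for j in range(len(ks) - 1):
        if G[j] > G[j + 1] - S[j + 1]:
            return KSelection(k=ks[j], elbow_found=True)
    return KSelection(k=ks[-1], elbow_found=False)
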