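"""Group-level nonparametric inference.

One-sample cluster-based sign-flip permutation tests over an ordered axis
(time or sample position): a one-sample t is computed per point, clusters
are maximal contiguous runs whose two-tailed pointwise p falls below the
cluster-forming alpha (same-sign t within a cluster), the cluster statistic
is the mass (sum of t), and the null distribution of the maximal absolute
mass is built by randomly flipping the sign of whole participants.  Cluster
p-values use the (1 + exceedances) / (n_perm + 1) convention, so the
smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "cluster_permutation_test",
    "paired_permutation_test",
]


@dataclass
class Cluster:
    start: int  # inclusive index
    stop: int  # exclusive index
    mass: float
    sign: int
    p: float

    @property
    def extent(self) -> int:
        return self.stop - self.start


@dataclass
class ClusterTestResult:
    t: np.ndarray
    threshold: float
    clusters: list[Cluster]
    n_permutations: int
    alpha_cluster: float
    seed: int
    excluded: np.ndarray  # zero-variance points excluded from clustering

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _t_onesample(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def _find_clusters(t: np.ndarray, thr: float, valid: np.ndarray):
    """Maximal contiguous same-sign supra-threshold runs -> [(start, stop, mass)]."""
    above = (np.abs(t) > thr) & valid
    sign = np.sign(t)
    clusters = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j] and sign[j] == sign[i]:
            j += 1
        clusters.append((i, j, float(t[i:j].sum())))
        i = j
    return clusters


def cluster_permutation_test(values: np.ndarray, alpha_cluster: float = 0.05,
                             n_perm: int = 1000, seed: int = 0) -> ClusterTestResult:
    """Two-tailed one-sample cluster permutation test.

    ``values``: participants x points.  Requires >= 5 participants.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (participants x points)")
    n_subj, n_pts = values.shape
    if n_subj < 5:
        raise ValueError(f"need >= 5 participants, got {n_subj}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")

    sd = values.std(axis=0, ddof=1)
    valid = sd > 0
    thr = sps.t.ppf(1.0 - alpha_cluster / 2.0, df=n_subj - 1)

    t_obs = _t_onesample(values)
    obs_clusters = _find_clusters(t_obs, thr, valid)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)[:, None]
        t_perm = _t_onesample(values * flips)
        cl = _find_clusters(t_perm, thr, valid)
        null_max[p] = max((abs(m) for _, _, m in cl), default=0.0)

    clusters = [
        Cluster(
            start=a,
            stop=b,
            mass=m,
            sign=int(np.sign(m)),
            p=float((1 + np.sum(null_max >= abs(m))) / (n_perm + 1)),
        )
        for a, b, m in obs_clusters
    ]
    return ClusterTestResult(
        t=t_obs,
        threshold=float(thr),
        clusters=clusters,
        n_permutations=n_perm,
        alpha_cluster=alpha_cluster,
        seed=seed,
        excluded=~valid,
    )


def paired_permutation_test(a: np.ndarray, b: np.ndarray, n_perm: int = 10_000,
                            seed: int = 0) -> float:
    """Two-tailed sign-flip permutation test on paired differences.

    Enumerates all 2^n sign patterns when that is no more work than
    2 * n_perm draws; otherwise Monte-Carlo with the add-one convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal lengths")
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    obs = abs(d.mean())
    if 2**n <= 2 * n_perm:
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n)] for i in range(2**n)],
            dtype=float,
        )
        null = np.abs((signs * d).mean(axis=1))
        return float(np.mean(null >= obs - 1e-15))
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.abs((flips * d).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-15)) / (n_perm + 1))
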