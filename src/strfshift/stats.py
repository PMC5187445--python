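"""Resampling inference for paired condition contrasts.

Sign-flip permutation tests exploit the paired design: under the null
the per-electrode condition differences are symmetric about zero, so
randomly negating them generates the null distribution of the group
mean.  The cluster-based variant corrects over time by thresholding a
per-timepoint one-sample t statistic, forming contiguous clusters, and
comparing each cluster's t-mass against the permutation distribution of
the maximum cluster mass.  Monte-Carlo p-values use the +1 convention
(the observed statistic counts as one permutation), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "Cluster",
    "ClusterPermutationResult",
    "signflip_permutation_test",
    "cluster_permutation_test",
    "bootstrap_ci",
]


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_two_sided: float
    n_permutations: int
    seed: int


@dataclass
class Cluster:
    start: int
    stop: int  # exclusive
    mass: float
    p: float


@dataclass
class ClusterPermutationResult:
    clusters: list[Cluster]
    t_series: np.ndarray
    threshold: float
    null_max_mass: np.ndarray
    n_permutations: int
    seed: int

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def signflip_permutation_test(
    differences: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Paired sign-flip permutation test of mean(differences) == 0.

    Two-sided p with the +1 convention:
    ``p = (1 + #{|null| >= |observed|}) / (n_perm + 1)``.
    """
    d = np.asarray(differences, dtype=float).ravel()
    if d.size < 5:
        raise ValueError("need at least 5 paired differences")
    rng = np.random.default_rng(seed)
    observed = float(d.mean())
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null = signs @ d / d.size
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed,
        null_distribution=null,
        p_two_sided=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


def _t_series(data: np.ndarray) -> np.ndarray:
    """One-sample t across electrodes (axis 0) at each time point."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    std = data.std(axis=0, ddof=1)
    std = np.where(std > 0, std, np.inf)
    return mean / (std / np.sqrt(n))


def _clusters_and_masses(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Contiguous supra-threshold runs of same-signed t; mass = sum of t."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * t > threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            out.append((int(start), int(stop), float(t[start:stop].sum())))
    out.sort()
    return out


def cluster_permutation_test(
    differences: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterPermutationResult:
    """Cluster-based sign-flip permutation test over time.

    ``differences`` is electrode x time.  Clusters are contiguous runs
    where the per-timepoint |t| exceeds the two-sided t-critical value
    at ``cluster_alpha``; the cluster statistic is the sum of t (mass);
    the null is the maximum |mass| under electrode-wise sign flips.
    An empty cluster list (no supra-threshold run) is a valid result.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    n_elec = d.shape[0]
    if n_elec < 5:
        raise ValueError("need at least 5 electrodes")
    threshold = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df=n_elec - 1))
    t_obs = _t_series(d)
    obs_clusters = _clusters_and_masses(t_obs, threshold)

    rng = np.random.default_rng(seed)
    # Sign flips leave sum(d^2) per time point unchanged, so the whole
    # permuted t series follows from the permuted means alone.
    signs = rng.integers(0, 2, size=(n_perm, n_elec)) * 2 - 1
    perm_mean = signs @ d / n_elec
    ss = np.sum(d**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_var = np.maximum(ss[None, :] - n_elec * perm_mean**2, 0.0) / (n_elec - 1)
        t_all = perm_mean / np.sqrt(perm_var / n_elec)
    t_all = np.nan_to_num(t_all, nan=0.0, posinf=np.inf, neginf=-np.inf)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        masses = _clusters_and_masses(t_all[i], threshold)
        if masses:
            null_max[i] = max(abs(m) for _, _, m in masses)

    clusters = [
        Cluster(
            start=start,
            stop=stop,
            mass=mass,
            p=float((1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)),
        )
        for start, stop, mass in obs_clusters
    ]
    return ClusterPermutationResult(
        clusters=clusters,
        t_series=t_obs,
        threshold=threshold,
        null_max_mass=null_max,
        n_permutations=n_perm,
        seed=seed,
    )


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10000,
    level: float = 0.99,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean.

    Returns the ((1-level)/2, 1-(1-level)/2) quantiles of the resampled
    mean; ``level=0.99`` gives the (0.5th, 99.5th) percentile pair.
    """
    v = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0 * 100.0
    return float(np.percentile(means, lo)), float(np.percentile(means, 100.0 - lo))
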