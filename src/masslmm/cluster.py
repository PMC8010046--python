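"""Temporal clusters over chi-square timecourses, the Monte-Carlo
label-permutation test, and FDR correction across ROIs.

A cluster is a maximal run of contiguous timepoints whose statistics
strictly exceed the cluster-forming threshold (the 95th percentile of the
central chi-square distribution with the test's degrees of freedom); its
mass is the sum of its member statistics.  Per ROI, the biggest cluster's
mass is compared against a null distribution built by re-shuffling the
condition labels of interest within each participant and re-running the
whole model comparison; the raw p-value is the proportion of permutations
whose biggest cluster is strictly larger than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "PermutationResult",
    "chi2_threshold",
    "find_clusters",
    "fdr_correct",
    "fdr_across_rois",
]


def chi2_threshold(df: int, alpha: float = 0.05) -> float:
    """Cluster-forming threshold: the (1 - alpha) quantile of chi2(df)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass(frozen=True)
class Cluster:
    """A maximal contiguous suprathreshold run; indices are half-open."""

    roi_id: str
    start_idx: int
    end_idx: int
    start_s: float
    end_s: float
    mass: float
    n_members: int


def find_clusters(
    chi2, threshold: float, times=None, roi_id: str = "ROI"
) -> list[Cluster]:
    """Maximal runs of strictly suprathreshold samples, sorted by mass
    (descending), ties broken by start index.

    ``start_s``/``end_s`` are the times of the first and last member sample.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    chi2 = np.asarray(chi2, dtype=float)
    if times is None:
        times = np.arange(len(chi2), dtype=float)
    times = np.asarray(times, dtype=float)
    above = chi2 > threshold
    clusters: list[Cluster] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append(_make_cluster(chi2, times, start, i, roi_id))
            start = None
    if start is not None:
        clusters.append(_make_cluster(chi2, times, start, len(chi2), roi_id))
    clusters.sort(key=lambda c: (-c.mass, c.start_idx))
    return clusters


def _make_cluster(chi2, times, start, end, roi_id) -> Cluster:
    return Cluster(
        roi_id=roi_id,
        start_idx=start,
        end_idx=end,
        start_s=float(times[start]),
        end_s=float(times[end - 1]),
        mass=float(chi2[start:end].sum()),
        n_members=end - start,
    )


@dataclass
class PermutationResult:
    """Per-ROI outcome of the cluster permutation test."""

    roi_id: str
    observed: Cluster | None
    clusters: list[Cluster]
    null: np.ndarray
    p_raw: float
    n_perm: int
    seed: int
    p_fdr: float | None = None
    no_cluster: bool = False

    @property
    def significant(self) -> bool:
        p = self.p_fdr if self.p_fdr is not None else self.p_raw
        return (not self.no_cluster) and p < 0.05


def permutation_p(observed_mass: float, null: np.ndarray, n_perm: int,
                  smoothing: bool = False) -> float:
    """Proportion of permutations with strictly larger biggest-cluster mass.

    ``smoothing`` applies the conventional (b + 1)/(m + 1) correction instead
    of the literal proportion rule.
    """
    b = int(np.sum(null > observed_mass))
    if smoothing:
        return (b + 1) / (n_perm + 1)
    return b / n_perm


def fdr_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fdr_across_rois(results: list[PermutationResult]) -> list[PermutationResult]:
    """Set ``p_fdr`` on each ROI's result by BH correction across ROIs."""
    adj = fdr_correct([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    return results
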