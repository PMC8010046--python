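"""Mass-univariate nested mixed-model comparison over an epoch window.

:class:`MassUnivariateLMM` pairs an :class:`~masslmm.containers.EpochSet`
with a trial table and a :class:`~masslmm.formula.ModelSpec`; ``fit()``
fits the full and reduced random-intercept models by maximum likelihood at
every timepoint of the test window and returns a
:class:`LRTTimecourseResults` carrying the chi-square timecourse, from which
clusters and the label-permutation test hang off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _lmm
from .cluster import (
    Cluster,
    PermutationResult,
    chi2_threshold,
    find_clusters,
    permutation_p,
)
from .containers import EpochSet
from .formula import DesignInfo, ModelSpec, build_design_matrices

__all__ = [
    "MassUnivariateLMM",
    "LRTTimecourseResults",
    "fit_lrt_at_timepoint",
    "lrt_timecourse",
    "permutation_test",
]

_NEG_TOL = 1e-6  # LR differences below -tol are flagged before clipping


class MassUnivariateLMM:
    """Per-timepoint full-vs-reduced random-intercept model comparison."""

    def __init__(
        self,
        epochs: EpochSet,
        trials: pd.DataFrame,
        spec: ModelSpec,
        window: tuple[float, float] | None = None,
    ):
        if len(trials) != epochs.n_trials:
            raise ValueError(
                f"trials table ({len(trials)} rows) does not match epochs "
                f"({epochs.n_trials} trials)"
            )
        self.epochs = epochs.crop(window) if window is not None else epochs
        self.trials = trials.reset_index(drop=True)
        self.spec = spec
        self.window = window
        self.design: DesignInfo = build_design_matrices(self.trials, spec)

    @property
    def df_interest(self) -> int:
        return self.design.df_interest

    def fit(self) -> "LRTTimecourseResults":
        d = self.design
        Y = np.ascontiguousarray(self.epochs.data.T)  # (T, n)
        gsz = np.bincount(d.groups, minlength=len(d.group_labels)).astype(float)
        chi2_raw, llf, llr = _lmm._timecourse(
            Y,
            np.ascontiguousarray(d.full),
            np.ascontiguousarray(d.reduced),
            d.groups,
            gsz,
        )
        converged = chi2_raw > -_NEG_TOL
        chi2 = np.clip(chi2_raw, 0.0, None)
        return LRTTimecourseResults(
            model=self,
            times=self.epochs.times.copy(),
            chi2=chi2,
            df=self.df_interest,
            loglik_full=llf,
            loglik_reduced=llr,
            converged=converged,
            roi_id=self.epochs.roi_id,
        )


@dataclass
class LRTTimecourseResults:
    """Likelihood-ratio chi-square timecourse for one ROI and window."""

    model: MassUnivariateLMM
    times: np.ndarray
    chi2: np.ndarray
    df: int
    loglik_full: np.ndarray
    loglik_reduced: np.ndarray
    converged: np.ndarray
    roi_id: str

    def threshold(self, alpha: float = 0.05) -> float:
        return chi2_threshold(self.df, alpha)

    def find_clusters(self, alpha: float = 0.05) -> list[Cluster]:
        return find_clusters(
            self.chi2, self.threshold(alpha), self.times, roi_id=self.roi_id
        )

    def permutation_test(
        self,
        n_perm: int = 10_000,
        seed: int = 0,
        alpha: float = 0.05,
        p_smoothing: bool = False,
    ) -> PermutationResult:
        """Monte-Carlo cluster test: shuffle the interest labels within each
        participant, re-fit the full model everywhere, and compare the
        observed biggest-cluster mass against the permutation biggest-cluster
        masses (permutations without clusters contribute mass 0)."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        d = self.model.design
        if len(d.group_labels) < 2:
            raise ValueError("permutation test needs >= 2 participants")
        if not d.interest_columns:
            raise ValueError("variables of interest are empty")
        thr = self.threshold(alpha)
        clusters = self.find_clusters(alpha)
        observed = clusters[0] if clusters else None

        Y = np.ascontiguousarray(self.model.epochs.data.T)
        gsz = np.bincount(d.groups, minlength=len(d.group_labels)).astype(float)
        group_rows = np.concatenate(
            [np.flatnonzero(d.groups == g) for g in range(len(d.group_labels))]
        ).astype(np.int64)
        group_offsets = np.concatenate(
            [[0], np.cumsum(gsz).astype(np.int64)]
        ).astype(np.int64)
        seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2**31 - 1)
        null = _lmm._perm_null(
            Y,
            np.ascontiguousarray(d.full),
            np.asarray(d.interest_columns, dtype=np.int64),
            self.loglik_reduced,
            d.groups,
            gsz,
            group_rows,
            group_offsets,
            thr,
            n_perm,
            seeds.astype(np.int64),
        )
        if observed is None:
            return PermutationResult(
                roi_id=self.roi_id,
                observed=None,
                clusters=[],
                null=null,
                p_raw=1.0,
                n_perm=n_perm,
                seed=seed,
                no_cluster=True,
            )
        p = permutation_p(observed.mass, null, n_perm, smoothing=p_smoothing)
        return PermutationResult(
            roi_id=self.roi_id,
            observed=observed,
            clusters=clusters,
            null=null,
            p_raw=p,
            n_perm=n_perm,
            seed=seed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "chi2": self.chi2,
                "df": self.df,
                "converged": self.converged,
            }
        )

    def summary(self) -> str:
        thr = self.threshold()
        clusters = self.find_clusters()
        lines = [
            f"Mass-univariate LMM LRT ({self.roi_id})",
            f"  timepoints: {len(self.times)}  "
            f"window: [{self.times[0]:.3f}, {self.times[-1]:.3f}] s",
            f"  df: {self.df}  cluster threshold (95th pct chi2): {thr:.4f}",
            f"  non-converged timepoints: {int((~self.converged).sum())}",
            f"  clusters: {len(clusters)}",
        ]
        for c in clusters:
            lines.append(
                f"    [{c.start_s:.3f}, {c.end_s:.3f}] s  "
                f"mass={c.mass:.2f}  n={c.n_members}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, alpha: float = 0.05):
        """Chi-square timecourse with the cluster-forming threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.chi2, color="k", lw=1)
        ax.axhline(self.threshold(alpha), color="r", lw=0.8)
        for c in self.find_clusters(alpha):
            ax.axvspan(c.start_s, c.end_s, color="g", alpha=0.3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"$\\chi^2({self.df})$")
        ax.set_title(self.roi_id)
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def fit_lrt_at_timepoint(y, design: DesignInfo) -> dict:
    """Single-timepoint LRT given built matrices; returns chi2 and both
    log-likelihoods with a convergence flag."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if len(y) < design.full.shape[1]:
        raise ValueError("fewer trials than fixed-effect columns")
    gsz = np.bincount(design.groups, minlength=len(design.group_labels)).astype(float)
    chi2_raw, llf, llr = _lmm._fit_pair(
        np.ascontiguousarray(design.full),
        np.ascontiguousarray(design.reduced),
        np.ascontiguousarray(y),
        design.groups,
        gsz,
    )
    return {
        "chi2": max(0.0, chi2_raw),
        "loglik_full": llf,
        "loglik_reduced": llr,
        "converged": chi2_raw > -_NEG_TOL,
    }


def lrt_timecourse(
    epochs: EpochSet,
    trials: pd.DataFrame,
    spec: ModelSpec,
    window: tuple[float, float] | None = None,
) -> LRTTimecourseResults:
    return MassUnivariateLMM(epochs, trials, spec, window=window).fit()


def permutation_test(
    epochs: EpochSet,
    trials: pd.DataFrame,
    spec: ModelSpec,
    window: tuple[float, float] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    p_smoothing: bool = False,
) -> PermutationResult:
    results = lrt_timecourse(epochs, trials, spec, window)
    return results.permutation_test(
        n_perm=n_perm, seed=seed, alpha=alpha, p_smoothing=p_smoothing
    )
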