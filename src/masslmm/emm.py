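"""Estimated marginal means and multiplicity-adjusted pairwise contrasts on
cluster-averaged activity.

After a significant cluster is found, the trial activity averaged over the
cluster's timepoints is regressed against the full model; EMMs are the
model's predictions on a reference grid that crosses the *family* factor
levels while averaging the remaining factors with equal weights and holding
covariates at their observed means.  Pairwise contrasts within the family
are adjusted by Tukey's studentized-range method (default), Bonferroni, or
left unadjusted; when an explicit subset of planned contrasts is given, the
family size for adjustment is the number of requested contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import RandomInterceptFit, fit_random_intercept_ml
from .cluster import Cluster
from .containers import EpochSet
from .formula import ModelSpec, build_design_matrices

__all__ = ["EMMResults", "ClusterEMM", "cluster_average", "emm_and_contrasts"]


def cluster_average(epochs: EpochSet, cluster: Cluster) -> np.ndarray:
    """Per-trial mean activity over the cluster's member timepoints."""
    if cluster.n_members < 1 or cluster.end_idx <= cluster.start_idx:
        raise ValueError("cluster has no member timepoints")
    if cluster.start_idx < 0 or cluster.end_idx > epochs.n_times:
        raise ValueError("cluster indices fall outside the epochs")
    return epochs.data[:, cluster.start_idx : cluster.end_idx].mean(axis=1)


class ClusterEMM:
    """Full-model refit on per-trial scalars, exposing EMMs and contrasts."""

    def __init__(
        self,
        scalars,
        trials: pd.DataFrame,
        spec: ModelSpec,
        family,
    ):
        self.scalars = np.asarray(scalars, dtype=float)
        if len(self.scalars) != len(trials):
            raise ValueError("scalars and trials have different lengths")
        self.trials = trials.reset_index(drop=True)
        self.spec = spec
        self.family = (family,) if isinstance(family, str) else tuple(family)
        self.design = build_design_matrices(self.trials, spec)
        for f in self.family:
            if f not in self.design._factors:
                raise ValueError(f"family factor {f!r} is not a model factor")

    def fit(
        self,
        adjust: str = "tukey",
        contrast_pairs=None,
    ) -> "EMMResults":
        fit = fit_random_intercept_ml(
            self.design.full, self.scalars, self.design.groups
        )
        grid, labels = self._reference_grid()
        L_expanded = self.design.encode_rows(grid)
        # collapse the non-family grid expansion by equal-weight averaging
        L = L_expanded.reshape(len(labels), self._n_other, -1).mean(axis=1)
        emm = L @ fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.cov_beta, L))
        emms = pd.DataFrame({"condition": labels, "emm": emm, "se": se})

        df_resid = fit.n - fit.p
        pairs = (
            list(itertools.combinations(range(len(labels)), 2))
            if contrast_pairs is None
            else [
                (labels.index(a), labels.index(b)) for a, b in contrast_pairs
            ]
        )
        k_family = len(labels) if contrast_pairs is None else None
        rows = []
        for i, j in pairs:
            d = L[i] - L[j]
            est = float(d @ fit.beta)
            cse = float(np.sqrt(d @ fit.cov_beta @ d))
            t = est / cse if cse > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df_resid)
            rows.append(
                {
                    "contrast": f"{labels[i]} - {labels[j]}",
                    "estimate": est,
                    "se": cse,
                    "t": t,
                    "p_unadjusted": p,
                }
            )
        contrasts = pd.DataFrame(rows)
        if len(contrasts):
            contrasts["p_adjusted"] = _adjust(
                contrasts, adjust, df_resid, k_family
            )
        return EMMResults(
            emms=emms,
            contrasts=contrasts,
            family=self.family,
            adjust=adjust,
            fit=fit,
        )

    def _reference_grid(self) -> tuple[pd.DataFrame, list[str]]:
        """One grid row per family cell, averaging other factors equally and
        holding covariates at their observed means.

        Equal-weight averaging over a non-family factor is encoded by
        averaging the encoded rows over that factor's levels, which is
        coding-scheme invariant.
        """
        factors = self.design._factors
        covariates = self.design._covariates
        family_levels = [factors[f].levels for f in self.family]
        other = [f for f in factors if f not in self.family]
        other_levels = [factors[f].levels for f in other]

        rows, labels = [], []
        for cell in itertools.product(*family_levels):
            # expand over the full grid of non-family levels; encode_rows of
            # the expansion is averaged later via repeated rows
            for other_cell in itertools.product(*other_levels):
                row = dict(zip(self.family, cell))
                row.update(dict(zip(other, other_cell)))
                for cov, sc in covariates.items():
                    row[cov] = sc.mean
                rows.append(row)
            labels.append(",".join(cell))
        grid = pd.DataFrame(rows)
        # collapse the non-family expansion by equal-weight averaging
        n_other = max(1, int(np.prod([len(l) for l in other_levels])))
        self._n_other = n_other
        return grid, labels

    # encode_rows handles the expansion; ClusterEMM.fit averages it back down


def _adjust(contrasts: pd.DataFrame, method: str, df_resid: int, k_family):
    p = contrasts["p_unadjusted"].to_numpy()
    t = contrasts["t"].to_numpy()
    m = len(contrasts)
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "tukey":
        k = k_family if k_family is not None else m
        if k_family is None:
            # all-pairwise family: k means give k(k-1)/2 contrasts
            k = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        q = np.abs(t) * np.sqrt(2.0)
        return np.clip(stats.studentized_range.sf(q, k, df_resid), 0.0, 1.0)
    raise ValueError(f"unknown adjustment {method!r}")


@dataclass
class EMMResults:
    """EMM table plus multiplicity-adjusted pairwise contrasts."""

    emms: pd.DataFrame
    contrasts: pd.DataFrame
    family: tuple[str, ...]
    adjust: str
    fit: RandomInterceptFit

    def summary(self) -> str:
        lines = [f"Estimated marginal means (family: {', '.join(self.family)})"]
        for r in self.emms.itertuples(index=False):
            lines.append(f"  {r.condition:<30s} {r.emm: .4f} (SE {r.se:.4f})")
        lines.append(f"Pairwise contrasts ({self.adjust}-adjusted)")
        for r in self.contrasts.itertuples(index=False):
            lines.append(
                f"  {r.contrast:<45s} {r.estimate: .4f}  t={r.t: .2f}  "
                f"p={r.p_adjusted:.4g}"
            )
        return "\n".join(lines)


def emm_and_contrasts(
    scalars,
    trials: pd.DataFrame,
    spec: ModelSpec,
    family,
    adjust: str = "tukey",
    contrast_pairs=None,
) -> EMMResults:
    """Functional wrapper over :class:`ClusterEMM`."""
    model = ClusterEMM(scalars, trials, spec, family)
    return model.fit(adjust=adjust, contrast_pairs=contrast_pairs)
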