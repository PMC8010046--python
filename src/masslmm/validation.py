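"""Simulation-based operating characteristics of the cluster pipeline.

These routines run many replicate synthetic experiments to measure the
family-wise false-positive rate of the cluster permutation test under the
null and its power/recovery behaviour with a known injected effect.  They
are used by the test suite and the reproduction script; desk-scale problem
sizes (tens of participants, tens of timepoints, hundreds of permutations)
keep a full calibration run in the minutes range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .emm import ClusterEMM, cluster_average
from .formula import ModelSpec
from .model import MassUnivariateLMM
from .simulate import EffectSpec, NoiseSpec, simulate_roi_epochs

__all__ = ["null_calibration", "effect_recovery", "CalibrationResult", "RecoveryResult"]

_SPEC = ModelSpec(fixed=("condition",), interest=("condition",))


def _factorial_trials(n_participants: int, trials_per_cell: int,
                      levels=("a", "b", "c")) -> pd.DataFrame:
    rows = [
        {"participant_id": f"P{p:02d}", "condition": lv}
        for p in range(n_participants)
        for lv in levels
        for _ in range(trials_per_cell)
    ]
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    false_positive_rate: float
    n_experiments: int
    pvalues: np.ndarray


def null_calibration(
    n_experiments: int = 200,
    n_participants: int = 12,
    trials_per_cell: int = 24,
    n_timepoints: int = 50,
    n_perm: int = 200,
    alpha: float = 0.05,
    intercept_sd: float = 0.3,
    seed: int = 0,
) -> CalibrationResult:
    """Family-wise false-positive rate of the cluster permutation test on
    pure-noise experiments (three balanced within-participant conditions,
    participant random intercepts, no condition effect)."""
    trials = _factorial_trials(n_participants, trials_per_cell)
    sfreq = 200.0
    tmax = (n_timepoints - 1) / sfreq
    noise = NoiseSpec(participant_intercept_sd=intercept_sd, residual_sd=1.0, ar1=0.5)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_experiments) % (2**31 - 1)
    pvals = np.empty(n_experiments)
    for i in range(n_experiments):
        epochs, _ = simulate_roi_epochs(
            trials, effects=[], noise=noise, sfreq=sfreq,
            seed=int(seeds[2 * i]), tmin=0.0, tmax=tmax,
        )
        res = MassUnivariateLMM(epochs, trials, _SPEC).fit()
        perm = res.permutation_test(n_perm=n_perm, seed=int(seeds[2 * i + 1]),
                                    alpha=alpha)
        pvals[i] = perm.p_raw if not perm.no_cluster else 1.0
    return CalibrationResult(
        false_positive_rate=float(np.mean(pvals < alpha)),
        n_experiments=n_experiments,
        pvalues=pvals,
    )


@dataclass
class RecoveryResult:
    detection_rate: float  # significant cluster overlapping the true window
    emm_within_2se_rate: float  # injected contrast recovered within 2 SE
    n_replicates: int


def effect_recovery(
    n_replicates: int = 50,
    n_participants: int = 12,
    trials_per_cell: int = 24,
    n_timepoints: int = 50,
    n_perm: int = 200,
    amplitude: float = 3.0,
    residual_sd: float = 1.0,
    effect_window: tuple[float, float] = (0.100, 0.150),
    alpha: float = 0.05,
    seed: int = 0,
) -> RecoveryResult:
    """Power and estimation accuracy with a known injected condition effect.

    One condition level gets a boxcar bump of ``amplitude`` (in units of the
    residual standard deviation) inside ``effect_window``; a replicate counts
    as detected when the permutation test is significant and the biggest
    cluster overlaps the true window.  The injected pairwise mean difference
    must be recovered by the cluster-averaged EMM contrast within two
    standard errors.
    """
    trials = _factorial_trials(n_participants, trials_per_cell)
    sfreq = 200.0
    tmax = (n_timepoints - 1) / sfreq
    effect = EffectSpec(
        factor="condition",
        weights={"a": 1.0, "b": 0.0, "c": 0.0},
        window=effect_window,
        amplitude=amplitude * residual_sd,
    )
    noise = NoiseSpec(participant_intercept_sd=0.3, residual_sd=residual_sd, ar1=0.5)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_replicates) % (2**31 - 1)
    detected = np.zeros(n_replicates, dtype=bool)
    within = np.zeros(n_replicates, dtype=bool)
    for i in range(n_replicates):
        epochs, _ = simulate_roi_epochs(
            trials, effects=[effect], noise=noise, sfreq=sfreq,
            seed=int(seeds[2 * i]), tmin=0.0, tmax=tmax,
        )
        res = MassUnivariateLMM(epochs, trials, _SPEC).fit()
        perm = res.permutation_test(n_perm=n_perm, seed=int(seeds[2 * i + 1]),
                                    alpha=alpha)
        if perm.observed is None or perm.p_raw >= alpha:
            continue
        c = perm.observed
        overlaps = c.start_s <= effect_window[1] and c.end_s >= effect_window[0]
        detected[i] = overlaps
        if not overlaps:
            continue
        scalars = cluster_average(epochs, c)
        emm = ClusterEMM(scalars, trials, _SPEC, "condition").fit(adjust="none")
        row = emm.contrasts[emm.contrasts["contrast"] == "a - b"].iloc[0]
        # injected a-vs-b difference in the cluster average: amplitude times
        # the fraction of cluster samples inside the true window
        tmask = (epochs.times[c.start_idx:c.end_idx] >= effect_window[0] - 1e-9) & (
            epochs.times[c.start_idx:c.end_idx] <= effect_window[1] + 1e-9
        )
        injected = amplitude * residual_sd * tmask.mean()
        within[i] = abs(row["estimate"] - injected) <= 2.0 * row["se"]
    return RecoveryResult(
        detection_rate=float(detected.mean()),
        emm_within_2se_rate=float(within[detected].mean()) if detected.any() else 0.0,
        n_replicates=n_replicates,
    )
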