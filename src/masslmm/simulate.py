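"""Synthetic single-trial ROI timecourses and oscillatory sensor-like trials.

The ROI simulator mirrors the statistical structure the mixed-model analysis
assumes: a participant random intercept, linear effects of z-scored
covariates, condition effects confined to configurable time windows, and
AR(1) residual noise.  The oscillatory simulator produces sinusoidal bursts
that are either phase-locked across trials (evoked-like) or get an
independent uniform phase per trial (induced-like), for the induced/evoked
dissociation in the spectral module.

Ground truth (the noiseless expected signal per trial plus the drawn
participant intercepts) is returned alongside the data so recovery tests can
compare estimates against what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "BurstSpec",
    "GroundTruth",
    "simulate_roi_epochs",
    "simulate_oscillatory_trials",
]

DEFAULT_TMIN = -0.100
DEFAULT_TMAX = 1.200
DEFAULT_SFREQ = 200.0


@dataclass(frozen=True)
class EffectSpec:
    """A condition effect: per-level contrast weights times a temporal kernel.

    ``weights`` maps levels of ``factor`` to unitless contrast weights;
    unlisted levels get weight 0.  The kernel is 1 inside ``window`` for
    ``boxcar``, or a Gaussian bump centred on the window midpoint with the
    given ``sigma`` (seconds) for ``gaussian``.
    """

    factor: str
    weights: Mapping[str, float]
    window: tuple[float, float]
    amplitude: float = 1.0
    kernel: str = "boxcar"
    sigma: float = 0.020

    def kernel_values(self, times: np.ndarray) -> np.ndarray:
        start, end = self.window
        if start > end:
            raise ValueError(f"empty effect window {self.window}")
        if start < times[0] - 1e-9 or end > times[-1] + 1e-9:
            raise ValueError(
                f"effect window {self.window} outside epoch "
                f"[{times[0]:.3f}, {times[-1]:.3f}]"
            )
        if self.kernel == "boxcar":
            return ((times >= start) & (times <= end)).astype(float)
        if self.kernel == "gaussian":
            centre = 0.5 * (start + end)
            return np.exp(-0.5 * ((times - centre) / self.sigma) ** 2)
        raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and nuisance structure of the simulated activation."""

    participant_intercept_sd: float = 0.3
    residual_sd: float = 1.0
    ar1: float = 0.5
    slopes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.participant_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class BurstSpec:
    """A sinusoidal burst for the oscillatory simulator.

    ``phase_locked`` bursts share one phase across trials; otherwise each
    trial draws an independent uniform phase.  ``factor``/``levels`` restrict
    the burst to trials whose factor value is among the levels.
    """

    freq: float
    window: tuple[float, float]
    amplitude: float = 1.0
    phase_locked: bool = False
    factor: str | None = None
    levels: tuple[str, ...] | None = None


@dataclass
class GroundTruth:
    """What the simulator injected, for recovery tests."""

    expected: np.ndarray  # noiseless per-trial signal, trials x timepoints
    participant_intercepts: pd.Series
    effects: tuple[EffectSpec, ...]
    noise: NoiseSpec


def _epoch_times(sfreq: float, tmin: float, tmax: float) -> np.ndarray:
    n0 = int(round(tmin * sfreq))
    n1 = int(round(tmax * sfreq))
    return np.arange(n0, n1 + 1) / sfreq


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_roi_epochs(
    trials: pd.DataFrame,
    effects: Sequence[EffectSpec] = (),
    noise: NoiseSpec = NoiseSpec(),
    sfreq: float = DEFAULT_SFREQ,
    seed: int = 0,
    tmin: float = DEFAULT_TMIN,
    tmax: float = DEFAULT_TMAX,
    roi_id: str = "ROI",
) -> tuple[EpochSet, GroundTruth]:
    """Simulate one ROI's trials x timepoints activation matrix.

    The signal for trial *i* at time *t* is::

        b[participant(i)] + sum_c slope_c * z_c(i) + sum_e w_e(i) * A_e * k_e(t)

    plus stationary AR(1) noise with marginal standard deviation
    ``noise.residual_sd``.  Covariates named in ``noise.slopes`` are z-scored
    over the trials entering the simulation.
    """
    if len(trials) == 0:
        raise ValueError("trials table is empty")
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times = _epoch_times(sfreq, tmin, tmax)
    n, t = len(trials), len(times)

    participants = trials["participant_id"].to_numpy()
    unique_p = pd.unique(participants)
    intercepts = pd.Series(
        rng.normal(0.0, noise.participant_intercept_sd, size=len(unique_p)),
        index=unique_p,
    )
    per_trial = intercepts.loc[participants].to_numpy()

    for cov, slope in noise.slopes.items():
        if cov not in trials.columns:
            raise ValueError(f"covariate {cov!r} not in trials")
        z = _zscore(trials[cov].to_numpy(dtype=float))
        per_trial = per_trial + slope * z

    expected = np.repeat(per_trial[:, None], t, axis=1)
    for eff in effects:
        kern = eff.kernel_values(times)
        levels = trials[eff.factor].astype(str).to_numpy()
        w = np.array([eff.weights.get(lv, 0.0) for lv in levels])
        expected = expected + np.outer(w * eff.amplitude, kern)

    data = expected.copy()
    if noise.residual_sd > 0:
        e = np.empty((n, t))
        e[:, 0] = rng.normal(0.0, noise.residual_sd, size=n)
        innov_sd = noise.residual_sd * np.sqrt(1.0 - noise.ar1**2)
        for j in range(1, t):
            e[:, j] = noise.ar1 * e[:, j - 1] + rng.normal(0.0, innov_sd, size=n)
        data = data + e

    epochs = EpochSet(data=data, times=times, sfreq=sfreq, roi_id=roi_id)
    truth = GroundTruth(
        expected=expected,
        participant_intercepts=intercepts,
        effects=tuple(effects),
        noise=noise,
    )
    return epochs, truth


def simulate_oscillatory_trials(
    trials: pd.DataFrame,
    bursts: Sequence[BurstSpec] = (),
    noise_sd: float = 1.0,
    sfreq: float = DEFAULT_SFREQ,
    seed: int = 0,
    tmin: float = DEFAULT_TMIN,
    tmax: float = DEFAULT_TMAX,
    roi_id: str = "sensors",
) -> EpochSet:
    """Simulate sensor-like trials containing sinusoidal bursts plus white
    noise.

    Phase-locked bursts survive trial averaging at full amplitude; bursts
    with per-trial random phase cancel in the average (induced power only).
    """
    if len(trials) == 0:
        raise ValueError("trials table is empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times = _epoch_times(sfreq, tmin, tmax)
    n, t = len(trials), len(times)
    data = np.zeros((n, t))

    for burst in bursts:
        if burst.freq >= sfreq / 2:
            raise ValueError(
                f"burst frequency {burst.freq} Hz is at or above Nyquist "
                f"({sfreq / 2} Hz)"
            )
        start, end = burst.window
        if start < times[0] - 1e-9 or end > times[-1] + 1e-9:
            raise ValueError(f"burst window {burst.window} outside epoch")
        gate = (times >= start) & (times <= end)
        if burst.factor is None:
            rows = np.ones(n, dtype=bool)
        else:
            rows = trials[burst.factor].astype(str).isin(burst.levels or ()).to_numpy()
        if burst.phase_locked:
            phases = np.full(n, rng.uniform(0, 2 * np.pi))
        else:
            phases = rng.uniform(0, 2 * np.pi, size=n)
        wave = np.sin(
            2 * np.pi * burst.freq * times[None, :] + phases[:, None]
        )
        data[rows] += burst.amplitude * (wave * gate[None, :])[rows]

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=(n, t))
    return EpochSet(data=data, times=times, sfreq=sfreq, roi_id=roi_id)
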