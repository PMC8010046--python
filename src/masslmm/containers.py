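"""In-memory containers for trial-level ROI/sensor epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EpochSet:
    """Trials x timepoints matrix of signed activation for one ROI (or one
    virtual sensor), with a uniform time axis.

    ``data[i, j]`` is the activation of trial ``i`` at ``times[j]`` in
    arbitrary (dSPM-like, noise-normalised) units.  Rows are aligned with the
    rows of a trial metadata table; any subsetting must be applied to both.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    roi_id: str = "ROI"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (trials x timepoints) array")
        if self.data.shape[1] != self.times.shape[0]:
            raise ValueError(
                f"data has {self.data.shape[1]} timepoints but times has "
                f"{self.times.shape[0]} entries"
            )
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be 1-D with at least two samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced at 1/sfreq")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaNs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples inside the closed window [start, end]."""
        start, end = window
        if end < start:
            raise ValueError(f"empty window: {window}")
        tol = 0.5 / self.sfreq
        mask = (self.times >= start - tol * 1e-6) & (self.times <= end + tol * 1e-6)
        if not mask.any():
            raise ValueError(f"window {window} contains no samples")
        return mask

    def crop(self, window: tuple[float, float]) -> "EpochSet":
        """Restrict to samples inside the closed window (boundaries included)."""
        mask = self.time_mask(window)
        return replace(self, data=self.data[:, mask], times=self.times[mask])

    def subset(self, rows) -> "EpochSet":
        """Select trials by boolean mask or integer index array."""
        rows = np.asarray(rows)
        return replace(self, data=self.data[rows])
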