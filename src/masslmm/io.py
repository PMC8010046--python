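"""Reading and writing the on-disk formats: HDF5 epochs with a CSV trial
sidecar, TSV result tables, and YAML configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet

__all__ = [
    "SchemaError",
    "write_epochs",
    "read_epochs",
    "write_lrt_tsv",
    "write_cluster_tsv",
    "write_tfr_cluster_tsv",
    "config_hash",
]


class SchemaError(ValueError):
    """An on-disk container is missing required fields."""

    def __init__(self, path, missing):
        self.missing = list(missing)
        super().__init__(f"{path}: missing required field(s) {self.missing}")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".csv")


def write_epochs(epochs: EpochSet, trials: pd.DataFrame, path) -> Path:
    """Write epochs as HDF5 (datasets ``data``, ``times``; attrs ``sfreq``,
    ``roi_id``) with the trial table as a CSV sidecar next to it."""
    path = Path(path)
    if len(trials) != epochs.n_trials:
        raise ValueError("trials table does not match epoch count")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["roi_id"] = epochs.roi_id
    trials.to_csv(_sidecar(path), index=False)
    return path


_TRIAL_COLUMNS = {
    "trial_id",
    "participant_id",
    "block_id",
    "block_type",
    "onset_time_s",
}


def read_epochs(path) -> tuple[EpochSet, pd.DataFrame]:
    """Read an HDF5 epochs container and its CSV trial sidecar.

    Extra CSV columns are preserved; missing required fields raise a
    :class:`SchemaError` naming them.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        missing = [k for k in ("data", "times") if k not in f]
        missing += [a for a in ("sfreq", "roi_id") if a not in f.attrs]
        if missing:
            raise SchemaError(path, missing)
        epochs = EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            roi_id=str(f.attrs["roi_id"]),
        )
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise SchemaError(sidecar, ["<trial table sidecar>"])
    trials = pd.read_csv(sidecar)
    missing_cols = _TRIAL_COLUMNS - set(trials.columns)
    if missing_cols:
        raise SchemaError(sidecar, sorted(missing_cols))
    if len(trials) != epochs.n_trials:
        raise SchemaError(sidecar, ["<row count matching epochs>"])
    return epochs, trials


def write_lrt_tsv(results, path, extra_header: dict | None = None) -> Path:
    path = Path(path)
    frame = results.to_frame()
    with open(path, "w") as f:
        for k, v in (extra_header or {}).items():
            f.write(f"# {k}: {v}\n")
        frame.to_csv(f, sep="\t", index=False)
    return path


def write_cluster_tsv(results, path, extra_header: dict | None = None) -> Path:
    """Write per-ROI permutation results as TSV."""
    path = Path(path)
    rows = []
    for r in results:
        obs = r.observed
        rows.append(
            {
                "roi": r.roi_id,
                "cluster_start_s": obs.start_s if obs else np.nan,
                "cluster_end_s": obs.end_s if obs else np.nan,
                "mass": obs.mass if obs else 0.0,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr if r.p_fdr is not None else np.nan,
                "no_cluster": r.no_cluster,
            }
        )
    with open(path, "w") as f:
        for k, v in (extra_header or {}).items():
            f.write(f"# {k}: {v}\n")
        pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
    return path


def write_tfr_cluster_tsv(results, path, extra_header: dict | None = None) -> Path:
    path = Path(path)
    rows = []
    for r in results:
        if r.clusters:
            c = r.clusters[0]
            rows.append(
                {
                    "comparison": r.comparison,
                    "t_start_s": c.t_start_s,
                    "t_end_s": c.t_end_s,
                    "f_lo_hz": c.f_lo_hz,
                    "f_hi_hz": c.f_hi_hz,
                    "mass": c.mass,
                    "p_raw": r.p_raw,
                    "p_fdr": r.p_fdr if r.p_fdr is not None else np.nan,
                }
            )
        else:
            rows.append(
                {
                    "comparison": r.comparison,
                    "t_start_s": np.nan,
                    "t_end_s": np.nan,
                    "f_lo_hz": np.nan,
                    "f_hi_hz": np.nan,
                    "mass": 0.0,
                    "p_raw": r.p_raw,
                    "p_fdr": r.p_fdr if r.p_fdr is not None else np.nan,
                }
            )
    with open(path, "w") as f:
        for k, v in (extra_header or {}).items():
            f.write(f"# {k}: {v}\n")
        pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
    return path


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_yaml(obj: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=True)
    return path
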