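"""End-to-end synthetic replication pipeline.

Runs the whole analysis chain on simulated data with known ground truth:
design generation -> ROI simulation -> per-ROI LRT timecourses -> cluster
permutation tests -> FDR across ROIs -> cluster-averaged EMMs and contrasts
-> spectral suite (single-trial and evoked TFR cluster tests with FDR over
the three comparisons) -> design-based information-theoretic report.  Every
stage logs its timing; a JSON manifest records the configuration, its hash,
all seeds and every output path.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cluster import fdr_across_rois, fdr_correct
from .design import (
    augment_trials,
    design_transition_probabilities,
    generate_design,
)
from .emm import ClusterEMM, cluster_average
from .formula import PRESETS
from .infotheory import entropy, entropy_reduction, sequence_metrics, surprisal
from .model import MassUnivariateLMM
from .simulate import BurstSpec, EffectSpec, NoiseSpec, simulate_oscillatory_trials, simulate_roi_epochs
from .spectral import baseline_and_aggregate, evoked_tfr, morlet_tfr, tfr_cluster_test

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ROI_LABELS = ("LPTL", "LATL", "LIFC", "LAG")

logger = logging.getLogger("masslmm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one synthetic replication run."""

    n_sets: int = 36
    n_participants: int = 12
    seed: int = 0
    preset: str = "syntactic-complexity"
    rois: tuple[str, ...] = ROI_LABELS
    effect_roi: str = "LPTL"
    effect_window: tuple[float, float] = (0.850, 0.970)
    effect_amplitude: float = 0.45
    intercept_sd: float = 0.3
    residual_sd: float = 1.0
    ar1: float = 0.5
    sfreq: float = 200.0
    n_perm: int = 200
    alpha: float = 0.05
    adjust: str = "tukey"
    spectral_n_perm: int = 500
    spectral_trials_per_cond: int = 144
    beta_freq: float = 18.0
    beta_window: tuple[float, float] = (0.780, 1.180)
    beta_amplitude: float = 0.35

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.spectral_n_perm < 1:
            raise ValueError("spectral_n_perm must be >= 1")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.effect_roi not in self.rois:
            raise ValueError("effect_roi must be among the ROIs")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.load_yaml(path)
        for key in ("rois", "effect_window", "beta_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return decorator


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full synthetic replication and return the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.to_dict())
    header = {"config_hash": chash}

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "outputs": {},
        "results": {},
    }
    manifest_path = outdir / "manifest.json"
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(16) % (2**31 - 1)

    try:
        trials = _stage("design")(generate_design)(
            config.n_sets, config.n_participants, seed=int(seeds[0])
        )
        trials = augment_trials(trials)
        preset = PRESETS[config.preset]
        mask = preset.subset_mask(trials)
        sub_trials = trials[mask].reset_index(drop=True)

        @_stage("simulate")
        def _simulate():
            noise = NoiseSpec(
                participant_intercept_sd=config.intercept_sd,
                residual_sd=config.residual_sd,
                ar1=config.ar1,
                slopes={"noun_zipf": 0.1, "log_onset_time": -0.05},
            )
            per_roi = {}
            for i, roi in enumerate(config.rois):
                effects = []
                if roi == config.effect_roi:
                    factor = preset.spec.interest[0].split(":")[0]
                    levels = sorted(sub_trials[factor].astype(str).unique())
                    weights = {lv: float(j) for j, lv in enumerate(levels)}
                    effects = [
                        EffectSpec(
                            factor=factor,
                            weights=weights,
                            window=config.effect_window,
                            amplitude=config.effect_amplitude,
                        )
                    ]
                epochs, truth = simulate_roi_epochs(
                    sub_trials,
                    effects=effects,
                    noise=noise,
                    sfreq=config.sfreq,
                    seed=int(seeds[1 + i]),
                    roi_id=roi,
                )
                path = io.write_epochs(epochs, sub_trials, outdir / f"epochs_{roi}.h5")
                manifest["outputs"][f"epochs_{roi}"] = str(path)
                per_roi[roi] = epochs
            return per_roi

        per_roi = _simulate()

        @_stage("lrt-and-permutation")
        def _lrt():
            results = []
            for i, roi in enumerate(config.rois):
                res = MassUnivariateLMM(
                    per_roi[roi], sub_trials, preset.spec, window=preset.window
                ).fit()
                path = io.write_lrt_tsv(
                    res, outdir / f"lrt_{roi}.tsv", extra_header=header
                )
                manifest["outputs"][f"lrt_{roi}"] = str(path)
                perm = res.permutation_test(
                    n_perm=config.n_perm,
                    seed=int(seeds[8 + i]),
                    alpha=config.alpha,
                )
                results.append((res, perm))
            fdr_across_rois([p for _, p in results])
            path = io.write_cluster_tsv(
                [p for _, p in results], outdir / "clusters.tsv", extra_header=header
            )
            manifest["outputs"]["clusters"] = str(path)
            manifest["results"]["cluster_p_fdr"] = {
                p.roi_id: p.p_fdr for _, p in results
            }
            return results

        lrt_results = _lrt()

        @_stage("emm")
        def _emm():
            res, perm = next(
                (r, p) for r, p in lrt_results if p.roi_id == config.effect_roi
            )
            if perm.observed is None:
                manifest["results"]["emm"] = "no cluster in effect ROI"
                return None
            scalars = cluster_average(res.model.epochs, perm.observed)
            family = preset.spec.interest[0].split(":")[0].replace("*", ":").split(":")[0]
            emm = ClusterEMM(scalars, sub_trials, preset.spec, family).fit(
                adjust=config.adjust
            )
            path = outdir / "emm.tsv"
            with open(path, "w") as f:
                f.write(f"# config_hash: {chash}\n")
                emm.emms.to_csv(f, sep="\t", index=False)
                f.write("\n")
                emm.contrasts.to_csv(f, sep="\t", index=False)
            manifest["outputs"]["emm"] = str(path)
            return emm

        _emm()

        @_stage("spectral")
        def _spectral():
            two = trials[trials["block_type"] == "two_word"]
            rng = np.random.default_rng(int(seeds[13]))
            keep = []
            for pid in two["participant_id"].unique():
                for cond in ("indefinite_phrase", "sentence", "definite_phrase"):
                    idx = two.index[
                        (two["participant_id"] == pid) & (two["syntactic"] == cond)
                    ]
                    take = min(config.spectral_trials_per_cond, len(idx))
                    keep.extend(rng.choice(idx, size=take, replace=False))
            sp_trials = two.loc[sorted(keep)].reset_index(drop=True)
            bursts = [
                BurstSpec(
                    freq=config.beta_freq,
                    window=config.beta_window,
                    amplitude=config.beta_amplitude,
                    phase_locked=False,
                    factor="syntactic",
                    levels=("sentence", "definite_phrase"),
                )
            ]
            epochs = simulate_oscillatory_trials(
                sp_trials, bursts, noise_sd=1.0, sfreq=config.sfreq,
                seed=int(seeds[14]),
            )
            power, edge = morlet_tfr(epochs)
            stacks = {
                cond: baseline_and_aggregate(
                    power,
                    sp_trials,
                    epochs,
                    np.arange(8.0, 33.0),
                    condition_mask=(sp_trials["syntactic"] == cond).to_numpy(),
                    condition=cond,
                    edge_mask=edge,
                )
                for cond in ("indefinite_phrase", "sentence", "definite_phrase")
            }
            pairs = [
                ("sentence", "indefinite_phrase"),
                ("definite_phrase", "indefinite_phrase"),
                ("sentence", "definite_phrase"),
            ]
            results = [
                tfr_cluster_test(
                    stacks[a], stacks[b],
                    n_perm=config.spectral_n_perm,
                    seed=int(seeds[15]) + k,
                )
                for k, (a, b) in enumerate(pairs)
            ]
            adj = fdr_correct([r.p_raw for r in results])
            for r, a in zip(results, adj):
                r.p_fdr = float(a)
            path = io.write_tfr_cluster_tsv(
                results, outdir / "tfr_clusters.tsv", extra_header=header
            )
            manifest["outputs"]["tfr_clusters"] = str(path)

            ev_stacks = {
                cond: evoked_tfr(
                    epochs,
                    sp_trials,
                    condition_mask=(sp_trials["syntactic"] == cond).to_numpy(),
                    condition=cond,
                )
                for cond in ("indefinite_phrase", "sentence", "definite_phrase")
            }
            ev_results = [
                tfr_cluster_test(
                    ev_stacks[a], ev_stacks[b],
                    n_perm=config.spectral_n_perm,
                    seed=int(seeds[15]) + 100 + k,
                )
                for k, (a, b) in enumerate(pairs)
            ]
            adj = fdr_correct([r.p_raw for r in ev_results])
            for r, a in zip(ev_results, adj):
                r.p_fdr = float(a)
            path = io.write_tfr_cluster_tsv(
                ev_results, outdir / "tfr_clusters_evoked.tsv", extra_header=header
            )
            manifest["outputs"]["tfr_clusters_evoked"] = str(path)
            manifest["results"]["tfr_p_fdr"] = {
                r.comparison: r.p_fdr for r in results
            }
            manifest["results"]["tfr_evoked_p_fdr"] = {
                r.comparison: r.p_fdr for r in ev_results
            }

        _spectral()

        @_stage("infotheory")
        def _info():
            table = design_transition_probabilities(
                trials, "noun_definiteness", outcome="adj_definiteness"
            )
            table.to_csv(outdir / "transitions.csv")
            struct = design_transition_probabilities(
                trials, "noun_definiteness", outcome="syntactic"
            )
            start = np.full(3, 1.0 / 3.0)
            report = {
                "structure_entropy_start_bits": entropy(start),
                "entropy_reduction_indefinite_noun_bits": entropy_reduction(
                    start, struct.distribution("indefinite").to_numpy()
                ),
                "entropy_reduction_definite_noun_bits": entropy_reduction(
                    start, struct.distribution("definite").to_numpy()
                ),
                "surprisal_indefinite_noun_bits": surprisal(1.0 / 3.0),
                "surprisal_definite_noun_bits": surprisal(2.0 / 3.0),
                "adj_surprisal_after_definite_bits": surprisal(
                    table.prob("definite", "indefinite")
                ),
                "adj_surprisal_after_indefinite_bits": surprisal(
                    table.prob("indefinite", "indefinite")
                ),
            }
            seq = sequence_metrics(table, ["definite", "indefinite"])
            path = outdir / "infotheory.json"
            with open(path, "w") as f:
                json.dump(report, f, indent=2)
            seq.to_csv(outdir / "sequence_metrics.tsv", sep="\t", index=False)
            manifest["outputs"]["infotheory"] = str(path)
            manifest["results"]["infotheory"] = report

        _info()
    finally:
        manifest["seeds"] = [int(s) for s in seeds]
        with open(manifest_path, "w") as f:
            json.dump(manifest, f, indent=2, default=str)
        logger.removeHandler(handler)
        handler.close()
    manifest["manifest_path"] = str(manifest_path)
    return manifest
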