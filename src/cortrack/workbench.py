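"""End-to-end pipeline plumbing: configuration, study I/O, reports.

A run executes envelope/EEG pairing -> nested-LOO decoding -> behavioral
coding -> group statistics, reading every parameter from a single
:class:`RunConfig` and emitting a frozen copy of that config plus a
machine-readable summary.  Studies are stored as text/flat-binary files:

* ``trials.csv`` — one row per epoch (subject, stimulus, presentation,
  epoch index, questionnaire answers, and, after decoding, accuracy);
* ``epochs/<key>.env.bin`` / ``epochs/<key>.eeg.bin`` — little-endian
  float64 arrays (EEG row-major channels x samples);
* ``arrays.json`` — sidecar with fs, channel names and per-file shapes;
* ``ground_truth.json`` — what the generator planted;
* ``config.json`` — frozen configuration with its hash.

Real EEG enters through the same contract: any reader that yields a
channels x time float array at a stated rate (for instance mne's
``raw.get_data()``) can populate a study directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoder, indicators, stats
from .simulate import GroundTruth, SimConfig, Study, simulate_study

__all__ = [
    "RunConfig",
    "write_study",
    "read_study",
    "decode_study",
    "run_pipeline",
    "make_fixtures",
]

log = logging.getLogger("cortrack")


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, in one frozen object.

    Decoder defaults are the canonical analysis settings: lag window
    [-0.2 s, +0.35 s] at 64 Hz (36 shifts), lambda grid 10^-6..10^6,
    1-9 Hz band, 30 s epochs, 500 ms onset discard for real audio/EEG.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    t_min: float = -0.2
    t_max: float = 0.35
    band: tuple = (1.0, 9.0)
    epoch_seconds: float = 30.0
    discard_head_ms: float = 500.0
    lambda_grid: tuple = decoder.DEFAULT_LAMBDA_GRID
    alpha_fixed: float = 0.05
    alpha_random: float = 0.1
    n_permutations: int = 50
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["lambda_grid"] = list(self.lambda_grid)
        d["band"] = list(self.band)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            snr = sim.pop("snr_map", None)
            cfg = SimConfig(**sim)
            if snr:
                cfg.snr_map = {tuple(k.split("|")): float(v) for k, v in snr.items()}
            sim = cfg
        d.pop("config_hash", None)
        if "lambda_grid" in d:
            d["lambda_grid"] = tuple(float(x) for x in d["lambda_grid"])
        if "band" in d:
            d["band"] = tuple(float(x) for x in d["band"])
        return cls(sim=sim, **d)


def _key_name(key) -> str:
    subj, stim, pres, ep = key
    return f"s{subj:03d}_m{stim:03d}_p{pres}_e{ep:03d}"


def write_study(study: Study, out_dir) -> Path:
    """Serialize a study to a directory (see module docstring for layout)."""
    out = Path(out_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    study.records.to_csv(out / "trials.csv", index=False)
    sidecar = {
        "fs": study.config.fs,
        "channel_names": [f"ch{c:02d}" for c in range(study.config.n_channels)],
        "dtype": "<f8",
        "arrays": {},
    }
    for key in study.envelopes:
        name = _key_name(key)
        env = np.ascontiguousarray(study.envelopes[key], dtype="<f8")
        eeg = np.ascontiguousarray(study.eeg[key], dtype="<f8")
        env.tofile(out / "epochs" / f"{name}.env.bin")
        eeg.tofile(out / "epochs" / f"{name}.eeg.bin")
        sidecar["arrays"][name] = {
            "key": list(key),
            "env_shape": list(env.shape),
            "eeg_shape": list(eeg.shape),
        }
    (out / "arrays.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    truth = study.ground_truth
    gt = {
        "kernels": truth.kernels.tolist(),
        "true_familiarity_label": {str(k): v for k, v in truth.true_familiarity_label.items()},
        "true_mw_group": {str(k): v for k, v in truth.true_mw_group.items()},
        "subject_effect": {str(k): v for k, v in truth.subject_effect.items()},
        "stimulus_effect": {str(k): v for k, v in truth.stimulus_effect.items()},
        "per_trial_snr": truth.per_trial_snr.to_dict(orient="list"),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, sort_keys=True))
    cfg = study.config.to_dict()
    cfg["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]
    (out / "config.json").write_text(json.dumps(cfg, sort_keys=True, indent=1))
    return out


def read_study(study_dir) -> Study:
    """Load a study directory written by :func:`write_study`."""
    d = Path(study_dir)
    cfg = json.loads((d / "config.json").read_text())
    cfg.pop("config_hash", None)
    snr = cfg.pop("snr_map")
    config = SimConfig(**cfg)
    config.snr_map = {tuple(k.split("|")): float(v) for k, v in snr.items()}
    records = pd.read_csv(d / "trials.csv")
    sidecar = json.loads((d / "arrays.json").read_text())
    envelopes, eeg = {}, {}
    for name, meta in sidecar["arrays"].items():
        key = tuple(meta["key"])
        env = np.fromfile(d / "epochs" / f"{name}.env.bin", dtype="<f8")
        envelopes[key] = env.reshape(meta["env_shape"])
        dat = np.fromfile(d / "epochs" / f"{name}.eeg.bin", dtype="<f8")
        eeg[key] = dat.reshape(meta["eeg_shape"])
    gt = json.loads((d / "ground_truth.json").read_text())
    truth = GroundTruth(
        kernels=np.asarray(gt["kernels"]),
        true_familiarity_label={int(k): v for k, v in gt["true_familiarity_label"].items()},
        true_mw_group={int(k): v for k, v in gt["true_mw_group"].items()},
        subject_effect={int(k): v for k, v in gt["subject_effect"].items()},
        stimulus_effect={int(k): v for k, v in gt["stimulus_effect"].items()},
        per_trial_snr=pd.DataFrame(gt["per_trial_snr"]),
    )
    return Study(config=config, records=records, envelopes=envelopes, eeg=eeg, ground_truth=truth)


def decode_study(study: Study, run: RunConfig):
    """Nested-LOO decode every subject; returns (records, recons, originals).

    ``records`` is the trial table with ``accuracy`` and
    ``lambda_selected`` filled per epoch; ``recons`` / ``originals`` map
    subject -> ordered lists of traces for the null-distribution stage.
    """
    lw = decoder.lag_grid(run.t_min, run.t_max, study.config.fs)
    records = study.records.copy()
    records["accuracy"] = np.nan
    records["lambda_selected"] = np.nan
    recons, originals = {}, {}
    for subj in sorted(records["subject_id"].unique()):
        pairs, idx = study.epoch_pairs(subj)
        results = decoder.nested_loo_decode(pairs, lw, run.lambda_grid)
        records.loc[idx, "accuracy"] = [r.accuracy for r in results]
        records.loc[idx, "lambda_selected"] = [r.lambda_selected for r in results]
        recons[subj] = [r.reconstruction for r in results]
        originals[subj] = [np.asarray(getattr(e, "samples", e), dtype=float) for _, e in pairs]
        lams = pd.Series([r.lambda_selected for r in results])
        log.info(
            "decoded subject %s: %d epochs, mean r=%.4f, lambda mode=%g",
            subj,
            len(results),
            records.loc[idx, "accuracy"].mean(),
            lams.mode().iloc[0],
        )
    return records, recons, originals


def run_pipeline(run: RunConfig, out_dir) -> dict:
    """Simulate (or load), decode, code, and analyse one study.

    Writes ``results.csv``, the elimination table, best-model and
    null-comparison reports, follow-up fits, the Familiarity x
    MindWandering cell means, a frozen config and ``summary.json``.
    Deterministic under a fixed config (the run seed feeds both the
    generator and the permutation null).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = run.digest()

    sim_cfg = dataclasses.replace(run.sim, seed=run.seed)
    log.info("simulating study (%d subjects, hash %s)", sim_cfg.n_subjects, tag)
    study = simulate_study(sim_cfg)

    records, recons, originals = decode_study(study, run)
    coded = indicators.code_indicators(records)
    coded.to_csv(out / "results.csv", index=False)

    nulls = stats.null_distribution(
        recons, originals, n_permutations=run.n_permutations, seed=run.seed + 1
    )
    comparison = stats.compare_to_null(
        nulls["observed_mean_r"].to_numpy(), nulls["null_mean_r"].to_numpy()
    )

    full_spec = stats.full_factorial_spec()
    reduced_spec, elimination = stats.stepwise_backward(
        full_spec, coded, alpha_random=run.alpha_random, alpha_fixed=run.alpha_fixed
    )
    elimination.to_csv(out / "elimination.csv", index=False)
    best = stats.fit_lmm(reduced_spec, coded, reml=True)
    follow = stats.follow_up_by_level(coded)
    agreement = indicators.familiarity_agreement(
        coded, study.ground_truth.true_familiarity_label
    )
    stats.cell_means(coded).to_csv(out / "cell_means.csv", index=False)

    def fit_report(fit: stats.LMMFit) -> dict:
        return {
            "formula": fit.spec.formula(),
            "coefficients": json.loads(fit.coef.reset_index().to_json(orient="records")),
            "std_coefficients": json.loads(fit.std_coef.reset_index().to_json(orient="records")),
            "random_variances": fit.random_variances,
            "sigma2": fit.sigma2,
            "r2_marginal": fit.r2_marginal,
            "r2_conditional": fit.r2_conditional,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "n": fit.n,
        }

    summary = {
        "config_hash": tag,
        "seed": run.seed,
        "config": run.to_dict(),
        "n_subjects": int(coded["subject_id"].nunique()),
        "n_epochs_total": int(len(coded)),
        "epochs_per_subject": int(len(coded) / coded["subject_id"].nunique()),
        "mean_accuracy": float(coded["accuracy"].mean()),
        "sd_accuracy": float(coded["accuracy"].std(ddof=1)),
        "null_comparison": dataclasses.asdict(comparison),
        "reduced_model": reduced_spec.formula(),
        "best_model": fit_report(best),
        "follow_up": {level: fit_report(fit) for level, fit in follow.items()},
        "familiarity_agreement": agreement,
    }
    (out / "best_model.json").write_text(json.dumps(fit_report(best), sort_keys=True, indent=1))
    (out / "null_comparison.json").write_text(
        json.dumps(dataclasses.asdict(comparison), sort_keys=True, indent=1)
    )
    (out / "config.frozen.json").write_text(
        json.dumps({**run.to_dict(), "config_hash": tag}, sort_keys=True, indent=1)
    )
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    log.info("pipeline done: mean r=%.4f, reduced model %s", summary["mean_accuracy"], summary["reduced_model"])
    return summary


def make_fixtures(seed: int = 0) -> Study:
    """A seconds-scale miniature study for tests: 3 subjects, 2 stimuli,
    2 presentations of 30 s trials (4 epochs per subject), 4 channels."""
    cfg = SimConfig(
        n_subjects=3,
        n_stimuli=2,
        n_presentations=2,
        trial_duration=30.0,
        epoch_duration=30.0,
        n_channels=4,
        fs=64.0,
        seed=seed,
    )
    return simulate_study(cfg)
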