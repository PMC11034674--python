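"""Synthetic behavioural datasets with known ground truth.

No raw behavioural data ships with this package; every analysis is exercised
on synthetic cohorts whose generating process is known exactly, so that
recovery of the generating regime (history-free vs memory-of-errors
learning, correction-function parameters, retention) can be asserted.

Three generators:

* ``gen_median_correction_table`` — a median correction-vs-error-size table
  over the 19-condition error set (0, +/-1.5, 3.5, 10, 18, 30, 45, 60, 75,
  90 degrees), emulating the trial-by-trial dataset the correction function
  is fit to.
* ``gen_experiment`` — full trial tables for the blocked rotation design
  (``albert6``) and the two clamp experiments (``exp1``, ``exp2``), with
  per-participant counterbalanced perturbation direction, lognormal movement
  times, and injected invalid trials to exercise the exclusion filters.
* ``gen_trial_by_trial_dataset`` — zero-mean trial-by-trial tables for the
  triplet analysis.

The planted "reference" correction function (:func:`tsay_like_truth`) is a
synthetic stand-in for a function estimated from published group medians; it
is constructed to have the three properties reported for the real one — a
peak near 7.5 degrees, a monotone-decreasing sensitivity function, and a
near-linear descending limb over 15-45 degrees — and is scaled so that a
gain of k = 4 yields a baseline sensitivity of 0.037 to a 30-degree error.
Every dataset is returned together with a JSON-serializable ground-truth
sidecar sufficient to regenerate it bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .correction_function import (
    CorrectionParams,
    MedianCorrectionTable,
    motor_correction,
)
from .learning_models import ModelParams, run_model
from .simulator import (
    DEFAULT_ERROR_SET,
    make_albert_exp6_schedule,
    make_clamp_schedule,
    make_trial_by_trial_schedule,
)

__all__ = [
    "TSAY_ERROR_SET",
    "TRUTH_SIGMA_V",
    "TRUTH_SIGMA_P",
    "TRUTH_C",
    "tsay_like_truth",
    "GeneratorConfig",
    "gen_median_correction_table",
    "gen_experiment",
    "gen_trial_by_trial_dataset",
    "write_dataset",
]

#: The 19-condition perturbation set of the emulated trial-by-trial study.
TSAY_ERROR_SET = (
    0.0, 1.5, -1.5, 3.5, -3.5, 10.0, -10.0, 18.0, -18.0, 30.0,
    -30.0, 45.0, -45.0, 60.0, -60.0, 75.0, -75.0, 90.0, -90.0,
)

# Shape parameters of the planted correction function (see module docstring).
TRUTH_SIGMA_V = 3.0
TRUTH_SIGMA_P = 22.0
TRUTH_C = 0.0218

#: Baseline sensitivity to a 30-degree error after scaling by k = 4.
_CALIBRATION_B30 = 0.037
_CALIBRATION_K = 4.0
_CALIBRATION_ERROR = 30.0


@lru_cache(maxsize=1)
def tsay_like_truth() -> CorrectionParams:
    """The planted synthetic correction-function ground truth.

    The overall scale kS is derived, not free: it is set so that
    k * M(30)/30 = 0.037 holds exactly for k = 4, making the baseline
    calibration of the simulations reproducible by construction.
    """
    unit = CorrectionParams(TRUTH_SIGMA_V, TRUTH_SIGMA_P, TRUTH_C, 1.0)
    m30_unit = motor_correction(_CALIBRATION_ERROR, unit)
    kS = (_CALIBRATION_B30 * _CALIBRATION_ERROR / _CALIBRATION_K) / m30_unit
    return CorrectionParams(TRUTH_SIGMA_V, TRUTH_SIGMA_P, TRUTH_C, kS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the trial-table generators.

    Defaults emulate the study conditions: 40 recruited participants per
    condition, motor noise SD 3 degrees, lognormal movement times with a
    350 ms median, ~3% invalid trials for compliant participants and a small
    fraction of noncompliant participants whose invalid rate puts them below
    the 70%-valid inclusion bar.
    """

    n_per_condition: int = 40
    motor_noise_sd: float = 3.0
    mt_median_ms: float = 350.0
    mt_log_sigma: float = 0.12
    invalid_rate: float = 0.03
    noncompliant_rate: float = 0.04
    noncompliant_invalid_rate: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("invalid_rate", "noncompliant_rate", "noncompliant_invalid_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")


def gen_median_correction_table(
    truth: CorrectionParams | None = None,
    error_set=TSAY_ERROR_SET,
    noise_sd: float = 0.0,
    seed=None,
) -> tuple[MedianCorrectionTable, dict]:
    """Median-correction table: M(e; truth) plus Gaussian noise on each median."""
    if truth is None:
        truth = tsay_like_truth()
    errors = np.asarray(error_set, dtype=float)
    if errors.size == 0:
        raise ValueError("error_set must be non-empty")
    medians = motor_correction(errors, truth)
    if noise_sd > 0:
        medians = medians + np.random.default_rng(seed).normal(0.0, noise_sd, errors.size)
    table = MedianCorrectionTable(errors, np.asarray(medians, dtype=float))
    sidecar = {
        "kind": "median_correction_table",
        "truth": asdict(truth),
        "error_set": list(errors),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return table, sidecar


_SCHEDULE_FACTORIES = {
    "albert6": lambda variance, seed: make_albert_exp6_schedule(variance, seed),
    "exp1": lambda variance, seed: make_clamp_schedule("exp1", variance, seed),
    "exp2": lambda variance, seed: make_clamp_schedule("exp2", variance, seed),
}


def _movement_times(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    return config.mt_median_ms * np.exp(rng.normal(0.0, config.mt_log_sigma, n))


def _inject_invalid(
    rng: np.random.Generator, mt: np.ndarray, angles: np.ndarray, rate: float
) -> None:
    """Corrupt a random subset of trials in place so they fail the filters."""
    bad = rng.random(len(mt)) < rate
    for i in np.flatnonzero(bad):
        if rng.random() < 0.5:
            mt[i] = rng.uniform(520.0, 900.0)
        else:
            angles[i] = rng.choice([-1.0, 1.0]) * rng.uniform(70.5, 120.0)


def gen_experiment(
    design: str,
    engine_params: ModelParams,
    config: GeneratorConfig = GeneratorConfig(),
    correction: CorrectionParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full synthetic trial table for a blocked design, both variance conditions.

    Per participant: a perturbation direction (counterbalanced CW/CCW), a
    freshly drawn schedule, a latent learning trace from the requested
    engine, movement times, and injected invalid trials.  Hand angles are
    written in the lab frame (adaptation appears opposite the perturbation
    direction); the perturbation column carries the signed perturbation.
    """
    if design not in _SCHEDULE_FACTORIES:
        raise ValueError(f"design must be one of {sorted(_SCHEDULE_FACTORIES)}, got {design!r}")
    if correction is None and engine_params.engine in ("nlmc", "hybrid"):
        correction = tsay_like_truth()
    engine_params = engine_params.replace(motor_noise_sd=config.motor_noise_sd)

    root = np.random.SeedSequence(config.seed)
    rows = []
    participants_meta = []
    for c_idx, condition in enumerate(("zero", "high")):
        for p_idx in range(config.n_per_condition):
            pid = f"{design}_{condition}_{p_idx:03d}"
            child = np.random.SeedSequence(config.seed, spawn_key=(c_idx, p_idx))
            sched_ss, noise_ss, nuisance_ss = child.spawn(3)
            nuisance = np.random.default_rng(nuisance_ss)
            sign = 1.0 if p_idx % 2 == 0 else -1.0
            noncompliant = bool(nuisance.random() < config.noncompliant_rate)
            inv_rate = config.noncompliant_invalid_rate if noncompliant else config.invalid_rate

            schedule = _SCHEDULE_FACTORIES[design](
                condition, int(sched_ss.generate_state(1)[0] % (2**31))
            )
            trace = run_model(schedule, engine_params, correction, seed=noise_ss)
            angles = -sign * trace.y
            mt = _movement_times(nuisance, len(schedule), config)
            _inject_invalid(nuisance, mt, angles, inv_rate)

            for t_idx, trial in enumerate(schedule.trials):
                rows.append(
                    {
                        "participant": pid,
                        "trial": t_idx + 1,
                        "phase": trial.phase,
                        "target_deg": trial.target,
                        "perturbation_deg": sign * trial.perturbation,
                        "hand_angle_deg": angles[t_idx],
                        "mt_ms": mt[t_idx],
                        "condition": condition,
                    }
                )
            participants_meta.append(
                {
                    "participant": pid,
                    "condition": condition,
                    "sign": sign,
                    "noncompliant": noncompliant,
                }
            )
    df = pd.DataFrame(rows)
    sidecar = {
        "kind": "experiment",
        "design": design,
        "engine_params": asdict(engine_params),
        "correction": asdict(correction) if correction is not None else None,
        "config": asdict(config),
        "participants": participants_meta,
    }
    return df, sidecar


def gen_trial_by_trial_dataset(
    engine_params: ModelParams,
    correction: CorrectionParams | None = None,
    error_set=DEFAULT_ERROR_SET,
    n_participants: int = 100,
    cycles: int = 40,
    seed: int = 0,
    motor_noise_sd: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Zero-mean trial-by-trial dataset for the error-history analysis.

    Errors are delivered as non-contingent (clamped) feedback in permuted
    cycles of the error set; hand angles are written directly in the
    adaptation frame (the schedule has no net direction to counterbalance).
    """
    errors = np.asarray(error_set, dtype=float)
    if abs(errors.mean()) > 1e-9:
        raise ValueError("trial-by-trial error set must have zero mean")
    if correction is None and engine_params.engine in ("nlmc", "hybrid"):
        correction = tsay_like_truth()
    engine_params = engine_params.replace(motor_noise_sd=motor_noise_sd)

    rows = []
    for p_idx in range(n_participants):
        child = np.random.SeedSequence(seed, spawn_key=(p_idx,))
        sched_ss, noise_ss, nuisance_ss = child.spawn(3)
        nuisance = np.random.default_rng(nuisance_ss)
        pid = f"tbt_{p_idx:03d}"
        schedule = make_trial_by_trial_schedule(
            error_set, cycles, int(sched_ss.generate_state(1)[0] % (2**31))
        )
        trace = run_model(schedule, engine_params, correction, seed=noise_ss)
        mt = _movement_times(nuisance, len(schedule), GeneratorConfig(seed=seed))
        for t_idx, trial in enumerate(schedule.trials):
            rows.append(
                {
                    "participant": pid,
                    "trial": t_idx + 1,
                    "phase": trial.phase,
                    "target_deg": trial.target,
                    "perturbation_deg": trial.perturbation,
                    "hand_angle_deg": trace.y[t_idx],
                    "mt_ms": mt[t_idx],
                }
            )
    df = pd.DataFrame(rows)
    sidecar = {
        "kind": "trial_by_trial",
        "engine_params": asdict(engine_params),
        "correction": asdict(correction) if correction is not None else None,
        "error_set": list(errors),
        "n_participants": n_participants,
        "cycles": cycles,
        "seed": seed,
        "motor_noise_sd": motor_noise_sd,
    }
    return df, sidecar


def write_dataset(df: pd.DataFrame, sidecar: dict, out_dir, name: str) -> tuple[Path, Path]:
    """Write a trial table CSV plus its ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    json_path = out_dir / f"{name}.truth.json"
    df.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)
    return csv_path, json_path
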