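"""Perturbation schedules and cohort-level simulation.

Builds the trial schedules of the three blocked designs studied here — the
visuomotor-rotation design of a classic perturbation-variability experiment
(40 baseline, 240 training, 40 no-feedback trials; rotation fixed at 30
degrees or drawn per trial from Normal(30, 12)) and two error-clamp designs
(40 no-feedback + 40 veridical familiarization trials, then 240 clamp
trials; clamp fixed at 12 vs Normal(12, 12), or fixed at 30 vs
Uniform(15, 45)) — plus zero-mean trial-by-trial schedules built from cycles
in which every member of an error set appears once in random order.

``simulate_cohort`` runs independent simulated participants through a
schedule factory and summarizes cycle-averaged learning curves and the
late-learning asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .correction_function import CorrectionParams
from .learning_models import ModelParams, SimTrace, run_model

__all__ = [
    "TARGETS_DEG",
    "Trial",
    "Schedule",
    "CohortSummary",
    "make_albert_exp6_schedule",
    "make_clamp_schedule",
    "make_trial_by_trial_schedule",
    "simulate_cohort",
    "calibrate_sim_scale",
    "DEFAULT_ERROR_SET",
]

#: The four reach targets, visited once per cycle.
TARGETS_DEG = (45.0, 135.0, -45.0, -135.0)

#: Zero-mean trial-by-trial error set: +/- 4, 8, 16, 32 plus 0 (nine values).
DEFAULT_ERROR_SET = (0.0, 4.0, -4.0, 8.0, -8.0, 16.0, -16.0, 32.0, -32.0)

#: Default late-learning window: final 10 cycles = 40 trials of training.
ASYMPTOTE_CYCLES = 10
CYCLE_LEN = 4


class Trial(NamedTuple):
    phase: str
    design: str  # rotation | clamp | veridical | none
    perturbation: float
    target: float


@dataclass
class Schedule:
    """An ordered list of trials plus design metadata."""

    trials: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials):
            if t.design in ("rotation", "clamp") and (
                not np.isfinite(t.perturbation) or abs(t.perturbation) > 180
            ):
                raise ValueError(f"perturbation out of range at trial {i + 1}: {t.perturbation!r}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def perturbations(self) -> np.ndarray:
        return np.array([t.perturbation for t in self.trials])

    @property
    def phases(self) -> np.ndarray:
        return np.array([t.phase for t in self.trials])

    def phase_mask(self, phase: str) -> np.ndarray:
        return np.array([t.phase == phase for t in self.trials])


def _cycle_targets(n: int) -> np.ndarray:
    reps = int(np.ceil(n / len(TARGETS_DEG)))
    return np.tile(TARGETS_DEG, reps)[:n]


def make_albert_exp6_schedule(variance: str, seed=None) -> Schedule:
    """Blocked visuomotor-rotation design: 40 baseline (veridical feedback),
    240 rotation-training trials, 40 no-feedback trials.

    ``variance='zero'`` fixes the rotation at 30 degrees; ``'high'`` draws it
    per trial from Normal(30, 12) (clipped to +/-180).
    """
    if variance not in ("zero", "high"):
        raise ValueError(f"variance must be 'zero' or 'high', got {variance!r}")
    rng = np.random.default_rng(seed)
    if variance == "zero":
        rotations = np.full(240, 30.0)
    else:
        rotations = np.clip(rng.normal(30.0, 12.0, 240), -180.0, 180.0)
    targets = _cycle_targets(40 + 240 + 40)
    trials = (
        [Trial("baseline", "veridical", 0.0, t) for t in targets[:40]]
        + [Trial("training", "rotation", r, t) for r, t in zip(rotations, targets[40:280])]
        + [Trial("washout", "none", 0.0, t) for t in targets[280:]]
    )
    return Schedule(trials, {"design": "albert6", "variance": variance, "seed": seed})


def make_clamp_schedule(experiment: str, variance: str, seed=None) -> Schedule:
    """Error-clamp design: 40 no-feedback + 40 veridical familiarization
    trials, then 240 clamp-training trials.

    Experiment 1 centers the clamp on 12 degrees (the concave region of the
    correction function): fixed 12 vs per-trial Normal(12, 12).  Experiment 2
    centers it on 30 degrees (the linear descending limb): fixed 30 vs
    Uniform(15, 45).
    """
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"experiment must be 'exp1' or 'exp2', got {experiment!r}")
    if variance not in ("zero", "high"):
        raise ValueError(f"variance must be 'zero' or 'high', got {variance!r}")
    rng = np.random.default_rng(seed)
    if experiment == "exp1":
        clamps = (
            np.full(240, 12.0)
            if variance == "zero"
            else np.clip(rng.normal(12.0, 12.0, 240), -180.0, 180.0)
        )
    else:
        clamps = np.full(240, 30.0) if variance == "zero" else rng.uniform(15.0, 45.0, 240)
    targets = _cycle_targets(40 + 40 + 240)
    trials = (
        [Trial("baseline_nofb", "none", 0.0, t) for t in targets[:40]]
        + [Trial("baseline_veridical", "veridical", 0.0, t) for t in targets[40:80]]
        + [Trial("training", "clamp", c, t) for c, t in zip(clamps, targets[80:])]
    )
    return Schedule(trials, {"design": experiment, "variance": variance, "seed": seed})


def make_trial_by_trial_schedule(
    error_set: Sequence[float] = DEFAULT_ERROR_SET, cycles: int = 10, seed=None
) -> Schedule:
    """Permuted-block schedule: each cycle holds every error once, shuffled.

    The errors are delivered as clamped (non-contingent) feedback, so the
    experienced error is the scheduled value regardless of the state.
    """
    error_set = list(error_set)
    if not error_set:
        raise ValueError("error_set must be non-empty")
    rng = np.random.default_rng(seed)
    values = np.concatenate([rng.permutation(error_set) for _ in range(cycles)])
    targets = _cycle_targets(len(values))
    trials = [Trial("training", "clamp", float(v), t) for v, t in zip(values, targets)]
    return Schedule(trials, {"design": "tbt", "error_set": error_set, "cycles": cycles, "seed": seed})


@dataclass
class CohortSummary:
    """Cycle-averaged cohort learning curve and late-learning asymptote."""

    mean_curve: np.ndarray
    sem_curve: np.ndarray
    asymptote: float
    asymptote_sem: float
    n: int
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "cycle": np.arange(1, len(self.mean_curve) + 1),
                "mean_hand_angle_deg": self.mean_curve,
                "sem_deg": self.sem_curve,
            }
        ).to_csv(path, index=False)


def _per_cycle(values: np.ndarray) -> np.ndarray:
    n_cycles = int(np.ceil(len(values) / CYCLE_LEN))
    padded = np.full(n_cycles * CYCLE_LEN, np.nan)
    padded[: len(values)] = values
    return np.nanmean(padded.reshape(n_cycles, CYCLE_LEN), axis=1)


def simulate_cohort(
    schedule_factory: Callable[[int], Schedule],
    params: ModelParams,
    correction=None,
    n_participants: int = 100,
    seed=None,
    asymptote_cycles: int = ASYMPTOTE_CYCLES,
) -> tuple[CohortSummary, list[SimTrace]]:
    """Run ``n_participants`` independent simulated participants.

    ``schedule_factory`` maps an integer seed to a Schedule, so that
    per-trial perturbation draws are independent across participants.  Each
    participant also gets an independent noise substream.  The asymptote is
    the mean reach angle over the final ``asymptote_cycles`` cycles (default
    10 cycles = 40 trials) of the training phase, averaged across
    participants.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    traces: list[SimTrace] = []
    curves = []
    asymptotes = []
    for child in children:
        sched_seed, noise_seed = child.spawn(2)
        schedule = schedule_factory(sched_seed.generate_state(1)[0] % (2**31))
        trace = run_model(schedule, params, correction, seed=noise_seed)
        traces.append(trace)
        curves.append(_per_cycle(trace.y))
        train = schedule.phase_mask("training")
        y_train = trace.y[train]
        asymptotes.append(np.mean(y_train[-asymptote_cycles * CYCLE_LEN:]))
    curves = np.asarray(curves)
    asymptotes = np.asarray(asymptotes)
    n = n_participants
    summary = CohortSummary(
        mean_curve=curves.mean(axis=0),
        sem_curve=curves.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(curves.shape[1]),
        asymptote=float(asymptotes.mean()),
        asymptote_sem=float(asymptotes.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
        meta={"asymptote_cycles": asymptote_cycles, "seed": seed, "engine": params.engine},
    )
    return summary, traces


def calibrate_sim_scale(
    correction: CorrectionParams, target_sensitivity: float, at_error: float = 30.0
) -> float:
    """Scale k such that k * M(at_error) / at_error equals a target sensitivity.

    Used to put a correction function measured in one paradigm on the
    baseline learning-rate scale of another (e.g. k = 4 makes the sensitivity
    to a 30-degree error equal 0.037).
    """
    if at_error == 0:
        raise ValueError("at_error must be nonzero")
    from .correction_function import motor_correction

    m = motor_correction(at_error, correction)
    if m == 0:
        raise ZeroDivisionError(f"M({at_error}) = 0; cannot calibrate")
    return float(target_sensitivity / (m / at_error))
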