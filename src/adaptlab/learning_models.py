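"""Trial-by-trial state-space learning with interchangeable sensitivity engines.

The motor state x (degrees, compensation-positive) evolves as

    x(n+1) = a * x(n) + b(e, n) * e(n) + eps_x(n)
    y(n)   = x(n) + eps_y(n)

where a is the retention factor, e(n) the experienced error, b the error
sensitivity and eps_x / eps_y planning and motor noise.  Three engines supply b:

* ``nlmc``   — fixed non-linear motor correction: the drive is k * M(e), i.e.
  b(e) = k * M(e) / e at every trial; no history dependence whatsoever.
* ``moe``    — memory of errors: b starts flat at b0 and, per 3-degree error
  bin, grows when consecutive errors share a sign and shrinks when the sign
  flips.
* ``hybrid`` — memory-of-errors updating, but the bins are initialized from
  the non-linear correction function, b(e, 1) = k * M(e) / e.

Error semantics per trial design: rotation trials experience e = r - x (the
error shrinks as learning proceeds); clamp trials experience e equal to the
clamp angle regardless of the state (the defining property of error-clamp
feedback); veridical-feedback trials behave as a rotation of 0; no-feedback
trials apply retention only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import json
import math
from typing import Callable

import numpy as np
import pandas as pd

from .correction_function import (
    CorrectionParams,
    correction_interpolator,
    error_sensitivity,
)

__all__ = [
    "ENGINES",
    "ModelParams",
    "SensitivityState",
    "SimTrace",
    "step_state",
    "sensitivity_lookup",
    "update_sensitivity",
    "run_model",
]

ENGINES = ("nlmc", "moe", "hybrid")

# Trial designs understood by run_model.
_FEEDBACK_DESIGNS = ("rotation", "clamp", "veridical")


@dataclass(frozen=True)
class ModelParams:
    """State-space and sensitivity-engine parameters.

    Defaults are the literature estimates used throughout: retention
    a = 0.945, memory-of-errors rates alpha = 0.9568, beta = 0.0558 with
    baseline sensitivity b0 = 0.037, 3-degree sensitivity bins, motor noise
    SD 3 degrees and no planning noise.
    """

    engine: str = "nlmc"
    a: float = 0.945
    b0: float = 0.037
    alpha: float = 0.9568
    beta: float = 0.0558
    sim_scale: float = 4.0
    bin_width: float = 3.0
    planning_noise_sd: float = 0.0
    motor_noise_sd: float = 3.0
    decay_unvisited: bool = False

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}, got {self.engine!r}")
        if not 0 < self.a <= 1:
            raise ValueError(f"retention a must be in (0, 1], got {self.a!r}")
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha!r}")
        for name in ("b0", "beta", "sim_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width!r}")
        for name in ("planning_noise_sd", "motor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ModelParams":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            data = json.loads(text) if text.lstrip().startswith("{") else json.load(open(text))
        return cls(**data)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class SensitivityState:
    """Per-bin error sensitivities b(e, n).

    Bins partition the error axis into half-open ``bin_width``-wide intervals
    [i*w, (i+1)*w); negative errors fall in the mirrored intervals.  Bins not
    yet stored hold their engine-specific base value.
    """

    bin_width: float = 3.0
    bins: dict = field(default_factory=dict)

    def bin_index(self, e: float) -> int:
        return int(math.floor(e / self.bin_width))

    def bin_center(self, index: int) -> float:
        return (index + 0.5) * self.bin_width

    def copy(self) -> "SensitivityState":
        return SensitivityState(self.bin_width, dict(self.bins))


def _resolve_m(correction) -> Callable:
    """Accept CorrectionParams or a plain callable M(e)."""
    if isinstance(correction, CorrectionParams):
        return correction_interpolator(correction)
    if callable(correction):
        return correction
    raise TypeError(f"correction must be CorrectionParams or callable, got {correction!r}")


def _base_sensitivity(e: float, params: ModelParams, correction, state: SensitivityState) -> float:
    """b(e, 1): b0 for the MoE engine, k*M(center)/center for the hybrid."""
    if params.engine == "moe":
        return params.b0
    center = state.bin_center(state.bin_index(e))
    m = _resolve_m(correction)
    if center == 0:
        if isinstance(correction, CorrectionParams):
            return params.sim_scale * error_sensitivity(0.0, correction)
        return params.sim_scale * (m(0.01) / 0.01 + m(-0.01) / -0.01) / 2.0
    return params.sim_scale * float(m(center)) / center


def step_state(
    x: float, e: float, b: float, a: float, planning_noise: float = 0.0
) -> float:
    """One state-space update: x' = a*x + b*e + eps_x."""
    return a * x + b * e + planning_noise


def sensitivity_lookup(e: float, state: SensitivityState, params: ModelParams, correction) -> float:
    """The sensitivity the engine applies to an error of size ``e`` now.

    The NLMC engine reads k*M(e)/e off the fixed function (its state never
    changes); the MoE and hybrid engines read the current value of the bin
    containing ``e``, falling back to the engine's base value for bins that
    have not been visited.
    """
    if params.engine == "nlmc":
        if e == 0:
            if isinstance(correction, CorrectionParams):
                return params.sim_scale * error_sensitivity(0.0, correction)
            m = _resolve_m(correction)
            return params.sim_scale * (m(0.01) / 0.01 + m(-0.01) / -0.01) / 2.0
        return params.sim_scale * float(_resolve_m(correction)(e)) / e
    idx = state.bin_index(e)
    if idx in state.bins:
        return state.bins[idx]
    return _base_sensitivity(e, params, correction, state)


def update_sensitivity(
    state: SensitivityState,
    e_prev: float,
    e_curr: float,
    params: ModelParams,
    correction=None,
) -> SensitivityState:
    """Apply one memory-of-errors update after observing the pair (e_prev, e_curr).

    The bin containing ``e_prev`` moves toward its base value with retention
    ``alpha`` and gains ``+beta`` when the two errors share a sign,
    ``-beta`` when they differ (``sign(0) = 0``: a zero error neither
    enhances nor attenuates).  The result is clipped at 0 — a negative
    sensitivity would invert corrections.  For the NLMC engine this is a
    no-op.  Returns a new state; the input is not mutated.
    """
    if params.engine == "nlmc":
        return state.copy()
    new = state.copy()
    idx = new.bin_index(e_prev)
    base = _base_sensitivity(e_prev, params, correction, new)
    current = new.bins.get(idx, base)
    sign_term = params.beta * np.sign(e_prev * e_curr)
    new.bins[idx] = max(0.0, base + params.alpha * (current - base) + sign_term)
    if params.decay_unvisited:
        for other in new.bins:
            if other != idx:
                other_base = _base_sensitivity(new.bin_center(other), params, correction, new)
                new.bins[other] = max(
                    0.0, other_base + params.alpha * (new.bins[other] - other_base)
                )
    return new


@dataclass
class SimTrace:
    """Per-trial record of one simulated participant.

    x is the internal state before the trial's update, y = x + motor noise is
    the produced reach angle, e the experienced error (NaN on no-feedback
    trials) and b_used the sensitivity applied.
    """

    x: np.ndarray
    y: np.ndarray
    e: np.ndarray
    b_used: np.ndarray
    schedule: object = None

    def __len__(self) -> int:
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(1, len(self.x) + 1),
                "e_deg": self.e,
                "x_deg": self.x,
                "y_deg": self.y,
                "b_used": self.b_used,
            }
        )
        if self.schedule is not None:
            df.insert(1, "phase", [t.phase for t in self.schedule.trials])
            df.insert(2, "perturbation_deg", [t.perturbation for t in self.schedule.trials])
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_model(
    schedule,
    params: ModelParams,
    correction=None,
    seed=None,
    x0: float = 0.0,
) -> SimTrace:
    """Simulate one participant through a schedule.

    ``schedule`` is anything with a ``trials`` sequence of records carrying
    ``design`` (rotation | clamp | veridical | none) and ``perturbation``
    (degrees).  ``correction`` (CorrectionParams or callable M(e)) is required
    for the nlmc and hybrid engines.  Sensitivity updates for the
    history-dependent engines use consecutive feedback trials only; a
    no-feedback trial breaks the chain.
    """
    if params.engine in ("nlmc", "hybrid") and correction is None:
        raise ValueError(f"the {params.engine} engine requires a correction function")
    rng = np.random.default_rng(seed)
    trials = schedule.trials
    n = len(trials)
    x_arr = np.empty(n)
    y_arr = np.empty(n)
    e_arr = np.full(n, np.nan)
    b_arr = np.full(n, np.nan)

    m_func = _resolve_m(correction) if correction is not None else None
    state = SensitivityState(params.bin_width)
    x = float(x0)
    prev_e = None

    for i, trial in enumerate(trials):
        design = trial.design
        x_arr[i] = x
        eps_y = rng.normal(0.0, params.motor_noise_sd) if params.motor_noise_sd else 0.0
        y_arr[i] = x + eps_y
        eps_x = rng.normal(0.0, params.planning_noise_sd) if params.planning_noise_sd else 0.0

        if design == "none":
            x = params.a * x + eps_x
            prev_e = None
        elif design in _FEEDBACK_DESIGNS:
            if design == "clamp":
                e = float(trial.perturbation)
            elif design == "rotation":
                e = float(trial.perturbation) - x
            else:  # veridical: rotation of 0
                e = -x
            e_arr[i] = e
            if params.engine != "nlmc" and prev_e is not None:
                state = update_sensitivity(state, prev_e, e, params, correction)
            if params.engine == "nlmc":
                b = sensitivity_lookup(e, state, params, correction)
                drive = params.sim_scale * float(m_func(e))
            else:
                b = sensitivity_lookup(e, state, params, correction)
                drive = b * e
            b_arr[i] = b
            x = params.a * x + drive + eps_x
            prev_e = e
        else:
            raise ValueError(f"unknown trial design {design!r} at trial {i + 1}")

        if not np.isfinite(x):
            raise RuntimeError(f"state diverged (non-finite) at trial {i + 1}")

    return SimTrace(x_arr, y_arr, e_arr, b_arr, schedule)
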