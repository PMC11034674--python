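"""Raw trial tables -> analysis-ready hand-angle series.

A trial table holds one row per reach:
``participant, trial, phase, target_deg, perturbation_deg, hand_angle_deg, mt_ms``.
Hand angle is the angular difference between target and hand at the target
radius, in the lab frame (the perturbation column carries the participant's
perturbation direction).  Processing steps:

1. ``flag_valid`` — a trial is valid iff movement time <= 500 ms and
   |hand angle| <= 70 degrees (trials beyond either bound are excluded).
2. ``exclude_participants`` — drop participants with under 70% valid trials.
3. ``to_cycles`` — flip signs so adaptation is positive (opposite the
   perturbation direction) and average over cycles of four consecutive
   trials (one reach per target), using valid trials only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MT_LIMIT_MS",
    "ANGLE_LIMIT_DEG",
    "VALID_FRACTION_THRESHOLD",
    "ExclusionReport",
    "flag_valid",
    "exclude_participants",
    "to_cycles",
]

REQUIRED_COLUMNS = (
    "participant",
    "trial",
    "phase",
    "target_deg",
    "perturbation_deg",
    "hand_angle_deg",
    "mt_ms",
)

MT_LIMIT_MS = 500.0
ANGLE_LIMIT_DEG = 70.0
VALID_FRACTION_THRESHOLD = 0.70


def _check_schema(trials: pd.DataFrame, columns=REQUIRED_COLUMNS) -> None:
    missing = [c for c in columns if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table is missing required columns: {missing}")


def flag_valid(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a boolean ``valid`` column; rows are retained, only flagged.

    The bounds are strict: movement time *longer than* 500 ms or |hand angle|
    *larger than* 70 degrees invalidates a trial, so a trial exactly at
    either limit is valid.
    """
    _check_schema(trials, ("hand_angle_deg", "mt_ms"))
    out = trials.copy()
    out["valid"] = (out["mt_ms"] <= MT_LIMIT_MS) & (out["hand_angle_deg"].abs() <= ANGLE_LIMIT_DEG)
    return out


@dataclass
class ExclusionReport:
    threshold: float
    entries: list = field(default_factory=list)  # dicts: participant, valid_fraction, excluded
    warning: str | None = None

    @property
    def excluded_ids(self) -> list:
        return [e["participant"] for e in self.entries if e["excluded"]]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"threshold": self.threshold, "entries": self.entries, "warning": self.warning},
            indent=2,
            default=str,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def exclude_participants(
    trials: pd.DataFrame, threshold: float = VALID_FRACTION_THRESHOLD
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop participants whose valid-trial fraction is strictly below ``threshold``."""
    if "valid" not in trials.columns:
        raise KeyError("run flag_valid first: 'valid' column missing")
    report = ExclusionReport(threshold=threshold)
    fractions = trials.groupby("participant")["valid"].mean()
    for pid, frac in fractions.items():
        report.entries.append(
            {"participant": pid, "valid_fraction": float(frac), "excluded": bool(frac < threshold)}
        )
    keep = fractions[fractions >= threshold].index
    retained = trials[trials["participant"].isin(keep)].copy()
    if retained.empty:
        report.warning = "no participants retained after exclusion"
    return retained, report


def _participant_sign(group: pd.DataFrame) -> float:
    """Perturbation direction of one participant's condition (0 if unsigned).

    Uses the mean perturbation over training-phase trials, so designs with a
    zero-mean trial-by-trial perturbation come out unsigned and are left
    unflipped.
    """
    training = group[group["phase"] == "training"]
    pert = training["perturbation_deg"] if not training.empty else group["perturbation_deg"]
    mean = pert.mean()
    if not np.isfinite(mean) or abs(mean) < 1e-9:
        return 0.0
    return float(np.sign(mean))


def to_cycles(
    trials: pd.DataFrame,
    sign_convention: str = "adaptation_positive",
    baseline_subtract: bool = False,
    cycle_len: int = 4,
) -> pd.DataFrame:
    """Cycle-averaged, adaptation-positive hand-angle series.

    Returns one row per (participant, cycle) with the mean hand angle over
    the cycle's valid trials (NaN when no trial in the cycle is valid),
    ``n_valid`` and a ``partial`` flag for a trailing incomplete cycle.
    Signs are flipped per participant so that compensation opposite the
    perturbation is positive.  ``baseline_subtract`` optionally removes each
    participant's per-target mean hand angle of the no-feedback baseline
    phase before averaging (off by default).
    """
    if sign_convention != "adaptation_positive":
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    _check_schema(trials)
    if "valid" not in trials.columns:
        raise KeyError("run flag_valid first: 'valid' column missing")

    rows = []
    for pid, group in trials.groupby("participant", sort=False):
        group = group.sort_values("trial")
        sign = _participant_sign(group)
        flip = -sign if sign != 0 else 1.0
        angles = group["hand_angle_deg"].to_numpy() * flip
        if baseline_subtract:
            base_mask = group["phase"].str.contains("nofb") | (group["phase"] == "baseline")
            base = group[base_mask]
            if not base.empty:
                per_target = (base["hand_angle_deg"] * flip).groupby(base["target_deg"]).mean()
                offsets = group["target_deg"].map(per_target).fillna(0.0).to_numpy()
                angles = angles - offsets
        valid = group["valid"].to_numpy()
        phases = group["phase"].to_numpy()
        # cycles are counted within each contiguous phase run, with a global
        # running cycle index; a phase length not divisible by cycle_len
        # leaves a trailing partial cycle, kept and flagged
        cycle = 0
        boundaries = np.flatnonzero(np.r_[True, phases[1:] != phases[:-1], True])
        for start, stop in zip(boundaries[:-1], boundaries[1:]):
            for c_start in range(start, stop, cycle_len):
                sl = slice(c_start, min(c_start + cycle_len, stop))
                a, v = angles[sl], valid[sl]
                cycle += 1
                rows.append(
                    {
                        "participant": pid,
                        "cycle": cycle,
                        "phase": phases[c_start],
                        "hand_angle_deg": float(np.mean(a[v])) if v.any() else np.nan,
                        "n_valid": int(v.sum()),
                        "partial": len(a) < cycle_len,
                    }
                )
    return pd.DataFrame(rows)
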