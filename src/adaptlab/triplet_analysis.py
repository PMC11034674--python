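"""Trial-triplet test of error-history effects on single-trial learning.

If error sensitivity is modulated by recent errors (memory-of-errors), the
correction made to an error of a given size should be larger when the
immediately preceding error had the same sign and smaller after a sign flip.
The test compares, within triplets of trials (n-1, n, n+1) where the errors
on n-1 and n+1 share a sign and differ by less than a small window (2
degrees by default), the forgetting-corrected change in hand angle driven by
trial n-1 against the one driven by trial n+1:

    delta_pre  = y(n)   - a * y(n-1)
    delta_post = y(n+2) - a * y(n+1)

each aligned by the sign of its driving error so that a correction opposing
the error is positive.  ``contrast = delta_post - delta_pre`` is averaged
within participant for sign-consistent and sign-inconsistent triplets
separately, then across the cohort.  A history-free learner predicts zero
contrast in both classes; memory-of-errors predicts positive consistent and
negative inconsistent contrasts.

The retention factor ``a`` used for the forgetting correction is estimated
per participant from the same series by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Triplet",
    "TripletSummary",
    "estimate_retention",
    "select_triplets",
    "triplet_contrast",
    "analyze_trials",
]

DEFAULT_WINDOW_DEG = 2.0
RETENTION_BOUNDS = (0.0, 1.05)


@dataclass(frozen=True)
class Triplet:
    """One selected triplet, centered on trial index n (0-based)."""

    n: int
    e_pre: float
    e_mid: float
    e_post: float
    consistent: bool


@dataclass
class TripletSummary:
    """Cohort-level triplet contrasts per consistency class."""

    per_participant: pd.DataFrame  # participant, class, mean_contrast, n_triplets
    cohort: dict = field(default_factory=dict)  # class -> {mean, se, n}
    missing_classes: list = field(default_factory=list)


def _profile_sse(a: float, y: np.ndarray, e: np.ndarray, bin_width: float) -> float:
    """Output-error SSE at retention ``a``, profiled over the linear parameters.

    With measurement noise on y only, the latent state implied by
    x(t+1) = a*x(t) + sum_bins b_bin*e(t)*1[e(t) in bin] is, for fixed a, a
    *linear* function of (x0, b_bins): each is a filtered regressor channel.
    The inner linear least squares therefore concentrates them out exactly.
    """
    T = len(y)
    feedback = np.isfinite(e)
    bins = sorted({int(math.floor(v / bin_width)) for v in e[feedback] if v != 0})
    col_of = {b: j + 1 for j, b in enumerate(bins)}
    G = np.zeros((T, 1 + len(bins)))
    g = np.zeros(1 + len(bins))
    g[0] = 1.0  # initial-state channel
    for t in range(T):
        G[t] = g
        g = a * g
        if feedback[t] and e[t] != 0:
            g[col_of[int(math.floor(e[t] / bin_width))]] += e[t]
    ok = np.isfinite(y)
    coef, *_ = np.linalg.lstsq(G[ok], y[ok], rcond=None)
    resid = y[ok] - G[ok] @ coef
    return float(resid @ resid)


def estimate_retention(
    y: np.ndarray,
    e: np.ndarray,
    bin_width: float = 3.0,
    fallback_a: float = 0.945,
    min_trials: int = 50,
) -> float:
    """State-space retention estimate from a reach series.

    Fits the output-error model y(t) = x(t) + noise,
    x(t+1) = a*x(t) + sum_bins b_bin*e(t)*1[e(t) in bin], by least squares on
    the predicted state (same bin partition as the sensitivity engines).
    Because the noise sits on the output only, regressing y(t+1) on the noisy
    y(t) directly would attenuate a severely; profiling the linear parameters
    at each candidate ``a`` and searching a in [0, 1.05] is consistent and
    exact for noise-free data.  A pure-decay (no-feedback) segment reduces to
    the one-parameter decay fit.  Falls back to ``fallback_a`` when the
    series carries no usable signal.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    if len(y) != len(e):
        raise ValueError("y and e must have equal length")
    if len(y) < min_trials:
        raise ValueError(f"need >= {min_trials} trials to estimate retention, got {len(y)}")
    if np.isfinite(y).sum() < 3 or not np.any(y[np.isfinite(y)] != 0):
        return float(fallback_a)
    lo, hi = RETENTION_BOUNDS
    grid = np.arange(lo, hi + 1e-12, 0.005)
    sses = [_profile_sse(a, y, e, bin_width) for a in grid]
    a0 = grid[int(np.argmin(sses))]
    res = optimize.minimize_scalar(
        lambda a: _profile_sse(a, y, e, bin_width),
        bounds=(max(lo, a0 - 0.005), min(hi, a0 + 0.005)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(np.clip(res.x, lo, hi))


def select_triplets(e: np.ndarray, window: float = DEFAULT_WINDOW_DEG) -> list[Triplet]:
    """All triplets (n-1, n, n+1) with same-signed, closely matched flanking errors.

    Requires sign(e[n-1]) == sign(e[n+1]) != 0, |e[n+1] - e[n-1]| < window,
    sign(e[n]) != 0 and an existing trial n+2 (needed for delta_post).
    Overlapping triplets are all kept.  Classified consistent when e[n]
    shares the flanking sign.
    """
    e = np.asarray(e, dtype=float)
    out: list[Triplet] = []
    for n in range(1, len(e) - 2):
        pre, mid, post = e[n - 1], e[n], e[n + 1]
        if not (np.isfinite(pre) and np.isfinite(mid) and np.isfinite(post)):
            continue
        s_pre, s_mid, s_post = np.sign(pre), np.sign(mid), np.sign(post)
        if s_pre == 0 or s_post == 0 or s_mid == 0:
            continue
        if s_pre != s_post or abs(post - pre) >= window:
            continue
        out.append(Triplet(n, pre, mid, post, consistent=bool(s_mid == s_pre)))
    return out


def triplet_contrast(
    y: np.ndarray, triplets: list[Triplet], a_hat: float
) -> pd.DataFrame:
    """Per-triplet forgetting-corrected contrasts.

    Returns a DataFrame with one row per triplet: the sign-aligned deltas and
    their difference (``contrast``), plus the consistency class.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for t in triplets:
        n = t.n
        delta_pre = (y[n] - a_hat * y[n - 1]) * np.sign(t.e_pre)
        delta_post = (y[n + 2] - a_hat * y[n + 1]) * np.sign(t.e_post)
        rows.append(
            {
                "n": n,
                "consistent": t.consistent,
                "delta_pre": delta_pre,
                "delta_post": delta_post,
                "contrast": delta_post - delta_pre,
            }
        )
    return pd.DataFrame(rows, columns=["n", "consistent", "delta_pre", "delta_post", "contrast"])


def analyze_trials(
    trials: pd.DataFrame,
    window: float = DEFAULT_WINDOW_DEG,
    a_source: str | float = "per_participant",
    bin_width: float = 3.0,
    fallback_a: float = 0.945,
) -> TripletSummary:
    """Run the full triplet analysis on a trial table.

    ``trials`` needs columns participant, trial, hand_angle_deg (adaptation
    frame) and perturbation_deg (the experienced error; valid for clamp and
    trial-by-trial designs where the error is independent of the hand).
    ``a_source`` is 'per_participant' (default) or a fixed retention value.
    """
    per_rows = []
    for pid, group in trials.groupby("participant", sort=False):
        group = group.sort_values("trial")
        y = group["hand_angle_deg"].to_numpy(dtype=float)
        e = group["perturbation_deg"].to_numpy(dtype=float)
        if isinstance(a_source, (int, float)):
            a_hat = float(a_source)
        else:
            a_hat = estimate_retention(y, e, bin_width=bin_width, fallback_a=fallback_a)
        contrasts = triplet_contrast(y, select_triplets(e, window), a_hat)
        for cls, flag in (("consistent", True), ("inconsistent", False)):
            sub = contrasts[contrasts["consistent"] == flag] if len(contrasts) else contrasts
            if len(sub):
                per_rows.append(
                    {
                        "participant": pid,
                        "class": cls,
                        "mean_contrast": float(sub["contrast"].mean()),
                        "n_triplets": int(len(sub)),
                        "a_hat": a_hat,
                    }
                )
    per = pd.DataFrame(
        per_rows, columns=["participant", "class", "mean_contrast", "n_triplets", "a_hat"]
    )
    summary = TripletSummary(per_participant=per)
    for cls in ("consistent", "inconsistent"):
        vals = per.loc[per["class"] == cls, "mean_contrast"].to_numpy()
        if len(vals):
            summary.cohort[cls] = {
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
        else:
            summary.missing_classes.append(cls)
    return summary
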