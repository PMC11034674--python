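"""Grid-search fitting of the hybrid learning model and related estimators.

The hybrid model (memory-of-errors updating on top of bins initialized from
the non-linear correction function) is fit to per-participant reach series
by exhaustive grid search over (alpha, beta, k) — by default alpha and beta
from 0 to 1 in steps of 0.01 and k from 0 to 5 in steps of 0.1 — minimizing
the summed squared residual between the model's state prediction and the
observed reach angles.  The actually experienced errors drive the model and
motor noise is set to 0 during fitting, so the objective is deterministic.

Also here:

* a participant-level bootstrap of (alpha, beta) with the remaining
  parameters frozen, used to ask whether any sensitivity modulation
  (beta > 0) is needed by the data;
* a nested joint fit of the four correction-function parameters together
  with the (alpha, beta, k) grid;
* the naive blocked-design error-sensitivity estimator
  b_hat(e) = mean[(y(n+1) - a*y(n)) / e_obs(n)] per error bin, which is
  biased by motor noise — selectively inflating the zero-variance
  condition — because the observed error e_obs = r - y shares noise with
  the numerator.

Internally the grid search simulates every grid point simultaneously
(vectorized across points), which makes even the full ~520k-point grid
tractable; the bootstrap precomputes each participant's SSE surface once
and re-weights it per resample, which is algebraically identical to
refitting because the objective is a sum over participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np
import pandas as pd
from scipy import optimize

from .correction_function import CorrectionParams, motor_correction, FIT_BOUNDS
from .learning_models import _resolve_m
from .preprocess import _participant_sign

__all__ = [
    "ParticipantSeries",
    "GridSpec",
    "FitGrid",
    "FitResult",
    "BootstrapDistribution",
    "JointFitResult",
    "series_from_trials",
    "sse_objective",
    "grid_fit",
    "fit_correction_jointly",
    "bootstrap_alpha_beta",
    "estimate_error_sensitivity_blocked",
]


@dataclass
class ParticipantSeries:
    """One participant's training series in the adaptation-positive frame."""

    participant: object
    errors: np.ndarray
    y: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.errors.shape != self.y.shape:
            raise ValueError("errors and y must have equal length")


def series_from_trials(trials: pd.DataFrame, phase: str = "training") -> list[ParticipantSeries]:
    """Extract per-participant training series from a trial table.

    Flips hand angles and perturbations into the adaptation-positive frame
    using each participant's perturbation direction; the perturbation column
    is taken as the experienced error (valid for clamp designs, where the
    error is independent of the hand).
    """
    out = []
    for pid, group in trials.groupby("participant", sort=False):
        group = group.sort_values("trial")
        sign = _participant_sign(group)
        sub = group[group["phase"] == phase]
        e = sub["perturbation_deg"].to_numpy(dtype=float)
        y = sub["hand_angle_deg"].to_numpy(dtype=float)
        if sign != 0:
            e = e * sign
            y = y * -sign
        condition = None
        if "condition" in sub.columns and len(sub):
            condition = sub["condition"].iloc[0]
        out.append(ParticipantSeries(pid, e, y, condition))
    return out


def _axis(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step))
    return np.round(np.linspace(start, stop, n + 1), 10)


@dataclass(frozen=True)
class GridSpec:
    """Axes of the (alpha, beta, k) search grid, as (start, stop, step)."""

    alpha: tuple = (0.0, 1.0, 0.01)
    beta: tuple = (0.0, 1.0, 0.01)
    k: tuple = (0.0, 5.0, 0.1)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return _axis(*self.alpha), _axis(*self.beta), _axis(*self.k)

    def coarse(self, factor: int = 5) -> "GridSpec":
        return GridSpec(
            (self.alpha[0], self.alpha[1], self.alpha[2] * factor),
            (self.beta[0], self.beta[1], self.beta[2] * factor),
            (self.k[0], self.k[1], self.k[2] * factor),
        )


@dataclass
class FitGrid:
    alpha_axis: np.ndarray
    beta_axis: np.ndarray
    k_axis: np.ndarray
    sse: np.ndarray  # shape (n_alpha, n_beta, n_k)


@dataclass
class FitResult:
    alpha: float
    beta: float
    k: float
    sse: float
    tie_note: str = ""
    grid: FitGrid | None = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "alpha": self.alpha,
                "beta": self.beta,
                "k": self.k,
                "sse": self.sse,
                "tie_note": self.tie_note,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _bin_sensitivities(errors: np.ndarray, correction, bin_width: float):
    """Bin index per trial, plus z(center) for each distinct bin.

    Uses the same tabulated M as the simulation engines so that a fit to
    noiselessly generated data can reach SSE = 0 at the generating point.
    """
    idx = np.floor(errors / bin_width).astype(int)
    distinct = np.unique(idx)
    col_of = {b: j for j, b in enumerate(distinct)}
    cols = np.array([col_of[b] for b in idx])
    m = _resolve_m(correction)
    centers = (distinct + 0.5) * bin_width
    zc = np.asarray(m(centers), dtype=float) / centers
    return cols, zc


def _series_sse_grid(
    series: ParticipantSeries,
    alpha_vec: np.ndarray,
    beta_vec: np.ndarray,
    k_vec: np.ndarray,
    correction,
    a: float,
    bin_width: float,
) -> np.ndarray:
    """SSE of one series at every grid point simultaneously.

    Simulates the hybrid model (noise 0, driven by the actually experienced
    errors) with the state per grid point held in a vector and sensitivity
    bins in a (points x bins) array.  NaN observations are skipped in the
    residual sum (the simulation continues through them).
    """
    e = series.errors
    y = series.y
    keep = np.isfinite(y)
    cols, zc = _bin_sensitivities(e, correction, bin_width)
    base = k_vec[:, None] * zc[None, :]
    b = base.copy()
    x = np.zeros_like(k_vec)
    sse = np.zeros_like(k_vec)
    signs = np.sign(e[:-1] * e[1:]) if len(e) > 1 else np.empty(0)
    for t in range(len(e)):
        if t > 0:
            c = cols[t - 1]
            b[:, c] = np.maximum(
                0.0, base[:, c] + alpha_vec * (b[:, c] - base[:, c]) + beta_vec * signs[t - 1]
            )
        if keep[t]:
            sse += (x - y[t]) ** 2
        x = a * x + b[:, cols[t]] * e[t]
    return sse


def _grid_sse(
    data: list[ParticipantSeries],
    alpha_axis: np.ndarray,
    beta_axis: np.ndarray,
    k_axis: np.ndarray,
    correction,
    a: float,
    bin_width: float,
    per_participant: bool = False,
):
    A, B, K = np.meshgrid(alpha_axis, beta_axis, k_axis, indexing="ij")
    av, bv, kv = A.ravel(), B.ravel(), K.ravel()
    shape = A.shape
    if per_participant:
        mat = np.empty((len(data), av.size))
        for i, s in enumerate(data):
            mat[i] = _series_sse_grid(s, av, bv, kv, correction, a, bin_width)
        return mat, shape
    total = np.zeros(av.size)
    for s in data:
        total += _series_sse_grid(s, av, bv, kv, correction, a, bin_width)
    return total, shape


def _argmin_tiebreak(
    sse_flat: np.ndarray, shape, alpha_axis, beta_axis, k_axis
) -> tuple[int, int, int, str]:
    """Index of the minimum; exact ties broken by smallest beta, alpha, k."""
    best = sse_flat.min()
    ties = np.flatnonzero(sse_flat == best)
    ia, ib, ik = np.unravel_index(ties, shape)
    order = np.lexsort((k_axis[ik], alpha_axis[ia], beta_axis[ib]))
    j = order[0]
    note = "" if len(ties) == 1 else f"{len(ties)} exact ties; smallest (beta, alpha, k) chosen"
    return int(ia[j]), int(ib[j]), int(ik[j]), note


def sse_objective(
    point: tuple[float, float, float],
    data: list[ParticipantSeries],
    correction,
    a: float = 0.945,
    bin_width: float = 3.0,
) -> float:
    """Summed squared residual of the hybrid model at one (alpha, beta, k)."""
    alpha, beta, k = point
    total = 0.0
    for s in data:
        total += float(
            _series_sse_grid(
                s, np.array([alpha]), np.array([beta]), np.array([k]), correction, a, bin_width
            )[0]
        )
    return total


def grid_fit(
    data: list[ParticipantSeries],
    correction,
    grid: GridSpec = GridSpec(),
    a: float = 0.945,
    bin_width: float = 3.0,
    mode: str = "exhaustive",
    keep_grid: bool = False,
) -> FitResult:
    """Exhaustive (or two-stage coarse-to-fine) grid search.

    ``mode='exhaustive'`` evaluates every grid point.  ``mode='coarse_fine'``
    evaluates a 5x-thinned grid first, then the full-resolution grid within
    one coarse step of each of the ``top_n`` best coarse candidates, keeping
    the overall optimum.  The SSE surface is extremely sharp near alpha = 1
    (sensitivity compounds geometrically), so a single coarse optimum can sit
    in the wrong basin; refining several candidate basins recovers the
    exhaustive optimum in practice, and the equivalence is asserted on small
    grids in the tests.
    """
    if not data:
        raise ValueError("no data to fit")
    if mode == "exhaustive":
        aa, ba, ka = grid.axes()
        sse_flat, shape = _grid_sse(data, aa, ba, ka, correction, a, bin_width)
        ia, ib, ik, note = _argmin_tiebreak(sse_flat, shape, aa, ba, ka)
        fg = FitGrid(aa, ba, ka, sse_flat.reshape(shape)) if keep_grid else None
        return FitResult(
            float(aa[ia]),
            float(ba[ib]),
            float(ka[ik]),
            float(sse_flat.reshape(shape)[ia, ib, ik]),
            note,
            fg,
        )
    if mode != "coarse_fine":
        raise ValueError(f"unknown mode {mode!r}")
    factor, top_n = 5, 5
    aa, ba, ka = grid.coarse(factor).axes()
    sse_flat, shape = _grid_sse(data, aa, ba, ka, correction, a, bin_width)
    order = np.argsort(sse_flat)[: min(top_n, sse_flat.size)]

    def _window(axis_spec, center):
        start, stop, step = axis_spec
        lo = max(start, center - factor * step)
        hi = min(stop, center + factor * step)
        return (round(lo, 10), round(hi, 10), step)

    best: FitResult | None = None
    for flat_idx in order:
        ia, ib, ik = np.unravel_index(flat_idx, shape)
        fine = GridSpec(
            _window(grid.alpha, aa[ia]),
            _window(grid.beta, ba[ib]),
            _window(grid.k, ka[ik]),
        )
        candidate = grid_fit(data, correction, fine, a, bin_width, mode="exhaustive")
        if (
            best is None
            or candidate.sse < best.sse
            or (
                candidate.sse == best.sse
                and (candidate.beta, candidate.alpha, candidate.k)
                < (best.beta, best.alpha, best.k)
            )
        ):
            best = candidate
    best.tie_note = (best.tie_note + "; " if best.tie_note else "") + "coarse-to-fine search"
    return best


@dataclass
class BootstrapDistribution:
    """Participant-level bootstrap distribution of (alpha, beta)."""

    alphas: np.ndarray
    betas: np.ndarray
    n_resamples: int
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resample": np.arange(1, self.n_resamples + 1),
                "alpha": self.alphas,
                "beta": self.betas,
            }
        )


def bootstrap_alpha_beta(
    data: list[ParticipantSeries],
    correction,
    k: float,
    a: float = 0.945,
    n_resamples: int = 100,
    seed=None,
    alpha_axis_spec: tuple = (0.0, 1.0, 0.01),
    beta_axis_spec: tuple = (0.0, 1.0, 0.01),
    bin_width: float = 3.0,
    identity: bool = False,
) -> BootstrapDistribution:
    """Bootstrap the (alpha, beta) fit at the participant level.

    Participants are drawn with replacement within strata defined by their
    ``condition`` label (preserving the design balance of each resample) and
    the grid fit is repeated with k and the correction function frozen.
    ``identity=True`` disables resampling (every draw is the original
    cohort), which must reproduce the point fit.
    """
    aa = _axis(*alpha_axis_spec)
    ba = _axis(*beta_axis_spec)
    kv = np.array([k])
    # SSE surface per participant, computed once; a resample's SSE is the
    # count-weighted sum of these, so refitting reduces to re-weighting.
    mat, shape = _grid_sse(data, aa, ba, kv, correction, a, bin_width, per_participant=True)
    strata: dict = {}
    for i, s in enumerate(data):
        strata.setdefault(s.condition, []).append(i)
    rng = np.random.default_rng(seed)
    alphas = np.empty(n_resamples)
    betas = np.empty(n_resamples)
    for r in range(n_resamples):
        if identity:
            weights = np.ones(len(data))
        else:
            weights = np.zeros(len(data))
            for members in strata.values():
                members = np.asarray(members)
                draw = rng.choice(members, size=len(members), replace=True)
                np.add.at(weights, draw, 1.0)
        sse_flat = weights @ mat
        ia, ib, _, _ = _argmin_tiebreak(sse_flat, shape, aa, ba, kv)
        alphas[r], betas[r] = aa[ia], ba[ib]
    return BootstrapDistribution(alphas, betas, n_resamples, seed)


@dataclass
class JointFitResult:
    correction: CorrectionParams
    fit: FitResult
    sse_history: list = field(default_factory=list)  # best-so-far SSE per outer iteration


def fit_correction_jointly(
    data: list[ParticipantSeries],
    grid: GridSpec = GridSpec((0.0, 1.0, 0.05), (0.0, 1.0, 0.05), (0.0, 5.0, 0.25)),
    a: float = 0.945,
    bin_width: float = 3.0,
    seed=0,
    n_restarts: int = 4,
    maxiter: int = 60,
) -> JointFitResult:
    """Nested fit: continuous (sigma_v, sigma_p, C, kS) outside, grid inside.

    The outer search runs over the log of the correction-function parameters
    (bounded differential evolution followed by a Nelder-Mead polish; the
    4-parameter product model has steep ridges that trap purely local
    searches); each evaluation runs the inner (alpha, beta, k) grid search
    and returns its best SSE.  ``n_restarts`` scales the evolution's
    population.  The returned history is the best-so-far SSE sequence,
    non-increasing by construction.

    For speed the inner evaluation computes bin-center sensitivities from the
    quadrature curve directly rather than through the cached interpolant.
    """
    if not data:
        raise ValueError("no data to fit")
    names = ("sigma_v", "sigma_p", "C", "kS")
    lo = np.array([FIT_BOUNDS[n][0] for n in names])
    hi = np.array([FIT_BOUNDS[n][1] for n in names])
    rng = np.random.default_rng(seed)
    history: list[float] = []
    best: tuple[float, np.ndarray] | None = None

    aa, ba, ka = grid.axes()

    # search in log-parameter space: the four parameters live on very
    # different scales (C is a density, kS a gain), and a scale-free simplex
    # is far less prone to collapsing on a ridge
    def objective(log_theta: np.ndarray) -> float:
        nonlocal best
        theta = np.clip(np.exp(log_theta), lo, hi)
        params = CorrectionParams(*theta)

        def m_direct(e):
            return motor_correction(np.asarray(e, dtype=float), params)

        sse_flat, _ = _grid_sse(data, aa, ba, ka, m_direct, a, bin_width)
        value = float(sse_flat.min())
        if best is None or value < best[0]:
            best = (value, theta.copy())
        history.append(best[0])
        return value

    log_bounds = list(zip(np.log(lo), np.log(hi)))
    optimize.differential_evolution(
        objective,
        bounds=log_bounds,
        seed=int(rng.integers(2**31)),
        maxiter=maxiter,
        popsize=max(8, 4 * n_restarts),
        tol=1e-10,
        polish=False,
        init="sobol",
    )
    optimize.minimize(
        objective,
        np.log(best[1]),
        method="Nelder-Mead",
        bounds=log_bounds,
        options={"maxiter": 200, "xatol": 1e-5, "fatol": 1e-10},
    )
    if best is None:
        raise RuntimeError("joint fit failed to evaluate any point")
    params = CorrectionParams(*best[1])

    def m_best(e):
        return motor_correction(np.asarray(e, dtype=float), params)

    fit = grid_fit(data, m_best, grid, a, bin_width)
    return JointFitResult(params, fit, history)


def estimate_error_sensitivity_blocked(
    traces,
    a: float = 0.945,
    bin_width: float = 3.0,
    min_abs_error: float = 1.0,
    phase: str = "training",
) -> pd.DataFrame:
    """Naive per-bin error-sensitivity estimate from noisy rotation traces.

    For each consecutive pair of training trials the single-trial learning
    estimate is (y(n+1) - a*y(n)) / e_obs(n) with e_obs(n) = r(n) - y(n), the
    error an experimenter can actually observe.  Estimates are binned by
    e_obs and averaged.  Because the motor noise in y enters both numerator
    and denominator, this estimator is biased — most strongly where the true
    error is nearly constant, as in a zero-variance blocked design.  Trials
    with |e_obs| below ``min_abs_error`` are dropped (the ratio degenerates).

    Returns a DataFrame with bin_center, b_hat, n per populated bin.
    """
    samples: dict[int, list] = {}
    for trace in traces:
        sched = trace.schedule
        mask = sched.phase_mask(phase)
        idx = np.flatnonzero(mask)
        r = sched.perturbations
        y = trace.y
        for t0, t1 in zip(idx[:-1], idx[1:]):
            if t1 != t0 + 1:
                continue
            e_obs = r[t0] - y[t0]
            if abs(e_obs) < min_abs_error:
                continue
            b_hat = (y[t1] - a * y[t0]) / e_obs
            samples.setdefault(int(math.floor(e_obs / bin_width)), []).append(b_hat)
    rows = [
        {
            "bin": b,
            "bin_center": (b + 0.5) * bin_width,
            "b_hat": float(np.mean(v)),
            "n": len(v),
        }
        for b, v in sorted(samples.items())
    ]
    return pd.DataFrame(rows, columns=["bin", "bin_center", "b_hat", "n"])
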