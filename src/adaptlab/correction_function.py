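"""The non-linear motor correction function M(e) and its error-sensitivity form.

Implicit adaptation corrects a movement error ``e`` (degrees) by an amount
that first grows roughly in proportion to the error and then, for large
errors, declines again.  This module models that profile as the product of
two probabilistic factors:

* ``prob_positive(e, sigma_v)`` — the probability (expressed as a signed
  expectation in [-1, 1]) that a noisy visual system perceives the error in
  the correct direction.  Small errors are frequently mis-perceived in sign,
  which suppresses the net correction near e = 0.
* ``prob_relevant(e, sigma_p, C)`` — a relevance-inference weight: very large
  errors are unlikely to originate from miscalibration of the motor system
  and are therefore discounted.

The full correction is ``M(e) = kS * prob_positive(e) * prob_relevant(e)``
where ``kS`` is a single fitted scale (the product of an overall gain and the
relevance prior's scale; the two are not separately identifiable and are
never estimated individually).  Error sensitivity is ``z(e) = M(e) / e``.

All angles are in degrees; integrals run over the half-circle [-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
import json
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import simpson
from scipy.stats import norm

__all__ = [
    "DOMAIN_DEG",
    "QUAD_STEP_DEG",
    "CorrectionParams",
    "CorrectionCurve",
    "MedianCorrectionTable",
    "CorrectionFit",
    "GaussianPerturbation",
    "UniformPerturbation",
    "prob_positive",
    "prob_relevant",
    "motor_correction",
    "error_sensitivity",
    "correction_interpolator",
    "convolve_with_perturbation",
    "fit_correction",
]

#: Half-width of the angular integration domain (degrees).
DOMAIN_DEG = 180.0
#: Default fixed step of the trapezoid quadrature (degrees).
QUAD_STEP_DEG = 0.1
#: Offset used for the symmetric small-e limit of z(0).
_Z0_EPS = 0.01

# Bounds used by the multi-start fit (sigma_v, sigma_p, C, kS).
FIT_BOUNDS = {
    "sigma_v": (0.5, 30.0),
    "sigma_p": (1.0, 60.0),
    "C": (1e-6, 1.0),
    "kS": (0.1, 100.0),
}


@dataclass(frozen=True)
class CorrectionParams:
    """Parameters of the motor correction function.

    Attributes
    ----------
    sigma_v : float
        Visual noise SD (degrees, > 0).
    sigma_p : float
        Proprioceptive noise SD of the relevance kernel (degrees, > 0).
    C : float
        Relevance prior constant; carries density units (1/degrees) because
        the relevance kernel is a Gaussian pdf evaluated in degrees.
    kS : float
        Overall scale, the product of the gain k and the relevance scale S;
        only this product is identifiable and it is fitted as one quantity.
    """

    sigma_v: float
    sigma_p: float
    C: float
    kS: float

    def __post_init__(self) -> None:
        for name in ("sigma_v", "sigma_p", "C", "kS"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"CorrectionParams.{name} must be finite and > 0, got {value!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CorrectionParams":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            data = json.loads(text) if text.lstrip().startswith("{") else json.load(open(text))
        return cls(**data)


@dataclass(frozen=True)
class CorrectionCurve:
    """A correction function evaluated on an error grid.

    ``correction`` holds M(e) (degrees) and ``sensitivity`` holds
    z(e) = M(e)/e (dimensionless) at each point of ``error_grid``.
    """

    error_grid: np.ndarray
    correction: np.ndarray
    sensitivity: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"e_deg": self.error_grid, "M_deg": self.correction, "z": self.sensitivity}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class MedianCorrectionTable:
    """Group-median trial-to-trial correction per error size.

    The empirical input for fitting: one row per probed perturbation size,
    with the group-median change in hand angle from trial n to n + 1.
    """

    error_size: np.ndarray
    median_correction: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.error_size, dtype=float)
        m = np.asarray(self.median_correction, dtype=float)
        if e.shape != m.shape:
            raise ValueError("error_size and median_correction must have equal length")
        if len(np.unique(e)) != e.size:
            raise ValueError("error sizes must be unique")
        object.__setattr__(self, "error_size", e)
        object.__setattr__(self, "median_correction", m)
        if self.se is not None:
            object.__setattr__(self, "se", np.asarray(self.se, dtype=float))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"error_size_deg": self.error_size, "median_correction_deg": self.median_correction}
        )
        df["se_deg"] = self.se if self.se is not None else np.nan
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MedianCorrectionTable":
        df = pd.read_csv(path)
        se = df["se_deg"].to_numpy() if "se_deg" in df and df["se_deg"].notna().any() else None
        return cls(df["error_size_deg"].to_numpy(), df["median_correction_deg"].to_numpy(), se)


@dataclass(frozen=True)
class GaussianPerturbation:
    """Gaussian perturbation distribution (sd in degrees; sd = 0 degenerate)."""

    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError(f"Gaussian sd must be finite and >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class UniformPerturbation:
    """Uniform perturbation distribution on [lo, hi] degrees (lo == hi degenerate)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)) or self.hi < self.lo:
            raise ValueError(f"Uniform bounds invalid: [{self.lo!r}, {self.hi!r}]")

    @property
    def half_width(self) -> float:
        return 0.5 * (self.hi - self.lo)


def _quad_grid(step: float) -> np.ndarray:
    n = int(round(2 * DOMAIN_DEG / step))
    return np.linspace(-DOMAIN_DEG, DOMAIN_DEG, n + 1)


def prob_positive(e, sigma_v: float, step: float = QUAD_STEP_DEG):
    """Signed probability that the error is perceived in its true direction.

    Computes ``integral over [-180, 180] of sign(e') Norm(e - e'; sigma_v) de'``
    by fixed-step quadrature.  The sign factor is folded analytically into
    the smooth half-domain integrand ``Norm(e - e') - Norm(e + e')`` on
    [0, 180], which composite Simpson then integrates with O(step^4) error;
    the plain signed integrand has a jump at e' = 0 that would cap a
    fixed-step rule at O(step^2).  Antisymmetric and monotone increasing in
    ``e``; equals ``2 * Phi(e / sigma_v) - 1`` up to the (negligible)
    truncation of the Gaussian at +/-180 degrees.
    """
    if not np.isfinite(sigma_v) or sigma_v <= 0:
        raise ValueError(f"sigma_v must be finite and > 0, got {sigma_v!r}")
    e = np.asarray(e, dtype=float)
    n = int(round(DOMAIN_DEG / step))
    if n % 2:  # Simpson needs an even interval count
        n += 1
    ep = np.linspace(0.0, DOMAIN_DEG, n + 1)
    integrand = norm.pdf(e[..., None] - ep, scale=sigma_v) - norm.pdf(
        e[..., None] + ep, scale=sigma_v
    )
    out = simpson(integrand, x=ep, axis=-1)
    return out if np.ndim(out) else float(out)


def prob_relevant(e, sigma_p: float, C: float):
    """Relevance weight of an error: Norm(e; sigma_p) / (Norm(e; sigma_p) + C).

    Even in ``e``, strictly decreasing in |e| and vanishing for very large
    errors.  The relevance scale S is *not* included here; it lives inside
    the fitted product ``kS`` of :class:`CorrectionParams`.
    """
    if not np.isfinite(sigma_p) or sigma_p <= 0:
        raise ValueError(f"sigma_p must be finite and > 0, got {sigma_p!r}")
    if not np.isfinite(C) or C <= 0:
        raise ValueError(f"C must be finite and > 0, got {C!r}")
    e = np.asarray(e, dtype=float)
    dens = norm.pdf(e, scale=sigma_p)
    out = dens / (dens + C)
    return out if out.ndim else float(out)


def motor_correction(e, params: CorrectionParams, step: float = QUAD_STEP_DEG):
    """M(e) = kS * prob_positive(e) * prob_relevant(e), in degrees."""
    out = (
        params.kS
        * np.asarray(prob_positive(e, params.sigma_v, step))
        * np.asarray(prob_relevant(e, params.sigma_p, params.C))
    )
    return out if out.ndim else float(out)


def error_sensitivity(e, params: CorrectionParams, step: float = QUAD_STEP_DEG):
    """z(e) = M(e)/e; at e = 0 the symmetric small-e limit (finite)."""
    e = np.asarray(e, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    out = np.empty_like(e)
    nz = e != 0
    if nz.any():
        out[nz] = motor_correction(e[nz], params, step) / e[nz]
    if (~nz).any():
        z0 = 0.5 * (
            motor_correction(_Z0_EPS, params, step) / _Z0_EPS
            + motor_correction(-_Z0_EPS, params, step) / -_Z0_EPS
        )
        out[~nz] = z0
    return float(out[0]) if scalar else out


@lru_cache(maxsize=16)
def correction_interpolator(
    params: CorrectionParams, grid_step: float = 0.05, quad_step: float = QUAD_STEP_DEG
) -> Callable[[np.ndarray], np.ndarray]:
    """A fast tabulated evaluator of M(e) on [-180, 180].

    Trial-by-trial simulations evaluate M thousands of times; this builds the
    quadrature-based curve once on a fine grid and returns a linear
    interpolant of it.  Cached per parameter set.
    """
    grid = _quad_grid(grid_step)
    values = motor_correction(grid, params, quad_step)
    return lambda e: np.interp(e, grid, values)


def convolve_with_perturbation(
    params: CorrectionParams | Callable,
    dist: GaussianPerturbation | UniformPerturbation,
    e_grid: Sequence[float] | None = None,
    step: float = QUAD_STEP_DEG,
) -> CorrectionCurve:
    """Expected correction as a function of the expected error.

    For a perturbation drawn around its mean ``e`` from ``dist``, the average
    correction is the convolution ``integral M(e') f(e' - e) de'`` over
    [-180, 180].  A degenerate distribution (Gaussian sd = 0, or uniform with
    lo == hi) returns M(e) itself, exactly, on the grid.

    ``params`` may be a :class:`CorrectionParams` or any callable ``M(e)``
    (the pluggable-correction-function interface used to show that the
    variance effect does not hinge on this particular functional form).
    """
    if callable(params) and not isinstance(params, CorrectionParams):
        m_func = params
    else:
        m_func = lambda e: motor_correction(np.asarray(e, float), params, step)

    if e_grid is None:
        e_grid = np.arange(-90.0, 90.0 + 0.5, 0.5)
    e_grid = np.asarray(e_grid, dtype=float)

    if isinstance(dist, GaussianPerturbation):
        degenerate = dist.sd == 0
    elif isinstance(dist, UniformPerturbation):
        degenerate = dist.hi == dist.lo
    else:
        raise TypeError(f"unsupported perturbation distribution spec: {dist!r}")

    if degenerate:
        correction = np.asarray(m_func(e_grid), dtype=float)
    elif isinstance(dist, GaussianPerturbation):
        ep = _quad_grid(step)
        m_vals = np.asarray(m_func(ep), dtype=float)
        weights = norm.pdf(ep - e_grid[:, None], scale=dist.sd)
        correction = np.trapezoid(m_vals * weights, ep, axis=-1)
    else:
        # uniform kernel: average M over [e - h, e + h] on a local subgrid
        # aligned with the support, so the box edges are quadrature nodes
        # (and a linear M integrates exactly)
        half = dist.half_width
        n_local = max(2, int(np.ceil(2 * half / step))) + 1
        offsets = np.linspace(-half, half, n_local)
        m_vals = np.asarray(m_func(e_grid[:, None] + offsets), dtype=float)
        correction = np.trapezoid(m_vals, offsets, axis=-1) / (2.0 * half)

    with np.errstate(divide="ignore", invalid="ignore"):
        sensitivity = np.where(e_grid != 0, correction / np.where(e_grid == 0, 1, e_grid), np.nan)
    return CorrectionCurve(e_grid, correction, sensitivity)


@dataclass(frozen=True)
class CorrectionFit:
    params: CorrectionParams
    sse: float
    n_starts: int


def _fit_residuals(theta: np.ndarray, e: np.ndarray, m_obs: np.ndarray, step: float) -> np.ndarray:
    sv, sp, C, kS = theta
    pred = kS * prob_positive(e, sv, step) * prob_relevant(e, sp, C)
    return pred - m_obs


def fit_correction(
    table: MedianCorrectionTable,
    starts: int = 20,
    seed: int | None = 0,
    step: float = QUAD_STEP_DEG,
) -> CorrectionFit:
    """Bounded nonlinear least squares on (sigma_v, sigma_p, C, kS).

    Runs ``starts`` multi-start optimizations with log-uniform initial points
    inside the bounds and keeps the best.  This 4-parameter product model
    admits local minima, so a single start is not trusted.
    """
    e = table.error_size
    m_obs = table.median_correction
    distinct = np.unique(e)
    if distinct.size < 6:
        raise ValueError(f"need >= 6 distinct error sizes to fit, got {distinct.size}")
    signs = np.sign(distinct[distinct != 0])
    if signs.size and (np.all(signs > 0) or np.all(signs < 0)):
        raise ValueError("error sizes all share one sign; fit is unconstrained")

    lo = np.array([FIT_BOUNDS[k][0] for k in ("sigma_v", "sigma_p", "C", "kS")])
    hi = np.array([FIT_BOUNDS[k][1] for k in ("sigma_v", "sigma_p", "C", "kS")])
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, int(starts))):
        x0 = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        try:
            res = optimize.least_squares(
                _fit_residuals, x0, bounds=(lo, hi), args=(e, m_obs, step), xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise RuntimeError("all fit starts failed")
    sse, x = best
    return CorrectionFit(CorrectionParams(*x), sse, int(starts))
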