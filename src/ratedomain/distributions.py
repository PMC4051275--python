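"""Distribution theory for reaction times and their reciprocals ("rates").

The central objects are the left-truncated Normal on the rate axis (the
promptness model: a Normal rate distribution cut off at the experiment's
time-out bound), the inverse Gaussian (single-boundary first-passage time of
drifting Brownian motion), and the two-boundary drift-diffusion first-passage
densities.  Reciprocal transforms move any of these between the time domain
and the rate domain.

Parameterizations
-----------------
The inverse Gaussian is parameterized by its *mean* ``mu`` (s) and *variance*
``sigma2`` (s²), not the conventional (mean, shape) pair; the shape parameter
is ``lambda = mu**3 / sigma2``.

The truncated Normal is parameterized by the mean ``mu`` and SD ``sigma`` of
the underlying (untruncated) Normal plus the left bound ``a`` (default 1/60
s⁻¹, the rate implied by a 60-s time-out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

__all__ = [
    "TruncNormParams",
    "IGParams",
    "DDMParams",
    "SeriesControl",
    "trunc_normal_density",
    "reciprocal_density",
    "reciprocal_trunc_normal_density",
    "inverse_gaussian_density",
    "reciprocal_inverse_gaussian_density",
    "ddm_first_passage_density",
    "ddm_absorption_probability",
    "sample",
    "ParameterError",
    "ConvergenceError",
]


class ParameterError(ValueError):
    """Invalid distribution parameters."""


class ConvergenceError(RuntimeError):
    """An infinite series failed to converge within its term cap."""


@dataclass(frozen=True)
class TruncNormParams:
    """Left-truncated Normal on the rate axis.

    mu, sigma are the underlying Normal mean/SD (s⁻¹); a is the left
    truncation bound (s⁻¹).  sigma must be positive and the surviving mass
    1 − Φ((a−μ)/σ) must be positive (it always is for finite a).
    """

    mu: float
    sigma: float
    a: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if not np.isfinite(self.a):
            raise ParameterError("truncation bound a must be finite")

    @property
    def alpha(self) -> float:
        """Standardized truncation point (a − μ)/σ."""
        return (self.a - self.mu) / self.sigma

    @property
    def log_survival(self) -> float:
        """log[1 − Φ((a−μ)/σ)], computed stably via the upper tail."""
        return float(log_ndtr(-self.alpha))


@dataclass(frozen=True)
class IGParams:
    """Inverse Gaussian in (mean, variance) form; both in time units."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma2 <= 0:
            raise ParameterError("IG requires mu > 0 and sigma2 > 0")

    @property
    def shape(self) -> float:
        """Conventional IG shape parameter λ = μ³/σ²."""
        return self.mu**3 / self.sigma2


@dataclass(frozen=True)
class DDMParams:
    """Pure drift-diffusion with two absorbing boundaries.

    Drift ``xi``, boundaries ``b_lo < z < a_up`` with start point ``z``,
    diffusion constant ``s`` (infinitesimal SD).  No across-trial parameter
    variability.
    """

    xi: float
    a_up: float
    b_lo: float
    z: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.b_lo < self.z < self.a_up):
            raise ParameterError("require b_lo < z < a_up")
        if self.s <= 0:
            raise ParameterError("diffusion constant s must be positive")


@dataclass(frozen=True)
class SeriesControl:
    """Truncation control for the infinite first-passage sine series."""

    tol: float = 1e-10
    max_terms: int = 10_000

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.max_terms < 10:
            raise ParameterError("max_terms must be at least 10")


def trunc_normal_density(x, p: TruncNormParams):
    """pdf of the left-truncated Normal: φ((x−μ)/σ) / (σ·[1−Φ((a−μ)/σ)]) for
    x ≥ a, zero below the bound.  Vectorized in ``x``."""
    x = np.asarray(x, dtype=float)
    zed = (x - p.mu) / p.sigma
    logpdf = stats.norm.logpdf(zed) - np.log(p.sigma) - p.log_survival
    out = np.where(x >= p.a, np.exp(logpdf), 0.0)
    return out if out.ndim else float(out)


def reciprocal_density(f: Callable[[np.ndarray], np.ndarray], x):
    """Density of 1/T when T has density ``f``: f(1/x)/x².

    The change of variables is an involution, so applying it twice recovers
    the original density.  Only defined for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("reciprocal_density requires x > 0")
    out = np.asarray(f(1.0 / x)) / x**2
    return out if out.ndim else float(out)


def reciprocal_trunc_normal_density(x, p: TruncNormParams):
    """Closed-form pdf of 1/R when rate R is trN(μ, σ, a): the RT model.

    Support is (0, 1/a) for a > 0 (RTs longer than 1/a are censored away),
    (0, ∞) for a ≤ 0 restricted to positive rates.
    """
    return reciprocal_density(lambda t: trunc_normal_density(t, p), x)


def inverse_gaussian_density(chi, p: IGParams):
    """IG pdf in (mean μ, variance σ²) form:
    (μ³/(2πσ²χ³))^{1/2} exp[−μ(χ−μ)²/(2σ²χ)] for χ > 0."""
    chi = np.asarray(chi, dtype=float)
    if np.any(chi <= 0):
        raise ValueError("inverse Gaussian density requires chi > 0")
    out = np.sqrt(p.mu**3 / (2.0 * np.pi * p.sigma2 * chi**3)) * np.exp(
        -p.mu * (chi - p.mu) ** 2 / (2.0 * p.sigma2 * chi)
    )
    return out if out.ndim else float(out)


def reciprocal_inverse_gaussian_density(x, p: IGParams):
    """pdf of 1/T when T is IG(μ, σ²); the rate-domain counterpart."""
    return reciprocal_density(lambda t: inverse_gaussian_density(t, p), x)


def _fp_density_lower(t: np.ndarray, xi: float, w: float, z0: float,
                      s: float, ctrl: SeriesControl) -> np.ndarray:
    # First-passage density at the lower of two boundaries separated by w,
    # start z0 above the lower boundary, drift xi, diffusion s.  Standard
    # sine-series solution of the backward equation.
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    pos = t > 1e-6  # below this the series is numerically degenerate; density ~ 0
    tt = t[pos]
    if tt.size:
        pref = (np.pi * s**2 / w**2) * np.exp(
            -xi * z0 / s**2 - xi**2 * tt / (2.0 * s**2)
        )
        total = np.zeros_like(tt)
        # the term envelope k·exp(−k²π²s²t/(2w²)) peaks at k* = w/(πs√t);
        # truncation is only safe past the peak, where terms decay
        k_star = w / (np.pi * s * np.sqrt(tt))
        for k in range(1, ctrl.max_terms + 1):
            envelope = k * np.exp(-(k**2) * np.pi**2 * s**2 * tt / (2.0 * w**2))
            total += envelope * np.sin(k * np.pi * z0 / w)
            done = (k >= k_star) & (
                envelope < ctrl.tol * np.maximum(np.abs(total), 1e-12)
            )
            if done.all() and k >= 10:
                break
        else:
            raise ConvergenceError(
                f"first-passage series did not converge in {ctrl.max_terms} terms"
            )
        out[pos] = pref * total
    np.maximum(out, 0.0, out=out)  # clip tiny negative truncation residue
    return out


def ddm_first_passage_density(t, p: DDMParams, ctrl: SeriesControl | None = None,
                              boundary: str = "upper"):
    """Defective first-passage density at one boundary of the two-boundary
    drift-diffusion process.

    The returned density integrates to the absorption probability at that
    boundary (< 1 in general); the two boundaries' densities together
    integrate to 1.  The upper-boundary density is obtained from the
    lower-boundary series by reflection (ξ → −ξ, z → a_up + b_lo − z).
    """
    ctrl = ctrl or SeriesControl()
    w = p.a_up - p.b_lo
    if boundary == "lower":
        xi, z0 = p.xi, p.z - p.b_lo
    elif boundary == "upper":
        xi, z0 = -p.xi, p.a_up - p.z
    else:
        raise ValueError("boundary must be 'upper' or 'lower'")
    out = _fp_density_lower(np.asarray(t, dtype=float), xi, w, z0, p.s, ctrl)
    return out if np.ndim(t) else float(out[0])


def ddm_absorption_probability(p: DDMParams, boundary: str = "upper") -> float:
    """Total probability of absorbing at the given boundary (Wald identity)."""
    w = p.a_up - p.b_lo
    if p.xi == 0:
        frac_up = (p.z - p.b_lo) / w
    else:
        th = 2.0 * p.xi / p.s**2
        frac_up = (np.expm1(-th * (p.z - p.b_lo))) / (np.expm1(-th * w))
    return float(frac_up if boundary == "upper" else 1.0 - frac_up)


_FAMILIES = ("trN", "rectrN", "IG", "recIG")


def sample(family: str, p, n: int, seed: int | None = None,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Seeded draws from trN / rectrN (rate/time) or IG / recIG (time/rate).

    Reciprocal families are obtained by elementwise inversion of draws from
    the base family, which is exact.  One explicit generator per call; pass
    either ``seed`` or an existing ``rng``.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {_FAMILIES}")
    if n <= 0:
        raise ValueError("n must be positive")
    gen = rng if rng is not None else np.random.default_rng(seed)
    if family in ("trN", "rectrN"):
        if not isinstance(p, TruncNormParams):
            raise ParameterError("trN/rectrN sampling requires TruncNormParams")
        draws = stats.truncnorm.rvs(
            p.alpha, np.inf, loc=p.mu, scale=p.sigma, size=n, random_state=gen
        )
        return 1.0 / draws if family == "rectrN" else draws
    if not isinstance(p, IGParams):
        raise ParameterError("IG/recIG sampling requires IGParams")
    lam = p.shape
    draws = stats.invgauss.rvs(p.mu / lam, scale=lam, size=n, random_state=gen)
    return 1.0 / draws if family == "recIG" else draws
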