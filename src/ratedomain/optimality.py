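"""Optimal response timing by maximizing expected rate of reward.

A correct response earns utility U⁺ > 0, an error costs U⁻ > 0, and the
probability of being correct given a response at time t is a concave,
non-decreasing accuracy function p(t) with p(0) = 1/n for n alternatives.
The expected gain is

    G(t) = (U⁺ + U⁻)·p(t) − U⁻,

negative below the break-even time t_min where p(t_min) = 1/(U⁺/U⁻ + 1).
Because only one reward can occur per trial, the relevant objective is the
expected *rate* of gain R(t) = G(t)/(t + T_ND), including the non-decision
time T_ND; the optimum t* solves (t* + T_ND)·G′(t*) = G(t*) — geometrically,
the tangent of G at t* passes through −T_ND on the time axis.

With the single-parameter family p(t) = p₁(ε̂·t), time simply rescales: at
T_ND = 0 the optimum is t* = t₁/ε̂ exactly (so optimal rate is linear in ε̂
and a Normally distributed ε̂ yields a reciprocal-Normal distribution of
optimal times); for T_ND > 0 the relationship t*(ε̂) is no longer an exact
power law but remains very close to one, t* ≈ a·ε̂^(−k) with 0 < k < 1.

The default accuracy function is exponential:
p(t) = 1/2 + (1 − exp(−ε̂·t))/2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import optimize, stats

__all__ = [
    "UtilityModel",
    "OptimalSolution",
    "PowerLawFit",
    "expected_gain",
    "min_profitable_time",
    "solve_optimal_time",
    "power_law_fit",
    "predict_rate_distribution",
    "NoOptimumError",
]


class NoOptimumError(RuntimeError):
    """No profitable response time exists for these payoffs."""


@dataclass(frozen=True)
class UtilityModel:
    """Payoffs, accuracy function, time scale and non-decision time."""

    u_plus: float = 1.0
    u_minus: float = 5.0
    t_nd: float = 0.0
    epsilon_hat: float = 1.0
    n_alternatives: int = 2
    p_form: str | Callable[[np.ndarray], np.ndarray] = "exponential"

    def __post_init__(self) -> None:
        if self.u_plus <= 0 or self.u_minus <= 0:
            raise ValueError("payoffs U+ and U- must be positive")
        if self.t_nd < 0:
            raise ValueError("non-decision time must be >= 0")
        if self.epsilon_hat <= 0:
            raise ValueError("epsilon_hat must be positive")

    def p(self, t):
        """Accuracy p(t); the ε̂ scale is applied inside."""
        t = np.asarray(t, dtype=float)
        if callable(self.p_form):
            out = self.p_form(self.epsilon_hat * t)
        elif self.p_form == "exponential":
            p0 = 1.0 / self.n_alternatives
            out = p0 + (1.0 - p0) * -np.expm1(-self.epsilon_hat * t)
        else:
            raise ValueError(f"unknown p_form {self.p_form!r}")
        return out if out.ndim else float(out)

    def p_prime(self, t):
        """dp/dt — analytic for the exponential form, central differences
        (h = 1e−6·max(t, 1)) for a user-supplied p."""
        t = np.asarray(t, dtype=float)
        if not callable(self.p_form) and self.p_form == "exponential":
            p0 = 1.0 / self.n_alternatives
            out = (1.0 - p0) * self.epsilon_hat * np.exp(-self.epsilon_hat * t)
        else:
            h = 1e-6 * np.maximum(t, 1.0)
            out = (self.p(t + h) - self.p(np.maximum(t - h, 0.0))) / (
                h + np.minimum(t, h)
            )
        return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class OptimalSolution:
    t_star: float
    t_min: float
    rate_star: float
    gain_at_opt: float
    converged: bool


@dataclass(frozen=True)
class PowerLawFit:
    """log-log regression t* ≈ a·ε̂^(−k), optionally plus a fixed delay γ."""

    k: float
    a_coef: float
    gamma: float
    epsilon_grid: np.ndarray
    t_star: np.ndarray
    r_squared: float


def expected_gain(t, model: UtilityModel):
    """G(t) = (U⁺ + U⁻)·p(t) − U⁻ for t ≥ 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = (model.u_plus + model.u_minus) * np.asarray(model.p(t)) - model.u_minus
    return out if out.ndim else float(out)


def _gain_prime(t, model: UtilityModel):
    return (model.u_plus + model.u_minus) * model.p_prime(t)


def min_profitable_time(model: UtilityModel, t_upper: float = 1e6) -> float:
    """Break-even time: the root of G(t) = 0, i.e. p(t) = 1/(U⁺/U⁻ + 1).

    Zero when p(0) already breaks even; raises NoOptimumError when the
    accuracy ceiling never pays (the "no response is optimal" regime).
    """
    target = 1.0 / (model.u_plus / model.u_minus + 1.0)
    if model.p(0.0) >= target:
        return 0.0
    hi = 1.0 / model.epsilon_hat
    while expected_gain(hi, model) <= 0:
        hi *= 2.0
        if hi > t_upper:
            raise NoOptimumError("expected gain never becomes positive")
    return float(optimize.brentq(lambda t: expected_gain(t, model), 0.0, hi,
                                 xtol=1e-14, rtol=8.9e-16))


def solve_optimal_time(model: UtilityModel) -> OptimalSolution:
    """Maximize R(t) = G(t)/(t + T_ND) over t > t_min.

    Solves h(t) = (t + T_ND)·G′(t) − G(t) = 0 by bracketed Brent iteration
    (the bracket upper end grows geometrically until h changes sign), then
    verifies t* is a maximum of R by comparing against t*·(1 ± 0.01).
    """
    t_min = min_profitable_time(model)
    h = lambda t: (t + model.t_nd) * _gain_prime(t, model) - expected_gain(t, model)
    lo = t_min + 1e-12 if t_min > 0 else 1e-12
    if h(lo) <= 0:  # should be positive just above break-even for concave p
        lo = t_min + 1e-9 / model.epsilon_hat
    hi = max(2.0 * lo, 1.0 / model.epsilon_hat)
    for _ in range(200):
        if h(hi) < 0:
            break
        hi *= 2.0
    else:
        raise NoOptimumError("rate of gain has no interior maximum")
    t_star = float(optimize.brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16))
    R = lambda t: expected_gain(t, model) / (t + model.t_nd)
    ok = R(t_star) >= max(R(t_star * 1.01), R(t_star * 0.99))
    return OptimalSolution(
        t_star=t_star, t_min=t_min, rate_star=1.0 / t_star,
        gain_at_opt=float(expected_gain(t_star, model)), converged=bool(ok),
    )


def power_law_fit(model: UtilityModel, epsilon_grid=None,
                  gamma: float = 0.0) -> PowerLawFit:
    """Fit t* ≈ a·ε̂^(−k) across a grid of time-acceleration scales.

    Solves the optimum at each ε̂ on the grid (default 50 log-spaced points
    over [0.01, 1]) and regresses log₁₀ t* on log₁₀ ε̂; k = −slope,
    a = 10^intercept.  At T_ND = 0 the law is exact with k = 1 and a = t₁.
    Grid points without an optimum are excluded.
    """
    if epsilon_grid is None:
        epsilon_grid = np.logspace(-2, 0, 50)
    eps = np.asarray(epsilon_grid, dtype=float)
    ts = np.full(eps.shape, np.nan)
    for i, e in enumerate(eps):
        try:
            ts[i] = solve_optimal_time(replace(model, epsilon_hat=float(e))).t_star
        except NoOptimumError:
            pass
    ok = np.isfinite(ts)
    if ok.sum() < 3:
        raise NoOptimumError("too few grid points with an optimum")
    slope, intercept, r, _, _ = stats.linregress(np.log10(eps[ok]), np.log10(ts[ok]))
    return PowerLawFit(k=float(-slope), a_coef=float(10.0**intercept), gamma=gamma,
                       epsilon_grid=eps[ok], t_star=ts[ok], r_squared=float(r**2))


def predict_rate_distribution(model: UtilityModel, eps_mean: float, eps_sd: float,
                              n_draws: int = 10_000, seed: int | None = None,
                              gamma: float = 0.0):
    """Distribution of optimal rates r* = 1/(t* + γ) when ε̂ varies Normally
    across trials (truncated to ε̂ > 0).

    Per-draw optimization; returns the r* sample and its moments.  At
    T_ND = 0 and γ = 0 this is exactly (ε̂/t₁)-distributed, i.e. a truncated
    Normal on the rate axis.
    """
    rng = np.random.default_rng(seed)
    a = -eps_mean / eps_sd
    eps = stats.truncnorm.rvs(a, np.inf, loc=eps_mean, scale=eps_sd,
                              size=n_draws, random_state=rng)
    if model.t_nd == 0 and not callable(model.p_form):
        t1 = solve_optimal_time(replace(model, epsilon_hat=1.0)).t_star
        t_star = t1 / eps
    else:
        t_star = np.array([
            solve_optimal_time(replace(model, epsilon_hat=float(e))).t_star
            for e in eps
        ])
    r_star = 1.0 / (t_star + gamma)
    return {
        "epsilon": eps,
        "t_star": t_star,
        "r_star": r_star,
        "mean": float(r_star.mean()),
        "sd": float(r_star.std(ddof=1)),
        "skewness": float(stats.skew(r_star)),
    }
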