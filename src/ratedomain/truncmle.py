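"""Maximum-likelihood fitting of the left-truncated Normal to block rates.

The observed rate in a block is modeled as Normal(μ, σ²) restricted to
[a, ∞), where a is the rate implied by the experiment's time-out (1/60 s⁻¹
for a 60-s time-out).  When little mass is truncated the ML estimates agree
with the sample moments; under heavy truncation the ML mean falls below the
sample mean and the ML SD rises above the sample SD.  A negative ML mean is
permitted — it simply places most of the underlying Normal below the bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

from .distributions import ParameterError

__all__ = ["TruncNormFit", "neg_log_likelihood", "fit_truncated_normal"]

DEFAULT_BOUND = 1.0 / 60.0


@dataclass(frozen=True)
class TruncNormFit:
    """ML estimates of the underlying Normal (mu_hat, sigma_hat) with the
    fixed truncation bound, the attained log-likelihood and sample size."""

    mu_hat: float
    sigma_hat: float
    a: float
    loglik: float
    converged: bool
    n: int


def neg_log_likelihood(data, mu: float, sigma: float, a: float = DEFAULT_BOUND) -> float:
    """−Σ log f(x_i; μ, σ, a) for the left-truncated Normal pdf
    f = φ((x−μ)/σ) / (σ·[1−Φ((a−μ)/σ)]).

    The survival normalizer is evaluated through ``log_ndtr`` so deep
    truncation (α ≫ 0) stays finite.
    """
    x = np.asarray(data, dtype=float)
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if np.any(x < a):
        raise ValueError("data below the truncation bound")
    z = (x - mu) / sigma
    log_surv = log_ndtr(-(a - mu) / sigma)
    return float(-(stats.norm.logpdf(z).sum() - x.size * (np.log(sigma) + log_surv)))


def fit_truncated_normal(data, a: float = DEFAULT_BOUND,
                         xtol: float = 1e-8, maxfev: int = 10_000) -> TruncNormFit:
    """Fit (μ, σ) by derivative-free simplex (Nelder–Mead) minimization of the
    negative log-likelihood, initialized at the sample moments.

    Optimization runs over (μ, log σ) so σ stays positive without
    constraints.  Non-convergence is flagged on the result, not raised.
    Requires n ≥ 20.
    """
    x = np.asarray(data, dtype=float)
    if x.size < 20:
        raise ValueError(f"need at least 20 observations, got {x.size}")
    m0, s0 = float(x.mean()), float(x.std(ddof=1))
    if s0 <= 0:
        raise ValueError("degenerate (constant) data")

    def nll(theta):
        return neg_log_likelihood(x, theta[0], np.exp(theta[1]), a)

    res = optimize.minimize(
        nll, x0=[m0, np.log(s0)], method="Nelder-Mead",
        options={"xatol": xtol, "fatol": xtol, "maxfev": maxfev},
    )
    mu_hat, sigma_hat = float(res.x[0]), float(np.exp(res.x[1]))
    return TruncNormFit(mu_hat, sigma_hat, a, loglik=-float(res.fun),
                        converged=bool(res.success), n=int(x.size))
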