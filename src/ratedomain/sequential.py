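"""Sequential-dependency analysis of trial-by-trial rate series.

Temporal side: partial autocorrelations, autoregressive (AR) maximum
likelihood, decorrelation (inversion to the stochastic input), conversion to
the equivalent moving-average (MA) feed-forward form by partial fractions of
the transfer function B(z) = 1/(1 − a₁z⁻¹ − … − a_m z⁻ᵐ), steady-state
mean/SD gains, the start-of-block step response, and the stationary output
density as a convolution of scaled input-density copies.

Spatial side: the 4-lag repeat/alternate binary coding of stimulus laterality
history and the per-code summary with a one-way repeated-measures F test.

The AR model is r_n = a₁r_{n−1} + … + a_m r_{n−m} + u_n with u_n i.i.d.
Normal(μ_u, σ_u²); stationarity requires all poles of the characteristic
polynomial strictly inside the unit circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.tsa.stattools import pacf as _sm_pacf

__all__ = [
    "ARModel",
    "MASystem",
    "PACFResult",
    "SpatialSummary",
    "pacf",
    "pacf_blocks",
    "shuffle_control",
    "fit_ar_ml",
    "decorrelate",
    "ar_to_ma",
    "ma_weights_recursion",
    "steady_state_gains",
    "yule_walker_autocorrelations",
    "step_response",
    "steady_state_density",
    "spatial_code",
    "spatial_summary",
    "InstabilityError",
    "InsufficientDataError",
]


class InstabilityError(ValueError):
    """AR weights define an unstable (non-stationary) system."""


class InsufficientDataError(ValueError):
    """Series too short for the requested analysis."""


def _poles(weights: np.ndarray) -> np.ndarray:
    """Roots of z^m − a₁z^{m−1} − … − a_m."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return np.array([])
    return np.roots(np.concatenate(([1.0], -w)))


def ar_is_stable(weights) -> bool:
    p = _poles(np.asarray(weights, dtype=float))
    return bool(p.size == 0 or np.max(np.abs(p)) < 1.0)


@dataclass
class ARModel:
    """Fitted (or specified) pure AR model with Normal input."""

    weights: np.ndarray
    mu_u: float = 0.0
    sigma_u: float = 1.0
    loglik: float = np.nan
    stderr: np.ndarray | None = None
    stable: bool = True

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.stable = ar_is_stable(self.weights)

    @property
    def order(self) -> int:
        return int(self.weights.size)


@dataclass
class MASystem:
    """Feed-forward equivalent of a stable AR model.

    b[0] = 1 and b[i] = Σ_k ρ_k λ_k^i, truncated where |b_i| falls below
    ``tol``; poles/residues from the partial-fraction expansion of B(z).
    """

    b: np.ndarray
    poles: np.ndarray
    residues: np.ndarray
    mean_gain: float
    sd_gain: float

    def __len__(self) -> int:
        return int(self.b.size)


@dataclass
class PACFResult:
    """Partial autocorrelations at lags 1..max_lag (per block and averaged)."""

    lags: np.ndarray
    coefficients: np.ndarray       # averaged across blocks
    per_block: np.ndarray          # shape (n_blocks, max_lag)
    stderr: np.ndarray             # SE of the mean across blocks (or 1/√n)
    n_effective: int


@dataclass
class SpatialSummary:
    """Per-code (0–15) mean RT/rate with within-subject SEs and the
    repeated-measures F statistic over codes."""

    table: pd.DataFrame            # index code 0..15; mean_rt_ms, mean_rate, se_rate, se_rt_ms, count
    f_statistic: float
    df_effect: int
    df_error: int
    p_value: float
    n_trials: int


# ---------------------------------------------------------------------------
# temporal analysis


def pacf(series, max_lag: int = 20, skip_initial: int = 10) -> np.ndarray:
    """Partial autocorrelations at lags 1..max_lag of one block.

    The first ``skip_initial`` trials are dropped to avoid the start-of-block
    transient; the remainder is de-meaned and the Durbin–Levinson recursion is
    applied to biased (1/n) autocovariances.
    """
    x = np.asarray(series, dtype=float)[skip_initial:]
    x = x[~np.isnan(x)]  # rare censored trials; splicing bias is negligible
    if x.size <= max_lag + 10:
        raise InsufficientDataError(
            f"need > {max_lag + 10} post-transient points, got {x.size}"
        )
    return _sm_pacf(x - x.mean(), nlags=max_lag, method="ywm")[1:]


def pacf_blocks(blocks, max_lag: int = 20, skip_initial: int = 10) -> PACFResult:
    """PACF per block, averaged across blocks, with across-block SEs."""
    per = np.array([pacf(b, max_lag, skip_initial) for b in blocks])
    se = per.std(axis=0, ddof=1) / np.sqrt(per.shape[0]) if per.shape[0] > 1 \
        else np.full(max_lag, np.nan)
    n_eff = int(min(len(np.asarray(b)) - skip_initial for b in blocks))
    return PACFResult(np.arange(1, max_lag + 1), per.mean(axis=0), per, se, n_eff)


def shuffle_control(blocks, seed: int | None = None, max_lag: int = 20,
                    skip_initial: int = 10) -> PACFResult:
    """Within-block random permutation followed by the same PACF analysis.

    Shuffling destroys sequential structure while preserving each block's
    marginal distribution exactly, so all coefficients should fall inside the
    white-noise band.
    """
    rng = np.random.default_rng(seed)
    shuffled = [rng.permutation(np.asarray(b, dtype=float)) for b in blocks]
    return pacf_blocks(shuffled, max_lag, skip_initial)


def _lagged_design(x: np.ndarray, order: int):
    y = x[order:]
    X = np.column_stack([x[order - j: len(x) - j] for j in range(1, order + 1)])
    return y, X


def fit_ar_ml(blocks, order: int = 6, skip_initial: int = 10,
              method: str = "conditional") -> ARModel:
    """Gaussian maximum likelihood for a pure AR(m) with constant-mean input,
    pooled across blocks.

    ``conditional`` (default): least squares on the lagged regression of
    per-block-centered rates, concatenated across blocks with no cross-block
    lag pairs — the conditional Gaussian ML solution.  Centering each block
    before pooling is essential: blocks from different conditions have
    different stationary means, and a single pooled intercept would let the
    between-block mean variance masquerade as autocorrelation.  The input
    mean is recovered per block as r̄·(1 − Σâ_j) and averaged.  ``exact``:
    statsmodels ARIMA(m,0,0) exact likelihood per block, weights averaged.
    Blocks may contain NaN (censored trials); affected rows are dropped.
    """
    arrays = [np.asarray(b, dtype=float)[skip_initial:] for b in blocks]
    if method == "exact":
        from statsmodels.tsa.arima.model import ARIMA

        fits = []
        for x in arrays:
            x = x[~np.isnan(x)]
            res = ARIMA(x, order=(order, 0, 0), trend="c").fit()
            fits.append(res.arparams)
        w = np.mean(fits, axis=0)
        resid = np.concatenate(
            [_ar_residuals(x[~np.isnan(x)], w) for x in arrays]
        )
        return ARModel(w, mu_u=float(resid.mean()), sigma_u=float(resid.std()),
                       loglik=np.nan)
    if method != "conditional":
        raise ValueError("method must be 'conditional' or 'exact'")
    ys, Xs, block_means = [], [], []
    for x in arrays:
        if x.size <= order + 2:
            continue
        xc = x - np.nanmean(x)
        block_means.append(np.nanmean(x))
        y, X = _lagged_design(xc, order)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        ys.append(y[ok])
        Xs.append(X[ok])
    if not ys:
        raise InsufficientDataError("no usable blocks for AR fitting")
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n          # ML variance
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2 * n / (n - X.shape[1]))
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    mu_u = float(np.mean(block_means) * (1.0 - beta.sum()))
    return ARModel(beta, mu_u=mu_u, sigma_u=float(np.sqrt(sigma2)),
                   loglik=loglik, stderr=se)


def _ar_residuals(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    m = len(weights)
    y, X = _lagged_design(x, m)
    return y - X @ weights


def decorrelate(series, model: ARModel) -> np.ndarray:
    """Invert the AR filter to recover the stochastic input:
    u_n = r_n − Σ a_j r_{n−j}.

    Only defined for n > m; the first m values (with incomplete history) are
    returned as NaN so array alignment is preserved.
    """
    x = np.asarray(series, dtype=float)
    m = model.order
    out = np.full_like(x, np.nan)
    if m == 0 or not model.weights.any():
        return x.copy()
    out[m:] = _ar_residuals(x, model.weights)
    return out


def ma_weights_recursion(weights, length: int) -> np.ndarray:
    """Impulse-response weights by the direct recursion
    b_i = Σ_{j ≤ min(i,m)} a_j b_{i−j}, b_0 = 1.  Brute-force oracle for
    :func:`ar_to_ma`."""
    a = np.atleast_1d(np.asarray(weights, dtype=float))
    b = np.zeros(length)
    b[0] = 1.0
    for i in range(1, length):
        jmax = min(i, a.size)
        b[i] = sum(a[j] * b[i - 1 - j] for j in range(jmax))
    return b


def ar_to_ma(model: ARModel, tol: float = 1e-10, max_len: int = 10_000) -> MASystem:
    """Convert a stable AR model to its MA (feed-forward) equivalent.

    Poles are the roots of the characteristic polynomial; residues come from
    the partial-fraction expansion of B(z) (``scipy.signal.residuez``), so
    b_i = Σ_k ρ_k λ_k^i.  Complex-conjugate pole pairs combine to real b_i;
    the residual imaginary part is asserted < 1e−10.  The weight sequence is
    truncated at the first |b_i| < tol (cap ``max_len``).
    """
    a = model.weights
    if not ar_is_stable(a):
        raise InstabilityError(f"unstable AR weights {a}")
    nonzero = np.flatnonzero(np.abs(a) > 1e-12)
    if nonzero.size == 0:
        b = np.array([1.0])
        return MASystem(b, np.array([]), np.array([]), 1.0, 1.0)
    # trailing (near-)zero weights put spurious poles at the origin
    a = a[: int(nonzero.max()) + 1]
    denom = np.concatenate(([1.0], -a))
    residues, poles, _ = signal.residuez([1.0], denom)
    # b_i from residues/poles (handles distinct roots; repeated roots fall
    # back to the recursion, which is exact in all cases)
    lmax = float(np.max(np.abs(poles)))
    if tol > 0:
        est_len = min(max_len, max(10, int(np.ceil(np.log(tol) / np.log(lmax))) + 2))
    else:
        est_len = max_len
    if np.unique(np.round(poles, 10)).size == poles.size:
        i = np.arange(est_len)
        b_c = (residues[None, :] * poles[None, :] ** i[:, None]).sum(axis=1)
        assert np.max(np.abs(b_c.imag)) < 1e-10, "conjugate pairs did not cancel"
        b = b_c.real
    else:  # repeated roots: residuez returns higher-order terms; use recursion
        b = ma_weights_recursion(a, est_len)
    b[0] = 1.0  # exact by construction; clears residue round-off
    # truncate at first negligible weight
    if tol > 0:
        small = np.flatnonzero(np.abs(b) < tol)
        if small.size:
            b = b[: max(int(small[0]), 1)]
    mean_gain = 1.0 / (1.0 - a.sum())
    sd_gain = float(np.sqrt(np.sum(ma_weights_recursion(a, max(est_len, 2000)) ** 2)))
    return MASystem(b, poles, residues, float(mean_gain), sd_gain)


def yule_walker_autocorrelations(weights, max_lag: int) -> np.ndarray:
    """Theoretical autocorrelations ρ_1..ρ_max_lag of a stable AR model, from
    the Yule–Walker equations (independent cross-check on the MA route)."""
    a = np.atleast_1d(np.asarray(weights, dtype=float))
    m = a.size
    if m == 0:
        return np.zeros(max_lag)
    # solve rho_k = sum_j a_j rho_{|k-j|} for k=1..m, with rho_0 = 1
    A = np.eye(m)
    rhs = np.zeros(m)
    for k in range(1, m + 1):
        for j in range(1, m + 1):
            lag = abs(k - j)
            if lag == 0:
                rhs[k - 1] += a[j - 1]
            else:
                A[k - 1, lag - 1] -= a[j - 1]
    rho = np.linalg.solve(A, rhs)
    out = np.empty(max_lag)
    out[: min(m, max_lag)] = rho[:max_lag]
    ext = np.concatenate(([1.0], out))  # ext[k] = rho_k
    for k in range(m + 1, max_lag + 1):
        ext[k] = sum(a[j] * ext[k - 1 - j] for j in range(m))
    return ext[1: max_lag + 1]


def steady_state_gains(ma: MASystem) -> tuple[float, float]:
    """(mean_gain, sd_gain) of the stationary system: Σb_i = 1/(1 − Σa_j) and
    √(Σb_i²), as stored on the MASystem."""
    return ma.mean_gain, ma.sd_gain


def step_response(ma: MASystem, n_trials: int, input_mean: float = 1.0) -> np.ndarray:
    """Response to a sustained constant input from zero history: cumulative
    sums of the impulse-response weights, scaled by the input mean.  The
    asymptote is mean_gain × input_mean; for non-negative weights the
    approach is monotone."""
    b = ma.b
    full = np.zeros(n_trials)
    k = min(n_trials, b.size)
    full[:k] = b[:k]
    return np.cumsum(full) * input_mean


def steady_state_density(input_density, ma: MASystem, grid: np.ndarray,
                         weight_tol: float = 1e-6) -> np.ndarray:
    """Stationary output density of the MA system by iterated convolution of
    scaled input-density copies (1/|b_i|)·p_u(x/b_i).

    ``input_density`` is a callable pdf; ``grid`` a uniform output grid.  The
    convolution uses trapezoid quadrature, so for inputs supported on [0, ∞)
    the output density at the origin is exactly zero — the analytic smoothing
    of truncation.  Terms stop once |b_i| < weight_tol.  Raises if the
    resulting density's normalization is off by more than 1e−3 (grid too
    coarse or too narrow).
    """
    grid = np.asarray(grid, dtype=float)
    dx = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dx, rtol=1e-8):
        raise ValueError("grid must be uniform")
    terms = [float(b) for b in ma.b if abs(b) >= weight_tol]
    # input mean, for terms too small to resolve on the grid (see below)
    x_in = np.arange(grid[0], grid[-1] + dx / 2, dx)
    p_in = input_density(x_in)
    mean_u = float(np.trapezoid(x_in * p_in, dx=dx) / np.trapezoid(p_in, dx=dx))

    def scaled_copy(bi):
        # support of b_i * U sampled on its own grid with common spacing dx
        lo, hi = sorted((grid[0] * bi, grid[-1] * bi))
        x = np.arange(lo, hi + dx / 2, dx)
        return x[0], input_density(x / bi) / abs(bi)

    x0, dens = scaled_copy(terms[0])
    for bi in terms[1:]:
        if (grid[-1] - grid[0]) * abs(bi) < 8 * dx:
            # copy narrower than the grid can resolve: acts as a delta at
            # b_i·E[u], i.e. a pure shift of the running density
            x0 += bi * mean_u
            continue
        x0b, db = scaled_copy(bi)
        conv = np.convolve(dens, db) * dx
        # trapezoid end-correction: subtract the half-weighted endpoints
        n1, n2 = len(dens), len(db)
        j = np.arange(n1 + n2 - 1)
        lo_idx = np.maximum(0, j - (n2 - 1))
        hi_idx = np.minimum(j, n1 - 1)
        conv -= 0.5 * dx * dens[lo_idx] * db[j - lo_idx]
        conv -= 0.5 * dx * np.where(j - hi_idx < n2, dens[hi_idx] * db[j - hi_idx], 0.0)
        single = lo_idx == hi_idx  # only one sample in the overlap
        conv[single] = 0.0
        dens = np.maximum(conv, 0.0)
        x0 = x0 + x0b
    xs = x0 + dx * np.arange(len(dens))
    out = np.interp(grid, xs, dens, left=0.0, right=0.0)
    mass = np.trapezoid(out, grid)
    if abs(mass - 1.0) > 1e-3:
        raise ValueError(
            f"normalization off by {abs(mass - 1.0):.2e}: grid too coarse/narrow"
        )
    return out / mass


# ---------------------------------------------------------------------------
# spatial (repeat/alternate) analysis


def spatial_code(side_history) -> int:
    """4-lag repeat/alternate code of a 5-symbol laterality history.

    Each of the four transitions is labeled R (repeat → bit 0) or A
    (alternate → bit 1); the earliest transition is the most significant bit,
    the last symbol is the current trial.  RRRR → 0, RRAR → 2, AARA → 13.
    """
    s = list(side_history)
    if len(s) != 5:
        raise ValueError(f"need exactly 5 consecutive side labels, got {len(s)}")
    code = 0
    for i in range(1, 5):
        code = (code << 1) | (0 if s[i] == s[i - 1] else 1)
    return code


def transitions_code(transitions: str) -> int:
    """Code straight from a 4-letter R/A transition string (e.g. 'RRAR' → 2)."""
    t = transitions.upper()
    if len(t) != 4 or set(t) - {"R", "A"}:
        raise ValueError("expected 4 characters from {R, A}")
    return int(t.replace("R", "0").replace("A", "1"), 2)


def spatial_summary(table: pd.DataFrame, conditions=("AE", "UE"),
                    use_rate: bool = True) -> SpatialSummary:
    """Mean RT and rate by 4-lag repeat/alternate code, with within-subject
    standard errors and a one-way repeated-measures F over the 16 codes.

    Expects the canonical trial table (columns subject, block, condition,
    trial_index, side, rt_ms, timed_out).  Trials 1–4 of each block lack the
    full history and are skipped; per-subject centering removes between-
    subject level differences before the SEs and F are computed.  Codes with
    empty cells are reported as missing and excluded from the F.
    """
    df = table[table["condition"].isin(conditions)].copy()
    rows = []
    for (subj, block), g in df.groupby(["subject", "block"], sort=True):
        g = g.sort_values("trial_index")
        sides = g["side"].to_numpy()
        rt = g["rt_ms"].to_numpy(dtype=float)
        rate = 1000.0 / rt
        timed = g["timed_out"].to_numpy(dtype=bool)
        for i in range(4, len(g)):
            if timed[i]:
                continue
            rows.append((subj, spatial_code(sides[i - 4: i + 1]), rt[i], rate[i]))
    long = pd.DataFrame(rows, columns=["subject", "code", "rt_ms", "rate"])
    value = "rate" if use_rate else "rt_ms"

    # subject x code cell means
    cell = long.groupby(["subject", "code"])[["rt_ms", "rate"]].mean()
    wide = cell[value].unstack("code")
    codes_full = [
        c for c in range(16) if c in wide.columns and not wide[c].isna().any()
    ]
    Y = wide.loc[:, codes_full].to_numpy() if codes_full else np.empty((0, 0))
    if Y.size and Y.shape[0] > 1 and Y.shape[1] > 1:
        ns, nc = Y.shape
        grand = Y.mean()
        ss_cond = ns * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_subj = nc * ((Y.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((Y - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        df_eff = nc - 1
        df_err = (nc - 1) * (ns - 1)
        F = (ss_cond / df_eff) / (ss_err / df_err)
        pval = float(stats.f.sf(F, df_eff, df_err))
    else:
        F, df_eff, df_err, pval = np.nan, 0, 0, np.nan
    # within-subject SEs (Cousineau-style: center each subject first)
    centered = cell.copy()
    subj_means = cell.groupby("subject")[["rt_ms", "rate"]].transform("mean")
    centered[["rt_ms", "rate"]] = cell[["rt_ms", "rate"]] - subj_means \
        + cell[["rt_ms", "rate"]].mean()
    agg = pd.DataFrame(index=pd.RangeIndex(16, name="code"))
    agg["mean_rt_ms"] = cell["rt_ms"].groupby("code").mean()
    agg["mean_rate"] = cell["rate"].groupby("code").mean()
    agg["se_rt_ms"] = centered["rt_ms"].groupby("code").sem()
    agg["se_rate"] = centered["rate"].groupby("code").sem()
    agg["count"] = long.groupby("code").size().reindex(agg.index, fill_value=0)
    return SpatialSummary(agg, float(F), int(df_eff), int(df_err), pval,
                          n_trials=len(long))
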