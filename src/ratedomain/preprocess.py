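"""From recorded trial tables to analyzable rate series.

Recorded RTs are integer milliseconds; taking reciprocals of quantized values
produces artifactual clumps and gaps in the rate histogram, so a uniform
±0.5 ms dither is added before the reciprocal transform.  RTs under the
anticipation bound (0.15 s, i.e. rate above 6.67 s⁻¹) are masked as
anticipatory.  Timed-out trials enter the rate series at the time-out bound
(left-censoring) but stay flagged so downstream analyses can drop them.

Per-block sample moments, coefficient-of-variation truncation classification
(threshold 0.4: CV ≥ 0.4 → "truncated"), z-standardization by the block's
ML moments, pooling across blocks, and probit (Normal quantile) coordinates
complete the group-distribution analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .truncmle import TruncNormFit

__all__ = [
    "BlockStats",
    "dither_rts",
    "to_rates",
    "block_moments",
    "classify_blocks",
    "standardize_and_collapse",
    "probit_coordinates",
    "block_rate_series",
]

ANTICIPATION_BOUND_S = 0.15
CV_THRESHOLD = 0.4


@dataclass(frozen=True)
class BlockStats:
    """Sample central moments of one block (time or rate domain)."""

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    median: float
    cv: float
    n_used: int
    n_excluded_anticipatory: int = 0
    n_timed_out: int = 0
    domain: str = "rate"
    truncation_class: str | None = None


def dither_rts(rt_ms, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Add an independent U(−0.5, +0.5) ms perturbation to each recorded RT.

    Statistically inverts millisecond rounding (the dithered values have the
    same distribution as the underlying continuous RTs up to the quantizer's
    resolution) and removes clumping/gaps from the rate histogram.
    """
    gen = rng if rng is not None else np.random.default_rng(seed)
    rt_ms = np.asarray(rt_ms, dtype=float)
    return rt_ms + gen.uniform(-0.5, 0.5, size=rt_ms.shape)


def to_rates(rt_ms_dithered, anticipation_bound: float = ANTICIPATION_BOUND_S):
    """Reciprocal transform to rates (s⁻¹) plus the anticipation mask.

    Returns ``(rates, keep)`` where ``keep`` is False for RTs strictly below
    the anticipation bound.  The masked entries still carry their rate value;
    callers index with the mask.
    """
    rt_s = np.asarray(rt_ms_dithered, dtype=float) / 1000.0
    if np.any(rt_s <= 0):
        raise ValueError("nonpositive RT")
    rates = 1.0 / rt_s
    keep = rt_s >= anticipation_bound
    return rates, keep


def block_moments(values, domain: str = "rate",
                  n_excluded_anticipatory: int = 0,
                  n_timed_out: int = 0) -> BlockStats:
    """Sample central moments of one block's series.

    Skewness and kurtosis are SD-normalized, kurtosis reported as excess;
    the median uses the midpoint convention.  For a constant series the
    shape moments are undefined and reported as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True))
    return BlockStats(
        mean=mean, sd=sd, skewness=skew, excess_kurtosis=kurt,
        median=float(np.median(x)), cv=(sd / mean if mean != 0 else np.inf),
        n_used=int(x.size), n_excluded_anticipatory=n_excluded_anticipatory,
        n_timed_out=n_timed_out, domain=domain,
    )


def classify_blocks(stats_or_cv, cv_threshold: float = CV_THRESHOLD):
    """Label each block 'truncated' (CV ≥ threshold) or 'untruncated'.

    Accepts BlockStats objects, TruncNormFit objects (CV = σ̂/μ̂), or bare CV
    floats.  The boundary CV == threshold is assigned to the truncated side.
    """
    labels = []
    for s in stats_or_cv:
        if isinstance(s, BlockStats):
            cv = s.cv
        elif isinstance(s, TruncNormFit):
            cv = s.sigma_hat / s.mu_hat if s.mu_hat != 0 else np.inf
        else:
            cv = float(s)
        labels.append("truncated" if (cv >= cv_threshold or cv < 0) else "untruncated")
    return labels


def standardize_and_collapse(block_rates: dict, fits: dict,
                             group: str = "untruncated",
                             labels: dict | None = None) -> np.ndarray:
    """z-score each trial by its block's ML moments and pool across blocks.

    ``block_rates`` and ``fits`` are keyed identically (e.g. by
    (subject, block)).  ``labels`` maps keys to truncation classes; only
    blocks in ``group`` enter the pool.  For the truncated group only
    positive z-scores are retained, because truncation under-represents the
    negative half.
    """
    if group not in ("untruncated", "truncated"):
        raise ValueError("group must be 'untruncated' or 'truncated'")
    pool = []
    for key, rates in block_rates.items():
        if labels is not None and labels.get(key) != group:
            continue
        f = fits[key]
        if f.sigma_hat <= 0:
            raise ValueError(f"non-positive fitted sigma for block {key}")
        z = (np.asarray(rates, dtype=float) - f.mu_hat) / f.sigma_hat
        if group == "truncated":
            z = z[z > 0]
        pool.append(z)
    if not pool:
        return np.array([])
    return np.concatenate(pool)


def probit_coordinates(z_pool, band: tuple[float, float] = (0.05, 0.95)):
    """Normal-quantile (probit) coordinates of a pooled sample with a linear
    fit over the central band.

    Ordered data are paired with Φ⁻¹ of the plotting positions
    (i − 3/8)/(n + 1/4).  Returns a dict with the coordinate arrays and the
    slope/intercept/R² of the straight-line fit restricted to the band
    (default 5th–95th percentile) — linearity there diagnoses Normality.
    """
    z = np.sort(np.asarray(z_pool, dtype=float))
    n = z.size
    if n < 100:
        raise ValueError(f"need at least 100 values for a probit fit, got {n}")
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(pp)
    lo, hi = band
    sel = (pp >= lo) & (pp <= hi)
    slope, intercept, r, _, _ = stats.linregress(theo[sel], z[sel])
    return {
        "empirical": z,
        "theoretical": theo,
        "plotting_positions": pp,
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r**2),
        "band": band,
    }


def block_rate_series(table: pd.DataFrame, seed: int = 0,
                      anticipation_bound: float = ANTICIPATION_BOUND_S,
                      drop_timed_out: bool = False):
    """Canonical trial table → per-block rate arrays and bookkeeping.

    Returns ``(rates, masks, counts)``, each keyed by (subject, block):
    ``rates`` are dithered reciprocal rates in trial order; ``masks`` has
    boolean columns keep/timed_out; counts reconcile n_input =
    n_used + n_anticipatory (+ timed-out handling per flags).  Timed-out
    trials keep the bound rate unless ``drop_timed_out``; anticipatory trials
    are always masked.
    """
    root = np.random.SeedSequence(seed)
    rates_d, masks_d, counts_d = {}, {}, {}
    for key, g in table.groupby(["subject", "block"], sort=True):
        g = g.sort_values("trial_index")
        rng = np.random.default_rng(root.spawn(1)[0])
        timed = g["timed_out"].to_numpy(dtype=bool)
        dithered = dither_rts(g["rt_ms"].to_numpy(), rng=rng)
        # a timed-out trial is recorded at the bound, not dithered noise
        dithered = np.where(timed, g["rt_ms"].to_numpy(dtype=float), dithered)
        rates, keep = to_rates(dithered, anticipation_bound)
        if drop_timed_out:
            keep = keep & ~timed
        rates_d[key] = rates
        masks_d[key] = {"keep": keep, "timed_out": timed}
        counts_d[key] = {
            "n_input": int(len(g)),
            "n_used": int(keep.sum()),
            "n_excluded_anticipatory": int((~keep & ~timed).sum()),
            "n_timed_out": int(timed.sum()),
        }
    return rates_d, masks_d, counts_d
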