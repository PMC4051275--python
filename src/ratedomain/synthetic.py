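"""Synthetic two-alternative choice RT experiments.

Emulates the study design the analysis assumes: 24 subjects × 4 blocks × 200
trials, one block per condition (AE/AD/UE/UD — Accurate/Urgent instruction ×
Easy/Difficult discrimination), with

* trial-to-trial rates following a stationary Gaussian AR process
  r_n = Σ a_j r_{n−j} + u_n started from zero history (so each block opens
  with the characteristic transient lasting under ~10 trials),
* left-censoring at the time-out rate bound (a trial whose rate falls below
  1/60 s⁻¹ is recorded at the 60-s time-out and flagged),
* millisecond quantization of recorded RTs,
* Bernoulli(0.5) stimulus laterality with an optional additive rate offset
  keyed by the 4-lag repeat/alternate history code, applied in the easy
  conditions only, and
* condition-specific error rates (1% easy, 24% difficult).

The AR recursion runs on the latent rate; only the observation is censored.
Everything is driven by one seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .sequential import ar_is_stable
from .truncmle import TruncNormFit
from . import distributions as dist

__all__ = [
    "ConditionParams",
    "SynthConfig",
    "generate_block_rates",
    "generate_experiment",
    "clone_parametric",
    "write_trial_table",
    "read_trial_table",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "subject", "block", "condition", "trial_index",
    "side", "rt_ms", "correct", "timed_out",
]

CONDITIONS = ("AE", "AD", "UE", "UD")
EASY_CONDITIONS = ("AE", "UE")

# default input-rate parameters per condition: steady-state rate mean is
# mean_gain (≈1.67) times mu_u; easy conditions land near 3.3–3.7 s⁻¹
# (RT ≈ 300 ms), difficult ones near 0.6–0.8 s⁻¹ where left-censoring at the
# time-out bound starts to bite.  Error rates follow the 1% / 24% design.
DEFAULT_CONDITION_PARAMS = {
    "AE": {"mu_u": 2.0, "sigma_u": 0.30, "error_rate": 0.01},
    "UE": {"mu_u": 2.2, "sigma_u": 0.30, "error_rate": 0.01},
    "AD": {"mu_u": 0.35, "sigma_u": 0.30, "error_rate": 0.24},
    "UD": {"mu_u": 0.50, "sigma_u": 0.30, "error_rate": 0.24},
}

# codes the spatial analysis singles out (AAAR=14, RRRA=1, ARRA=9 carry the
# slowest responses); offsets are additive on rate in the easy conditions
DEFAULT_SPATIAL_DELTAS = {1: -0.12, 9: -0.12, 14: -0.12}


@dataclass(frozen=True)
class ConditionParams:
    mu_u: float
    sigma_u: float
    error_rate: float

    def __post_init__(self) -> None:
        # sigma_u = 0 is allowed for deterministic step-response checks
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")


@dataclass
class SynthConfig:
    """Full specification of one synthetic experiment."""

    n_subjects: int = 24
    n_blocks_per_subject: int = 4
    n_trials: int = 200
    condition_params: dict = field(
        default_factory=lambda: {
            k: ConditionParams(**v) for k, v in DEFAULT_CONDITION_PARAMS.items()
        }
    )
    ar_weights: tuple = (0.222, 0.104, 0.076)
    truncation_bound: float = 1.0 / 60.0
    anticipation_bound: float = 0.15
    spatial_deltas: dict = field(default_factory=lambda: dict(DEFAULT_SPATIAL_DELTAS))
    quantize_ms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_blocks_per_subject, self.n_trials) <= 0:
            raise ValueError("all design counts must be positive")
        cp = {}
        for k, v in self.condition_params.items():
            if k not in CONDITIONS:
                raise ValueError(f"unknown condition key {k!r}")
            cp[k] = v if isinstance(v, ConditionParams) else ConditionParams(**v)
            if cp[k].sigma_u <= 0:
                raise ValueError(f"sigma_u must be positive for condition {k}")
        self.condition_params = cp
        if not ar_is_stable(self.ar_weights):
            raise ValueError(f"unstable AR weights {self.ar_weights}")
        if any(not 0 <= c <= 15 for c in self.spatial_deltas):
            raise ValueError("spatial_deltas keys must be codes 0..15")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "ar_weights" in d:
            d["ar_weights"] = tuple(d["ar_weights"])
        if "spatial_deltas" in d:
            d["spatial_deltas"] = {int(k): float(v)
                                   for k, v in d["spatial_deltas"].items()}
        return cls(**d)


def generate_block_rates(cond: ConditionParams, ar_weights, n_trials: int,
                         seed=None, rng: np.random.Generator | None = None,
                         truncation_bound: float = 1.0 / 60.0):
    """One block's latent and observed rate sequences.

    r_n = Σ a_j r_{n−j} + u_n with u_n i.i.d. Normal(mu_u, sigma_u²) and zero
    pre-history.  Returns ``(observed, latent, timed_out)``: the observation
    is the latent rate censored from below at the time-out bound, with the
    censored trials flagged.
    """
    a = np.atleast_1d(np.asarray(ar_weights, dtype=float))
    if not ar_is_stable(a):
        raise ValueError(f"unstable AR weights {a}")
    gen = rng if rng is not None else np.random.default_rng(seed)
    u = gen.normal(cond.mu_u, cond.sigma_u, size=n_trials)
    m = a.size
    latent = np.empty(n_trials)
    for n in range(n_trials):
        hist = sum(a[j] * latent[n - 1 - j] for j in range(min(n, m)))
        latent[n] = hist + u[n]
    timed_out = latent < truncation_bound
    observed = np.where(timed_out, truncation_bound, latent)
    return observed, latent, timed_out


def _condition_orders(n_subjects: int) -> list[tuple[str, ...]]:
    orders = list(permutations(CONDITIONS))  # 24 distinct orders
    return [orders[i % len(orders)] for i in range(n_subjects)]


def generate_experiment(config: SynthConfig) -> pd.DataFrame:
    """Full factorial trial table under ``config``.

    Each subject runs ``n_blocks_per_subject`` blocks, cycling through the 24
    distinct condition orders across subjects (the balanced design).  Side is
    Bernoulli(0.5); in easy conditions the latent rate receives the
    configured additive offset for the trial's 4-lag repeat/alternate code
    before censoring; correctness is Bernoulli(1 − error_rate); RT = 1/rate,
    quantized to integer milliseconds when ``quantize_ms``.
    """
    from .sequential import spatial_code

    root = np.random.SeedSequence(config.seed)
    orders = _condition_orders(config.n_subjects)
    frames = []
    for s in range(config.n_subjects):
        for b in range(config.n_blocks_per_subject):
            condition = orders[s][b % len(CONDITIONS)]
            if condition not in config.condition_params:
                raise ValueError(f"no parameters configured for {condition!r}")
            cp = config.condition_params[condition]
            rng = np.random.default_rng(root.spawn(1)[0])
            n = config.n_trials
            sides = np.where(rng.random(n) < 0.5, "L", "R")
            _, latent, _ = generate_block_rates(
                cp, config.ar_weights, n, rng=rng,
                truncation_bound=config.truncation_bound,
            )
            if condition in EASY_CONDITIONS and config.spatial_deltas:
                for i in range(4, n):
                    code = spatial_code(sides[i - 4: i + 1])
                    latent[i] += config.spatial_deltas.get(code, 0.0)
            timed_out = latent < config.truncation_bound
            rate = np.where(timed_out, config.truncation_bound, latent)
            rt_ms = 1000.0 / rate
            if config.quantize_ms:
                rt_ms = np.maximum(np.rint(rt_ms), 1.0)
            rt_ms = np.where(timed_out, 1000.0 / config.truncation_bound, rt_ms)
            correct = rng.random(n) >= cp.error_rate
            frames.append(pd.DataFrame({
                "subject": s + 1,
                "block": b + 1,
                "condition": condition,
                "trial_index": np.arange(1, n + 1),
                "side": sides,
                "rt_ms": rt_ms.astype(int) if config.quantize_ms else rt_ms,
                "correct": correct,
                "timed_out": timed_out,
            }))
    return pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]


def clone_parametric(table: pd.DataFrame, family: str,
                     fits: dict[tuple, TruncNormFit] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Parametric surrogate of an experiment: per block, replace the RTs with
    draws from the chosen family at that block's fitted moments, preserving
    the design columns and per-block sample sizes exactly.

    ``family='rectrN'``: RT = 1/trN(μ̂, σ̂, a) at the block's truncated-Normal
    ML fit (``fits`` keyed by (subject, block) is required).
    ``family='IG'``: inverse Gaussian at the block's RT sample mean and
    variance (no truncation issue, so sample moments suffice).
    """
    if family not in ("rectrN", "IG"):
        raise ValueError("family must be 'rectrN' or 'IG'")
    root = np.random.SeedSequence(seed)
    out = table.copy()
    for (subj, blk), g in table.groupby(["subject", "block"], sort=True):
        rng = np.random.default_rng(root.spawn(1)[0])
        n = len(g)
        if family == "rectrN":
            if fits is None or (subj, blk) not in fits:
                raise KeyError(f"missing truncated-Normal fit for block {(subj, blk)}")
            f = fits[(subj, blk)]
            p = dist.TruncNormParams(f.mu_hat, f.sigma_hat, f.a)
            rt_s = dist.sample("rectrN", p, n, rng=rng)
        else:
            rt_s = g["rt_ms"].to_numpy(dtype=float) / 1000.0
            p = dist.IGParams(float(rt_s.mean()), float(rt_s.var(ddof=1)))
            rt_s = dist.sample("IG", p, n, rng=rng)
        rt_ms = np.maximum(np.rint(rt_s * 1000.0), 1.0).astype(int)
        out.loc[g.index, "rt_ms"] = np.minimum(rt_ms, 60_000)
        out.loc[g.index, "timed_out"] = rt_ms >= 60_000
    return out


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write the canonical tab-delimited trial table (header row included)."""
    table[TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    return df[TABLE_COLUMNS]
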