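"""Config-driven end-to-end orchestration.

Stages: simulate → preprocess → truncated-Normal fits → group probit →
sequential (PACF / AR / MA / spatial) → optimality.  Every stage reads and
writes delimited text under the output directory, records its seed, and can
be re-run independently; a manifest captures the config hash and seeds so a
full run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import optimality, preprocess, sequential, synthetic, truncmle

log = logging.getLogger("ratedomain")

__all__ = ["PipelineConfig", "run", "load_config", "StageError"]

_KNOWN_KEYS = {
    "out_dir", "synth", "cv_threshold", "pacf_max_lag", "pacf_skip_initial",
    "ar_order", "clone_family", "optimality_model", "epsilon_grid", "seeds",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, msg: str):
        super().__init__(f"[{stage}:{code}] {msg}")
        self.stage, self.code = stage, code


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)
    cv_threshold: float = preprocess.CV_THRESHOLD
    pacf_max_lag: int = 20
    pacf_skip_initial: int = 10
    ar_order: int = 6
    clone_family: str | None = None
    optimality_model: dict = field(
        default_factory=lambda: {"u_plus": 1.0, "u_minus": 5.0, "t_nd": 0.0}
    )
    epsilon_grid: list | None = None
    seeds: dict = field(
        default_factory=lambda: {"simulate": 1, "dither": 2, "clone": 3,
                                 "shuffle": 4, "rate_dist": 5}
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "synth" in d and not isinstance(d["synth"], synthetic.SynthConfig):
            d["synth"] = synthetic.SynthConfig.from_dict(d["synth"])
        return cls(**d)

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        d = asdict_safe(self)
        d.pop("out_dir", None)  # paths don't affect the science
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(cfg: PipelineConfig) -> dict:
    d = dict(cfg.__dict__)
    sy = dict(cfg.synth.__dict__)
    sy["condition_params"] = {k: vars(v) for k, v in cfg.synth.condition_params.items()}
    d["synth"] = sy
    return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _stage_simulate(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    synth = synthetic.SynthConfig(**{**cfg.synth.__dict__,
                                     "seed": cfg.seeds["simulate"]})
    table = synthetic.generate_experiment(synth)
    synthetic.write_trial_table(table, out / "trials.tsv")
    log.info("simulate: %d trials", len(table))
    return table


def _stage_preprocess(cfg: PipelineConfig, table: pd.DataFrame, out: Path):
    rates, masks, counts = preprocess.block_rate_series(
        table, seed=cfg.seeds["dither"])
    stats_rows, fits = [], {}
    for key in rates:
        r = rates[key][masks[key]["keep"]]
        bs = preprocess.block_moments(
            r, domain="rate",
            n_excluded_anticipatory=counts[key]["n_excluded_anticipatory"],
            n_timed_out=counts[key]["n_timed_out"])
        fit = truncmle.fit_truncated_normal(r)
        fits[key] = fit
        stats_rows.append({
            "subject": key[0], "block": key[1],
            **{k: v for k, v in vars(bs).items() if k != "truncation_class"},
            "mu_ml": fit.mu_hat, "sigma_ml": fit.sigma_hat,
            "ml_converged": fit.converged,
        })
    stats_df = pd.DataFrame(stats_rows)
    cvs = [f.sigma_hat / f.mu_hat if f.mu_hat != 0 else np.inf
           for f in fits.values()]
    stats_df["truncation_class"] = preprocess.classify_blocks(
        cvs, cfg.cv_threshold)
    stats_df.to_csv(out / "block_stats.tsv", sep="\t", index=False)
    labels = dict(zip(fits.keys(), stats_df["truncation_class"]))
    return rates, masks, fits, labels, stats_df


def _stage_group(cfg, rates, masks, fits, labels, out: Path) -> dict:
    report = {}
    kept = {k: rates[k][masks[k]["keep"]] for k in rates}
    for group in ("untruncated", "truncated"):
        pool = preprocess.standardize_and_collapse(kept, fits, group, labels)
        if pool.size < 100:
            report[group] = {"n": int(pool.size)}
            continue
        pr = preprocess.probit_coordinates(pool)
        from scipy.stats import skew
        report[group] = {
            "n": int(pool.size), "slope": pr["slope"],
            "intercept": pr["intercept"], "r_squared": pr["r_squared"],
            "skewness": float(skew(pool)),
        }
        np.savetxt(out / f"zpool_{group}.tsv", pool, header="z", comments="")
    return report


def _stage_sequential(cfg, table, rates, masks, labels, out: Path) -> dict:
    # censored/anticipatory trials become NaN so lag adjacency is preserved;
    # fit_ar_ml drops regression rows touching them
    blocks = []
    for k in rates:
        if labels[k] != "untruncated":
            continue
        arr = rates[k].copy()
        arr[masks[k]["timed_out"] | ~masks[k]["keep"]] = np.nan
        blocks.append(arr)
    pr = sequential.pacf_blocks(blocks, cfg.pacf_max_lag, cfg.pacf_skip_initial)
    shuf = sequential.shuffle_control(blocks, seed=cfg.seeds["shuffle"],
                                      max_lag=cfg.pacf_max_lag,
                                      skip_initial=cfg.pacf_skip_initial)
    model = sequential.fit_ar_ml(blocks, order=cfg.ar_order,
                                 skip_initial=cfg.pacf_skip_initial)
    ma = sequential.ar_to_ma(sequential.ARModel(model.weights[:3]))
    pd.DataFrame({
        "lag": pr.lags, "pacf": pr.coefficients, "pacf_se": pr.stderr,
        "pacf_shuffled": shuf.coefficients,
    }).to_csv(out / "pacf.tsv", sep="\t", index=False)
    pd.DataFrame({"lag": np.arange(1, model.order + 1),
                  "weight": model.weights,
                  "stderr": model.stderr}).to_csv(
        out / "ar_weights.tsv", sep="\t", index=False)
    pd.DataFrame({"i": np.arange(len(ma.b)), "b": ma.b}).to_csv(
        out / "ma_weights.tsv", sep="\t", index=False)
    spatial = sequential.spatial_summary(table)
    spatial.table.to_csv(out / "spatial_summary.tsv", sep="\t")
    return {
        "ar_weights": model.weights.tolist(),
        "mean_gain": ma.mean_gain, "sd_gain": ma.sd_gain,
        "spatial_F": spatial.f_statistic, "spatial_p": spatial.p_value,
        "spatial_df": [spatial.df_effect, spatial.df_error],
    }


def _stage_optimality(cfg, out: Path) -> dict:
    model = optimality.UtilityModel(**cfg.optimality_model)
    sol = optimality.solve_optimal_time(model)
    grid = np.asarray(cfg.epsilon_grid) if cfg.epsilon_grid else None
    pl = optimality.power_law_fit(model, grid)
    pd.DataFrame({"epsilon": pl.epsilon_grid, "t_star": pl.t_star}).to_csv(
        out / "optimal_times.tsv", sep="\t", index=False)
    return {"t_star": sol.t_star, "t_min": sol.t_min,
            "rate_star": sol.rate_star, "power_law_k": pl.k,
            "power_law_a": pl.a_coef}


def run(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report bundle (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seeds": config.seeds}
    stages = [("simulate", _stage_simulate)]
    try:
        table = _stage_simulate(config, out)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", "E_SIM", str(e)) from e
    try:
        rates, masks, fits, labels, stats_df = _stage_preprocess(config, table, out)
    except Exception as e:
        raise StageError("preprocess", "E_PRE", str(e)) from e
    if config.clone_family:
        try:
            table = synthetic.clone_parametric(
                table, config.clone_family, fits, seed=config.seeds["clone"])
            synthetic.write_trial_table(table, out / "trials_clone.tsv")
            base_labels = labels
            rates, masks, fits, labels, stats_df = _stage_preprocess(
                config, table, out)
            # the clone replays the same blocks, so group membership stays
            # with the base experiment's truncation classes
            labels = base_labels
            report["clone_family"] = config.clone_family
        except Exception as e:
            raise StageError("clone", "E_CLONE", str(e)) from e
    try:
        report["group"] = _stage_group(config, rates, masks, fits, labels, out)
    except Exception as e:
        raise StageError("group", "E_GRP", str(e)) from e
    try:
        report["sequential"] = _stage_sequential(
            config, table, rates, masks, labels, out)
    except Exception as e:
        raise StageError("sequential", "E_SEQ", str(e)) from e
    try:
        report["optimality"] = _stage_optimality(config, out)
    except Exception as e:
        raise StageError("optimality", "E_OPT", str(e)) from e
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
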