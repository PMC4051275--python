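#!/usr/bin/env python
"""Group rate-distribution analysis: is rate Normal, truncated Normal, or
reciprocal inverse Gaussian?

Dithers and reciprocal-transforms the trial table, fits each block's
left-truncated Normal by ML, classifies blocks by coefficient of variation
(threshold 0.4), standardizes trials into z-scores by their block's ML
moments, collapses, and reads Normality off the 5-95% probit band.  Two
parametric surrogates of the same blocks calibrate the diagnostic: rates
drawn from the fitted reciprocal truncated Normal should land on the probit
line; rates from an inverse Gaussian (first-passage-time) fit should bend
away from it and skew right.
"""

import json
from pathlib import Path

import pandas as pd
from scipy import stats

from ratedomain import preprocess as pp
from ratedomain import synthetic as sy
from ratedomain import truncmle as tm

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def analyze(table, labels=None, dither_seed=2):
    rates, masks, _ = pp.block_rate_series(table, seed=dither_seed)
    kept = {k: rates[k][masks[k]["keep"]] for k in rates}
    fits = {k: tm.fit_truncated_normal(v) for k, v in kept.items()}
    if labels is None:
        labels = dict(zip(fits, pp.classify_blocks(fits.values())))
    out = {}
    for group in ("untruncated", "truncated"):
        pool = pp.standardize_and_collapse(kept, fits, group, labels)
        pr = pp.probit_coordinates(pool)
        out[group] = {"n": int(pool.size), "slope": pr["slope"],
                      "intercept": pr["intercept"],
                      "band_r2": pr["r_squared"],
                      "skewness": float(stats.skew(pool))}
    return out, fits, labels


def main() -> None:
    table = sy.read_trial_table(OUT / "trials.tsv")
    report = {}
    report["empirical"], fits, labels = analyze(table)

    rect = sy.clone_parametric(table, "rectrN", fits, seed=31)
    report["rectrN_surrogate"], _, _ = analyze(rect, labels, dither_seed=32)

    ig = sy.clone_parametric(table, "IG", seed=33)
    report["IG_surrogate"], _, _ = analyze(ig, labels, dither_seed=34)

    (OUT / "group_distribution.json").write_text(json.dumps(report, indent=2))
    df = pd.DataFrame({(k, g): v for k, r in report.items()
                       for g, v in r.items()}).T
    print(df.round(4).to_string())
    r2r = report["rectrN_surrogate"]["untruncated"]["band_r2"]
    r2i = report["IG_surrogate"]["untruncated"]["band_r2"]
    print(f"\nReciprocal-Normal surrogate probit band R^2 = {r2r:.5f} "
          f"(linear: Normal rate); IG surrogate R^2 = {r2i:.5f} with skewness "
          f"{report['IG_surrogate']['untruncated']['skewness']:.2f} "
          "(visibly non-Normal) - the rate domain separates the two models.")


if __name__ == "__main__":
    main()
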