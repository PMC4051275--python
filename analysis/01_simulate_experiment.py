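#!/usr/bin/env python
"""Simulate the study-design experiment and summarize what it recorded.

Generates the 24-subject x 4-block x 200-trial two-alternative choice
experiment (conditions AE/AD/UE/UD) with AR(3) rate dynamics, time-out
censoring at 60 s, millisecond quantization and laterality-history effects in
the easy conditions, then writes the trial table and per-condition summary.
"""

from pathlib import Path

import pandas as pd

from ratedomain import synthetic as sy

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = sy.SynthConfig(seed=SEED)
    table = sy.generate_experiment(cfg)
    sy.write_trial_table(table, OUT / "trials.tsv")

    summary = table.groupby("condition").agg(
        n=("rt_ms", "size"),
        median_rt_ms=("rt_ms", "median"),
        error_rate=("correct", lambda c: 1.0 - c.mean()),
        timeout_rate=("timed_out", "mean"),
    )
    summary.to_csv(OUT / "condition_summary.tsv", sep="\t")
    print(f"wrote {len(table)} trials for {table['subject'].nunique()} subjects")
    print(summary.round(4).to_string())
    print("\nEasy blocks respond in ~300 ms with ~1% errors; difficult blocks "
          "slow several-fold, err ~24%, and occasionally hit the 60-s time-out "
          "- the left-censoring the truncated-Normal analysis must absorb.")


if __name__ == "__main__":
    main()
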