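#!/usr/bin/env python
"""Spatial (repeat/alternate) sequential dependency.

Codes each trial's 4-lag laterality history as a binary integer (repeat -> 0,
alternate -> 1, earliest transition most significant: RRRR=0 ... AAAA=15) and
asks whether mean rate depends on the code, separately for easy and difficult
conditions.  The generator injects small negative rate offsets at codes 1, 9
and 14 (RRRA, ARRA, AAAR) in the easy conditions only, so the analysis should
find a significant effect there and none in the difficult conditions.
"""

import json
from pathlib import Path

from ratedomain import sequential as sq
from ratedomain import synthetic as sy

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = sy.read_trial_table(OUT / "trials.tsv")
    results = {}
    for name, conds in [("easy", ("AE", "UE")), ("difficult", ("AD", "UD"))]:
        sp = sq.spatial_summary(table, conditions=conds)
        sp.table.round(5).to_csv(OUT / f"spatial_{name}.tsv", sep="\t")
        results[name] = {"F": round(sp.f_statistic, 3),
                         "df": [sp.df_effect, sp.df_error],
                         "p": sp.p_value, "n_trials": sp.n_trials}
        print(f"{name}: F({sp.df_effect},{sp.df_error}) = "
              f"{sp.f_statistic:.2f}, p = {sp.p_value:.2e}")
        if name == "easy":
            t = sp.table["mean_rate"]
            lows = t.nsmallest(3).index.tolist()
            print(f"  slowest codes: {lows} (injected: [1, 9, 14])")
    (OUT / "spatial_summary.json").write_text(json.dumps(results, indent=2))
    print("\nHistory dependence is detected in the easy conditions and "
          "absent in the difficult ones, dissociating the spatial effect "
          "from the (condition-independent) temporal AR process.")


if __name__ == "__main__":
    main()
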