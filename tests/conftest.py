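import numpy as np
import pytest

from ratedomain import preprocess, synthetic, truncmle

AR_WEIGHTS = (0.222, 0.104, 0.076)


@pytest.fixture(scope="session")
def experiment_table():
    """One full-scale synthetic experiment (24 subjects x 4 blocks x 200
    trials) under the default study conditions."""
    return synthetic.generate_experiment(synthetic.SynthConfig(seed=20_260_101))


@pytest.fixture(scope="session")
def block_data(experiment_table):
    """Dithered per-block rate series with truncated-Normal ML fits and
    truncation-class labels for the session experiment."""
    rates, masks, counts = preprocess.block_rate_series(
        experiment_table, seed=424_242)
    kept = {k: rates[k][masks[k]["keep"]] for k in rates}
    fits = {k: truncmle.fit_truncated_normal(v) for k, v in kept.items()}
    labels = dict(zip(fits, preprocess.classify_blocks(fits.values())))
    return {"rates": rates, "masks": masks, "counts": counts,
            "kept": kept, "fits": fits, "labels": labels}


@pytest.fixture(scope="session")
def untruncated_blocks(block_data):
    """Rate arrays of untruncated blocks with censored/anticipatory trials
    as NaN (lag adjacency preserved), ready for AR fitting."""
    out = []
    for k, r in block_data["rates"].items():
        if block_data["labels"][k] != "untruncated":
            continue
        arr = r.copy()
        m = block_data["masks"][k]
        arr[m["timed_out"] | ~m["keep"]] = np.nan
        out.append(arr)
    return out
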