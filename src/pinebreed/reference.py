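"""Published reference tables from the Spanish stone pine breeding programme.

These small tables are the published per-clone genotyping-replicate
statistics for the 15 registered clones and the clone-level BLUP summary of
the fully replicated clonal test (99 clones at one site).  They serve as
fixed reference inputs for summary arithmetic (error-rate summaries,
selection-gain percentages) and as calibration anchors for the synthetic
generator defaults; the underlying individual-level data are not shipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gpred import gain_percent

#: Genotyping statistics of the 15 registered clones: number of retained
#: ramet genotypes, mean proportion of complete genotypes, mean mismatches
#: against the clonal consensus and the resulting per-clone error rate.
REGISTERED_CLONE_GENOTYPING = pd.DataFrame(
    [
        ("c1011", 7, 0.970, 3, 0.001, "ES1"),
        ("c1012", 5, 0.959, 4, 0.002, "ES1"),
        ("c1073", 12, 0.965, 15, 0.006, "ES1"),
        ("c1123", 12, 0.959, 10, 0.004, "ES1"),
        ("c1201", 11, 0.958, 11, 0.005, "ES1"),
        ("c2004", 10, 0.948, 33, 0.014, "ES2"),
        ("c2048", 13, 0.960, 13, 0.006, "ES2"),
        ("c2068", 10, 0.952, 28, 0.012, "ES2"),
        ("c3029", 11, 0.962, 13, 0.005, "ES3"),
        ("c3048", 12, 0.955, 11, 0.005, "ES3"),
        ("c3057", 11, 0.955, 9, 0.004, "ES3"),
        ("c3063", 11, 0.961, 14, 0.006, "ES3"),
        ("c6010", 11, 0.960, 12, 0.005, "ES6"),
        ("c6015", 10, 0.957, 8, 0.004, "ES6"),
        ("c6053", 12, 0.967, 6, 0.003, "ES6"),
    ],
    columns=["clone_id", "n_genotypes", "prop_complete", "mismatches", "error_rate", "region"],
).set_index("clone_id")

#: Clone-level BLUP summary for the fully replicated clonal test:
#: cohort mean, registered-clone subset mean and top-decile mean (with SD),
#: for number of cones (NC) and mean cone weight in grams (MCW).
CLONAL_TEST_BLUP_SUMMARY = pd.DataFrame(
    {
        "subset": ["all", "registered", "top10"],
        "n": [99, 15, 10],
        "nc_mean": [31.26, 37.41, 51.67],
        "nc_sd": [9.75, 9.92, 4.74],
        "mcw_mean": [267.61, 276.58, 321.67],
        "mcw_sd": [30.27, 29.06, 10.35],
    }
).set_index("subset")


def error_rate_summary() -> dict:
    """Mean and maximum registered-clone genotyping error rate, in percent."""
    rates = REGISTERED_CLONE_GENOTYPING["error_rate"].to_numpy() * 100.0
    return {
        "mean_pct": float(np.round(rates.mean(), 1)),
        "max_pct": float(np.round(rates.max(), 1)),
        "n_clones": len(rates),
    }


def published_selection_gains() -> dict:
    """Selection-gain percentages implied by the published BLUP summary.

    Percentage advantage of the top-decile and registered-clone subsets
    over the cohort mean, per trait, rounded to the nearest integer.
    """
    out = {}
    tbl = CLONAL_TEST_BLUP_SUMMARY
    for trait in ("nc", "mcw"):
        all_mean = tbl.loc["all", f"{trait}_mean"]
        for subset in ("top10", "registered"):
            g = gain_percent(tbl.loc[subset, f"{trait}_mean"], all_mean)
            out[f"{trait}_{subset}_gain_pct"] = int(round(g))
    return out
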