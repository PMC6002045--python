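#!/usr/bin/env python
"""Run the full analysis: thin → screen → background → candidate grid →
rank → best-model fit → MTSPS threshold → classify → overlay → areas.

Writes every artifact (ranked candidate tables, lambdas files, suitability
and class rasters, risk maps, area and change summaries, run log) under
results/run/ and prints the headline numbers: the winning candidate per
species, its CV statistics, the MTSPS thresholds, and the percent change of
each risk class between the current climate and each future slice.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import CONFIG, RUN_DIR

from sdmrisk.pipeline import run_all


def main() -> None:
    run_all(CONFIG)
    log = json.load(open(os.path.join(RUN_DIR, "run_log.json")))
    print(f"retained predictors: {log['stages']['select_variables']['retained']}")
    for role in ("pest", "host"):
        s = log["stages"][f"model_{role}"]
        b = s["best"]
        print(f"{role}: best {b['features']} RM {b['rm']} | "
              f"AUC_cv {b['auc_cv']:.3f} OR0 {b['or0']:.4f} OR10 {b['or10']:.4f} | "
              f"MTSPS t = {s['mtsps_threshold']:.3f} | thinned "
              f"{log['stages']['thin'][role]['before']} -> "
              f"{log['stages']['thin'][role]['after']}")
    ch = pd.read_csv(os.path.join(RUN_DIR, "change_stats.csv"))
    for _, r in ch.iterrows():
        if not r["defined"]:
            continue
        word = "extension" if r["change_percent"] > 0 else "shortening"
        print(f"{r['future_slice']} {r['class']}: {word} of "
              f"{abs(r['change_percent']):.0f}% "
              f"({r['area_current_km2']:.0f} -> {r['area_future_km2']:.0f} km²)")


if __name__ == "__main__":
    main()
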