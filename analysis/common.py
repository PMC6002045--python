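"""Shared configuration for the numbered analysis drivers.

One mid-sized synthetic study: a 40×40 one-degree window, 500 presences per
species, 5,000 bias-weighted background points, the full published
feature-set grid at a reduced knot count, 5 CV folds, and two warmed future
slices. Sized to finish in minutes on one CPU; all stage logic lives in the
sdmrisk package.
"""

import os

from sdmrisk.pipeline import RunConfig, SyntheticSpec
from sdmrisk.synthetic import TruthParams

RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results")
RUN_DIR = os.path.join(RESULTS_DIR, "run")
INPUT_DIR = os.path.join(RUN_DIR, "inputs")

CONFIG = RunConfig(
    outdir=RUN_DIR,
    seed=20_18,
    background_n=5_000,
    bias_bandwidth_km=1_500.0,
    feature_sets=["LQPH", "LQPTH", "LQH", "LQP", "LH", "LQPT"],
    rms=[1.0, 1.5, 2.0],
    folds_k=5,
    n_hinge_knots=8,
    n_threshold_knots=8,
    synthetic=SyntheticSpec(
        shape=(40, 40),
        pest=TruthParams(n_presence=500, seed=1),
        host=TruthParams(temp_optimum=20.1, temp_sd=4.3, n_presence=500, seed=2),
        future_slices={
            "2050": {"delta_temp": 1.5, "precip_scale": 0.95},
            "2070": {"delta_temp": 2.0, "precip_scale": 0.90},
        },
    ),
)
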