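#!/usr/bin/env python
"""Generate the synthetic study system and write its inputs to disk.

Produces, under results/run/inputs/: current-climate rasters (ESRI ASCII),
two warmed future slices, occurrence CSVs for a warm-adapted pest (thermal
optimum 23.8 °C) and a cooler-adapted host crop (20.1 °C), and a JSON truth
manifest recording the generator parameters, so later stages can be checked
against the known truth.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import CONFIG, INPUT_DIR

from sdmrisk.grids import write_grid
from sdmrisk.pipeline import _load_occurrences, _load_stacks


def main() -> None:
    os.makedirs(INPUT_DIR, exist_ok=True)
    stacks = _load_stacks(CONFIG)
    for label, stack in stacks.items():
        for name, grid in stack.layers.items():
            write_grid(grid, os.path.join(INPUT_DIR, f"{name}_{label}.asc"))
    occs = _load_occurrences(CONFIG, stacks, INPUT_DIR)
    for role, occ in occs.items():
        occ.to_csv(os.path.join(INPUT_DIR, f"occurrences_{role}.csv"))
    manifest = {
        "seed": CONFIG.seed,
        "shape": list(CONFIG.synthetic.shape),
        "pest": vars(CONFIG.synthetic.pest),
        "host": vars(CONFIG.synthetic.host),
        "future_slices": CONFIG.synthetic.future_slices,
    }
    with open(os.path.join(INPUT_DIR, "truth_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    t = stacks["current"]["bio1"].values
    print(f"wrote {len(stacks)} climate slices ({t.shape[0]}x{t.shape[1]} cells, "
          f"bio1 range {t.min():.1f}..{t.max():.1f} °C) and "
          f"{', '.join(f'{len(o)} {r} presences' for r, o in occs.items())} "
          f"to {INPUT_DIR}")


if __name__ == "__main__":
    main()
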