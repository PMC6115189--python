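#!/usr/bin/env python
"""Generate the synthetic study data for all three regimes.

Emits, per regime (control, xdd1_like, pk2dpdl_like): the mesh time series,
junction/cytoplasm trace tables, planted ground truth, and the early/late
cell-shape epochs, under results/data/<regime>/.
"""

from pathlib import Path

from pcpdyn.core_model import save_mesh, save_traces
from pcpdyn.presets import PRESET_NAMES, load_preset
from pcpdyn.synthetic_tissue import (
    generate_intensities,
    generate_reorientation_epochs,
    generate_tissue,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for preset in PRESET_NAMES:
        out = ROOT / "results" / "data" / preset
        out.mkdir(parents=True, exist_ok=True)
        cfg = load_preset(preset, seed=SEED)
        frames, gt = generate_tissue(cfg)
        traces, cyto = generate_intensities(frames, gt, cfg)
        early, late = generate_reorientation_epochs(cfg)
        save_mesh(frames, out / "mesh.json")
        save_traces(traces, out / "traces.csv")
        cyto.to_csv(out / "cytoplasm.csv", index=False)
        gt.to_json(out / "ground_truth.json")
        save_mesh([early], out / "epoch_early.json")
        save_mesh([late], out / "epoch_late.json")
        print(
            f"{preset}: {gt.n_cells} cells, {len(frames)} frames, "
            f"{traces['junction_id'].nunique()} junction traces, "
            f"{len(gt.t1_events)} planted T1s, {len(gt.rosette_events)} rosettes"
        )


if __name__ == "__main__":
    main()
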