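"""Small end-to-end cohort: generate, quantify, report.

A 2 x 2 design (shape x state, 3 cells each) run through the pipeline;
prints the per-condition summary table that mirrors how cohorts of
patterned cells are reported (median-of-medians FRET, IQR, spacing, S).
"""

from sarcomech.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    seed=1, output_dir="scratch/example06",
    stages={"simulate": True, "quantify": True, "model": False, "report": True},
    dataset={"conditions": [
        {"name": "rect-contracted", "preset": "live-contracted",
         "shape": "rectangle", "n_cells": 3},
        {"name": "rect-relaxed", "preset": "live-relaxed",
         "shape": "rectangle", "n_cells": 3, "seed_offset": 50},
        {"name": "circ-contracted", "preset": "circle-contracted",
         "shape": "circle", "n_cells": 3, "seed_offset": 100},
        {"name": "circ-relaxed", "preset": "circle-relaxed",
         "shape": "circle", "n_cells": 3, "seed_offset": 150},
    ]})
report = run_pipeline(cfg)
print(report.conditions.to_string(index=False))
print("\ncontracted rectangles show the lowest FRET (tension on the z-disk)")
print("and the highest order parameter; circles stay near the relaxed level.")
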