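"""Generate one ground-truthed synthetic cardiomyocyte image pair.

Builds a striated rectangular cell (17 x 118 μm pattern) with the
live-contracted preset, writes the donor/acceptor TIFFs and prints the
ground truth: every rendered z-line knows its spacing, orientation and
FRET index, which is what makes the downstream measurements testable.
"""

from pathlib import Path

from sarcomech.io import write_channel
from sarcomech.synth import generate_cell

cell = generate_cell("live-contracted", seed=1)
out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)
write_channel(cell.donor, out / f"{cell.cell_id}_donor.tif")
write_channel(cell.acceptor, out / f"{cell.cell_id}_acceptor.tif")

truth = cell.truth_summary()
print(f"cell {cell.cell_id}: {truth['n_sarcomeres']} sarcomeres")
print(f"  true mean spacing : {truth['mean_spacing_um']:.3f} μm "
      "(preset cohort mean 1.63)")
print(f"  true median FRET  : {truth['median_fret_index']:.2f} index units "
      "(preset median 44.21)")
print(f"  true order param  : {truth['order_parameter']:.3f} "
      "(uniaxial cell, near 1)")
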