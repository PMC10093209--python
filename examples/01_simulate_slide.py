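"""Generate a synthetic six-channel multiplex slide with known ground truth.

The generator produces a grid of overlapping, jittered tiles; elliptical
nuclei with class-conditional log-normal intensities; and a smooth tumour
mask.  Everything downstream (alignment, features, models) is testable
against this truth.
"""

import numpy as np

import mifscore as m

config = m.SimulationConfig(seed=1)
tiles, truth = m.generate_slide(config)

print(f"tiles: {len(tiles)} of {tiles[0].size} px, overlap {tiles[0].overlap_px} px")
print(f"cells: {len(truth.cells)} (tumour fraction {truth.cells['cls'].mean():.2f})")
print(f"mask coverage: {truth.mask.mean():.2f}")
jitter = {
    gi: (ty - t.nominal_offset_px[0], tx - t.nominal_offset_px[1])
    for t, (gi, (ty, tx)) in zip(tiles, truth.tile_true_offsets.items())
}
print("per-tile jitter (true - nominal):", dict(list(jitter.items())[:4]), "...")
print("tumour cells are brighter in DAPI:",
      f"{truth.cells.loc[truth.cells.cls == 1, 'I_DAPI'].mean():.0f} vs",
      f"{truth.cells.loc[truth.cells.cls == 0, 'I_DAPI'].mean():.0f} (mean intensity)")
# The jitter values are what tile alignment must recover; the class-conditional
# intensity difference is what the cancer-score models must learn.
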