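"""Detect cells in the chlorophyll channel and measure both channels.

Simulates one field, segments it, and prints the per-cell table head.
The GFP statistics are computed under the *chlorophyll-derived* mask —
the mask transfer that lets untransformed (GFP-dark) cells be measured
at all, which is what makes the efficiency denominator meaningful.
"""

from greenseg import CountSpec, SimulationConfig, measure_cells, segment_chlorophyll
from greenseg.simulate import simulate_field

config = SimulationConfig(
    image_height_px=512,
    image_width_px=512,
    cells_per_field=CountSpec(mean=120, dispersion=8.0),
    true_positive_fraction=0.3,
    seed=11,
)
field, truth = simulate_field(config, 0, "B01")
mask = segment_chlorophyll(field)
records = measure_cells(field, mask)

print(f"simulated {len(truth)} cells, detected {mask.max()} "
      "(border cells excluded, residual clumps may merge)")
print(records[["label", "area_px", "chl_median", "gfp_median"]].head(8).round(1))
print("\nGFP-channel medians are bimodal in a p=0.3 field:")
print(records.gfp_median.describe().round(1).to_string())
# Untransformed cells sit near the background (~hundreds of counts),
# transformed ones orders of magnitude higher - the gap the wild-type
# percentile threshold will cut through.
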