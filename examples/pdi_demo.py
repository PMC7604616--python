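"""Peripheral Distribution Index on synthetic RNA spot patterns.

Builds one disk cell and samples spot patterns at three radial bias
exponents: perinuclear (beta = -2), diffuse (beta = 0) and peripheral
(beta = 4).  PDI = 1 marks a diffuse distribution; values above/below 1
mark peripheral/perinuclear localization.
"""

from zipquant.spatial import compute_pdi
from zipquant.synthetic import CellSimParams, SpotSimParams, gen_cell, gen_spots

cell = gen_cell(CellSimParams(image_size=256, cell_radius=100, nucleus_radius=30))

for beta, label in ((-2.0, "perinuclear"), (0.0, "diffuse"), (4.0, "peripheral")):
    spots = gen_spots(cell, SpotSimParams(n_spots=1000, bias_exponent=beta, seed=42))
    result = compute_pdi(cell, spots)
    print(f"beta = {beta:+.0f} ({label:11s}): PDI = {result.pdi:.3f}  (n = {result.n_spots})")

print(
    "\nPDI near 1 means the RNA is spread like the cytoplasm itself; the\n"
    "peripheral pattern scores well above 1, the perinuclear one well below."
)
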