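"""Scan synthetic 3'UTR groups for the RGAAGRR zipcode motif.

Generates two labeled UTR groups (a "localized" group with planted
motifs inside a planted GA-rich region, and a low-rate control group),
scans both for the degenerate consensus, calls GA-rich regions
(> 75% GA over >= 30 nt), and tests the two-group enrichment.
"""

from zipquant.motifs import (
    MotifSpec,
    RegionParams,
    detect_ga_rich_regions,
    motif_enrichment,
    motif_region_overlap,
    scan_motif,
    summarize_groups,
)
from zipquant.synthetic import RegionPlant, UtrSimParams, gen_utr_set

records, truth = gen_utr_set(
    UtrSimParams(n_per_group=40, region_plant=RegionPlant(length=171, ga_fraction=0.85), seed=11)
)

spec = MotifSpec()  # RGAAGRR, R = purine
per_utr, per_group = summarize_groups(records, spec, RegionParams())
print(per_group.to_string(index=False))

hits = [h for r in records for h in scan_motif(r, spec)]
regions = [g for r in records for g in detect_ga_rich_regions(r)]
overlap = motif_region_overlap(hits, regions)
print(
    f"\nmotifs inside GA-rich regions: {overlap.n_inside}/{overlap.n_total} "
    f"({100 * overlap.fraction:.0f}%)"
)

flags = {
    g: [bool(scan_motif(r, spec)) for r in records if r.group == g]
    for g in ("localized", "control")
}
res = motif_enrichment(flags["localized"], flags["control"])
print(f"Fisher two-sided p = {res.p_value:.2e} (odds ratio {res.odds_ratio:.1f})")
print(
    "\nThe localized group carries the motif more often than the control\n"
    "group (chance matches occur in both backgrounds), and its motifs often\n"
    "sit inside extended GA-rich regions — the sequence signature of\n"
    "protrusion-targeting zipcode elements."
)
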