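# zipquant

Quantification toolkit for studying how mRNAs are targeted to cell
protrusions by GA-rich 3′UTR "zipcode" elements, and what that
localization does downstream. It is written for cell biologists and
image/sequence analysts who have (i) 3′UTR sequences for groups of
transcripts that do or do not localize peripherally, (ii) single-molecule
FISH spot coordinates and cell/nucleus masks, (iii) proximity ligation
assay (PLA) images, and (iv) count tables from protrusion/cell-body
fractionation or RNA co-immunoprecipitation. Every analysis is paired
with a synthetic-data generator that records its ground truth, so the
whole pipeline can be validated closed-loop without any external data.

## What it computes

**Zipcode sequence analysis.** Degenerate IUPAC motif scanning for the
7-nt consensus RGAAGRR (R = purine), reporting *all* occurrences,
overlapping included, in 1-based inclusive coordinates; sliding-window
%GA profiles (default W = 30 nt); GA-rich region calling as maximal
unions of windows with GA fraction strictly > 0.75; the fraction of
motifs fully contained in GA-rich regions; deletion constructs with
coordinate remapping of surviving annotations; classification of 25-nt
antisense-probe (PMO) intervals against motifs and regions; and
two-group motif enrichment by Fisher's exact test (two-sided, by exact
hypergeometric enumeration) with Bonferroni correction.

**Peripheral Distribution Index (PDI).** For a spot pattern
{xᵢ} in a cell with nucleus centroid c,

    PDI = ⟨‖xᵢ − c‖²⟩_spots / ⟨‖p − c‖²⟩_cell pixels

i.e. the second moment of the spots about the nucleus centroid,
normalized by the same moment of the cell mask. PDI = 1 for a diffuse
(uniform) distribution, > 1 for peripheral and < 1 for perinuclear
patterns, 0 when all spots sit at the centroid. The statistic is
invariant to translation and isotropic rescaling of the scene.

**Compartment statistics.** Peripheral/perinuclear mean-intensity
ratios over distance-transform bands (default band width: 10% of the
cell's equivalent radius); PLA dot calling as 8-connected components of
pixels strictly above a robust background (median + k·1.4826·MAD,
default k = 3) with a minimum area, and per-compartment dot counts.

**Fractionation / RIP enrichment.** Protrusion/cell-body (Ps/CB)
ratios normalized per replicate to the geometric mean of a designated
housekeeping set; spike-normalized RIP enrichment
(eluate/input, referenced to a control gene); both aggregated as
mean ± s.e.m. across replicates, with normalizers canceling any
per-sample scaling.

## Worked example

```bash
python examples/pdi_demo.py
```

```
beta = -2 (perinuclear): PDI = 0.183  (n = 1000)
beta = +0 (diffuse    ): PDI = 0.989  (n = 1000)
beta = +4 (peripheral ): PDI = 1.499  (n = 1000)
```

One synthetic disk cell (radius 100 px, nucleus 30 px), three spot
patterns sampled with radial bias exponent β (sampling weight ∝
(d/d_max)^β): the diffuse pattern scores ≈ 1, the perinuclear one well
below, the peripheral one well above — exactly the contrast used to read
localization phenotypes off FISH images.

```bash
python examples/fractionation_demo.py
```

```
Ps/CB enrichment (housekeeping-normalized, mean +/- sem over 3 replicates):
  RAB13   3.06 +/- 0.12 (true 3.0)
  NET1    2.08 +/- 0.03 (true 2.0)
  CTRL    1.03 +/- 0.03 (true 1.0)
...
RIP enrichment of GFP over GAPDH (spike-normalized): 10.0x
```

Poisson-noisy counts with deliberately unequal library sizes: the
normalized estimator recovers the planted enrichment ratios.

The other examples cover motif/region scanning on two UTR groups
(`scan_zipcode_motifs.py`), PLA dot counting (`pla_demo.py`) and the
config-driven end-to-end pipeline with a checksummed run manifest
(`full_pipeline.py`). A thin CLI exposes the same operations on files:
`zipquant --help`.

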