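# Methods

This note documents the models, estimators and numerical choices behind
zipquant, what the synthetic generators do and do not emulate, and the
package's known limitations.

## Sequence analysis

**Coordinates.** All sequence coordinates are 1-based inclusive
(position 1 = first nucleotide of the supplied 3′UTR), which makes
deletion arithmetic read naturally (deleting 204–211 removes 8 nt).
BED export converts to 0-based half-open. Input sequences are
case-folded and U-mapped to T; any residue other than A/C/G/T is
rejected with its position — the analysis operates on resolved mRNA
sequence, and a degenerate input base would make motif matching
ill-defined.

**Motif scanning.** A position matches a degenerate consensus iff every
sequence character lies in the IUPAC set of the corresponding consensus
character (R = {A,G}, etc.; sets taken from Biopython's table, restricted
to the 15 standard codes). All occurrences are reported, overlapping
ones included: with no published overlap policy for motif counts, the
all-occurrences rule is the conservative choice and the one a brute-force
oracle can check exactly. Scanning is single-stranded; the reverse
complement is never considered, since the input is mRNA sense sequence.

**GA windows and regions.** The %GA profile uses a 30-nt window, step 1,
computed from a cumulative-sum array. GA-rich regions are maximal merged
unions of windows whose GA fraction is strictly greater than the
threshold (default 0.75). Strictness matters at exact ties
(24/30 = 0.80 is *not* > 0.80); because the count is an integer, the
comparison snaps the float product θ·W to the nearest integer when it is
within 1e-9 of one, making the tie decision exact for any rational-like
threshold. A documented consequence of the union-of-windows definition:
regions can extend a few nucleotides into flanking pyrimidine sequence
(a pure GA run of 40 nt embedded in T's yields a region wider than the
run itself). `min_len` (≥ W) can filter short regions; with the default
`min_len = W` every merged union qualifies.

**Overlap semantics.** A motif counts as "inside" a GA-rich region only
when its full 7-nt span is contained in the region (the statistic asks
whether motifs *lie within* extended GA-rich context). Antisense-probe
classification instead uses any-overlap (≥ 1 nt) semantics: a 25-nt
probe need only cover part of a motif to block it. Probes are always
specified by explicit coordinates, never parsed from probe names.

**Enrichment.** The two-group test builds a 2×2 table (group ×
has-motif) and computes the two-sided Fisher exact p by summing, at
fixed margins, the hypergeometric probabilities of all tables whose
probability is at most the observed table's. The tail comparison is done
on exact integer weights, so probability ties are handled without
floating-point ambiguity; a test cross-checks against
`scipy.stats.fisher_exact`. Bonferroni correction is min(1, m·p) with
m = 1 by default — the number of tests is context the caller must
supply. The odds ratio is the sample odds ratio ad/bc (∞ when only the
denominator vanishes, NaN for 0/0).

**Deletions.** Deletion intervals must be non-overlapping and in range.
Annotations overlapping a deleted interval are dropped with a warning;
surviving annotations shift left by the total deleted length upstream of
them. A property test verifies that rescanning a spliced record equals
brute-force scanning of the literally spliced string.

## Spatial statistics

**PDI.** Implemented as the mean squared distance of spots from the
nucleus centroid divided by the mean squared distance of all cell-mask
pixels from the same centroid. This reconstruction satisfies the
statistic's defining anchors — exactly 1 in expectation for spots
uniform over the mask, 0 when all spots sit at the centroid, ≈ 2 for
spots on the boundary of a disk cell (mean r² over a disk of radius R is
R²/2) — and is invariant to translation and isotropic rescaling. Whether
the distance origin should be the nucleus centroid, cell centroid or
nucleus boundary is genuinely open; the nucleus centroid matches the
perinuclear-vs-peripheral contrast the statistic is used to read out,
and the choice is documented rather than asserted as the canonical
formula.

`compute_pdi` accepts an optional closed-form reference second moment
for analytically known geometries. This matters for validation: the
raster denominator of a disk of radius R converges to R²/2 only slowly
(relative error ≈ 3·10⁻⁴ at R = 200 px, set by boundary-pixel
quantization), so closed-form checks at tight tolerance run through the
continuum reference while a separate assertion tracks the raster
estimate's convergence. Scale invariance is likewise exercised on the
formula's inputs (spot coordinates and reference moment scaled jointly,
plus exact integer translation of the raster scene), because
re-rasterizing a scaled disk does not reproduce the same pixel set.

**Compartment bands.** The peripheral band is the set of cell pixels
within w_p of the cell boundary (Euclidean distance transform of the
cell mask); the perinuclear band is the set of cytoplasmic pixels within
w_n of the nucleus boundary. Defaults: w_p = w_n = 10% of the cell's
equivalent radius √(area/π) — unspecified in the source protocol, chosen
as a scale-free default and configurable everywhere. Overlapping bands
are an error, not silently partitioned. Dots/spots are assigned by
center-point membership; partial-overlap assignment was rejected for
determinism.

**PLA dot calling.** Background is estimated robustly over the cell mask
as (median, 1.4826·MAD), so the dots themselves do not inflate the
estimate (with ≲ 1% of pixels occupied by dots, median and MAD are
essentially unaffected). Candidate pixels must exceed the threshold
strictly — a dot whose peak sits exactly at median + k·SD is not called —
and are grouped 8-connected; components smaller than `min_dot_area`
(default 4 px) are discarded, which suppresses single-pixel Gaussian
excursions (null calibration in the tests: < 1 false dot/cell averaged
over 100 noise-only images at defaults). A flat image (SD = 0) is an
error rather than a division by zero. Analysis is strictly 2D, intended
for maximum-intensity projections.

## Fractionation / RIP estimators

Per replicate, Ps/CB enrichment of gene g is
(Ps_g/G_Ps)/(CB_g/G_CB) with G the geometric mean of the designated
housekeeping set (the geometric mean is the standard compositional
choice and makes single-sample rescaling cancel exactly). The
housekeeping set is a required input — there is no defensible default.
RIP enrichment first normalizes each gene's eluate and input counts to
the spike row, then references the target's recovery to a control
gene's; any constant factor applied to one sample cancels. Replicates
with zero normalizer counts are excluded with a warning; a zero
reference-fraction count makes that gene's replicate ratio NaN (flagged)
rather than infinite. Aggregation is arithmetic mean ± s.e.m.
(sd/√n, ddof = 1) across replicates, matching how such ratios are
conventionally reported; no log transform is applied by default.

## Synthetic data: what it emulates, and what it does not

The generators define the test conditions; their defaults are fixed
once and documented here.

- **UTR sets** — two groups of 50 UTRs, lengths 300–1500 nt (the span of
  typical mammalian 3′UTRs), i.i.d. uniform base background. Planted
  RGAAGRR copies per UTR are Poisson with rate 1.0 in the localized
  group (P(≥1) ≈ 63%, emulating the observed "majority of localized
  transcripts carry it") and 0.15 in the control group. An optional
  GA-rich region (default 171 nt, matching the span of the
  nts 98–268 region of the human RAB13 3′UTR; GA fraction 0.85 with
  evenly spaced pyrimidines so every internal 30-nt window stays above
  threshold) is planted per localized-group UTR. Truth records planted
  features only; an i.i.d. background of this composition produces
  chance consensus matches (P ≈ 5·10⁻⁴ per position, i.e. a sizable
  minority of control UTRs carry a chance hit), so recall of planted
  features is testable but the planted/background distinction of any
  individual hit is not — real UTRs differ in composition, covariation
  and repeat structure, none of which is modeled.
- **Cells** — concentric or offset disks. Real protrusive cells are
  strongly non-convex; the disk geometry isolates the statistics from
  segmentation questions (out of scope) and makes closed-form checks
  possible. Pixel centers at integer coordinates; a pixel belongs to a
  disk when its center does.
- **Spots** — support pixels sampled with weight ∝ (d/d_max)^β
  (distance from the nucleus centroid, clipped below at 0.5 px so
  negative exponents stay finite), then jittered uniformly within the
  pixel. β is the minimal one-parameter family spanning
  perinuclear/uniform/peripheral; it does not model clustering,
  transport tracks, or spot-detection noise. At β = 0 the spot pattern
  is uniform over the mask, so the PDI estimator is unbiased there by
  construction.
- **PLA images** — Gaussian background (mean 100, SD 10, clipped at 0)
  plus hard disks (radius 2 px) at background + amplitude (default 100
  = 10 SD); dot centers are kept ≥ 2r+3 px apart and fully inside the
  cell so planted dots are resolvable as distinct components. No PSF
  convolution: the downstream calling is threshold-based, not subpixel,
  so blur would add realism without changing what is being tested.
  A `band_fraction` parameter shares the peripheral-band definition with
  the classifier.
- **Counts** — expected count = baseline (1000) × per-sample size factor
  × (true ratio in the enriched fraction), optional Poisson noise,
  housekeeping and spike rows with ratio 1; 3 replicates by default.
  No over-dispersion beyond Poisson and no probe-efficiency effects.

Determinism: every generator takes an explicit seed; the pipeline
derives per-stage seeds from one master seed by fixed offsets, and
re-running with the same config + seed reproduces byte-identical outputs
(checksummed in the run manifest).

Passing tests on these conditions show the estimators are correct and
well-calibrated *given* segmented cells, detected spots and clean count
tables; they do not validate segmentation, spot detection, or behavior
on real microscope noise.

## Problem sizes used in the validation suite

Oracle equivalence runs on 1,000 random sequences of length ≤ 200;
Fisher enumeration covers all 2×2 tables with n ≤ 30; PDI calibration
uses a radius-100 cell with 500–2,000 spots over 10–20 seeds (closed-form
disk checks at radius 200–400); PLA null calibration uses 100 noise-only
images; fractionation recovery uses 50 Poisson replicates at baseline
1,000 counts. These sizes give the Monte-Carlo assertions comfortable
statistical margins at sub-minute runtimes.

## Limitations

- No de novo motif discovery, position weight matrices or RNA secondary
  structure; the motif layer is match/count/enrich on a given consensus.
- No cell segmentation, FISH spot detection from raw images, or 3D
  statistics; spots arrive as coordinates, cells as masks.
- PDI here is a documented reconstruction of a peripheral-dispersion
  index, not a certified reimplementation of any specific published
  calculator.
- Group-comparison inferential statistics beyond the Fisher enrichment
  (ANOVA families, multiple-comparison procedures across conditions) are
  deliberately left to downstream tools; outputs are tidy tables.
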