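"""Synthetic data with recorded ground truth for every analysis stage.

Generators for labeled 3'UTR sequence sets with planted zipcode motifs
and GA-rich regions, disk-based cell geometries, radially biased RNA spot
patterns, PLA-like images with planted dots, and fractionation count
tables with known enrichment ratios.  Each generator is deterministic
under a fixed seed and returns its ground truth alongside the data, so
the downstream analysis can be validated closed-loop.

The radial spot model uses a single bias exponent beta: sampling weight
w(x) proportional to (d(x)/d_max)^beta where d is the distance from the
nucleus centroid.  beta = 0 is uniform over the support, beta > 0 pushes
spots toward the periphery, beta < 0 concentrates them perinuclearly —
the minimal one-parameter family spanning the qualitative patterns seen
in FISH images of localized transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .motifs import MotifSpec, UtrRecord
from .spatial import CellGeometry, SpotSet, peripheral_band

__all__ = [
    "UtrSimParams",
    "RegionPlant",
    "CellSimParams",
    "SpotSimParams",
    "PlaSimParams",
    "FractionSimParams",
    "gen_utr_set",
    "gen_cell",
    "gen_spots",
    "gen_pla_image",
    "gen_fraction_counts",
    "derive_seed",
]

_PYRIMIDINES = ("C", "T")


def derive_seed(master_seed: int, offset: int) -> int:
    """Derive a per-stage seed from a master seed by a fixed offset."""
    return (int(master_seed) + int(offset)) % (2 ** 31)


@dataclass(frozen=True)
class RegionPlant:
    """A GA-rich region to plant: length (>= 30 nt) and target GA
    fraction (> 0.75).  Pyrimidines are spaced evenly so that every
    30-nt window inside the planted region stays above the threshold."""

    length: int = 171
    ga_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.length < 30:
            raise ValueError("planted region length must be >= 30 nt")
        if not 0.75 < self.ga_fraction < 1.0:
            raise ValueError("planted region GA fraction must be in (0.75, 1)")


@dataclass(frozen=True)
class UtrSimParams:
    """Two-group 3'UTR simulation.

    Group sizes, UTR length range, i.i.d. background base composition,
    and expected planted motif copies per UTR for the localized and
    control groups (Poisson counts).  ``region_plant`` optionally plants
    one GA-rich region per localized-group UTR.  The defaults emulate the
    published contrast: roughly 60% of localized-group UTRs carry at
    least one planted motif (rate 1.0 => 1 - e^-1 ~ 63%) against a low
    control rate.
    """

    n_per_group: int = 50
    length_range: tuple = (300, 1500)
    background_alphabet_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    motif_rate_localized: float = 1.0
    motif_rate_control: float = 0.15
    region_plant: Optional[RegionPlant] = None
    group_labels: tuple = ("localized", "control")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length_range must satisfy 30 <= min <= max")
        w = self.background_alphabet_weights
        if set(w) != set("ACGT"):
            raise ValueError("background weights must cover exactly A/C/G/T")
        if any(v < 0 for v in w.values()) or not math.isclose(
            sum(w.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background weights must be non-negative and sum to 1")
        if self.motif_rate_localized < 0 or self.motif_rate_control < 0:
            raise ValueError("motif rates must be >= 0")
        if len(self.group_labels) != 2:
            raise ValueError("exactly two group labels required")


def _region_pattern(rng: np.random.Generator, plant: RegionPlant) -> str:
    # Even pyrimidine spacing keeps every 30-nt window above threshold.
    spacing = max(2, round(1.0 / (1.0 - plant.ga_fraction)))
    bases = []
    for i in range(plant.length):
        if i % spacing == spacing - 1:
            bases.append(_PYRIMIDINES[rng.integers(2)])
        else:
            bases.append("AG"[rng.integers(2)])
    return "".join(bases)


def _motif_instance(rng: np.random.Generator, spec: MotifSpec) -> str:
    out = []
    for sets in spec.position_sets():
        choices = sorted(sets)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def gen_utr_set(
    params: UtrSimParams, spec: MotifSpec = MotifSpec()
) -> tuple[list[UtrRecord], list[dict]]:
    """Generate two labeled UTR groups with planted motifs/regions.

    Returns ``(records, truth)`` where truth holds, per record, the
    planted motif intervals (1-based inclusive, with the planted
    sequence) and the planted region interval, if any.  Truth lists
    planted features only: the i.i.d. background can, by chance, spell
    out additional consensus matches, so a rescan may find more hits than
    truth records — never fewer.
    """
    rng = np.random.default_rng(params.seed)
    weights = params.background_alphabet_weights
    bases = np.array(list("ACGT"))
    probs = np.array([weights[b] for b in "ACGT"], dtype=float)
    probs = probs / probs.sum()
    k = spec.length
    records: list[UtrRecord] = []
    truth: list[dict] = []
    for gi, (label, rate) in enumerate(
        zip(params.group_labels, (params.motif_rate_localized, params.motif_rate_control))
    ):
        for j in range(params.n_per_group):
            rec_id = f"{label}_{j + 1:03d}"
            lo, hi = params.length_range
            length = int(rng.integers(lo, hi + 1))
            seq = list(rng.choice(bases, size=length, p=probs))
            region_span = None
            if params.region_plant is not None and gi == 0:
                plant = params.region_plant
                if plant.length > length:
                    raise ValueError(
                        f"record {rec_id!r}: planted region ({plant.length} nt) "
                        f"longer than UTR ({length} nt)"
                    )
                rstart = int(rng.integers(1, length - plant.length + 2))
                pattern = _region_pattern(rng, plant)
                seq[rstart - 1 : rstart - 1 + plant.length] = list(pattern)
                region_span = (rstart, rstart + plant.length - 1)
            n_motifs = int(rng.poisson(rate))
            planted: list[tuple] = []
            if n_motifs > 0 and k > length:
                raise ValueError(
                    f"record {rec_id!r}: motif ({k} nt) longer than UTR "
                    f"({length} nt); cannot plant"
                )
            occupied: list[tuple] = []
            for _ in range(n_motifs):
                placed = False
                for _try in range(1000):
                    start = int(rng.integers(1, length - k + 2))
                    end = start + k - 1
                    if all(not (start <= oe and os_ <= end) for os_, oe in occupied):
                        placed = True
                        break
                if not placed:
                    break  # UTR too crowded; plant fewer copies
                inst = _motif_instance(rng, spec)
                seq[start - 1 : end] = list(inst)
                occupied.append((start, end))
                planted.append((start, end, inst))
            records.append(UtrRecord(rec_id, "".join(seq), label))
            truth.append(
                {
                    "id": rec_id,
                    "group": label,
                    "motifs": sorted(planted),
                    "region": region_span,
                }
            )
    return records, truth


@dataclass(frozen=True)
class CellSimParams:
    """Disk cell with a (possibly offset) disk nucleus, on a square image."""

    image_size: int = 256
    cell_radius: float = 100.0
    nucleus_radius: float = 30.0
    nucleus_offset: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius <= 0 or self.nucleus_radius <= 0:
            raise ValueError("radii must be > 0")
        ox, oy = self.nucleus_offset
        if math.hypot(ox, oy) + self.nucleus_radius > self.cell_radius:
            raise ValueError("nucleus must lie fully inside the cell")
        if self.cell_radius > (self.image_size - 1) / 2:
            raise ValueError("cell does not fit inside the image")


def gen_cell(params: CellSimParams) -> CellGeometry:
    """Rasterize a disk cell and nucleus as boolean masks.

    Pixel centers are at integer coordinates; a pixel belongs to a disk
    when its center lies within the radius.  The cell is centered on the
    image; the nucleus center is displaced by ``nucleus_offset`` (x, y).
    """
    n = params.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    cell = (xx - c) ** 2 + (yy - c) ** 2 <= params.cell_radius ** 2
    ox, oy = params.nucleus_offset
    nucleus = (xx - c - ox) ** 2 + (yy - c - oy) ** 2 <= params.nucleus_radius ** 2
    return CellGeometry(cell, nucleus)


@dataclass(frozen=True)
class SpotSimParams:
    """Radially biased spot sampling; see the module docstring for the
    bias model."""

    n_spots: int = 500
    bias_exponent: float = 0.0
    support: str = "whole_cell"  # or "cytoplasm_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if not math.isfinite(self.bias_exponent):
            raise ValueError("bias exponent must be finite")
        if self.support not in ("whole_cell", "cytoplasm_only"):
            raise ValueError("support must be 'whole_cell' or 'cytoplasm_only'")


def gen_spots(cell: CellGeometry, params: SpotSimParams) -> SpotSet:
    """Sample a spot pattern with radial bias exponent beta.

    Pixels of the support are sampled with probability proportional to
    (d / d_max)^beta (d = distance of the pixel center from the nucleus
    centroid, clipped below at half a pixel so negative exponents stay
    finite), then each spot is jittered uniformly within its pixel.
    """
    support = (
        cell.cell_mask
        if params.support == "whole_cell"
        else cell.cell_mask & ~cell.nucleus_mask
    )
    if not support.any():
        raise ValueError("empty spot support")
    rng = np.random.default_rng(params.seed)
    rows, cols = np.nonzero(support)
    if params.n_spots == 0:
        return SpotSet(np.empty((0, 2)), cell_id="sim")
    cx, cy = cell.nucleus_centroid
    d = np.hypot(cols - cx, rows - cy)
    beta = params.bias_exponent
    if beta == 0:
        p = None
    else:
        d_max = d.max()
        if d_max == 0:
            raise ValueError("degenerate support: all pixels at the centroid")
        w = (np.maximum(d, 0.5) / d_max) ** beta
        p = w / w.sum()
    idx = rng.choice(rows.size, size=params.n_spots, p=p)
    jitter = rng.uniform(-0.5, 0.5, size=(params.n_spots, 2))
    xy = np.column_stack([cols[idx] + jitter[:, 0], rows[idx] + jitter[:, 1]])
    return SpotSet(xy, cell_id="sim")


@dataclass(frozen=True)
class PlaSimParams:
    """PLA-like image: Gaussian background plus hard-disk dots.

    ``dot_region_split`` is the fraction of dots placed in the peripheral
    band (width = ``band_fraction`` of the cell's equivalent radius); the
    rest go to the cell body.  Dot disks are drawn at a constant level of
    background_mean + dot_amplitude, with no point-spread blur: the
    downstream dot calling is threshold-based, not subpixel.
    """

    background_mean: float = 100.0
    background_sd: float = 10.0
    n_dots: int = 10
    dot_amplitude: float = 100.0
    dot_radius: int = 2
    dot_region_split: float = 0.5
    band_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd <= 0:
            raise ValueError("background_sd must be > 0")
        if self.dot_amplitude < 0:
            raise ValueError("dot_amplitude must be >= 0")
        if not 0.0 <= self.dot_region_split <= 1.0:
            raise ValueError("dot_region_split must be in [0, 1]")
        if self.n_dots < 0 or self.dot_radius < 1:
            raise ValueError("n_dots must be >= 0 and dot_radius >= 1")


def gen_pla_image(
    cell: CellGeometry, params: PlaSimParams
) -> tuple[np.ndarray, list[dict]]:
    """Render a PLA-like image and return it with its dot truth list.

    Background pixels are Normal(background_mean, background_sd), clipped
    at 0.  Dots are disks with every pixel at background_mean +
    dot_amplitude, placed entirely inside the cell mask with enough
    mutual separation that they are resolvable as distinct components.
    Truth records each dot center and its compartment
    ("peripheral"/"body").
    """
    rng = np.random.default_rng(params.seed)
    shape = cell.cell_mask.shape
    image = rng.normal(params.background_mean, params.background_sd, shape).clip(min=0)
    truth: list[dict] = []
    if params.n_dots == 0:
        return image, truth

    from scipy import ndimage

    depth = ndimage.distance_transform_edt(cell.cell_mask)
    eligible = depth > params.dot_radius + 1
    band = peripheral_band(
        cell, params.band_fraction * cell.equivalent_radius
    )
    n_peri = int(round(params.dot_region_split * params.n_dots))
    n_body = params.n_dots - n_peri
    min_sep = 2 * params.dot_radius + 3
    centers: list[tuple] = []
    for mask, count, label in (
        (eligible & band, n_peri, "peripheral"),
        (eligible & ~band, n_body, "body"),
    ):
        if count == 0:
            continue
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise ValueError(f"no eligible pixels in the {label} compartment")
        order = rng.permutation(rows.size)
        placed = 0
        for i in order:
            r, c = int(rows[i]), int(cols[i])
            if all(
                (r - rr) ** 2 + (c - cc) ** 2 >= min_sep ** 2 for rr, cc, _ in centers
            ):
                centers.append((r, c, label))
                placed += 1
                if placed == count:
                    break
        if placed < count:
            raise ValueError(
                f"could not place {count} separated dots in the {label} compartment"
            )
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    level = params.background_mean + params.dot_amplitude
    for r, c, label in centers:
        disk = (xx - c) ** 2 + (yy - r) ** 2 <= params.dot_radius ** 2
        if (disk & ~cell.cell_mask).any():
            raise ValueError("dot placed outside the cell mask")
        image[disk] = level
        truth.append({"x": float(c), "y": float(r), "compartment": label})
    return image, truth


@dataclass(frozen=True)
class FractionSimParams:
    """Fractionation/RIP count simulation with known enrichment ratios.

    ``true_ratio_per_gene`` maps each gene of interest to its
    enriched/reference (Ps/CB or eluate/input) ratio.  Housekeeping genes
    and an optional spike row behave with ratio 1.  Expected counts are
    baseline x size_factor x (ratio for the enriched fraction); Poisson
    noise is applied when ``noise`` is on.  ``library_size_factors`` has
    one entry per sample, ordered (enriched, reference) per replicate.
    """

    true_ratio_per_gene: Mapping[str, float] = field(
        default_factory=lambda: {"RAB13": 3.0, "NET1": 2.0, "CTRL": 1.0}
    )
    baseline: float = 1000.0
    library_size_factors: tuple = (1.0,) * 6
    housekeeping: tuple = ("HK1", "HK2")
    spike: Optional[str] = None
    fraction_labels: tuple = ("Ps", "CB")
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.true_ratio_per_gene.values()):
            raise ValueError("true ratios must be > 0")
        if any(s <= 0 for s in self.library_size_factors):
            raise ValueError("library size factors must be > 0")
        if len(self.library_size_factors) % 2 or not self.library_size_factors:
            raise ValueError(
                "library_size_factors needs one entry per sample, two per replicate"
            )
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")


def gen_fraction_counts(params: FractionSimParams):
    """Simulate a fractionation count table; returns (CountMatrix, truth).

    Truth is the ``true_ratio_per_gene`` mapping (housekeeping and spike
    rows behave with ratio 1 by construction).
    """
    import pandas as pd

    from .fractions import CountMatrix

    rng = np.random.default_rng(params.seed)
    enriched_label, reference_label = params.fraction_labels
    n_rep = len(params.library_size_factors) // 2
    genes = (
        list(params.true_ratio_per_gene)
        + list(params.housekeeping)
        + ([params.spike] if params.spike else [])
    )
    ratios = {g: 1.0 for g in genes}
    ratios.update(params.true_ratio_per_gene)
    sample_names = []
    meta_rows = []
    columns = {}
    for rep in range(1, n_rep + 1):
        for k, label in enumerate(params.fraction_labels):
            sf = params.library_size_factors[(rep - 1) * 2 + k]
            name = f"{label}_{rep}"
            sample_names.append(name)
            meta_rows.append({"fraction": label, "replicate": rep})
            expected = np.array(
                [
                    params.baseline
                    * sf
                    * (ratios[g] if label == enriched_label else 1.0)
                    for g in genes
                ]
            )
            columns[name] = (
                rng.poisson(expected).astype(float) if params.noise else expected
            )
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_names, name="sample"))
    matrix = CountMatrix(
        counts, samples, housekeeping=params.housekeeping, spike=params.spike
    )
    return matrix, dict(params.true_ratio_per_gene)
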