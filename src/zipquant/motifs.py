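"""Sequence-level zipcode analysis for 3'UTRs.

Degenerate (IUPAC) motif scanning, sliding-window GA-content profiles,
GA-rich region calling, motif/region overlap statistics, construct
deletions with coordinate remapping, antisense-probe classification, and
two-group motif enrichment by Fisher's exact test.

All coordinates are 1-based inclusive on the provided 3'UTR sequence
(position 1 = first nucleotide of the UTR).  BED export converts to
0-based half-open; see :mod:`zipquant.io`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "UtrRecord",
    "MotifSpec",
    "MotifHit",
    "GaWindowParams",
    "GaProfile",
    "RegionParams",
    "GaRichRegion",
    "DeletionInterval",
    "DeletionResult",
    "ProbeInterval",
    "OverlapSummary",
    "EnrichmentResult",
    "scan_motif",
    "ga_profile",
    "detect_ga_rich_regions",
    "motif_region_overlap",
    "summarize_groups",
    "motif_enrichment",
    "fisher_exact_two_sided",
    "apply_deletion",
    "classify_probe",
]

_VALID_BASES = frozenset("ACGT")
# IUPAC code -> set of concrete bases it matches (R = {A,G}, Y = {C,T}, ...).
# Biopython's table also carries the non-standard "X"; only the 15 IUPAC
# nucleotide codes are accepted here.
_IUPAC_SETS: Mapping[str, frozenset] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}


def normalize_sequence(raw: str, *, name: str = "sequence") -> str:
    """Uppercase, map U->T, and validate that only A/C/G/T remain.

    Ambiguity codes in input sequences are rejected: the analysis operates
    on resolved mRNA sequence, and a degenerate input base would make motif
    matching ill-defined.
    """
    seq = raw.upper().replace("U", "T")
    for pos, base in enumerate(seq, start=1):
        if base not in _VALID_BASES:
            raise ValueError(
                f"{name}: invalid residue {base!r} at position {pos} "
                "(only A/C/G/T/U accepted)"
            )
    return seq


@dataclass
class UtrRecord:
    """A labeled 3'UTR sequence.

    Position 1 is the first nucleotide of the provided sequence.  The raw
    sequence is normalized on construction (case-folded, U mapped to T).
    """

    id: str
    sequence: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("UtrRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"UtrRecord {self.id!r}: empty sequence")
        self.sequence = normalize_sequence(self.sequence, name=f"UtrRecord {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif consensus in IUPAC nucleotide code.

    The default, RGAAGRR (R = purine, i.e. A or G), is the 7-nt GA-rich
    zipcode consensus enriched in 3'UTRs of protrusion-localized,
    APC-dependent transcripts.
    """

    consensus: str = "RGAAGRR"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("motif consensus must be non-empty")
        for ch in self.consensus:
            if ch.upper() not in _IUPAC_SETS:
                raise ValueError(f"invalid IUPAC code {ch!r} in consensus")
        object.__setattr__(self, "consensus", self.consensus.upper())

    @property
    def length(self) -> int:
        return len(self.consensus)

    def position_sets(self) -> list[frozenset]:
        """Per-position sets of concrete bases the consensus accepts."""
        return [_IUPAC_SETS[c] for c in self.consensus]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; start/end are 1-based inclusive."""

    utr_id: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("MotifHit span does not match its sequence")


@dataclass(frozen=True)
class GaWindowParams:
    """Sliding-window parameters for the %GA profile (defaults: 30 nt, step 1)."""

    window: int = 30
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class GaProfile:
    """GA fraction per window start (1-based) along one sequence."""

    utr_id: str
    starts: np.ndarray
    ga_fractions: np.ndarray
    sequence_length: int
    window: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts, "ga_fraction": self.ga_fractions})


@dataclass(frozen=True)
class RegionParams:
    """GA-rich region calling: windows of `window` nt with GA fraction
    strictly greater than `min_ga`, merged into maximal regions of at
    least `min_len` nt.  Defaults follow the >75% over >=30 nt rule."""

    window: int = 30
    min_ga: float = 0.75
    min_len: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.min_ga < 1.0:
            raise ValueError("min_ga must be in (0, 1)")
        if self.min_len < self.window:
            raise ValueError("min_len must be >= window")


@dataclass(frozen=True)
class GaRichRegion:
    """Maximal union of qualifying GA windows; 1-based inclusive span."""

    utr_id: str
    start: int
    end: int
    ga_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DeletionInterval:
    """1-based inclusive interval to remove from the unmodified UTR."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid deletion interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProbeInterval:
    """Antisense-probe target interval (default 25 nt, the PMO length)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid probe interval [{self.start}, {self.end}]")

    @classmethod
    def from_start(cls, start: int, length: int = 25) -> "ProbeInterval":
        return cls(start, start + length - 1)


@dataclass(frozen=True)
class OverlapSummary:
    """How many motif hits fall entirely within GA-rich regions."""

    n_inside: int
    n_total: int

    @property
    def fraction(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return self.n_inside / self.n_total


@dataclass(frozen=True)
class EnrichmentResult:
    """Two-group motif enrichment (Fisher exact, Bonferroni-corrected)."""

    table: tuple  # ((a_with, a_without), (b_with, b_without))
    odds_ratio: float
    p_value: float
    p_bonferroni: float
    n_tests: int


def scan_motif(record: UtrRecord, spec: MotifSpec = MotifSpec()) -> list[MotifHit]:
    """Find all occurrences of a degenerate consensus, overlapping included.

    Position p (1-based) matches iff for every consensus position i the
    sequence character at p+i lies in the IUPAC set of consensus[i].
    Scanning is single-stranded: the UTR is mRNA sense sequence and the
    reverse complement is never considered.
    """
    seq = record.sequence
    sets = spec.position_sets()
    k = spec.length
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(base in s for base, s in zip(window, sets)):
            hits.append(MotifHit(record.id, i + 1, i + k, window))
    return hits


def _ga_indicator(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ((arr == ord("G")) | (arr == ord("A"))).astype(np.int64)


def ga_profile(record: UtrRecord, params: GaWindowParams = GaWindowParams()) -> GaProfile:
    """%GA content in sliding windows along the sequence.

    One entry per window start 1..len-W+1 (subject to `step`); the GA
    fraction of a window is (#G + #A) / W.
    """
    w = params.window
    n = len(record.sequence)
    if n < w:
        raise ValueError(
            f"sequence {record.id!r} ({n} nt) shorter than window ({w} nt)"
        )
    ind = _ga_indicator(record.sequence)
    csum = np.concatenate([[0], np.cumsum(ind)])
    starts = np.arange(1, n - w + 2, params.step)
    counts = csum[starts - 1 + w] - csum[starts - 1]
    return GaProfile(record.id, starts, counts / w, n, w)


def _window_qualifies(ga_count: int, window: int, min_ga: float) -> bool:
    # Strict "> min_ga" on an integer count; snap the float product to the
    # nearest integer when it is one, so ties at the threshold are exact.
    t = min_ga * window
    if abs(t - round(t)) < 1e-9:
        t = round(t)
    return ga_count > t


def detect_ga_rich_regions(
    record: UtrRecord, params: RegionParams = RegionParams()
) -> list[GaRichRegion]:
    """Call GA-rich regions as merged unions of qualifying windows.

    Every window of `params.window` nt with GA fraction strictly above
    `params.min_ga` qualifies; overlapping/adjacent qualifying windows are
    merged into maximal regions.  Each region reports its overall GA
    fraction.  Because regions are unions of fixed-width windows they can
    extend a few nucleotides into flanking pyrimidine sequence.
    """
    w = params.window
    n = len(record.sequence)
    if n < w:
        raise ValueError(
            f"sequence {record.id!r} ({n} nt) shorter than window ({w} nt)"
        )
    ind = _ga_indicator(record.sequence)
    csum = np.concatenate([[0], np.cumsum(ind)])
    regions: list[GaRichRegion] = []
    cur_start = cur_end = None
    for s in range(1, n - w + 2):
        count = int(csum[s - 1 + w] - csum[s - 1])
        if not _window_qualifies(count, w, params.min_ga):
            continue
        e = s + w - 1
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            regions.append(_finish_region(record, cur_start, cur_end, csum))
            cur_start, cur_end = s, e
    if cur_start is not None:
        regions.append(_finish_region(record, cur_start, cur_end, csum))
    return [r for r in regions if r.length >= params.min_len]


def _finish_region(record: UtrRecord, start: int, end: int, csum: np.ndarray) -> GaRichRegion:
    ga = int(csum[end] - csum[start - 1])
    return GaRichRegion(record.id, start, end, ga / (end - start + 1))


def motif_region_overlap(
    hits: Sequence[MotifHit], regions: Sequence[GaRichRegion]
) -> OverlapSummary:
    """Count motif hits fully contained in a GA-rich region of the same UTR.

    A hit counts as inside iff its entire span lies within some region
    ("found within" semantics — full containment, not mere overlap).  The
    fraction is undefined (None) when there are no hits.
    """
    hit_ids = {h.utr_id for h in hits}
    region_ids = {r.utr_id for r in regions}
    if regions and hit_ids and not hit_ids & region_ids:
        raise ValueError(
            "motif hits and regions share no utr_ids; "
            "are they from the same record set?"
        )
    by_utr: dict[str, list[GaRichRegion]] = {}
    for r in regions:
        by_utr.setdefault(r.utr_id, []).append(r)
    n_inside = 0
    for h in hits:
        for r in by_utr.get(h.utr_id, ()):
            if r.start <= h.start and h.end <= r.end:
                n_inside += 1
                break
    return OverlapSummary(n_inside, len(hits))


def summarize_groups(
    records: Sequence[UtrRecord],
    spec: MotifSpec = MotifSpec(),
    params: RegionParams = RegionParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-UTR motif/region table plus group-level aggregates.

    Returns ``(per_utr, per_group)``: one row per record with its motif
    count, region count and motifs-in-region count, and one row per group
    with the fraction of UTRs carrying at least one motif.
    """
    if not records:
        raise ValueError("empty record set")
    ids = [r.id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate record ids: {sorted(dup)}")
    rows = []
    for rec in records:
        hits = scan_motif(rec, spec)
        regions = (
            detect_ga_rich_regions(rec, params) if len(rec) >= params.window else []
        )
        inside = motif_region_overlap(hits, regions).n_inside if hits else 0
        rows.append(
            {
                "utr_id": rec.id,
                "group": rec.group,
                "length": len(rec),
                "has_motif": bool(hits),
                "n_motifs": len(hits),
                "n_regions": len(regions),
                "n_motifs_in_region": inside,
            }
        )
    per_utr = pd.DataFrame(rows)
    per_group = (
        per_utr.groupby("group", sort=True)
        .agg(
            n_utrs=("utr_id", "size"),
            n_with_motif=("has_motif", "sum"),
            fraction_with_motif=("has_motif", "mean"),
            total_motifs=("n_motifs", "sum"),
        )
        .reset_index()
    )
    return per_utr, per_group


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p for a 2x2 table, by integer enumeration.

    At fixed margins, sums the hypergeometric probabilities of every
    table whose probability is at most the observed table's.  The tail
    comparison is done on exact integer weights, so ties at the observed
    probability are handled without floating-point ambiguity.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be >= 0")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    return sum(w for w in weights if w <= observed) / math.comb(r1 + r2, c1)


def motif_enrichment(
    flags_a: Sequence[bool], flags_b: Sequence[bool], n_tests: int = 1
) -> EnrichmentResult:
    """Two-sided Fisher exact test for motif presence between two groups.

    Builds the 2x2 table (group x has-motif), computes the two-sided
    Fisher exact p (sum of hypergeometric probabilities of tables at most
    as probable as the observed one at fixed margins) and applies a
    Bonferroni correction for `n_tests` tests.
    """
    if not len(flags_a) or not len(flags_b):
        raise ValueError("both groups must be non-empty")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    a_with = int(sum(bool(f) for f in flags_a))
    b_with = int(sum(bool(f) for f in flags_b))
    table = ((a_with, len(flags_a) - a_with), (b_with, len(flags_b) - b_with))
    (a, b), (c, d) = table
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    p = fisher_exact_two_sided(table)
    return EnrichmentResult(
        table=table,
        odds_ratio=odds,
        p_value=p,
        p_bonferroni=min(1.0, n_tests * p),
        n_tests=n_tests,
    )


@dataclass
class DeletionResult:
    """Outcome of applying deletions to a UTR record."""

    record: UtrRecord
    remapped_hits: list[MotifHit] = field(default_factory=list)
    dropped_hits: list[MotifHit] = field(default_factory=list)


def remap_position(pos: int, deletions: Sequence[DeletionInterval]) -> Optional[int]:
    """Map a 1-based position on the original sequence to the deleted one.

    Returns None if the position itself was deleted.  Positions downstream
    of deletions shift left by the total deleted length upstream of them.
    """
    shift = 0
    for d in deletions:
        if d.start <= pos <= d.end:
            return None
        if d.end < pos:
            shift += d.length
    return pos - shift


def apply_deletion(
    record: UtrRecord,
    deletions: Sequence[DeletionInterval],
    hits: Sequence[MotifHit] = (),
    new_id: Optional[str] = None,
) -> DeletionResult:
    """Splice intervals out of a UTR and remap surviving annotations.

    Deletions must be non-overlapping and within the sequence.  Annotations
    (motif hits) that overlap any deleted interval are dropped with a
    warning; the rest shift left by the removed length upstream of them.
    """
    dels = sorted(deletions, key=lambda d: d.start)
    for d in dels:
        if d.end > len(record):
            raise ValueError(
                f"deletion [{d.start}, {d.end}] out of range for "
                f"{record.id!r} ({len(record)} nt)"
            )
    for prev, nxt in zip(dels, dels[1:]):
        if nxt.start <= prev.end:
            raise ValueError(
                f"overlapping deletion intervals [{prev.start}, {prev.end}] "
                f"and [{nxt.start}, {nxt.end}]"
            )
    seq = record.sequence
    kept = []
    cursor = 1
    for d in dels:
        kept.append(seq[cursor - 1 : d.start - 1])
        cursor = d.end + 1
    kept.append(seq[cursor - 1 :])
    new_seq = "".join(kept)
    out_id = new_id or record.id
    new_record = UtrRecord(out_id, new_seq, record.group)

    remapped: list[MotifHit] = []
    dropped: list[MotifHit] = []
    for h in hits:
        if any(d.start <= h.end and h.start <= d.end for d in dels):
            dropped.append(h)
            continue
        ns = remap_position(h.start, dels)
        ne = remap_position(h.end, dels)
        assert ns is not None and ne is not None
        remapped.append(MotifHit(out_id, ns, ne, h.matched))
    if dropped:
        warnings.warn(
            f"{len(dropped)} annotation(s) overlapped deleted intervals on "
            f"{record.id!r} and were dropped",
            stacklevel=2,
        )
    return DeletionResult(new_record, remapped, dropped)


def _intersects(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_probe(
    probe: ProbeInterval,
    regions: Sequence[GaRichRegion],
    hits: Sequence[MotifHit],
    sequence_length: Optional[int] = None,
) -> str:
    """Classify an antisense-probe target interval against motifs/regions.

    Returns ``"overlaps_motif"`` if the probe intersects any motif hit by
    at least 1 nt, else ``"overlaps_ga_region"`` if it intersects any
    GA-rich region, else ``"outside"``.  Any-overlap semantics: a probe
    need only cover part of a motif to block it.
    """
    if sequence_length is not None and probe.end > sequence_length:
        raise ValueError(
            f"probe [{probe.start}, {probe.end}] exceeds sequence length "
            f"{sequence_length}"
        )
    if any(_intersects(probe.start, probe.end, h.start, h.end) for h in hits):
        return "overlaps_motif"
    if any(_intersects(probe.start, probe.end, r.start, r.end) for r in regions):
        return "overlaps_ga_region"
    return "outside"
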