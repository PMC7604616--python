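"""Sequence-analysis unit and property tests against naive oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from zipquant.motifs import (
    DeletionInterval,
    GaRichRegion,
    GaWindowParams,
    MotifHit,
    MotifSpec,
    ProbeInterval,
    RegionParams,
    UtrRecord,
    apply_deletion,
    classify_probe,
    detect_ga_rich_regions,
    fisher_exact_two_sided,
    ga_profile,
    motif_enrichment,
    motif_region_overlap,
    scan_motif,
    summarize_groups,
)

# ---------------------------------------------------------------------------
# Naive oracles, written independently of the implementation.

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_scan(seq, consensus="RGAAGRR"):
    k = len(consensus)
    out = []
    for s in range(1, len(seq) - k + 2):
        window = seq[s - 1 : s - 1 + k]
        if all(b in IUPAC[c] for b, c in zip(window, consensus)):
            out.append((s, s + k - 1, window))
    return out


def oracle_profile(seq, w=30):
    return [
        (s, sum(1 for b in seq[s - 1 : s - 1 + w] if b in "GA") / w)
        for s in range(1, len(seq) - w + 2)
    ]


def oracle_regions(seq, w=30, theta=Fraction(3, 4)):
    spans = []
    for s in range(1, len(seq) - w + 2):
        cnt = sum(1 for b in seq[s - 1 : s - 1 + w] if b in "GA")
        if Fraction(cnt, w) > theta:
            spans.append((s, s + w - 1))
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# scan_motif


@pytest.mark.parametrize(
    "seq,expected_starts",
    [
        ("AGAAGAA", [1]),  # direct instantiation of R G A A G R R
        ("CGAAGAA", []),  # C is not a purine
        ("AGAAGAAGAAGAA", [1, 4, 7]),  # overlapping occurrences all counted
        ("GGAAGGG", [1]),
        ("TTTTTTT", []),
    ],
)
def test_scan_motif_examples(seq, expected_starts):
    hits = scan_motif(UtrRecord("u", seq))
    assert [h.start for h in hits] == expected_starts
    for h in hits:
        assert h.end - h.start + 1 == 7
        assert h.matched == seq[h.start - 1 : h.end]


def test_scan_motif_rejects_invalid_residue():
    with pytest.raises(ValueError, match="position 3"):
        UtrRecord("u", "AGNAGAA")


def test_uracil_mapped_to_thymine():
    rec = UtrRecord("u", "agaagaa".replace("t", "u"))
    assert rec.sequence == "AGAAGAA"
    assert len(scan_motif(rec)) == 1


def test_scan_is_single_stranded():
    # The reverse complement of a hit-bearing sequence need not have hits.
    seq = "AGAAGAA"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    assert len(scan_motif(UtrRecord("u", seq))) == 1
    assert len(scan_motif(UtrRecord("u", rc))) == 0


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=7, max_size=120))
def test_scan_motif_matches_oracle(seq):
    hits = scan_motif(UtrRecord("u", seq))
    assert [(h.start, h.end, h.matched) for h in hits] == oracle_scan(seq)


# ---------------------------------------------------------------------------
# ga_profile


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("G" * 30, [(1, 1.0)]),
        ("C" * 30, [(1, 0.0)]),
    ],
)
def test_ga_profile_constant(seq, expected):
    prof = ga_profile(UtrRecord("u", seq))
    assert list(zip(prof.starts.tolist(), prof.ga_fractions.tolist())) == expected


def test_ga_profile_periodic_sequence():
    # 33 nt of GACT repeats: 30-nt windows hover around half GA content
    # (direct counting gives 16/30, 15/30, 14/30, 15/30 — a 30-nt window
    # over a period-4 sequence covers 7.5 periods, so the exact count
    # depends on the phase).
    seq = ("GACT" * 9)[:33]
    prof = ga_profile(UtrRecord("u", seq))
    assert prof.starts.tolist() == [1, 2, 3, 4]
    assert oracle_profile(seq) == list(
        zip(prof.starts.tolist(), prof.ga_fractions.tolist())
    )
    assert prof.ga_fractions.tolist() == [16 / 30, 15 / 30, 14 / 30, 15 / 30]
    assert np.allclose(prof.ga_fractions.mean(), 0.5)


def test_ga_profile_short_sequence_errors():
    with pytest.raises(ValueError, match="shorter than window"):
        ga_profile(UtrRecord("u", "ACGT"))


def test_ga_profile_step():
    seq = "GACT" * 20
    prof = ga_profile(UtrRecord("u", seq), GaWindowParams(window=30, step=10))
    assert prof.starts.tolist() == [1, 11, 21, 31, 41, 51]


# ---------------------------------------------------------------------------
# detect_ga_rich_regions


def test_region_embedded_ga_run():
    seq = "T" * 30 + "GA" * 20 + "T" * 30
    regions = detect_ga_rich_regions(UtrRecord("u", seq))
    assert [(r.start, r.end) for r in regions] == [(24, 77)]
    assert oracle_regions(seq) == [(24, 77)]


def test_region_all_pyrimidine_empty():
    assert detect_ga_rich_regions(UtrRecord("u", "CT" * 40)) == []


def test_region_pure_ga():
    regions = detect_ga_rich_regions(UtrRecord("u", "GA" * 50))
    assert [(r.start, r.end, r.ga_fraction) for r in regions] == [(1, 100, 1.0)]


def test_region_threshold_is_strict():
    # Exactly 75% GA in every window: no window qualifies under strict ">".
    seq = "GGGT" * 10  # every 4-mer window pattern gives 3/4 GA at W=4
    params = RegionParams(window=4, min_ga=0.75, min_len=4)
    assert detect_ga_rich_regions(UtrRecord("u", seq), params) == []
    # One extra G pushes a window above threshold.
    seq2 = "GGGTGGGG" + "T" * 30
    assert detect_ga_rich_regions(UtrRecord("u", seq2), params) != []


def test_region_soundness_random(rng):
    """Every region contains a qualifying window; no qualifying window
    escapes all regions; exact agreement with the oracle."""
    for _ in range(200):
        seq = random_seq(rng, int(rng.integers(30, 200)))
        regions = detect_ga_rich_regions(UtrRecord("u", seq))
        assert [(r.start, r.end) for r in regions] == oracle_regions(seq)
        spans = oracle_regions(seq)
        for s, e in spans:
            assert any(r.start == s and r.end == e for r in regions)


# ---------------------------------------------------------------------------
# motif_region_overlap


def test_overlap_full_containment_semantics():
    hits = [MotifHit("u", 10, 16, "AGAAGAA"), MotifHit("u", 95, 101, "AGAAGAA")]
    regions = [GaRichRegion("u", 5, 100, 0.9)]
    s = motif_region_overlap(hits, regions)
    # The second hit sticks 1 nt out of the region: not contained.
    assert (s.n_inside, s.n_total) == (1, 2)


def test_overlap_no_regions_gives_zero_fraction():
    hits = [MotifHit("u", 1, 7, "AGAAGAA")]
    s = motif_region_overlap(hits, [])
    assert s.n_inside == 0 and s.fraction == 0.0


def test_overlap_spanning_region_gives_one():
    hits = [MotifHit("u", i, i + 6, "AGAAGAA") for i in (1, 10, 20)]
    s = motif_region_overlap(hits, [GaRichRegion("u", 1, 50, 1.0)])
    assert s.fraction == 1.0


def test_overlap_empty_hits_fraction_undefined():
    assert motif_region_overlap([], [GaRichRegion("u", 1, 50, 1.0)]).fraction is None


def test_overlap_mismatched_ids_error():
    with pytest.raises(ValueError, match="utr_id"):
        motif_region_overlap(
            [MotifHit("a", 1, 7, "AGAAGAA")], [GaRichRegion("b", 1, 50, 1.0)]
        )


# ---------------------------------------------------------------------------
# summarize_groups


def test_summarize_groups_fraction():
    with_motif = [UtrRecord(f"m{i}", "AGAAGAA" + "CT" * 20, "loc") for i in range(6)]
    without = [UtrRecord(f"n{i}", "CT" * 20, "loc") for i in range(4)]
    per_utr, per_group = summarize_groups(with_motif + without)
    assert len(per_utr) == 10
    row = per_group.set_index("group").loc["loc"]
    assert row["fraction_with_motif"] == pytest.approx(0.6)


def test_summarize_groups_duplicate_ids_error():
    recs = [UtrRecord("x", "ACGT" * 10), UtrRecord("x", "ACGT" * 10)]
    with pytest.raises(ValueError, match="duplicate"):
        summarize_groups(recs)


def test_summarize_pyrimidine_group_zero():
    recs = [UtrRecord(f"p{i}", "CTCT" * 10, "pyr") for i in range(3)]
    _, per_group = summarize_groups(recs)
    assert per_group.set_index("group").loc["pyr", "fraction_with_motif"] == 0.0


# ---------------------------------------------------------------------------
# motif_enrichment


def oracle_fisher(a, b, c, d):
    """Independent exact two-sided Fisher p by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    return Fraction(sum(w for w in weights if w <= obs), denom)


def test_enrichment_identical_proportions():
    res = motif_enrichment([True] * 5 + [False] * 5, [True] * 5 + [False] * 5)
    assert res.p_value == 1.0


def test_enrichment_perfect_separation():
    res = motif_enrichment([True] * 10, [False] * 10)
    assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=0, abs=0)


def test_enrichment_bonferroni():
    res = motif_enrichment([True] * 10, [False] * 10, n_tests=5)
    assert res.p_bonferroni == pytest.approx(min(1.0, 5 * res.p_value))
    res2 = motif_enrichment([True, False], [True, False], n_tests=3)
    assert res2.p_bonferroni == 1.0  # capped at 1


def test_enrichment_input_validation():
    with pytest.raises(ValueError):
        motif_enrichment([], [True])
    with pytest.raises(ValueError):
        motif_enrichment([True], [True], n_tests=0)


def test_fisher_symmetry_and_monotonicity():
    # Swapping group labels leaves the two-sided p unchanged.
    for a, b, c, d in [(7, 3, 2, 8), (5, 5, 1, 9), (9, 1, 4, 6)]:
        p1 = fisher_exact_two_sided(((a, b), (c, d)))
        p2 = fisher_exact_two_sided(((c, d), (a, b)))
        assert p1 == p2
    # p decreases as proportions diverge at fixed group sizes.
    ps = [
        fisher_exact_two_sided(((5 + k, 5 - k), (5 - k, 5 + k))) for k in range(6)
    ]
    assert all(x > y for x, y in zip(ps, ps[1:]))


def test_fisher_cross_checked_against_scipy(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
        if (a + b) == 0 or (c + d) == 0:
            continue
        ours = fisher_exact_two_sided(((a, b), (c, d)))
        _, scipy_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert ours == pytest.approx(scipy_p, rel=1e-7)


# ---------------------------------------------------------------------------
# apply_deletion


def test_delete_simple_splice():
    res = apply_deletion(UtrRecord("u", "ACGTA"), [DeletionInterval(2, 3)])
    assert res.record.sequence == "ATA"


def test_delete_pmo_region_removes_53_nt():
    rec = UtrRecord("u", "ACGT" * 100)
    res = apply_deletion(rec, [DeletionInterval(202, 254)])
    assert len(rec) - len(res.record) == 53


def test_delete_two_regions_remaps_downstream_hit():
    rec = UtrRecord("u", "ACGT" * 100)
    dels = [DeletionInterval(204, 211), DeletionInterval(193, 200)]
    hit = MotifHit("u", 250, 256, rec.sequence[249:256])
    res = apply_deletion(rec, dels, hits=[hit])
    assert len(rec) - len(res.record) == 16
    assert (res.remapped_hits[0].start, res.remapped_hits[0].end) == (234, 240)


def test_delete_drops_overlapping_annotation_with_warning():
    rec = UtrRecord("u", "ACGT" * 100)
    hit = MotifHit("u", 205, 211, rec.sequence[204:211])
    with pytest.warns(UserWarning, match="dropped"):
        res = apply_deletion(rec, [DeletionInterval(204, 211)], hits=[hit])
    assert res.remapped_hits == [] and res.dropped_hits == [hit]


def test_delete_rejects_overlap_and_out_of_range():
    rec = UtrRecord("u", "ACGT" * 100)
    with pytest.raises(ValueError, match="overlapping"):
        apply_deletion(rec, [DeletionInterval(10, 20), DeletionInterval(15, 30)])
    with pytest.raises(ValueError, match="out of range"):
        apply_deletion(rec, [DeletionInterval(390, 401)])


@settings(max_examples=100, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=20, max_size=150),
    st.integers(min_value=1, max_value=140),
    st.integers(min_value=0, max_value=12),
)
def test_deletion_conservation(seq, start, extra):
    """Rescanning the spliced record equals brute-force scan of the
    literally spliced string."""
    end = min(len(seq), start + extra)
    if start > len(seq):
        return
    res = apply_deletion(UtrRecord("u", seq), [DeletionInterval(start, end)])
    spliced = seq[: start - 1] + seq[end:]
    if not spliced:
        return
    hits = scan_motif(res.record)
    assert [(h.start, h.end, h.matched) for h in hits] == oracle_scan(spliced)


# ---------------------------------------------------------------------------
# classify_probe


def test_probe_classification_within_ga_region():
    regions = [GaRichRegion("u", 98, 268, 0.8)]
    assert classify_probe(ProbeInterval(230, 254), regions, []) == "overlaps_ga_region"
    hits = [MotifHit("u", 230, 236, "AGAAGAA")]
    assert classify_probe(ProbeInterval(230, 254), regions, hits) == "overlaps_motif"


def test_probe_outside_region():
    regions = [GaRichRegion("u", 98, 268, 0.8)]
    assert classify_probe(ProbeInterval(300, 324), regions, []) == "outside"


def test_probe_abutting_region_is_outside():
    regions = [GaRichRegion("u", 98, 268, 0.8)]
    probe = ProbeInterval.from_start(269, 25)
    assert classify_probe(probe, regions, []) == "outside"
    # one nt of overlap flips it
    assert classify_probe(ProbeInterval.from_start(268, 25), regions, []) == (
        "overlaps_ga_region"
    )


def test_probe_out_of_range_error():
    with pytest.raises(ValueError, match="exceeds"):
        classify_probe(ProbeInterval(300, 324), [], [], sequence_length=310)


def test_probe_default_length_25():
    p = ProbeInterval.from_start(165)
    assert p.end - p.start + 1 == 25


# ---------------------------------------------------------------------------
# MotifSpec validation


def test_motif_spec_validation():
    with pytest.raises(ValueError):
        MotifSpec("")
    with pytest.raises(ValueError):
        MotifSpec("RGAXGRR")
    assert MotifSpec("rgaagrr").consensus == "RGAAGRR"
    assert MotifSpec().length == 7
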