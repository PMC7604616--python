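"""Ratio-based enrichment from fractionation and RIP count data.

Two estimators over a genes x samples count matrix:

* protrusion/cell-body (Ps/CB) enrichment, normalized per replicate to
  the geometric mean of a designated housekeeping gene set;
* spike-normalized RNA co-immunoprecipitation (RIP) enrichment of a
  target gene over a reference gene (eluate vs input).

Both are pure ratio statistics: multiplying any single sample's counts by
a constant leaves every output unchanged, because the normalizers cancel.
Replicates are aggregated as arithmetic mean +/- s.e.m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "EnrichmentRecord",
    "ps_cb_enrichment",
    "rip_enrichment",
]


@dataclass
class CountMatrix:
    """Genes x samples counts with sample metadata and normalizer genes.

    ``counts``: DataFrame indexed by gene, one column per sample.
    ``samples``: DataFrame indexed by sample name with columns
    ``fraction`` (e.g. Ps/CB or eluate/input) and ``replicate``.
    ``housekeeping`` names the normalizer gene set for fractionation;
    ``spike`` the spike-in control row for RIP.  Normalizer sets are a
    required input for the estimators that use them — there is no default.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    housekeeping: tuple = ()
    spike: Optional[str] = None

    def __post_init__(self) -> None:
        self.housekeeping = tuple(self.housekeeping)
        if (np.asarray(self.counts.values, dtype=float) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) ^ set(self.samples.index)
        if missing:
            raise ValueError(f"sample metadata does not match count columns: {sorted(missing)}")
        for col in ("fraction", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata must have a {col!r} column")
        for g in self.housekeeping:
            if g not in self.counts.index:
                raise ValueError(f"housekeeping gene {g!r} not in count matrix")
        if self.spike is not None and self.spike not in self.counts.index:
            raise ValueError(f"spike gene {self.spike!r} not in count matrix")

    def replicate_pairs(self, enriched: str, reference: str) -> list[tuple]:
        """(replicate, enriched-sample, reference-sample) triples, sorted."""
        pairs = []
        for rep, grp in self.samples.groupby("replicate", sort=True):
            by_frac = grp.groupby("fraction").groups
            if enriched not in by_frac or reference not in by_frac:
                raise ValueError(
                    f"replicate {rep!r} lacks a paired {enriched}/{reference} sample"
                )
            if len(by_frac[enriched]) != 1 or len(by_frac[reference]) != 1:
                raise ValueError(f"replicate {rep!r} has duplicated fraction samples")
            pairs.append((rep, by_frac[enriched][0], by_frac[reference][0]))
        return pairs


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-gene enrichment: per-replicate ratios and mean +/- s.e.m."""

    gene: str
    ratios: tuple
    mean: float
    sem: float
    n: int


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _aggregate(gene: str, ratios: Sequence[float]) -> EnrichmentRecord:
    arr = np.asarray(ratios, dtype=float)
    finite = arr[np.isfinite(arr)]
    n = finite.size
    mean = float(finite.mean()) if n else float("nan")
    sem = float(finite.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return EnrichmentRecord(gene, tuple(arr), mean, sem, n)


def ps_cb_enrichment(
    matrix: CountMatrix,
    enriched: str = "Ps",
    reference: str = "CB",
) -> list[EnrichmentRecord]:
    """Housekeeping-normalized protrusion/cell-body enrichment per gene.

    Per replicate, ratio_g = (Ps_g / geomean(Ps_housekeeping)) /
    (CB_g / geomean(CB_housekeeping)).  A replicate with a zero
    housekeeping count is excluded with a warning; a gene with zero count
    in the reference fraction yields an undefined (NaN) ratio for that
    replicate, flagged the same way.
    """
    if not matrix.housekeeping:
        raise ValueError("ps_cb_enrichment requires a housekeeping gene set")
    pairs = matrix.replicate_pairs(enriched, reference)
    counts = matrix.counts
    usable: list[tuple] = []
    for rep, s_en, s_ref in pairs:
        hk_en = counts.loc[list(matrix.housekeeping), s_en].to_numpy(dtype=float)
        hk_ref = counts.loc[list(matrix.housekeeping), s_ref].to_numpy(dtype=float)
        if (hk_en <= 0).any() or (hk_ref <= 0).any():
            warnings.warn(
                f"replicate {rep!r} excluded: zero housekeeping count",
                stacklevel=2,
            )
            continue
        usable.append((rep, s_en, s_ref, _geomean(hk_en), _geomean(hk_ref)))
    if not usable:
        raise ValueError("no usable replicates (zero housekeeping counts)")
    records = []
    for gene in counts.index:
        ratios = []
        for rep, s_en, s_ref, norm_en, norm_ref in usable:
            en = float(counts.at[gene, s_en]) / norm_en
            ref = float(counts.at[gene, s_ref]) / norm_ref
            if ref == 0:
                warnings.warn(
                    f"gene {gene!r}, replicate {rep!r}: zero {reference} count, "
                    "ratio undefined",
                    stacklevel=2,
                )
                ratios.append(float("nan"))
            else:
                ratios.append(en / ref)
        records.append(_aggregate(str(gene), ratios))
    return records


def rip_enrichment(
    matrix: CountMatrix,
    target: str,
    reference: str,
    spike: Optional[str] = None,
    eluate: str = "eluate",
    inp: str = "input",
) -> EnrichmentRecord:
    """Spike-normalized RIP enrichment of `target` over `reference`.

    Per replicate, each gene's eluate count is divided by the eluate spike
    count and its input count by the input spike count; the recovery
    E_g = (eluate_g / eluate_spike) / (input_g / input_spike) is then
    referenced: result = E_target / E_reference.  Replicates with zero
    spike or zero input counts are excluded with a warning.
    """
    spike = spike if spike is not None else matrix.spike
    if spike is None:
        raise ValueError("rip_enrichment requires a spike gene")
    for g in (target, reference, spike):
        if g not in matrix.counts.index:
            raise ValueError(f"gene {g!r} not in count matrix")
    counts = matrix.counts
    ratios = []
    for rep, s_el, s_in in matrix.replicate_pairs(eluate, inp):
        el_spike = float(counts.at[spike, s_el])
        in_spike = float(counts.at[spike, s_in])
        in_t = float(counts.at[target, s_in])
        in_r = float(counts.at[reference, s_in])
        el_r = float(counts.at[reference, s_el])
        if el_spike <= 0 or in_spike <= 0 or in_t <= 0 or in_r <= 0 or el_r <= 0:
            warnings.warn(
                f"replicate {rep!r} excluded: zero spike, input, or reference count",
                stacklevel=2,
            )
            continue
        e_target = (float(counts.at[target, s_el]) / el_spike) / (in_t / in_spike)
        e_reference = (el_r / el_spike) / (in_r / in_spike)
        ratios.append(e_target / e_reference)
    if not ratios:
        raise ValueError("no usable replicates for RIP enrichment")
    return _aggregate(target, ratios)


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records (one row per gene)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "mean": [r.mean for r in records],
            "sem": [r.sem for r in records],
            "n": [r.n for r in records],
            "ratios": [",".join(f"{x:.6g}" for x in r.ratios) for r in records],
        }
    )
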