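"""File I/O for the toolkit's standard formats.

Sequences travel as FASTA (ids must be unique) with a separate CSV
mapping id -> group.  Motif hits and GA-rich regions are written both as
BED (converted from the internal 1-based inclusive coordinates to BED's
0-based half-open; score = GA fraction x 1000) and as CSV with 1-based
columns.  Masks and intensity images are single-channel TIFF: label
images use 0 = background, 1 = cell, 2 = nucleus.  Spot tables and count
matrices are CSV; run manifests and truth files are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fractions import CountMatrix
from .motifs import GaRichRegion, MotifHit, UtrRecord
from .spatial import CellGeometry, SpotSet

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_utr_set",
    "write_features_bed",
    "write_features_csv",
    "read_label_tiff",
    "write_label_tiff",
    "read_image_tiff",
    "write_image_tiff",
    "read_spots_csv",
    "write_spots_csv",
    "read_counts_csv",
    "write_counts_csv",
    "write_json",
]


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[UtrRecord], path: PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.group) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_utr_set(fasta_path: PathLike, groups_csv: Optional[PathLike] = None) -> list[UtrRecord]:
    """Load UTR records from FASTA plus an optional id->group CSV.

    The groups CSV needs columns ``id`` and ``group``; records without a
    listed group get an empty label.
    """
    groups: dict[str, str] = {}
    if groups_csv is not None:
        df = pd.read_csv(groups_csv, dtype=str)
        if not {"id", "group"} <= set(df.columns):
            raise ValueError("groups CSV must have 'id' and 'group' columns")
        groups = dict(zip(df["id"], df["group"]))
    records = []
    seen = set()
    for rec_id, seq in read_fasta(fasta_path):
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        records.append(UtrRecord(rec_id, seq, groups.get(rec_id, "")))
    return records


def _ga_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("A")) / len(seq) if seq else 0.0


def write_features_bed(
    features: Sequence[Union[MotifHit, GaRichRegion]],
    path: PathLike,
    sequences: Optional[dict] = None,
) -> None:
    """Write motif hits / GA-rich regions as BED (0-based half-open).

    The BED name is ``motif`` or ``region``; the score is the feature's
    GA fraction x 1000 (motifs need `sequences`, a mapping id->sequence,
    to compute it; without it motif scores are the GA fraction of the
    matched substring).
    """
    lines = []
    for f in features:
        if isinstance(f, MotifHit):
            name = "motif"
            frac = _ga_fraction(f.matched)
        else:
            name = "region"
            frac = f.ga_fraction
        if sequences is not None and f.utr_id in sequences:
            frac = _ga_fraction(sequences[f.utr_id][f.start - 1 : f.end])
        lines.append(
            f"{f.utr_id}\t{f.start - 1}\t{f.end}\t{name}\t{int(round(frac * 1000))}\n"
        )
    Path(path).write_text("".join(lines))


def write_features_csv(
    features: Sequence[Union[MotifHit, GaRichRegion]], path: PathLike
) -> None:
    """Write features as CSV with 1-based inclusive coordinates."""
    rows = []
    for f in features:
        rows.append(
            {
                "utr_id": f.utr_id,
                "start": f.start,
                "end": f.end,
                "kind": "motif" if isinstance(f, MotifHit) else "region",
                "detail": f.matched if isinstance(f, MotifHit) else f"{f.ga_fraction:.6f}",
            }
        )
    pd.DataFrame(rows, columns=["utr_id", "start", "end", "kind", "detail"]).to_csv(
        path, index=False
    )


def write_label_tiff(cell: CellGeometry, path: PathLike) -> None:
    """Write a cell geometry as a 16-bit label image (0/1/2)."""
    label = np.zeros(cell.cell_mask.shape, dtype=np.uint16)
    label[cell.cell_mask] = 1
    label[cell.nucleus_mask] = 2
    tifffile.imwrite(str(path), label)


def read_label_tiff(path: PathLike, pixel_size: float = 1.0) -> CellGeometry:
    """Read a 0/1/2 label image back into a CellGeometry."""
    label = tifffile.imread(str(path))
    return CellGeometry(label >= 1, label == 2, pixel_size=pixel_size)


def write_image_tiff(image: np.ndarray, path: PathLike) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image_tiff(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_spots_csv(spots: SpotSet, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "cell_id": spots.cell_id,
            "x": spots.xy[:, 0],
            "y": spots.xy[:, 1],
        }
    )
    if spots.intensity is not None:
        df["intensity"] = spots.intensity
    df.to_csv(path, index=False)


def read_spots_csv(path: PathLike, cell_id: Optional[str] = None) -> SpotSet:
    """Read a spot table (columns cell_id,x,y[,intensity]); optionally
    restrict to one cell id."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError("spots CSV must have 'x' and 'y' columns")
    if cell_id is not None and "cell_id" in df.columns:
        df = df[df["cell_id"].astype(str) == str(cell_id)]
    intensity = df["intensity"].to_numpy() if "intensity" in df.columns else None
    cid = str(df["cell_id"].iloc[0]) if "cell_id" in df.columns and len(df) else ""
    return SpotSet(df[["x", "y"]].to_numpy(dtype=float), cell_id=cid, intensity=intensity)


def write_counts_csv(matrix: CountMatrix, path: PathLike) -> None:
    """Write a count matrix with a '#'-prefixed sample-metadata header.

    Header lines carry the per-sample fraction and replicate plus the
    normalizer gene designations; the body is a plain gene x sample CSV.
    """
    cols = list(matrix.counts.columns)
    lines = [
        "#fraction," + ",".join(str(matrix.samples.at[c, "fraction"]) for c in cols),
        "#replicate," + ",".join(str(matrix.samples.at[c, "replicate"]) for c in cols),
        "#housekeeping," + ",".join(matrix.housekeeping),
        "#spike," + (matrix.spike or ""),
    ]
    body = matrix.counts.to_csv()
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_counts_csv(path: PathLike) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts_csv`."""
    header: dict[str, list[str]] = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, rest = line[1:].partition(",")
            header[key] = rest.split(",") if rest else []
        else:
            body_lines.append(line)
    import io as _io

    counts = pd.read_csv(_io.StringIO("\n".join(body_lines)), index_col=0)
    cols = list(counts.columns)
    for key in ("fraction", "replicate"):
        if key not in header or len(header[key]) != len(cols):
            raise ValueError(f"counts CSV missing a valid #{key} header line")
    replicates = [int(r) if r.isdigit() else r for r in header["replicate"]]
    samples = pd.DataFrame(
        {"fraction": header["fraction"], "replicate": replicates},
        index=pd.Index(cols, name="sample"),
    )
    housekeeping = tuple(g for g in header.get("housekeeping", []) if g)
    spike = next(iter([g for g in header.get("spike", []) if g]), None)
    return CountMatrix(counts, samples, housekeeping=housekeeping, spike=spike)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
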