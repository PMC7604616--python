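"""Configuration-driven orchestration: simulate -> analyze -> report.

A single flat YAML/dict configuration drives every stage; a master seed
derives per-stage seeds by fixed offsets, so one integer reproduces the
whole run.  Outputs land under an output directory together with a JSON
run manifest recording the config snapshot, package version, timestamps
and a SHA-256 checksum of every file written — re-running with the same
config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import io as zio
from .fractions import enrichment_frame, ps_cb_enrichment
from .motifs import (
    MotifSpec,
    RegionParams,
    detect_ga_rich_regions,
    motif_enrichment,
    motif_region_overlap,
    scan_motif,
    summarize_groups,
)
from .spatial import CompartmentSpec, PlaParams, call_pla_dots, classify_dots, compute_pdi
from .synthetic import (
    CellSimParams,
    FractionSimParams,
    PlaSimParams,
    RegionPlant,
    SpotSimParams,
    UtrSimParams,
    derive_seed,
    gen_cell,
    gen_fraction_counts,
    gen_pla_image,
    gen_spots,
    gen_utr_set,
)

__all__ = ["ConfigError", "RunManifest", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger("zipquant")

# Fixed per-stage seed offsets from the master seed.
_SEED_OFFSETS = {"utr": 11, "cell": 22, "spots": 33, "pla": 44, "counts": 55}

# Allowed configuration schema: section -> allowed keys (None = any keys).
_SCHEMA: Mapping[str, Optional[set]] = {
    "seed": None,
    "outdir": None,
    "stages": {"simulate", "scan", "pdi", "pla", "fractions"},
    "inputs": {"fasta", "groups", "label_tiff", "spots", "pla_image", "counts"},
    "utr_sim": {
        "n_per_group",
        "length_range",
        "background_alphabet_weights",
        "motif_rate_localized",
        "motif_rate_control",
        "region_plant",
        "group_labels",
    },
    "cell_sim": {"image_size", "cell_radius", "nucleus_radius", "nucleus_offset"},
    "spot_sim": {"n_spots", "bias_exponent", "support"},
    "pla_sim": {
        "background_mean",
        "background_sd",
        "n_dots",
        "dot_amplitude",
        "dot_radius",
        "dot_region_split",
        "band_fraction",
    },
    "fraction_sim": {
        "true_ratio_per_gene",
        "baseline",
        "library_size_factors",
        "housekeeping",
        "spike",
        "noise",
    },
    "motif": {"consensus"},
    "region": {"window", "min_ga", "min_len"},
    "compartments": {"band_fraction"},
    "pla_params": {"k_sd", "min_dot_area"},
    "enrichment": {"n_tests"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "zipquant_run",
    "stages": {"simulate": True, "scan": True, "pdi": True, "pla": True, "fractions": True},
    "utr_sim": {
        "n_per_group": 30,
        "length_range": [300, 800],
        "motif_rate_localized": 1.0,
        "motif_rate_control": 0.15,
        "region_plant": {"length": 171, "ga_fraction": 0.85},
    },
    "cell_sim": {"image_size": 256, "cell_radius": 100, "nucleus_radius": 30},
    "spot_sim": {"n_spots": 500, "bias_exponent": 0.0, "support": "whole_cell"},
    "pla_sim": {"n_dots": 10, "dot_amplitude": 100.0, "dot_region_split": 0.5},
    "fraction_sim": {"true_ratio_per_gene": {"RAB13": 3.0, "NET1": 2.0, "CTRL": 1.0}},
    "motif": {},
    "region": {},
    "compartments": {"band_fraction": 0.1},
    "pla_params": {},
    "enrichment": {"n_tests": 1},
}


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    seed: int
    package_version: str
    started: float
    finished: float = 0.0
    checksums: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "package_version": self.package_version,
            "started": self.started,
            "finished": self.finished,
            "checksums": self.checksums,
        }


def validate_config(config: Mapping[str, Any]) -> dict:
    """Validate a configuration, collecting every offending key.

    Unknown sections or keys are rejected before any computation, listing
    all of them at once.
    """
    errors = []
    for section, value in config.items():
        if section not in _SCHEMA:
            errors.append(f"unknown section {section!r}")
            continue
        allowed = _SCHEMA[section]
        if allowed is None:
            continue
        if not isinstance(value, Mapping):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key in value:
            if key not in allowed:
                errors.append(f"unknown key {section}.{key}")
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    merged: dict = {}
    for section, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            merged[section] = {**default, **dict(config.get(section, {}))}
        else:
            merged[section] = config.get(section, default)
    for section in config:
        if section not in merged:
            merged[section] = config[section]
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _utr_params(cfg: dict, seed: int) -> UtrSimParams:
    kw = dict(cfg["utr_sim"])
    if kw.get("region_plant"):
        kw["region_plant"] = RegionPlant(**kw["region_plant"])
    if "length_range" in kw:
        kw["length_range"] = tuple(kw["length_range"])
    if "group_labels" in kw:
        kw["group_labels"] = tuple(kw["group_labels"])
    return UtrSimParams(seed=seed, **kw)


def run_pipeline(
    config: Mapping[str, Any],
    outdir: Optional[os.PathLike] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run the configured stages in dependency order.

    Stage failures abort with a diagnostic naming the stage.  Returns the
    run manifest (also written as ``manifest.json`` in the output
    directory, atomically).
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg["seed"])
    out = Path(outdir) if outdir is not None else Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg["outdir"] = str(out)

    from . import __version__

    manifest = RunManifest(
        config=cfg, seed=master, package_version=__version__, started=time.time()
    )
    written: list[Path] = []
    stages = cfg["stages"]
    state: dict[str, Any] = {}

    def emit(path: Path) -> None:
        written.append(path)

    try:
        if stages.get("simulate"):
            _stage_simulate(cfg, master, out, state, emit)
        if stages.get("scan"):
            _stage_scan(cfg, out, state, emit)
        if stages.get("pdi"):
            _stage_pdi(cfg, out, state, emit)
        if stages.get("pla"):
            _stage_pla(cfg, out, state, emit)
        if stages.get("fractions"):
            _stage_fractions(cfg, out, state, emit)
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest.finished = time.time()
    manifest.checksums = {p.name: _sha256(p) for p in written}
    _write_manifest(manifest, out / "manifest.json")
    return manifest


def _write_manifest(manifest: RunManifest, path: Path) -> None:
    payload = json.dumps(manifest.as_dict(), indent=2, default=str) + "\n"
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _stage_simulate(cfg, master, out, state, emit) -> None:
    logger.info("stage simulate: writing synthetic inputs to %s", out)
    records, truth = gen_utr_set(_utr_params(cfg, derive_seed(master, _SEED_OFFSETS["utr"])))
    state["records"] = records
    zio.write_fasta(records, out / "utrs.fasta")
    emit(out / "utrs.fasta")
    pd.DataFrame({"id": [r.id for r in records], "group": [r.group for r in records]}).to_csv(
        out / "groups.csv", index=False
    )
    emit(out / "groups.csv")
    zio.write_json(truth, out / "truth_utrs.json")
    emit(out / "truth_utrs.json")

    cell = gen_cell(
        CellSimParams(seed=derive_seed(master, _SEED_OFFSETS["cell"]), **cfg["cell_sim"])
    )
    state["cell"] = cell
    zio.write_label_tiff(cell, out / "cell_labels.tif")
    emit(out / "cell_labels.tif")

    spots = gen_spots(
        cell, SpotSimParams(seed=derive_seed(master, _SEED_OFFSETS["spots"]), **cfg["spot_sim"])
    )
    state["spots"] = spots
    zio.write_spots_csv(spots, out / "spots.csv")
    emit(out / "spots.csv")

    image, pla_truth = gen_pla_image(
        cell, PlaSimParams(seed=derive_seed(master, _SEED_OFFSETS["pla"]), **cfg["pla_sim"])
    )
    state["pla_image"] = image
    zio.write_image_tiff(image, out / "pla_image.tif")
    emit(out / "pla_image.tif")
    zio.write_json(pla_truth, out / "truth_pla.json")
    emit(out / "truth_pla.json")

    matrix, ratios = gen_fraction_counts(
        FractionSimParams(
            seed=derive_seed(master, _SEED_OFFSETS["counts"]),
            **{
                k: (
                    tuple(v)
                    if k in ("library_size_factors", "housekeeping") and v is not None
                    else v
                )
                for k, v in cfg["fraction_sim"].items()
            },
        )
    )
    state["counts"] = matrix
    zio.write_counts_csv(matrix, out / "counts.csv")
    emit(out / "counts.csv")
    zio.write_json(ratios, out / "truth_ratios.json")
    emit(out / "truth_ratios.json")


def _stage_scan(cfg, out, state, emit) -> None:
    logger.info("stage scan: motif/region analysis")
    if "records" not in state:
        inputs = cfg.get("inputs", {})
        state["records"] = zio.read_utr_set(inputs["fasta"], inputs.get("groups"))
    records = state["records"]
    spec = MotifSpec(**cfg["motif"])
    rparams = RegionParams(**cfg["region"])
    hits = [h for r in records for h in scan_motif(r, spec)]
    regions = [
        g
        for r in records
        if len(r) >= rparams.window
        for g in detect_ga_rich_regions(r, rparams)
    ]
    seqs = {r.id: r.sequence for r in records}
    zio.write_features_bed(hits, out / "hits.bed", sequences=seqs)
    emit(out / "hits.bed")
    zio.write_features_csv(hits, out / "hits.csv")
    emit(out / "hits.csv")
    zio.write_features_bed(regions, out / "regions.bed")
    emit(out / "regions.bed")
    zio.write_features_csv(regions, out / "regions.csv")
    emit(out / "regions.csv")
    per_utr, per_group = summarize_groups(records, spec, rparams)
    per_utr.to_csv(out / "summary_per_utr.csv", index=False)
    emit(out / "summary_per_utr.csv")
    per_group.to_csv(out / "summary_per_group.csv", index=False)
    emit(out / "summary_per_group.csv")
    overlap = motif_region_overlap(hits, regions) if hits else None
    groups = sorted({r.group for r in records})
    enrich = None
    if len(groups) == 2:
        flags = {
            g: [bool(scan_motif(r, spec)) for r in records if r.group == g] for g in groups
        }
        enrich = motif_enrichment(
            flags[groups[0]], flags[groups[1]], int(cfg["enrichment"]["n_tests"])
        )
    zio.write_json(
        {
            "overlap": None
            if overlap is None
            else {
                "n_inside": overlap.n_inside,
                "n_total": overlap.n_total,
                "fraction": overlap.fraction,
            },
            "enrichment": None
            if enrich is None
            else {
                "table": enrich.table,
                "odds_ratio": enrich.odds_ratio,
                "p_value": enrich.p_value,
                "p_bonferroni": enrich.p_bonferroni,
                "n_tests": enrich.n_tests,
            },
        },
        out / "motif_stats.json",
    )
    emit(out / "motif_stats.json")


def _require_cell(cfg, state):
    if "cell" not in state:
        state["cell"] = zio.read_label_tiff(cfg["inputs"]["label_tiff"])
    return state["cell"]


def _stage_pdi(cfg, out, state, emit) -> None:
    logger.info("stage pdi")
    cell = _require_cell(cfg, state)
    if "spots" not in state:
        state["spots"] = zio.read_spots_csv(cfg["inputs"]["spots"])
    result = compute_pdi(cell, state["spots"])
    pd.DataFrame(
        [
            {
                "cell_id": state["spots"].cell_id or "cell_1",
                "pdi": result.pdi,
                "n_spots": result.n_spots,
                "reference_moment": result.reference_moment,
            }
        ]
    ).to_csv(out / "pdi.csv", index=False)
    emit(out / "pdi.csv")


def _stage_pla(cfg, out, state, emit) -> None:
    logger.info("stage pla")
    cell = _require_cell(cfg, state)
    if "pla_image" not in state:
        state["pla_image"] = zio.read_image_tiff(cfg["inputs"]["pla_image"])
    params = PlaParams(**cfg["pla_params"])
    dots = call_pla_dots(state["pla_image"], cell, params)
    spec = CompartmentSpec.from_fraction(cell, float(cfg["compartments"]["band_fraction"]))
    summary = classify_dots(cell, dots, spec)
    pd.DataFrame(
        [
            {
                "cell_id": "cell_1",
                "n_total": summary.n_total,
                "n_peripheral": summary.n_peripheral,
                "n_body": summary.n_body,
                "n_excluded": summary.n_excluded,
            }
        ]
    ).to_csv(out / "pla_summary.csv", index=False)
    emit(out / "pla_summary.csv")
    pd.DataFrame([{"x": d.x, "y": d.y, "peak": d.peak, "area": d.area} for d in dots]).to_csv(
        out / "pla_dots.csv", index=False
    )
    emit(out / "pla_dots.csv")


def _stage_fractions(cfg, out, state, emit) -> None:
    logger.info("stage fractions")
    if "counts" not in state:
        state["counts"] = zio.read_counts_csv(cfg["inputs"]["counts"])
    records = ps_cb_enrichment(state["counts"])
    enrichment_frame(records).to_csv(out / "fraction_enrichment.csv", index=False)
    emit(out / "fraction_enrichment.csv")
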