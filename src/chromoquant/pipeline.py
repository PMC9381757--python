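"""Config-driven orchestration of the analysis stages with provenance.

A :class:`RunConfig` (YAML on disk) selects stages and carries every
tunable parameter; :func:`run_pipeline` executes the requested stages in
dependency order, writes one TSV per result table, and emits a provenance
file recording the resolved config, its hash and the package version.
Re-running with the same config and inputs is byte-identical except for the
timestamp line in the provenance file: all randomness flows from the config
seed and tables carry no timestamps.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import chromoquant
from chromoquant.foci import FociRecord, bin_and_tabulate, detect_foci
from chromoquant.profiles import delineate_chromocenter, extract_profile, pcc_enrichment, summarize_pcc
from chromoquant.satellites import bisulfite_conversion, count_satellite_reads
from chromoquant.synthetic import (
    SyntheticFociSpec,
    SyntheticNucleusSpec,
    SyntheticReadSpec,
    generate_fastq,
    generate_fish_image,
    generate_nucleus_image,
)

__all__ = ["RunConfig", "run_pipeline", "export_violin_data", "PipelineError"]

logger = logging.getLogger(__name__)

_STAGE_ORDER = ("simulate", "pcc", "foci", "satcount", "satmeth")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["simulate", "pcc"],
    "simulate": {
        "modes": ["colocalized", "cloudy", "diffuse"],
        "n_nuclei_per_mode": 20,
        "nucleus": {},       # overrides for SyntheticNucleusSpec fields
        "fish": None,        # overrides for SyntheticFociSpec fields, or None
        "reads": None,       # overrides for SyntheticReadSpec fields, or None
        "write_images": False,
    },
    "pcc": {
        "dapi_channel": "DAPI",
        "marker_channel": "marker",
        "half_length_um": 2.5,
    },
    "foci": {
        "fish_channel": "FISH",
        "spot_sigma_um": 0.3,
        "k": 6.0,
        "min_separation_um": 0.6,
    },
    "satcount": {"fastq": None},
    "satmeth": {"fastq": None},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict) and key not in (
            "nucleus", "fish", "reads",
        ):
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class RunConfig:
    """Resolved pipeline configuration (defaults filled in, keys validated)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        cfg = cls(_merge(DEFAULT_CONFIG, overrides))
        unknown = set(cfg.data["stages"]) - set(_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {_STAGE_ORDER}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        return cls.from_dict(raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def __getitem__(self, key):
        return self.data[key]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def export_violin_data(long_table: pd.DataFrame, path: Path) -> Path:
    """Write the long-format per-chromocenter table consumed by violin plots.

    One row per chromocenter with its group columns; an empty input still
    produces a header-only file.
    """
    cols = ["pcc", "marker", "chromocenter_id", "nucleus_id", "embryo_id", "stage", "lineage"]
    df = long_table.reindex(columns=[c for c in cols if c in long_table.columns] or cols)
    _write_tsv(df, path)
    return path


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Path]:
    """Execute the configured stages and return the output files by name.

    Stages run in dependency order (``simulate`` before analyses).  Any
    stage failure raises :class:`PipelineError` naming the stage; a
    ``provenance.yaml`` with the resolved config, config hash and package
    version is written last, so its presence marks a complete run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in _STAGE_ORDER if s in config["stages"]]
    outputs: dict[str, Path] = {}
    state: dict = {}

    for stage in stages:
        try:
            handler = _STAGE_HANDLERS[stage]
            handler(config, out_dir, state, outputs)
        except Exception as exc:
            (out_dir / "INCOMPLETE").write_text(f"stage {stage} failed: {exc}\n")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    prov = {
        "package": "chromoquant",
        "version": chromoquant.__version__,
        "config_hash": config.config_hash,
        "config": config.data,
        "outputs": {k: str(v.name) for k, v in outputs.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    prov_path = out_dir / "provenance.yaml"
    prov_path.write_text(yaml.safe_dump(prov, sort_keys=True))
    outputs["provenance"] = prov_path
    incomplete = out_dir / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return outputs


# ----------------------------------------------------------------- stages


def _stage_simulate(config: RunConfig, out_dir: Path, state: dict, outputs: dict) -> None:
    sim = config["simulate"]
    seed_root = int(config["seed"])
    nuc_ss, fish_ss, reads_ss = np.random.SeedSequence(seed_root).spawn(3)
    nucleus_seeds = nuc_ss.generate_state(10_000, dtype=np.uint32)

    nuclei = []  # (mode, index, image, truth)
    truth_frames = []
    k = 0
    for mode in sim["modes"]:
        for i in range(int(sim["n_nuclei_per_mode"])):
            spec = SyntheticNucleusSpec(
                marker_mode=mode, seed=int(nucleus_seeds[k]), **(sim["nucleus"] or {})
            )
            k += 1
            image, truth = generate_nucleus_image(spec)
            nucleus_id = f"{mode}_{i:03d}"
            nuclei.append((mode, nucleus_id, image, truth))
            tf = truth.to_frame()
            tf.insert(0, "nucleus_id", nucleus_id)
            truth_frames.append(tf)
            if sim["write_images"]:
                image.to_tiff(out_dir / f"nucleus_{nucleus_id}.tiff")
    state["nuclei"] = nuclei
    if truth_frames:
        truth_df = pd.concat(truth_frames, ignore_index=True)
        path = out_dir / "simulated_chromocenters.tsv"
        _write_tsv(truth_df, path)
        outputs["simulated_chromocenters"] = path

    if sim["fish"] is not None:
        spec = SyntheticFociSpec(seed=int(fish_ss.generate_state(1)[0]), **sim["fish"])
        image, mask, truth = generate_fish_image(spec)
        state["fish"] = (image, mask, truth)
        path = out_dir / "simulated_foci_truth.tsv"
        _write_tsv(truth.table, path)
        outputs["simulated_foci_truth"] = path
        if sim["write_images"]:
            image.to_tiff(out_dir / "fish.tiff")
            mask.to_tiff(out_dir / "fish_mask.tiff")

    if sim["reads"] is not None:
        spec = SyntheticReadSpec(seed=int(reads_ss.generate_state(1)[0]), **sim["reads"])
        fastq = out_dir / "simulated_reads.fastq"
        truth = generate_fastq(spec, fastq)
        state["fastq"] = fastq
        state["read_truth"] = truth
        outputs["simulated_reads"] = fastq


def _stage_pcc(config: RunConfig, out_dir: Path, state: dict, outputs: dict) -> None:
    if "nuclei" not in state:
        raise ValueError("pcc stage requires the simulate stage (or image inputs)")
    p = config["pcc"]
    records = []
    for mode, nucleus_id, image, truth in state["nuclei"]:
        for j, center in enumerate(truth.centroids_px):
            profile = extract_profile(
                image, center, half_length=float(p["half_length_um"]),
                channels=[p["dapi_channel"], p["marker_channel"]],
            )
            segment = delineate_chromocenter(profile, p["dapi_channel"])
            if segment is None or len(segment) < 3:
                continue
            records.append(
                pcc_enrichment(
                    profile, segment, p["marker_channel"], p["dapi_channel"],
                    metadata={
                        "chromocenter_id": f"{nucleus_id}_cc{j}",
                        "nucleus_id": nucleus_id,
                        "embryo_id": mode,
                    },
                )
            )
    summary, long_table = summarize_pcc(records, group_by=["embryo_id", "marker"])
    pcc_path = out_dir / "pcc_records.tsv"
    _write_tsv(pd.DataFrame([r.to_row() for r in records]), pcc_path)
    summary_path = out_dir / "pcc_summary.tsv"
    _write_tsv(summary, summary_path)
    violin_path = export_violin_data(long_table, out_dir / "pcc_violin.tsv")
    outputs.update(pcc_records=pcc_path, pcc_summary=summary_path, pcc_violin=violin_path)


def _stage_foci(config: RunConfig, out_dir: Path, state: dict, outputs: dict) -> None:
    if "fish" not in state:
        raise ValueError("foci stage requires simulate with a 'fish' spec")
    f = config["foci"]
    image, mask, truth = state["fish"]
    records = []
    for label in mask.ids():
        coords, saturated = detect_foci(
            image, f["fish_channel"], mask.binary(label),
            spot_sigma_um=float(f["spot_sigma_um"]), k=float(f["k"]),
            min_separation_um=float(f["min_separation_um"]),
        )
        records.append(FociRecord(nucleus_id=str(label), foci_coordinates=coords, saturated=saturated))
    rec_path = out_dir / "foci_records.tsv"
    _write_tsv(pd.DataFrame([r.to_row() for r in records]), rec_path)
    table = bin_and_tabulate(records)
    tab_path = out_dir / "foci_proportions.tsv"
    _write_tsv(table, tab_path)
    outputs.update(foci_records=rec_path, foci_proportions=tab_path)


def _sat_stage(kind: str):
    def handler(config: RunConfig, out_dir: Path, state: dict, outputs: dict) -> None:
        fastq = config[kind]["fastq"] or state.get("fastq")
        if fastq is None:
            raise ValueError(f"{kind} stage needs a 'fastq' path or simulate with 'reads'")
        assay = count_satellite_reads if kind == "satcount" else bisulfite_conversion
        result = assay(fastq)
        row = result.to_row()
        row["source"] = Path(row["source"]).name  # keep tables run-directory independent
        path = out_dir / f"{kind}.tsv"
        _write_tsv(pd.DataFrame([row]), path)
        outputs[kind] = path

    return handler


_STAGE_HANDLERS = {
    "simulate": _stage_simulate,
    "pcc": _stage_pcc,
    "foci": _stage_foci,
    "satcount": _sat_stage("satcount"),
    "satmeth": _sat_stage("satmeth"),
}
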