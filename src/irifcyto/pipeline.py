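"""End-to-end pipeline: simulate/load -> segment -> quantify -> classify ->
discriminate -> report, fully determined by one declarative config + seed.

Outputs written to the configured directory:

* ``records.csv``                 per-nucleus intensity records and phenotype calls
* ``histogram_<condition>.csv``   pooled pixel histogram, 4096 rows (intensity,count)
* ``phenotype_fractions.csv``     per-class percentages, mean +/- SEM over replicates
* ``discrimination.json``         verdict and components per non-baseline condition
* ``manifest.json``               full parameters, package versions, seeds, stage counts
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discriminate import discriminate_model
from .foci import (FociParams, analyze_nuclei, normalized_foci_intensity,
                   reference_diffuse_mean)
from .histogram import N_BINS, PixelHistogram, pixel_histogram
from .io import read_field
from .phenotype import PHENOTYPES, PhenotypeThresholds, classify_nucleus, phenotype_fractions
from .segmentation import SegmentationParams, mask_target, sample_nuclei, segment_nuclei
from .simulate import SimulationConfig, simulate_field

log = logging.getLogger("irifcyto")


@dataclass
class ConditionSpec:
    """One experimental condition: either a simulation config or image paths."""

    name: str
    simulate: Optional[SimulationConfig] = None
    dapi_path: Optional[str] = None
    target_path: Optional[str] = None
    image_path: Optional[str] = None  # two-page TIFF

    def validate(self) -> None:
        modes = sum([self.simulate is not None,
                     self.image_path is not None,
                     self.dapi_path is not None or self.target_path is not None])
        if modes != 1:
            raise ValueError(
                f"condition {self.name!r}: give exactly one of 'simulate', "
                f"'image', or 'dapi'+'target'"
            )
        if (self.dapi_path is None) != (self.target_path is None):
            raise ValueError(f"condition {self.name!r}: 'dapi' and 'target' must be paired")


@dataclass
class PipelineConfig:
    conditions: list[ConditionSpec]
    baseline: str                       # reference (unirradiated) condition name
    output_dir: str = "irifcyto_out"
    seed: int = 0
    replicates: int = 1
    sample_n: Optional[int] = None      # nuclei sampled per condition-replicate
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    foci: FociParams = field(default_factory=FociParams)
    classification: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    discrimination_q: float = 0.99
    discrimination_tau: float = 0.25

    def validate(self) -> None:
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError(f"condition names must be unique, got {names}")
        if self.baseline not in names:
            raise ValueError(f"baseline {self.baseline!r} is not a defined condition ({names})")
        for c in self.conditions:
            c.validate()
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    conditions = []
    for name, spec in raw["conditions"].items():
        spec = spec or {}
        sim = spec.get("simulate")
        conditions.append(ConditionSpec(
            name=name,
            simulate=SimulationConfig(condition=name, **sim) if sim is not None else None,
            image_path=spec.get("image"),
            dapi_path=spec.get("dapi"),
            target_path=spec.get("target"),
        ))
    cfg = PipelineConfig(
        conditions=conditions,
        baseline=raw["baseline"],
        output_dir=raw.get("output_dir", "irifcyto_out"),
        seed=int(raw.get("seed", 0)),
        replicates=int(raw.get("replicates", 1)),
        sample_n=raw.get("sample_nuclei"),
        segmentation=SegmentationParams(**raw.get("segmentation", {})),
        foci=FociParams(**raw.get("foci", {})),
        classification=PhenotypeThresholds(**raw.get("classification", {})),
        discrimination_q=float(raw.get("discrimination", {}).get("q", 0.99)),
        discrimination_tau=float(raw.get("discrimination", {}).get("tau", 0.25)),
    )
    cfg.validate()
    return cfg


def _acquire_field(cond: ConditionSpec, replicate: int, seed: int):
    if cond.simulate is not None:
        sim = cond.simulate.with_(seed=seed, condition=cond.name)
        fov, _truth = simulate_field(sim)
        return fov
    try:
        if cond.image_path is not None:
            return read_field(cond.image_path, condition=cond.name, replicate_id=replicate)
        return read_field(cond.dapi_path, cond.target_path,
                          condition=cond.name, replicate_id=replicate)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"condition {cond.name!r}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    record_rows = []
    hist_by_condition: dict[str, PixelHistogram] = {}
    labels_by_condition: dict[str, list[list[str]]] = {c.name: [] for c in config.conditions}
    records_by_condition: dict[str, list] = {c.name: [] for c in config.conditions}
    stage_counts: dict[str, dict] = {}

    # pass 1: per condition/replicate -> segment, quantify
    per_rep_records = {}
    for cond in config.conditions:
        pooled_counts = np.zeros(N_BINS, dtype=np.int64)
        pooled_nuclei = 0
        for rep in range(config.replicates):
            seed = config.seed + 1000 * rep + 17 * config.conditions.index(cond)
            fov = _acquire_field(cond, rep, seed)
            mask = segment_nuclei(fov.dapi, config.segmentation)
            n_found = len(mask)
            if config.sample_n is not None and config.sample_n < n_found:
                mask = sample_nuclei(mask, config.sample_n, seed=seed + 7)
            log.info("condition=%s replicate=%d nuclei=%d (kept %d)",
                     cond.name, rep, n_found, len(mask))
            collections = mask_target(fov.target, mask)
            hist = pixel_histogram(collections, condition=cond.name)
            pooled_counts += hist.counts
            pooled_nuclei += hist.n_nuclei
            records = analyze_nuclei(fov.target, mask, config.foci)
            per_rep_records[(cond.name, rep)] = records
            records_by_condition[cond.name].extend(records)
            stage_counts.setdefault(cond.name, {})[f"replicate_{rep}"] = {
                "nuclei_segmented": n_found,
                "nuclei_kept": len(mask),
                "pixels": hist.n_pixels,
            }
        hist_by_condition[cond.name] = PixelHistogram(
            counts=pooled_counts, n_nuclei=pooled_nuclei, condition=cond.name
        )

    # reference from the baseline condition
    reference = reference_diffuse_mean(records_by_condition[config.baseline])

    # pass 2: normalization, classification
    for cond in config.conditions:
        for rep in range(config.replicates):
            records = per_rep_records[(cond.name, rep)]
            normalized_foci_intensity(records, reference)
            calls = [classify_nucleus(r, reference, config.classification) for r in records]
            labels_by_condition[cond.name].append([c.label for c in calls])
            for r, c in zip(records, calls):
                record_rows.append({
                    "condition": cond.name,
                    "replicate": rep,
                    "nucleus_id": r.nucleus_id,
                    "area": r.area,
                    "mean_all": r.mean_all,
                    "mean_foci": r.mean_foci,
                    "mean_nucleoplasm": r.mean_nucleoplasm,
                    "focus_count": r.focus_count,
                    "focus_area": r.focus_area,
                    "normalized_foci_intensity": r.normalized_foci_intensity,
                    "phenotype": c.label,
                    "rho": c.rho,
                })

    records_df = pd.DataFrame(record_rows)
    records_df.to_csv(outdir / "records.csv", index=False)

    for name, hist in hist_by_condition.items():
        pd.DataFrame({"intensity": np.arange(N_BINS), "count": hist.counts}) \
            .to_csv(outdir / f"histogram_{name}.csv", index=False)

    frac_frames = []
    for name, reps in labels_by_condition.items():
        df = phenotype_fractions(reps).reset_index()
        df.insert(0, "condition", name)
        frac_frames.append(df)
    pd.concat(frac_frames, ignore_index=True).to_csv(
        outdir / "phenotype_fractions.csv", index=False)

    verdicts = {}
    for cond in config.conditions:
        if cond.name == config.baseline:
            continue
        res = discriminate_model(
            hist_by_condition[config.baseline], hist_by_condition[cond.name],
            q=config.discrimination_q, tau=config.discrimination_tau,
            seed=config.seed,
        )
        verdicts[cond.name] = asdict(res)
    with open(outdir / "discrimination.json", "w") as fh:
        json.dump(verdicts, fh, indent=2, sort_keys=True)

    manifest = {
        "irifcyto_version": __version__,
        "seed": config.seed,
        "replicates": config.replicates,
        "baseline": config.baseline,
        "reference_diffuse_mean": reference,
        "sample_n": config.sample_n,
        "segmentation": asdict(config.segmentation),
        "foci": asdict(config.foci),
        "classification": asdict(config.classification),
        "discrimination": {"q": config.discrimination_q, "tau": config.discrimination_tau},
        "conditions": {
            c.name: (asdict(c.simulate) if c.simulate is not None else
                     {"image": c.image_path, "dapi": c.dapi_path, "target": c.target_path})
            for c in config.conditions
        },
        "stage_counts": stage_counts,
        "phenotypes": list(PHENOTYPES),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
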