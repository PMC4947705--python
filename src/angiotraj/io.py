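"""Readers, writers and run configuration.

The canonical interchange format is a pair of long-format CSVs: a samples
table (one row per measurement) and a patients table (one row per patient).
Run configurations are YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import BiomarkerSpec, CohortConfig
from .dataset import PATIENT_COLUMNS, SAMPLE_COLUMNS, LongitudinalDataset
from .hierarchical import McmcSettings
from .pseudotrial import PseudoTrialConfig

__all__ = ["read_dataset", "write_dataset", "RunConfig", "load_config", "write_manifest"]

logger = logging.getLogger("angiotraj")


def patients_path_for(samples_path: str | Path) -> Path:
    """Companion patients CSV path: ``<stem>.patients.csv``."""
    p = Path(samples_path)
    return p.with_name(p.stem + ".patients" + p.suffix)


def write_dataset(dataset: LongitudinalDataset, samples_path: str | Path,
                  patients_path: str | Path | None = None) -> None:
    """Write a dataset as samples + patients CSVs (deterministic layout)."""
    samples_path = Path(samples_path)
    patients_path = Path(patients_path) if patients_path else patients_path_for(samples_path)
    samples_path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g preserves float64 exactly across a write/read cycle
    dataset.samples[SAMPLE_COLUMNS].to_csv(samples_path, index=False,
                                           float_format="%.17g")
    dataset.patients[PATIENT_COLUMNS].to_csv(patients_path, index=False,
                                             float_format="%.17g")


def read_dataset(samples_path: str | Path,
                 patients_path: str | Path | None = None) -> LongitudinalDataset:
    """Load and validate a dataset from its samples (+ patients) CSVs.

    The patients table defaults to the ``<stem>.patients.csv`` companion
    file; if absent, patient metadata is reconstructed assuming every
    patient progressed at their last sample time.
    """
    samples_path = Path(samples_path)
    samples = pd.read_csv(samples_path, float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"samples CSV missing required column(s): {missing}")
    samples = samples[SAMPLE_COLUMNS].astype(
        {"time_days": float, "concentration": float, "is_progression_sample": bool,
         "patient_id": str, "arm": str, "biomarker": str, "visit_label": str}
    )
    samples = samples.sort_values(
        ["patient_id", "biomarker", "time_days"], kind="stable"
    ).reset_index(drop=True)

    ppath = Path(patients_path) if patients_path else patients_path_for(samples_path)
    if ppath.exists():
        patients = pd.read_csv(ppath, float_precision="round_trip")
        missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
        if missing:
            raise ValueError(f"patients CSV missing required column(s): {missing}")
        patients = patients[PATIENT_COLUMNS].astype(
            {"patient_id": str, "arm": str, "pfs_days": float, "progressed": bool}
        )
    else:
        last = samples.groupby("patient_id").agg(
            arm=("arm", "first"), pfs_days=("time_days", "max")
        ).reset_index()
        last["progressed"] = True
        patients = last[PATIENT_COLUMNS]
        logger.warning("no patients table at %s; assuming progression at last sample", ppath)
    ds = LongitudinalDataset(samples, patients)
    logger.info("loaded %s", ds.summary())
    return ds


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    out_dir: str = "angiotraj_out"
    dataset_path: str | None = None
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig())
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    pseudo_trial: PseudoTrialConfig = field(default_factory=PseudoTrialConfig)
    biomarkers: tuple[str, ...] = ("Tie2", "Ang1", "Ca125")
    rule_thresholds: tuple[float, ...] = (0.5,)
    network_cutoff: float = 0.3

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = raw.pop("cohort", {})
    specs = tuple(
        BiomarkerSpec(**{**b, "no_inflection_arms": tuple(b.get("no_inflection_arms", ("standard",)))})
        for b in cohort_raw.pop("biomarkers", [])
    )
    if "visit_grid" in cohort_raw:
        cohort_raw["visit_grid"] = tuple(
            (str(lab), float(day)) for lab, day in cohort_raw["visit_grid"]
        )
    cohort = CohortConfig(biomarkers=specs, **cohort_raw)
    mcmc = McmcSettings(**raw.pop("mcmc", {}))
    ptc = PseudoTrialConfig(**raw.pop("pseudo_trial", {}))
    if "biomarkers" in raw:
        raw["biomarkers"] = tuple(raw["biomarkers"])
    if "rule_thresholds" in raw:
        raw["rule_thresholds"] = tuple(float(t) for t in raw["rule_thresholds"])
    return RunConfig(cohort=cohort, mcmc=mcmc, pseudo_trial=ptc, **raw)


def write_manifest(out_dir: str | Path, config: RunConfig, stage: str,
                   extra: dict | None = None) -> Path:
    """JSON run manifest: seed, config hash and package version per stage."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "angiotraj_version": __version__,
        "config": _to_jsonable(config),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
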