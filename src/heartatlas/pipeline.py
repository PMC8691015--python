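"""End-to-end orchestration: dataset -> agreement, dose and variability
tables (the per-structure reports mirroring a contouring-validation
study's summary tables).

Each stage reads the on-disk dataset written by
:func:`heartatlas.cohort.generate_cohort` and writes tidy CSVs; the
variability stage consumes the per-(patient, observer) volume and dose
tables and produces the per-structure CV/SD/ICC report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import agreement as agr
from .atlas import STRUCTURES, StructureSet
from .cohort import CohortConfig, load_dose
from .dosimetry import dose_metrics
from .geometry import load_mesh, voxelize
from .variability import variability_report

__all__ = [
    "PipelineConfig",
    "load_structure_sets",
    "run_agreement",
    "run_dose",
    "run_variability",
    "run_all",
]

log = logging.getLogger("heartatlas")


@dataclass
class PipelineConfig:
    """Analysis-stage knobs (the cohort has its own config)."""

    analysis_spacing: float = 1.0   # agreement voxel grid, mm isotropic
    resample_max_edge: float = 2.0  # distance-metric mesh refinement, mm
    dvh_bin_width: float = 0.10     # Gy
    n_boot: int = 1000              # beta-SD bootstrap resamples
    seed: int = 0
    write_dvhs: bool = False

    def __post_init__(self):
        if self.analysis_spacing <= 0 or self.dvh_bin_width <= 0:
            raise ValueError("spacing and bin width must be > 0")


def _read_manifest(dataset: Path) -> dict:
    path = Path(dataset) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {dataset}")
    return json.loads(path.read_text())


def load_structure_sets(dataset, patient_entry: dict) -> list[StructureSet]:
    """Load all observers' structure sets for one manifest patient entry.

    Missing mesh files are skipped with a warning (the run continues and
    reports them), matching partial-dataset behavior.
    """
    dataset = Path(dataset)
    sets = []
    for oid, files in sorted(patient_entry["observers"].items()):
        structures = {}
        for name, rel in files.items():
            path = dataset / rel
            if not path.exists():
                log.warning("missing mesh file %s", path)
                continue
            structures[name] = load_mesh(path)
        if "heart" in structures:
            sets.append(
                StructureSet(patient_entry["patient_id"], oid, structures)
            )
        else:
            log.warning(
                "observer %s of %s has no heart contour; skipped",
                oid,
                patient_entry["patient_id"],
            )
    return sets


def run_agreement(
    dataset, config: PipelineConfig | None = None, out_dir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise spatial agreement for every patient in the dataset.

    Returns (records, summary): one record per (patient, structure,
    observer pair) and the per-structure mean over pairs and patients.
    """
    config = config or PipelineConfig()
    manifest = _read_manifest(Path(dataset))
    frames = []
    for entry in manifest["patients"]:
        t0 = time.time()
        sets = load_structure_sets(dataset, entry)
        if len(sets) < 2:
            log.warning("patient %s has <2 observers; skipped",
                        entry["patient_id"])
            continue
        frames.append(
            agr.structure_set_agreement(
                sets,
                spacing=config.analysis_spacing,
                resample_max_edge=config.resample_max_edge,
            )
        )
        log.info("agreement %s: %.1fs", entry["patient_id"], time.time() - t0)
    if not frames:
        raise ValueError("no patients with >= 2 observers")
    records = pd.concat(frames, ignore_index=True)
    summary = agr.aggregate(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "agreement_records.csv", index=False)
        summary.to_csv(out / "agreement_summary.csv", index=False)
    return records, summary


def run_dose(
    dataset, config: PipelineConfig | None = None, out_dir=None
) -> pd.DataFrame:
    """DVH metrics per (patient, observer, structure).

    Structures are voxelized on each patient's dose grid; rows carry the
    structure volume, DMEAN, D2CC, V5GY and any flags.
    """
    config = config or PipelineConfig()
    dataset = Path(dataset)
    manifest = _read_manifest(dataset)
    rows = []
    for entry in manifest["patients"]:
        dose = load_dose(dataset / entry["patient_id"] / "dose.nrrd")
        for sset in load_structure_sets(dataset, entry):
            for name, mesh in sset.structures.items():
                # structures may overhang the dose grid (cranial valve
                # tails); dose is only defined inside it, so clip
                mask = voxelize(mesh, dose.grid, clip=True)
                if mask.count == 0:
                    log.warning(
                        "%s/%s/%s empty on dose grid; skipped",
                        entry["patient_id"], sset.observer_id, name,
                    )
                    continue
                m = dose_metrics(
                    dose, mask, structure=name, bin_width=config.dvh_bin_width
                )
                rows.append(
                    {
                        "patient_id": entry["patient_id"],
                        "observer_id": sset.observer_id,
                        "structure": name,
                        "volume_cc": mesh.volume / 1000.0,
                        "mask_volume_cc": m.volume_cc,
                        "dmean_gy": m.dmean,
                        "d2cc_gy": m.d2cc,
                        "v5gy": m.v5gy,
                        "flags": ";".join(m.flags),
                    }
                )
    metrics = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "dose_metrics.csv", index=False)
    return metrics


def _cells(metrics: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "structure": metrics["structure"],
            "patient": metrics["patient_id"],
            "observer": metrics["observer_id"],
            "value": metrics[value_col],
        }
    )


def run_variability(
    dose_metrics_table: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Per-structure CV/SD/ICC report from the dose-metrics table.

    Volume CV/ICC use the mesh volumes; DMEAN and D2CC CVs the dose
    metrics; V5GY the beta-model SD.  Byte-identical CSV on rerun with
    the same seed.
    """
    config = config or PipelineConfig()
    # keep structure order stable
    metrics = dose_metrics_table.copy()
    metrics["structure"] = pd.Categorical(
        metrics["structure"],
        categories=[s for s in STRUCTURES if s in set(metrics["structure"])],
        ordered=True,
    )
    metrics = metrics.sort_values(
        ["structure", "patient_id", "observer_id"]
    ).reset_index(drop=True)
    metrics["structure"] = metrics["structure"].astype(str)
    report = variability_report(
        volumes=_cells(metrics, "volume_cc"),
        dmean=_cells(metrics, "dmean_gy"),
        d2cc=_cells(metrics, "d2cc_gy"),
        v5gy=_cells(metrics, "v5gy"),
        n_boot=config.n_boot,
        seed=config.seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "variability_report.csv", index=False,
                      float_format="%.10g")
        flags = {
            row["structure"]: sorted(
                {
                    str(v)
                    for c, v in row.items()
                    if c.endswith("_flag") and v
                }
            )
            for _, row in report.iterrows()
        }
        (out / "variability_flags.json").write_text(
            json.dumps(flags, sort_keys=True, indent=1)
        )
    return report


def run_all(
    cohort_config: CohortConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    workdir=".",
    dataset=None,
    force: bool = False,
) -> dict:
    """Generate (or reuse) a dataset and run every analysis stage.

    Returns a dict with the dataset path and the three result tables.
    """
    from .cohort import generate_cohort

    cohort_config = cohort_config or CohortConfig()
    pipeline_config = pipeline_config or PipelineConfig()
    workdir = Path(workdir)
    if dataset is None:
        dataset = workdir / "dataset"
        t0 = time.time()
        generate_cohort(cohort_config, dataset, force=force)
        log.info("cohort generated in %.1fs", time.time() - t0)
    out = workdir / "results"
    records, summary = run_agreement(dataset, pipeline_config, out_dir=out)
    metrics = run_dose(dataset, pipeline_config, out_dir=out)
    report = run_variability(metrics, pipeline_config, out_dir=out)
    run_summary = {
        "dataset": str(dataset),
        "n_agreement_records": int(len(records)),
        "n_dose_rows": int(len(metrics)),
        "structures": sorted(set(records["structure"])),
    }
    (out / "run_summary.json").write_text(
        json.dumps(run_summary, sort_keys=True, indent=1)
    )
    return {
        "dataset": Path(dataset),
        "records": records,
        "summary": summary,
        "dose_metrics": metrics,
        "variability": report,
        "out_dir": out,
    }
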