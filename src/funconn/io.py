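"""Plain-text interchange formats for cohorts and results.

Everything the pipeline reads or writes is delimited text:

* ``subjects.csv`` — one row per subject with demographics and clinical
  covariates (empty cells for controls);
* ``<subject>_timeseries.tsv`` — time x regions matrix with a region-label
  header row;
* ``<subject>_nuisance.tsv`` — time x 8 nuisance regressors (three
  translations in mm, three rotations in degrees, white-matter and
  ventricle signals);
* square matrices (correlation, adjacency) as TSV with a label header;
* a JSON/YAML configuration echo accompanying every output directory.

Every file begins with a ``#`` comment line recording the producing stage,
package version, and configuration hash, and all readers skip such lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CohortConfig, PipelineConfig, config_hash
from .synthetic import Cohort, NuisanceSet, RoiTimeSeries, SubjectRecord

__all__ = [
    "read_subject_table", "write_subject_table",
    "read_timeseries", "write_timeseries",
    "read_nuisance", "write_nuisance",
    "write_matrix", "read_matrix",
    "write_cohort", "load_cohort",
    "write_config_echo",
]

_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male"}
_GROUP_ALIASES = {"patient": "patient", "pm": "patient", "p": "patient",
                  "migraine": "patient",
                  "control": "control", "hc": "control", "c": "control",
                  "healthy": "control"}

_CLINICAL_COLS = ("disease_duration", "attack_frequency", "attack_duration",
                  "pain_intensity")


def _header(stage: str, *configs) -> str:
    h = config_hash(*configs) if configs else "none"
    return f"# funconn v{__version__} stage={stage} config={h}\n"


def write_subject_table(path, subjects: list[SubjectRecord], *,
                        stage: str = "simulate", configs=()) -> None:
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id, "sex": s.sex, "group": s.group,
            "age": s.age,
            **{c: getattr(s, c) for c in _CLINICAL_COLS},
        })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_header(stage, *configs))
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def read_subject_table(path) -> list[SubjectRecord]:
    """Read and validate a subjects CSV, normalizing categorical values."""
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "sex", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dups}")
    records = []
    for _, row in df.iterrows():
        sex_raw = str(row["sex"]).strip().lower()
        grp_raw = str(row["group"]).strip().lower()
        if sex_raw not in _SEX_ALIASES:
            raise ValueError(
                f"subject {row['subject_id']}: unknown sex {row['sex']!r}")
        if grp_raw not in _GROUP_ALIASES:
            raise ValueError(
                f"subject {row['subject_id']}: unknown group {row['group']!r}")
        clinical = {}
        for c in _CLINICAL_COLS:
            v = row.get(c, np.nan)
            clinical[c] = None if pd.isna(v) else float(v)
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            sex=_SEX_ALIASES[sex_raw], group=_GROUP_ALIASES[grp_raw],
            age=float(row["age"]), **clinical,
        ))
    return records


def write_timeseries(path, ts: RoiTimeSeries, *, stage: str = "simulate",
                     configs=()) -> None:
    df = pd.DataFrame(ts.data.T, columns=list(ts.region_labels))
    with open(path, "w") as fh:
        fh.write(_header(stage, *configs))
        fh.write(f"# tr_seconds={ts.tr_seconds}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g",
                  lineterminator="\n")


def read_timeseries(path, tr_seconds: float | None = None) -> RoiTimeSeries:
    tr = tr_seconds
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# tr_seconds=") and tr is None:
                tr = float(line.split("=", 1)[1])
    if tr is None:
        tr = 2.0
    df = pd.read_csv(path, sep="\t", comment="#")
    return RoiTimeSeries(tuple(df.columns), df.to_numpy().T, tr)


_NUISANCE_COLS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_deg", "rot_y_deg", "rot_z_deg", "wm", "csf"]


def write_nuisance(path, nuis: NuisanceSet, *, stage: str = "simulate",
                   configs=()) -> None:
    df = pd.DataFrame(nuis.design().T, columns=_NUISANCE_COLS)
    with open(path, "w") as fh:
        fh.write(_header(stage, *configs))
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g",
                  lineterminator="\n")


def read_nuisance(path) -> NuisanceSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_NUISANCE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"nuisance file missing columns: {sorted(missing)}")
    arr = df[_NUISANCE_COLS].to_numpy().T
    return NuisanceSet(arr[:6], arr[6], arr[7])


def write_matrix(path, matrix: np.ndarray, labels, *, stage: str,
                 configs=()) -> None:
    """Square matrix as TSV with a label header and label index column."""
    df = pd.DataFrame(np.asarray(matrix), index=list(labels),
                      columns=list(labels))
    with open(path, "w") as fh:
        fh.write(_header(stage, *configs))
        df.to_csv(fh, sep="\t", float_format="%.8g", lineterminator="\n")


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.to_numpy(), tuple(str(c) for c in df.columns)


def write_config_echo(path, cohort_config: CohortConfig | None,
                      pipeline_config: PipelineConfig | None) -> None:
    payload = {
        "funconn_version": __version__,
        "cohort": cohort_config.to_dict() if cohort_config else None,
        "pipeline": pipeline_config.to_dict() if pipeline_config else None,
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a generated cohort as the pipeline's on-disk input layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfgs = (cohort.config,)
    write_subject_table(outdir / "subjects.csv", cohort.subjects, configs=cfgs)
    for sid, ts in cohort.timeseries.items():
        write_timeseries(outdir / f"{sid}_timeseries.tsv", ts, configs=cfgs)
    for sid, nuis in cohort.nuisance.items():
        write_nuisance(outdir / f"{sid}_nuisance.tsv", nuis, configs=cfgs)
    write_config_echo(outdir / "cohort_config.json", cohort.config, None)


def load_cohort(indir) -> tuple[list[SubjectRecord], dict, dict]:
    """Read a cohort directory: subjects table, time series, nuisance (if any)."""
    indir = Path(indir)
    subjects = read_subject_table(indir / "subjects.csv")
    timeseries, nuisance = {}, {}
    for s in subjects:
        ts_path = indir / f"{s.subject_id}_timeseries.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time series for {s.subject_id}")
        timeseries[s.subject_id] = read_timeseries(ts_path)
        np_path = indir / f"{s.subject_id}_nuisance.tsv"
        if np_path.exists():
            nuisance[s.subject_id] = read_nuisance(np_path)
    return subjects, timeseries, nuisance
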