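"""End-to-end pipeline: cohort → indices → encoding → Auto-CM map → ACS.

Configuration is a single validated object (unknown keys rejected); every
stage writes plain-text artifacts into a run directory and all randomness
flows from one root seed recorded in the run log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .acs import ACSParams, export_acs, run_acs
from .autocm import (
    AutoCMParams,
    export_map,
    link_strengths,
    minimum_spanning_tree,
    strengths_to_distances,
    train_autocm,
)
from .cohort import CohortTable, default_study_spec, simulate_cohort
from .indices import default_toxicity_weights
from .preprocess import VariableEncoding, encode_cohort
from .schema import default_element_schema

__all__ = [
    "PipelineConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "cohort.csv", "indices.csv", "encoded.csv", "linkstrengths.csv",
    "map.graphml", "map.dot", "acs_trajectories.csv", "acs_hierarchy.json",
    "run_log.txt",
)

_INDEX_COLUMNS = ("FLI", "VAI", "FRAM", "MET_S", "OB", "TI", "CV_RISK")


class AutoCMSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    contraction: float | None = None
    learning_rate: float = 0.1
    max_epochs: int = 2000
    tolerance: float = 1e-6


class ACSSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    clamp_variable: str = "FRAM"  # probe CV risk, the study's activation variable
    rest_value: float = 0.5
    step_gain: float = 0.1
    max_iterations: int = 5000
    steady_tolerance: float = 1e-5
    exclude_elements: bool = False  # prune the 31 single-element variables


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohort_csv: str | None = None  # when None, simulate the default cohort
    n_subjects: int = 95
    seed: int = 0
    encoding_mode: str = "dichotomic"
    autocm: AutoCMSettings = Field(default_factory=AutoCMSettings)
    acs: ACSSettings = Field(default_factory=ACSSettings)
    toxicity_weights: dict[str, float] | None = None
    output_dir: str = "autocmap_run"


def write_cohort_csv(table: CohortTable, path: str | Path) -> Path:
    """Write a cohort as CSV: subject_id column then variable columns."""
    path = Path(path)
    df = table.to_frame()
    df[np.column_stack([np.zeros(len(df), bool), table.missing_mask])] = np.nan
    df.to_csv(path, index=False, na_rep="")
    return path


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read a cohort CSV (header of variable names, one row per subject).

    Empty cells become missing-mask entries. Unknown columns raise with the
    nearest known variable names; duplicate subject ids raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if "subject_id" not in df.columns:
        raise ValueError("cohort CSV must have a 'subject_id' column")
    ids = df["subject_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")

    specs, _, _ = default_study_spec()
    known_units = {s.variable_name: s.unit for s in specs}
    known_units.update({"MET_S": "bool", "OB": "bool", "TI": "", "FLI": "",
                        "VAI": "", "FRAM": "points"})
    variables: list[tuple[str, str]] = []
    for col in df.columns:
        if col == "subject_id":
            continue
        if col not in known_units:
            near = [k for k in known_units if k[:2].lower() == col[:2].lower()]
            raise ValueError(
                f"unknown column {col!r}; nearest schema matches: {near or 'none'}"
            )
        variables.append((col, known_units[col]))

    n, p = len(ids), len(variables)
    values = np.empty((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for j, (name, _) in enumerate(variables):
        for i, cell in enumerate(df[name].tolist()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"malformed numeric cell at row {i + 2}, column {name!r}: {cell!r}"
                ) from exc
    return CohortTable(subject_ids=ids, variables=variables, values=values,
                       missing_mask=mask)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and emit the full artifact set into the run directory.

    Emits cohort.csv, indices.csv, encoded.csv, linkstrengths.csv,
    map.graphml, map.dot, acs_trajectories.csv, acs_hierarchy.json and
    run_log.txt. Fully reproducible given config + seed; partial outputs are
    preserved on stage failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"autocmap {__version__}", f"numpy {np.__version__}",
                 f"seed {config.seed}"]

    # --- cohort ---
    if config.cohort_csv:
        table = _stage("cohort")(read_cohort_csv)(config.cohort_csv)
        log_lines.append(f"cohort: loaded from {config.cohort_csv}")
    else:
        specs, structure, _ = default_study_spec()
        table = _stage("cohort")(simulate_cohort)(specs, structure,
                                                  n=config.n_subjects,
                                                  seed=config.seed)
        log_lines.append(f"cohort: simulated n={config.n_subjects}")
    write_cohort_csv(table, out / "cohort.csv")

    # --- indices table ---
    df = table.to_frame()
    idx_cols = ["subject_id"] + [c for c in _INDEX_COLUMNS if c in df.columns]
    df[idx_cols].to_csv(out / "indices.csv", index=False)
    if config.toxicity_weights:
        log_lines.append("toxicity weights: user override")
    else:
        log_lines.append("toxicity weights: default (1/reference_upper)")

    # --- encoding ---
    encodings = [VariableEncoding(name, mode=config.encoding_mode)
                 for name, _ in table.variables]
    matrix, labels = _stage("encode")(encode_cohort)(table, encodings)
    enc_df = pd.DataFrame(matrix, columns=labels)
    enc_df.insert(0, "subject_id", table.subject_ids)
    enc_df.to_csv(out / "encoded.csv", index=False)

    # --- Auto-CM + map ---
    params = AutoCMParams(contraction=config.autocm.contraction,
                          learning_rate=config.autocm.learning_rate,
                          max_epochs=config.autocm.max_epochs,
                          tolerance=config.autocm.tolerance,
                          seed=config.seed)
    model = _stage("autocm")(train_autocm)(matrix, params)
    log_lines.append(
        f"autocm: C={model.contraction:g} epochs={model.epochs_run} "
        f"converged={model.converged}"
    )
    lsm = link_strengths(model, labels=labels)
    pd.DataFrame(lsm.strengths, index=labels, columns=labels).to_csv(
        out / "linkstrengths.csv"
    )
    smap = minimum_spanning_tree(strengths_to_distances(lsm), labels)
    export_map(smap, "graphml", str(out / "map.graphml"))
    export_map(smap, "dot", str(out / "map.dot"))
    log_lines.append(f"map: central node {smap.central_node}")

    # --- ACS ---
    subset = None
    if config.acs.exclude_elements:
        element_syms = set(default_element_schema().symbols)
        subset = tuple(lab for lab in labels if lab not in element_syms)
    acs_params = ACSParams(clamp_variable=config.acs.clamp_variable,
                           rest_value=config.acs.rest_value,
                           step_gain=config.acs.step_gain,
                           max_iterations=config.acs.max_iterations,
                           steady_tolerance=config.acs.steady_tolerance,
                           variable_subset=subset)
    result = _stage("acs")(run_acs)(lsm, acs_params)
    export_acs(result, "csv", str(out / "acs_trajectories.csv"))
    export_acs(result, "json", str(out / "acs_hierarchy.json"))
    log_lines.append(
        f"acs: clamp={result.clamp_variable} iterations={result.iterations} "
        f"converged={result.converged}"
    )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
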