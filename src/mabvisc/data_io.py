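"""CSV/YAML/JSON readers and writers shared by all pipeline stages.

Cohorts travel as two CSV tables whose column names carry the units:

* molecules: ``molecule_id, dnp_um2_per_s, kd_ml_per_g, plasmon_shift_nm,
  split`` — note k_D is mL/g while K is mL/mg; the DLS calibration slope
  absorbs the factor, and encoding units in the headers is what prevents
  that distinction from silently collapsing;
* viscosity (long format): ``molecule_id, conc_mg_ml, visc_cp`` — long
  rather than wide because profiles have a variable number of points.

Missing measurements are empty cells, never zeros.  Configuration is a
YAML file with strictly validated keys; unknown keys are an error so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    CalibrationLine,
    CalibrationReport,
    ExclusionConfig,
    MoleculeRecord,
)
from .core_model import ModelParams

__all__ = [
    "MOLECULE_COLUMNS",
    "VISCOSITY_COLUMNS",
    "PipelineConfig",
    "read_cohort",
    "write_cohort",
    "read_config",
    "write_config",
    "write_results",
    "read_results",
    "write_calibration_report",
    "read_calibration_lines",
    "load_validation_panel",
    "load_test_panel",
]

logger = logging.getLogger(__name__)

MOLECULE_COLUMNS = [
    "molecule_id",
    "dnp_um2_per_s",
    "kd_ml_per_g",
    "plasmon_shift_nm",
    "split",
]
VISCOSITY_COLUMNS = ["molecule_id", "conc_mg_ml", "visc_cp"]

# Unit sanity bounds: readings outside these are logged, not rejected.
_DNP_SANE = (0.0, 20.0)   # um^2/s
_KD_SANE_ABS = 200.0      # mL/g


def _parse_float(value, row: int, column: str, path) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"{path}: unparseable number {value!r} at row {row}, column {column!r}"
        ) from None


def read_cohort(
    molecules_csv, viscosity_csv=None
) -> list[MoleculeRecord]:
    """Read a cohort from the molecules table and optional viscosity table.

    Duplicate molecule ids and unparseable numbers are hard errors;
    viscosity rows referencing unknown molecules break referential
    integrity and are also fatal.  Unit-sanity violations (D_np outside
    [0, 20] um^2/s, |k_D| > 200 mL/g) are logged warnings only.
    """
    # round_trip float parsing so write -> read -> write is byte-identical
    mols = pd.read_csv(
        molecules_csv, dtype={"molecule_id": str}, comment="#",
        float_precision="round_trip",
    )
    if "molecule_id" not in mols.columns:
        raise ValueError(f"{molecules_csv}: missing required column 'molecule_id'")
    dupes = mols["molecule_id"][mols["molecule_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(
            f"{molecules_csv}: duplicate molecule_id(s): {sorted(set(dupes))}"
        )

    records: dict[str, MoleculeRecord] = {}
    for i, row in mols.iterrows():
        dnp = _parse_float(row.get("dnp_um2_per_s"), i, "dnp_um2_per_s", molecules_csv)
        kd = _parse_float(row.get("kd_ml_per_g"), i, "kd_ml_per_g", molecules_csv)
        shift = _parse_float(
            row.get("plasmon_shift_nm"), i, "plasmon_shift_nm", molecules_csv
        )
        if dnp is not None and not (_DNP_SANE[0] <= dnp <= _DNP_SANE[1]):
            logger.warning(
                "%s: D_np=%.3g um^2/s outside sane range %s", row["molecule_id"], dnp, _DNP_SANE
            )
        if kd is not None and abs(kd) > _KD_SANE_ABS:
            logger.warning(
                "%s: |k_D|=%.3g mL/g exceeds sane bound %.0f", row["molecule_id"], kd, _KD_SANE_ABS
            )
        split = row.get("split")
        if isinstance(split, float) and np.isnan(split):
            split = None
        records[row["molecule_id"]] = MoleculeRecord(
            molecule_id=row["molecule_id"],
            dnp=dnp,
            kd=kd,
            plasmon_shift=shift,
            split=split,
        )

    if viscosity_csv is not None:
        visc = pd.read_csv(
            viscosity_csv, dtype={"molecule_id": str}, comment="#",
            float_precision="round_trip",
        )
        for col in VISCOSITY_COLUMNS:
            if col not in visc.columns:
                raise ValueError(f"{viscosity_csv}: missing required column {col!r}")
        for i, row in visc.iterrows():
            mol_id = row["molecule_id"]
            if mol_id not in records:
                raise ValueError(
                    f"{viscosity_csv}: row {i} references unknown molecule {mol_id!r}"
                )
            c = _parse_float(row["conc_mg_ml"], i, "conc_mg_ml", viscosity_csv)
            e = _parse_float(row["visc_cp"], i, "visc_cp", viscosity_csv)
            if c is None or e is None:
                raise ValueError(
                    f"{viscosity_csv}: row {i}: viscosity points must be complete"
                )
            if c <= 0:
                raise ValueError(
                    f"{viscosity_csv}: row {i}: concentration must be positive, got {c}"
                )
            records[mol_id].viscosity_points.append((c, e))
    return list(records.values())


def write_cohort(
    cohort: Sequence[MoleculeRecord], molecules_csv, viscosity_csv=None
) -> None:
    """Write a cohort back to the two-table CSV schema (round-trip stable)."""
    rows = [
        {
            "molecule_id": r.molecule_id,
            "dnp_um2_per_s": r.dnp,
            "kd_ml_per_g": r.kd,
            "plasmon_shift_nm": r.plasmon_shift,
            "split": r.split,
        }
        for r in cohort
    ]
    pd.DataFrame(rows, columns=MOLECULE_COLUMNS).to_csv(molecules_csv, index=False)
    if viscosity_csv is not None:
        vrows = [
            {"molecule_id": r.molecule_id, "conc_mg_ml": c, "visc_cp": e}
            for r in cohort
            for c, e in r.viscosity_points
        ]
        pd.DataFrame(vrows, columns=VISCOSITY_COLUMNS).to_csv(viscosity_csv, index=False)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    model: ModelParams = field(default_factory=ModelParams)
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    acsins_line: tuple = (4.9, 2045.0)    # (intercept um^2/s, slope per mL/mg)
    dls_line: tuple = (56.03, 15000.0)    # (intercept mL/g, slope per mL/mg)
    grid: tuple = (70.0, 250.0, 10.0)     # start, stop, step in mg/mL
    cutoff_cp: float = 20.0
    seed: Optional[int] = None


_CONFIG_KEYS = {
    "model": {"A", "nu"},
    "exclusions": {
        "dnp_min",
        "kd_abs_max",
        "k_branching_max",
        "ht_separator",
        "entanglement_floor",
    },
    "acsins_line": None,
    "dls_line": None,
    "grid": None,
    "cutoff_cp": None,
    "seed": None,
}


def read_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys (top-level or nested) are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    for section, allowed in _CONFIG_KEYS.items():
        if allowed is not None and isinstance(raw.get(section), dict):
            extra = set(raw[section]) - allowed
            if extra:
                raise ValueError(
                    f"{path}: unknown keys in section {section!r}: {sorted(extra)}"
                )
    cfg = PipelineConfig()
    if "model" in raw:
        cfg.model = ModelParams(**raw["model"])
    if "exclusions" in raw:
        exc = dict(raw["exclusions"])
        if exc.get("ht_separator") is not None:
            exc["ht_separator"] = tuple(float(v) for v in exc["ht_separator"])
        cfg.exclusions = ExclusionConfig(**exc)
    for key in ("acsins_line", "dls_line", "grid"):
        if key in raw:
            setattr(cfg, key, tuple(float(v) for v in raw[key]))
    if "cutoff_cp" in raw:
        cfg.cutoff_cp = float(raw["cutoff_cp"])
    if "seed" in raw and raw["seed"] is not None:
        cfg.seed = int(raw["seed"])
    return cfg


def write_config(cfg: PipelineConfig, path) -> None:
    """Serialize a config to YAML (read_config(write_config(c)) == c)."""
    payload = {
        "model": {"A": cfg.model.A, "nu": cfg.model.nu},
        "exclusions": {
            "dnp_min": cfg.exclusions.dnp_min,
            "kd_abs_max": cfg.exclusions.kd_abs_max,
            "k_branching_max": cfg.exclusions.k_branching_max,
            "ht_separator": list(cfg.exclusions.ht_separator)
            if cfg.exclusions.ht_separator is not None
            else None,
            "entanglement_floor": cfg.exclusions.entanglement_floor,
        },
        "acsins_line": list(cfg.acsins_line),
        "dls_line": list(cfg.dls_line),
        "grid": list(cfg.grid),
        "cutoff_cp": cfg.cutoff_cp,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_results(df: pd.DataFrame, path, columns: Optional[list] = None) -> None:
    """Write a results table with deterministic column order and a version line."""
    if columns is not None:
        df = df[columns]
    with open(path, "w", newline="") as fh:
        fh.write(f"# mabvisc {__version__}\n")
        df.to_csv(fh, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_calibration_report(report: CalibrationReport, json_path, csv_path=None) -> None:
    """Write line coefficients (JSON) and the exclusion ledger (CSV)."""
    payload = {
        "version": __version__,
        "lines": {
            line.source: {
                "intercept": line.intercept,
                "slope": line.slope,
                "n_used": line.n_used,
                "residual_sd": line.residual_sd,
            }
            for line in (report.acsins, report.dls)
        },
        "suspected_ht_ids": sorted(report.ht_ids),
        "skipped_ids": list(report.skipped_ids),
        "k_fits": {
            mol: {"value": k.value, "flags": sorted(k.flags)}
            for mol, k in sorted(report.k_fits.items())
        },
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
    if csv_path is not None:
        rows = [
            {"source": src, "molecule_id": mol, "reason": reason}
            for src, line in (("acsins", report.acsins), ("dls", report.dls))
            for mol, reason in line.excluded_ids
        ]
        pd.DataFrame(rows, columns=["source", "molecule_id", "reason"]).to_csv(
            csv_path, index=False
        )


def read_calibration_lines(json_path) -> tuple[CalibrationLine, CalibrationLine]:
    """Load (acsins, dls) lines from a calibration report JSON."""
    with open(json_path) as fh:
        payload = json.load(fh)
    lines = {}
    for src in ("acsins", "dls"):
        d = payload["lines"][src]
        lines[src] = CalibrationLine(
            source=src,
            intercept=float(d["intercept"]),
            slope=float(d["slope"]),
            n_used=int(d.get("n_used", 0)),
            residual_sd=float(d.get("residual_sd", float("nan"))),
        )
    return lines["acsins"], lines["dls"]


def _load_panel(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("mabvisc.datasets").joinpath(name)
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={"molecule_id": str})


def load_validation_panel() -> pd.DataFrame:
    """Bundled 17-molecule validation panel: per-molecule experimental
    concentration and viscosity plus AC-SINS/DLS predicted viscosities at
    both the experimental concentration and 150 mg/mL, with the published
    performance labels."""
    return _load_panel("validation_panel.csv")


def load_test_panel() -> pd.DataFrame:
    """Bundled 9-molecule test panel: experimental and predicted viscosity
    at 150 mg/mL with published performance labels."""
    return _load_panel("test_panel.csv")
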