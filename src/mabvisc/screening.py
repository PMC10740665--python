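"""Viscosity prediction and 20 cP developability classification.

The screening path is: dilute measurement -> K via a calibration line ->
concentration-viscosity curve via the reptation law -> classify at the
20 cP / 150 mg/mL developability cutoff.  A molecule is *good* when its
predicted viscosity at 150 mg/mL is at or below 20 cP, *bad* above; a
cohort-level flag marks molecules where either source (AC-SINS or DLS)
predicts above the cutoff.

When an experimental viscosity is available, each molecule gets a
performance label following the screening study's convention:

* ``FALSE_POSITIVE`` — both predictions low but the molecule is
  experimentally viscous (in standard screening terms this is a *false
  negative*: a viscous molecule the screen missed);
* ``FALSE_NEGATIVE`` — either prediction high but the molecule is
  experimentally fine (standard *false positive*: a false alarm);
* ``TRUE`` — every other combination.

The naming is the reverse of the usual convention; it is retained verbatim
because the labels are part of the method's reporting format, and a
standard-convention alias is emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationLine, ExclusionConfig, MoleculeRecord
from .core_model import (
    DEFAULT_PARAMS,
    FLAG_ABOVE_BRANCHING_CUTOFF,
    FLAG_BELOW_ENTANGLEMENT_FLOOR,
    FLAG_CLAMPED_TO_ZERO,
    FLAG_LOW_SENSITIVITY_DNP,
    KEstimate,
    ModelParams,
    viscosity,
)

__all__ = [
    "VISCOSITY_CUTOFF_CP",
    "REFERENCE_CONCENTRATION",
    "LABEL_TRUE",
    "LABEL_FALSE_POSITIVE",
    "LABEL_FALSE_NEGATIVE",
    "STANDARD_ALIAS",
    "CurvePoint",
    "ScreeningResult",
    "CohortSummary",
    "default_grid",
    "k_from_measurement",
    "predict_curve",
    "classify",
    "performance_label",
    "screen_molecule",
    "evaluate_cohort",
]

VISCOSITY_CUTOFF_CP = 20.0
REFERENCE_CONCENTRATION = 150.0

LABEL_TRUE = "TRUE"
LABEL_FALSE_POSITIVE = "FALSE_POSITIVE"
LABEL_FALSE_NEGATIVE = "FALSE_NEGATIVE"

# The study's labels are named from the molecule's, not the screen's, point
# of view; map to the standard screening convention for reporting.
STANDARD_ALIAS = {
    LABEL_TRUE: "correct",
    LABEL_FALSE_POSITIVE: "standard_false_negative_missed_viscous",
    LABEL_FALSE_NEGATIVE: "standard_false_positive_false_alarm",
}


def default_grid(start: float = 70.0, stop: float = 250.0, step: float = 10.0):
    """Prediction grid in mg/mL; default spans the measured range in 10s."""
    n = int(round((stop - start) / step))
    return [start + i * step for i in range(n + 1)]


@dataclass(frozen=True)
class CurvePoint:
    conc: float  # mg/mL
    visc: float  # cP
    flags: frozenset = frozenset()


@dataclass
class ScreeningResult:
    """Per-molecule screening output across both measurement sources."""

    molecule_id: str
    K_acsins: Optional[KEstimate] = None
    K_dls: Optional[KEstimate] = None
    curve_acsins: list = field(default_factory=list)
    curve_dls: list = field(default_factory=list)
    eta150_acsins: Optional[float] = None
    eta150_dls: Optional[float] = None
    class_acsins: Optional[str] = None
    class_dls: Optional[str] = None
    class_combined: Optional[str] = None  # bad iff any source predicts > cutoff
    experimental_cp: Optional[float] = None
    performance: Optional[str] = None
    performance_standard: Optional[str] = None


def k_from_measurement(
    x: Optional[float],
    line: CalibrationLine,
    exclusions: ExclusionConfig = ExclusionConfig(),
) -> Optional[KEstimate]:
    """Invert a calibration line: K = (intercept - x) / slope.

    Returns None (an absent-result marker, not an exception) when the
    measurement is missing.  A negative raw K is clamped to zero with the
    ``clamped_to_zero`` flag — the reptation law models associative
    entanglement only, so the baseline curve is the floor prediction.
    AC-SINS readings below the sensitivity floor (strictly, x < dnp_min)
    get ``low_sensitivity_dnp``; estimates above the branching cutoff get
    ``above_branching_cutoff`` (prediction unreliable: branched complexes).
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    raw = line.k_from(x)
    flags = set()
    value = raw
    if raw < 0:
        value = 0.0
        flags.add(FLAG_CLAMPED_TO_ZERO)
    if line.source == "acsins" and x < exclusions.dnp_min:
        flags.add(FLAG_LOW_SENSITIVITY_DNP)
    if value > exclusions.k_branching_max:
        flags.add(FLAG_ABOVE_BRANCHING_CUTOFF)
    return KEstimate(
        value=value,
        source=line.source,
        flags=frozenset(flags),
        diagnostics={"raw_value": raw, "measurement": x},
    )


def predict_curve(
    K: KEstimate,
    concentrations: Sequence[float],
    params: ModelParams = DEFAULT_PARAMS,
    entanglement_floor: float = 100.0,
) -> list[CurvePoint]:
    """Evaluate the viscosity law along a concentration grid.

    Points below the entanglement floor are still evaluated (the curve is
    defined there) but flagged ``below_entanglement_floor``: at those
    concentrations real solutions are too dilute for entangled dynamics
    and the law over-states the concentration scaling.
    """
    out = []
    for c in concentrations:
        if c <= 0:
            raise ValueError(f"concentrations must be positive, got {c}")
        flags = frozenset(
            [FLAG_BELOW_ENTANGLEMENT_FLOOR] if c < entanglement_floor else []
        )
        out.append(CurvePoint(conc=float(c), visc=viscosity(K.value, c, params), flags=flags))
    return out


def classify(eta150: float, cutoff: float = VISCOSITY_CUTOFF_CP) -> str:
    """Binary developability call at 150 mg/mL: good iff eta <= cutoff.

    The boundary is inclusive: exactly 20 cP is a good molecule.
    """
    if not math.isfinite(eta150) or eta150 < 0:
        raise ValueError(f"eta150 must be finite and non-negative, got {eta150}")
    return "good" if eta150 <= cutoff else "bad"


def performance_label(
    pred_acsins: Optional[float],
    pred_dls: Optional[float],
    experimental: float,
    cutoff: float = VISCOSITY_CUTOFF_CP,
) -> str:
    """Label a prediction pair against experiment ('high' means > cutoff).

    FALSE_POSITIVE: all available predictions low, experiment high.
    FALSE_NEGATIVE: any available prediction high, experiment low.
    TRUE: everything else.  With one prediction missing the label is
    computed from the available source alone.
    """
    preds = [p for p in (pred_acsins, pred_dls) if p is not None and not math.isnan(p)]
    if not preds:
        raise ValueError("at least one prediction is required")
    exp_high = experimental > cutoff
    any_pred_high = any(p > cutoff for p in preds)
    if exp_high and not any_pred_high:
        return LABEL_FALSE_POSITIVE
    if not exp_high and any_pred_high:
        return LABEL_FALSE_NEGATIVE
    return LABEL_TRUE


def screen_molecule(
    record: MoleculeRecord,
    acsins_line: CalibrationLine,
    dls_line: CalibrationLine,
    params: ModelParams = DEFAULT_PARAMS,
    exclusions: ExclusionConfig = ExclusionConfig(),
    grid: Optional[Sequence[float]] = None,
    experimental_cp: Optional[float] = None,
    cutoff: float = VISCOSITY_CUTOFF_CP,
) -> ScreeningResult:
    """Run the full per-molecule pipeline from measurements to labels."""
    grid = list(grid) if grid is not None else default_grid()
    res = ScreeningResult(molecule_id=record.molecule_id, experimental_cp=experimental_cp)

    res.K_acsins = k_from_measurement(record.dnp, acsins_line, exclusions)
    res.K_dls = k_from_measurement(record.kd, dls_line, exclusions)

    for src, kest in (("acsins", res.K_acsins), ("dls", res.K_dls)):
        if kest is None:
            continue
        curve = predict_curve(kest, grid, params, exclusions.entanglement_floor)
        eta150 = viscosity(kest.value, REFERENCE_CONCENTRATION, params)
        setattr(res, f"curve_{src}", curve)
        setattr(res, f"eta150_{src}", eta150)
        setattr(res, f"class_{src}", classify(eta150, cutoff))

    etas = [e for e in (res.eta150_acsins, res.eta150_dls) if e is not None]
    if etas:
        res.class_combined = "bad" if any(e > cutoff for e in etas) else "good"
    if experimental_cp is not None and etas:
        res.performance = performance_label(
            res.eta150_acsins, res.eta150_dls, experimental_cp, cutoff
        )
        res.performance_standard = STANDARD_ALIAS[res.performance]
    return res


@dataclass
class CohortSummary:
    """Confusion-style tallies over a screened cohort at the 20 cP cutoff."""

    n: int
    flagged_ids: tuple          # any prediction > cutoff at 150 mg/mL
    exp_viscous_ids: tuple      # experimental > cutoff
    missed_viscous_ids: tuple   # experimentally viscous, not flagged
    exp_low_ids: tuple          # experimental <= cutoff
    labels: dict                # molecule_id -> performance label

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_ids)

    @property
    def n_exp_viscous(self) -> int:
        return len(self.exp_viscous_ids)

    @property
    def n_missed_viscous(self) -> int:
        return len(self.missed_viscous_ids)

    @property
    def n_exp_low(self) -> int:
        return len(self.exp_low_ids)


def evaluate_cohort(
    table: pd.DataFrame,
    cutoff: float = VISCOSITY_CUTOFF_CP,
    pred_acsins_col: str = "acsins_pred_150_cp",
    pred_dls_col: str = "dls_pred_150_cp",
    experimental_col: str = "exp_visc_cp",
    id_col: str = "molecule_id",
) -> CohortSummary:
    """Tally flags, misses and performance labels over prediction columns.

    Accepts any DataFrame carrying per-molecule predicted viscosities (one
    or both sources) and an experimental viscosity; this covers both
    pipeline output and externally supplied prediction tables.
    """
    if table.empty:
        return CohortSummary(0, (), (), (), (), {})
    flagged, exp_viscous, missed, exp_low, labels = [], [], [], [], {}
    for _, row in table.iterrows():
        mol = row[id_col]
        preds = []
        for col in (pred_acsins_col, pred_dls_col):
            if col in table.columns and pd.notna(row[col]):
                preds.append(float(row[col]))
        exp = float(row[experimental_col])
        is_flagged = any(p > cutoff for p in preds)
        if is_flagged:
            flagged.append(mol)
        if exp > cutoff:
            exp_viscous.append(mol)
            if not is_flagged:
                missed.append(mol)
        else:
            exp_low.append(mol)
        labels[mol] = performance_label(
            preds[0] if preds else None,
            preds[1] if len(preds) > 1 else None,
            exp,
            cutoff,
        )
    return CohortSummary(
        n=len(table),
        flagged_ids=tuple(flagged),
        exp_viscous_ids=tuple(exp_viscous),
        missed_viscous_ids=tuple(missed),
        exp_low_ids=tuple(exp_low),
        labels=labels,
    )
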