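"""Calibration of dilute-solution measurements against fitted K values.

The screening method rests on two linear maps between a dilute self-
association readout and the dimerization constant K that controls the
high-concentration viscosity curve:

    D_np = 4.9  - 2045  * K     (AC-SINS nanoparticle diffusion, um^2/s)
    k_D  = 56.03 - 15000 * K    (DLS interaction parameter, mL/g; the slope
                                 absorbs the mL/g vs mL/mg unit factor)

These published coefficients ship as defaults so prediction works without a
training cohort.  Refitting them on a new cohort applies the exclusion
rules under which the published lines were obtained:

* molecules whose fitted K is negative are not in the entangled regime and
  are dropped from both fits (``non_entangled``);
* the AC-SINS fit drops molecules with D_np at or below the 1 um^2/s
  sensitivity floor (nanoparticle clusters grow too compact for diffusion
  to track affinity) and suspected head-to-tail (HT) binders, whose
  tethered-antibody readout under-reports the interaction;
* the DLS fit drops implausible |k_D| readings (default > 60 mL/g) and
  molecules with K above the 0.01 mL/mg branching cutoff, where branched
  complexes invalidate the reptation picture.

Suspected HT binders are detected geometrically: an HT molecule looks weak
to AC-SINS (tether occludes one binding site) but strong to DLS, so it sits
on the high-D_np side of the D_np-vs-k_D consistency trend.  The separating
line is a user configuration — no universal coefficients exist — and when
unset the detector returns nothing, loudly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core_model import (
    DEFAULT_PARAMS,
    FLAG_NON_ENTANGLED,
    ApplicabilityError,
    DomainError,
    KEstimate,
    ModelParams,
    fit_K_profile,
)

__all__ = [
    "MoleculeRecord",
    "ExclusionConfig",
    "CalibrationLine",
    "CalibrationError",
    "CalibrationReport",
    "DEFAULT_ACSINS_LINE",
    "DEFAULT_DLS_LINE",
    "fit_training_K",
    "detect_ht_outliers",
    "fit_calibration_line",
    "calibrate_cohort",
    # exclusion reason codes
    "REASON_NON_ENTANGLED",
    "REASON_LOW_DNP",
    "REASON_SUSPECTED_HT",
    "REASON_KD_RANGE",
    "REASON_BRANCHING",
    "REASON_MISSING",
]

logger = logging.getLogger(__name__)

REASON_NON_ENTANGLED = "non_entangled"
REASON_LOW_DNP = "dnp_at_or_below_sensitivity_floor"
REASON_SUSPECTED_HT = "suspected_ht_binder"
REASON_KD_RANGE = "kd_outside_plausible_range"
REASON_BRANCHING = "K_above_branching_cutoff"
REASON_MISSING = "missing_measurement"


class CalibrationError(ValueError):
    """Too few usable molecules survive the exclusion rules."""


@dataclass
class MoleculeRecord:
    """One antibody's dilute measurements plus its viscosity profile.

    ``dnp`` (um^2/s) and ``kd`` (mL/g) are the two modeled readouts; the
    AC-SINS plasmon shift (nm) is carried as an inert field.  Viscosity
    points are (concentration mg/mL, viscosity cP) pairs.
    """

    molecule_id: str
    dnp: Optional[float] = None
    kd: Optional[float] = None
    plasmon_shift: Optional[float] = None
    viscosity_points: list = field(default_factory=list)
    split: Optional[str] = None  # train | validation | test


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the calibration exclusion rules (defaults as published).

    ``ht_separator`` is (slope, intercept) of a line in (k_D, D_np) space:
    molecules strictly above it (D_np > slope*k_D + intercept) are flagged
    as suspected HT binders.  None disables HT detection.
    """

    dnp_min: float = 1.0            # um^2/s, AC-SINS sensitivity floor
    kd_abs_max: float = 60.0        # mL/g, plausibility bound for antibodies
    k_branching_max: float = 0.01   # mL/mg, onset of branched complexes
    ht_separator: Optional[tuple] = None  # (slope, intercept) in (kd, dnp)
    entanglement_floor: float = 100.0     # mg/mL

    def __post_init__(self) -> None:
        for name in ("dnp_min", "kd_abs_max", "k_branching_max", "entanglement_floor"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


@dataclass(frozen=True)
class CalibrationLine:
    """Linear map measurement = intercept - slope * K.

    ``slope`` is positive under the sign convention that the measurement
    decreases as self-association strengthens; ``K(intercept) = 0`` exactly.
    ``excluded_ids`` pairs each dropped molecule with its reason code.
    """

    source: str                      # acsins | dls
    intercept: float                 # measurement units
    slope: float                     # measurement units per (mL/mg)
    n_used: int = 0
    excluded_ids: tuple = ()
    residual_sd: float = float("nan")

    def k_from(self, x: float) -> float:
        """Invert the line: K = (intercept - x)/slope, signed."""
        return (self.intercept - x) / self.slope


# Published coefficients; usable without any training cohort.
DEFAULT_ACSINS_LINE = CalibrationLine(source="acsins", intercept=4.9, slope=2045.0)
DEFAULT_DLS_LINE = CalibrationLine(source="dls", intercept=56.03, slope=15000.0)


def fit_training_K(
    cohort: Sequence[MoleculeRecord],
    params: ModelParams = DEFAULT_PARAMS,
    entanglement_floor: float = 100.0,
) -> dict[str, KEstimate]:
    """Fit K from each molecule's viscosity profile.

    Molecules with no usable points (empty profile, or all points below the
    entanglement floor) are skipped with a logged reason rather than
    failing the cohort.  Negative-K fits are kept, flagged
    ``non_entangled``, so the calibration exclusions can act on them.
    """
    out: dict[str, KEstimate] = {}
    for rec in cohort:
        try:
            out[rec.molecule_id] = fit_K_profile(
                rec.viscosity_points, params, entanglement_floor
            )
        except (ApplicabilityError, DomainError) as exc:
            logger.warning("skipping %s: %s", rec.molecule_id, exc)
    return out


def detect_ht_outliers(
    cohort: Sequence[MoleculeRecord],
    exclusions: ExclusionConfig,
) -> set[str]:
    """Flag suspected head-to-tail binders in (k_D, D_np) space.

    A molecule with both measurements present is flagged when its D_np lies
    strictly above the configured separator line, i.e. nanoparticle
    diffusion is faster than the DLS readout predicts — consistent with the
    nanoparticle tether occluding an attracting site.  With no separator
    configured the set is empty and a warning is logged (the line must be
    drawn per-cohort; there are no universal coefficients).
    """
    if exclusions.ht_separator is None:
        logger.warning(
            "HT separator not configured: no head-to-tail outliers will be "
            "flagged; set ExclusionConfig.ht_separator=(slope, intercept)"
        )
        return set()
    slope, intercept = exclusions.ht_separator
    flagged = set()
    for rec in cohort:
        if rec.dnp is None or rec.kd is None:
            continue
        if rec.dnp > slope * rec.kd + intercept:
            flagged.add(rec.molecule_id)
    return flagged


def _as_value(k) -> float:
    return k.value if isinstance(k, KEstimate) else float(k)


def _has_flag(k, flag: str) -> bool:
    return isinstance(k, KEstimate) and flag in k.flags


def fit_calibration_line(
    points: Iterable[tuple],
    source: str,
    exclusions: ExclusionConfig = ExclusionConfig(),
    ht_ids: frozenset = frozenset(),
) -> CalibrationLine:
    """Ordinary least squares of a dilute measurement on K, with exclusions.

    ``points`` are (molecule_id, K, measurement) triples; K may be a raw
    float or a :class:`~mabvisc.core_model.KEstimate` (the ``non_entangled``
    flag is honoured either way: K < 0 is always dropped).  The regression
    is oriented as measurement-on-K, matching the functional form the lines
    are written in; plain unweighted OLS.

    Exclusion rules by source:

    * both: non-entangled (negative/flagged K), missing measurement;
    * acsins: D_np <= ``dnp_min``; membership of ``ht_ids``;
    * dls: |k_D| > ``kd_abs_max``; K > ``k_branching_max``.

    Raises
    ------
    CalibrationError
        If fewer than 3 molecules survive; the message carries the full
        exclusion ledger.
    """
    if source not in ("acsins", "dls"):
        raise ValueError(f"unknown source {source!r}")
    used_k, used_x, used_ids = [], [], []
    excluded: list[tuple[str, str]] = []
    for mol_id, k, x in points:
        kval = _as_value(k)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            excluded.append((mol_id, REASON_MISSING))
            continue
        if kval < 0 or _has_flag(k, FLAG_NON_ENTANGLED) and kval <= 0:
            excluded.append((mol_id, REASON_NON_ENTANGLED))
            continue
        if source == "acsins":
            if x <= exclusions.dnp_min:
                excluded.append((mol_id, REASON_LOW_DNP))
                continue
            if mol_id in ht_ids:
                excluded.append((mol_id, REASON_SUSPECTED_HT))
                continue
        else:
            if abs(x) > exclusions.kd_abs_max:
                excluded.append((mol_id, REASON_KD_RANGE))
                continue
            if kval > exclusions.k_branching_max:
                excluded.append((mol_id, REASON_BRANCHING))
                continue
        used_ids.append(mol_id)
        used_k.append(kval)
        used_x.append(float(x))

    if len(used_k) < 3:
        raise CalibrationError(
            f"{source}: only {len(used_k)} molecules survive exclusions "
            f"(need >= 3); ledger: {excluded}"
        )

    fit = stats.linregress(used_k, used_x)
    slope = -fit.slope  # store as positive magnitude: x = intercept - slope*K
    if slope <= 0:
        logger.warning(
            "%s calibration slope is non-positive (%.4g): measurement does "
            "not decrease with K on this cohort", source, slope,
        )
    resid = np.asarray(used_x) - (fit.intercept + fit.slope * np.asarray(used_k))
    dof = len(used_k) - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else float("nan")
    line = CalibrationLine(
        source=source,
        intercept=float(fit.intercept),
        slope=float(slope),
        n_used=len(used_k),
        excluded_ids=tuple(excluded),
        residual_sd=residual_sd,
    )
    for mol_id, reason in excluded:
        logger.info("%s calibration: excluded %s (%s)", source, mol_id, reason)
    return line


@dataclass
class CalibrationReport:
    """Everything a calibration run produced, for serialization and audit."""

    acsins: CalibrationLine
    dls: CalibrationLine
    k_fits: Mapping[str, KEstimate]
    ht_ids: frozenset
    skipped_ids: tuple = ()


def calibrate_cohort(
    cohort: Sequence[MoleculeRecord],
    params: ModelParams = DEFAULT_PARAMS,
    exclusions: ExclusionConfig = ExclusionConfig(),
) -> CalibrationReport:
    """Full training pass: fit per-molecule K, detect HT, fit both lines."""
    k_fits = fit_training_K(cohort, params, exclusions.entanglement_floor)
    skipped = tuple(r.molecule_id for r in cohort if r.molecule_id not in k_fits)
    ht_ids = frozenset(detect_ht_outliers(cohort, exclusions))
    acsins_pts = [
        (r.molecule_id, k_fits[r.molecule_id], r.dnp)
        for r in cohort
        if r.molecule_id in k_fits
    ]
    dls_pts = [
        (r.molecule_id, k_fits[r.molecule_id], r.kd)
        for r in cohort
        if r.molecule_id in k_fits
    ]
    acsins = fit_calibration_line(acsins_pts, "acsins", exclusions, ht_ids)
    dls = fit_calibration_line(dls_pts, "dls", exclusions)
    return CalibrationReport(
        acsins=acsins, dls=dls, k_fits=k_fits, ht_ids=ht_ids, skipped_ids=skipped
    )
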