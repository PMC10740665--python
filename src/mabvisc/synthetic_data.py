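"""Synthetic antibody cohorts with the statistical structure the method assumes.

Real screening cohorts of this kind (tens of molecules with AC-SINS
diffusion, DLS k_D and two-concentration viscosity profiles) are not
publicly deposited, so the calibration and screening stages are exercised
on generated cohorts instead.  The generator draws a true dimerization
constant K per molecule and pushes it through the same physics the method
inverts:

* viscosity at each profile concentration from the reptation law, times
  lognormal measurement noise;
* D_np and k_D from the published calibration lines plus Gaussian noise;
* head-to-tail (HT) outliers: the AC-SINS readout sees only the weak
  head-to-head constant K (the nanoparticle tether occludes the HT site),
  while k_D and the viscosity respond to an effective constant
  ``ht_K_multiplier * K`` — exactly the discordance the HT detector looks
  for;
* strong binders: K drawn high enough that D_np falls below the 1 um^2/s
  sensitivity floor of the nanoparticle assay.

Ground truth (role and true K per molecule) is returned, and written, as a
separate table so pipeline tests cannot accidentally leak it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_ACSINS_LINE,
    DEFAULT_DLS_LINE,
    CalibrationLine,
    MoleculeRecord,
)
from .core_model import DEFAULT_PARAMS, ModelParams, viscosity

__all__ = ["SyntheticConfig", "generate_cohort", "split_cohort"]

ROLE_NORMAL = "normal"
ROLE_HT = "ht"
ROLE_STRONG = "strong_binder"

# Physical saturation of the readouts: the linear calibration maps go
# negative at strong binding, but a nanoparticle cluster still diffuses and
# DLS k_D bottoms out.  These floors only act in the regime the exclusion
# rules remove anyway (D_np below the 1 um^2/s sensitivity floor,
# |k_D| > 60 mL/g), so they never distort calibration recovery.
DNP_SATURATION = 0.3   # um^2/s, large-cluster diffusion plateau
DNP_MEAS_MIN = 0.05    # um^2/s, instrument floor after noise
KD_FLOOR = -100.0      # mL/g


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation parameters; defaults mirror the assay conditions.

    ``K_log10_range`` spans weak to moderate binders (mL/mg); strong
    binders are drawn separately from ``strong_K_range`` so that their
    baseline D_np lands below the sensitivity floor.  ``seed`` is required:
    the same seed must reproduce the cohort byte-for-byte.
    """

    n_molecules: int = 89
    seed: int = 0
    K_log10_range: tuple = (-5.0, -2.0)
    dnp_noise_sd: float = 0.3       # um^2/s
    kd_noise_sd: float = 2.0        # mL/g
    visc_lognoise_sd: float = 0.05  # sd of log-viscosity
    concentrations: tuple = (70.0, 150.0)  # mg/mL profile points
    ht_fraction: float = 0.05
    ht_K_multiplier: float = 5.0
    strong_binder_fraction: float = 0.08
    strong_K_range: tuple = (2.1e-3, 9.0e-3)  # mL/mg, gives D_np < 1

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not (0 <= self.ht_fraction <= 1 and 0 <= self.strong_binder_fraction <= 1):
            raise ValueError("outlier fractions must lie in [0, 1]")
        if self.ht_fraction + self.strong_binder_fraction > 1:
            raise ValueError("outlier fractions must sum to <= 1")
        if self.K_log10_range[0] > self.K_log10_range[1]:
            raise ValueError("K_log10_range must be ordered (min, max)")
        if self.ht_K_multiplier <= 1:
            raise ValueError("ht_K_multiplier must exceed 1")
        if any(sd < 0 for sd in (self.dnp_noise_sd, self.kd_noise_sd, self.visc_lognoise_sd)):
            raise ValueError("noise standard deviations must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is required and must be an integer")


def generate_cohort(
    config: SyntheticConfig,
    params: ModelParams = DEFAULT_PARAMS,
    acsins_line: CalibrationLine = DEFAULT_ACSINS_LINE,
    dls_line: CalibrationLine = DEFAULT_DLS_LINE,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Generate a cohort of molecule records plus a ground-truth table.

    Returns ``(records, truth)`` where ``truth`` holds molecule_id, role
    (normal / ht / strong_binder), the true head-to-head constant K_true,
    and K_visc, the constant actually driving viscosity and k_D (equal to
    K_true except for HT molecules, where it is multiplied up).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    n_ht = int(round(n * config.ht_fraction))
    n_strong = int(round(n * config.strong_binder_fraction))
    roles = np.array(
        [ROLE_HT] * n_ht + [ROLE_STRONG] * n_strong + [ROLE_NORMAL] * (n - n_ht - n_strong),
        dtype=object,
    )
    rng.shuffle(roles)

    lo, hi = config.K_log10_range
    slo, shi = math.log10(config.strong_K_range[0]), math.log10(config.strong_K_range[1])
    records: list[MoleculeRecord] = []
    truth_rows = []
    width = len(str(n))
    for i, role in enumerate(roles):
        mol_id = f"M{i + 1:0{width}d}"
        if role == ROLE_STRONG:
            k_true = 10.0 ** rng.uniform(slo, shi)
        else:
            k_true = 10.0 ** rng.uniform(lo, hi)
        k_visc = k_true * (config.ht_K_multiplier if role == ROLE_HT else 1.0)

        # AC-SINS sees only the head-to-head constant (tether occludes the
        # HT site); DLS and viscosity respond to the full association.
        dnp = max(acsins_line.intercept - acsins_line.slope * k_true, DNP_SATURATION)
        kd = max(dls_line.intercept - dls_line.slope * k_visc, KD_FLOOR)
        dnp = max(dnp + rng.normal(0.0, config.dnp_noise_sd), DNP_MEAS_MIN)
        kd += rng.normal(0.0, config.kd_noise_sd)

        points = []
        for c in config.concentrations:
            eta = viscosity(k_visc, c, params)
            eta *= math.exp(rng.normal(0.0, config.visc_lognoise_sd))
            points.append((float(c), float(eta)))

        # Plasmon shift is carried but unmodeled: a red shift that grows
        # with association, with ~0.5 nm read noise.
        shift = 4.0 * math.log10(1.0 + k_visc / 1e-4) + rng.normal(0.0, 0.5)

        records.append(
            MoleculeRecord(
                molecule_id=mol_id,
                dnp=float(dnp),
                kd=float(kd),
                plasmon_shift=float(shift),
                viscosity_points=points,
            )
        )
        truth_rows.append(
            {"molecule_id": mol_id, "role": role, "K_true": k_true, "K_visc": k_visc}
        )
    truth = pd.DataFrame(truth_rows, columns=["molecule_id", "role", "K_true", "K_visc"])
    return records, truth


def split_cohort(
    cohort: Sequence[MoleculeRecord],
    sizes: tuple,
    seed: int,
) -> list[MoleculeRecord]:
    """Randomly partition a cohort into train/validation/test splits.

    ``sizes`` is (n_train, n_validation, n_test) and must sum to the cohort
    size; the permutation is drawn from ``seed`` (required — there is no
    hidden default).  Split labels are written onto copies of the records.
    """
    n_train, n_val, n_test = (int(s) for s in sizes)
    if n_train + n_val + n_test != len(cohort):
        raise ValueError(
            f"split sizes {sizes} do not sum to cohort size {len(cohort)}"
        )
    if any(s < 0 for s in (n_train, n_val, n_test)):
        raise ValueError("split sizes must be non-negative")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    labels = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            labels[idx] = "train"
        elif pos < n_train + n_val:
            labels[idx] = "validation"
        else:
            labels[idx] = "test"
    out = []
    for idx, rec in enumerate(cohort):
        out.append(
            MoleculeRecord(
                molecule_id=rec.molecule_id,
                dnp=rec.dnp,
                kd=rec.kd,
                plasmon_shift=rec.plasmon_shift,
                viscosity_points=list(rec.viscosity_points),
                split=labels[idx],
            )
        )
    return out
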