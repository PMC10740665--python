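"""Isodesmic chain statistics and the reptation viscosity law.

Antibodies that self-associate through their complementarity-determining
regions (CDRs) carry two equivalent binding sites, so association produces
linear chains.  Under the isodesmic assumption — every chain-extension step
shares one equilibrium constant ``K`` (mL/mg, defined through the dimer
mass action K = C2/C1**2) — the number-average chain length at total
antibody concentration ``C`` (mg/mL) is

    <L> = 2KC / (sqrt(1 + 4KC) - 1) = (1 + sqrt(1 + 4KC)) / 2

Entangled chains relax by reptation, giving a solution viscosity

    eta = A * C**(3/(3*nu - 1)) * <L>**3            [cP]

with Flory exponent nu = 3/5 (concentration power 3.75) and prefactor
``A`` = 5.4e-8 cP*(mg/mL)**-3.75 describing lateral chain-chain friction
within an antibody scaffold.

Everything in this module is a pure function of (K, C, params); the single
free parameter K is what calibration against dilute-solution measurements
must supply.  The inversion eta -> K is closed-form, so viscosity profiles
measured at one or two concentrations determine K without iteration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DomainError",
    "ApplicabilityError",
    "ConvergenceError",
    "ModelParams",
    "DEFAULT_PARAMS",
    "KEstimate",
    "FLAG_NON_ENTANGLED",
    "FLAG_CLAMPED_TO_ZERO",
    "FLAG_ABOVE_BRANCHING_CUTOFF",
    "FLAG_LOW_SENSITIVITY_DNP",
    "FLAG_BELOW_ENTANGLEMENT_FLOOR",
    "mean_chain_length",
    "isodesmic_oracle",
    "viscosity",
    "invert_viscosity_for_K",
    "fit_K_profile",
]


class DomainError(ValueError):
    """Input outside the physical/mathematical domain of the model."""


class ApplicabilityError(ValueError):
    """The model does not apply to the supplied data (e.g. all points dilute)."""


class ConvergenceError(RuntimeError):
    """A numerical routine failed to converge; diagnostics in args."""


# Flags attached to K estimates as they move through the pipeline.
FLAG_NON_ENTANGLED = "non_entangled"
FLAG_CLAMPED_TO_ZERO = "clamped_to_zero"
FLAG_ABOVE_BRANCHING_CUTOFF = "above_branching_cutoff"
FLAG_LOW_SENSITIVITY_DNP = "low_sensitivity_dnp"
FLAG_BELOW_ENTANGLEMENT_FLOOR = "below_entanglement_floor"


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the reptation viscosity law.

    Attributes
    ----------
    A : float
        Viscosity prefactor, cP*(mg/mL)**-exponent.  Constant within an
        antibody scaffold; captures lateral interactions between chains.
    nu : float
        Flory exponent for the effective chain volume (3/5 for a good
        solvent).  Must satisfy 1/3 < nu <= 1 so the concentration power
        3/(3*nu - 1) is finite and positive.
    """

    A: float = 5.4e-8
    nu: float = 3.0 / 5.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise DomainError(f"prefactor A must be positive, got {self.A}")
        if not (1.0 / 3.0 < self.nu <= 1.0):
            raise DomainError(
                f"Flory exponent nu must lie in (1/3, 1], got {self.nu}"
            )

    @property
    def exponent(self) -> float:
        """Concentration power 3/(3*nu - 1); 3.75 exactly at nu = 3/5."""
        return 3.0 / (3.0 * self.nu - 1.0)


DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class KEstimate:
    """A dimerization constant with provenance and applicability flags.

    ``value`` is signed (mL/mg): a negative fit means the measured viscosity
    sits below the monomer baseline A*C**3.75, i.e. the molecule is not in
    the entangled regime and the reptation law does not apply to it.  The
    value is only clamped (with ``clamped_to_zero``) at the screening layer;
    calibration needs the sign to apply the exclusion rules exactly.
    """

    value: float
    source: str = "profile_fit"  # acsins | dls | profile_fit
    flags: frozenset = frozenset()
    diagnostics: dict = field(default_factory=dict, compare=False)

    def with_flags(self, *flags: str) -> "KEstimate":
        return replace(self, flags=self.flags | frozenset(flags))


def mean_chain_length(K: float, C: float) -> float:
    """Number-average isodesmic chain length <L> at (K, C).

    Parameters are the association constant K (mL/mg; signed values are
    admitted for diagnostic use) and total concentration C (mg/mL).
    Continuous at K*C = 0 with limit 1 (pure monomer).

    Raises
    ------
    DomainError
        If C < 0 or K*C <= -1/4 (square root undefined; non-physical input).
    """
    if C < 0:
        raise DomainError(f"concentration must be non-negative, got C={C}")
    kc = K * C
    if kc <= -0.25:
        raise DomainError(
            f"K*C = {kc} <= -1/4: mean chain length undefined (non-physical)"
        )
    # 2KC/(sqrt(1+4KC)-1) rationalized; exact at KC=0 where the quotient
    # form is 0/0.
    return 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * kc))


def isodesmic_oracle(K: float, C: float, xtol: float = 1e-12) -> float:
    """Mean chain length from the defining mass balance, solved numerically.

    Independent check of :func:`mean_chain_length`: the free-monomer
    concentration C1 satisfies C = C1/(1 - K*C1)**2 with K*C1 in (0, 1),
    and the number average is <L> = 1/(1 - K*C1).  Solved by bracketing
    bisection (brentq) on x = K*C1 in (0, 1).

    Raises
    ------
    DomainError
        If K <= 0 or C <= 0 (use the closed form for limits).
    ConvergenceError
        If the bracketing solve fails.
    """
    if K <= 0 or C <= 0:
        raise DomainError("oracle requires K > 0 and C > 0")
    kc = K * C

    def balance(x: float) -> float:
        # x = K*C1; mass balance in dimensionless form: KC = x/(1-x)^2
        return x / (1.0 - x) ** 2 - kc

    lo, hi = 0.0, 1.0 - 1e-16
    try:
        x = optimize.brentq(balance, lo, hi, xtol=xtol, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise ConvergenceError(
            f"mass-balance solve failed for K={K}, C={C}: {exc}"
        ) from exc
    return 1.0 / (1.0 - x)


def viscosity(K: float, C: float, params: ModelParams = DEFAULT_PARAMS) -> float:
    """Reptation viscosity eta = A * C**exponent * <L>**3 in cP."""
    L = mean_chain_length(K, C)
    return params.A * C ** params.exponent * L ** 3


def invert_viscosity_for_K(
    eta: float, C: float, params: ModelParams = DEFAULT_PARAMS
) -> KEstimate:
    """Closed-form inversion of the viscosity law for K at one point.

    L = (eta / (A*C**exponent))**(1/3); then from the chain-length formula
    sqrt(1+4KC) = 2L - 1, hence K = (L**2 - L)/C.  The result is signed:
    eta below the monomer baseline gives L < 1 and K < 0, flagged
    ``non_entangled`` (the molecule is not experiencing entangled dynamics).

    Raises
    ------
    DomainError
        If eta <= 0, C <= 0, or the implied L <= 1/2 (sqrt(1+4KC) would be
        negative; inversion impossible).
    """
    if eta <= 0 or C <= 0:
        raise DomainError(f"inversion requires eta > 0 and C > 0, got ({eta}, {C})")
    L = (eta / (params.A * C ** params.exponent)) ** (1.0 / 3.0)
    if L <= 0.5:
        raise DomainError(
            f"implied chain length L={L:.4g} <= 1/2 at C={C}: inversion impossible"
        )
    K = (L * L - L) / C
    est = KEstimate(value=K, source="profile_fit", diagnostics={"L": L, "C": C})
    if K <= 0:
        est = est.with_flags(FLAG_NON_ENTANGLED)
    return est


def fit_K_profile(
    points: Iterable[tuple[float, float]],
    params: ModelParams = DEFAULT_PARAMS,
    entanglement_floor: float = 100.0,
) -> KEstimate:
    """Fit K to a viscosity profile of (concentration mg/mL, viscosity cP).

    Points below the entanglement floor (default 100 mg/mL) are excluded
    with a warning: below it, solutions are too dilute to exhibit entangled
    dynamics and the reptation law over-predicts the concentration scaling.
    A single usable point delegates to the closed-form inversion; two or
    more are fit by single-parameter least squares on log-viscosity
    residuals (viscosity spans an order of magnitude across the profile, so
    log residuals weight the concentrations evenly).

    Raises
    ------
    DomainError
        On non-positive concentrations or viscosities.
    ApplicabilityError
        If no point lies at or above the floor.
    ConvergenceError
        If the optimizer fails.
    """
    pts = [(float(c), float(e)) for c, e in points]
    if not pts:
        raise ApplicabilityError("empty viscosity profile")
    for c, e in pts:
        if c <= 0 or e <= 0:
            raise DomainError(f"profile point ({c}, {e}) must be positive")

    used = [(c, e) for c, e in pts if c >= entanglement_floor]
    dropped = [(c, e) for c, e in pts if c < entanglement_floor]
    if dropped:
        warnings.warn(
            f"{len(dropped)} profile point(s) below the {entanglement_floor} "
            "mg/mL entanglement floor excluded from the K fit "
            "(too dilute for entangled dynamics)",
            stacklevel=2,
        )
    if not used:
        raise ApplicabilityError(
            f"all {len(pts)} profile points lie below the entanglement floor "
            f"({entanglement_floor} mg/mL); reptation fit not applicable"
        )

    if len(used) == 1:
        c, e = used[0]
        est = invert_viscosity_for_K(e, c, params)
        diag = dict(est.diagnostics)
        diag.update(n_points=1, dropped_below_floor=len(dropped))
        return replace(est, diagnostics=diag)

    conc = np.array([c for c, _ in used])
    eta_obs = np.array([e for _, e in used])
    # Per-point closed-form inversions bracket the answer; the median is a
    # robust starting value and is exact on noise-free profiles.
    k0 = float(
        np.median([invert_viscosity_for_K(e, c, params).value for c, e in used])
    )
    # Keep 1 + 4KC positive at every fitted concentration.
    k_lower = -0.25 / conc.max() * (1.0 - 1e-9)

    def residuals(kvec: np.ndarray) -> np.ndarray:
        k = kvec[0]
        L = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * k * conc))
        model = params.A * conc ** params.exponent * L ** 3
        return np.log(eta_obs) - np.log(model)

    result = optimize.least_squares(
        residuals,
        x0=[max(k0, k_lower + abs(k_lower) * 1e-6)],
        bounds=([k_lower], [np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not result.success:  # pragma: no cover - defensive
        raise ConvergenceError(f"profile fit failed: {result.message}")
    K = float(result.x[0])
    est = KEstimate(
        value=K,
        source="profile_fit",
        diagnostics={
            "residuals": result.fun.tolist(),
            "n_points": len(used),
            "dropped_below_floor": len(dropped),
            "cost": float(result.cost),
        },
    )
    if K <= 0:
        est = est.with_flags(FLAG_NON_ENTANGLED)
    return est
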