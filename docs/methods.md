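# Methods

## Physical model

`mabvisc` treats antibody self-association as isodesmic head-to-head (HH)
chain growth: every chain-extension step shares the dimerization constant
K (mL/mg), defined through the dimer mass action K = C₂/C₁² with C₁, C₂
the monomer and dimer mass concentrations. Summing the resulting
geometric population gives the number-average chain length

    ⟨L⟩ = 2KC / (√(1+4KC) − 1),

which the code evaluates in the rationalized form (1 + √(1+4KC))/2 — the
two are algebraically identical, but the latter is finite and exact at
KC = 0 and loses no precision at small KC. An independent oracle
(`isodesmic_oracle`) solves the defining mass balance C = C₁/(1−KC₁)²
numerically (bracketing Brent solve on x = KC₁ ∈ (0,1), absolute
tolerance 1e−12) and returns 1/(1−KC₁); a property test holds the two
routes together to 1e−9 relative over KC ∈ [1e−6, 1e3].

Entangled linear chains relax by reptation, giving

    η(C) = A · C^(3/(3ν−1)) · ⟨L⟩³,

with ν = 3/5 (concentration power 3/(3ν−1) = 3.75) and
A = 5.4×10⁻⁸ cP·(mg/mL)⁻³·⁷⁵. A is treated as a scaffold constant, not a
per-molecule parameter. The law has two regimes visible in its log-log
slope: 3.75 as KC → 0 and 5.25 (= 3.75 + 3/2) as KC → ∞, both checked
numerically in the suite.

Head-to-tail (HT) association — a CDR binding a framework patch — raises
the valence and produces branched complexes that cannot reptate. No
quantitative HT size model is implemented; HT physics enters only as
outlier detection (below).

## Inversion and profile fitting

The map η → K at one concentration is closed-form:
L = (η/(A·C^3.75))^(1/3), then √(1+4KC) = 2L−1 gives K = (L²−L)/C.
K is kept *signed* at the model and calibration layers: η below the
monomer baseline A·C^3.75 yields L < 1 and K < 0, which is flagged
`non_entangled` — the diagnostic that the molecule is not in the
entangled regime and the reptation law does not apply. Clamping negative
K to zero happens only at the screening layer, where a prediction must
still be produced (the baseline curve is the natural floor, since the
model covers associative entanglement only).

Multi-point viscosity profiles are fit by single-parameter least squares
on **log**-viscosity residuals: profiles span roughly an order of
magnitude between 70 and 250 mg/mL, and log residuals weight the
concentrations evenly where linear residuals would let the highest
concentration dominate. (Linear-residual fitting is a defensible
alternative; the choice matters little for 2–5-point profiles.) Points
below the 100 mg/mL **entanglement floor** are excluded with a warning:
below that concentration solutions exhibit a distinctly weaker power
regime and the reptation law does not describe them. The optimizer is a
bounded `scipy.optimize.least_squares` started at the median of the
per-point closed-form inversions, with the bound K > −1/(4·C_max) keeping
the square root real; on noise-free profiles the starting value is
already the optimum, and the round-trip test demands 1e−8 relative
recovery.

## Calibration

Two linear maps connect dilute readouts to K, shipped with their
published coefficients so prediction needs no training cohort:

    D_np = 4.9 − 2045·K      k_D = 56.03 − 15000·K

(k_D is mL/g while K is mL/mg — the DLS slope absorbs the factor of
1000·concentration scaling; column names in all files carry units to keep
the two from being confused.) Refitting on a cohort is ordinary
unweighted least squares of the *measurement on K*, the orientation the
lines are written in. The exclusion rules applied before fitting:

* both lines: molecules with negative fitted K (`non_entangled`), and
  molecules missing the measurement;
* AC-SINS: D_np ≤ 1 μm²/s. Below this floor nanoparticle-cluster
  diffusion saturates (the Stokes radius of a cluster grows sublinearly
  with occupancy) and the readout no longer tracks affinity. Suspected
  HT binders are also removed, since the tether occludes one of their
  binding sites and D_np under-reports their association;
* DLS: |k_D| > 60 mL/g (readings beyond the plausible antibody range
  indicate experimental error; the bound generalizes a published single
  exclusion at 84 mL/g and is configurable), and K > 0.01 mL/mg, beyond
  which branched complexes are expected and the reptation fit of K is
  not meaningful.

Every input molecule lands exactly once in the ledger, either as used or
as excluded-with-reason; fewer than three survivors is an error carrying
the full ledger.

**HT detection.** An HT binder looks weak to AC-SINS but strong to DLS,
so in (k_D, D_np) space it sits above the consistency locus implied by
the two calibration lines. The separator is a configurable line
(slope, intercept); molecules strictly above it are flagged. No default
separator is shipped — the correct placement depends on the cohort's
noise and HT displacement — and with the separator unset the detector
returns the empty set and logs a warning rather than guessing.

## Screening and classification

Measurement → K (line inversion, with `clamped_to_zero`,
`low_sensitivity_dnp` for D_np < 1 μm²/s, and `above_branching_cutoff`
flags) → viscosity curve on a grid (default 70–250 mg/mL in 10 mg/mL
steps, matching the measured range; sub-floor points are flagged, not
suppressed) → binary call at 150 mg/mL: **good iff η(150) ≤ 20 cP**, the
boundary inclusive (a molecule at exactly 20.0 cP passes; 20.1 cP
fails). A cohort-level *flag* marks molecules where either source
predicts above the cutoff.

Performance labels against experiment follow the screening study's
convention: `FALSE_POSITIVE` = all predictions low but experiment high;
`FALSE_NEGATIVE` = any prediction high but experiment low; `TRUE`
otherwise. These names are the reverse of the standard screening usage
(the molecule, not the screen, is the subject), so a standard-convention
alias (`standard_false_negative_missed_viscous`,
`standard_false_positive_false_alarm`) is emitted alongside every label.

## Synthetic cohorts

The generator emulates the assay campaign the method was built for: a
cohort (default n = 89, split 63/17/9 by a seeded permutation) with per-
molecule true K drawn log-uniformly over [1e−5, 1e−2] mL/mg, viscosity
profiles at 70 and 150 mg/mL from the reptation law with lognormal noise
(σ_log = 0.05, typical cone-and-plate repeatability), and readouts from
the calibration lines with Gaussian noise (σ = 0.3 μm²/s for D_np,
σ = 2 mL/g for k_D, plausible assay-level scatter). Outlier injection:
an HT fraction (default 5%, matching the observed few-per-cohort rate)
whose D_np reflects the true K but whose k_D and viscosity respond to
`ht_K_multiplier`·K (default 5); and a strong-binder fraction (default
8%) with K drawn from [2.1e−3, 9e−3] mL/mg so that D_np lands below the
1 μm²/s floor. Because a linear map goes negative at strong binding, the
generated D_np saturates at 0.3 μm²/s (clusters still diffuse) with an
instrument floor of 0.05 μm²/s after noise, and k_D bottoms at
−100 mL/g; the saturation acts only in the regime the exclusion rules
remove, so calibration recovery is unaffected. Ground truth (role, true
K) is emitted as a separate table so pipeline code cannot read it by
accident.

What the generator does **not** emulate: nanoparticle cluster optics
(the plasmon shift is generated as an inert, loosely K-correlated
field), three-body bridging by soluble antibody in the AC-SINS assay,
concentration-dependent or many-body electrostatics, and any real
molecule-to-molecule variation in the prefactor A. Passing tests on
synthetic cohorts therefore demonstrate the *statistical machinery*
(fitting, exclusion, recovery under stated noise), not the physical
adequacy of the linear calibration maps for any particular real cohort.

In the HT-recovery test the HT population is drawn from K ∈
[10⁻³·⁵, 10⁻²·³] so its displacement above the consistency locus
(≈ 8180·K μm²/s at multiplier 5) clears the measurement noise; with K
spanning the full default range, weak HT binders are geometrically
indistinguishable from noise and no separator can recover them — a real
limitation of the geometric detector, not of the test.

## Numerical and design notes

* Exponent 3/(3ν−1) requires ν ∈ (1/3, 1]; ν = 1/3 is rejected at
  construction.
* The AC-SINS sensitivity boundary is exclusive at the screening layer
  (D_np = 1.0 exactly is not flagged) and inclusive at the calibration
  layer (D_np ≤ 1.0 is excluded from fits); measurements at the boundary
  to instrument precision are rare enough that the distinction is
  cosmetic, but both rules are stated explicitly.
* Results CSVs embed the package version as a comment line; cohort CSVs
  are read with round-trip float parsing so write → read → write is
  byte-identical.
* Problem sizes in the test suite (cohorts of 20–200, 20 replicates for
  slope recovery) keep each statistical check a few hundred milliseconds
  while leaving comfortable margins on the tested thresholds.

## Known limitations

* Predictions are point estimates; no uncertainty is propagated from the
  calibration-line scatter (the residual SD is reported but unused
  downstream).
* The method's reliable regime is weak-to-moderate association; above
  the branching cutoff or below the D_np floor, predictions carry flags
  but no correction.
* The 20 cP call is made at exactly 150 mg/mL; experimental
  concentrations that deviate from 150 mg/mL can flip borderline
  molecules, which is why the cross-concentration consistency of the law
  (invert at 150, re-evaluate at the experimental concentration) is part
  of the acceptance checks.
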