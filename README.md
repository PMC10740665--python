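# mabvisc

Early-stage screening of therapeutic monoclonal antibodies (mAbs) for
high-concentration viscosity, using only dilute-solution measurements.

Subcutaneous dosing forces antibody drug products to ≥ 100 mg/mL, where
some molecules become too viscous to manufacture or inject — but the
rheology is usually discovered late, when enough material exists to make a
150 mg/mL solution. `mabvisc` implements a physics-based bridge from
two-body measurements available at the discovery stage (AC-SINS
nanoparticle diffusion, DLS interaction parameter) to the many-body
viscosity at formulation concentrations, together with the 20 cP
developability classifier built on top of it.

## The model

Antibody self-association is dominated by CDR–CDR ("head-to-head")
contacts, whose two-site valence makes clusters *linear chains*. With an
isodesmic association constant K (mL/mg, from the dimer mass action
K = C₂/C₁²) the number-average chain length at total concentration C
(mg/mL) is

    ⟨L⟩ = 2KC / (√(1+4KC) − 1) = (1 + √(1+4KC)) / 2

Entangled chains relax by reptation, so

    η(C) = A · C^(3/(3ν−1)) · ⟨L⟩³        [cP]

with Flory exponent ν = 3/5 (concentration power 3.75) and
A = 5.4×10⁻⁸ cP·(mg/mL)⁻³·⁷⁵. Viscosity is controlled by the single
parameter K, which can be estimated from dilute data through two
calibration lines:

    D_np = 4.9 − 2045·K        (AC-SINS diffusion, μm²/s)
    k_D  = 56.03 − 15000·K     (DLS interaction parameter, mL/g)

The inversion η → K is closed-form (L = (η/AC^3.75)^(1/3),
K = (L²−L)/C), so measured viscosity profiles determine K directly; the
package also carries the method's applicability rules — the 1 μm²/s
AC-SINS sensitivity floor, the 100 mg/mL entanglement floor, the
0.01 mL/mg branching cutoff, |k_D| plausibility limits, negative-K
(non-entangled) flagging, and a configurable separator for suspected
head-to-tail binders.

## Worked example

```python
>>> from mabvisc import (DEFAULT_ACSINS_LINE, DEFAULT_DLS_LINE,
...                      k_from_measurement, viscosity, classify)
>>> k = k_from_measurement(2.9, DEFAULT_ACSINS_LINE)   # D_np = 2.9 um^2/s
>>> round(k.value, 6)
0.000978
>>> eta150 = viscosity(k.value, 150.0)
>>> round(eta150, 1)
11.3
>>> classify(eta150)
'good'
>>> k2 = k_from_measurement(2.0, DEFAULT_DLS_LINE)     # k_D = 2 mL/g
>>> round(viscosity(k2.value, 150.0), 1)
20.9
>>> classify(viscosity(k2.value, 150.0))
'bad'
```

A D_np of 2.9 μm²/s maps to K ≈ 9.8×10⁻⁴ mL/mg and a predicted
11.3 cP at 150 mg/mL — a developable molecule — while a nearly neutral
k_D of 2 mL/g maps to K ≈ 3.6×10⁻³ mL/mg and a predicted 20.9 cP,
above the 20 cP cutoff, so the molecule is flagged. The same pipeline is scriptable:

```sh
mabvisc simulate --seed 7 --n 89 --split 63,17,9 \
    --out-molecules m.csv --out-viscosity v.csv --out-truth truth.csv
mabvisc calibrate --molecules m.csv --viscosity v.csv --out cal.json
mabvisc predict --molecules m.csv --calibration cal.json --out results.csv
mabvisc evaluate --results results.csv
```

Two measured panels ship with the package (17 validation molecules with
experimental and predicted viscosities at two concentrations, and a
9-molecule test panel); load them with
`mabvisc.data_io.load_validation_panel()` / `load_test_panel()`.

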