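# sonocryst

Analysis pipeline for **ultrasound-assisted oiling-out crystallization**:
classical-nucleation-theory (CNT) kinetics from induction times, two-phase
ternary mass balance, a pulsed-field surrogate for ultrasound energy input,
and post-processing of molecular-dynamics-style outputs — plus the synthetic
generators (including a toy Brownian-dynamics demixing simulator) that make
the whole chain testable without instruments or an MD engine.

## The problem

Highly water-soluble, strongly charged solutes such as fructose
1,6-diphosphate trisodium (FDPNa3, C₆H₁₄O₁₂P₂ acid MW 340.12 g/mol) often
refuse to nucleate during anti-solvent crystallization: adding ethanol to the
aqueous solution drives liquid–liquid phase separation ("oiling-out") into a
solute-rich dense phase instead of crystals.  Ultrasound shortens the
induction period and alleviates solute clustering.  This package gives a
crystallization scientist the quantitative toolkit for such a study:

* **CNT kinetics** — for a spherical nucleus, ln t_ind = A + B/(ln S)², with
  B = 16πγ³v²/(3k³T³).  Oiling-out systems show two slope regimes, so the
  model is a two-branch changepoint OLS; from each branch slope the
  interfacial energy γ = (3Bk³T³/16πv²)^⅓, and per supersaturation the
  critical radius r_c = 2γv/(kT ln S), molar barrier
  ΔG_c = 16πγ³v²/(3(kT ln S)²)·N_A and nucleus size N_c = (4π/3)r_c³/v.
* **Phase equilibrium bookkeeping** — σ = (C − C*)/C*, per-component mass
  balance of dense/light splits, lever rule, ethanol–water composition
  conversion, and onset-boundary interpolation.
* **Pulsed field** — E(t) = E₀·exp(−(t−t₀)²/2σ_t²)·cos(ω(t−t₀)) with
  ω = 2πc/λ or given directly; sampling, fluence ∫E²dt against its closed
  form, and MD-engine input tables.
* **MD post-processing** — XVG energy tables (inter-group interaction =
  Coul-SR + LJ-SR, kJ/mol), GRO frames, axis density profiles, a demixing
  index (half total-variation distance between species distributions),
  periodic single-linkage clustering, and FBRM-like onset detection.

## Worked example

Fit the packaged 100 W-ultrasound induction table (v for the trisodium salt
from MW and an assumed crystal density of 1.8 g/cm³):

```python
import sonocryst as sc
from sonocryst.constants import MolecularParams, molecular_volume_from_density

mw_salt = 340.12 - 3 * 1.008 + 3 * 22.99          # acid -> trisodium salt
v = molecular_volume_from_density(mw_salt, 1.8)    # m^3 per molecule
mol = MolecularParams(molecular_volume=v)

model = sc.InductionTimeModel(sc.datasets.induction_records("ultrasound"), mol)
res = model.fit(split=2.05)   # or split="auto"
print(res.summary())
```

```
Two-branch CNT induction-time fit
======================================================
  model: ln t_ind = A + B/(ln S)^2   T = 298.15 K
  split at S = 2.05
------------------------------------------------------
  branch    n         A         B    gamma mJ/m^2       RSS
  low       4    8.7975    0.3752           2.233 2.544e-03
  high      3    7.8331    0.8906           2.978 6.987e-04
======================================================
```

The low-supersaturation branch (S ≤ 2.0) has the shallower slope; the jump
in slope — and hence in apparent interfacial energy (2.23 → 2.98 mJ/m² at
this assumed v; γ scales as v^(−2/3), so the absolute numbers move with the
density you assume) — marks the discontinuous kinetic regime typical of
oiling-out.  `res.cnt_table()` then yields the per-S parameters; e.g. the
first row (S = 1.8, t_ind = 19 800 s):

```
   S  t_ind_s  ln_t_ind branch  gamma_mJ_per_m2   N_c  dG_c_J_per_mol  r_c_nm
1.80  19800.0     9.893  low-S            2.233 3.695        2692.204   0.691
```

ln t_ind = 9.893 reproduces the published value exactly; r_c ≈ 0.7 nm and
N_c ≈ 4 molecules say the critical nucleus is only a handful of molecules —
yet ΔG_c is in the kJ/mol range, the high barrier that rationalises
oiling-out without nucleation.  `res.bootstrap_ci()` adds bootstrap
confidence intervals, and `res.fit_report()`/`res.to_json()` serialise the
fit.

The same pipeline runs from a shell:

```
sonocryst fit-cnt --input table.csv --volume 3.75e-28 --split auto
sonocryst simulate-toy --amplitude 2 --seed 7
sonocryst generate induction --seed 7
```

The toy simulator demonstrates the mechanism end to end:

```python
from sonocryst import field_response
print(field_response(amplitudes=(0.0, 1.0, 2.0), seed=3))
```

prints one row per field amplitude; with a matched seed the demixing index
and the solute–solute interaction-energy magnitude both fall as the
amplitude rises — clustering is alleviated by the pulsed energy input while
the silent run stays demixed.

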