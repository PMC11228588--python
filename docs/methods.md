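# Methods

`sonocryst` analyses ultrasound-assisted anti-solvent crystallization of a
highly water-soluble, triply charged organophosphate salt (fructose
1,6-diphosphate trisodium, "FDPNa3") that oils out — separates into a
solute-rich dense liquid and a light liquid — instead of nucleating.  The
package covers four linked analyses plus the synthetic generators that stand
in for the wet lab and the MD engine.

## 1. Nucleation kinetics from induction times

Classical nucleation theory for a spherical nucleus gives the induction-time
relation

    ln t_ind = A + B / (ln S)^2,      B = 16 π γ³ v² / (3 k³ T³),

with S = C/C* the supersaturation ratio, γ the solid–solution interfacial
energy, v the solute molecular volume, k Boltzmann's constant and T the
temperature.  A linear fit of y = ln t_ind on x = (ln S)⁻² yields B per
supersaturation regime, and

    γ = (3 B k³T³ / (16 π v²))^{1/3}.

Oiling-out systems typically show **two** slope regimes; the model fits a
two-branch changepoint OLS: all splits contiguous in S with at least two
points per side are enumerated and the split minimising the total residual
sum of squares is chosen (an explicit S threshold can be given instead).
Replicate S values stay on one side; an RSS tie (single-branch data) is
flagged rather than silently resolved.

Per-supersaturation CNT parameters follow from γ:

    r_c  = 2 γ v / (k T ln S)               critical radius
    ΔG_c = 16 π γ³ v² / (3 (kT ln S)²) · N_A   molar barrier
    N_c  = (4π/3) r_c³ / v                   molecules in the nucleus

Internally all quantities are strict SI; tables print γ in mJ/m², ΔG_c in
J/mol and r_c in nm, matching crystallization practice.  Uncertainty is
provided as pairs-bootstrap percentile intervals on (A, B, γ) per branch;
nothing beyond that is claimed.

**Molecular volume.** v is user input (every CNT formula needs it and it is
rarely tabulated); a helper computes v = MW/(ρ·N_A) from molecular weight
and crystal density.  Molecular weights come from the conventional IUPAC
atomic-weight table (C 12.0107, H 1.00794, O 15.9994, P 30.973762), which
yields 340.12 g/mol for C₆H₁₄O₁₂P₂ at two decimals.

**Temperature.** Carried per record; the model requires an unambiguous T
(unique across records or passed explicitly) because γ conversion mixes T³
into the slope.

**Packaged tables.** Two published CNT summary tables (100 W ultrasound and
silent) ship as CSV with the printed γ/N_c/ΔG_c/r_c columns for
cross-checking.  Printing quirks are preserved, not repaired: four rows'
printed ln t_ind values are off by one unit in the third decimal
(ln 25200 = 10.1346 → printed 10.134, and similarly for 14400, 21960,
16200), and one N_c cell is a typographic garble stored as missing; a
`ln_t_printed_ok` flag marks the affected rows.  The printed N_c values do
not close with N_c = (4π/3)r_c³/v for any plausible v at the printed γ and
r_c; the standard formula is implemented and the discrepancy documented
here rather than silently reconciled.  The identity ΔG_c = (4π/3)γ r_c² N_A,
by contrast, closes on the printed values to the printed precision and is
enforced at 1e-9 relative on every emitted row.

## 2. Two-phase ternary bookkeeping

Relative supersaturation is σ = (C − C*)/C* with C and C* in the same units
(g solute per g solvent by default; the formula is unit-invariant).
Measured dense/light splits are validated by per-component mass balance
(relative residuals; a zero overall component with non-zero phase content
reports an infinite residual, not an exception).  The lever rule returns
unclamped fractions with a consistency flag so an overall composition off
the tie-line is visible instead of hidden.  Ethanol–water solvent
compositions from volume ratios assume additive volumes (no excess-volume
model — an approximation; the experiments measure volumes directly).
Boundary (oiling-out/nucleation onset) curves interpolate piecewise-linearly
and refuse to extrapolate; solubility lookups outside the measured grid are
likewise errors, not extrapolations.  No thermodynamic modelling (activity
coefficients, flash calculations) is attempted: the module validates and
transforms measurements only.

## 3. Pulsed-field ultrasound surrogate

The energy input of an ultrasound bath is modelled, as in field-coupled MD
practice, by a Gaussian-enveloped sinusoidal electric field along one axis:

    E(t) = E₀ · exp(−(t−t₀)² / (2 σ_t²)) · cos(ω (t−t₀)).

σ_t is the envelope width (named to avoid collision with the supersaturation
σ), and ω may be given directly or derived from a wavelength as ω = 2πc/λ
with c the speed of light — the convention of the field-coupled MD setup
this mirrors, kept as-is even though c is physically odd for an acoustic
surrogate; a direct-ω override exists.  Times are picoseconds (MD
convention); defaults for t₀ and σ_t are configuration, not constants, since
no absolute pulse timing is canonical.  The pulse fluence ∫E²dt (a proxy for
delivered energy) has the closed form E₀²·σ_t·√π/2·(1 + exp(−ω²σ_t²));
quadrature over t₀ ± 8σ_t reproduces it to better than 1e-8 relative and is
tested against it.  Field tables are written at 17 significant digits so a
read-back is bit-exact.

There is no published mapping from bath watts to field amplitude; amplitudes
(e.g. 15/20/25 V/nm) are treated as independent scenario labels.

## 4. MD post-processing

* **Energies.** XVG-dialect tables ("#" comments, "@" directives) from a
  `gmx energy`-style workflow are parsed; legends of the form
  `<term>:<pair>` with term Coul-SR or LJ-SR become (group-pair, term)
  columns, anything else is preserved verbatim.  The inter-group interaction
  measure is the sum Coul-SR + LJ-SR; although often called a "force" in
  crystallization papers, it is an energy and is labelled kJ/mol here.  The
  steady-state estimate is the mean over the final quarter of frames
  (configurable; no canonical averaging window exists).
* **Density profiles.** Uniform half-open bins along a box axis; density =
  count/(bin width × cross-section), so density × bin volume returns exact
  counts (conservation is asserted, not assumed).
* **Demixing index.** d = ½ Σ_bins |p_a − p_b| over the two species'
  normalised bin distributions — half the total-variation distance: 0 for
  identical distributions, 1 for disjoint support.  It is symmetric and
  invariant under order-preserving relabelling of bins.  With n particles
  and m bins the sampling floor is O(√(m/n)), so small systems never reach
  exactly 0.
* **Clustering.** Single-linkage components under a minimum-image distance
  cutoff (orthorhombic boxes only; triclinic rejected).  Neighbour pairs
  come from a periodic k-d tree; components from a sparse connected-
  components pass; ids are deterministic (ordered by lowest member index).
  A brute-force O(n²) union-find serves as the oracle in tests.
* **Onset detection.** A count series onsets at the first index exceeding
  baseline mean + k·sd for m consecutive samples (defaults k = 5, m = 3,
  baseline = first 10 %).  This is a generic change detector for FBRM-like
  count signals; no chord-length physics is modelled.

## 5. Toy Brownian-dynamics simulator

A desk-scale surrogate for the all-atom MD: labelled point particles
(solute, counterion, ethanol, water) in a periodic 5×5×5 nm box under
overdamped Langevin dynamics,

    x ← x + dt·(F_pair + q·E(t)·ê_axis) + √(2·T_eff·dt)·N(0,1).

**Pair potential.** A soft-core generalised Lennard-Jones,
u = 4(ε_rep s¹² − ε_ab s⁶) with s² = σ²/(r² + δ²), δ = σ = 0.35 nm,
truncated at 1.2 nm and energy-shifted to vanish there.  The soft core keeps
overdamped steps stable near contact; the global ε_rep = 1 gives every pair
excluded volume while the species-pair depth ε_ab sets attraction (binding
minimum −ε_ab² for ε_ab ≤ 2).  Charged pairs add a screened-charge term
k_c·q_iq_j·exp(−r_eff/λ_D)/r_eff (k_c = 0.05, λ_D = 0.5 nm).  A divergence
guard aborts if any |F|·dt exceeds half the box.  Energies are logged per
species pair, split into "LJ-SR" and "Coul-SR" columns, deliberately reusing
those legend strings so the XVG parser path is exercised end to end.

**Field coupling and local heating.** The pulsed field exerts the
deterministic force q·E(t) on charged particles.  A uniform field, however,
pushes every identically charged particle equally: clusters translate
rigidly, and in pilot runs coherent sweeping *promoted* aggregation
(orthokinetic collision enhancement) — it cannot disperse anything by
itself.  The dispersing channel of ultrasound-like energy input is modelled
as local heating: a charged particle drifting against friction dissipates
power ∝ (qE)², which raises its noise temperature,

    T_eff(t) = T + η·(q·E(t))²,       η = 0.45 by default.

This is the package's analogue of cavitation bursts disrupting the ordered
shell around the charged solute: heating above the pair binding melts
clusters, and in the troughs of a slow carrier (ω = 0.5, period ≈ 13 time
units) the species cools and partially re-aggregates, so the cycle-averaged
cluster content varies *continuously* with amplitude instead of switching at
a threshold.

**The demixing scenario** (`demixing_sim_spec`): 72 solute (q = −3),
168 counterions (+1), 96 ethanol, 96 water; solute–solute attraction 1.2,
solute–ion 0.8, weak solvent couplings; T = 0.1; dt = 0.005 for 5000 steps;
the pulse peaks at ¾ of the run with σ_t = run/4, so clusters form
undisturbed and the closing quarter — the analysis window — lies under the
pulse.  Explicit counterions are simulated (rather than folding them into
the solute charge) because the mechanism requires field-driven *relative*
motion between oppositely charged species; with a single charged species the
field produces only rigid translation.  `field_response` measures, with one
matched seed across amplitudes {0, 1, 2}: the demixing index (solute vs
ethanol) averaged over the closing window, and the tail-mean solute–solute
interaction energy.  Demixing is measured along y, perpendicular to the
field: along x the coherent q·E sloshing displaces the solute distribution
and would inflate the index without any de-clustering.  Under these frozen
conditions both observables are monotone non-increasing in amplitude on
every pilot seed tried (margins ≈ 0.38/0.24/0.18 for the index and
≈ −260/−30/−2 for the energy).

**What the toy does and does not emulate.** It reproduces, qualitatively:
demixing of a self-attracting solute, counterion accumulation around it,
and field-graded alleviation of clustering.  It has no force-field realism,
no water structure, no hydration-shell molecular detail, no hydrodynamics,
and its energy/time units are reduced units merely labelled like MD output.
Passing trend tests therefore says the *pipeline logic* behaves correctly on
data with the right structure — not that any real system parameter has been
estimated.

## 6. Other synthetic generators

* **Induction datasets**: ln t = A_branch + B_branch·(ln S)⁻² + N(0, sd)
  (i.e. lognormal noise on t_ind, sd 0.05 by default), 8 grid points per
  branch spanning S ≈ 1.6–2.6 with the changepoint at 2.05.  Branch slopes
  can be specified via target γ values so recovery is measured on the γ
  scale.  The Monte-Carlo recovery study (200 replicates) recovers γ with
  well under 5 % median error and the changepoint in ≥ 95 % of replicates.
* **Phase splits**: component masses are allocated to the dense phase with
  share φK_c/(φK_c + 1 − φ) (K_c the dense:light distribution ratio, φ the
  nominal dense mass fraction), so splits close mass balance to machine
  precision by construction and K_solute > 1 enriches the dense phase.
* **Count series**: baseline + Gaussian noise + step-plus-ramp after a known
  onset, clipped at zero.

Every generator is a pure function of its spec including the seed; repeated
calls are byte-identical.

## Numerical choices and degenerate inputs

* Natural logarithms throughout; printed values rounded half-even at 3 d.p.
* OLS via `numpy.linalg.lstsq`; verified against explicit normal equations
  to 1e-10.
* Quadrature via adaptive `scipy.integrate.quad` at 1e-11 relative target.
* Binning is half-open, left-inclusive, 0-based; a particle exactly at the
  box length wraps to 0 (and a floating-point `mod` that rounds up to the
  box edge is clamped to 0).
* Duplicate S values are replicates; at an explicit split, ties go to the
  low-S branch.
* Problem sizes in tests and the reproduction script (desk-scale simulator
  runs of ≤ 450 particles × 5000 steps, 200-replicate recovery studies,
  100-frame oracle sweeps) were chosen so the whole suite runs in well under
  a minute of compute after JIT warm-up while leaving comfortable
  statistical margins.

## Known limitations

* The two-branch fit assumes exactly one changepoint; more regimes require
  refitting subsets.
* γ from slopes inherits the v³ sensitivity of CNT: an uncertain molecular
  volume shifts γ as v^(−2/3); absolute γ values are only as good as v.
* The demixing index depends on bin count; comparisons are only meaningful
  at fixed binning (tests use 8 bins).
* The pulsed-field "wavelength" convention ties ω to the speed of light;
  physical acoustic frequencies should use the direct-ω override.
* The toy simulator's heating coefficient η is a scenario parameter with no
  physical mapping to bath power; amplitude ladders are labels, not watts.
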