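# Methods

This note documents the models implemented in `leafgm`, the numerical
choices behind the fits, what the synthetic-data generators emulate, and
the known limitations. Everything stated here is computed by the package
itself (the test suite and `scripts/acceptance.py` exercise each claim);
no empirical result is asserted beyond what those runs produce.

## 1. The biochemical model (FvCB)

Net CO₂ assimilation of a C3 leaf is modelled as

    Wc = Vcmax (Cc − Γ*) / (Cc + Kc (1 + O/Ko))
    Wj = J (Cc − Γ*) / (4 Cc + 8 Γ*)
    Wp = 3 Tp (Cc − Γ*) / (Cc − (1 + 3α) Γ*)      (Cc > (1+3α) Γ*)
    An = min(Wc, Wj, Wp) − Rd

with `Cc` the chloroplastic CO₂ mole fraction. The limiting-rate
combination is a strict minimum, not a smoothed hyperbola, so every
evaluated point carries a well-defined limiting-process label (`Wc`, `Wj`,
`Wp`). The glycolate-return fraction α defaults to 0, in which case the
TPU-limited rate is the constant 3·Tp above Γ* and is treated as
non-limiting below it.

Temperature scaling of Vcmax, J, Rd, Tp, Kc, Ko (and Γ* in Arrhenius
mode) uses the factor `exp[Ea (T − 298.15)/(298.15 R T)]`, identically 1
at 25 °C. Default kinetics (Bernacchi-style, mole-fraction basis at
1 atm): Kc₂₅ = 404.9 μmol mol⁻¹ (Ea 79430 J mol⁻¹), Ko₂₅ = 278.4
mmol mol⁻¹ (36380), Γ*₂₅ = 42.75 μmol mol⁻¹ (37830), Ea(Vcmax) = 65330,
Ea(J) = 43540, Ea(Rd) = 46390, Ea(Tp) = 53100. All live in the editable
constants registry (`ConstantsRegistry`, YAML-serializable), never in
code.

Γ* can alternatively be derived from the liquid-phase Rubisco CO₂/O₂
specificity (default S_c/o = 97.3 M M⁻¹):
Γ* = ½·O / (S_c/o · k_H,CO₂/k_H,O₂), with van't Hoff Henry's-law
solubilities (CO₂: 0.034 M atm⁻¹, 2400 K; O₂: 0.0013 M atm⁻¹, 1700 K).
This is the default mode and gives ≈ 41.3 μmol mol⁻¹ at 21 % O₂/25 °C and
≈ 3.9 μmol mol⁻¹ at the 2 % O₂ used in isotope sessions. The solubility
functions are pluggable registry entries because published
temperature-response choices differ between labs; every downstream
correctness test is a round trip and therefore independent of this
convention.

## 2. Variable-J fitting

The variable-J method combines gas exchange with chlorophyll
fluorescence. The fluorescence-based electron transport rate is
`J_F = τ · Qin · φPSII`, with τ = absorptance × β fitted as a free
parameter (β never appears separately). Each candidate parameter vector
implies a per-point chloroplastic CO₂

    Cc = Γ* (J_F + 8 (A + Rd)) / (J_F − 4 (A + Rd))

and hence a per-point mesophyll conductance `gm = A/(Ci − Cc)`. Points at
or beyond the pole `J_F = 4(A + Rd)` are excluded from the objective with
a fixed penalty (never clipped — clipping biases gm); a fit in which more
than 25 % of points are singular at the optimum fails.

### Objective design

A least-squares objective on A alone is exactly degenerate. On
Rubisco-limited points the two equations combine to

    J_F = [12 Γ* Vcmax − (8 Γ* − 4 Km)(A + Rd)] / (Γ* + Km),

linear in (A + Rd): a shift in Rd is absorbed exactly by Vcmax (and by Tp
through the plateau A = 3 Tp − Rd), leaving the A-residuals unchanged
along a one-dimensional ridge while the implied gm drifts by tens of
percent. The default objective therefore adds a J-consistency block: a
sixth parameter, the common mesophyll resistance `rm`, defines a
supply-line Cc_s = Ci − A·rm, and the block penalizes

    λ · (τ Qin φPSII − (A + Rd)(4 Cc_s + 8 Γ*)/(Cc_s − Γ*))

on the well-lit points (A > 25 % of the curve maximum), with the
denominator clamped at 0.5 μmol mol⁻¹ so the term acts as a continuous
barrier as Cc_s → Γ*. The block is formulated in J-space deliberately:
measured Qin·φPSII enters linearly, so measurement noise does not bias
the ridge position (Cc-space variants are biased because E[Cc] is convex
in J_F near the pole). λ (`FitConfig.j_consistency_weight`) defaults
to 1.0; setting it to 0 restores the pure-A objective. With noiseless
data the term is exactly zero at the truth, so it cannot distort an
ideal fit; with noisy data it shrinks the per-point gm profile toward a
common value, which slightly biases fits of leaves whose gm varies
strongly with Ci — the per-point gm(Ci) output remains free and still
shows such structure.

### Optimization

Both fits use bounded trust-region least squares with a Latin-hypercube
multistart (default 10 starts; bounds Vcmax₂₅ ∈ [5, 500], J₂₅ ∈ [10,
600], Rd₂₅ ∈ [0, 10], Tp₂₅ ∈ [1, 40], τ ∈ [0.2, 0.6], rm ∈ [10⁻⁴, 50]),
preceded by a deterministic data-driven start (Rd from 2 % of peak A, J
from the saturated plateau, Vcmax from the steepest low-Ci point, Tp from
the plateau) and followed by a high-precision polish
(xtol = ftol = 2.3·10⁻¹⁶, Jacobian scaling) because the objective has
long, nearly flat valleys where default tolerances stall. Parameter
standard errors come from the Jacobian at the optimum. A fit whose best
solution leaves an entire limiting regime unvisited flags the
corresponding parameter as weakly identified rather than failing.

### Operating point

`gm_at_reference` extracts the value at the 400 μmol mol⁻¹ setpoint from
the logged sequence (400, 300, 200, 150, 75, 50, 20, 400, 400, 500, 600,
800, 1000, 1200, 1500, 1800): the mid-sequence 400,400 recovery pair is
averaged when its two values agree within 10 % (a stability check),
otherwise the pre-ramp 400 point is used; a single matching setpoint is
returned directly.

### Apparent vs true Vcmax

Fitting with gm = ∞ (Cc = Ci) yields *apparent* parameters: on data
generated with finite gm the apparent Vcmax is strictly below the
generating value (≈ 79 vs 100 at gm = 0.3 mol m⁻² s⁻¹ under the default
conditions), while refitting the same assimilation data against the
variable-J Cc recovers the generating Vcmax. This contrast is the
mechanism check for attributing genotype differences to gm rather than
Rubisco activity.

## 3. ¹³C discrimination

A tunable-diode laser measures ¹²CO₂ and ¹³CO₂ in nine streams per
~3-minute cycle: a CO₂-free zero, three spans of one isotopic signature
(60/300/1000 μmol mol⁻¹), a δ¹³C reference tank, and inlet/outlet air of
two leaf chambers. Per cycle, a linear (gain + offset) model per
isotopologue is least-squares fitted through the zero and spans, and a
residual multiplicative ¹³C correction is anchored on the δ reference
tank; the model is applied to that cycle's chamber streams only, so slow
gain drift is removed cycle by cycle. Calibrated chamber streams are
paired with the gas-exchange log entry of the same chamber nearest in
time within ±90 s (cycles and logs both run on ~180-s cadence).

Isotopic quantities (δ and fractionations in absolute units internally):

* δ¹³C = R/R_VPDB − 1, R = [¹³CO₂]/[¹²CO₂], R_VPDB = 0.0111797;
* drawdown ratio ξ = C_in/(C_in − C_out), on ¹²CO₂ mixing ratios by
  default (configurable to total CO₂);
* observed discrimination Δobs = ξ(δ_out − δ_in)/(1 + δ_out − ξ(δ_out − δ_in));
* ternary correction t = (1 + ā)E/(2 g_ac), ā = 4.4 ‰, g_ac the series
  boundary-layer + stomatal CO₂ conductance;
* apparent respiratory fractionation
  e* = e + (δ_substrate − δ_meas)/(1 + δ_meas/1000), encoding the
  disequilibrium between the respiratory substrate (fixed by growth
  conditions — respiration is treated as isotopically disconnected from
  the Calvin–Benson cycle) and the measurement CO₂; e* is by construction
  independent of the measurement O₂ level;
* comprehensive model
  Δ = ā(Ca−Ci)/[Ca(1−t)] + (1+t)/(1−t)·[a_m(Ci−Cc) + b·Cc −
  ê(Cc−Γ*) − f·Γ*]/Ca, with ê = e*·Rd/(A+Rd), a_m = 1.8 ‰, b = 29 ‰,
  f = 11 ‰ (all registry entries; the higher-order isotope-effect ratio
  factors are taken as 1).

With Δi the model prediction at Cc = Ci, the Cc-dependent terms cancel to

    Δi − Δobs = (1+t)/(1−t) · (b − a_m − e*·Rd/(A+Rd)) · (Ci − Cc)/Ca,

so `gm = (1+t)/(1−t)(b − a_m − e*·Rd/(A+Rd))(A/Ca)/(Δi − Δobs)` and
Cc = Ci − A/gm. Δobs = Δi maps to infinite gm (zero drawdown); Δobs > Δi
is flagged nonphysical and reported as NaN rather than clipped. Rd for
the respiration term comes from the post-session dark measurement
(configurable). The forward model used by the TDL generator is an
independent transcription of the same equations (it shares only the
constants registry), so the forward–inverse round trip (recovery to
≤10⁻⁶ relative over gm = 0.05…2.0 mol m⁻² s⁻¹, and ~10⁻¹³ in practice) is
a genuine two-path check of the algebra, not a tautology.

## 4. Conductance partitioning and effective porosity

gm is decomposed into three serial barriers on a projected-leaf-area
basis, 1/gm = 1/g_ias + 1/g_cw + 1/g_mem:

* **intercellular airspace** g_ias = D_air·f_ias/L_ias · ρ, with
  ρ = P/(RT) and the effective path L_ias = ½·T_mes by default;
* **cell wall** g_cw = (p/τ)·D_water·H/T_cw · ρ · S_c — proportional to
  effective porosity (porosity/tortuosity) and inversely proportional to
  wall thickness, scaled from wall area to leaf area by S_c; H ≈ 0.83 is
  the dimensionless gas/liquid CO₂ partition coefficient;
* **membranes** g_mem = γ·P_mem·H·ρ·S_c/2 for the plasma membrane and
  chloroplast envelope in series (P_mem = 3.5·10⁻³ m s⁻¹, enhancement
  factor γ = 1 by default; a five-component mode is out of scope — the
  three barriers named are the ones with leverage on gm).

The gas↔liquid conversion (H·ρ) is one shared helper so basis conventions
cannot diverge between components. Partitioning inverts this: g_ias and
g_mem follow from anatomy, g_cw by series subtraction (an error naming
the binding component if non-positive), and

    p/τ = (g_cw/S_c) · T_cw / (D_water · H · ρ),

strictly increasing in g_cw and T_cw; values outside (0, 1] are flagged
implausible but returned. Micrograph traits: S_m = (L_mes/W)·F and
S_c = (L_c/W)·F with the curvature factor F a required input column (it
is section-geometry specific and has no defensible default); wall
thickness = traced wall area / wall length; technical replicates are
averaged to one value per biological replicate before any physics.

All default membrane/diffusivity constants are literature-level values
exposed in the registry; every correctness test of this module is a
forward–inverse round trip and therefore convention-free.

## 5. Synthetic data

Each generator is the round-trip partner of exactly one analysis stage
and is driven by a `TruthSpec` (seeded; identical seed ⇒ identical output
bytes).

* **CO₂-response curves** — the 16-step field protocol (sequence above,
  Qin = 1800 μmol m⁻² s⁻¹, 28 °C, 21 % O₂), default truth Vcmax₂₅ = 100,
  J₂₅ = 180, Rd₂₅ = 1.5, Tp₂₅ = 12 μmol m⁻² s⁻¹, τ = 0.42, constant
  gm = 0.3 mol m⁻² s⁻¹, gsw drawn once per curve (mean 0.4, CV 10 %).
  Per setpoint the coupled supply/demand system (FvCB demand, stomatal
  supply Ci = Ca − 1.6A/gsw, mesophyll drawdown Cc = Ci − A/gm) is solved
  exactly by bracketed root finding (the total-conductance form makes the
  residual strictly increasing, so the root is unique); φPSII is emitted
  as J_actual/(τ·Qin) with J_actual the electron transport sustaining
  carboxylation + oxygenation at the solution, making the curve exactly
  invertible at zero noise. Default noise: 1 % multiplicative on A and
  φPSII.
* **TDL sessions** — the greenhouse protocol (25 °C, 2 % O₂, Ca = 400
  μmol mol⁻¹, 180-s logging, two chambers, chamber flow 0.833 mol m⁻²
  s⁻¹): chamber steady states are solved with the same physics, outlet
  isotopologues follow from the independent forward discrimination model
  plus the chamber mass balance (δ_out obtained by a fixed-point solve so
  the ¹²C-basis ξ is exactly consistent), and all nine streams pass
  through a gain/offset instrument model with optional linear gain drift
  and per-mil δ-noise. Transpiration dilution of the outlet stream is not
  modelled (the ternary effect enters the discrimination model only).
* **Cohorts** — one wild type plus three events, n = 4 biological
  replicates (×3 technical) by default; WT anatomy means T_cw = 160 nm,
  f_ias = 0.30, T_mes = 250 μm, S_c = 12 m² m⁻², p/τ = 0.05, CV 8 %;
  transgenic multipliers T_cw×0.90, p/τ×1.75, f_ias×1.12, S_c×1.05,
  T_mes×1.05. gm is composed forward through the serial model, so the
  cohort supports both the partition round trip and genotype contrasts;
  these effect sizes reproduce a >100 % increase in recomputed g_cw.

What the generators do **not** emulate: environmental drift within a
curve, stomatal patchiness, fluorescence signal saturation artefacts,
leaks/diffusion through gaskets, TDL nonlinearity beyond gain/offset, or
Ci-dependent gm (the truth gm is constant). Passing round trips therefore
demonstrate correctness of the algebra and estimators under the stated
noise model, not robustness to every field artefact.

## 6. Statistics

Genotype contrasts report per-genotype mean ± SEM, percent change of each
event against the wild type, and the unweighted mean percent change
across events. Many-to-one familywise-controlled decisions use Dunnett's
test (scipy), significant at P < 0.05 and marginal at P < 0.1. Percent
changes are scale-invariant by construction. The broader hypothesis-test
menu (normality/heteroscedasticity triage, Welch/Games-Howell, Wilcoxon)
is deliberately out of scope.

## 7. Problem sizes and numerical tolerances

The simulation study behind the headline recovery numbers uses 50 curves
× 16 points with 10+1 multistart fits (seconds per curve); the isotope
round trip uses a 9-value gm grid; calibration checks use 5 drifted
cycles; the noisy-isotope bias check uses 500 cycles (1000 paired
points). Root finding uses Brent's method at xtol 10⁻¹²; the TDL δ_out
fixed point iterates to 10⁻¹⁶; round-trip assertions sit at 10⁻⁶ (grid
inversion), 10⁻¹⁰ (porosity) and 10⁻¹² (series identity), all far above
observed errors (~10⁻¹³–10⁻¹⁶).

## 8. Known limitations

* The discrimination algebra follows the standard comprehensive model in
  the simplified form stated above (unit isotope-effect ratios, boundary
  layer lumped upstream); labs using a different printed variant can
  adjust only the fractionation registry, but structural differences
  (e.g. an explicit boundary-layer term) require editing both the
  inversion and the independent forward model.
* The J-consistency default assumes a common gm is a good description
  over the well-lit part of a curve; for strongly peaked gm(Ci) profiles
  reduce `j_consistency_weight` (at the cost of the Rd/Vcmax ridge
  returning).
* Rd enters the isotope inversion as an external input; no Laisk/Kok
  estimation is provided.
* Pressure correction is off by default; all gas quantities are mole
  fractions at the registry pressure.
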