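# Methods

## Model structure

The simulator couples two subsystems integrated as one stiff ODE
system.

**Patient (three compartments).** State per toxin: free concentration
T in plasma, interstitium and intracellular water; complex PT and free
albumin P in plasma and interstitium; plasma and interstitial volumes.
All concentrations are molar internally; mg/L appears only at I/O
boundaries (mass-action kinetics are molar). The balances are written
for d(V·C)/dt and integrated in concentration form
dC/dt = (RHS − C·dV/dt)/V, which is algebraically identical and keeps
the state well scaled. The extracellular-volume fraction
α = V_is/(V_is+V_pl) is recomputed from current volumes each step; the
ultrafiltration law dV_pl = −(1−α)Q_uf, dV_is = −αQ_uf preserves
V_is/V_pl, so α is in fact constant along a session (asserted in the
tests). The convective inter-compartment term αQ_uf·T_is carries free
toxin only, exactly as the balances are written; complex and albumin do
not cross the capillary endothelium.

**Dialyzer (counter-current fibers).** Blood flows +x inside N
identical fibers, dialysate −x in the per-fiber annulus
A_d = πD_h²/(4N) − π(r_f+t_f)². Plug flow; axial diffusion is
neglected, so the only axial mixing is the numerical diffusion of the
first-order upwind scheme. Plasma flow falls linearly along the fiber
by the ultrafiltration rate and the dialysate flow gains it (no
back-filtration). Free toxin crosses the membrane by diffusion
(KoA-driven) plus Péclet-weighted convection with in-membrane
concentration T̄ = T(1−φ) + T_d·φ; φ is evaluated with `expm1` and a
series fallback (φ → 1/2 − Pe/12) below Pe = 1e-6. The same KoA is
used for all PBUTs (all below 300 g/mol, where KoA is flat in
molecular weight) and is constant in time. Mass-action binding acts in
every blood-side cell.

## Numerics

Method of lines, n_x = 100 cells by default (first-order upwind per
flow direction, fresh dialysate T_d = 0 entering at x = L). The
coupled system (9 patient states + 4·n_x fields + cumulative removal)
is integrated with SciPy's BDF at rtol 1e-8 and atol 1e-12 M on
concentrations (1e-8 on volumes) and a hand-built Jacobian sparsity
pattern; negative concentrations are excluded by tolerance rather than
clipping. A 240-min session at n_x = 100 takes well under a second.
Verification anchors:

* the discretized steady-state clearance of an unbound solute converges
  at first order in 1/n_x to the closed-form counter-current clearance
  (0.19% at n_x = 200; Richardson extrapolation of the two finest grids
  reproduces the closed form to <0.05%),
* a global mass audit (initial + generated = final + dialyzer holdup +
  dialysate removal) closes to ~1e-7 at n_x = 100,
* albumin mass (patient + blood-side holdup) is conserved to 1e-8 while
  its concentration rises under ultrafiltration.

**Priming transient.** The dialyzer starts toxin- and albumin-free (a
saline-primed circuit). During the first minutes the circuit holdup
(~0.1 L blood side) dilutes plasma albumin by ~1.5%, transiently
lowering the bound fraction, so the free-concentration reduction ratio
briefly trails the total-concentration one. From ~2 h onward — the
window where clinical samples are compared — the expected ordering
RR(free) ≥ RR(total) holds, with the 240-min gap increasing with
binding strength (pCG < IAA < IS < pCS). Bench reservoir runs show the
same effect: the circuit holdup acts as ~5% extra distribution volume
relative to the 4.5 L pool.

## Parameters and presets

Reference-patient presets: V_pl0 2.4 L, V_ex0 12.9 L (interstitium
10.5 L), V_ic 25.9 L; hematocrit 0.37; albumin 4 g/dL (MW 66 500
g/mol) with 40% of its mass in plasma; session 240 min, Q_b 300 /
Q_d 700 mL/min, 2 L ultrafiltration at constant rate. Per-toxin
kinetics (G mg/min; K_ip,T, K_ic,T mL/min; k1 M⁻¹min⁻¹): IAA
0.0053/1366/160/1.5e3, IS 0.0285/1210/103/3.6e7, pCG
0.0136/1148/67/1.9e6, pCS 0.0277/1060/98/4.0e7. Urea: two-pool model
with G 8.17 mg/min, K_ic,T 363 mL/min, fixed clearance K_D 224 mL/min.
F180NR geometry: 12 300 fibers (8800 for F6, 13 660 for F200NR), inner
radius 105 µm, wall 35 µm, length 0.23 m, housing diameter 0.04 m; KoA
600 mL/min in vivo (bench KoA values are de-rated 20% for in-vivo use,
761 → 609 mL/min).

Molecular weights are not part of the calibrated table; the package
ships free-acid defaults (IAA 175.18, IS 213.21, pCG 284.26, pCS
188.20, urea 60.06, phenol red 354.38 g/mol), overridable in
configuration because reported clinical concentrations sometimes refer
to salts. K_A per toxin follows from the pre-dialysis bound fraction
and albumin level via K_A = PT₀/(P₀T₀) (IS ≈ 2.5e4 M⁻¹, pCS ≈ 4.3e4,
IAA ≈ 4.6e3, pCG ≈ 2.5e2), and k₂ = k₁/K_A.

## Metric definitions

* **Reduction ratio**: (pre − post)/pre on the plasma total (or free)
  concentration — the raw pre/post sampling definition, no rebound
  correction.
* **Relative removal**: toxin mass carried out with spent dialysate
  over the session divided by the pre-dialysis whole-body load
  (free + bound in plasma and interstitium, free-only intracellular).
  This "fraction of the initial load removed" differs from the *net*
  load change by intra-session generation and the small dialyzer
  holdup; the net change is available separately as `load_reduction`.
  For urea the removed mass is recovered from the balance
  m₀ + G·t − m_end.

## Generation and the periodicity condition

Generation rates satisfy a periodicity condition: after one session
plus an inter-dialytic interval with fluid intake equal to the
ultrafiltered volume, the next pre-dialysis concentration is 95% of the
current one (the next session being the last of the week, with a lower
pre-dialysis level). The cycle ratio is monotone in G, so a bracketed
scalar root finder suffices; an outer loop can alternate G-updates with
re-calibration (0.1% relative tolerance on G). The interval length is
not part of the calibrated table; the package default is 44 h
(mid-week spacing), configurable. For urea the pre-dialysis
concentration itself is not an input; it is obtained by inverting the
same condition at the tabulated G = 8.17 mg/min (≈ 950 mg/L with the
defaults, within the uremic range).

## Calibration

Plasma total concentrations sampled at {0, 15, 30, 60, 120, 240} min
are fitted by bounded trust-region least squares on log-transformed
parameters (k1 spans 1e3–4e7 M⁻¹min⁻¹ across toxins), residuals
(pred − obs)/obs stacked jointly across toxins so that the compartment
volumes can be shared, with a seeded multi-start (default 8). The fit
report carries per-toxin relative error
√Σ((y_pred−y_obs)/y_obs)², convergence diagnostics and Jacobian
column norms as a local sensitivity summary.

**Identifiability.** For toxins whose binding runs at near-equilibrium
on the transit timescale (pCG, IS, pCS: k₂ ≳ 1e3 min⁻¹), k₁ has almost
no influence on plasma totals once K_A is fixed — the sensitivity
column is ~0 and k₁ is structurally unidentifiable from 6-point
concentration series. IAA (k₂ ≈ 0.33 min⁻¹) is kinetically limited and
all three constants are recoverable. Noise-free synthetic fixtures are
recovered to well under 10% (volumes under 5%) from half-decade
perturbed starts.

**Synthetic fixtures.** The generator forward-simulates the calibrated
session and samples it at the clinical time points, optionally with
multiplicative Gaussian noise c → c(1 + σε), seeded and deterministic.
It emulates clean single-toxin plasma series from one representative
patient; it does not emulate assay-specific error structure,
inter-patient variability, access recirculation or intra-session
parameter drift — passing recovery tests therefore demonstrates
estimator correctness, not robustness to those real-data features.

## Scenario and test problem sizes

Production runs (acceptance script, quantitative session checks) use
n_x = 100. Property and sweep tests use n_x = 15–60, where the
monotone, sign-based and conservation properties are already
grid-converged; the calibration recovery study uses n_x = 20 with the
fixture generated at the same resolution so discretization cancels.
The coarse flow sweep covers Q_b ∈ {300, 400, 500} × Q_d ∈ {500, 650,
800} mL/min; full 10 mL/min-step grids are available through
`sweep_flows`.

## Design choices on open points

* Dialyzer outlet blood mixes instantaneously into plasma (no circuit
  transport delay or access recirculation), matching the structure of
  the plasma balance.
* Urea generation enters the extracellular pool by default
  (conventional two-pool practice); intracellular generation is a
  config switch.
* Bench phenol-red runs: blood-side (plasma) flow 200 mL/min, pool
  loading 20 mg/L, Q_uf = 0, 120-min duration; albumin level derived
  from the 6% free fraction and K_A = 2.8e4 M⁻¹ via
  P_free = (1−f)/(f·K_A); k₁ borrowed from pCS (similar bound
  fraction). KoA per run is inverted from the measured clearances
  (11/14/16/23 mL/min) through the free-fraction clearance formula,
  whose removable singularity at f·Q_d = Q_p is evaluated by its limit
  Cl = f·KoA/(1 + f·KoA/Q_p).
* Rebound default 120 min; inter-dialytic interval default 44 h with
  2 L intake distributed in proportion to compartment volumes —
  all configurable.
* One binding site per albumin, no inter-toxin competition, no
  residual renal clearance, no back-filtration, no hemodiafiltration.

## Known limitations

Single-patient physiology (no population variability); KoA treated as
toxin-independent and time-constant; the intracellular pool is a single
well-mixed space with passive exchange; upwind discretization introduces
first-order numerical diffusion (quantified above); calibration is
exercised on synthetic fixtures, with the caveats listed there.
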