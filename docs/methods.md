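# Methods

## The model

`depotsim` simulates the plasma pharmacokinetics of a long-acting injectable
(LAI) suspension administered intramuscularly, using aripiprazole lauroxil
(AR-L, the ester prodrug of aripiprazole, AR) as the built-in reference
compound set. The model chains four mechanisms:

1. **Polydisperse dissolution in the depot fluid.** The injected solid is a
   log-normal (volume-weighted) population of crystals, discretized into
   radius bins (20 by default, truncated at ±3σ in log space). Each bin
   dissolves by a Nernst–Brunner/Johnson film law

   dm_i/dt = −N_i · 4π r_i² · (D_aq / h) · max(S_site − C_u, 0),

   with fixed particle counts N_i, shrinking radii r_i = r_i0 (m_i/m_i0)^{1/3},
   a constant diffusion-layer thickness h (65 μm, a fitted literature value;
   an `h = min(r, h)` rule is available but is 3–5× too fast against the
   reference kinetics), and the *unbound* dissolved concentration
   C_u = f_ut · A_d/V_depot as the back-pressure term. Because the tissue
   unbound fraction of the prodrug is ~2×10⁻⁸, the depot is effectively a
   sink at all times and release is dissolution-limited over months despite
   the ~10⁻⁴ mg/mL aqueous solubility.

2. **An inflammatory cell layer (ICL) around the depot.** The foreign-body
   reaction wraps the depot in a layer of immune cells whose thickness
   follows a pulse A·(t−t_lag)·e^{−B(t−t_lag)} (zero before the onset lag):
   it grows, peaks at t_lag + 1/B, and resolves. Dissolved drug must diffuse
   through it, modelled as a conductance

   G_ICL(t) = κ · SA · D_ICL · fu_ICL / thickness(t)   [mL/h],

   where SA is the surface area of a sphere holding the injected solid
   volume (SA = (36π)^{1/3} (Dose/ρ)^{2/3}, ρ = 1.774 g/cm³ calibrated once
   so the 400 mg-eq dose gives 2.32 cm²), D_ICL = 10^{−5.9514} cm²/s on the
   only defined branch of its lipophilicity correlation (logD(7.4) > 3;
   less lipophilic compounds must supply a measured value), and
   fu_ICL = 1/(2.12 e^{0.523·logD}) is the unbound fraction in the layer
   (only unbound drug permeates — an assumption). κ is a dimensionless
   scale absorbing the unknown proportionality between these physical
   quantities and the layer's actual permeability; it is a fitted parameter.
   Note that thickness enters only through G_ICL, so A and κ are exactly
   redundant: the identifiable quantities are κ/A and B. The calibration
   exposes all three for interface completeness, but only the ratio and
   the rate are meaningful.

3. **Perfusion/partition-limited washout.** Without a barrier, drug leaves
   the depot at G_perf = Q·R_bp/K_p with tissue blood flow
   Q = perfusion · (V_depot/100 g) · 60 (unit tissue density; default
   perfusion 9.6 mL/min/100 g, the geometric center of the published
   4.8–19.2 exploration range). The ICL acts in series:
   G_tot = (1/G_perf + 1/G_ICL)⁻¹. Egress flux is
   G_tot · (A_d/V_depot − backterm); the backterm is K_p-scaled plasma
   concentration for a same-species depot (IM solution of the parent) and
   zero for a prodrug depot, because the prodrug is cleaved to the parent
   instantly and completely on reaching the circulation, making the depot
   one-way. The effective depot fluid volume is the injection volume over
   the muscle extracellular volume fraction (0.118).

4. **Linear three-compartment systemic disposition** of the parent with
   hepatic clearance CL_H (all /kg parameters scaled by a configurable body
   weight, default 70 kg — the subject weight is not reported with the
   disposition parameters). Absorbed prodrug mass is converted by the
   molecular-weight ratio MW_parent/MW_prodrug.

The state vector is [m_1..m_B, A_depot, A_central, A_periph2, A_periph3,
A_out, A_cleared]; the last two accumulate egress (depot species) and
hepatic elimination (parent), so mass balance is checked pointwise against
explicit state, not reconstructed. Integration uses LSODA with rtol 1e-8 /
atol 1e-12 mg and output every hour; exhausted bins are handled by clamping
rates at zero mass (the (m/m0)^{1/3} radius vanishes smoothly), not by
events. IV infusions restart the solver at the infusion-end discontinuity
and match the matrix-exponential solution of the linear system to ~1e-6.

Depot-site solubility is evaluated at the site pH (default 7.4) from the
reference measurement via the monoprotic-base relation
S(pH) = S_int(1 + 10^{pKa−pH}), capped at S_int × solubility-factor. Both
reference compounds are single-pKa bases; multiprotic chemistry is out of
scope. Where no aqueous diffusivity is supplied, D_aq = 9.9e-5·MW^{−0.453}
cm²/s.

## Calibration and validation workflow

The layer kinetics cannot be measured directly; they are estimated from
clinical PK. `fit_icl` minimizes weighted squared relative errors of
(Cmax, AUC0-t, Tmax) — weights 1/1/0.5, Tmax down-weighted for its coarse
observability — or weighted squared log-residuals of a concentration
profile, over a subset of {A, B, t_lag, κ, h}. Positive parameters are
optimized in log10 space. Optimization is deterministic: a fixed grid of 3
points per free parameter, centered a decade up and down from the scenario's
baseline values (grids spanning the full bound box waste starts in
degenerate corners — no barrier or total block — where the objective is
flat), is screened by objective value and the best three starts are polished
with bounded trust-region least squares (finite-difference step 1e-4, well
above the ODE solver noise floor). Default bounds follow the published
exploration ranges for A (2.09e-8–0.29 cm/h), B (0.003–0.07 1/h) and lag
(0–1500 h); κ gets a broad bracket (1e-4–1e4).

The reference workflow calibrates (A, B, κ) to the observed 400 mg-eq
metrics and predicts the 150 and 300 mg-eq doses with the same kinetics,
changing only dose-specific geometry (injection volume → depot volume,
dose → surface area). A prediction passes when |FE − 1| ≤ 0.25 with
FE = simulated/observed, applied symmetrically (FE 0.75 and 1.25 are both
boundary passes). AUC0-t is computed by linear trapezoid on the dense grid
up to the simulation horizon (2136 h for suspensions; the clinical sampling
windows behind the observed AUC0-t values are not published, so the horizon
stands in for t_last). With the packaged scenarios this yields fold errors
0.83–1.08 (max |FE−1| ≈ 17%).

## Synthetic observed data

Clinical mean profiles are not published point-by-point, so the calibration
test-bed generates its own: a scenario is simulated, sampled on a
clinical-style grid, and multiplied by independent log-normal noise
e^{N(−σ²/2, σ²)} with σ² = ln(1 + cv²) — mean exactly one, coefficient of
variation cv, seeded and reproducible. The default recovery study uses a
rich single-dose LAI design (6, 12, 24 h; daily through week 1; then
weekly/biweekly to 1680 h) at cv = 0.10; over 20 replicates the median
absolute error of the recovered A and B (κ held at truth, since only κ/A is
identifiable) is ~7% and ~10%. Sparse biweekly-only sampling roughly
doubles these errors. What the generator does *not* emulate: between-subject
variability (profiles are noisy means, not populations), assay quantitation
limits, dropout, or model misspecification — parameter-recovery results
therefore bound estimator noise, not real-data bias.

## Numerical and design choices

- **Driving-force species.** Dissolution is driven against the unbound
  depot concentration. The alternative — saturation of the depot fluid by
  *total* dissolved drug — caps release at G_perf·S ≈ 2.6e-3 mg/h for the
  reference suspension, ~150× too slow for the observed months-long but
  complete absorption, and is rejected. A consequence worth knowing: with a
  sink depot, egress flux is linear in the dissolved pool, so very small
  particles (fast dissolution) raise exposure even while the barrier is in
  place; a depot that saturated would instead be particle-size-blind during
  the barrier window. The reference implementation this model is benchmarked
  against shows the latter behaviour; this one shows the former. The
  post-barrier direction (smaller particles → higher exposure) agrees.
- **Full-horizon Cmax under barrier sweeps.** A thicker barrier (larger A)
  lowers exposure while it stands but stores the dose for a later, *higher*
  peak; "larger A → lower exposure" statements therefore refer to the
  pre-decay window (first ~300 h), and sweep tables report both windows.
- **Bins.** 20 bins by default; metric changes going 20 → 40 are below 1%
  for the reference scenarios. Property tests run 6–8 bins with loosened
  tolerances (rtol 1e-6–1e-7) where sub-percent accuracy is not needed.
- **Degenerate inputs.** σ = 0 or a single bin collapses the distribution
  to its mean; zero ICL magnitude, κ = 0 and `enabled=false` all reduce
  exactly to the barrier-free model (or a fully blocked depot for κ = 0
  with A > 0); exhausted bins and negative-mass excursions are clamped.
- **Tie-breaks.** Tmax is the *first* grid time attaining the maximum.
- **IV infusion duration** for the 2 mg reference study is not reported;
  the fixture uses 0.5 h (AUC is duration-invariant by the clearance
  identity).
- **Observed-metric fixtures** ship as a package CSV with per-value source
  descriptions, so validation tables are regenerable and auditable.

## Known limitations

- Single dose only; no repeat dosing, population variability, or oral/
  first-pass routes.
- The ICL conductance law (κ, series resistance, unbound-only permeation)
  is an assumption set; only κ/A and B are identifiable from PK data.
- No injection-site precipitation, macrophage uptake, or lymphatic routing;
  depot geometry is a single sphere.
- Published simulated reference values from the closed-source benchmark are
  reproducible only in magnitude and direction, not bit-exactly; its no-ICL
  peak concentration is ~1.9× this model's under the default solubility
  settings (see the driving-force note above).
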