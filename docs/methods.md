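# Methods

`vinesim` simulates one grapevine growing season from veraison (onset of
ripening) to harvest at an hourly time step, for a canopy of isolated
single-shoot plants, and layers on top of the simulator the statistical
machinery a field calibration/validation study needs: staged random-walk
Metropolis calibration, RMSE/RRMSE evaluation with an accuracy rubric, and
advanced-veraison virtual experiments. This note documents the model, its
assumptions, the numerical choices, and what the synthetic data do and do
not represent.

## Model structure

The plant is a steady-state hydraulic network solved hourly, coupled to a
carbon balance and a biophysical mean-berry model. Within an hour the
chain is:

1. **Soil water status.** Measured predawn leaf water potential is the
   proxy for soil water potential; values between sampling dates are
   linearly interpolated to the hour. There is no rainfall/soil water
   bookkeeping: the dry-down is imposed, exactly as the simulator consumes
   it in the field setting it reproduces.
2. **Soil-to-root resistance.** Rsp = RSC / k(Ψ_soil), where k is the
   four-parameter van Genuchten–Mualem conductivity evaluated at suction
   h = |Ψ_soil| and RSC (root specific conductance) absorbs the root
   geometry terms of the underlying Gardner formulation. Defaults for
   (ks, α_v, n, p) are labeled representative of a fine-textured vineyard
   soil, not measurements.
3. **Canopy light.** Beer–Lambert attenuation over the cumulative leaf
   area index above each leaf (extinction coefficient 0.7 by default)
   replaces a 3-D ray tracer; this is the package's principal structural
   simplification. Geometry constants (15 cm shoot spacing, 135° azimuth
   step) are carried as configuration metadata only.
4. **Leaf gas exchange.** FvCB biochemistry (Rubisco- and RuBP-limited,
   Arrhenius-scaled, TPU limitation omitted), Vcmax25 linear in leaf
   nitrogen with zero intercept, Tardieu–Davies stomatal conductance
   combining a collar-ABA chemical signal with a leaf-water-potential
   hydraulic signal, and a leaf energy balance with two-sided sensible
   exchange and a linearized longwave conductance. With ABA and Ψ_leaf
   prescribed, gs is explicit, T_leaf is a 1-D root (Newton with a
   bisection fallback, residual < 1e-8 W m⁻²), and Ci is the positive
   root of a quadratic per FvCB branch — so the single-leaf state is a
   direct cascade, not an iteration.
5. **Hydraulic network.** Ψ_xylem = Ψ_soil − E_total·(Rsp + r_ax). Each
   leaf's water potential balances vulnerable-blade supply,
   area·k_leaf,max·f(Ψ_leaf)·(Ψ_xylem − Ψ_leaf) with a logistic
   vulnerability curve (midpoint Ψ50, field default −1.80 MPa), against
   the transpiration demand of its gas-exchange state. The balance can
   have multiple roots under stress; the solver always takes the
   shallowest (hydraulically stable) crossing, scanning downward from
   Ψ_xylem — this selection is canonical and keeps the hour-to-hour map
   single-valued. The outer fixed point on Ψ_xylem is damped (factor 0.5,
   tolerance 1e-5 MPa, ≤200 sweeps); on convergence Ψ_xylem is assigned
   exactly from the flux sum, so Kirchhoff closure holds to rounding.
   There is no plant capacitance and no nocturnal stomatal control beyond
   the residual conductance. Two further numerical safeguards: per-leaf
   flux updates are relaxed (factor 0.6) and the outer damping halves
   after every 50 stalled sweeps — both suppress small limit cycles near
   leaf branch boundaries without moving the fixed point (grid-search
   oracles in the tests confirm the solution). When demand exceeds the
   maximal vulnerable supply at every potential (transiently, under severe
   stress), the leaf is pinned at the least-deficit potential with its
   flux capped at the supply there, which is continuous across the
   root-existence boundary.
6. **Carbon balance.** Hourly supply integrates per-leaf net assimilation;
   maintenance respiration is Q10-scaled per organ class (the berry class
   is zero here because berry respiration is charged inside the berry
   module). The phloem sucrose concentration closes loading = unloading
   across sinks (berries, fine-root turnover, reserve deposition, with
   reserve mobilization buffering shortfalls). Because the spec'd berry
   water-flux convention makes the advective berry term non-monotone at
   high concentration, the solver brackets the *first* sign change
   scanning up from c = 0 (64-step coarse scan, then bisection to a
   residual below 1e-9·max(supply, 1 g C/h)), which keeps c continuous in
   time and monotone in supply. Maintenance shortfall beyond the reserve
   flags carbon starvation; surplus beyond all sinks at the concentration
   cap deposits to the reserve and flags overflow.
7. **Berry.** Mean berry × berries per shoot. Water: phloem influx through
   a conductance Lp(FM) declining sigmoidally with fresh mass between
   Lp,max and Lp,min (inflection FM*, slope k_Lp), a xylem path, and skin
   transpiration at air temperature. Sugar: Michaelis–Menten active import
   (Vmax,berry, Km,berry) plus the sugar advected by a positive phloem
   influx; maintenance respiration and a first-order conversion of sugar
   to structural dry mass (with growth respiration) drain the pool.
   Growth is turgor-gated (Lockhart): net influx balances
   V·φ·max(0, P − Y). With these flux laws the quasi-steady turgor balance
   is piecewise linear in P, so the hourly turgor is solved in closed form
   (the prescribed bisection would converge to the same root; a grid-scan
   oracle in the tests confirms agreement to <2e-4 MPa). Explicit Euler at
   1 h with 4× sub-stepping when any pool would change by more than 5%.

The hydraulic pass does not depend on the carbon or berry state, so a
season is computed as one hydraulic sweep plus a carbon/berry replay; the
berry calibration stages re-run only the replay.

## Parameters

Fourteen quantities are treated as calibrated: five soil–root (ks, α_v, n,
p, RSC), three gas-exchange (leaf N content, the Vcmax–N slope, Ψ50), six
berry (Vmax,berry, Km,berry, Lp,max, Lp,min, FM*, k_Lp). Everything else is
a documented fixed default in the configuration (≈100 constants: FvCB
kinetics, TD coefficients, hydraulic constants, organ biomasses,
respiration coefficients, densities). Defaults were chosen once so that a
default-parameter season lands in the empirically realistic post-veraison
ranges for a rainfed Bordeaux-style vineyard — midday Ψ_xylem between
about −0.4 and −1.6 MPa across wet to dry soils, berry fresh weight near
1.0–1.4 g and sugar concentration near 200–250 g/L at harvest — as a
realism anchor, not as a fitted result. Units: potentials MPa, plant water
flux mg s⁻¹, carbon g C h⁻¹, berry masses g, phloem concentration
mol m⁻³, PAR conversion 2.1 µmol J⁻¹, GDD base 10 °C (viticulture
convention; the source formulation leaves it unstated).

Notable default choices, with reasons:

- `sigma_p = 0.15` (phloem reflection coefficient): the flux convention
  used here subtracts σ_p(π_phloem − π_berry) from the phloem driving
  gradient, so a large σ_p makes berry water exchange whipsaw with the
  diurnal phloem-concentration cycle; a leaky membrane is also consistent
  with the substantial advective sugar import of the ripening berry.
- `phi_ext = 0.01 MPa⁻¹ h⁻¹`, `y_thresh = 0.3 MPa`: growth is
  supply-limited rather than extensibility-limited, so the declining
  Lp(FM) actually throttles late-season growth.
- Berry conductances (~1e-4 g cm⁻² MPa⁻¹ h⁻¹ scale) are set to give
  realistic net water accumulation (~0.3 mg h⁻¹) against ~1 MPa potential
  differences and a skin transpiration of a few mg per berry-hour.
- ABA signal is produced at the collar (a·max(0, −Ψ_xylem)/(E + b)) and
  the hydraulic signal in the TD exponential uses Ψ_leaf: the chemical
  and hydraulic channels are deliberately separated.
- Ci may exceed ambient CO2 under net respiration (dark hours): the
  diffusion constraint then has CO2 leaving the leaf. (A hard Ci ≤ Ca
  clamp would contradict An(PPFD=0) = −Rd together with the diffusion
  residual contract.)

## Calibration

Random-walk Metropolis with Gaussian priors, hard bounds (out-of-bounds
proposals rejected), joint per-parameter Gaussian proposals (default scale
5% of the prior SD), and Gaussian observation likelihoods (default σ:
0.08 MPa for midday Ψ_xylem, 0.05 g FW, 0.01 g DW, 8 g/L [Sugar]; the
source study does not state likelihood widths). Stages: A (RSC, Ψ50) on
biweekly midday Ψ_xylem; B (leaf N, Vcmax slope, Ψ50) on a gas-exchange
response dataset; C (Vmax,berry, Km,berry) on berry DW; D (the four Lp
coefficients) on berry FW and [Sugar]. Ψ50 is sampled in both A and B and
keeps the stage-B value, matching its final discussion under gas exchange.
Stage likelihoods simulate only what they need: stage A solves the
observation hours alone (the steady-state network has no memory), stages
C–D replay the carbon/berry chain over a cached hydraulic pass. Simulation
failures inside a likelihood score the proposal at −inf and are logged.

The sampler offers burn-in-only adaptive proposals (the empirical chain
covariance with the standard 2.38²/d scaling, frozen after burn-in so the
post-burn-in kernel is Markovian); adaptation is off by default for strict
interpretability of the proposal scales.

In twin (known-truth) experiments, noise-free berry observations make the
posterior a narrow ridge whose mode sits at the truth while the prior
drags the posterior mean along the ridge; the recovery tests therefore
read the MAP for noise-free data and the posterior mean for noisy data.
One genuine identifiability limit deserves emphasis: the phloem
conductance floor Lp,min cannot be constrained by seasonal FW/[Sugar]
trajectories. Holding it 25% off its true value and re-optimizing the
other three conductance coefficients changes even a noise-free
log-likelihood by less than 0.3 — the four-parameter sigmoid is
over-flexible on the fresh-mass range a berry actually traverses. The
recovery test suite states this check and fails it deliberately rather
than hiding the limit.

## Synthetic data

The generator emulates a 13-vintage Bordeaux-like campaign: diurnal
temperature (minimum 05:00, maximum 15:00) around daily means that follow
a hotter-earlier seasonal template (−0.07 °C/day, clear-sky radiation
−2.2 W m⁻²/day) with an AR(1) anomaly; half-sine radiation 06:00–20:00
scaled by daily cloudiness; RH anti-correlated with temperature, clipped
to [20, 100]%; log-normal wind. Predawn dry-downs are sampled biweekly
from 30 days before veraison past harvest, with 0.02 MPa measurement
noise, clipped to the field-observed envelope (−0.01 to −1.03 MPa); the
default exponential shape completes most of the decline around veraison,
as in rainfed late-season conditions. Berry observations are weekly
(8–10 dates per season). A gas-exchange response dataset (whole-plant
midday solutions over the predawn envelope with jittered weather and 8%
multiplicative observation noise) stands in for a literature
meta-analysis.

What passing tests on these data do **not** show: the generator has no
rainfall events, no heat waves or weather fronts beyond AR(1) anomalies,
no canopy growth or senescence, no berry-to-berry variability, and its
gas-exchange "observations" are produced by the same model family being
calibrated. Parameter-recovery results therefore demonstrate correctness
of the estimation machinery, not transferability to field data.

## Evaluation

RMSE and relative RMSE (RMSE over the magnitude of the observed mean,
×100 — the magnitude keeps the index positive for negative-scale
variables such as water potentials) with the four-class rubric: <10%
excellent, [10,20)% good, [20,30)% fair, ≥30% poor. The 1:1-line check is
an OLS of observed on simulated with separate t-tests of slope = 1 and
intercept = 0. Driver importance uses the LMG decomposition (sequential
R² gains averaged over all predictor orderings, exhaustively enumerated,
at most 5 predictors).

## Scenarios

Advanced-veraison experiments shift the simulation window earlier by 14 or
28 days with unchanged duration and initial state, over the same forcing
series. Reported per vintage: the GDD difference over the window, relative
changes of final FW/DW/[Sugar] at the (shifted) end of simulation, and the
maturity day — the first day the scenario reaches the default run's
maximum [Sugar]; never reaching it is reported as such. The ripening
duration classifies as shortened/lengthened/unchanged by comparing the
maturity advancement with the imposed shift. Across-vintage significance
uses a one-way F-test of scenario versus default final values.

## Problem sizes

Default test and analysis sizes were chosen to keep a desk-scale run
responsive: 30–60 day seasons at 1 h (≈1–2 s each), 13-vintage cohorts,
Metropolis chains of 1–3 thousand iterations per stage with a few hundred
burn-in, 2e3–2e4 iterations for the sampler-correctness checks, and
hierarchical exhaustive grids for the oracle comparisons. All are
configurable upward.

## Known limitations

- Steady-state hydraulics (no capacitance) makes predawn plant potential
  equal soil potential by construction.
- The multi-root structure of the leaf balance under severe stress is
  resolved by a canonical shallow-root rule; true hysteresis (a leaf
  staying cavitated) is not represented.
- The 3 p.m. extraction is the default plant-water-status observable; a
  2–4 p.m. window mean is available but not default.
- The berry model's unit choices are self-consistent but not guaranteed to
  match any particular published parameter table numerically.
- Under permanently favorable constant forcing the berry keeps growing
  slowly (no senescence), so [Sugar] approaches its balance point
  asymptotically rather than reaching an exact plateau.
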