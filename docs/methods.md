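# Methods

`lianacomp` asks a mechanistic question: when lianas (woody vines) compete
with tropical trees, how much of the interaction runs through **water**
(below ground) versus **light** (above ground)?  It answers it the way a
model-analysis study would: simulate a liana-infested forest with a
process model, propagate parameter uncertainty through it, and attribute
the output variance to water-related versus light-related liana
parameters.  This note records the models, the choices behind them, and
what the synthetic experiments do and do not demonstrate.

## 1. Trait priors and the Bayesian meta-analysis

Each of the 32 liana parameters carries a prior: a named distribution
family with constants (a, b), parameterized as uniform(min, max),
normal(mean, sd), lognormal(meanlog, sdlog), gamma(shape, rate),
beta(a, b) or weibull(shape, scale).  Physically negative parameters
(P50, the stomatal-closure potential, the turgor loss point, the
rooting-depth intercept) are stored on the positive scale and multiplied
by −1 at use time; the order-reversing identity Q₋ₓ(p) = −Qₓ(1−p) is
available through `signed=True` quantiles.

Observed trait means are combined with the prior through a two-level
random-effects model:

    y_i | θ_j(i)  ~ Normal(θ_j(i), s_i²)        (observation within study j)
    θ_j | β₀, τ²  ~ Normal(β₀, τ²)              (study-level random effect)
    β₀            ~ prior (its stated family)
    τ²            ~ scaled-inv-χ²(ν₀ = 1, s₀²)

The posterior of the across-study mean β₀ is what the rest of the
pipeline consumes.  Missing standard errors are imputed as the prior sd
(divided by √n when the sample size is known) and flagged in provenance.

**Sampler.**  The posterior is low-dimensional with conjugate structure,
so sampling is Metropolis-within-Gibbs written directly in numpy: θ and
τ² are exact conjugate draws; β₀ is updated by (i) an independence
proposal from its Gaussian conditional N(θ̄, τ²/J), whose acceptance
ratio reduces to the prior density ratio, and (ii) a translation move
shifting β₀ and every θ_j together, half the time proposing β₀ fresh
from the prior.  Move (ii) makes the weak-data limit reduce *exactly* to
prior sampling (verified by a Kolmogorov–Smirnov test against prior
draws), and move (i) gives near-iid mixing when data dominate (split-R̂
≈ 1.000 in the test suite).  Defaults: 4 chains × 5,000 draws, 1,000
burn-in, fixed seed; chains with split-R̂ > 1.1 raise a warning recorded
in the posterior's provenance.

**τ² scale choice.**  The 1-df scaled-inverse-χ² prior on τ² is anchored
at the empirical spread of the study means (floored at 5% of the prior
sd) rather than at the prior sd itself: trait priors are deliberately
wide, and anchoring τ at the prior scale would inflate the between-study
variance and hence the posterior CV of β₀ for every well-observed trait.

**Allometric pairs.**  For the leaf/stem/rooting-depth allometries there
are too few studies for the hierarchical model, so data-informed priors
come from OLS on log y = log b1 + b2 log x with posterior draws from the
bivariate-normal coefficient sampling distribution (intercept
exponentiated).  Zero residual variance degenerates to a point mass.

**Parameter uncertainty** is summarized as CV = sd/|median| of the
posterior draws; an error is raised (naming the trait) when the median
is zero.

Five rows of the shipped prior table print medians that are inconsistent
with their stated family constants (b1Bl, V_m0, SLA and both
capacitances, the latter two apparently a unit-conversion issue); the
printed medians are stored alongside the analytic ones and used for the
parameter-set fixtures, but the sampling distributions keep the stated
constants and no agreement is forced.

## 2. Physiology of the liana PFT

All pure functions; water potentials in m H₂O (≤ 0), gravitational head
equal to height in m.

- **Allometry.**  Bl = b1Bl·DBH^b2Bl, Bs = b1Bs·DBH^b2Bs, Br = q·Bl
  (kg C per plant); leaf area = SLA·Bl.  Height follows a saturating
  form h = h_max·(1 − exp(−b1Ht·(DBH + ΔDBH)^b2Ht)) with h_max = 35 m
  by default — the exact height form used upstream is not published, and
  this shape is monotone, bounded and analytically invertible (the
  inverse is needed to update ΔDBH when the climbing cap binds).
  Rooting depth is −b1Rd·h^b2Rd.
- **Xylem vulnerability.**  K(ψ) = K_max·exp(−ln 2·(ψ/P50)^K_exp), a
  Weibull-type curve anchored so K(0) = K_max and K(P50) = K_max/2
  exactly.
- **Stomatal drought response.**  f = 1/(1 + (ψ_leaf/ψ_b)^c), halving at
  ψ_b, with a hard cutoff f = 0 below the leaf turgor loss point.  The
  TLP cutoff also bounds transpiration in the water-transport solver.
- **Carbon uptake.**  A co-limited hyperbola
  A_g = f_sw·αQVm/(αQ + Vm) (α = quantum efficiency, Q = PAR,
  Vm = V_m0); no temperature kinetics (V_m0 used as-is) and CO₂ fixed at
  370 ppm.  Leaf respiration dark_respiration·Vm is paid day and night.
  Ball–Berry stomatal conductance g_s = m·A·rh/ca + g_min, floored at
  g_min = 0.01 mol m⁻² s⁻¹; transpiration demand 1.6·g_s·D.
- **Water transport.**  Two storage compartments (stem, leaf) with
  capacitances C_wood·Bs and C_leaf·Bl.  Flows: soil→stem
  q₁ = G_sr·(ψ_soil − ψ_stem) and stem→leaf
  q₂ = G_sl·(ψ_stem − ψ_leaf − h).  Both conductances scale with K(ψ_stem)
  and a sapwood-area proxy (stem volume over height); G_sr additionally
  scales with fine-root area SRA·Br and with rooted-zone wetness to the
  power `soilk_exp` (default 6), standing in for the collapse of soil
  hydraulic conductivity as the rhizosphere dries.  The two calibration
  constants (`c_xylem` = 5, `c_soilroot` = 0.01) were set once so an
  unstressed canopy tree transpires O(10⁻⁴) kg s⁻¹ per m² leaf.
  The update is backward Euler (unconditionally stable) with K frozen at
  the current stem potential; transpiration is capped so ψ_leaf does not
  cross the TLP within a step, extraction is capped at the available
  soil water, and when wet soil would push a potential positive the
  *inflow* is limited instead of clipping the state — every branch of
  the solver closes the water balance exactly (≤ 10⁻⁹ relative, tested).

## 3. The demographic simulator

Cohorts (PFT, density, DBH, pools, hydraulic state) live in patches;
each patch carries a 9-layer soil column with interfaces at
0.05/0.15/0.3/0.5/0.75/1/2/4/8 m and Clapp–Hornberger retention
ψ = ψ_sat·(θ/θ_sat)^(−b) (clay-loam defaults: θ_sat 0.48, ψ_sat −0.5 m,
b = 8).  Patches are spatially implicit and carry area weights summing
to 1.

**Daily step.**  (1) Beer–Lambert light: cohorts sorted by height, PAR
at cohort i is PAR_top·exp(−k·ΣLAI above), k = 0.5.  Liana leaf area
sits at the cohort's (capped) height — the climbing mechanism's light
advantage.  (2) Gas exchange and transpiration demand per cohort from
the current ψ_leaf.  (3) Sub-daily (24 steps) implicit water transport;
each cohort draws soil water from layers in proportion to root fraction
× layer wetness, capped by a per-day claim system that never overdraws
a layer.  (4) Soil bucket: 10% canopy interception, tipping-bucket
infiltration, gravity percolation of water above field capacity
(θ_fc = 0.38, 30%/day) cascading to bottom drainage, and soil
evaporation from the top layer scaled by ground-reaching light.
(5) Per-PFT flux accumulation.

**Root profiles.**  (1 − root_beta) of the roots follow a
surface-concentrated exponential (e-folding depth = rooting depth / 3,
truncated at the rooting depth); root_beta sits uniformly below.  A
uniform-over-depth profile was tried first and rejected: with it almost
no stand uptake comes from the topsoil, shallow layers never dry, and
the dry season never differentiates shallow-rooted lianas from
deep-rooted trees.  The exponential shape mirrors observed fine-root
profiles and, together with field-capacity percolation and the
wetness-limited root pathway, produces the expected seasonal behaviour:
in the BCI-like run liana GPP falls to ≈ 30–40% of its annual mean in
March (late dry season) while deep-rooted trees are buffered.

**Monthly demography.**  Per cohort: carbon balance
CB = GPP − R_leaf − R_root − turnover, growth respiration
growth_respiration·max(CB, 0); a reproduction fraction of the positive
balance feeds a patch recruit pool (new cohorts spawn at 1 cm DBH once
the pool affords a minimum density); the remainder increments DBH via
the derivative of total structural biomass, split across pools in
proportion to their allometric derivatives so the cohort carbon budget
closes exactly.  Negative balances are paid from storage, then by
burning tissue (proportional shedding); a cohort starved beyond its own
biomass dies.  Mortality: rate = mort3 + mort1/(1 + exp(mort2·c̄b)) per
year, where c̄b is the trailing 12-month mean of realized/potential GPP
clipped to [0, 1] (potential = same leaves under full light, no water
stress); mort1 = 1 yr⁻¹ is a fixed amplitude.  Trees take height from
allometry; lianas compute a potential height from their ΔDBH-shifted
allometry and are then capped at the patch's tallest tree + h_offset
(0.5 m), ΔDBH being updated to record the deviation — this is the
climbing algorithm, applied at initialization and after every monthly
growth step (DBH threshold 3 cm).  Same-PFT cohorts within 8% DBH merge
monthly; cohorts below 10⁻⁸ m⁻² are dropped.

**Initialization.**  Trees are classified early/mid/late successional by
wood density (cuts at 0.53 and 0.71 g cm⁻³), stems merged into DBH-bin
cohorts.  Canopy lianas (DBH ≥ 3 cm) start at tallest tree + h_offset
with the corresponding ΔDBH; lianas in tree-less patches fall back to
their own allometry with a logged warning.  Tree PFT parameter sets are
package defaults chosen once to give a plausible closed-canopy tropical
forest (LAI ≈ 6, AGB ≈ 25–30 kg C m⁻², GPP ≈ 5 kg C m⁻² yr⁻¹ in the
BCI-like configuration); they are shipped as editable CSVs and held
fixed in all analyses — only liana parameters vary.

**Bookkeeping.**  Every run records a water ledger (per patch-day:
precipitation = interception + drainage + soil evaporation + root
extraction + Δsoil storage, with plant storage tracked separately) and a
carbon ledger (per cohort-month: GPP = respiration terms + turnover +
reproduction + pool changes).  Both close to ≤ 10⁻⁶ relative error over
full 5-year runs (observed ~10⁻¹²); the liana height-cap invariant is
asserted after every month.

## 4. Sensitivity, variance decomposition, ensembles

One-at-a-time design: each parameter is evaluated at the ±1, 2, 3 SD
normal-CDF probability levels {0.00135, 0.02275, 0.15866, 0.5, 0.84134,
0.97725, 0.99865} pushed through its *own* quantile function (analytic
for priors, empirical for posterior draws) — probability levels rather
than additive SD shifts, so the design respects bounded and skewed
families.  All other parameters stay at their medians.  Responses are
interpolated with a monotone-slope-limited cubic Hermite spline (scipy
PCHIP) continued linearly beyond the outer nodes; failed runs become
missing points (≥ 4 required).  Elasticity is g′(β̄)·β̄/g(β̄).

The contribution of parameter p to predictive uncertainty is
Var[g_p(β₀ₚ)] over the posterior draws; the total is the sum over
parameters and relative (partial) variances are the fractions, which sum
to 1 by construction.  Aggregating relative variances over the shipped
classification table (competition: water/light/unclassified; organ;
process) yields the water-vs-light competition shares, computed for any
scenario (full year vs dry-season months, all patches vs young patches).
Dry months are those below 100 mm (strong: below 60 mm).  Young patches
are selected by jointly relaxing three thresholds from their extremes —
highest liana density, lowest late-successional share, lowest canopy
height — until a minimum patch count qualifies.

Monte-Carlo ensembles draw parameters independently across traits
(n = 250 by default), run the model per draw, and report medians and
95% envelopes; the posterior/prior CI-spread ratio measures what the
meta-analysis bought.

## 5. Synthetic study conditions

Two site templates reproduce the aggregate census and climate contrasts
the analysis exploits:

| feature | BCI-like | Paracou-like |
|---|---|---|
| annual precipitation (mm, ±1 SD) | 2,640 ± 94 | 3,088 ± 117 |
| strong-dry months (< 60 mm) | Jan–Mar | Sep–Oct |
| dry months (< 100 mm) | Apr | Aug, Nov |
| liana density (ha⁻¹) | 1,428.9 | 126.3 |
| tree density, DBH ≥ 10 cm (ha⁻¹) | 416.0 | 319.4 |
| tree basal area (m² ha⁻¹) | 26.7 | 19.2 |
| liana basal area (m² ha⁻¹) | 1.01 | 0.34 |

Monthly precipitation targets place strong-dry months at 35–55 mm, dry
months at 65–95 mm and scale wet months (floored at 110 mm) so the
sampled annual total matches the template; daily rain follows a
first-order wet/dry chain whose amounts are renormalized to preserve
monthly totals exactly.  PAR, temperature and humidity carry mild
seasonality (drier months sunnier and less humid).  Tree DBHs follow a
truncated power law whose exponent is solved by two-moment matching so
stem density and basal area are met jointly (a mild rescale pins the
realized basal area); small trees (1–10 cm) continue the fitted power
law as density-multiplied representative stems, and a log–log OLS
extrapolation utility fills missing small-DBH classes.  Patch-level
liana loading is a lognormal multiplier (σ = 1) normalized to preserve
the site mean, spanning near-liana-free to several-fold-infested
patches.  Trait datasets are two-level normal draws with known truth,
between-study and within-study components.

Default scale: 10 patches per site and a 5-year horizon.  The original
analysis initialized 1,250 patches from a 50-ha census; 10 patches keep
every mechanism (patch heterogeneity, young-patch selection, patch-level
climbing caps) while making the full chain run in about a minute.

**What the synthetic experiments show — and don't.**  Passing tests
demonstrate internal correctness (conservation, invariants, calibration
against known truth) and the *directional* mechanisms: tree growth is
strictly higher without lianas, liana GPP bottoms out inside the dry
season, the dry season raises the water-related share of output
variance, and the meta-analysis contracts parameter uncertainty.  They
do not reproduce site-level magnitudes (observed flux-tower GPP, the
28%/15% liana GPP shares, or the published partial-variance rankings),
which came from a full land-surface model driven by real censuses and
tower meteorology; no quantitative claim of that kind is made here.

## 6. Numerical choices and degenerate inputs

- Hydraulic substep: backward Euler, 24 steps/day; linear solves in
  closed form; every cap (TLP, soil availability, non-positive
  potentials) re-solves the budget so conservation is exact.
- Quantile design collapses (a point-mass posterior yields < 7 distinct
  values) produce a warning; splines require ≥ 4 valid points and refuse
  duplicated abscissae.
- Elasticity at g(β̄) = 0 is reported as NaN (undefined), not an error.
- Ensemble runs that raise are logged, excluded, and the effective n is
  reported; an all-failed ensemble raises.
- The meta-analysis floors τ² at 10⁻¹² of its prior scale to keep the
  conjugate draws finite with a single study.
- Seeds: every stochastic entry point takes one; chains derive child
  seeds from a root `numpy` SeedSequence, and identical seeds reproduce
  results bit-for-bit (tested).

## 7. Known limitations

Radiative transfer is single-band Beer–Lambert; there is no energy
balance, no temperature response of photosynthesis, no deciduous
phenology, no treefall disturbance, no nutrient cycling and no
mechanical damage by lianas on their hosts.  Xylem refilling is
implicit (conductivity follows the current potential with no hysteresis).
The one-at-a-time design measures local sensitivity around the medians
and, by construction, cannot capture parameter interactions; partial
variances therefore depend on the reference parameter set, which is why
both prior-median and posterior-median configurations ship as fixtures.
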