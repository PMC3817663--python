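# Methods

`sourcesink` simulates daily carbon source–sink regulation of plant growth
under drought for two contrasted monocots — a rice seedling (annual, small
fast-turnover reserves) and an adult oil palm (perennial, large trunk
reserves) — and runs factorial sensitivity experiments on the two
drought-sensitivity thresholds that control, respectively, the carbon
source (transpiration and hence assimilation) and a carbon sink (leaf
expansion for rice, leaf appearance for palm).

## Shared core

**Water.** A single-layer bucket holds the total transpirable soil water
(TTSW, mm over the relevant footprint). Its state is summarised by the
fraction of transpirable soil water, FTSW = (SWC − SWC_min)/(SWC_fc −
SWC_min), clamped to [0, 1]. Each day: optional morning irrigation (refill
policies for greenhouse treatments), then all process rates are evaluated
at the morning FTSW, then transpiration is withdrawn (clamped at the
residual store) and water input added, with drainage above field capacity.
Order per day: FTSW → stress factors → development → demand → supply →
carbon budget → soil step. Water closes to 1e-9 relative every run.

**Drought response.** Every drought-sensitive rate V is scaled by a
broken-stick function of FTSW with a genotypic threshold:
V/V_max = 1 if FTSW > threshold, else FTSW/threshold. A threshold of 0
means insensitivity (factor ≡ 1); a threshold of 1 means the rate declines
as soon as the soil departs from field capacity (isohydric extreme for
transpiration). One threshold (`transpiration_th`) governs transpiration
and assimilation jointly — stomatal closure cuts both proportionally.

**Carbon.** Supply per plant is PAR × Beer–Lambert interception
(1 − exp(−k·LAI)) × radiation use efficiency × transpiration stress factor
/ density, in g CH₂O. Demand is growth (potential organ expansion priced
through structural cost) plus maintenance (m_coef × living structural
mass), with maintenance served first. The index of competition
Ic = supply/demand routes the day: Ic ≥ 1 stores a fraction of the excess
in reserve pools up to capacity (the unstorable remainder *overflows* and
is discarded — assimilate that can be neither used nor stored is lost);
Ic < 1 mobilizes a fraction of reserves, and any remaining deficit delays
growth and (for rice) accelerates senescence. The daily identity
supply + mobilized = growth_realized + stored + overflow is asserted at
1e-9 relative on every simulated day.

## Rice seedling (vegetative phase only)

Phytomers initiate on each axis every `plasto` = 50 °Cd (plastochron =
phyllochron; thermal time above t_base = 12 °C, so one leaf per ~3.7 days
at 25.4 °C and leaf 6 around day 22 — the stage at which the dry-downs
start). Each new leaf is pre-dimensioned to its predecessor's potential
length + MGC (10 cm), the increment scaled by yesterday's Ic when Ic < 1.
Leaves extend at potential length / plasto per °Cd, scaled by the
broken-stick factor at `ler_th`; blade area follows the lanceolate
allometry area = 0.725 × length × (0.05 × length). Areal growth is priced
through a rank-dependent structural SLA, SLA(rank) = sla_ref ×
(1 + sla_p·ln rank) with sla_ref = 450 cm² g⁻¹ and sla_p = 0.3 (later
leaves cheaper per cm²), times a chemical cost of 1.4 g CH₂O per g DM
(growth respiration). Roots are a bulk sink demanding 0.55 × shoot growth
demand. The reserve pool (seed starch 0.02 g initially) is capped at
0.3 g per g structural biomass, with 90% of excess storable and 90%
mobilizable per day.

Tillering: at each phytomer event a bud activates iff yesterday's
Ic > Ict (= 1). A tiller's first leaf is pre-dimensioned at 0.9 × the
parent's newest potential length — tillers emerge at near-contemporaneous
leaf size, which makes tillering an effective demand regulator: surplus
carbon recruits sinks until Ic is pulled back toward 1. This is the
mechanism that keeps the stand near source–sink balance and is essential
to the sensitivity results below; with token-sized tiller leaves the model
degenerates to permanent surplus and the transpiration threshold loses its
leverage on biomass.

Deficit response: unmet growth is carried (expansion merely slows);
green area senesces at 0.1 × (deficit/demand) per day, oldest leaves
first — a weeks-scale decline under total starvation, matching greenhouse
dry-down behaviour (plateau, then decline) rather than a days-scale
collapse; after 3 consecutive deficit days the youngest tiller aborts; the
plant dies when green area falls below a 0.25 cm² viability floor (a
proportional senescence rate never reaches exactly zero).

Water: potential transpiration is the evaporative demand on the plant's
ground share, ETP × (1 − e^{−k·LAI}) / density, expressed as depth over
the 0.01 m² pot footprint. TTSW defaults to 30 mm: a 1-litre pot holds
~450 cm³ at field capacity of which ~300 cm³ is plant-extractable. This
reproduces the documented dry-down pace (FTSW ≈ 0.2–0.4 after 11
unthrottled days rather than a still-wet or bone-dry pot).

## Oil palm (adult, vegetative regulation)

Initialization builds a 10-year-old tree at canopy steady state: ~45
standing leaves spaced 1/prod_rate °Cd apart in age, each as far along its
expansion sigmoid as its age implies, and a trunk integrating all past
internodes (≈250 kg structural mass) holding reserves at 25% NSC.

Leaves appear at prod_rate = 0.005 leaves per °Cd (t_base 15 °C; ≈2.5
leaves/month), slowed by drought below `leaf_appearance_th`. Each leaf
expands along a logistic in thermal age, normalized to reach exactly its
potential final area (10 m² for adults) at the end of a finite growth
window (t50 = 450 °Cd, scale 120 °Cd, window t50 + 8·scale ≈ 1410 °Cd).
Demand prices potential area through cost/max_SLA (1.44 / 250 cm² g⁻¹);
each leaf carries an internode growing toward 6000 cm³ priced through
min_dens × cost (0.2 g cm⁻³ structural wood). A constant reproductive
demand (350 g CH₂O d⁻¹, an adult bunch load) replaces the stochastic
reproductive submodel so the experiments isolate vegetative regulation.
Maintenance is 0.0008 g per g structural mass per day.

Reserves live in the trunk (concentration capped at max_NSC = 0.5 of
total trunk mass) and in each leaf (the mass between the max_SLA skeleton
and the min_SLA = 150 cm² g⁻¹ reserve-saturated state, i.e. a saturated
leaf is 40% NSC). Surplus is stored (60% of excess) proportionally to
remaining pool headroom; shortfalls draw on pools proportionally to their
offers (10% of reserve per day, weighted by filling status). Crucially,
growth that cannot be financed is *postponed*, never cancelled: unmet
area/volume joins a pending pool realized when carbon returns, so every
surviving leaf ends at exactly its potential area regardless of drought
history (no size plasticity — only delay). Leaves die at a thermal age of
9000 °Cd; aging accelerates by the inverse of the broken-stick factor at
`senescence_drought_th` = 0.25 (capped 20-fold), so deep drought shortens
leaf lifespan.

Water: canopy potential transpiration is ETP × interception (LAI ≈ 5.7 →
~0.94), per m² of ground. TTSW is 150 mm (deep-rooted palms on the sandy
coastal soils the scenario emulates); stand density 143 trees ha⁻¹. RUE is
1.5 g CH₂O MJ⁻¹, which puts an unstressed adult near 290 kg CH₂O yr⁻¹ and,
against the demand above, near source–sink balance: wet-season Ic ≈
1.1–1.6 (reserves accumulate slowly), severe dry season Ic < 1 (reserves
mobilized) — the regime in which both thresholds have consequences.

## Scenario factory

All forcing is synthetic and deterministic given (parameters, seed).

* Rice greenhouse: constant PAR 7.6 MJ m⁻² d⁻¹, 25.4 °C, ETP 1.85 mm d⁻¹.
  Two dry-downs after 20 well-watered days (daily refill to field
  capacity): 11 days at ETP 1.85 (short severe) or 21 days at ETP 0.9
  (long moderate), no water input.
* Palm two-season tropical climate: smooth seasonal curves for ETP
  (4.0 ± 0.8 mm), temperature (26.5 ± 1 °C) and PAR (8.5 ± 1.5 MJ),
  peaking mid dry season; rain falls as pulses (every 3rd day wet season,
  every 5th day dry season). Dry-season pulse amounts are rescaled so that
  Σ(rain − ETP) over each Jan–Apr window equals the requested deficit
  exactly (−179 mm severe, −2 mm mild); wet months all have positive water
  balance. Daily PAR/temperature values are declared defaults for a West
  African plantation climate, not measurements. What this generator does
  not emulate: day-to-day stochastic weather, VPD, within-season rainfall
  autocorrelation — so passing tests demonstrate the regulatory logic
  under controlled forcing, not predictive skill on observed weather.
* Sweep scenario for palm: 18 months (8 wet months, one Jan–Apr dry season
  of chosen severity, 6 months recovery) so that slow drought
  after-effects (canopy loss, reserve refill) register in end-of-run
  responses.

## Sensitivity experiment

`run_sweep` varies two threshold parameters on a uniform grid spanning
[0.02, 1.0] (the model is deterministic: one run per cell; several
response extractors can share one sweep). Variance decomposition is the
closed-form two-way ANOVA for a single-replicate full factorial:
SS_A = n_b Σ(ȳᵢ. − ȳ)², SS_B = n_a Σ(ȳ.ⱼ − ȳ)², SS_AB = SS_total − SS_A −
SS_B (the residual *is* the interaction with one replicate); shares are
SS/SS_total, summing to 1. A zero-variance grid is flagged degenerate with
shares (0, 0, 0) and a warning. Optima are exhaustive arg-max with
lexicographic tie-breaking (all ties reported). The shipped analyses use
20×20 grids, which resolve the qualitative structure of the response
surfaces at a fraction of the cost of denser grids.

## Numerical choices and degenerate inputs

* Zero demand → Ic is a "no-demand" sentinel treated as surplus.
* Zero threshold → stress factor ≡ 1 (insensitive limit of the broken stick).
* Transpiration is clamped at the remaining transpirable store, so discrete
  days cannot overshoot the bucket; FTSW stays in [0, 1] under arbitrary
  non-negative forcing (property-tested).
* The palm expansion sigmoid is renormalized over a finite window so daily
  increments sum *exactly* to the potential area (no truncated tails).
* Drought-accelerated aging divides by the stress factor, floored at 1/20
  so a bone-dry day cannot deliver infinite aging.
* Composition shares are rounded half-even to one decimal; the three
  rounded shares can drift up to 0.15 from 100.

## Known limitations

* Single whole-plant assimilate pool; no transport resistances or
  source–sink distances, no within-plant concentration gradients.
* Big-leaf light interception is crude for isolated seedlings at very low
  LAI; the density-shared energy cap is a pragmatic pot-scale compromise.
* No soil evaporation, runoff or layered soil; no root water-uptake
  profile (root systems are assumed to explore the full store).
* Rice maintenance and chemical cost coefficients, the SLA–rank relation's
  exact form, palm sigmoid parameters and potential organ-size functions
  are declared defaults, not fitted values; absolute outputs (biomass,
  kg CH₂O) are order-of-magnitude realistic but not calibrated to any
  particular genotype. The qualitative response-surface structure, which
  is what the test suite asserts, is robust to moderate changes in these
  constants; the variance shares and optimum locations shift with them.
* The greenhouse NSC computations (composition shares, relative
  variation, whole-plant concentration, normalized transpiration) are
  measurement arithmetic, deliberately independent of the simulators.
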