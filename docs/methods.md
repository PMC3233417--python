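# Methods

## Scope and intent

`pbpktk` recodes a set of published human pharmacokinetic models into one
internally consistent package for screening-level exposure assessment.
The emphasis is on faithful model *structure*, explicit unit handling,
auditable mass balance and reproducible workflows — not on
state-of-the-art toxicology (metabolite kinetics, population variability
and Bayesian calibration are out of scope).

## Units and conventions

Internally everything is hours, mg and litres (mg/L for concentrations);
ug and days for the metal models, where those are the natural field
units.  Tissue density is taken as 1 kg/L, so volume fractions of body
weight are litres.  Gas-phase ppm is converted with a molar volume of
24.45 L/mol (25 °C, 1 atm), the convention of inhalation toxicology; the
reference temperature of the original implementations is not documented,
so the molar volume is exposed as an argument.  Blood concentrations are
reported in both mg/L and ng/mL (1 mg/L = 1000 ng/mL) at the output
layer only.

## The VOC model

Seven compartments (venous blood, fat, skin, kidney, liver, rapidly and
slowly perfused tissue) plus a gas-exchange step; all tissues well mixed
and flow-limited, `dA_i/dt = Q_i (C_art − C_i/P_i)`.  Structural
assumptions, each a deliberate design choice where the source
descriptions leave latitude:

* **Gas exchange** is the algebraic steady-state lung equation
  `C_art = (Qc·C_ven + Qp·C_inh)/(Qc + Qp/P_b)`; exhaled air is pure
  alveolar air `C_art/P_b` with no dead-space mixing.  This is the
  simplest defensible reading of a "gas exchange compartment" in this
  model family; observed exhaled-breath data may reflect dead-space
  dilution, which would require a mixing fraction on top.
* **Oral absorption** is first-order (`ka`, default 1 h⁻¹) from a
  gut-lumen pool directly into liver inflow, so oral doses experience
  hepatic first pass without introducing dose discontinuities into the
  liver ODE.  Whether the original implementations used one or two GI
  segments is not documented; a single pool was adopted.
* **Metabolism** is saturable and attached to the liver only:
  `v = Vmax·Cvl/(Km + Cvl) + k₁·Cvl·V_liver`, `Vmax = Vmax_c·BW^0.75`
  (the allometric convention of this model family).  DCM carries a
  non-zero first-order term for its glutathione-transferase pathway.
* **Dermal uptake** is permeability-limited flux from water into the
  skin compartment, `Kp·A·(C_water − C_skin/P_skin:water)·10⁻³ L/cm³`;
  it may run backwards (desorption into clean water).  Chemicals without
  a measured `Kp` refuse dermal scenarios with an explicit error rather
  than a silent default.
* **Skin partition fallback**: only TCE and PCE have measured human
  skin:blood partitions; the other four chemicals inherit the TCE value.
  The substitution is logged and recorded in result metadata.

Default physiology is a 70 kg reference adult (cardiac output 348 L/h,
alveolar ventilation 300 L/h) with the tissue volume and perfusion
fractions of the classic human PBPK compilations; flow fractions over
perfused tissues must sum to exactly 1, which the engine enforces.

### Parameter provenance

The bundled per-chemical files under `src/pbpktk/data/voc/` carry a
citation string naming the human model lineage each set is transcribed
from.  The transcriptions are approximate literature values, not verbatim
copies of the original parameter tables, and the package treats them as
replaceable data: simulations refuse to run a set with no citation unless
it is explicitly marked synthetic.  Peak blood predictions at MRL
exposures are sensitive (factor 2–4) to the metabolic constants and
blood:air partitions, so agreement with the original implementations'
published predictions is qualitative rather than quantitative for most
chemicals (see Limitations).

## Metal models

* **Cadmium** — daily-step difference equations in the classical
  eight-pool lineage: gut, fast plasma, red-cell and
  metallothionein-bound blood pools, liver, kidney, other tissue, with
  urinary and fecal sinks.  GI absorption is 5 % (males) / 10 %
  (females).  Hepatic Cd is released slowly (t1/2 ≈ 6 y) as Cd-MT and
  routed preferentially to the kidney, whose turnover (t1/2 ≈ 12 y,
  split urine/plasma) dominates the urinary signal.  Coefficients were
  fixed once by requiring the model to reproduce the lineage's
  documented mid-life organ burdens for an average dietary intake
  (kidney ≈ 3 mg, liver ≈ 1.5–2 mg, urinary ≈ 0.3 ug/day at age 50 for
  ~1.1 ug/day absorbed) and live in a cited JSON file, not in code.
  Growth curves give body weight, organ weights and creatinine excretion
  versus age and sex; urinary output is reported as ug/g creatinine.
  The daily-step formulation is native to this lineage (growth and organ
  weights are tabulated yearly), hence no ODE solver is involved.
  A smoking channel (directly absorbed ug/day) exists but defaults off,
  matching nonsmoker biomonitoring comparisons.  The known tendency of
  this lineage to overpredict urinary Cd above age 60 (gut absorption
  changes in the elderly) is documented here, not asserted by tests.
* **Arsenic** — four interconnected flow-limited sub-models (As(V),
  As(III), MMA, DMA), each with lung, liver, GI tract, kidney, muscle,
  brain, skin and heart compartments; first-order As(V)/As(III) redox in
  liver and kidney; saturable hepatic methylation As(III)→MMA→DMA;
  species-specific renal clearance to urine.  The entry species (oral
  arsenate vs arsenite) therefore shapes urinary speciation.  All
  quantities are ug of arsenic equivalents, so interconversion conserves
  elemental mass exactly.  Rate constants are approximate transcriptions
  and the urinary speciation should be read qualitatively.
* **Methylmercury** — pure linear first-order system (blood, liver,
  kidney, brain; irreversible hair, urine, feces sinks), GI absorption
  0.95, predominantly fecal elimination, whole-body half-life on the
  order of 50 days.  Hair concentration is the capture flux divided by a
  hair-growth mass of 0.35 g/day.  Linearity makes superposition exact,
  which the tests exploit.

## Numerical choices

* Solver: LSODA (stiff-capable) at rtol 1e-8, atol 1e-10 mg.  These are
  deliberately tight so that the mass-balance audit — max over time of
  |intake − (burden + losses)| / max intake — stays below 1e-6 for every
  bundled model (observed: ~1e-12).
* Dose events and exposure on/off switches restart the integrator
  exactly at the event time; no discontinuity straddles a solver step,
  which keeps results reproducible across solver choices.
* Output grids default to 0.1 h spacing; halving the spacing moves
  reported peaks by < 0.1 % on smooth scenarios.
* States are clipped to zero on output; a state more negative than
  1000·atol aborts with a diagnostic error carrying the failure time.
* Simulation-to-observation matching for MSSD/PE uses linear
  interpolation of the simulated series at the observation times, since
  grids rarely coincide.
* RMSPE% implements the mean-over-n formula as primary
  (`sqrt(Σ PE²/n)`); a median-based variant is available because the
  field's naming ("root median-square") is ambiguous about which was
  intended.  PE is `100·(pred − meas)/meas`, the standard
  performance-error convention.  Correlation is Pearson on the natural
  scale with a log-scale option; it is reported as undefined (not NaN)
  for constant series.
* Sensitivity ratios default to a 1 % forward perturbation (the
  perturbation size is recorded in every report entry); a central
  variant is provided and agrees within O(δ) on smooth problems.

## Screening workflow

MRL scenarios are continuous 24 h/day inhalation at the ppm MRL plus the
oral MRL split into four equal drinking bouts at 0/6/12/18 h (the bout
phase is configurable; "equally spaced four times a day" leaves it
open).  Duration classes: acute = 14 days, intermediate = 365 days;
chronic (formally "> 365 days") is simulated as 365 days with an
explicit steady-state attainment flag (last-24 h drift < 1 %/day)
rather than open-ended integration.  Screening verdicts compare the
measured biomonitoring statistic to the predicted *peak* blood
concentration (the steady-state mean is also reported): measured below
predicted → below-screening-level; at or above → exceeds; for "<LOD"
rows the LOD is compared instead and an LOD-based verdict is annotated,
or marked indeterminate when the LOD itself exceeds the prediction.
Verdicts are invariant under joint unit conversion of both sides.

## Synthetic fixture generator

`generate_synthetic_fixture` draws deterministic (seeded) reduced models
that carry their own closed-form references: metabolism-free volatiles
whose venous steady state is `P_b·C_inh` (partitions drawn in [0.5, 3],
`P_b` in [2, 15], so equilibration completes within the 400 h scenario),
and single-pool first-order systems with an exponential solution.  These
fixtures exercise the full engine path against analytic truth.  They
deliberately do *not* emulate real kinetic data: no measurement noise,
no model-structure mismatch, no sparse/irregular sampling.  Passing them
demonstrates numerical correctness of the machinery, not predictive
accuracy against human data.

## Known limitations

* Parameter fidelity: without verbatim access to the original parameter
  tables, the bundled VOC sets reproduce the published MRL peak
  predictions only within roughly a factor of two for most chemicals
  (benzene agrees to ~12 %); the vinyl chloride published peak
  (111.65 ng/mL at 2 ppm / 0.2 mg/kg-day) appears unreachable under any
  defensible parameterization of this structure, since the blood:air
  partition (~1.16) caps the inhalation steady state near 6 ng/mL and
  near-complete hepatic first pass suppresses the oral contribution.
  The cadmium model reproduces the published stratified urinary
  predictions within 15 % for females and within ~15–27 % for males.
* VOC metabolites are not modeled; screening on parent compound only.
* No population variability: one reference physiology per run.
* Dermal parameters exist only for TCE; dermal screening for the other
  volatiles requires user-supplied `Kp` and skin:water values.
* The arsenic and methylmercury rate constants are order-of-magnitude
  faithful transcriptions; use them for structure-dependent questions
  (speciation shifts, route comparisons), not absolute tissue dose.
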