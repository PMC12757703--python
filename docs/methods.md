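# Methods

## Model overview

`nicotine_pbpk` is a whole-body physiologically based pharmacokinetic (PBPK)
model of nicotine in a healthy adult. Drug amounts (mg) are tracked in eleven
perfused tissue compartments (lung, liver, kidney, heart, spleen, adipose,
muscle, skin, gut, brain, rest-of-body), arterial and venous blood, six
respiratory-tract/oral depots (buccal, nasal, ET2, BB, bb, AI) and the gut
lumen. Tissue uptake is perfusion-limited: each tissue equilibrates
instantaneously with its emergent venous blood through a tissue:plasma
partition coefficient Kp, so

    V_i dC_i/dt = Q_i (C_b,art − C_i·(B:P)/Kp_i) / ...   (written in amounts)

with the lung in series carrying the full cardiac output and all other
tissues in parallel. Concentrations are carried internally in mg/L and
reported as venous plasma ng/mL (blood concentration divided by the
blood:plasma ratio, B:P = 1.2).

This structure deliberately assumes: instantaneous intra-tissue mixing, no
permeability limitation (appropriate for a small, lipophilic, highly
permeable base like nicotine), linear binding (constant fu,p = 0.95), and a
parallel splanchnic circulation (the gut tissue drains to venous blood;
portal first pass is represented by routing *lumenal* gut absorption
directly into the liver compartment).

## Physiology and distribution

Tissue volumes and blood-flow fractions are standard reference-human values
for a 70-kg adult (cardiac output 390 L/h, blood 5.3 L split 1.8 arterial /
3.5 venous); all volumes, flows and liver mass scale linearly with body
weight over 30–150 kg. The liver receives the total hepatic (arterial +
portal) flow fraction, 25% of cardiac output, because clearance capacity in
the well-stirred formulation below is bounded by organ flow.

Per-tissue Kp values for nicotine are not published; what is constrained is
their ranking (highest in lung, liver, kidney, heart, spleen; lowest in
adipose) and the aggregate plasma-referenced steady-state volume of
distribution, Vss = 2.70 L/kg. We therefore ship a ranked template
(lung 3.0, liver/kidney 3.5, heart/spleen 2.5, brain/gut 2.0,
muscle/skin/rest 1.5, adipose 0.4) and rescale it by a single scalar so that

    Vss·BW = V_plasma + Σ_i Kp_i·V_i,   V_plasma = V_blood·(1 − hct)

equals the target exactly (closed form, round-trip error < 1e-6 L/kg).
Uniform scaling preserves the ranking. Hematocrit (default 0.44) enters only
through V_plasma; it is exposed for sensitivity analysis, where changing it
re-calibrates the Kp scalar.

## Elimination

Total systemic clearance is 50 L/h split 80:20 hepatic:renal (CL_H = 40,
CL_R = 10 L/h, plasma-referenced organ clearances). Elimination in each
organ is driven by its venous-equilibrium outflow concentration; to make the
configured organ clearance refer to the *inflowing* plasma (so that the
whole-body identity dose/AUC_inf = CL_H + CL_R holds exactly for IV dosing),
the organ clearance is converted once to an intrinsic clearance by
well-stirred inversion:

    CLint = CL·Q_b / (Q_b − CL/(B:P)),     rate = CLint · C_plasma,outflow

This convention also gives swallowed drug entering the liver a genuine
hepatic first pass (extraction ≈ 0.37 at the default parameters).

The alternative CYP2A6 kinetic mode scales recombinant-enzyme
Michaelis–Menten parameters (Vmax = 0.011 nmol/min/pmol, Km = 11 µmol/L,
ISEF = 0.36) to a whole-liver unbound intrinsic clearance:

    CLint_u = ISEF·(Vmax/Km)·abundance·MPPGL·liver mass

with MPPGL = 40 mg/g and liver mass 1800 g (70 kg). The hepatic rate is the
full Michaelis–Menten form applied to the unbound outflow concentration.
The default CYP2A6 abundance is calibrated at runtime so that the linear
regime reproduces the clearance-based mode (fu_p·CLint_u equals the inverted
mode-1 intrinsic clearance); this yields ≈41 pmol/mg, inside the measured
human range. Because plasma nicotine stays far below Km (11 µmol/L ≈ 1785
ng/mL) in all scenarios, the two modes agree within 0.5% in AUC. Renal
elimination is clearance-based in both modes.

## Respiratory-tract dosing

Inhaled doses are allocated to regions using the coarse published split
(20% buccal, 25% upper respiratory tract → ET2, 50% lower respiratory
tract, 5% exhaled). The LRT mass is divided 10/15/75% among BB/bb/AI — an
alveolar-dominant choice consistent with the near-immediate plasma peak
seen during smoking; only the aggregate 50% is constrained by data.
E-cigarette dosing assumes complete absorption with no exhalation loss (the
coarse fractions renormalized over the retained 95%); nasal sprays deposit
95% in the nasal region with 5% lost.

Each region absorbs first-order into the systemic circulation: AI/bb/BB
into the lung compartment, ET2/buccal/nasal into venous blood. Default
absorption half-lives are 0.5 min (AI), 5 min (bb, BB), 15 min (ET2),
20 min (buccal) and 10 min (nasal); regional kinetics for nicotine are not
published, and these values were chosen once so that the smoking peak falls
at the end of the puffing period and the non-exhaled dose is >99.9%
absorbed within hours. A slow mucociliary ladder (0.1/h per step) moves
mass bb → BB → ET2 → swallowed; swallowed drug enters the gut lumen and is
absorbed with a single first-order constant ka = 2·Peff/r ≈ 1.76 h⁻¹
(Peff = 4.28×10⁻⁴ cm/s, intestinal radius 1.75 cm) into the liver.
All rate constants are exposed in configuration.

## Numerical implementation

The ODE system is integrated with `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-8, atol 1e-12 mg). Every dose event time is an integration
breakpoint: boluses and depositions are state jumps, infusions constant
inputs over their interval; breakpoints are also inserted into the output
grid, so an infusion peak lands exactly on a grid point. Concentrations are
clamped at zero inside the rate function to guard against stiff-solver
transients, and the output grid (default step 0.005 h) reports the
post-jump value at event times. A mass-balance audit — body amounts +
unabsorbed depot mass + cumulative hepatic/renal elimination + exhaled
losses vs. total scheduled dose — must close to better than 1e-4
(relative); in practice it closes to ~1e-15, and tightening tolerances
tightens it further.

## Non-compartmental analysis

Cmax/Tmax use an earliest-maximum tie-break; AUC is linear trapezoidal;
λz comes from a log-linear regression over the terminal point subset that
maximizes adjusted R² (last 3…n positive post-peak points, peak excluded;
near-ties within 1e-4 go to the larger subset); AUC_inf = AUC_last +
C_last/λz and t½ = ln2/λz. Qualification statistics: R ratio =
observed/predicted with the inclusive two-fold acceptance band [0.5, 2.0];
fold error = predicted/observed; AFE = 10^(mean log10 fold error); RMSE and
MAE over paired values. Table comparisons are rounded to 3 significant
figures.

## Verification scenarios

The registry holds the nine clinical verification scenarios (six IV rows,
smoking, nasal spray, e-cigarette) with their published observed PK
parameters. Scenario-resolution choices where the sources are silent:

* per-kg infusion rates use the scenario body weight (default 70 kg);
* the repeated-infusion scenario is two 30-min infusions of 2.5 µg/kg/min,
  90 min start-to-start;
* the bolus row's ambiguous dose notation ("0.2 µg/kg/mL") is interpreted
  as a 1.7 mg dose back-calculated from the observed AUC_inf × total
  clearance; the literal string is stored alongside;
* smoking is 10 puffs of 0.24 mg at 60-s intervals (2.4 mg over 10 min);
  the e-cigarette comparison uses a single 10-puff session (0.14 mg/puff,
  30-s intervals; a two-session variant one hour apart ships as well);
* each scenario carries a fixed observation window for AUC_0-t (2, 6, 48,
  3, 8, 1, 2, 1 and 2 h in registry order), standing in for the clinical
  sampling durations which the sources report only through their truncated
  AUCs. These windows are scenario properties, not fitting parameters.

Simulations run to 24 h (48 h for the 24-h infusion) at a 0.005-h output
step — small enough that trapezoidal AUC error and Tmax grid quantization
are negligible against every stated tolerance, and the full registry runs
in about a second.

## Synthetic data

`generate_fixture_profile` produces mono-/bi-exponential concentration
profiles with optional multiplicative log-normal noise (seeded); these
stand in for digitized clinical profiles, which are not published in
machine-readable form. They emulate the shape and sampling of real plasma
data but not assay error structure, below-quantification censoring, or
inter-subject variability — so NCA tests on them verify the estimator
implementations, not field performance on noisy clinical data.
`population_range` perturbs total clearance (80:20 split preserved) and the
global Kp scalar log-normally to produce spread statistics analogous to the
published prediction ranges; the generating mechanism of those published
ranges is unknown, so no quantitative match is claimed.

## Known limitations

* The platform predictions printed alongside the observed data imply
  study-specific effective clearances between ~48 and ~98 L/h, while the
  published parameter table fixes 50 L/h. With 50 L/h, two scenarios from
  one source (the 5.1 mg IV infusion and 2.4 mg smoking) predict AUCs more
  than two-fold above their observed values; the corresponding qualification
  test documents this rather than adjusting the clearance per scenario.
* The observed e-cigarette Tmax (1.08 h) reflects a second puffing session;
  the single-session registry scenario peaks minutes after puffing ends.
* No cotinine (metabolite) kinetics, no permeability-limited tissues, no
  enterohepatic recirculation, no special-population physiologies, and no
  particle-size-resolved deposition physics (deposition fractions are
  inputs).
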