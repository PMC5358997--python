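# Methods

`oralbe` implements an in vitro → in silico bioequivalence workflow for
immediate-release oral formulations, built around the amlodipine (5 mg) /
atorvastatin (10 mg) single versus fixed-dose-combination (FDC) case:
dissolution-profile similarity testing, Caco-2 permeability analysis, a
mechanistic segmented-gut absorption model, and a minimal PBPK disposition
model driving virtual clinical trials.

## Dissolution similarity (f1/f2)

For reference and test mean profiles R_t, T_t on a common sampling grid:

    f1 = 100 * Σ|R_t − T_t| / ΣR_t
    f2 = 50 * log10( 100 / sqrt(1 + (1/n) Σ(R_t − T_t)²) )

Profiles are similar when f1 < 15 and f2 > 50; when both products release
more than 85% of dose within 15 min the comparison is waived (rapidly
dissolving). Choices the formulas leave open:

- **Point selection.** Scheduled common points up to and including the
  first point at which both profiles exceed 85% (the standard regulatory
  convention — later points carry no discriminating information once both
  curves plateau). Switchable off (`apply_85_rule=False`).
- **Replicates.** Statistics are computed on replicate means (assay
  reports are mean ± SD, n = 3).
- **Grids.** Mismatched time grids are an error, never silently
  interpolated: both statistics are grid-sensitive.
- **Sampling correction.** Cumulative dissolved mass from sampled
  concentrations uses M_n = C_n·V + v_s·Σ_{i<n} C_i (withdrawn analyte is
  added back; withdrawn medium is replaced with fresh).

Fitted release models use the Weibull family
F(t) = plateau·(1 − exp(−(t/td)^β)); first-order release is the β = 1
special case, and a `tabulated` family passes the (monotonized) measured
curve through directly with plateau clamping.

## Caco-2 permeability

TEER = (R − R_blank)·A in Ω·cm². Apparent permeability is
Papp = (dQ/dt)/(C₀·A) in cm/s, with dQ/dt taken from the linear window of
the sampling-corrected cumulative receiver-mass curve. The default window
keeps points while receiver mass is below 10% of the initial donor mass
(sink criterion), falling back to the best-r² contiguous window of ≥ 4
points. Because the curve passes through the origin by construction and
concentration error is multiplicative (constant CV), the slope estimator is
the relative-variance-weighted through-origin slope — the mean of the
per-point rates m_i/t_i — rather than an intercept-fitted OLS line; on
noiseless data the two coincide, under CV-type noise the weighted form has
roughly half the error. Efflux ratio = Papp(B→A)/Papp(A→B); mass balance =
(donor end + receiver end + withdrawn samples)/donor start.

## Compound algebra

Ionization uses Henderson–Hasselbalch per compound class (a diprotic base
uses both pKa values). Blood binding: fu_b = fu_p/(B:P). The hepatic model
is the well-stirred liver, CL_h = Q_h·fu_b·CLu_int/(Q_h + fu_b·CLu_int),
with F_oral = fa·fg·fh. The retrograde calculation inverts
CLpo = CL_h/(fa·fg·fh); under the well-stirred model CL_h/fh =
fu_b·CLu_int identically, so the inversion is closed-form
(CLu_int = CLpo_blood·fa·fg/fu_b) and always admits a solution for positive
inputs — the "no positive root" failure mode reduces to input validation.

**Oral clearance units.** The source table prints CLpo in "L/min" (24.8 and
949), which is physiologically impossible (it would imply oral clearances of
~1,500 and ~57,000 L/h). The values are interpreted as L/h, which matches
the literature oral clearances of both drugs; the unit tag is explicit in
the compound YAML files and logged on load.

**Peff/Vss pairing.** The parameter-estimated values (1.35×10⁻⁴ and
6.12×10⁻⁴ cm/s; 13.78 and 4.78 L/kg) are assigned as Peff = 1.35×10⁻⁴
(amlodipine) / 6.12×10⁻⁴ cm/s (atorvastatin) and Vss = 13.78 (amlodipine) /
4.78 L/kg (atorvastatin) — the assignment consistent with the drugs' known
disposition (amlodipine Vss ≈ 20 L/kg, long half-life).

Amlodipine has no enzyme-specific in vitro clearance; its systemic
clearance is back-calculated from CLpo with fa = 0.92 (its own absorption
simulation) and fg = 1 (no gut-wall metabolism modeled). Atorvastatin's
CLint_3A4 = 8.28 µL/min/pmol is accepted as an input (its retrograde
assumptions fa = 1, fg = 0.24 are stored with the compound); the system
abundances behind it are not re-derived.

## Gut absorption model

Structure: stomach + 7 small-intestinal segments (duodenum, jejunum I/II,
ileum I–IV) + colon. First-order transit: gastric emptying half-life 0.25 h
fasted / 1.0 h fed; each SI segment k_t = 7/3.3 h⁻¹ (mean SI transit
3.3 h); colon exit 1/18 h⁻¹. Absorption ka = 2·Peff/r with r = 1.25 cm
(SI) and 2.5 cm (colon, additionally scaled ×0.2, switchable off).

**Release.** The in vivo release hazard is derived from the *normalized*
in vitro profile F(t)/F∞: the profile sets the kinetics, and release is
complete in vivo. Rationale: the closed-vessel plateaus are assay/
solubility-limited (one exceeds 100%), and fasted-state absorbed fractions
of formulations with different plateaus are observed to be identical — an
extent-limited reading would contradict that. For Weibull release the
hazard is the closed form (β/td)(t/td)^(β−1), capped at 100 h⁻¹.
`fraction_dissolved` still reports the raw in vitro curve.

**Gastric release scaling.** The profiles are measured in intestinal media
(pH 6.5/5.0). Total solubility of an ionizable compound scales with
1/f_unionized, so the gastric release rate is scaled by
S(gastric pH)/S(reference pH 6.5), capped at 1. For the weak acid
atorvastatin (pKa 4.46) this suppresses gastric dissolution almost
entirely (as expected physicochemically); bases and neutral compounds are
unaffected. Gastric pH: 1.8 fasted, 5.0 fed.

**Gut-wall metabolism.** Enterocyte compartments (0.25 L total, split
evenly across segments; mucosal blood flow 18 L/h, split evenly) clear
drug at CLu = CLint_3A4 · total gut CYP3A4 abundance (70,000 pmol default)
· regional weight, with enterocyte unbound fraction 1. The regional CYP3A4
weights default to a geometric decline (halving per segment aborally,
normalized): human duodenal CYP3A4 density exceeds distal-ileal density by
roughly an order of magnitude, and a shallower (e.g. linear) ramp damps
the regional-metabolism mechanism well below its documented effect.
Equal-volume enterocyte compartments keep the *density* gradient monotone
decreasing, which is the physiologically meaningful quantity. Both weight
vectors are user-overridable. P-gp efflux from enterocyte back to lumen is
Michaelis–Menten: RAF·w_i·Jmax·A_i·C/(Km + C), with weights increasing
linearly aborally and C the enterocyte concentration in µM.

**Fed state** = slower gastric emptying (1.0 h half-life), gastric pH 5.0,
+50% luminal volumes, and the FeSSIF release profile (FaSSIF↔fasted,
FeSSIF↔fed mapping). Colon absorbs but does not metabolize.

**Outputs.** fa is the *net* fraction of dose entering enterocytes (apical
uptake minus P-gp secretion — gross uptake would double-count recycled
drug); fg is portal appearance / net uptake; both come with regional
decompositions, and every simulation carries a mass-conservation check
(dose = unreleased + luminal + enterocyte + metabolized + portal + colon
exit) that holds to solver tolerance (BDF, rtol 1e-8, atol 1e-10).

## Minimal PBPK and virtual trials

Portal input feeds a well-stirred liver compartment (2 L) exchanging with
a central compartment of volume Vss·BW at hepatic blood flow 90 L/h;
elimination is hepatic, fu_b·CLu_int·C_liver, with fu_b·CLu_int =
CLpo_blood·fa·fg from the retrograde identity. This two-compartment
arrangement reproduces the well-stirred oral relationships exactly:
steady-state analysis gives CL_iv = Q·x/(Q+x) and CLpo = x = fu_b·CLu_int,
so AUC_po = F·D/CL by construction. Blood quantities are converted to
plasma via B:P for reporting (ng/mL).

Populations are exchangeable log-normal mean-1 multipliers: CV 30% on
clearance and Vss, 40% on gut and liver CYP3A4 abundance (simulator-style
population libraries do not publish their values; these are conventional
magnitudes). Hepatic intrinsic clearance is scaled by the product of the
clearance and liver-CYP multipliers, gut metabolism by the gut-CYP
multiplier. Body weight is fixed at 70 kg. No age/sex covariates,
inter-occasion variability, or allometry.

PK summaries follow bioequivalence-report conventions: geometric mean and
geometric SD for Cmax, median (min–max) for AUC (linear trapezoid) and
tmax (time of first maximum on the 0.1 h sampling grid). Arms are compared
by unpaired two-tailed t-test (Welch by default) on untransformed
parameters, with a geometric-mean-ratio + 90% CI diagnostic.

A degenerate verification mode (`absorption="bolus"`) places the dose in
the central compartment with no first pass and eliminates it with the oral
blood clearance, so the profile has the closed form C(t) = D/V·e^(−kt);
this exercises the same integrator against an analytic solution.

## Parameter estimation

Bounded weighted least squares (uniform, 1/y or 1/y² weights) of simulated
versus observed concentrations, simulating the typical (multiplier-1)
subject. Multi-start derivative-free Powell search within bounds (default
5 starts: the bound-box center plus seeded uniform draws); a truncated
line search can end worse than its start, so each start's result is
floored at the start point. Per-start initial/final points and objectives
are returned for diagnosis.

## Synthetic data

The generators emulate the study's assays with known ground truth:

- **Dissolution**: Weibull mean curves with additive Gaussian noise
  (default SD 1.5% of dose, truncated at 0; replicate scatter is not
  reported in the source beyond "mean ± SD, n = 3", so the default is a
  conventional assay SD), n = 3 replicates, 2 h grid
  {2,5,10,15,20,30,45,60,90,120} min. Preset plateaus are the observed
  values (94.9/101.2/87.9/79.9% amlodipine; 80.0/89.3/76.9/86.2%
  atorvastatin single/FDC in FaSSIF/FeSSIF). Time scales are chosen once
  to match the stated kinetics: amlodipine FaSSIF rapid (>50% at 5 min,
  >85% at 15 min for both formulations; td = 4/5 min), amlodipine FeSSIF
  slow and formulation-discordant (td = 25/45 min → f1/f2 fail),
  atorvastatin FaSSIF initially rapid but incomplete (td = 6/5.5 min) and
  FeSSIF slow (td = 41/40 min) with single/FDC similar. The fed-state
  slowdown (~7× for atorvastatin) encodes the slower in vivo fed
  dissolution that drives the food-effect mechanism.
- **Transport**: sink-regime linear mass transfer J = Papp·C₀·A with exact
  bookkeeping of receiver withdrawal/replacement (0.5/1.5 mL compartments,
  100/200 µL samples over 2 h), multiplicative log-normal measurement
  noise, and donor endpoints for mass balance. A `retained_fraction`
  diverts transported drug into the monolayer for loss fixtures.
- **Plasma**: forward trial simulation with log-normal CL/Vss multipliers
  and multiplicative log-normal residual error (default CV 10%).
- **Populations**: log-normal mean-1 multipliers per subject.

All generators draw from named streams derived from one integer seed
(seed, CRC32(stream name)), so runs are reproducible and modules testable
independently. What the generators do *not* emulate: inter-laboratory
assay drift, non-sink transport kinetics, time-varying absorption
physiology, and real digitized clinical profiles — passing round-trip
tests therefore demonstrates internal consistency of the pipeline, not
field accuracy on external data.

## Numerical choices

ODE systems are stiff-solved (BDF) at rtol 1e-8/atol 1e-10 by default;
estimation workflows use rtol 1e-5/1e-6 for speed, which changes simulated
concentrations by far less than assay noise. Release hazards are capped at
100 h⁻¹ (a 25 s dissolution half-life, effectively instantaneous relative
to transit). Reported study sizes — 100 seeded transport runs, 50-subject
trial arms, 20 estimation replications with 12 subjects — are the
package's verification defaults and can be scaled up by argument.

## Known limitations

- Release is profile-driven: no mechanistic solubility/precipitation,
  bile-micelle partitioning, or regional pH-dependent dissolution beyond
  the gastric solubility scale; no enterohepatic recirculation.
- The FDC is represented by its own dissolution profile only — no
  pharmacokinetic drug–drug interaction between the two actives (an
  optional Peff scaling by the combination/single Papp ratio exists on
  `SolverOptions.peff_scale`, off by default).
- System physiology (enzyme abundances, flows, enterocyte volumes) uses
  round literature values, not a proprietary population library; absolute
  exposures are therefore indicative, while within-model contrasts
  (fed/fasted, single/FDC) are the supported endpoints.
- Atorvastatin's active hydroxy-metabolites and OATP-mediated hepatic
  uptake are out of scope.
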