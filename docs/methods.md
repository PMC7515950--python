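# Methods

This note documents the model, its parameters, the calibration
procedure, the synthetic-data generator, and the numerical and design
choices behind `fedrapbpk`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model structure

**Distribution.** Each compound uses a minimal PBPK layout: a central
systemic compartment (volume `vss` L/kg), a single adjusting peripheral
compartment (`v_sac` L/kg, flow `q_sac` L/h), and an explicit
well-stirred liver (volume = liver weight / 1000 L, liver:plasma
partition of one) perfused at the hepatic blood flow times the
blood:plasma ratio. A full multi-organ PBPK adds nothing for metabolic
DDI questions: all interaction terms are driven by liver (or enterocyte)
unbound concentrations, which this layout represents explicitly.

**Absorption.** First-order absorption (`ka`, absorbable fraction `fa`,
lag time) from a gut lumen into the liver inlet, i.e. all absorbed drug
transits the liver (hepatic first pass is emergent, not a factor).
Permeability/efflux limitation and enterohepatic recirculation are out
of scope.

**Gut first pass.** Two options per compound: a fixed `fg`, or a
gut-extraction model `fg(t) = Qvilli / (Qvilli + fu_gut·CLint_gut·a(t))`
with `Qvilli = 18 L/h`, `fu_gut = 1`, and `a(t)` the relative activity of
the gut CYP3A4 pool (enzyme fraction divided by the reversible-inhibition
factor). The enterocyte inhibitor concentration is approximated as
absorption flux / villous flow plus the systemic unbound concentration —
a standard surrogate that captures both the large transient during
perpetrator absorption and the sustained systemic component.

**Elimination.** Per-enzyme unbound intrinsic clearances declared in
µL/min/pmol (scaled by subject abundance × MPPGL × liver weight),
µL/min/mg microsomal protein, or directly in L/h; plus renal (scaled by
a GFR scalar), biliary (driven by liver concentration) and additional
systemic clearances. Mass is conserved to well below 0.1% at every
output time (asserted in tests); cumulative eliminated mass per pathway
is integrated as part of the state, which is what makes the fm/fe
partition exact rather than post-hoc.

**Interactions.** Reversible inhibition divides each effective CLint by
`1 + Σ Iu/Ki`. Enzyme pools targeted by time-dependent inactivation or
induction get a turnover state
`dE/dt = kdeg·(1 + IndMax·Iu/(IndC50+Iu)) − E·(kdeg + kinact·Iu/(KI_app+Iu))`,
`E(0) = 1` — the standard dynamic net-effect form from the PBPK
literature; the mechanisms (mixed reversible/TDI/induction) are the
modelled substance, the specific functional form is a documented design
choice. `kdeg` defaults: hepatic CYP3A4 0.0193 h⁻¹ (t½ ≈ 36 h), gut
CYP3A4 0.03 h⁻¹, other CYPs 0.026 h⁻¹. Auto-interaction (a compound
perturbing the enzymes that clear it) uses exactly the same terms.

**Fedratinib's gut CYP3A4.** The engine applies gut interactions by
default (`apply_gut_interactions=True`), and the ketoconazole fixture
carries a gut CYP3A4 entry. The fedratinib fixture deliberately does
not: a µM-scale reversible Ki at the gut would be swamped by fedratinib's
own enterocyte concentrations (tens of µM during absorption), driving
its own fg to ~1 and erasing the gut first-pass component that the
observedly larger AUC-than-Cmax inhibitor effect requires, while gut
auto-TDI would push the accumulation ratio well above its target. With
hepatic-only auto-interaction every calibration target is reachable
simultaneously; this is recorded in each fixture's provenance.

## Units

Internal: hours, litres, milligrams (concentrations mg/L ≡ µg/mL;
reported as ng/mL). Interaction constants are unbound µM; conversion
uses each compound's molecular weight and unbound fraction. Units for
clearance entries are declared per entry and converted once at
subject-scaling time — never inferred.

## Population

Subjects are sampled log-normally per field with the central value as
geometric mean (so CV = 0 degenerates exactly and no draw can be
non-positive), using `numpy.random.default_rng` (PCG64) for cross-platform
seed determinism. Central values and CVs (documented in
`population.py`): body weight 70 kg/15%, liver 1650 g/20%, hepatic blood
flow 90 L/h/15%, MPPGL 40 mg/g/30%, hepatic CYP3A4 137 pmol/mg/40%,
CYP2C19 14/50%, CYP2D6 8/60%, CYP2C8 24/40%, CYP2C9 73/40%, gut CYP3A4
66.4 nmol/40%, hematocrit 0.45/8% (clipped to (0.2, 0.6)). These are
widely published human defaults; the analysis surface (geometric-mean
ratios from paired arms) is robust to moderate shifts in them.

The cancer population is a calibrated design choice, not a measured
dataset: unbound fraction × 0.8 (raised α1-acid glycoprotein), body
weight × 0.95, hepatic and gut CYP3A4 abundance × 0.75, MPPGL × 0.8.
Reduced CYP3A4 abundance lowers fedratinib's fm_CYP3A4 and hence its
victim DDI magnitude; the reduced functional liver mass raises
fedratinib exposure and hence its perpetrator effect — reproducing the
qualitative healthy-vs-cancer orderings the analysis expects.

## Calibration (middle-out)

1. **Empirical layer** — `fit_oral_pk`: weighted least squares on log
   concentrations against the closed-form two-compartment oral solution;
   initial values from NCA; returns apparent (/F) ka, CL, Vc, Vsac, Q
   with log-scale standard errors.
2. **Retrograde layer** — `retrograde_clint`: with absorption,
   distribution and the interaction constants fixed, iteratively rescale
   each per-enzyme CLint (and renal/biliary CL) by
   (target share / achieved share) × (achieved dnAUCinf / target),
   re-simulating the reference single dose each round. Iteration is
   needed because hepatic availability and the excreted fractions both
   depend on total clearance; convergence (AUC within 0.5%, each fm
   within 0.25 points) typically takes 2–5 rounds. Diverging clearances
   (>10⁶-fold) raise an infeasibility error.
3. **Accumulation refinement** — `refine_by_accumulation`: bisection on
   the CYP3A4 ↔ additional-HLM split (total first-dose hepatic CLint
   preserved) until the simulated AUC accumulation ratio enters the
   observed range; the direction is monotone because only the CYP3A4
   pathway is auto-inactivated.

fm/fe are defined on first-dose elimination fluxes over one dosing
interval; the steady-state partition is a model *output*. The partition
covers systemic elimination only: gut first-pass loss is a
bioavailability factor, tracked separately and includable via
`include_first_pass=True`.

λz selection: log-linear regression over the last 3..10 post-peak
points, window chosen by best adjusted R² (stated because vendor NCA
defaults differ). AUC uses linear-up/log-down trapezoids.

## Compound fixtures

Perpetrator and probe parameters are shipped as editable YAML fixtures
with per-value provenance. Literature-anchored physicochemical values
(MW, fu, B:P) are combined with clearances and interaction constants
*calibrated* so that (a) each perpetrator's effect on a sensitive
CYP3A4 index substrate lands in its regulatory class — ketoconazole and
itraconazole strong (≥5×), erythromycin, diltiazem and fluconazole
moderate (2–5×), efavirenz a moderate and rifampin a strong inducer —
and (b) the fedratinib-specific study ratios are reproduced. The
fedratinib auto-interaction constants (Ki 0.85 µM, kinact 0.95 h⁻¹,
KI_app 1.0 µM, IndMax 1.5, IndC50 1.5 µM, all unbound) were calibrated
jointly against the steady-state fm_CYP3A4, the AUC accumulation ratio,
and the midazolam perpetrator ratios; its CYP2C8/2C9/2C19 Ki values
against the repaglinide/warfarin/omeprazole probes. Fixture values are
therefore reproducible outputs of the package's own calibration
machinery, not independent measurements — the provenance strings say so.

## Virtual trials

Paired design: both arms reuse the same sampled subjects (the
crossover-style GM ratio this analysis reports implies within-subject
pairing), so the ratio of arm GMs equals the GM of within-subject ratios
(asserted). 90% CIs are t-intervals on log ratios across all subjects
pooled over trials; the per-arm n is carried in the output. The AUC
metric follows the study design: AUCinf for single-dose victims (216-h
sampling with λz extrapolation), AUCτ on the last dose for QD victims at
steady state. Default replication is 10 trials × 10 subjects; the test
suite runs 1 × 4–6 subjects, which moves the GM ratios by far less than
the tolerances checked.

## Synthetic data

`synthetic_data` emulates mean plasma concentration–time profiles with
log-normal residual error (proportional error, the standard PK
assumption), for single and repeated QD/BID dosing, with rich sampling
grids (15-min early, out to 96+ h) since actual clinical sampling times
are not available. Each dataset carries a truth sidecar (generating
parameters, noise-free profile) for recovery scoring. It does **not**
emulate between-study heterogeneity, dropout, BLQ censoring, or
real-world sampling irregularity — so passing recovery tests shows the
estimation machinery is consistent, not that it is robust to real
clinical data pathologies.

## Numerics

LSODA (stiff/non-stiff switching) with rtol 1e-8 / atol 1e-10,
integrated segment-by-segment between dose events (no impulse
smoothing); dense output evaluated on the caller's grid. Output AUC is
insensitive to halving the grid step to well under 0.5% (asserted).
States below −1e-6 mg are a hard error; smaller negative excursions are
floored at segment restarts. A perpetrator entry with zero dose is
dropped from the co-administration arm so that zero-dose ratios are
exactly 1. Ties in `recommend_dose` at a threshold take the
more conservative lower-dose branch.

## Known limitations

* Transporter-mediated DDI (OATP1B1, P-gp, BCRP, OCT1/2) is parsed but
  inert; predictions for transporter substrates are out of scope.
* CYP2C19/CYP2D6 perpetrator predictions (omeprazole, metoprolol
  fixtures) are mechanically supported but not a verified surface.
* The cancer population is a consequence-calibrated construct; its
  field-level values should not be quoted as physiology.
* Single-dose terminal phases beyond ~96 h are under-represented by the
  two-compartment distribution layer; exposure metrics that weight the
  deep terminal phase heavily inherit that approximation.
* Hematocrit pathology, pediatrics, organ impairment and
  ethnicity-specific physiology are not modelled.
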