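# Methods

## The model

`canipbpk` implements a whole-body, flow-limited (perfusion-limited)
pharmacokinetic model for intravenous propofol in dogs. Every tissue is a
well-stirred compartment in instant equilibrium with its exiting blood:

    V_t dC_t/dt = Q_t (C_art − (C_t / Kp_t) · B:P)

with the lung in series between the venous and arterial blood pools (it
receives the entire cardiac output), the liver receiving hepatic-arterial
plus portal (gut + spleen) inflow, and intravenous input (bolus and
infusions, both zero-order) entering the venous pool. The reported
concentration is venous blood divided by the blood:plasma ratio B:P = 2.36;
arterial plasma is available as an option. The compartment list is
{lung, liver, kidney, brain, heart, muscle, fat, skin, gut, spleen, bone,
rest-of-body} plus the two blood pools; a documented "lumped" mode pools the
non-portal tissues into richly/slowly perfused compartments for fast tests.

### Anatomy and physiology

Organ volumes are fractions of body weight (1 kg/L density) and scale
linearly with BW; cardiac output — and with it every organ flow — scales as
BW^0.75 around a 10.5 kg reference with CO = 120 mL/min/kg. The fractions
are assembled from published canine physiology compilations and standard
tissue-composition tables (Poulin–Theil-style water / neutral lipid /
phospholipid / protein fractions); they are an implementation source, not a
claim about any particular physiology database, and the calibration steps
below absorb residual differences. Hematocrit defaults to 0.45 and is used
only for bookkeeping. `validate_physiology` asserts flow conservation at the
venous pool (systemic flow fractions sum to 1), volume conservation
(organs + blood within (0.85, 1.05) × BW), and composition-sum sanity.

### Distribution

Tissue:plasma partition coefficients come from a composition-based
homogenate scheme with a protein-binding correction:

    Kp = kp_scale · [P·f_nl,t + (0.3P+0.7)·f_ph,t + f_w,t]
                  / [P·f_nl,p + (0.3P+0.7)·f_ph,p + f_w,p] · fu_p / fu_t,
    fu_t = 1 / (1 + ((1 − fu_p)/fu_p) · (f_pr,t / f_pr,p)),   P = 10^logP.

A no-binding variant (`method="nobind"`) omits the fu term. Both satisfy
Kp = kp_scale when tissue composition equals plasma composition. Schemes
requiring inputs the data model does not carry (membrane-affinity
calibrations, acidic-phospholipid fractions) are out of scope; the global
`kp_scale` factor is the declared mechanism for absorbing scheme and
composition-table differences.

### Elimination and its calibration

Elimination is a hepatic plasma-clearance term acting on the liver
plasma-equivalent concentration. The quantity the model controls is the
*realized* total plasma clearance CL (dose / AUC∞ referenced to venous
plasma); the liver coefficient k is obtained from the well-stirred inversion

    CL = k / (1 + k / (B:P · Q_hep)),   k = CL / (1 − CL / (B:P · Q_hep)),

which makes AUC∞ = dose/CL hold exactly in the linear system (the same
algebra applies to the time-integrals as to steady state). CL is calibrated
by dose-over-AUC arithmetic on a reference bolus+infusion study (28 mg/kg
over 13.81 µg·h/mL → 33.79 mL/min/kg) and verified by re-simulation; a
single reference study is used because the implied per-kg clearances of the
literature designs are not mutually consistent (they range 33.8–38
mL/min/kg, plausibly reflecting truncation of each study's AUClast at its
last sample), and the chosen study is the development design whose exposure
is reproduced exactly by construction. The substance file's 47.08 mL/min/kg
"unspecific hepatic clearance" is retained as specification metadata: with
our hepatic flows the well-stirred inversion gives k ≈ 56–61 mL/min/kg for a
realized 33.8, which is the same flow-limitation gap that separates the two
printed numbers. pKa (11.1, neutral at physiologic pH) and solubility are
carried but inert in this i.v., flow-limited model.

`kp_scale` is calibrated so that the 10.5 kg reference dog's venous plasma
concentration at the end of the standard maintenance regimen (5 mg/kg bolus
over 60 s + 0.13 mg/kg/min for 3 h) equals the geometric midpoint of the
2.5–4.7 µg/mL maintenance window, √(2.5·4.7) ≈ 3.43 µg/mL (concentration
windows are ratio-scaled). The end-of-infusion concentration is monotone
decreasing in kp_scale, so a bracketing root-finder suffices; the calibrated
value is ≈ 0.130.

### Hepatic impairment

Two semantics are implemented. `mode="plasma"` scales realized plasma
clearance directly to (1 − impairment) of healthy — the literal reading of
"a decrease in total plasma clearance". `mode="process"` scales the hepatic
elimination coefficient k — the knob a whole-body simulator actually
exposes — and lets hepatic flow limitation compress the realized reduction
(HI20/40/60/80 retain 83/69/51/29% of healthy realized clearance instead of
80/60/40/20%). The protocol layer defaults to process mode because it
simultaneously reproduces the three published impairment-adjusted infusion
rates within ~3%, while plasma mode misses them by 20–35% at any
window-compliant kp_scale; both modes are available everywhere.

## Numerics

The system is linear and time-invariant with piecewise-constant inputs, so
the default integrator is an exact propagator: per segment and step size, a
matrix exponential of the (input-augmented) rate matrix advances the state
with no truncation error at grid nodes. Dose on/off times are always grid
nodes, eliminating discontinuity smearing. An adaptive stiff solver (LSODA,
rtol 1e-6, atol 1e-9 mg) is kept as `method="ivp"` and cross-checked in the
tests to ~1e-6 relative agreement. A cumulative eliminated-amount state
makes mass balance checkable at every node (it holds to ~1e-13 relative).
The output grid uses 1-s steps during the bolus, 5-s steps to 10 min, and
1-min steps thereafter; AUC is the linear trapezoid on that grid, and
halving the steps moves AUC0–12h by far less than 0.1%. Exposure matching
exploits superposition: each arm is simulated once for the bolus and once
for a unit-rate infusion, so the profile at any candidate rate r is
`bolus + r·unit` and the rate that equalizes median AUC0–3h is found by
Brent's method on precomputed per-subject AUC components. AUC0–3h is
operationalized as bolus start → infusion end (181 min with the 60-s bolus;
the bolus duration is configurable — figure captions in the source
literature vary between 30 and 60 s, to which the 3-h endpoints are
insensitive). Recovery time is measured from infusion end on the pointwise
median population profile, by linear interpolation to the 2.15 µg/mL
threshold; profiles that never cross within the horizon are reported as
censored rather than numeric.

## Virtual populations

A population subgroup is n = 1000 dogs with body weight uniform on
7.5–13.5 kg. Physiology scales deterministically with body weight;
stochastic inter-individual variability enters only as multiplicative
mean-one log-normal factors on realized clearance (CV 20%) and on muscle and
fat volumes (CV 15%) — the parameters the sensitivity analysis identifies as
exposure-relevant. The variability magnitudes are an assumption (the study
conditions fix only the body-weight distribution); they are the defaults
under which the compliance checks run. Multipliers are truncated at ±3.5 SD
so that sampled clearances stay below the hepatic plasma-flow ceiling
B:P·Q_hep that the well-stirred inversion requires; the truncation bias on
the mean is < 0.1%. Impaired arms reuse the healthy arm's dogs with reduced
hepatic function (a paired design, which makes the zero-impairment
adjustment exactly the identity). Everything is reproducible bit-for-bit
from the config seed. Summaries report the pointwise median with a
2.5–97.5 percentile band; a geometric-mean variant is available since the
source figures mix both conventions.

## Statistics

Group comparisons follow the published pipeline: a Kolmogorov–Smirnov
normality screen per group (on standardized values), a Kruskal–Wallis
omnibus test, and Dunn's pairwise rank test with tie correction. The
multiplicity adjustment is Holm (the published procedure does not name
one); it is configurable, and the Dunn machinery is implemented directly
(rank sums, tie term, normal z) with a hand-ranked oracle in the tests.
Degenerate all-tied inputs are reported, not raised. Local sensitivities are
central differences at ±10%: S = (ΔAUC/AUC)/(Δp/p) on the reference
individual under the standard regimen, for AUC0–12h and Cmax.

## Synthetic observations

The concentration–time profiles behind the nine literature studies are not
redistributable, so the validation stage is exercised against synthetic
stand-ins: each study design is simulated (optionally with perturbed
parameters) and multiplicative log-normal residual noise — the standard
assay error model — is applied per sample, default CV 15% (an assumption).
The default sampling schedule (2-min spacing to 30 min, then 15-min to 8 h)
is a guess at a typical design, since the true schedules are unprinted; it
is overridable per study. Each dataset carries a ground-truth sidecar, and
the tests close the loop by recovering a perturbed clearance via
non-compartmental dose/AUC to within 2% (dense, noiseless) and 5% (noisy,
8 replicates). Passing these tests shows the pipeline is self-consistent
under its own error model; it does not show the model reproduces real
observed profiles, which are outside the package's data.

## What the package reproduces, and what it does not

With the calibrations above, the package reproduces: the printed
predicted/observed exposure-ratio arithmetic exactly; the predicted AUClast
of the two long-infusion validation designs within ~1.5%; the three
published impairment-adjusted infusion rates within ~3% (process-mode
impairment); exposure equalization with Kruskal–Wallis p > 0.05 on AUC0–3h
and p < 0.0001 on AUC3–12h; zero subjects above the 6.5 µg/mL adverse
threshold in every adjusted arm; and healthy window compliance of ~94–95%
at the end of maintenance (the published claim is > 95%; the shortfall is a
direct consequence of the assumed variability magnitudes, whose 95% band
essentially coincides with the window).

Known limitations. (1) Recovery-time magnitudes are only partially
reproduced: the healthy median recovery is ~18 min (published: 22), and the
percent increases under impairment, while strictly ordered, are far steeper
than published (~+1500% for the severest group versus +550%). Within this
model family the combination {realized clearance pinned at 33.8 mL/min/kg by
the exposure table, 3-h median inside the window, recovery 22 → 143 min}
appears unattainable: the published recovery arithmetic implies an effective
distribution volume during washout that is inconsistent with any linear
flow-limited configuration of the printed inputs we could construct. The
discrepancy is reported, not tuned away. (2) The sensitivity ordering for
exposure (muscle volume above fat volume) is reversed here for AUC metrics
(−0.004 vs −0.021 on AUC0–12h) because the composition-based Kp scheme makes
fat the dominant distribution pool; for Cmax the published ordering does
hold (−0.004 vs −0.000). (3) No effect-site/CSF compartment, no
pharmacodynamics, no drug–drug interactions, no enzyme-level (CYP2B11)
kinetics, no covariates beyond body weight and impairment; bolus-only
literature designs are over-predicted by ~10% relative to their printed
predictions, consistent with those predictions being truncated at each
study's last observation while this package integrates to 24 h.
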