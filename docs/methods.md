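# Methods

This note documents the models and numerical choices behind `inosim`: the
backend contract and the analytic surrogate cell, biomarker extraction
conventions, the population calibration, the pore-block and dose–response
models, mechanism projection, classification rules, and what the test
suite does and does not establish.

## Backend contract and the analytic surrogate

Every pipeline stage consumes `BeatTraces` — one paced beat's membrane
potential (mV), intracellular free calcium (mM) and active tension (kPa)
on a strictly increasing time grid — produced by a backend implementing
`simulate(params: ModelParameters, config: SimulationConfig)`.
`ModelParameters` carries 11 multiplicative scale factors (sNa, sNaL,
sCaL, sTo, sKr, sKs, sK1, sNCX, sNaK, sJup, sJrel; baseline 1.0) and
three mechanism parameters: extracellular calcium `cao` (mM, baseline
1.8), a calcium-sensitivity scale `ca50_scale` and a myosin
attachment-rate scale `kuw_scale`. `SimulationConfig` carries the cycle
length (1000 ms, i.e. 1 Hz pacing), the output step `dt` (0.5 ms) and a
beat count used by ODE backends to reach diastolic steady state (500
beats for calibration-style runs, 1000 for drug runs); the surrogate is
algebraic and beat-invariant, so it honours only cycle length and `dt`.

The shipped backend is a phenomenological surrogate in three layers:

1. **Latent biomarker map.** Each biomarker is a baseline value times a
   product of power laws in the scale factors. The baselines are
   RMP −88 mV, V_peak 40 mV, dV/dt_max 300 mV/ms, APD40/50/90
   180/210/270 ms, CaiD 1e−4 mM, CT_peak 5e−4 mM, CTD50/90 250/420 ms,
   AT_ttp 150 ms, ATrt50/90 110/250 ms. The exponents (see
   `surrogate.EXPONENTS`) encode effect directions: hERG block prolongs
   the APD (sKr exponent −0.35 on all APDx); calcium-channel activation,
   NCX/NaK inhibition and extracellular calcium raise the calcium
   transient (CT_peak exponents +0.80 for sCaL, −0.35 for sNCX, −0.10 for
   sNaK, +0.70 for cao/1.8); SERCA activation speeds relaxation (negative
   exponents on CTD and ATrt). Tension is a Hill function of the
   calcium-transient peak,
   `AT_peak = 120 kPa · c²/(c² + k²) · g(kuw)`, with `c = CT_peak`,
   `k = 9.7468e−4 mM · ca50_scale` (fixed so the baseline cell develops
   25 kPa) and the saturating myosin gain `g = 3·kuw / (2·(kuw + 0.5))`
   (g(1) = 1, g(∞) = 1.5). The NaK exponent on CT_peak is deliberately
   mild (−0.10): pump inhibition acts indirectly through sodium loading,
   and the reference physiology shows only a modest tension gain from
   this mechanism, far smaller than direct calcium-pathway effects — this
   is what makes the glycoside EC50 effects unreachable in the mechanism
   scan, as observed. Diastolic calcium is clamped to at most 80% of the
   transient peak so that extreme calcium-entry block collapses both
   coherently.
2. **Abnormality injection.** Deterministic rules stand in for the
   arrhythmic dynamics an ODE model would produce: repolarisation failure
   when the latent APD90 reaches 95% of the cycle length; early
   afterdepolarisations (EAD) when the calcium-to-hERG balance
   sCaL/sKr ≥ 6; depolarisation abnormality when sNa ≤ 0.15.
3. **Trace synthesis.** Piecewise-analytic traces exhibit the latent
   biomarkers exactly up to grid resolution: the AP rises linearly at
   dV/dt_max from RMP to V_peak and declines through the APDx anchor
   points (V_x = V_peak − x/100·(V_peak−RMP) at t = APDx from the
   upstroke) by shape-preserving monotone (PCHIP) interpolation,
   returning to RMP 80 ms after APD90; calcium and tension are built
   analogously from their own anchors. The sampling grid is the uniform
   `dt` grid augmented with the anchor instants and a refined upstroke,
   so threshold crossings and the maximal slope are recovered exactly by
   linear interpolation. Anchor sequences that would outlast the beat are
   pinned at the cycle end. Flagged beats are deformed so the trace-level
   detector reproduces the latent flags (a +10 mV post-plateau bump for
   EADs; the tail held ≥ RMP+15 mV for repolarisation failure; the peak
   clipped to −5 mV for depolarisation abnormalities).

All constants are surrogate design values: they emulate directions and
saturations, not the quantitative output of any biophysical model.
Consequently the tests establish the correctness of the *pipeline* —
extraction, calibration, block arithmetic, fitting, projection,
classification — on a backend whose ground truth is known exactly; they
do not validate predictions of any particular ODE model, whose absolute
IC50s, calibration yield and mechanism scaling factors will differ.

## Biomarker extraction

Thresholds are crossed by linear interpolation between samples, ties
broken by the first crossing. Conventions the source protocols leave
open are fixed as follows: APDx runs from the instant of maximal upstroke
velocity to the first downward crossing; RMP is the pre-upstroke
diastolic value (median of samples before the maximal-slope interval);
CTDx runs from calcium upstroke onset, defined as the first upward
crossing of CaiD + 10% of the transient amplitude; tension onset is the
1%-amplitude crossing, relaxation times run from the tension peak. EAD
detection uses a +0.01 mV/ms derivative guard after the voltage peak;
"reaching the resting condition" means ending within 5 mV of the
diastolic reference; a depolarisation abnormality is a peak below 0 mV or
0 mV reached later than 100 ms after the stimulus. qNet is the
trapezoidal integral of the summed I_NaL, I_CaL, I_to, I_Kr, I_Ks and
I_K1 series over the beat (inward negative, µC/µF); the surrogate emits
no currents, so qNet is reported as unavailable rather than fabricated.

## Population calibration

The initial ensemble draws the 11 scale factors independently and
uniformly on [0.5, 1.5] (Latin hypercube available as an option;
mechanism parameters stay at baseline). A cell is accepted when its beat
carries no abnormality flag and every calibrated biomarker lies inside
its interval; the packaged intervals (`data/calibration_ranges.json`)
describe healthy human left-ventricular myocytes at 1 Hz. The baseline
cell is always prepended (id 0) and its own range check recorded in the
provenance. With the shipped intervals and the surrogate's variability,
the seed-7 ensemble of 1000 is accepted in full: the intervals bound the
surrogate's physiological spread (only the AT_peak interval [5, 60] kPa
can clip extreme corners), so the filter acts as a guard against
abnormal and non-physiological cells rather than as a strong selector —
an ODE backend with richer nonlinearities will see a material rejection
rate here. Every result records the range set, seed and a configuration
digest.

## Pore block and dose–response

Ion-channel inhibition is instantaneous pore block: the residual fraction
`1/(1 + (C/IC50)^h)` multiplies the matching conductance scale per
channel, independently across channels. State- or rate-dependent binding
is out of scope. Concentration grids are log-spaced at 4 points per
decade over 0.1×–100× EFTPC_max (13 points, always containing 1×); when
the top-of-grid median AT_peak fraction stays above 0.5 the grid extends
to 100,000× (grid density balances fit stability against run time).

Responses are per-model fractions of that same model's drug-free control,
so the sigmoid's upper asymptote is fixed at 1 and no top parameter is
fitted. The lower asymptote B captures the saturation of the negative
inotropic effect. The median route minimises squared deviations of the
sigmoid from per-concentration medians over non-flagged cells, with
multistart (Hill ∈ {0.5, 1, 2}, pIC50 initialised at the concentration
nearest the half-way crossing), pIC50 bounded two decades beyond the
grid, Hill ∈ (0, 10], B ∈ [0, 1). The Bayesian route models every
response with a normal likelihood around the sigmoid mean and one
isotropic noise SD across concentrations (the same cells are run at every
concentration, so concentration-dependent noise structure is not
assumed); priors are pIC50 ~ N(centre, 3) with the centre at the negative
log of the geometric-mean tested concentration in molar (keeping the
prior weakly informative across compounds whose EFTPCs span many
decades), Hill ~ N(1, 1) truncated positive, B ~ N(0, 0.25) truncated to
[0, 1), σ ~ HalfNormal(0.1). Sampling uses an affine-invariant ensemble
MCMC sampler run as 4 independent ensembles of 16 walkers (1000 warm-up
+ 1000 retained ensemble steps by default; the likelihood reduces to
per-concentration sufficient statistics, so a fit costs seconds);
ensembles are treated as chains for R-hat and effective sample size, and
any R-hat above 1.05 attaches a convergence warning to the result. IC50
summaries are computed on the transformed µM-scale samples. Compounds
whose median response never falls below 0.9 anywhere on the extended
grid are short-circuited as "no effect" and their IC50 reported as not
reached rather than extrapolated.

## Mechanism perturbation

Each mechanism multiplies its target parameter(s) on top of every cell's
own values: cao (range 1–3×), sCaL (1–3×), sJrel (1–3×), sJup (1–3×),
sNCX (0.1–1×), ca50_scale (0.1–1×), sNaK (0.1–1×), kuw_scale (1–5×), and
for β-adrenergic stimulation sCaL and sKs co-scaled (1–3× each). Scans
use 11 equally spaced factors (the control factor 1 is always included
and must return a fraction of 1). Because the scaling factors are
dose-independent the response need not be sigmoid, so a degree-2
polynomial is fitted by ordinary least squares to the median fractions
and the in vitro EC50 effect is solved for on that parabola by the
quadratic formula; roots must be real and inside the scanned range, and
when two are admissible the one nearest 1.0 (the smallest perturbation)
is chosen — the projection is exactly the parabola's intersection, so a
returned root re-evaluates to its target to 1e−9. Targets above the
curve's reach are reported as not reachable. The β-adrenergic projection
reports the sCaL factor: the tension response is calcium-driven and the
sKs contribution to tension is negligible in this model, as the 2-D
(sCaL × sKs) mean/SD grid shows. Phosphodiesterase-inhibitor and
adenylyl-cyclase modes of action are out of scope.

## Classification

Negative verdict: median AT_peak fraction below 0.75 at any concentration
up to 100× EFTPC_max; positive: above 1.25 within the same cap and never
below 0.75; otherwise neutral. The 100× cap is a design choice — effects
appearing only beyond it fall outside the exposure window the in vitro
comparison speaks to, and 100× the maximal free plasma concentration is
the customary exploratory bound in cardiac safety screening. Delta is
`floor(log10 IC50_insilico) − floor(log10 IC50_invitro)`; the floor
formalisation (rather than a rounded log-ratio) is what reproduces the
published per-compound decade classifications for all 22 reference pairs,
including those sitting just past a decade boundary. The agreement
percentage is rounded to the nearest integer. The packaged reference
table (`data/table2_reference.csv`) transcribes the published in vitro
and in silico contractility IC50s (µM) with their bracketed
IC50/EFTPC_max ratios; it is consumed as reference input by the
classification stage and never regenerated by the surrogate.

## Synthetic compound panels

The per-channel affinities of the reference compound set are not publicly
available, so `inosim.fixtures` generates synthetic panels in their
place: one pure blocker per channel at IC50 = EFTPC_max × {0.3, 3, 30}
(Hill coefficients cycled over {1.0, 0.8, 1.2}), and four multichannel
profiles with hERG-led block and calcium/sodium off-targets typical of
screening compounds. They exercise every code path (strong/weak block,
EAD onset under hERG block, grid extension, no-effect guard) but do not
reproduce any real compound's pharmacology, and conclusions drawn from
them are about the pipeline, not about drugs.

## Numerical choices and degenerate inputs

Non-positive scale factors, concentrations, IC50s or Hill coefficients
are rejected with typed errors; flat traces raise extraction errors;
inconsistent biomarker anchors raise synthesis errors; an empty
calibration result raises an error carrying per-biomarker rejection
counts. Per-model failures inside population runs and per-compound
failures inside the pipeline are recorded and do not abort the run. All
randomness flows from explicit seeds (population sampling, synthetic
data, MCMC); identical configurations give byte-identical non-MCMC
outputs and MCMC summaries reproducible exactly for a fixed seed.

## Problem sizes

The analysis drivers use a 1000-cell sampled population and run scans on
a 200-cell subsample; the test suite uses 25–120-cell populations,
7–11-point mechanism scans and reduced MCMC chains (2 ensembles,
250–600 warm-up steps) — sizes chosen so the full suite and the analysis
complete in minutes on a single CPU while leaving every statistical
check well-powered (e.g. the credible-interval coverage test uses 50
seeded replicates of the full 323-replicate × 13-concentration design).

## Known limitations

* The surrogate has no APD-mediated calcium loading, so pure hERG block
  never raises tension and biphasic multichannel responses (positive
  inotropy at low block turning negative at high block) cannot emerge;
  with a biophysical backend they can.
* Pore block is instantaneous and state-independent; metabolism and
  solubility are ignored.
* Only 1 Hz pacing is modelled; rate dependence, alternans and
  tissue-level effects are out of scope.
* The published absolute in silico IC50s, the 322-of-1000 calibration
  yield and the published mechanism scaling factors depend on the
  withheld biophysical model and are shipped as reference data only.
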