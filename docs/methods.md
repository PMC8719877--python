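# Methods

`adipostat` implements a complete measurement-to-inference chain for
quantifying nightly torpor use in small endotherms (built around captive
ruby-throated hummingbirds, *Archilochus colubris*) and its relationship to
body fat across the breeding-to-migration transition. This note documents
the models, the numerical choices, and what the synthetic-data tests do and
do not establish.

## 1. Gas exchange (respirometry)

Push-mode flow-through respirometry meters dry incurrent air into the
chamber at a known rate FRᵢ (mL·min⁻¹, converted to dry-gas STP) and
subsamples the excurrent stream. At steady state the chamber satisfies

    FRₑ  = FRᵢ − V̇O₂ + V̇CO₂
    FeO₂  = (FRᵢ·FiO₂  − V̇O₂) / FRₑ
    FeCO₂ = (FRᵢ·FiCO₂ + V̇CO₂) / FRₑ

Eliminating the unknown excurrent flow gives the closed-form inversion

    FRₑ  = FRᵢ (1 − FiO₂ − FiCO₂) / (1 − FeO₂ − FeCO₂)
    V̇O₂  = FRᵢ·FiO₂ − FeO₂·FRₑ,    V̇CO₂ = FeCO₂·FRₑ − FRᵢ·FiCO₂

verified in the test-suite against a brute-force numerical solution of the
balance and against the forward simulator (round-trip error < 1e-12 in
practice). STP correction removes water vapour by partial-pressure
dilution, `flow·(bp − wvp)/bp`, then rescales by ideal-gas ratios to the
configurable reference (default 0 °C, 101.325 kPa). Per-second rates are
averaged into whole clock minutes from lights-off; a partial trailing
minute is dropped. An optional two-point linear baseline correction is
available (off by default) for traces recorded with animal-free baselines.

Incurrent fractions default to FiO₂ = 0.2095, FiCO₂ = 0.0004. Pull-mode
(downstream-metered) equations and multiplexed chambers are out of scope.

## 2. Energetics and the fat ledger

The respiratory exchange ratio RER = V̇CO₂/V̇O₂ is clamped to
[0.71, 1.0] (pure fat to pure carbohydrate oxidation) before use; clamped
minutes are counted, and a night where more than 20% of minutes were
clamped is flagged as bookkeeping-suspect. Energy expenditure uses the
oxyjoule equivalent

    E_rate = (16 + 5.164·RER) · V̇O₂      [J·min⁻¹]

integrated by the trapezoidal rule (kJ). Fat-mass equivalents use
37 kJ·g⁻¹ throughout: the instantaneous fat store is evening fat minus
cumulative expenditure / 37, and the fat content at torpor entry is

    100 · (evening fat − E_cum(entry)/37) / morning body mass    [%]

The denominator is the *morning* body mass — the convention is kept
exactly for comparability. Lean-mass catabolism is ignored in the ledger;
negative instantaneous fat is flagged rather than clipped.

## 3. Metabolic-state annotation

Each minute is labelled normo-pre / entry / torpor / arousal / normo-post
from the slope of a smoothed V̇O₂ trace.

**Smoother.** The load-bearing primitive is a penalized cubic smoothing
spline whose 0-to-1 smoothing parameter maps to the roughness penalty via
`λ = r·256^(3·span−1)` with `r = tr(XᵀX)/tr(Ω)` on a unit-scaled abscissa
(the `spar` convention of classical smoothing-spline implementations).
A degree-2 loess with span-as-fraction-of-points semantics is available as
an alternative, but at the default parameters it smears 20–40-minute
transitions over hundreds of minutes and cannot localize bout boundaries
to the ±3-minute level the annotation is held to; the spline can.

**Procedure** (defaults in parentheses):

1. Smooth the whole night (span 0.6) and find the *preliminary arousal
   point*: the first minute after the global minimum with slope above the
   arousal cut-off (0.005 mL·min⁻¹·min⁻¹). Absent → no-torpor night.
   This point only needs to land between entry end and the arousal peak;
   it splits the night into separately smoothed segments (span 0.6 each).
2. On the preliminary slope, the start of the *dominant* decline below the
   entry demarcation (−0.003) ends the normothermic reference window.
   Using the dominant (largest-drop) run rather than the first
   sub-threshold minute makes the demarcation robust to noise dips.
3. Entry = the contiguous pre-segment run of negative slopes whose
   magnitude exceeds mean + 2·SD of the normo-pre slope magnitudes,
   choosing the run with the largest smoothed drop.
4. Depth gate: the stable phase must sit below 0.5× the normothermic
   level, otherwise the dip is not torpor. This is the specificity
   guard — on torpor-free nights the false-bout rate is 0/200 in the
   acceptance sweep; without a depth criterion slope noise alone can
   fabricate bouts.
5. Arousal = the post-segment run of slopes above mean + 5·SD of the
   torpid-phase slope magnitudes with the largest total rise; it ends at
   peak V̇O₂ (the end of the rise run, i.e. the first maximum when the
   peak plateaus). Everything after is normo-post.

SD thresholds are computed on smoothed slopes. Torpor duration runs from
the start of entry to the start of arousal (entry included, arousal
excluded); entry time is also expressed as a fraction of the night.
Multi-bout nights (a second large decline after arousal) are flagged and
the first bout is reported. Nights shorter than 3 h are rejected.

## 4. Body-mass period segmentation

The morning-mass series is smoothed on the calendar-day axis (span 0.35)
and differentiated (`np.gradient`). The bird-specific cut-off is 75% of
the maximum derivative; the fattening period is the contiguous above-cutoff
run, days before it are breeding, days after are migration. Two
refinements make the window and its magnitude unbiased against generator
truth: above-cutoff runs separated by dips that stay above 0.5× the
cutoff are bridged, and the chosen run is extended outward to plateau
contact (derivative below 0.25× cutoff). Without the extension the strict
cutoff rule excludes the ramp's corner days and under-measures the gain by
roughly two days of slope (≈0.15 g on typical ramps).

Non-fatteners: a bird is a non-fattener when the maximum slope is below an
absolute floor (0.01 g·day⁻¹) *or* the best candidate's smoothed gain is
below a magnitude floor (0.20 g, configurable). The magnitude floor does
the real discrimination — with a smoother tight enough to localize ramps,
derivative noise on a flat series exceeds 0.01 g·day⁻¹ routinely, while
noise excursions never approach the 0.34–0.90 g gains of true fatteners.

Manual bound adjustments (used in the field when automatic bounds clearly
disagree with the curve) are supported and leave an audit record; the
fattening summary (magnitude, relative gain, duration) is always measured
on the smoothed trace at the current bounds.

## 5. Night records, propensity, and the adipostat rule

One tidy row per bird-night joins composition (replicate-mean QMR
fat/lean/mass, evening and morning), the annotation, and the energy ledger:
evening fat content, torpor occurrence, entry time and fraction, duration,
fat content at entry, pre-torpor energy, whole-night energy, and overnight
fat loss (= total energy / 37, in mg). Torpor propensity is the percentage
of a bird's focal nights with torpor, per period, summarized across birds
as mean ± SE.

**Adipostat compliance.** The two-clause rule: a night complies when the
bird either (a) entered torpor while its instantaneous fat content was at
the threshold (5% of body mass, tolerance band ±1.5 percentage points), or
(b) stayed normothermic and its fat content first crossed the threshold
after the late-night cut-off (75% of the night) or never crossed it.
The band is a package choice (the threshold is only ever stated as
"approximately 5%") and is configurable and reported with results.

## 6. Statistical battery

The statistics layer is deliberately a thin declarative contract over
established machinery: gaussian mixed models via `statsmodels` `MixedLM`
(random intercept per bird), binomial-logit mixed models via the
variational `BinomialBayesMixedGLM` (a Laplace-fit GLMM in the `lme4`
style is not available in the Python stack; the variational posterior
means/SDs play the role of coefficient estimates and are sign- and
scale-calibrated in the tests), repeated-measures correlation via
`pingouin.rm_corr`, and Tukey-adjusted pairwise contrasts computed from
estimated marginal means on a reference grid (covariates at their means,
studentized-range p-values).

Candidate fixed-effect structures are compared by ML-fit AIC: the lowest
AIC wins only if it beats the others by ≥2 points, otherwise the most
parsimonious model within 2 points is retained. AIC selection applies to
the gaussian family; binomial specs are fitted as declared. Singular fits
are reported and dropped from the candidate set. Non-fattener birds are
excluded from the seasonal models (exclusion list is config-driven).
α = 0.05.

## 7. Synthetic data: what it emulates, what it does not

The night simulator drives a minute-level V̇O₂ profile from a decision
rule — `adipostat(threshold, late_cutoff)`, `fixed_normo(h)`, `always_at(t)`
or `never` — with linear entry/arousal ramps (exponential shapes are not
modelled; the ±3-min boundary tolerance absorbs the shape choice), an RER
profile declining from 0.85 to 0.71 over the first two hours, and a fat
ledger integrated from the oxyjoule rate. Defaults (normothermic
0.60 mL·min⁻¹, torpid 0.06, 150 mL·min⁻¹ flow at 20 °C, arousal completing
≈40 min before lights-on) put the emergent quantities where the study
conditions put them: ≈190 mg of fat per normothermic 10-h night and
≈17 mg saved per torpor hour. The adipostat rule thresholds instantaneous
fat against *morning* mass through a short fixed-point iteration (morning
mass depends on expenditure, which depends on entry time; converges to
<1 mg in 3 steps). Gas traces are emitted at 1 Hz through the forward
chamber balance, with noise proportional to the instantaneous level
(default 2%) or flat at a fraction of the normothermic level ("absolute"
mode, used by the recovery sweeps at up to 5%). Replicate QMR noise:
0.01 g fat, 0.03 g lean per scan, means of 4 scans. Chamber washout
dynamics (volume mixing) are omitted by default.

The season simulator gives each bird a plateau–ramp–plateau morning-mass
trajectory (breeding plateau 2.77 ± 0.15 g across birds; gains uniform on
0.34–0.90 g over 6–18 days starting in the late season; 13 of 16 birds
fatten), nights lengthening 9 → 12 h across the season, evening fat
drawn per period (breeding 9 ± 2.5%, migration 33 ± 3%), the adipostat
rule in breeding and a fixed normothermic period (4 ± 0.5 h) with a
propensity logit (positive in fat and night length) afterwards, and
night-to-night metabolic-level variation (SD 0.04 mL·min⁻¹ normothermic) —
without that last ingredient overnight fat loss is a deterministic
function of duration and the mixed models are degenerate. Daily plateau
mass noise defaults to 0.008 g so that even the shallowest ramps
(≈0.019 g·day⁻¹) stay at least 2× the noise SD, the regime the
derivative-threshold segmentation is designed for. Real morning masses
wobble more than this; on real data the shallowest fatteners are exactly
the cases where automatic bounds may need the manual-adjustment path.

**What passing tests show** — that the algorithms recover the truth of
trapezoidal bouts and ramps under Gaussian noise at realistic amplitudes,
and that the estimators are calibrated (type-I error ≈5%). **What they do
not show** — robustness to chamber washout smearing, non-Gaussian analyzer
artifacts (drift, steps), disturbed/aborted arousals, multi-bout nights
(detected and flagged, not resolved), or mass trajectories with multiple
fattening episodes.

## 8. Reproducibility and problem sizes

Every stochastic path takes a seed; identical seeds give byte-identical
outputs. The recovery sweeps use 200 nights / 200 trajectories / 100
model seeds, sized to estimate rates to a couple of percentage points
while keeping a full desk-scale evaluation run in the low minutes;
`scripts/acceptance.py` recomputes everything from scratch from a single
command-line seed.
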