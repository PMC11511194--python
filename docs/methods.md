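# Methods

## Scope and model structure

`pbbmkit` implements a mechanistic oral-absorption workflow for weakly
basic, poorly water-soluble drugs in immediate-release formulations. The
chain is: biorelevant solubility calibration → diffusion-layer-model
(DLM) dissolution with a particle population balance → two-stage
gastric-to-intestinal transfer with supersaturation/precipitation
kinetics → multi-compartment GI absorption → compartmental disposition
with population variability → food-effect and predicted/observed
diagnostics. Formulations are treated as instantly dispersed API
particles (no disintegration model); hydrodynamics are not modeled
(paddle rpm is metadata).

## Solubility model

Total solubility in a medium of pH, bile-salt concentration [BS] and
water concentration C_H2O (55,500 mM):

    STot = So·Soscalar_m·(1 + [BS]/C_H2O·Km:w,u)
         + Si·(1 + [BS]/C_H2O·Km:w,i) + Sbound,excip

* `So` (mg/mL): intrinsic (un-ionized) solubility.
* `Si`: ionized aqueous solubility, `So·f_ion/f_un` from the
  Henderson–Hasselbalch fractions, **capped** so `So + Si ≤ So·SF`. The
  cap is applied to the aqueous ionized term before micelle enhancement;
  it keeps `Si` finite at gastric pH and expresses the common-ion /
  salt-form limit. `SF ≥ 1` is dimensionless.
* `Soscalar_m`: per-medium free multiplier (default 1.0), intended for
  biorelevant media whose surfactants solubilize beyond the bile term.
  Without it, a gastric (low-bile) solubility exceeding the intestinal
  (high-bile) one is infeasible for a neutral-at-both-pH compound with
  non-negative `Km:w` — the calibration of the worked examples relies on
  this term.
* `Km:w,u / Km:w,i` (dimensionless): micelle/buffer partition
  coefficients of the un-ionized and ionized species. When a design
  cannot separate them, `Km:w,i` can be tied to `Km:w,u/10` (flagged).

Multi-pKa drugs: basic and acidic groups contribute independently, with
successive same-kind pKa values treated as cumulative steps.

Calibration is weighted least squares on `log(pred) − log(obs)`
(solubilities span orders of magnitude across pH), with seeded
multi-starts, per-parameter bounds, at-bound and identifiability flags,
and a medium-exclusion mechanism for points outside the model family
(e.g., a very acidic buffer whose solubility the single-SF form cannot
reach). Identifiability requires ≥ 2 bile-containing media to free a
`Km:w`, and a design whose points span the capped and uncapped pH
regimes to separate `So` from `SF`; degenerate designs either raise or
flag, never silently default.

## Particle size and dissolution

Laser-diffraction quantiles D(0.1)/D(0.5)/D(0.9) are fitted by least
squares in log space at z = ∓1.2816, 0, giving geometric mean/SD and an
RMS residual (zero iff d50 = √(d10·d90)). Near-monodisperse triples
(geometric SD < 1.05) warn. A distribution plus dose discretizes into
equal volume-fraction bins between the 0.5th and 99.5th volume
percentile, each bin a cohort of identical spheres; total bin volume
equals dose/density exactly by construction. 20 bins is the default;
profiles from 20 vs 200 bins agree within 1%.

Per-bin dissolution follows the amended Wang–Flanagan diffusion layer
form with `h_eff = min(a, 30 µm)` and `S_surface = STot` of the bulk
medium (no surface microclimate pH model — a known limitation for
salts). `D_eff` defaults to the molecular-weight correlation
`9.9e-5·MW^-0.453` cm²/s, user-overridable. `DLM_scalar` (default 1) is
the fitted empirical scalar; per-profile estimates are averaged across
vessels/media before use in vivo, and the fit report includes a ±2-fold
sensitivity table on the SSE. An optional `SF` refit during dissolution
fitting accommodates excipient effects; both the solubility-stage and
dissolution-stage values are reported when it is used.

## Transfer and precipitation

The two-chamber apparatus: 300 mL gastric medium empties first-order
(half-life 15 min = average fasted gastric emptying) into an intestinal
chamber; volume, dissolved drug and suspended solid transfer in
proportion to the volumetric flow (well-mixed assumption). The
compensation feed of the physical apparatus is idealized as holding the
intestinal chamber at the target medium's pH/bile while its volume ramps
as `V_i(t) = V_final − V_g(t)`.

Precipitation is single first-order kinetics on the supersaturated
amount: `J = PRC·max(0, C − STot)·V`, active while a hysteretic trigger
holds (on when `C/STot > CSC`, off when `C/STot ≤ 1`; crystal growth
continues below the nucleation threshold once nuclei exist). PRC is in
1/h. No classical nucleation theory or precipitate particle-number
dynamics are modeled. Precipitate may redissolve through the DLM as
monodisperse 1 µm particles (configurable off). The convention
`CSC = 1.001, PRC = 1e-4` encodes "no precipitation": simulations with
these values match precipitation-disabled runs to well under 0.1%.

The decision rule (`detect_precipitation`) declares precipitation when
the post-peak intestinal concentration sustains a decline exceeding the
noise band (3× replicate SD, or 5% of peak without an SD) for ≥ 10 min;
fewer than 6 post-transfer points is an explicit "inconclusive".
`fit_precipitation` refuses non-detected profiles and recommends the
minimal values — an anti-overparameterization guard; otherwise it fits
(CSC, PRC) by bounded multi-start least squares (CSC ∈ [1.001, 10],
PRC ∈ [1e-4, 100]/h, ≥ 8 seeded starts by default).

A geometric consequence worth noting: with the 300 mL → 500 mL layout,
the intestinal concentration is bounded by
`STot_gastric·V_gastric/V_final`, so a drug whose gastric and intestinal
solubilities are within ~2-fold of each other cannot supersaturate in
this idealized apparatus. The bundled precipitating archetype therefore
carries a steeply pH-dependent solubility profile (gastric ≈ 12,
intestinal ≈ 2 µg/mL).

## GI absorption

Nine compartments (stomach, duodenum, jejunum 1–2, ileum 1–4, colon)
with first-order transit (stomach by emptying half-life, others by mean
residence time; colon exits to stool). Per compartment, the DLM acts
against a local STot recomputed from compartment pH and bile with the
drug's calibrated parameters; the per-medium `Soscalar` maps by segment
family (stomach → FaSSGF scalar; small intestine → FaSSIF fasted /
FeSSIF fed; colon → the small-intestine scalar). Precipitation follows
the transfer-module rules in all non-gastric compartments. Absorption
from the small intestine is `J = (2·Peff/R)·C·V` (cylindrical
surface-to-volume); stomach and colon absorption are off by default.
There are no transporters, gut-wall metabolism, lymphatic uptake, or
bicarbonate dynamics.

Physiology presets (all package defaults unless anchored in vitro, and
every value overridable with provenance recorded): fasted — gastric pH
1.6, emptying half-life 15 min, small-intestine pH 6.5 with 3 mM bile;
fed — initial gastric pH 5.0 relaxing to 1.6 with a 1 h half-life,
emptying half-life 60 min, 500 mL gastric fluid, small-intestine pH 5.8
with 15 mM bile. Segment volumes, radii and residence times are standard
human values (fasted small-intestinal fluid ≈ 135 mL total, SI transit
≈ 3.5 h, colon ≈ 18 h).

Papp → Peff uses ordinary least squares of log10(Peff) on log10(Papp)
over a user-supplied calibration set (≥ 3 pairs), reporting slope,
intercept and R²; a non-positive slope is flagged. Fasted/fed runs use
the FaSSIF/FeSSIF PAMPA Papp respectively — the permeability-module swap
that drives food-effect predictions for permeability-limited compounds.

## Disposition and population simulation

Disposition is 1 or 2 linear compartments parameterized directly
(vc, vp, q, cl) — not predicted from tissue composition — with a global
`kp_scalar` multiplying distribution volumes as the single tuning knob,
and well-stirred hepatic first pass `F_h = 1 − CL/Q_h` (CL read as
hepatic blood clearance; `Q_h` default 90 L/h). The portal flux from the
GI model is differentiated from the cumulative absorbed curve with a
monotone (PCHIP) spline. PK metrics use the linear-up/log-down
trapezoid; AUC∞ extrapolates from a log-linear fit of the last ≥ 3
positive points and reports the extrapolated fraction. Disposition
fitting is 1/ŷ-weighted multi-start least squares with an
identifiability guard: `kp_scalar` and a distribution volume cannot be
freed together (pure scale confounding).

Population simulation draws lognormal inter-individual variability
(`σ = √ln(1 + CV²)`) per subject from a seeded generator; default CVs
are 30% on clearance, 30% on gastric emptying, 25% on bile. The 90%
band is the 5th–95th percentile across per-trial mean profiles with the
10 trials × 10 subjects reporting convention. A caveat established
empirically here: percentiles estimated from only 10 trial means are
biased narrow, giving ~82% realized coverage of new trial means; the
calibration test therefore checks coverage against a 100-trial band
(~90%), while 10×10 remains the reporting default.

## Validation metrics

Predicted/observed AUC and Cmax ratios are flagged against the 0.5–2.0
("within 2-fold") and 0.80–1.25 bands, strictly inside; to avoid
grid-density bias the predicted profile is restricted to the observed
timepoints and both use the same trapezoid. Both AUC(0–t) and AUC∞
ratios are reported. Food effect is the fed/fasted ratio pair;
classification is "none" within 0.8–1.25 on both metrics, otherwise
positive/negative/mixed. CI coverage is the fraction of observed points
inside the linearly interpolated band.

## Synthetic data

The generator evaluates the forward models and adds seeded noise
(multiplicative lognormal by CV%, or additive Gaussian): triplicate
equilibrium solubilities per medium, 1-min vessel dissolution profiles,
two-chamber transfer series, and subject-level concentration–time data
drawn through the population model with observation noise on top. It
emulates assay magnitude and sampling layout, not instrument artifacts:
no drift, no LOQ censoring, no correlated residuals, and the transfer
"observations" inherit the compensation-feed idealization. Passing
round-trip tests therefore demonstrates internal consistency of the
estimators under the stated noise model, not robustness to real assay
pathology. Three archetypes are bundled: `rivaroxaban_like`
(pH-insensitive, non-precipitating, positive food effect via bile and
permeability), `ticagrelor_like` (bile-sensitive, high intestinal
solubility, measured FaSSIF/FeSSIF Papp), and `pb201_like` (steeply
pH-dependent, precipitating; a synthetic construction, see the transfer
section).

## Numerical choices

* Units internally: mg, mL, min, µm/cm in vitro; h, L, ng/mL for PK.
  Serialized columns always carry unit suffixes.
* Vessel and transfer ODEs: LSODA, rtol 1e-8, atol 1e-12 mg, output on
  a 1-min grid matching per-minute fiber-optic sampling. GI: BDF with a
  hand-derived analytic Jacobian of the transit/dissolution/precipitation
  system (rtol 1e-7, atol 1e-10); particle counts are stored as
  fractions of the initial bin count so all states share a comparable
  absolute scale.
* The DLM rate is non-Lipschitz at bin depletion (flux ∝ m^(1/3));
  every simulator tapers the flux smoothly by `m²/(m² + (1e-5·m0)²)`,
  leaving a ≤ 1e-5 relative mass residual per bin — far below all stated
  tolerances — and restoring solver stability.
* Hysteretic precipitation triggers are integrated piecewise with
  terminal events at the CSC (arming) and saturation (disarming)
  crossings; trigger states are reconciled at segment starts and a
  switch-count guard detects chattering.
* Mass balance (solid + dissolved + precipitated + absorbed + excreted
  = dose) is identically zero in every right-hand side, so conservation
  holds to solver tolerance (observed ≤ 1e-12 relative, asserted at
  1e-6).
* Bins shrink at fixed particle count; there is no birth/death beyond
  the depletion taper. Transferred particles merge into the receiving
  compartment's bin as (count, mass) with radius derived from the ratio,
  which averages resident and incoming radii within a bin.

## Problem sizes used in the shipped tests

Round-trip and property tests run on deliberately small configurations
chosen as the package's own regression scale: 3–8 particle bins for GI
scenarios (20-bin results differ by < 0.1% in fa), 12–24 h simulated
horizons, 10–20 seeded replicates for noisy-recovery medians, and
pre-dissolved transfer scenarios (no solid bins) for precipitation
fitting studies, where the kinetics of interest are fully expressed at a
fraction of the cost.

## Known limitations

* No surface-pH (microclimate) model: `S_surface = STot(bulk)`, so
  salt-form dissolution enhancement is not captured.
* The compensation-feed idealization holds intestinal composition
  exactly at the target medium; real feeds approach it asymptotically.
* Precipitation is one first-order pool; ripening, polymorph conversion
  and precipitate size distributions are out of scope.
* Disposition is deliberately reduced (no tissue-composition Vss/Kp
  prediction, no enzyme-specific metabolism or DDI); `kp_scalar` and CL
  must come from fitting or user input.
* Fed-state gastric pH dynamics (5.0 → 1.6, half-life 1 h) and segment
  fluid volumes are package defaults, flagged as such in provenance
  notes, not measured quantities.
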