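# Methods

This note documents the models, parameter choices and numerical
conventions behind `accelcal`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Feature extraction: SVM-gs counts

The accelerometer count is the gravity-subtracted signal vector magnitude:
per sample `|√(x²+y²+z²) − 1|` (in g), summed over all samples in a
half-open 1 s epoch aligned to the recording start. Conventions:

- **Absolute value, not truncation at zero**, so dynamic accelerations of
  0.9 g and 1.1 g contribute equally; this matches the post-processing
  convention of the raw-acceleration monitors this pipeline targets and
  makes the count symmetric in the deviation's sign.
- **Sum, not mean**, over samples within the epoch — this is what gives
  cut-points their published magnitude (units g·s per 1 s epoch; published
  tables print the unit as "g/s").
- A trailing epoch not fully covered by the recording is dropped rather
  than scaled; epochs containing no samples (gaps between bouts) are
  omitted, never reported as zero. No resampling or band-pass filtering is
  applied; irregular timestamps are binned by epoch membership.

## Energy expenditure and METs

Energy expenditure comes from the Weir equation,
`EE [kcal/min] = 3.941·V̇O₂ + 1.106·V̇CO₂` (L/min). Breaths are assigned to
10 s epochs by timestamp membership (no interpolation); an epoch's EE is
the mean over its breaths, and epochs without breaths are marked missing,
not zero. METs divide epoch EE by the *predicted* resting metabolic rate
from the Schofield weight-only equations (slope·mass + intercept, MJ/day;
sex-specific age bands 3–10 and 10–18 y, the boundary age in the upper
band), converted at 1 MJ = 239.006 kcal and 1440 min/day. A fixed
4.85 kcal/L·O₂ conversion is available as a sensitivity switch
(`ee_rate`'s Weir constants are the default used throughout).

MET bands are half-open — sedentary [0, 1.5), light [1.5, 3), moderate
[3, 6), vigorous [6, ∞) — closing the gaps of the printed scheme
(…2.99 | 3…); exactly one band contains any nonnegative MET.

## Protocol alignment

Each activity bout must last ≥ 240 s; its analysis window is
[start+120 s, start+240 s) — the first two minutes (on-transient) and the
final minute are discarded. Steady state is screened by the coefficient of
variation of in-window METs (pass if CV ≤ 0.10 by default); the screen is
*advisory* metadata and never drops bouts, since by-eye inspection in
laboratory practice rarely excludes any. Each 1 s count epoch inside a
window inherits the MET category of the 10 s epoch containing its start;
1 s rows whose calorimetry epoch is missing are excluded and counted in a
join report. All participants' epochs are pooled for the statistics.
(Aggregating counts to 10 s instead is a documented alternative the API
leaves to the caller; epoch-level pooling is the default analysed here.)

## Cut-point derivation

Per wear location:

- **Sedentary ROC**: positive class = sedentary epochs, *low* counts
  predict positive. Internally scores are negated so one convention
  (score ≥ threshold ⇒ positive) serves both directions; the reported
  cut-point is on the original count scale with rule count ≤ cut.
- **Moderate ROC**: positive = moderate, negatives = sedentary + light
  (one-vs-rest), high counts positive, rule count ≥ cut.
- **AUC** is the Mann–Whitney pair statistic with ties counted ½, computed
  from integer pair counts so it equals brute-force pair enumeration
  exactly. The 95% CI uses the DeLong structural-components variance
  (cross-checked against R pROC to 1e-9 on a frozen fixture), truncated to
  [0, 1]; perfect separation yields a zero-width interval. Grading:
  ≥ 0.90 excellent, 0.80–0.89 good, 0.70–0.79 fair, < 0.70 poor
  (half-open, AUC = 1 excellent).
- **Youden cut-point**: candidates are the unique observed scores; the
  candidate maximising J = Se + Sp − 1 wins, ties broken by larger Se,
  then the smaller direction-normalised threshold. The winner is rounded
  to the 0.1 g·s reporting grid and **Se/Sp are recomputed at the rounded
  cut-point** under the final boundary rules. This sacrifices a sliver of
  J but makes the reported numbers exactly self-consistent: applying a
  reported cut-point set back to its own calibration table reproduces the
  reported Se/Sp bit for bit.
- **Light band**: (sedentary cut + 0.1, moderate cut − 0.1); light gets no
  AUC/Se/Sp of its own in calibration (the band is defined by the other
  two cut-points), and the report writer prints it accordingly.
- **FMS ROC**: positive = epochs from fundamental-movement-skill bouts
  (passing, dribbling, throwing), high counts positive — same machinery.
- **Criterion validity**: Spearman's rho (midrank ties, large-sample p)
  between counts and METs; a Shapiro–Wilk screen (subsampled at n > 5000)
  records that pooled counts are non-normal, which is why rank
  correlation is reported.

## Cross-validation of fixed cut-points

A fixed cut-point set classifies counts by: ≤ sedentary cut → sedentary,
≥ moderate cut → moderate, otherwise light (a partition by construction).
Validation on an independent labelled table reports, per location and
intensity, Se/Sp of that fixed rule, plus the one-vs-rest ROC AUC of the
raw counts on the new data (low-counts-positive for sedentary). A fixed
threshold has no AUC of its own; the AUC column measures how discriminable
each intensity remains in the new sample. **Caveat**: for the middle
(light) band a monotone score cannot represent band membership, so the
light AUC on raw counts is ill-posed — it typically lands below 0.5 here —
and is reported only for comparability with what standard ROC software
outputs, never as a quality measure of the band itself.

## Synthetic study generator

The generator emulates the two study designs end to end. Defaults are the
calibration conditions: 20 boys aged 8–12 (10.1 ± 1.5 y, 36.5 ± 7.5 kg,
1.4 ± 0.2 m, truncated normals), five wear locations, seven 5 min bouts
(lying, standing, medium run 4.5 km/h, football passing at 10 and
20 passes/min, dribbling at 6 and 12 circuits/min) with 5 min rests, 80 Hz
sampling, breaths ~3 s apart. The validation configuration mirrors the
independent cohort: 30 children (16 boys, 14 girls, 9.4 ± 1.4 y), four
locations (no non-dominant ankle), six bouts including throwing-catching.

- **Target METs** are placeholders at the midpoints of the band each bout
  is meant to occupy (lying 1.0, standing 1.25; slow-cadence skills 2.0 and
  2.5; run 4.5, fast-cadence skills 3.5 and 4.0) — the source protocol
  reports measured bout METs only graphically, so these are design values,
  not measurements.
- **Counts**: expected epoch count = base gain(location) ×
  activity gain(location) × subject gain × (MET − 1), with base gains
  (waist 4, wrists 5–6, ankles 16–30 g·s per MET) sized so cut-points land
  at realistic magnitudes (waist ≈ units, ankles ≈ tens), and skill bouts
  loading ankles (passing/dribbling) or wrists (throwing) preferentially.
  Noise is lognormal (σ = 0.6, mean-preserving) times the expected count,
  plus an additive Gaussian floor (sd 0.8 g·s), clipped at zero; the
  per-child gain is lognormal (σ = 0.35). These values were chosen once
  for realism: they reproduce the qualitative pattern real calibrations
  report (sedentary discrimination excellent ≈ 0.96–0.99, moderate good
  ≈ 0.89–0.91, FMS fair/poor, pooled rho ≈ 0.8) instead of the near-perfect
  separation a low-noise toy would show. A pure-Gaussian count mode exists
  so tests can compare empirical AUCs with the binormal closed form
  Φ(δ/(σ√2)).
- **Raw signal**: each sample's dynamic deviation is count/samples-per-
  epoch in a uniformly random 3-d direction on top of 1 g, so epoching the
  raw stream recovers the drawn counts exactly; the model makes no attempt
  at biomechanically realistic limb trajectories.
- **Breaths**: gamma renewal process (shape 4, mean 3 s). V̇O₂ rises from
  rest along a mono-exponential on-kinetic (τ = 30 s) *rescaled to reach
  the steady state exactly at 120 s* — only the final two minutes are
  analysed, so the rise shape is irrelevant downstream, and the rescaling
  makes the zero-noise steady state exactly constant. Steady-state V̇O₂ is
  set so Weir EE equals target MET × predicted RMR (RER drawn per bout
  from [0.80, 0.95]); multiplicative Gaussian noise (5% default) is
  applied per breath.
- **Seeding**: a single master seed; every sub-stream is keyed by
  (seed, stage, participant id, location, activity), so outputs are
  bit-reproducible and deleting one bout never shifts another's data.

**What passing tests show — and don't.** The generator satisfies the
assumptions the analysis makes (monotone count–intensity relation,
steady-state windows, independent epochs within bouts). Passing parameter
recovery and cross-validation tests therefore demonstrates correctness of
the *statistics and plumbing*, not the field validity of any particular
cut-point: real children produce autocorrelated, activity-patterned
signals, device miscalibration and clock drift, and between-day
variability that this model deliberately omits (as are non-wear, heart
rate, and free-living behaviour).

## Numerical conventions and degenerate inputs

Ties in AUC count ½ and all tied candidates are evaluated in the Youden
scan; count ratios are formed directly (k/m) so equal ratios compare
bit-identically. If all scores are equal the single candidate yields J = 0
(degenerate separation, Se 100/Sp 0). DeLong variance uses ddof = 1 and is
0 for single-member classes. Shapiro–Wilk subsampling uses a fixed
auxiliary seed. Cut-point and band values are rounded via integer grid
arithmetic to avoid float drift. Problem sizes in the test suite are
reduced (2–6 participants, 10–40 Hz) where the property under test does
not depend on scale; the acceptance script runs both cohorts at full study
scale.

## Known limitations

- Cut-points from synthetic data are illustrative; only the published
  reference cut-points in `accelcal.reference` should be applied to real
  children.
- The MET denominator is predicted RMR; protocols using measured supine
  VO₂ as the baseline will yield systematically different METs.
- Vigorous-intensity cut-points are out of scope (no protocol bout exceeds
  6 METs), as are device binary formats and automatic bout detection.
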