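# Methods

This note documents the models, conventions and design choices behind
`metaboqc`, in the order the pipeline applies them.

## Data model

A `FeatureTable` holds a features × injections intensity matrix with feature
metadata (m/z, retention time, assay mode, optional annotation) and an
injection manifest (run index, plate, role, sample id, dilution fold).  NaN
marks an undetected cell.  A literal 0 is kept as 0 in arithmetic but counts
as *undetected* for RQC reliability, because a zero intensity carries no
quantitative signal; this deliberately treats "missing" and "zero" the same
way for reliability purposes while preserving them distinctly in the data.
Run indices are 0-based and global across plates of one analytical sequence,
since the drift model needs a single total order.

## Drift normalization

**Model.**  Instrument sensitivity for each feature is assumed to drift
linearly between two neighbouring *reliable* RQC injections.  With flanking
intensities M1, M2 and S study injections in the segment, the correction is

    y = x_n · M1 / ( M1 + n·(M2 − M1)/(S + 1) ).

The canonical design has S = 8 (divisor 9); the divisor generalizes to S + 1
when unreliable-RQC exclusion merges segments, because the equation is
endpoint interpolation.

**Reliability.**  An RQC with ≥ 1,000 undetectable features (strictly
"fewer than" passes) is unreliable and skipped; its study injections fall
into the enclosing longer segment.  The absolute default of 1,000 is
meaningless for small synthetic tables, so a threshold in (0, 1) is
interpreted as a fraction of the feature count.

**Segment coordinate.**  The equation's n counts study injections 1…8, but
the emitted run order places one SQC between the last study injection of a
block and the next RQC.  We therefore define n as the *study-injection rank*
within the segment; QC injections between two RQCs inherit the rank of the
preceding study injection, the flanks sit at n = 0 and n = S + 1.  The
simulator generates its piecewise-linear sensitivity in the same coordinate,
which is what makes the normalization oracle exact to machine precision on
noiseless data.  On real data the convention is an approximation of order
(one injection slot)/(segment length) and is irrelevant wherever the drift is
close to linear.

**Anchoring.**  The printed equation anchors each segment to its own left
RQC, which corrects within-segment drift but leaves segments (and plates) on
different scales.  Since the stated goal is correcting intra- *and*
inter-plate variation, the default `anchored` mode rescales every segment per
feature by M1_first/M1_segment, mapping all reliable RQCs onto the first one;
`literal` mode reproduces the equation as printed.  After anchored
normalization every reliable RQC equals the first RQC's value per feature —
used as a self-test.

**Fallbacks.**  A feature unquantified (missing/zero/negative) in a flanking
RQC falls back to the nearest reliable RQC that does quantify it (searching
its own side first); if no RQC quantifies it at all, its values stay raw for
that segment.  All substitutions are counted in the normalization report.
Injections before the first or after the last reliable RQC (the conditioning
SQCs and the end-of-run dilution block) are uncovered: they pass through
unchanged and are flagged.  The correction never changes missingness and, as
a ratio of positive quantities, never produces negative intensities.

## QC filtering

* **SQC CV**: sample CV (n − 1 denominator) over intercalated SQCs; strictly
  greater than 0.30 fails.  The ten conditioning SQCs are excluded (column
  equilibration makes the first injections unrepresentative), as are SQCs
  after the closing RQC, which are uncovered by normalization.
* **dQC response**: within-triplet CV ≤ 0.30 at every fold, and mean
  intensity strictly decreasing across folds 1 → 2 → 4 → 8 → 16.  The fold-1
  level is the trailing SQC triplet injected with the dilution series.  A
  Spearman-rule variant (perfect negative rank correlation, equivalent on
  five complete levels) is available.  A feature with an entirely absent fold
  level is unevaluable and removed under the monotonicity reason.
* **m/z caps**: features above m/z 950 (C18) or 700 (HILIC) are removed as
  probable noise or column contaminants.  The caps are exclusive.  The HILIC
  cap is configurable because published descriptions of the protocol vary
  between 700 and 900 for the HILIC assays; 700 is the default.

Filters are pure predicates composed order-independently; the report
satisfies retained + removed = total, with ≥ 1 reason per removal.  Filtering
runs on normalized intensities (it follows normalization in the pipeline).

## Storage-time trendlines and the quality score

Marker abundance versus hours of whole-blood storage at 25 °C is modelled as
power (a·x^b), linear (a·x + b) or logarithmic (a·ln x + b).  Power and
logarithmic fits are ordinary least squares after log transforms; R² is
always computed in the original y space so kinds are comparable, and
`select_trendline` picks the highest R² with exact ties breaking
linear < logarithmic < power.  x = 0 control points are excluded from
power/logarithmic fits (ln 0 undefined).

The packaged 40-marker panel (10 HILICpos, 15 HILICneg, 10 C18pos, 5 C18neg;
30 increasing, 10 decreasing) stores both the printed trendline *label* and
the functional *form* of the printed equation.  Two rows (uric acid, ribonic
acid) pair a label with the other row's functional form; arithmetic always
follows the form, and a `swap_corrected` variant exchanging the two
coefficient sets (making label and form agree) is selectable.

P_k = (100/40)·(NLA_k(48 h) − NLA_k(sample))/NLA_k(48 h), clamped to ±2.5 so
no single marker can exceed its share of the 100-point scale.  The reference
NLA_k(48 h) defaults to the trendline value at 48 h; for the one marker whose
printed linear fit crosses zero inside the design window (tetradecanedioic
acid) the reference falls back to the smallest positive trendline value over
{3, 6, 12, 24, 48} h, and a measured mean can always be supplied instead.
When fewer than 40 markers are measured the per-marker factor rescales to
100/n (reported).  Pass/fail is score ≥ 85 by default (the published rule
leaves exactly 85 undefined; we treat it as a pass).

Two modes: `literal` applies the formula as printed; `direction_aware` flips
the sign for decreasing markers, because the literal formula penalizes fresh
samples on markers whose abundance falls during storage (glucose above the
degraded 48-h reference would otherwise score negative).  Both are exposed;
literal is the default for fidelity, direction-aware is what the pipeline
uses for triage ordering.

**Scale caveat.**  The packaged trendlines are on the raw abundance scale of
the original assays, and the 85-point cut was calibrated there (with NLAs
possibly log-transformed — the published description is ambiguous).  On
synthetic data the score's *ordering* in storage time is reproduced exactly
(fresh ≈ 65 points, 48 h ≈ 0 under direction-aware scoring), but the absolute
placement of the 85-point threshold is not transferable to simulation and is
kept configurable.

## Marker discovery

PCA and OPLS-DA default to Pareto scaling (centre, divide by √sd), the
common choice for LC-MS intensities; unit-variance and centre-only are
available.  OPLS-DA uses the NIPALS orthogonal-projection algorithm: each
orthogonal component is the part of the X-loading orthogonal to the
class-predictive weight vector; after removing `n_orthogonal` such components
(default 1) a single predictive component is computed.  With 0 orthogonal
components the model reduces exactly to single-component PLS1 (verified
against scikit-learn's PLS implementation in the tests).  The predictive
score is oriented so the second class has the higher mean.

S-plot: p[1] is the covariance and p(corr)[1] the Pearson correlation of
each (scaled) feature with the predictive score; zero-variance features are
excluded.  Selection keeps |p(corr)[1]| > 0.7 (a 0.55 variant exists for
weaker designs).  No p[1] magnitude cut is applied by default — the SQC/dQC
filters already remove non-quantitative features, which is what a p[1] cut
would otherwise guard against.

Candidate ranking uses the two-sample t-test between control and stored
samples — Welch by default, pooled-variance ("Student") as an option for
faithfulness to the original description — ordered by ascending p, then
descending |log fold change|.  Missing values are imputed feature-wise by
half the feature's minimum observed intensity before multivariate analysis.

## Synthetic data

The generator emulates the protocol's design: 96-well plates (study wells
A1–H11, QC wells in column 12), ten conditioning SQCs, blocks of
[RQC, 8 randomized study injections, SQC], a closing RQC, then d16/d8/d4/d2
triplets and a closing SQC triplet.  Intensities are
truth · sensitivity · lognormal noise.  Sensitivity is piecewise linear
between RQC nodes in the normalizer's segment coordinate, with per-node
relative steps bounded by `drift_amplitude` (default 30%), an extra
per-feature discontinuity of `plate_jump` (default 20%) at plate boundaries,
and constant sensitivity outside the RQC-bracketed region (so the end-of-run
dilution series is not confounded by drift).  QC truths derive from the
study samples: SQC is the pooled mean, dQC is SQC/fold, RQC is an
independent reference at the pooled level.  Noise is multiplicative
lognormal with σ = √ln(1 + CV²), matching CV-based acceptance and keeping
intensities positive; donor effects are lognormal with CV 20% by default.

The storage-series generator gives each of 6 donors a 0-h control plus every
(time ∈ {3, 6, 12, 24, 48} h) × (temperature ∈ {4, 25} °C) condition — 66
samples.  Marker features follow their packaged 25 °C trendline; the 4 °C
series and the control sit at the 1-h trendline value (power and logarithmic
curves are undefined at 0 h and some printed linear fits are negative there),
and truths are floored at 10⁻³ of baseline where a printed trendline crosses
zero.  Null features are time-independent.  Degraded RQC injections
(probability `rqc_failure_prob`, or forced by ordinal) have 80% of features
set missing so the reliability rule rejects them.

**What the simulator does not emulate** — chromatographic peak shape,
retention-time drift, adduct/isotope structure, feature-feature correlation
(optional block correlation excepted), heteroscedastic detector saturation,
and missingness that depends on abundance.  Passing tests therefore
demonstrate the correctness of the algorithms under the protocol's own
assumptions (multiplicative, piecewise-linear drift; CV-stable QCs), not
robustness to every failure mode of real acquisitions.

## Numerical conventions

* CVs use the n − 1 standard deviation; CV thresholds are strict ("over 30%").
* Trendline ties break toward the simpler kind at equal R² (tolerance 1e-12).
* Normalization computes a multiplicative factor first and applies it once,
  so the no-drift case is the exact identity (bit-for-bit).
* All randomness flows from a single integer seed per simulation config;
  identical configs give bit-identical outputs.

## Problem sizes used in tests and the acceptance script

Oracle and identity checks use 40–60 features on 1–2 plates of 24 study
samples; the repeatability design uses 3 plates × 24 injections × 300
features; marker-recovery uses the 40-marker panel plus 400 nulls over 66
storage samples; monotonicity uses 20 seeded replicates of the 40-marker
storage series; the null S-plot check uses 500 pure-noise features at 12
samples per class.  These sizes were chosen so each property is measured with
comfortable statistical margin while the whole suite runs in seconds.

## Known limitations

* The drift model corrects only multiplicative sensitivity drift; LOESS-type
  QC-RLSC, total-intensity and quantile normalization are out of scope.
* The score's absolute calibration (the 85-point rule) is tied to the
  original assays' abundance scale (see caveat above).
* The dQC monotonicity rule is strict; with > 3 replicate injections per fold
  or very low-abundance features a tolerance-based rule may be preferable
  (the Spearman option is a first step).
* Raw vendor data, peak picking, alignment and compound identification are
  upstream of this package and intentionally absent.
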