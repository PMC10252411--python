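# Methods and conventions

This note documents the models implemented by `ciderdry`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic-data
tests do and do not demonstrate about real cider data.

## Units

All chemistry is stored in fixed units and never auto-converted: alcohol
% v/v; pH units; malic acid and titratable acidity (as malic acid) in g/L;
residual sugar in mg/100 mL; polyphenols, hydroxybenzoic acids,
hydroxycinnamic acids and tannins in mg/L; absorbances at 280/320 nm in AU
for a 1-cm path. CSV readers rename columns via a dialect map but never
rescale. The one internal conversion is in the scale scorer: the IRF ratio
compares residual sugar and malic acid in the same unit, so the stored
mg/100 mL sugar is divided by 100 before the ratio.

## Dryness scales

**IRF ratio.** `irf_ratio` returns residual sugar / malic acid. When malic
acid falls below 1e-6 g/L the ratio is computed against that epsilon and
flagged `unstable` instead of raising: commercial score tables contain
samples at 0.001 g/L malic acid whose enormous ratios are the scale's known
failure mode, and callers need to see — not crash on — that regime.

**Category boundaries.** The published scale guideline prints its bins on a
one-decimal grid ("medium dry 1.0 to 2.0", "medium sweet 2.1 to 4.0"),
which leaves scores between grid points unassigned and says nothing about
the bin edges themselves. The applied labels in the 76-sample score table
resolve both: 1.000 is rated dry, 2.195 semi-dry, 2.587 semi-sweet, 4.000
semi-sweet. The implementation therefore closes the bins as

    dry <= 1.0 < semi-dry < 2.2 <= semi-sweet <= 4.0 < sweet

with 2.2 the next one-decimal grid point above the printed "2.1" edge — the
applied labels outrank the printed interval notation, and with this closure
the categorizer replays all 76 printed IRF ratings and all 76 NYCA ratings
exactly.

**pH shift.** The shift matrix operates on categories, not scores (the
guideline specifies category transitions only). Rules per base category are
ordered most-extreme-threshold-first and the first match wins, so pH 2.7
under semi-sweet shifts all the way to dry.

**NYCA correction.** The tannin deduction is a step function — 0 for
<= 500 mg/L, 0.25 for (500, 750], 0.5 for (750, 1000], 0.75 above 1000 —
with half-open bins so the partition of a continuous measurement is
exhaustive. The corrected score floors at zero (a negative sugar/acid ratio
is meaningless).

**Sensory scale.** Panel scores live on 0–8 anchored at glucose references
(9 g/L → 2, 18 → 4, 45 → 6); `anchor_score` interpolates piecewise-linearly
through those anchors plus the origin and extrapolates at the last segment's
slope, capped at 8. Categories: dry <= 2 < semi-dry <= 4 < semi-sweet <= 6 <
sweet.

**Printed anomalies.** The packaged transcriptions are authoritative and
keep the source's internal inconsistencies as printed: two samples' sensory
labels (KS2 at score 7.0 and BB1 at 3.4, both printed "semi-sweet")
contradict the anchored boundaries, and one sample's NYCA score exceeds its
IRF score (OH1, 0.100 vs 0.034; two further rows differ by 0.001 print
rounding). Replay tests assert these exceptions explicitly rather than
silently tolerating them.

## PLS1 engine

A single-response NIPALS implementation. X is column-centered and scaled to
unit variance by default (autoscaling), y centered only. Autoscaling is the
default because the weighted coefficients Bw are interpreted *across*
variables whose raw units differ by five orders of magnitude (mg/100 mL
sugar vs AU absorbance); raw-scale coefficients plus intercept are always
back-transformed and stored alongside.

Per factor: weight w ∝ Xᵀy (unit norm), scores t = Xw, loadings
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then deflation of X and y. For one response the
weight converges in a single pass; an inner-loop guard (tolerance 1e-10,
max 500 iterations) remains for pathological inputs. Factor extraction
raises if the residual X norm drops below 1e-12 of the original before the
requested factor count is reached — asking for more factors than the data
support is an error, never silent truncation. Coefficients:
b = W(PᵀW)⁻¹q in autoscaled space (= Bw), divided by the column scales for
the raw-scale form.

**Explained variance** per factor is tᵀt·pᵀp / SSX and q²·tᵀt / SSY on the
centered (and scaled) data, in percent. **Factor selection** takes the
smallest count after which the relative RMSECV improvement falls below a
plateau tolerance (default 1%).

**Cross-validation** permutes samples with a seeded `default_rng`, splits
them into near-equal segments (default 20; the source tool's "cross-
validation with randomization" does not state a count, so it is a config
knob), and predicts each segment from a model fitted on the rest. RMSEC
uses the n denominator; SEC removes the mean residual and uses n−1, so the
pair mirrors chemometric software conventions (SEC slightly larger); R² is
1 − SSres/SStot on the calibration fit; RMSECV comes from the held-out
predictions.

**Jackknife screening** follows the Martens formulation: per-variable
variance = (M−1)/M · Σₘ (b⁽ᵐ⁾ − b)² over the M segment submodels, limits
b ± t(1−α/2, M−1)·SE on the Bw coefficients, a variable significant when
its interval excludes zero. Whether the original tool used segments or
leave-one-out is unknown; both are reachable through `n_segments`.

**Hotelling T².** Factor scores are mutually orthogonal, so the score
covariance is diagonal and T²ᵢ = Σₐ t²ᵢₐ/var(tₐ) over factors with nonzero
variance. The critical value is k(n−1)/(n−k)·F(1−α; k, n−k). All-centroid
scores yield T² = 0 and no flags.

## Dryness predictor

`EQUATION_1` stores the published selected-variables equation. With residual
sugar in mg/100 mL its coefficient (0.0005243) spans about four panel-scale
units over the observed sugar range; that is the only unit reading under
which the equation's arithmetic is plausible, and the packaged distribution
summaries confirm it. Predictions are clipped to [0, 8] (the source is
silent on out-of-range predictions) and categorized with the *sensory*
boundaries, since predicted scores live on the panel scale. Note the
equation's positive titratable-acidity coefficient contradicts the source
narrative's claim of a negative acidity relationship; the printed equation
is implemented as printed.

Equation extraction from a PLS model requires the variable set to equal the
fitted set: PLS coefficients are not transferable across subsets, so
narrowing variables goes through `fit_equation` (a fresh fit), never through
zeroing. The all-variables and important-variables models are shipped as
variable-subset presets only — their calibration chemistry is unpublished,
so their printed validation ratings are fixtures, not recomputations. The
important-variables subset is named inconsistently in the source (pH vs
hydroxycinnamic acid as the third variable); both presets ship.

## Evaluation

Rating agreement is strict label inequality with severity measured as
absolute ordinal distance (dry=0 … sweet=3); "off by more than one level"
means distance >= 2. Replaying the packaged validation table yields 20
mismatches for the NYCA scale, 18 for the all-variables model and 14 for
the important-variables model against the panel, and 12 for the selected-
variables model — the source narrative says 11 for the latter, but direct
counting of its own table gives 12, and the table governs.

## Synthetic generator

The generator's defaults emulate the calibration-set summary statistics:
right-skewed concentrations are log-normal matched to the printed median and
upper quartile (e.g. residual sugar: median 361.83, Q3 1738.67 mg/100 mL),
pH is uniform over the printed [3.26, 3.98] range, the two acids triangular
with the printed median as mode, and every draw is hard-truncated to the
printed min/max. Tannins have no published summary, so their marginal is
uniform on [0, 5000] mg/L (the narrative's extreme case) and deliberately
unanchored. Dependence is a Gaussian copula with rank-correlation targets
0.8 for (polyphenols, A₂₈₀) and (hydroxycinnamic, A₃₂₀) and 0.85 for
(malic acid, titratable acidity) — the source documents these relationships
only qualitatively, so a copula over named pairs was chosen over a
structural chemistry model. Panel scores are the latent equation plus
homoscedastic Gaussian noise (default SD 0.5 on the 0–8 scale), clipped to
the scale; no per-judge process is simulated. Outlier injection displaces
chosen samples along the first principal direction of the autoscaled
chemistry by a stated number of pooled SDs.

**Recovery-test equation.** Statistical tests use a latent equation on the
same five routine variables as `EQUATION_1` but with coefficients sized so
every per-variable contribution SD is at least ~0.35 panel-scale units
(ph −2.0, TA +3.0, A₂₈₀ −2.0, A₃₂₀ −6.0, RS +0.0005, intercept 10). The
published equation itself is unsuitable as recovery truth: its A₃₂₀ term
contributes ~0.004 scale units against 0.5 panel noise, so no finite
calibration of realistic size could pin it within a meaningful tolerance.
Recovery is therefore demonstrated for a detectable 5-variable truth, and
the shipped equation is verified by exact evaluation instead.

**What the synthetic tests show.** Passing recovery/screening tests show
the engine is correct under the generator's assumptions: linear latent
truth, Gaussian noise, copula dependence, truncated marginals. Real panel
data have judge effects, session effects and heteroscedastic disagreement
near category boundaries; none of that is emulated, so the tests validate
the software, not the sensory methodology.

## Problem sizes and runtime

Test and acceptance simulations use n = 200 × 50 replicates for coefficient
recovery, n = 60 × 60 replicates with 20-segment CV for jackknife rates,
n = 40 for outlier flagging, and n = 1500–2000 single draws for marginal and
copula checks — sizes at which the asserted rates are stable across seeds
while the whole suite runs in a few seconds.

## Known limitations

* The original calibration fits (R² = 0.909/0.857 etc.) are not
  reproducible: per-sample calibration chemistry was never published. The
  engine is validated against a least-squares oracle, an independent PLS
  implementation and synthetic ground truth instead.
* The pH-corrected IRF column of the packaged score table cannot be replayed
  (per-sample pH is unpublished, and at least one printed row is
  inconsistent with the shift rules); it is transcription-only.
* Scale-score categorization near 2.2 rests on a single printed label pair
  (2.195 semi-dry, 2.587 semi-sweet); any closure between those scores would
  replay the table equally well.
* The jackknife treats segment submodels as exchangeable; with very few
  segments the t-quantile with M−1 degrees of freedom is conservative.
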