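# Methods

## Analysis population and time axis

Time is stored as months since each patient's baseline visit (the first
visit of the supplied series, at t = 0); if calendar dates are converted
upstream, 1 month = 365.25/12 days. Eligibility retains adults (≥ 18
years) with FVC and DLCO measured at baseline and at least one FVC
measurement in the 12±3-month window [9, 15]. DLCO is required only at
baseline: the primary per-period outcome needs follow-up FVC alone, and a
missing follow-up DLCO gates only the combined FVC+DLCO endpoint (flagged
as indeterminate rather than silently negative). Each excluded patient is
logged with the first failing criterion in the fixed order age → baseline
FVC → baseline DLCO → follow-up FVC, so exclusion logs are deterministic.
ILD presence and SSc classification are assumed established upstream.

## Period anchoring

Registry visits are irregular, so 12-month observation periods are anchored
to baseline-fixed anniversaries a_k = 12·k rather than rolled forward from
whichever visit happened to match last; this keeps period identity
well-defined when periods are skipped. The period-k end is the FVC-bearing
visit inside [a_k − 3, a_k + 3] closest to a_k, with an exact tie broken
toward the earlier visit (deterministic, and it reduces overlap with the
next window). A period's start is the previous period's end when one
exists, so consecutive periods share endpoints — required for transition
matrices — and a period whose (k−1)-anniversary has no matched visit is not
emitted at all (except k = 1, which starts at baseline). Consequences: no
visit ends two periods, no period spans more than 18 months, and on a
perfectly annual schedule the periods are exactly the adjacent-visit
differences. Periods need not be consecutive. Visits with missing FVC are
invisible to matching.

Whether per-period changes should chain through matched visits or always
re-anchor to baseline is genuinely open in this kind of analysis; chaining
was chosen because it makes consecutive periods commensurable (the end of
one is the start of the next), which any transition analysis presumes.

## Classification conventions

All thresholds operate on absolute changes in % predicted and are
configurable (`Thresholds`), with defaults following the standard printed
interval text: per-period significant decline is strict (Δ < −10) and both
−10 and −5 belong to moderate decline; +5 belongs to improvement. For the
overall course, −20 belongs to significant decline (major is Δ < −20). The
combined progressive-fibrosis endpoint uses an inclusive FVC arm (Δ ≤ −10),
matching its usual published wording even though the FVC-only bin is
strict; both edges are exposed in configuration and the discrepancy is
deliberate, not an error. The DLCO threshold (−15) is in absolute
%-predicted points, the same convention as FVC.

Two tie/edge rules in the pattern taxonomy are package decisions:

* equal decline and stable counts → *progressive* (a tie is not "more
  stability than decline", and flagging progression is the clinically
  conservative reading);
* *rapid* requires at least two decline periods with none stable; a lone
  decline period with no others is *progressive*.

Patterns are computed for every long-term patient (non-declining when no
decline period exists); the headline pattern percentages are reported over
patients with an overall decline only. The cross-tabulation population is
patients with ≥ 3 usable FVC measurements and ≥ 2 computable periods.
Printed percentages round half away from zero, matching clinical tables.

## Synthetic registry generator

The generator emulates the statistical structure the analysis assumes, not
any particular registry's data. Per patient: covariates are drawn
independently at registry-typical prevalences (male 18%, diffuse subtype
50%, anti-topoisomerase 53%, reflux/dysphagia 67%, ...); an archetype is
drawn from a mixture (defaults: rapid decliner −12 points/yr × 8%, slow
decliner −3 × 22%, stable 0 × 40%, improver +4 × 15%, fluctuating 15%); the
latent trajectory is

FVC(t) = b + s·t/12 + A·sin(2πt/24 + φ),

where b ~ N(87, 21.1²) (DLCO baseline N(59, 18.3²)), the annual slope s
adds covariate effects (male −1.30, mRSS −0.06/point, reflux −0.72
points/yr) to the archetype slope, and the sinusoid (amplitude 8 for the
fluctuating archetype, else 0, period ≈ 2 years) produces alternating
decline/improvement periods without net trend. Visits occur at baseline and
jittered anniversaries (jitter SD 1 month, clipped at ±5) over 5 years,
thinned by independent Bernoulli missingness (p = 0.15/visit; follow-up
DLCO additionally missing with p = 0.30). Observations add N(0, 3²)
measurement noise — within-patient lung-function error is not published for
such registries, so 3 points is a free choice, labelled as such — and are
truncated to [10, 160] % predicted. Death is administrative truncation with
an annual probability 0.02·exp(−0.10·s), i.e. inflated for steeper decline;
no survival realism is claimed beyond exercising the mortality summary.

A truth table records each patient's archetype, latent slope and the
noise-free category of every computable period (latent values pass through
the same truncation as observations). With zero noise and zero jitter,
pipeline classification equals the truth table exactly — the oracle test.
Identical (config, seed) yields byte-identical output; all draws happen for
every scheduled visit whether or not it is retained, so retention decisions
never shift the random stream.

What the generator does **not** emulate: covariate correlations (e.g.
antibody–subtype association), informative (FVC-dependent) dropout,
centre effects, or measurement-error autocorrelation. Tests passing on
synthetic cohorts therefore demonstrate the pipeline's correctness under
the stated model, not robustness to those real-data features.

Deterministic fixture builders complement the stochastic generator: given
target classified counts (an initial-period split, a full overall-course ×
episode-column grid, or the composite headline cohort) they construct
noise-free annual trajectories realising those counts exactly, raising a
feasibility error naming any unrealisable cell. Fixture cells are built
from a column-specific multiset of decline deltas, padded with −4-point
stable periods while the remaining adjustment would itself be a decline,
and closed with one stable/improving period landing the cumulative change
in the row's overall bin.

## Risk models

Estimation delegates to statsmodels; the module's own content is the
contracts around it. Logistic: outcome is significant decline in the
initial period; complete-case with logged drop counts; Wald 95% CIs on the
OR scale; complete separation raises instead of returning estimates; a
warning fires when events < 10 × covariates (the conventional
events-per-variable floor). Mixed model: REML, response FVC % predicted,
time coded by rounding t/12 to integer years and capped at 5; random
intercept and slope per patient with an unstructured 2×2 covariance; only
patients with ≥ 3 serial FVC measurements enter; if the estimated
random-effect covariance is singular the model is refit with independent
intercept/slope variances and the result flagged. Covariate lists are
explicit inputs — mirroring expert-opinion selection — with no stepwise
machinery and no multiple-testing adjustment. Coefficients are validated by
simulation recovery (a −1.3 points/yr time×sex effect recovered within
±0.4 at n = 1000; an OR of 2.0 within [1.7, 2.4] at n = 5000; ≥ 90%
CI coverage for a null covariate over 100 replicates), never against any
particular registry's estimates.

## Problem sizes and numerical notes

The test suite and acceptance script use the sizes at which the properties
they check are statistically decidable: 10⁵ random deltas for the partition
properties, 2000 patients for the noise-free oracle, 1000/5000 patients for
mixed/logistic recovery and 100 replicates for coverage; the whole suite
runs in well under a minute. On degenerate noise-free mixed-model data the
REML optimizer attains ≈ 10⁻⁴ absolute precision on fixed effects (the
analytic OLS equivalence holds, but not to machine precision). Percentage
rounding is half-away-from-zero throughout. Empty groups report blank
percentages rather than dividing by zero.

## Known limitations

Visit-wise dropout is non-informative; death is a crude slope-scaled
hazard; DLCO trajectories are a fixed ratio (0.6) of the FVC slope rather
than independently modelled; covariates are drawn independently. The
eligibility filter assumes the supplied baseline is the analysis baseline.
These are deliberate v1 simplifications, documented so that conclusions
drawn from synthetic experiments are scoped correctly.
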