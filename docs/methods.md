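# Methods

## Score construction

The structural fragility score treats bone loss as displacement in the
(cortical porosity, trabecular density) plane. All geometry is computed in
standardized coordinates: raw values are centered on the premenopausal means
O = (o_x, o_y) and divided by the premenopausal sample SDs (n−1 denominator,
the standard convention for reference-interval work). Standardization is a
deliberate design choice — the two traits carry incommensurable units (% vs
mg HA/cm³), and any geometric construction mixing them (slopes, Euclidean
distances) would otherwise depend on arbitrary unit conventions. With it, the
score is provably invariant to affine unit rescaling of either trait (tested
to 1e−9).

The deterioration axis U is fitted as the *arithmetic mean of per-point
slopes* zy_i/zx_i from O to each fracture-derivation subject, taken literally
rather than as an angle average or a total-least-squares direction. Points
numerically on the vertical axis (|zx| ≤ 1e−8) contribute no usable slope;
they are excluded and counted in a diagnostics record. The fitted slope must
be negative — the method presumes the fracture cohort is displaced toward
quadrant IV (high porosity, low density) — and a non-negative slope is a
hard error, not a warning. Note the mean-of-ratios estimator is heavy-tailed
when fracture points sit near the vertical through O; the derivation cohort
must be well displaced from O for the axis to be stable (the synthetic
generator guarantees this by construction).

Z, the maximum-deterioration point, is the maximal orthogonal projection of
the fracture-derivation subjects onto U. The alternative — a fixed
anatomical bound such as 100% porosity — was rejected because it would make
the score scale depend on a point no subject occupies; the observed-data
maximum makes "100" mean "as deteriorated as the worst derivation subject".
The score scale maps |O→Z| to 100 score units, so scale = 100/ell_z exactly.

A subject decomposes into the perpendicular distance A to U and the signed
along-axis coordinate ell (both in score units); B = 100 − ell is the
remaining distance to Z and SFS = 100 − (A + B) = ell − A. Two consequences
worth stating explicitly:

- SFS is **unclamped**. Values < 0 (better than reference) and > 100 (beyond
  Z) are meaningful and preserve monotonicity: moving along +U strictly
  increases the score, moving orthogonally off-axis strictly decreases it
  (property-tested on random frames).
- The off-axis penalty A is unsigned ("perpendicular length"), so a
  reference population scattered isotropically about O has median
  *along-axis* coordinate ≈ 0 but median *SFS* strictly below 0: every
  off-axis subject pays a positive A while the ell term is symmetric. A
  claim that the median SFS itself is ≈ 0 in a symmetric reference sample
  holds only on the axis (A = 0) or when the score scale is very small; the
  test suite asserts the correct version. Which side of U a subject lies on
  (cortical- vs trabecular-dominant deficit) is retained in the score record
  but does not enter the score.

Quadrants are assigned relative to O with ties falling to the "low" side;
quadrant IV (high porosity, low density) is the bone-loss-consistent region.

## Diagnostic battery

Thresholds follow the at-risk directions: porosity ≥ cut, density ≤ cut,
T-score ≤ cut, SFS ≥ cut, with boundary equality counting as positive.
Percentile cuts use the linear-interpolation quantile at fractional order
statistic p/100·(n−1). Percentiles are computed on the premenopausal
reference cohort by default (the population implied by tying the score cut
to the reference 90th percentile); this is configurable.

Odds ratios are the 2×2 cross-product with Woolf log-normal CIs
(SE = √(Σ 1/cell)) and two-sided Wald p-values; a zero cell is an error
unless the Haldane–Anscombe 0.5 correction is requested. Proportion CIs are
exact Clopper–Pearson via beta quantiles (lower bound exactly 0 at zero
successes, upper exactly 1 at full successes); the exact coverage at the
study's case-arm size (n = 99, p = 0.10) is verified to be ≥ 95% by summing
the binomial mass directly. These two interval methods were fixed because
together they reproduce published intervals recomputed from reconstructed
counts.

`reconstruct_table` inverts printed summaries: tp = round(sens·n_cases),
tn = round(spec·n_controls), rounding half away from zero. Recomputed ORs
and CI bounds then agree with published values to within one unit in the
last printed digit — the resolution limit imposed by the rounding of the
printed inputs, since the original analyses were run at full precision.

"Accounting for" a second predictor is implemented two ways, and reports
label which was used: (a) *reclassification* — a subject positive on the
accounted-for trait is removed from the index trait's positives, which
reproduces published after-adjustment sensitivities/specificities from
consistent 2×2 tables; (b) a *joint logistic model* on both binary
indicators, reporting the index indicator's adjusted OR. Logistic fits use
IRLS with an always-included intercept, convergence at max |score| < 1e−8
within 100 iterations, Wald SEs from the inverse observed information, and
an explicit non-identifiability error when a coefficient passes 15 on the
log-odds scale (complete separation). Matched-pair (conditional) logistic
regression is out of scope: the validation analysis is unconditional.

Replicate precision is the root-mean-square coefficient of variation:
cv_i = sd_i/mean_i per subject (n−1 SD, ≥2 replicates, positive mean),
RMS-CV = √(mean cv_i²) × 100%.

## Synthetic cohorts

No subject-level data are deposited with the source study, so the generator
produces cohorts in which the method's assumptions are *true by
construction*, making parameter-recovery tests interpretable:

- **Premenopausal reference** (default n = 324, ages 20–40): bivariate
  Gaussian, porosity 36 ± 4 %, density 102 ± 25 mg HA/cm³, correlation −0.3,
  truncated by redraw to porosity ∈ [0, 100] % and density ≥ 0 (an
  acceptance rate below 1% is an error). The reference means/SDs are free
  parameters of the generator — no published values exist for them — chosen
  so the downstream postmenopausal arms land near published control medians.
- **Fracture-derivation cohort** (default n = 33, ages 50–90): points placed
  directly on the latent deterioration axis (true slope −1 in standardized
  space), along-axis displacement ~ N(4.5, 0.8) SD units, orthogonal noise
  SD 0.4. The displacement is kept well away from O because the
  mean-of-slopes estimator's ratio bias scales as ~σ²/m²; at these defaults
  the fitted slope recovers the truth within 0.03 at large n.
- **Postmenopausal evaluation** (default 99 cases / 105 controls, ages
  50–80): a premenopausal-style draw plus drift of 0.9 SD units per decade
  after age 50 (subject-level SD 0.5) along the axis plus orthogonal noise,
  then fracture ~ Bernoulli(logistic(−2.5 + 0.05·SFS)) under a frame fitted
  to the generated reference cohorts, then quota sampling to the configured
  case/control counts. Under these defaults the control-arm medians land
  near 39 % porosity and 84 mg HA/cm³ density and the case medians near 43 %
  and 57 mg HA/cm³ — close to the published cohort's values — and age is
  positively correlated with porosity and negatively with density, as in
  observed aging data.

One master seed drives everything; each cohort derives an independent child
stream (`SeedSequence.spawn`), so cohorts are individually reproducible.

What the generator does **not** emulate: HR-pQCT measurement error beyond a
single orthogonal noise term, longitudinal trajectories, matching structure
between cases and controls, non-Gaussian trait distributions, and any
systematic relation between BMD T-score and the microarchitecture traits
(synthetic cohorts carry no T-scores). Passing recovery tests therefore show
the pipeline is self-consistent under its own geometric model — not that the
model describes real bone.

## Numerical choices

- Percentile convention: linear interpolation on sorted order statistics
  (documented above); other quantile conventions change thresholds by
  O(1/n).
- Frame YAML serializes floats at full precision; reload is bit-exact.
- Scored CSVs write floats via `repr`, so read∘write is the identity on
  numeric fields.
- Problem sizes in tests: geometric identities on 10⁴ random frame/point
  pairs; recovery at n = 10⁴ derivation subjects and a 10⁴-subject
  postmenopausal pool; the end-to-end power check uses 100 replicates of the
  default 324/33/204 bundle.

## Limitations

- The axis estimator (mean of ratios) is intentionally literal; it is biased
  O(σ²/m²) toward zero slope when the derivation cohort is close to O, and
  a total-least-squares axis would be more robust but is a different method.
- Whether the original derivation averaged slopes in raw or normalized
  coordinates is not stated in the source description; standardized-space
  averaging is this package's documented convention, and raw-space averaging
  would yield a different (unit-dependent) axis.
- Reconstruction from printed proportions recovers counts exactly only when
  the printed rounding is faithful; a half-unit discrepancy in a printed
  percentage can shift a reconstructed cell by one.
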