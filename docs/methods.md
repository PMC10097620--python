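# Methods

## Generative model of the synthetic study

The generator reproduces the statistical structure the downstream analysis
assumes, not mass spectra. For protein *i* in run *r*:

    latent_ir = baseline_i + x_r' · beta_i + b_i,c(r),k(r) + e_ir

where `x_r` is the run's one-hot factor vector (brafwt, v600e, dimerizer,
sorafenib, vemurafenib), `b` is a biological-replicate effect ~ N(0,
sigma_bio²) shared by the two technical replicates of the same pulldown, and
`e` ~ N(0, sigma_tech²) is per-injection noise. The raw LFQ intensity is
2^latent. Each cell is independently left-censored with probability

    P(missing) = logistic((censor_midpoint − latent) / max(censor_slope, 1e-8))

and censored cells are written as raw intensity 0, as MaxQuant reports them.
`censor_slope` is the logistic *scale*: smaller values give a sharper
detection limit, and a scale of 0 with the midpoint below all latent values
switches censoring off entirely. Censoring probability is monotone
non-increasing in latent intensity by construction (the MNAR assumption that
motivates downshift imputation). Decoy rows (contaminant / reverse /
only-by-site) draw from the same baseline distribution; they exist purely to
exercise the category filter.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| n_proteins | 600 | — | a mid-sized AP-MS prey list after MaxQuant filtering |
| frac_interactors | 0.15 | — | ~90 condition-specific interactors; 1–2 affected factors each |
| effect sizes | 1–3 | log₂ | clearly quantifiable enrichments; 80% positive, 20% depletions |
| baseline | N(26, 2²) | log₂ LFQ | bulk of a typical LFQ dynamic range |
| sigma_bio | 0.3 | log₂ | ~23% CV between biological pulldown replicates |
| sigma_tech | 0.15 | log₂ | ~11% CV between technical re-injections |
| censor_midpoint | 23 | log₂ | ~11% of prey cells censored, concentrated at low abundance |
| censor_slope | 0.8 | log₂ | gradual detection limit |
| decoys | 30/15/15 | rows | contaminant / reverse / only-by-site |

The noise levels were chosen so that differential calling has non-trivial —
but not saturated — power at 3 biological replicates: with t-tests at ~4
residual df and ~600 simultaneous tests, meaningfully larger replicate noise
drives BH-adjusted calls to zero for all but the strongest effects.

### What the generator does not emulate

Peptide-level quantification and protein inference, shared-peptide
ambiguity, run-order and batch drift, normalization artefacts,
heavy-tailed or protein-dependent noise, and correlated missingness within
a run. Passing tests therefore demonstrate that the *statistical machinery*
is correct under its stated assumptions (additive log-scale model, Gaussian
noise, logistic left-censoring); they do not certify performance on real
instrument data.

## Pipeline order and replicate handling

Stages run: category filter → log₂ (0 → missing) → min-valid filter (≥3
observed in ≥1 condition) → max-missing filter (discard only when *every*
condition has >2 missing) → technical-replicate averaging → imputation →
inference.

Technical replicates are nested inside biological replicates and share the
biological effect, so treating the 6 runs per condition as independent
samples is pseudoreplication: it roughly halves the estimated variance of a
group-mean difference and visibly inflates one-sided t rejection rates. The
pipeline therefore averages technical replicates onto one column per
biological replicate before any test or fit (the collapse is exposed as an
explicit, optional stage for users who want the per-column treatment some
established proteomics GUIs apply). After averaging, the rows of each
collapsed condition are i.i.d. N(·, sigma_bio² + sigma_tech²/2), which is
what makes the t-tests and OLS intervals calibrated.

The max-missing rule's published phrasing is ambiguous about the quantifier
and about exactly-2-missing; this implementation discards a protein only
when every condition exceeds the threshold and retains exactly-2 (the most
permissive consistent reading); both the threshold and the every/any
quantifier are configurable. The valid-value groups are the 16 condition
labels.

## Imputation

**Downshift (volcano branch).** Per column, missing cells draw from
N(mean_obs − 1.8·sd_obs, (0.3·sd_obs)²). Columns with <2 observed values
fall back to the whole-matrix observed mean/sd (with a warning); any
estimated sd is floored at 0.01 log₂ units so degenerate columns still
produce non-identical draws.

**Condition-wise log-normal (regression branch).** A log-normal on the raw
scale is a Gaussian on the log scale, so draws are made directly in log₂
units. Location = mean of the protein's observed same-condition replicates.
Spread falls back through: (1) the protein-within-condition sd when ≥3
values are observed; (2) the condition-level pooled within-protein sd;
(3) the whole-matrix pooled within-protein sd — per-protein estimates from
1–2 points are undefined or unstable. A (protein, condition) cell with *no*
observed same-condition value uses the protein's overall observed mean and
the whole-matrix pooled spread (warned); this fallback ignores the censoring
mechanism and biases such cells upward — an accepted limitation, since the
max-missing filter makes the case rare. A per-condition "global" variant
(location/spread from all observed values in the condition) is available via
`per_protein=False`.

Observed cells are bit-identical before and after imputation; the imputation
mask marks exactly the filled cells. Each stage consumes a dedicated child
of the master seed (`AnalysisParams.stage_seeds`), so stages re-run in
isolation reproduce the full-run draws.

**Calibration caveat.** Single imputation treats drawn values as data. On
null synthetic data at default censoring this leaves the raw one-tailed
rejection rate close to, but not exactly at, the nominal level (measured
~0.044 at alpha 0.05 with Welch tests; the Welch approximation at 3-vs-3 is
itself slightly conservative). The BH+fold-change branch remains safely
below its FDR target under the null. Analyses that need exact interval
coverage should be read on the uncensored/complete-case results.

## Differential testing

Welch (unequal-variance) t-tests by default — the safer choice for
3-replicate groups — with a pooled-variance option. p is the right tail, so
only enrichment in the bait condition counts; identical groups give p = 0.5,
and zero-se cases are resolved by the sign of the difference and flagged.
BH adjustment is the standard step-up with monotonicity (delegated to
statsmodels); calls require diff > log₂(1.5) ≈ 0.585 (the fold-change gate is
interpreted as a linear ratio) *and* q < 0.05, adjusted per comparison.

**Permutation FDR.** d = diff/(se + s0) with s0 = 0.1 stabilises
small-variance proteins. Columns of the two groups are pooled and relabelled
into groups of the original sizes (250 random relabelings by default, or
exhaustive enumeration — all C(6,3) = 20 on a 3-vs-3 comparison). Estimated
FDR at threshold c = mean permuted exceedance count / observed exceedance
count (mean, not median, by default; configurable). The significance
threshold is the smallest observed positive d at which estimated FDR ≤ 0.1;
significant proteins additionally need a positive difference. If no
candidate reaches the target the threshold is +∞ and the set is empty. The
reported cutoff curve is the single-parameter locus d = c mapped into
volcano coordinates: along the curve se = diff/c − s0 and p is the right
tail of diff/se at the comparison's median residual df. Relabelling columns
(rather than permuting within rows) preserves the per-protein correlation
structure, matching the SAM-style scheme.

## Regression and contrasts

Per-protein OLS on intercept + five factors (full column rank checked; a
constant factor raises a configuration error naming the column). Residual
variance = RSS/(n − 6); coefficient covariance σ̂²(X′X)⁻¹. Coefficient and
contrast tests are two-sided ("different from zero" is a two-sided
question), unlike the deliberately one-sided differential branch; BH runs
across proteins within each coefficient or contrast, not pooled, because
each coefficient answers a distinct question. Plain per-protein variances
are used rather than empirical-Bayes moderation, keeping the math fully
specified by standard OLS theory; the model is purely additive (no
drug × mutant interactions) by design. Contrast estimate = c′β̂ with
se = √(c′Σ̂c); a positive sign means the positively weighted variable
increases log-LFQ more. The regression consumes the log-normal-imputed
matrix; noise-free data reproduce the true coefficients exactly, and on
uncensored data at default noise the 95% intervals cover the true
coefficients at the nominal rate.

## QC and overlap

PCA is computed on the centred, fully imputed sample × protein matrix
(deterministic up to component sign). Outlier flagging measures each
sample's PC1/PC2 distance to its condition centroid against a robust scale —
the pooled median distance divided by √(2 ln 2), the Rayleigh median factor,
so the scale estimates the isotropic scatter sd — and flags samples beyond
k·σ̂ (default k = 4). Flagging never removes runs; removal is the analyst's
explicit action, mirroring how such outliers are handled by inspection in
practice.

Overlap matrices use the n/d dialect: entry (row, col) has numerator
|S_row ∩ S_col| and denominator |S_row|, so the diagonal is n/n and
numerators are symmetric. The default set source is the BH branch
(configurable to the permutation branch). Reference comparison intersects
the pooled interactor set with a local identifier file — never a live
database query — for reproducibility; the bundled analysis uses a synthetic
reference assembled from the simulation's own ground truth.

## Determinism

All randomness flows from `AnalysisParams.seed` through per-stage
`SeedSequence` children (simulate, downshift, log-normal, permutation).
Identical config + seed ⇒ byte-identical output tables (fixed float format
`%.10g`); this is asserted end-to-end in the test suite.

## Known limitations

- Single imputation understates uncertainty (no multiple-imputation
  pooling); downstream p-values on heavily censored proteins are
  approximate.
- The zero-observed-in-condition imputation fallback is MNAR-naive (biased
  upward for truly censored conditions).
- Welch tests at 3 biological replicates have ~4 df; power against
  1 log₂-unit effects is limited and BH across ~600 proteins compounds this
  (visible in the worked example's conservative BH branch).
- The volcano cutoff curve uses the median residual df across proteins;
  per-protein curves would differ slightly when group sizes vary.
- No normalization beyond log₂ is applied; LFQ normalization is assumed
  upstream.
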