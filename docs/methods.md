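# Methods

This note documents the models, the numerical choices, and the synthetic
test-bench behind `diinpx`. It is the place where open design decisions are
recorded in one place; the README covers usage.

## The analysis chain

The package reproduces, as a reusable pipeline, a cross-sectional design
that links habitual diet to the circulating inflammatory proteome:

1. **Intake aggregation.** Seven-day dietary records (subject, day, food,
   grams) are resolved against a per-100 g food-composition table. The
   record is treated as a complete consumption log: days with no entries
   are days with no intake, so every per-subject mean divides by exactly 7.
   Intakes are linear in the entries, which gives the module its main
   testable invariants (scaling, additivity, agreement with an entry-wise
   oracle). Foods missing from the composition table are resolved only
   through an explicit substitution map ("analogous food" choices are an
   upstream, human decision; the code never fuzzy-matches names).
   Percent-energy shares use configurable kcal-per-gram factors
   (4 for carbohydrate and protein, 9 for all lipid classes, 7 for
   alcohol); total energy always comes from the composition table's own
   kcal column, so the factors affect shares only.

2. **DII scoring.** For each nutrient parameter `p` with reference mean
   `mu_p`, reference SD `sigma_p` and inflammatory effect score
   `w_p in [-1, +1]`:

       z_p  = (x_p - mu_p) / sigma_p
       c_p  = 2 * Phi(z_p) - 1          (centered percentile, in (-1, 1))
       DII  = sum_p  c_p * w_p

   The centered percentile is computed through the normal CDF, which is
   the distributional assumption the z-score step already makes. A user
   who has an empirical reference distribution can attach a `quantiles`
   column to a reference row; the percentile is then interpolated from
   those quantiles instead (clipped half a grid step away from 0 and 1 so
   the transform never saturates at exactly ±1). Parameters missing from
   a profile are skipped by default (`n_parameters_used` is reported) or
   can be made a hard error. DII is computed on unadjusted mean daily
   intakes; no per-1000-kcal standardisation is applied. The packaged
   reference table is **illustrative**: its means and SDs were chosen to
   match the mixed-population marginals of the synthetic food model
   (rounded), and its effect scores encode the standard qualitative
   pattern (saturated fat and refined carbohydrate pro-inflammatory;
   fibre, PUFA — especially omega-3 — vitamin C, and moderate alcohol
   anti-inflammatory). No test depends on the published global-database
   values, which are deliberately not reproduced here.

3. **Median split.** Subjects at or above the sample median DII are
   labelled `high`, the rest `low`. The tie-to-upper rule makes an odd
   cohort of distinct values split (n+1)/2 high — e.g. 663 subjects into
   332 high / 331 low.

4. **Differential NPX.** NPX is already log2-scale, so a protein's log2
   fold change is the difference of group means; values are never
   re-logged. Test selection per protein: Kolmogorov-Smirnov against a
   moment-fitted normal in each group at `alpha_normality = 0.05`; the
   two-sample t-test (pooled variance) if neither group rejects, else the
   Mann-Whitney U test. The rank test uses the exact null distribution
   when the pooled sample has at most 20 observations and no ties, and
   the tie-corrected normal approximation otherwise. A constant protein
   (zero within-group variance) fails the normality gate by definition
   and falls through to the rank test, where all-tied data give p = 1.
   Proteins with fewer than three usable observations in either group are
   flagged untestable and excluded from the Benjamini-Hochberg
   adjustment, which runs across all testable proteins. Two significance
   modes are always carried side by side: `fdr` (q < 0.05, the default)
   and `paper` (raw p < 0.05, the uncorrected convention some studies
   report); the active mode only controls the `significant` flag.

5. **Classification.** The cohort is split 60/40 (stratified by group,
   seeded), and an XGBoost binary classifier is trained with 1000
   boosting rounds at learning rate 5e-4 (the protocol constrains it
   below 1e-3). Tree depth {2, 3, 4} and per-tree column subsampling
   {0.3, 1.0} are tuned by stratified 5-fold cross-validation inside the
   training set. Two deliberate choices here:

   * *Column subsampling rather than row subsampling in the grid.* At a
     near-zero learning rate the ensemble's logit is essentially an
     average of trees fitted to almost-unchanged residuals, so the fit is
     variance-limited, like bagging; decorrelating the trees by column
     subsampling is what improves held-out ranking, and cross-validation
     selects it reliably when it helps. Row subsampling is kept fixed at
     0.8. On the default synthetic cohort this raises held-out AUC from
     ~0.82 to ~0.89.
   * *Train-only feature selection.* The differential table for the whole
     cohort is a descriptive result; reusing it to pick classifier
     features would let test subjects influence feature selection and
     inflates the null AUC to ~0.6. By default the classify stage re-runs
     the differential test on training subjects only and selects features
     there (`train_only_selection: true`); setting it to false restores
     the single full-cohort selection some published designs use.

   Importance is total split gain, normalised to shares; ties in the
   ranking are broken lexicographically by protein id, and the full
   ranking is always written (any "top n" cut is a view of it).
   Histogram binning is capped at 64 bins — lossless at a few hundred
   subjects and considerably faster over thousands of rounds.

6. **ROC.** AUC is the concordance probability, computed from midranks
   (identical to all-pairs counting with ties scored ½ — this equivalence
   is tested exhaustively). The 95% CI is a percentile bootstrap over
   test subjects (2000 resamples, seeded; degenerate resamples with one
   class are redrawn); the p-value against AUC = 0.5 comes from the
   Mann-Whitney correspondence (AUC is a rescaled U statistic). The CI is
   clamped to bracket the point estimate, which matters only in
   pathological small-sample corners of the bootstrap.

7. **Enrichment.** Plain one-sided hypergeometric over-representation:
   `p = P[X >= k]` for `X ~ Hypergeom(N, K, n)`, fold enrichment
   `(k/n)/(K/N)`, BH across the terms actually hit by the query (k >= 1),
   significance at FDR < 0.05. This is deliberately the exact Fisher-type
   tail, not the modified EASE-style score some web services use: it is
   oracle-testable by enumeration. The background defaults to the union
   of term members and should normally be set to the full measured panel.
   Term categories (immune-inflammatory, cell-cell signaling, metabolic,
   other) are editorial metadata used only for tallies.

## The synthetic test-bench

`diinpx.synthetic` generates every pipeline input from one seed. What it
emulates and what it does not:

* **Diet.** ~30 foods with invented but nutritionally plausible per-100 g
  values and a group > subgroup > item hierarchy. Each subject belongs to
  a "western" or a "prudent" archetype; each day each food is consumed
  with an archetype-specific probability, at a Gamma-jittered typical
  portion (CV 25%). The preference weights make western subjects ingest
  more saturated fat and less fibre, PUFA and vitamin C. Under the
  packaged reference this puts the two archetypes ~2 SD apart in DII
  (prudent ≈ −1.8, western ≈ +0.5 at defaults), so the median split
  recovers archetype membership almost perfectly. The generator does not
  model seasonality, under-reporting, recipe decomposition, or realistic
  national food-composition values.

* **Proteome.** `NPX[s, p] = baseline_p + subject_s + effect + noise`,
  all Gaussian on the log2 scale: baseline ~ N(4, 1.5²) per protein, a
  small shared subject offset (SD 0.1, a technical/biological row effect
  that correlates proteins within a subject), residual SD 1.0. In the
  default `archetype` link mode the planted effect adds
  `planted_shift × residual SD` (default 0.5) to planted proteins for
  western subjects, ~90% shifted up and ~10% down, echoing the
  predominantly upward signatures seen in pro-inflammatory-diet studies;
  `dii-quantile` mode scales the shift by each subject's centered DII
  rank instead, for sharper dose-response power studies. Olink-specific
  artefacts (LOD censoring, plate effects, bridging) are not simulated,
  so passing tests validate the statistics, not assay QC.

* **Annotation.** A GMT over the synthetic panel with one term collecting
  the planted proteins plus random terms of size 15-40.

### Standard study sizes

The validation studies run at the sizes the analysis is designed around,
chosen to keep a full run in minutes on one core: null calibration uses
20 cohorts of 300 subjects × 368 proteins with `planted_shift = 0`
(feature selection falls back to the raw-p rule there, since FDR
correctly selects nothing under the null); recovery uses 20 default
cohorts (400 subjects, 30 planted proteins at 0.5 SD). Unit tests use a
20-subject, 40-protein `tiny` bundle.

## Numerical notes and edge cases

* All randomness flows from explicit `numpy.random.default_rng` seeds; no
  global RNG state is touched. Rerunning any stage with the same seed and
  configuration is byte-identical (the manifest timestamp excepted).
* BH p-values entering the adjustment are clipped at the smallest
  positive float only to guard against underflow at p = 0; the rank and
  t tests cannot produce 0 exactly.
* `stratified_split` delegates to scikit-learn's stratified splitter;
  with 663 subjects labelled 332/331 it yields a 397/266 partition with
  class shares within one subject of 60% each.
* Substitution chains are followed transitively with cycle detection.
* Nutrient units are declared once per table (g, mg, µg accepted, with µg
  aliases) and validated, never converted; a unit mismatch between a
  profile and the reference is a hard, named error.

## Known limitations

* The DII reference shipped here is a synthetic stand-in; real analyses
  must supply the published parameter table they intend to use.
* The normality gate uses the moment-fitted KS test, which is
  anti-conservative at small n (the Lilliefors correction is not
  applied); at cohort sizes of hundreds this has negligible effect on
  which test is chosen.
* Fold-enrichment results depend entirely on the supplied annotation and
  background; no GO graph propagation is performed.
* The classifier protocol (single 60/40 split, fixed 1000 rounds) is kept
  faithful to the study design it mirrors rather than to best-possible
  predictive practice (no nested CV, no early stopping).
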