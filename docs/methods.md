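# Methods

`rootstress` reimplements, as a tested library, the statistical analysis
of maize (*Zea mays*) root-type morphology under single and combined
abiotic stress: four treatments (well-watered control at 25 °C, drought
at 30% field capacity, heat at 32 °C, and their combination), four
replicate plants per treatment, and four root types (the embryonic
primary and seminal axes and their lateral roots). This note records the
models, the defaults and why, the numerical choices, and what the
synthetic data can and cannot show.

## Trait decomposition

For each plant and root type, with root length L (cm), volume V (cm³),
dry weight DW (g) and whole-plant dry weight PDW (g):

- root length ratio RLR = L / PDW (cm g⁻¹),
- root mass ratio RMR = DW / PDW (g g⁻¹),
- root fineness RF = L / V (cm cm⁻³),
- root tissue density RTD = DW / V (g cm⁻³).

These satisfy the exact identity **RLR = RMR × RF / RTD**, since
(DW/PDW)(L/V)/(DW/V) = L/PDW. The identity is enforced as a property
test over random positive inputs and across every generated raw-level
plant. Axis root types additionally carry a branching density
BD = lateral count / branching-zone length (n cm⁻¹); lateral classes
carry their count and the average lateral length, defined here as total
lateral length / count (the source tables report the quantity without a
formula). Root and plant totals are sums over the four root types plus
the shoot.

A point of internal tension in the published summary tables: the
printed RLR cells are consistent neither with means of per-plant ratios
nor with ratios of treatment means (e.g. the control primary row gives
0.01381 × 336 / 0.075 ≈ 61.9 against a printed RLR of 63). This package
computes per-plant ratios and averages them, the estimand a per-plant
decomposition supports.

## Synthetic data

No per-plant data are deposited, so the generator regenerates the
design from the published evidence: per-treatment trait means and
standard errors (n = 4). The plant-to-plant law is normal with
SD = SE × √4, truncated to positive values by resampling — the simplest
law matching the two published moments; normality is an assumption of
this artifact, not a claim about the real data. A zero SE yields the
mean exactly. All draws come from one `numpy` generator seeded from the
config, so a config and seed fully determine the dataset.

`raw_level` mode instead draws raw measurements and *computes* the
derived traits, so the decomposition identity holds exactly per plant.
Whole-plant dry weight is anchored first (from the primary axis's dry
weight / mass ratio, ≈0.62–0.80 g depending on treatment, with a 10%
coefficient of variation across plants), then lengths, dry weights and
fineness are drawn per root type and the volume set as length/fineness.
Two constraints are imposed by bumping: fresh weight ≥ 1.05 × dry
weight, and axis length ≥ root zone + branching zone (the published
control primary row violates the latter on average — 9 + 42 > 49 cm —
so a small upward length bias for that cell is accepted and documented
here). Shoot fresh weight follows from a whole-plant dry-matter
fraction of 0.10, a typical value for young maize seedlings; it only
affects plant fresh weight, which no downstream statistic in this
package depends on critically. Because ratio traits are drawn via their
components, their per-treatment means match the tables only
approximately (within a few percent at large n); `trait_level` mode is
exact in expectation and is the default for calibration work.

What passing tests on these data do show: the estimators, the
permutation machinery and the cross-validation loops behave correctly
at the study's exact design size. What they cannot show: anything about
trait–trait correlation structure (traits are drawn independently in
`trait_level` mode), non-normal tails, or measurement error of the
imaging pipeline — so multivariate results on synthetic data
(e.g. PERMANOVA R², sPLS-DA error rates) are qualitative analogues, not
predictions of the published values.

## Univariate screen

One-way ANOVA per (root type × trait), followed by Tukey's HSD over all
six treatment pairs at α = 0.05 (Tukey–Kramer for unbalanced groups,
an extension beyond the balanced study design) and a compact letter
display via the insert-and-absorb algorithm: start from one column
holding all treatments, split a column for each significant pair,
absorb columns that become subsets, and letter the surviving columns so
that the largest mean carries "a" — the convention of the published
tables. Sharing a letter is equivalent to "not significantly
different"; non-transitive patterns are representable (a treatment may
carry several letters). Degenerate traits (zero variance) are flagged
rows, not failures.

The screen reports two counting conventions, because the source text's
"eight significantly modified primary traits" is not recoverable from a
single rule: the count of traits with a significant ANOVA, and the
count whose combined/stress letters share nothing with the control's.

## Combined-stress interaction classification

For a trait with control mean m_c, each combined-treatment plant
contributes an observed effect size Ob_i = |ob_i − m_c| / m_c, and each
single stressor an independent effect Ind = |m_stress − m_c| / m_c.
The expected additive effect under the multiplicative risk model is

    Ex = Ind_D + Ind_H − Ind_D · Ind_H,

which is bounded by max(Ind_D, Ind_H) ≤ Ex ≤ Ind_D + Ind_H and
saturates at 1 — avoiding the inflation of a plain sum. Ex is a scalar
computed from treatment means; only Ob varies per plant. The classifier
takes the two-sided 95% CI of mean(Ob_i − Ex): synergistic if entirely
above zero, antagonistic if entirely below, additive otherwise. The
default CI is a Student-t interval with n−1 df (the source describes
only "mean difference ± 95% CI"); a seeded percentile bootstrap is
available behind a flag, and on clearly one-sided inputs the two agree.
Because effect sizes are absolute values, the direction of the raw
change (increase/decrease) is tracked separately for reporting.

Eligibility mirrors the published workflow: only traits whose combined
letters are disjoint from the control's in the univariate screen are
classified. From the printed means alone, the six published nonadditive
directions reproduce deterministically: Ob − Ex < 0 for primary
fineness and branching density, > 0 for primary-lateral length, surface
area and RLR and for seminal-lateral length.

## PERMANOVA

Traits are z-scored column-wise (zero-variance columns dropped with a
warning) and Euclidean distances taken — the source does not name a
metric; Euclidean on standardized morphometric traits is the standard
choice and makes the 1-D equivalence with classical ANOVA an exactly
testable oracle. The total sum of squares is Σ d²ᵢⱼ / N over pairs; the
within-group part sums each group's pairwise d²/n_g; pseudo-F =
(SS_between/(k−1))/(SS_within/(N−k)). p-values come from free
permutation of all labels (no strata), with the observed statistic
included in the reference set (p ≥ 1/(B+1)); B = 999 by default.
Pairwise contrasts rerun the test on each pair's samples and adjust the
six p-values by Benjamini–Hochberg (via `statsmodels`). For the study
design the df row is always (3, 12, 15). Which trait set enters is
configurable; the default is all root-type traits (plant-level totals
excluded).

## Sparse PLS-DA

A NIPALS PLS2 regression of the class-indicator matrix on the trait
matrix. X is centred and unit-variance scaled (traits have mixed
units); scaling parameters are stored in the model for prediction. The
indicator matrix is centred but not scaled or sparsified — only the
number of X variables (traits) is tuned. Per component the X-weight
vector is soft-thresholded so that `keepX_h` entries survive: the
threshold is the largest magnitude strictly below the keepX-th largest,
so boundary ties are all retained (count may exceed keepX); magnitudes
shrink by the threshold, signs are restored and the vector is
renormalised. With keepX = p the operator is inert and the fit is dense
PLS-DA — verified both internally and against scikit-learn's NIPALS
PLS regression to < 10⁻⁸ on the scores. X and the indicator matrix are
deflated by the rank-one regression on each score; new samples project
through R = W(PᵀW)⁻¹. Per-component explained X-variance is
(tᵀt)(pᵀp)/‖X₀‖²_F, cross-checked against explicit residual deflation.

Classification is nearest class centroid in score space (Euclidean),
with exact ties broken to the earlier class in label order. The
balanced error rate (BER) is the mean over classes of each class's
misclassification fraction, invariant to class-size imbalance.

Model selection uses repeated stratified k-fold cross-validation,
5 folds × 50 repeats by default — but with n = 4 per class a literal
stratified 5-fold is impossible, so folds shrink to the smallest class
size with a warning (an unstated wrinkle of the original design size).
`perf` scores component counts with dense fits; `tune` selects keepX
greedily per component, holding earlier components fixed and taking the
*smallest* grid value attaining the minimal mean BER (parsimony; a
"within one SE" rule is a documented alternative, not implemented).
Repeat r uses seed + r, so curves are reproducible.

Selected traits are attributed to treatments as in contribution plots:
the class whose group mean of the scaled trait is maximal (minimal for
negative loadings), reported with the loading sign; ties break to the
earlier class and are flagged. Pearson correlations (with two-sided
t-test p) link plant fresh/dry weights to the latent scores when
plant-level totals are present.

The `planted_class_data` benchmark encodes the structure the method is
meant to detect — one discriminative trait per component, as mutually
orthogonal class contrasts (linear/quadratic/cubic over the four
classes, amplitudes 3/4/2.5 against unit noise, five further pure-noise
traits, n = 4 per class). Under it, tuning recovers keepX = 1 and the
planted columns in ≳90% of seeded runs, and dense CV error falls far
below the 4-class chance BER of 0.75.

## Pipeline

`run_all` sequences load/simulate → univariate → interaction →
PERMANOVA → sPLS-DA → correlations, writing CSV/JSON reports and a
manifest (seed, config, package version, stage summaries) that
reproduces the bundle bit-identically. Stages derive their seeds from
the run seed by fixed offsets. A failing stage aborts with a
stage-named error; outputs already written are kept. All computation
lives in the stage modules; the orchestrator only sequences and
serialises.

## Problem sizes and numerical choices

Defaults chosen for the analyses and checks shipped here: synthetic
designs at the study's own n (4 × 4 plants); large-n calibration checks
at 10⁴ draws (2% tolerance); identity checks on 1000 raw-level plants;
PERMANOVA null calibration over 1000 simulated datasets at 99
permutations each (KS uniformity); tuning recovery over 50 seeded
benchmark runs at 10 CV repeats; chance-BER estimation over 25 noise
datasets × 8 repeats (200 CV repeats in total); type-I error of the
ANOVA screen over 1000 null datasets × 10 traits. NIPALS converges at
10⁻⁹ on the weight change (tightenable per call); permutation and
bootstrap streams are always explicitly seeded.

## Known limitations

- Treatments are labels; no soil-physics, water-balance or temperature
  response is simulated.
- The interaction model is defined for exactly two stressors.
- No nested/strata PERMANOVA, no dispersion (PERMDISP) test.
- No multilevel sPLS-DA, no AUROC tuning, no plotting beyond CSV/JSON
  exports of plot data.
- Published multivariate endpoints (R² = 0.6693, the 27/14/11%
  explained-variance split, BER ≈ 0.18) depend on the real trait
  correlation structure and are therefore not reproduction targets of
  the synthetic pipeline; the package reproduces the deterministic
  worked examples and the method-level calibration properties instead.
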