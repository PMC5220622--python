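# Methods

## Association model

Each feature's log10 intensity is modelled as a linear mixed-effect
regression with serum FT4 (pmol/L) as the exposure and a random intercept per
participant absorbing the repeated-measures correlation. Fixed effects are
the intercept, FT4, baseline age (years) and BMI (kg/m²); the proteome layer
additionally receives treatment-coded experimental-batch indicators. The fit
is on complete cases per feature: samples with a missing intensity are
dropped for that feature only, samples with missing FT4 or covariates are
dropped globally.

### Estimation

Writing λ = τ²/σ² for the ratio of the random-intercept and residual
variances, the marginal covariance is σ²(I + λZZ'), block diagonal over
participants, so β and σ² can be profiled out analytically and the restricted
likelihood becomes a smooth scalar function of λ. `thyromics.lmm` evaluates
this profile on a fixed grid (λ = 0 plus 101 log-spaced points over
10⁻⁶…10⁴) and polishes the per-feature optimum by parabolic interpolation in
log10 λ. Per-group inverses use the Woodbury identity, and the whole grid is
evaluated jointly for every feature sharing a missingness pattern, which is
what makes the 101-subset robustness stage and the repeated-simulation
calibration experiments affordable (hundreds of thousands of refits in
minutes on one CPU). λ = 0 is an admissible optimum: a feature without
between-participant variance cleanly reduces to ordinary least squares.

The fitter is cross-checked in the test suite against statsmodels `MixedLM`
(REML) — coefficients agree to ~10⁻⁵, residual variance to machine precision
— and against the closed-form GLS solution when λ is fixed at its true value.

### Inference

The Wald statistic for the FT4 coefficient is referenced against a
t distribution with df = n − g − p + 1 (n complete-case samples, g
participants, p fixed effects) — the residual degrees of freedom once group
means and fixed effects are absorbed. For a within-participant exposure like
FT4 this is close to the Satterthwaite value and slightly conservative. A
plain normal reference is tempting but measurably anti-conservative here: at
16 participants it inflates the far tail (where BH rejections happen, p ~
5·10⁻⁴) by roughly a factor of two, which breaks family-wise false-positive
calibration. Both alternatives remain available via
`df_method = {"within", "residual", "normal"}`.

REML is the default (`reml=False` gives full ML); the Benjamini-Hochberg
adjustment (statsmodels `multipletests`) is applied separately per omics
layer, mirroring the separately curated metabolome and proteome panels.

## Robustness by leave-three-out subsampling

`make_subsets` draws 100 distinct leave-three-out participant triples
uniformly at random (collisions with each other or with the fixed exclusion
are rejected) and appends one fixed subset excluding the designated
idiosyncratic responders: 101 pairwise distinct subsets on 16 participants
(C(16,3) = 560 triples exist). The screen is re-run per subset with FDR
re-computed *within* the subset, and per feature the mean and SD of the
estimate and of the adjusted value are taken across subsets; the significance
rule is mean FDR < 0.05. Averaging adjusted values (not p values) follows the
procedure's literal description; it makes calls depend on consistent
behaviour across subsets rather than on a single lucky split. A feature must
converge in ≥ 80% of subsets to receive a call at all — this threshold is a
package choice preventing averages over tiny denominators. SDs are
descriptive (sample SD over converged subsets, 0 for a single subset).

## Fold changes

For every feature and visit, each participant's value is divided by that
participant's own baseline value and the cell is the mean of the log2 ratios
(not the log of the mean ratio) over participants with both values present;
contributing counts are exported alongside. The summary is invariant to
per-feature rescaling and antisymmetric under ratio inversion, and the
baseline column is identically zero — all asserted as tests.

## Classification

Labels: `bas`/`w16` → euthyroid, `w4`/`w8` → hyperthyroid, `w12` dropped as
an intermediate state. Only features without any missing value among labelled
samples enter. Splits default to 2/3 training / 1/3 held out at both stages,
stratified by class (the fractions are a package choice; they are not pinned
by the procedure description). Sample-level splits are the default — a
participant's samples may land on both sides, matching the described
procedure; `subject_aware=True` instead keeps each participant entirely on
one side, which is the honest setting for generalization to new individuals
(classes are balanced within participant, so stratification is preserved).
Degenerate one-class splits are re-drawn.

Forests use scikit-learn defaults matching the classical implementation's
conventions: 500 trees, ⌊√p⌋ candidate features per split, unlimited depth.
Variable importance is scikit-learn's impurity-based (Gini) importance; ROC
scores are the forest's class-probability for the hyperthyroid class (the
average of per-tree leaf probabilities — with fully grown trees this is the
vote fraction). AUC is the trapezoidal area under the empirical ROC, which
equals pairwise concordance with ties counted ½ (asserted against brute-force
enumeration). Inner-loop importances are aggregated as
I = Σ AUC·g / Σ AUC. Two panels are reported rather than guessing which the
procedure intended: each outer loop's inner-aggregate panel (which drives
that loop's validation AUC), and the single global panel aggregated over all
outer × inner loops. Importance ties are broken by stable sort, then
lexicographic feature id.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes, with
planted ground truth:

- **Design**: n_subjects × 5 visits (defaults: 16 subjects → 80 samples);
  ages uniform on 22–34 years, BMI uniform on 21–30 kg/m²; exactly
  `n_outliers` (default 3) participants flagged as idiosyncratic responders.
- **Hormones**: FT4 and TSH are independent truncated normals (at zero) per
  participant and visit with per-visit means/SDs — FT4:
  13.2 (1.4), 28.6 (6.5), 25.9 (5.7), 11.5 (1.5), 12.8 (1.5) pmol/L;
  TSH: 2.104 (1.017), 0.017 (0.029), 0.007 (0.007), 2.298 (1.309),
  2.177 (0.897) mU/L. No within-participant autocorrelation is imposed (the
  trajectory source reports only per-visit moments); the parameter dict is
  fully configurable.
- **Features**: log10 intensity = μ_j + β_j·FT4 + γ_age·age + γ_bmi·BMI +
  b_participant + batch shift (proteins) + idiosyncratic outlier shift + ε,
  then multiplied by a run-day scale factor and exponentiated to the raw
  scale. Defaults: μ_j uniform on log10 raw counts 4–7; a fraction of
  features (0.19 metabolites, 0.14 proteins) carries a nonzero β_j with sign
  splits 45:20 and 47:16 and |β_j| log-uniform on 0.005–0.03 (per pmol/L;
  with FT4 spanning ~17 pmol/L this is ~1.2- to 3-fold excursions);
  participant intercept SD 0.20, residual SD 0.15, proteome batch-shift SD
  0.10 (two batches assigned by participant), run-day scale factors
  10^U(−0.2, 0.2) over run days of 10 samples each.
- **Acquisition order** is randomised before run days are chunked. This
  matters: if acquisition were visit-blocked, run day would be confounded
  with visit and the per-run-day median rescaling would absorb most of the
  FT4 signal (~3× attenuation of fitted slopes in our measurements).
  Randomised measurement order is standard practice for exactly this reason.
- **Missingness** concentrates in a subset of features, as in LC-MS data:
  half the features (configurable) draw a per-feature missingness rate
  uniform on (0, 0.5], straddling the 40% filter boundary so the filter is
  genuinely exercised; modes are completely-at-random or left-censoring below
  the per-feature rate quantile.
- **Outlier responders** receive an extra per-feature shift (SD 0.5) on a
  designated 5% feature subset, emulating participants whose response
  deviates on specific markers.

What the generator does **not** emulate: compound identities and correlated
feature blocks (features are conditionally independent given the design),
peptide-to-protein roll-up, intensity-dependent variance beyond
left-censoring, assay drift within a run day, or hormone autocorrelation.
Passing tests therefore demonstrate that the *procedures* are correct and
calibrated under the assumed model — not that the model captures every
property of measured plasma omics data.

## Preprocessing conventions

Run-day rescaling divides each feature by its median (standard mid-point
convention, non-missing values only) within each run day; a zero median
cannot be divided out, so those cells become missing with a logged warning.
By default only the metabolome is rescaled (the correction is a metabolome
platform convention); a flag extends it to the proteome. The missingness
filter keeps features with *strictly* less than 40% missing values, computed
per layer over all samples before any subsetting. Zeros and negative raw
values become missing at the log10 step rather than being imputed (the log is
undefined and imputation is out of scope).

## Numerical choices and degenerate inputs

- λ grid 0 ∪ 10⁻⁶…10⁴ (10 points/decade); boundary optima are accepted
  (λ = 0 → OLS). RSS is floored at the smallest positive float so noiseless
  features fit exactly instead of producing −∞ logs.
- Features with fewer than two participants contributing two or more
  observations, or with n ≤ p complete cases, are flagged unfit and excluded
  from the FDR computation with a warning.
- Rank-deficient designs surface as linear-algebra failures and flag the
  whole pattern batch unfit rather than returning garbage.
- Single-batch subsets drop the batch column (nothing to adjust).
- Classification re-draws degenerate one-class splits up to 100 times, then
  raises.

## Experiment sizes

The calibration experiments (`thyromics.experiments`, also driven by
`scripts/acceptance.py` and the acceptance tests) use desk-scale sizes chosen
to keep Monte-Carlo error small while remaining minutes-fast on one CPU: 200
global-null cohorts of 100 features with a reduced 20-subset robustness plan
for false-positive calibration; 200 replicates at low noise (residual SD
0.05, intercept SD 0.10, β = 0.02) for recovery and coverage; 20 permuted-
label replicates and one strong-separation run (|β| 0.02–0.04, residual SD
0.10) at reduced CV sizes (5 × 6 loops, 40 trees) for classifier sanity; and
10,000 subjects for hormone-trajectory calibration. The structural nested-CV
check runs the full 30 × 50 loop counts with 100 features and a reduced
forest (40 trees), since loop structure does not depend on forest size.

## Known limitations

- Wald/t inference ignores uncertainty in the estimated variance ratio; at 16
  participants the reported SEs are ~4–5% optimistic (measured by
  simulation), giving ~93% coverage of nominal 95% intervals. The robust
  mean-FDR rule remains conservatively calibrated.
- The mean-FDR significance rule has no finite-sample FDR guarantee; it is a
  stability heuristic, reproduced here literally.
- Random forests with strongly correlated informative features spread Gini
  importance across them; panel composition is therefore seed-sensitive when
  effects are weak, even though panel *performance* is stable.
- The generator's independence across features makes power estimates
  optimistic relative to correlated real data.
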