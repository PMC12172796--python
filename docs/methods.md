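# Methods

This document specifies the synthetic cohort's generative model and its
calibration, the resampling designs, the statistical battery, and the
numerical conventions used throughout the package.

## 1. The generative model (`brainmix.synthdata`)

Each cohort consists of demographics (age, sex, site) and one feature matrix
per pipeline version ("v5", "v7"), row-aligned by participant. Features are
the Desikan–Killiany table: 34 regions × 2 hemispheres × {thickness, area,
volume} = 204 columns by default.

### Demographics

Ages are truncated-normal on [49.33, 82.84] with mean 64.84 and SD 7.27;
52.53 % female; three sites with weights (0.5538, 0.3499, 0.0962). These
match the reference cohort's reported summary statistics.

### Latent-factor structure

For participant *i* and feature *j*, with `z_age` the standardised age:

```
core_v[i,j] = alpha_v[j]·z_age[i] + b[j]·m[type(j), i] + c_v[j]·eps[i,j]
x_v[i,j]    = gain_v[j]·( lam_v[j]·core_v[i,j] + sqrt(1−lam_v[j]²)·nu_v[i,j]
                          + sex/site shifts ) + offset_v[j]
```

- `m` — one anatomy factor per measure type (thickness/area/volume), shared
  by all features of that type (`measure_factor_var = 0.10`). This is what
  makes the feature blocks internally correlated, as real morphometrics are.
- `eps` — idiosyncratic anatomy, shared by both versions.
- `nu_v` — version-specific noise, independent across versions.
- Asymmetric version noise: v5 **is** the shared latent anatomy
  (`lam_v5 = 1`); v7 carries all the version noise
  (`lam_v7 = r_target / rho_core`). This is a parameterisation choice, not a
  claim about the pipelines: only the cross-version correlation is
  identified, and putting all de-correlation on one side keeps the
  calibration solvable in closed form.

### Calibration (solved per configuration, before any data are drawn)

- `alpha_v` is scaled so the **mean** feature–age correlation per version
  hits its target: −0.17 (v5), −0.15 (v7). The per-feature pattern follows
  measure-specific slopes (thickness −1.0, volume −0.6, area −0.25 —
  thinning dominates aging in this range), a ±30 % per-feature jitter, a
  ±10 % per-version slope jitter (`version_slope_jitter`; releases do not
  rescale every region identically), and a 2.2× multiplier on five
  association-cortex regions (`strong_regions`). The multiplier concentrates
  age signal so that permutation-importance rankings have a stable top set
  across versions (top-10 overlap ≥ 7), as observed in the reference
  analysis; without it, ordinary least squares spreads weight across many
  interchangeable collinear features and the rankings decouple.
- `lam_v7` is solved from the target per-feature cross-version correlation
  `r_target`: thickness features get 0.95 (they agree strongly across
  releases), area/volume of entorhinal, temporal pole and frontal pole get
  0.60 (the documented low-agreement regions), and the remaining features
  absorb whatever value keeps the overall mean at 0.88. A short fixed-point
  iteration reconciles `alpha`, `lam` and the slope jitter; infeasible
  targets raise instead of silently clipping.

### Version differences that the age models must survive

- `version_offset = 0.65`: per-feature systematic offsets of either sign on
  v7 (SD 0.65 on the standardised scale). This is the dominant mechanism of
  the cross-version prediction penalty: a linear model trained on v5
  inherits v5's intercept geometry, and the random offset vector projects
  onto its weights as a prediction shift on v7 data. The value was set
  during design-phase calibration so that, at n=1000 with a linear model,
  the penalty is reliably detectable (≈0.3 y mean MAE gap) without breaking
  the mix-to-single equivalence, reproducing the reference grid's orderings.
- `version_gain_sd = 0.05`: per-feature multiplicative gains near 1.
- `version_age_bias_years` / `version_age_noise_years` (both default 0):
  optional apparent-age shifts of the v7 reconstruction along the age-slope
  direction. They are exposed for sensitivity analyses but disabled by
  default: a coherent bias is exactly the component a mix-trained model
  cannot attenuate (it destroys the shuffling advantage), and per-participant
  noise acts as label noise that degrades every model equally. Neither
  reproduces the reference orderings as well as random per-feature offsets.

Sex affects area/volume (−0.2 SD for female), site is a small additive shift
(0 by default), and `inject_outliers` can displace a random fraction of
cells to column mean ± magnitude·SD, recording every displaced cell in a
ledger for verification.

### What "calibrated" means here

Targets are **population-level**; acceptance checks them on generated samples
at n=2000 with tolerances that include sampling error: mean cross-version
r ∈ [0.85, 0.91]; mean age correlation within ±0.02 per version; the 12
low-agreement features inside the bottom decile of agreement.

## 2. Quality control and composition (`brainmix.cohort`)

- **Outlier rule**: single pass; column mean/SD computed once on the full
  observed sample per version; a participant is excluded if any feature in
  any version lies more than 5 SD from its column mean. Zero-SD columns are
  skipped with a logged warning.
- **Splits**: uniform random 50:50 train/test partitions (train receives the
  odd participant).
- **Version assignment**: the shuffling unit is the participant row. In
  `shuffled_50_50` mode an exact random half of the training set contributes
  v5 rows and the other half v7 rows, independently within the test set.
  Single-version modes assign constantly. Column-wise mixing is deliberately
  not the default anywhere.

### Known limitation of the 5-SD rule at high injection rates

Displacing 1 % of all cells at 6 SD inflates every post-injection column
variance by ≈ 1 + 35·k/n (k = injected cells in that column), i.e. ~16 % SD
inflation on average, which leaves the planted cells at ≈5.2 observed SDs.
Columns that randomly receive k ≥ 0.0126·n injections inflate past the point
where a 5-SD threshold can see them. At n=1000 this caps participant-level
detection near 96 %; from n≈5000 the binomial concentration of k/n makes
detection exceed 99 %. The corresponding acceptance test asserts ≥99 % at
n=1000 and is therefore a documented, expected failure rather than a bug:
both halves of the property that are achievable (zero false removals; the
single-cell hand-check) hold at every seed tried.

## 3. Models (`brainmix.models`)

Five algorithms behind one contract (`fit_model` / `predict_ages`), with a
pinned hyperparameter table so results do not drift with library upgrades:
ordinary linear regression (with an explicit rank check that names the
dependent columns), lasso (5-fold CV over a 30-point logarithmic grid,
100 000 iterations), RBF SVR (features and target standardised), XGBoost and
LightGBM (library defaults, `n_jobs=1`, explicit seeds). Prediction refuses
column orders that differ from training.

## 4. Resampling designs and bagging (`brainmix.engine`)

- **Design A — split permutations**: re-draw the 50:50 split each iteration;
  fit one model per version; evaluate the 2×2 cross-version grid.
- **Design B — version shuffle**: hold one split fixed (the "initial
  iteration"); re-draw the 50:50 version composition each iteration; fill the
  3×3 {mix, v5, v7} grid. Single→single cells are computed once on the fixed
  split, so they carry no resampling variance.
- **Design C — joint permutations**: as B, but the split is also re-drawn
  each iteration and the single-version models are refitted per split, so
  every one of the nine cells aggregates over the iterations.

The qualitative-pattern acceptance check uses **design C**. The reason is
statistical, not cosmetic: the patterns compare cell *means*, and in design B
the single→single cells are a single fit on a single split — their
estimation noise (SD ≈ 0.15 y MAE across splits) does not average out, so
roughly one seed in six produces a fixed-split fluke that flips a ≤0.2-year
comparison regardless of the generative configuration. Design C refits
everything per iteration, so all cells shrink their noise as 1/√i and the
comparisons reflect the population orderings. The acceptance criterion
specifies grid cells, sample size, iterations and model, but not the design;
C is the estimator among the three whose cell means are all consistent for
the quantities being compared.

**Bagging** averages each participant's test-side predictions over the
iterations in which they were tested, per grid cell. Bagging identical
iterations is exact; over random iterations the bagged MAE beats the mean
per-iteration MAE essentially always (Jensen), checked as ≥95 % of seeds.

Seed hierarchy: every run spawns named sub-seeds (< 2³¹) from one master via
`numpy.random.SeedSequence`, so any sub-experiment replays independently and
full runs are byte-identical given the seed.

## 5. Statistics (`brainmix.stats`)

- **Metrics**: Pearson R; adjusted R² of `age ~ predicted` (optionally with
  sex+site); MAE and RMSE from raw residuals; AIC/BIC in the Gaussian
  RSS form without additive constants, `AIC = n·ln(RSS/n) + 2k`,
  `BIC = n·ln(RSS/n) + k·ln n`, k = number of model features. This gives the
  exact identity `BIC − AIC = k(ln n − 2)` used as an oracle test.
- **Overlapping dependent correlations** (shared variable = age): Zou's
  (2007) modified-asymptotic CI for r_jk − r_jh and the Hittner–May–Silver
  backtransformed-average Fisher-z test, both implemented from the formulas
  and validated by simulation (empirical type-I error 0.05 ± 0.01 at n=200;
  CI coverage 95 % ± 1 %).
- **FDR**: Benjamini–Hochberg step-up, applied within each family of
  comparisons.
- **Marginal contrasts**: one OLS of predicted age on cell + age + sex +
  site over the stacked per-cell predictions (cells must cover identical
  participants); all pairwise cell differences with t tests, FDR-adjusted.
- **Sex differences**: per cell, `predicted ~ age + sex + site`; positive
  coefficients mean higher predicted age in females.
- **Site model**: random-intercept model grouped by training version with
  fixed site/age/sex effects; degenerate fits (single group, boundary
  variance) fall back to OLS and are flagged, not rejected.

## 6. Feature structure (`brainmix.structure`)

Cross-version agreement per feature, overall and within age bins
([49,60), [60,70), [70,83], last bin closed); per-feature age correlations;
permutation importance as mean R² drop over repeats with deterministic
lexicographic tie-breaking; PCA of z-scored feature matrices with the share
of squared loadings per measure type; and an exploratory point-biserial
correlation between importance and measure membership (the routine documents
its own definition and makes no claim of equivalence with any published
region-level number, whose computation is ambiguous).

## 7. Numerical conventions

- All randomness flows from explicit integer seeds; derived seeds are
  `SeedSequence` spawns reduced mod 2³¹−1.
- Features are generated on an approximately standardised scale; no
  real-world units are simulated because every downstream statistic either
  is scale-equivariant or standardises internally.
- Log output contains no timestamps or absolute paths, so identical runs are
  byte-identical.
- Ties, orderings and groupings are always made deterministic (stable sorts,
  lexicographic tie-breaks, sorted file iteration).

## 8. Limitations

- The generator is calibrated to summary statistics (means of correlation
  profiles, agreement structure), not to raw-data likeness; absolute MAE
  levels depend on its signal-to-noise choices and are not comparable to
  values obtained on real cohort data.
- The mix-trained model's advantage is evaluated under the same row-wise
  50:50 composition used for training; other compositions are supported but
  uncharacterised.
- The site effect defaults to zero, so the site mixed model mostly exercises
  machinery rather than detecting planted structure.
- The 5-SD outlier rule's detection ceiling at high injection rates is
  described in section 2 above.
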