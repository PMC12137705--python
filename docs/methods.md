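# Methods

This note documents the models and procedures implemented in `couplemap`,
the assumptions behind them, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not emulate.

## Data model

The pipeline consumes, per participant: a symmetric non-negative weighted
structural connectome (SC) with zero diagonal on N ≥ 3 regions
(streamline-density-like weights); one functional connectome (FC) per
scanning condition, stored as Fisher z-transformed Pearson correlations with
the diagonal fixed at 0 (the self-correlation is infinite after atanh and is
excluded everywhere downstream); and a participant row with the phenotype
score `g` and nuisance covariates age (years), gender (0/1), handedness
(signed laterality score) and mean framewise displacement (mm) per
condition. Matrices live one-per-file (delimited text or HDF5) bound by a
YAML manifest; multiple FC runs per condition (e.g. opposite phase-encoding
directions) are averaged element-wise on load. Asymmetry up to 1e-6 is
treated as I/O noise and averaged away; beyond that an SC is rejected while
an FC is symmetrized with a warning, since FC asymmetry can only be a
storage artifact whereas an asymmetric SC signals upstream corruption.

Out of scope by design: image-level processing (tractography, parcellation,
nuisance regression) and the construction of the phenotype score from raw
test batteries; both happen upstream and the package consumes their outputs.

## Predictor matrices

Four matrices are derived from each SC, chosen to span signaling strategies
from protocol-free similarity to routing, diffusion and path accessibility:

* **Cosine similarity (CoS).** Entry (i, j) is the cosine between SC columns
  i and j with entries i and j removed from both profiles, so the direct
  edge and the (zero) self-weights cannot trivially inflate similarity; a
  config flag restores the full-profile variant for sensitivity analyses.
  Zero-strength regions get a zero row/column with a warning. Diagonal 1.
* **Path length (PL).** Dijkstra all-pairs distances on edge lengths from a
  configurable weight-to-length rule: `1/w` (default) or `−log(w / max w)`.
  Both are standard in weighted connectomics; the choice is isolated in one
  function and recorded in the output metadata.
* **Communicability (G).** `exp(S)` with `S = D^{-1/2} W D^{-1/2}`,
  `D = diag(strength)`, computed by symmetric eigendecomposition.
  The strength normalization is required for streamline-density-scale
  weights, whose raw exponential overflows; it is also the form used in the
  weighted-brain-network communicability literature. No post-adjustment.
* **Search information (SI).** Raw directed SI(i→j) is `−log2` of the
  product of step probabilities `w_uv / strength(u)` along the shortest path
  from i to j (paths on the weight-to-length graph); the matrix is then
  symmetrized, `(SI(i→j)+SI(j→i))/2`, and adjusted.

**The "adjustment".** PL and SI measure cost, the other two affinity. Both
cost matrices are inverted so that larger uniformly means easier
communication. Inversion is implemented as negation (default) rather than
elementwise reciprocal: negation is monotone over the whole range, keeps
zeros and sentinels well behaved, and only the ordering matters for the
column-wise correlations downstream. The reciprocal is available as a config
option for sensitivity analyses.

**Degenerate inputs.** Unreachable pairs receive a sentinel of 1.5× the most
extreme finite value (with a warning) instead of being dropped, keeping
matrix shape; synthetic SCs are generated connected, so sentinels arise only
in pathological inputs. Tied shortest paths take the deterministic
predecessor choice of the Dijkstra implementation and are documented as an
approximation; the SI oracle tests use continuous random weights, where ties
have probability zero.

## Coupling

Region-specific coupling `r_C[i]` is the Pearson correlation between column
i of a predictor matrix and column i of a condition's FC matrix over the
N−1 off-diagonal entries. Both i↔j entries remain in the profiles; only the
undefined diagonal is dropped. Degenerate (constant) profiles produce
`r_C = 0` with a warning rather than NaN, keeping downstream means defined.
The cohort's values form a 4-D table (participant × condition × measure ×
region); brain-average coupling is the mean over regions, then over measures
(per condition) or conditions (per measure).

## Group-level descriptives

* **Condition/measure contrasts.** One-way repeated-measures ANOVA over the
  brain-average values (Greenhouse–Geisser corrected when Mauchly's test
  gives p < 0.05 — standard practice; the contrast itself does not presume
  sphericity), followed by all pairwise contrasts of marginal means. In this
  balanced within-participant design the marginal means are the condition
  means, each contrast a paired t statistic; the default family-wise
  adjustment is Tukey-style via the studentized range (`q = |t|·√2` on k
  groups and n−1 df), with Bonferroni as the configurable alternative. If
  all levels are identical within participants the F ratio is 0/0; it is
  reported as F = 0, p = 1 with a warning.
* **Regional patterns.** Per condition, each region is assigned the measure
  with the highest participant-mean `r_C²` (variance in FC explained); the
  pattern value is the mean winning `r_C²` and the dispersion its SD across
  participants. Ties go to the earliest measure in the canonical order
  (CoS, PL, G, SI) and are logged.
* **Pattern similarity.** Pearson correlations between the condition
  patterns for all condition pairs; whether rest sits apart from the tasks
  is tested by a two-sample z-test comparing the Fisher-z of (rest, task)
  pairs against (task, task) pairs, using the theoretical variance
  1/(N−3) of a transformed correlation over N regions. Degenerate
  (|r| = 1) inputs are reported non-significant with a warning.
* **Adaptation maps.** Per task, |rest − task| per region
  (task-specific); |rest − mean over tasks| (task-general); and
  |task − mean over the remaining tasks| (task-specific against a
  leave-one-task-out task-general baseline). A task map's relative
  percentage is `100 · (mean_t − grand mean of task-map means) / grand
  mean`. The percentage baseline is a convention of this package (no
  canonical definition exists); raw map means are always reported alongside.

## Association

The partial correlation of x and y given covariates Z is the correlation of
their OLS residuals on [1, Z], with a two-sided p from the t distribution on
n − 2 − k degrees of freedom; rank-deficient covariate sets are rejected
with the collinear columns named. Residual norms below 1e-10 of the input
norm are treated as exact linear dependence (r = 0, p = 1). The
brain-average association scan runs one partial correlation per condition ×
measure (covariates include that condition's motion) and flags significance
at the Bonferroni threshold 0.05/4 = 0.0125.

## NMA prediction

The Basic model's protocol per repetition: draw a uniform random 5-fold
split (no stratification; each repetition reseeded from a spawned child of
the master seed); per fold, compute `r_P` (region × measure partial
correlations with `g` under the full covariate set) from the training folds
only, build the positive mask (argmax over measures) and negative mask
(argmin), extract each participant's features X1/X2 as masked region-means,
fit OLS on the training folds, predict the test fold. Predictions are
concatenated across folds and correlated with the observed scores;
performance is the mean of this correlation over repetitions (concatenation
over per-fold averaging is the dominant convention in connectome-based
prediction and is stable at n/5-sized folds). `R²` is reported both as the
squared mean r and as the mean per-repetition r², since the two diverge
under noise. Regions whose `r_P` are all of one sign keep the
argmax/argmin assignment and are flagged rather than dropped, preserving a
fixed feature definition. Argmax ties break by measure order. Raw `g` is
the regression target; covariates enter only through the `r_P` used to
build masks.

The Expanded model builds the two features per task condition (resting
state excluded), each condition's masks using its own condition-specific
motion covariate, and fits one OLS on all of them; a guard rejects
configurations whose feature count reaches the training fold size. With a
single task condition it reduces exactly (bitwise) to the Basic model.

**Permutation inference.** Phenotype scores are shuffled across
participants; covariates stay attached to the imaging data, preserving the
confound structure under the null. The full CV pipeline re-runs per
permutation with the same fold scheme and a reduced repetition count
(default 10, configurable to the full 100; the 1000-permutation × 100-
repetition protocol is cluster-scale). p uses add-one smoothing
`(1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, avoiding p = 0. Model
comparisons re-train both models on the same shuffled phenotype and count
`|Δr_perm| ≥ |Δr_obs|`. Cross-sample generalization freezes the masks and
coefficients of every fold model (5 per repetition), applies each to the
full replication cohort, averages the resulting correlations, and permutes
the replication phenotype against the frozen predictions for significance.

**Performance.** Fold "contexts" (orthonormal covariate bases and
residualized, normalized coupling columns) are precomputed once per fold
split; a permutation then costs one phenotype residualization and a matrix–
vector product per fold, which keeps the 100-permutation calibration studies
(200 cohorts × 101 pipeline runs) in the minutes range on one core.

## Synthetic cohorts

Two generators cover complementary needs.

The **matrix-level generator** emulates the joint structure of real
derivatives: participant SCs are multiplicative log-normal perturbations of
a group template built as a distance-dependent random geometric graph
(unit-cube coordinates, exponential distance decay, heavy-tailed log-normal
weights, connectivity guaranteed by the distance minimum spanning tree).
Condition-specific FC columns follow each region's preferred predictor
column, scaled by a regional coupling gradient (emulating the high-coupling
"unimodal" to low-coupling "multimodal" axis), a global condition offset
(rest +0.05, one low task −0.05 — the orderings the analysis should
recover), a rest-specific pattern component (SD 0.10, against task-specific
jitter SD 0.045, chosen so rest-task pattern correlations fall visibly below
task-task ones at realistic levels ~0.85 vs ~0.95), participant deviations
(SD 0.05), phenotype-linked amplitude modulation in signal regions, and
additive noise (SD 1.0, putting typical coupling near r ≈ 0.3–0.5). A
time-series mode samples multivariate-normal BOLD-like frames whose
correlation matches a target FC, for integration-testing the
time-series-to-FC path.

The **coupling-level generator** plants the same structure directly on the
`r_C` table with *exact* effect sizes: base levels combine a regional
gradient (0.25–0.55), measure offsets (CoS +0.05, SI −0.05) and condition
offsets (rest +0.05, one task −0.05); dispersion decomposes into a
participant effect (SD 0.015), condition interaction (SD 0.012) and cell
noise (SD 0.05), making the across-participant SD of brain-average coupling
≈ 0.02; each planted signal entry loads a latent factor such that
corr(g, r_C) equals the requested `effect_r` exactly, with the total
phenotype signal variance fixed (default R² = 0.10) and split evenly over
latent groups (one per signal condition). The phenotype is reported on a
mean 0.25 / SD 0.83 scale and is approximately normal. Covariates carry
weak phenotype correlations (age −0.10, gender +0.10, handedness 0,
motion −0.15); by default they do not load on coupling itself (a
`motion_on_coupling` knob exists), because phenotype-only permutation is an
exact null only under that independence — the calibration studies use the
default, and analyses of confounded coupling should treat the permutation p
as approximate. The resampling-heavy validation studies (condition-ordering
recovery, mask recovery, null calibration, effect-size monotonicity,
task-combined dominance, cross-sample transfer) run on this generator,
where the planted quantities are the quantities being recovered; the
matrix-level path is exercised end-to-end by the identifiability and
coupling-identity checks. Neither generator attempts biophysical realism:
no hemodynamics, no spatial autocorrelation of noise, no
acquisition artifacts — so passing tests certify the statistical machinery,
not robustness to scanner physics.

**Study geometries.** Validation runs use 60 regions with cohorts of
200–500 participants (condition ordering: n = 200; mask recovery: n = 400;
prediction calibration and transfer: n = 500; 100–200 simulations; 100
permutations × 10 repetitions inside calibration loops), which keeps the
full suite in the minutes range while leaving all planted-recovery margins
wide. A full-scale geometry (358 regions, ~500 participants, 1000
permutations, 100 repetitions) is a config change, not a code path.

**Task-combined dominance study.** The phenotype signal is split across two
task conditions (6 signal regions each, |effect_r| = 0.2, bounded by the
per-task latent share √0.05 ≈ 0.22) in a cohort containing exactly those
two tasks. Conditions that carry no signal are deliberately absent: the
adaptive mask-selection step manufactures training features from noise
conditions that look informative in-sample and dilute the combined
regression out-of-sample, so the dominance property is a statement about
combining *informative* conditions — consistent with cohorts in which every
retained task shows phenotype signal.

## Known limitations

* The marginal-mean pairwise adjustment uses the studentized range on
  paired t statistics — a Tukey-style convention, not an exact
  repeated-measures Tukey procedure.
* Shortest-path tie-breaking follows the underlying Dijkstra implementation
  rather than an explicit lexicographic rule; with continuous weights this
  is immaterial.
* The permutation test's reduced per-permutation repetition count (10 vs
  100) adds Monte-Carlo noise to the null distribution's tails; the
  calibration study bounds the resulting size distortion (rejection rate
  within [0.02, 0.09] at nominal 0.05).
* Effect sizes planted by the matrix-level generator are approximate
  (amplitude modulation propagates nonlinearly into correlations); exact
  effect-size statements use the coupling-level generator.

## Packaging

The package is a library: the importable API plus `examples/` scripts are
the interface, and `scripts/acceptance.py` reproduces the headline numbers
end to end. No command-line entry point is installed — the intended use is
from analysis code and notebooks, where the objects (coupling tables,
masks, prediction results) are the product.
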