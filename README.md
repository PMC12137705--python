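# couplemap

Structure–function brain network coupling and phenotype prediction.

`couplemap` is a Python library for asking how closely functional brain
connectivity (FC) follows the underlying structural connectome (SC), how that
alignment shifts between resting state and cognitive tasks, and whether its
regional organization predicts a behavioral phenotype such as a general
cognitive ability score. It is aimed at researchers working with
parcellated connectome derivatives (e.g. streamline-density SC matrices and
condition-specific FC matrices on a few hundred cortical regions) who want a
tested, reproducible implementation of coupling-based predictive modeling —
including all of its resampling-based significance machinery — plus a
synthetic cohort generator that makes every stage verifiable without access
to restricted neuroimaging data.

## The method

**Predictor matrices.** Each participant's weighted SC is transformed into
one similarity and three communication matrices that operationalize distinct
signaling strategies:

- **CoS** — cosine similarity of regional connection profiles (the
  protocol-free baseline),
- **PL** — shortest weighted path length (routing), on edge lengths
  `L_ij = 1 / w_ij`,
- **G** — weighted communicability `exp(D^{-1/2} W D^{-1/2})` with
  `D = diag(strength)` (diffusive broadcasting over all walks),
- **SI** — search information, `−log2` of the probability that a random
  walker follows the shortest path (path accessibility).

PL and SI are negated (SI additionally symmetrized) so that larger always
means easier communication.

**Coupling.** Region-specific coupling is the Pearson correlation between
matrix columns,

```
r_C(i) = corr( M[:, i], FC_c[:, i] )        over the N−1 off-diagonal entries
```

for measure matrix `M`, condition `c` and region `i`, giving a participant ×
condition × measure × region table. Averaging over regions (and then
measures or conditions) yields brain-average coupling, which is compared
across conditions and measures with repeated-measures ANOVA and
marginal-mean contrasts, and related to the phenotype `g` by partial
correlation controlling for age, gender, handedness and condition-specific
head motion (Bonferroni-corrected across the four measures, p < 0.0125).

**Node-measure assignment (NMA) prediction.** In training data, each
region's four coupling values are partially correlated with `g`, giving
`r_P` per region × measure. The measure with the most positive `r_P` forms
the positive assignment mask, the most negative the negative mask. Each
participant contributes the masked region-means `X1` and `X2`, and `g` is
predicted by OLS

```
y = β0 + β1·X1 + β2·X2 + ε                  (Basic NMA, one condition)
y = β0 + Σ_c (β_{2c−1} X1_c + β_{2c} X2_c)  (Expanded NMA, all task conditions)
```

inside 5-fold cross-validation (masks and coefficients never see test
folds), repeated 100× with fresh splits; performance is the mean Pearson
correlation between fold-concatenated predictions and observed scores.
Significance uses phenotype-permutation tests, model comparisons use
shared-permutation differences `|Δr|`, and out-of-sample generalization
freezes every trained fold model and applies it to a replication cohort.

## Worked example

`examples/04_prediction_nma.py` plants a region × measure phenotype signal
(three regions positively coupled through communicability, three negatively
through search information, total signal R² = 0.10) in the WM condition of a
synthetic 500-participant cohort and runs the Basic NMA model:

```
signal condition (WM):  r = 0.293, R^2 = 0.086, p = 0.0050  (20 repetitions, 200 permutations)
null condition (MOT):   r = -0.042, R^2 = 0.002, p = 0.7761
```

The planted condition predicts near the oracle ceiling `sqrt(0.10) ≈ 0.32`
minus mask/coefficient estimation loss, with the smallest p the permutation
count allows (1/201); the unplanted condition sits at chance. The other
example scripts walk through measure construction (`01`), coupling and
group-level descriptives (`02`), covariate-controlled association (`03`) and
cross-sample model generalization (`05`); each prints the numbers it
computes with a line on what they mean.

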