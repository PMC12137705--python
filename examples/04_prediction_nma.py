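"""Predict the phenotype from region-specific coupling with the NMA models.

Plants a region x measure phenotype signal (three regions positively coupled
via communicability, three negatively via search information; total planted
signal R^2 = 0.10) in one condition, runs the cross-validated Basic NMA
model with permutation significance, and contrasts it against an
uninformative condition.
"""

from couplemap import AnalysisConfig, fit_predict_bnma, permutation_test
from couplemap.synthetic import CouplingGenConfig, SignalSpec, generate_coupling_cohort

signal = tuple(SignalSpec(r, "G", 0.3, "WM") for r in range(3)) + \
    tuple(SignalSpec(r, "SI", -0.3, "WM") for r in range(3, 6))
table, participants, _ = generate_coupling_cohort(
    CouplingGenConfig(n_participants=500, signal=signal), seed=17
)
cfg = AnalysisConfig(rng_seed=1, perm_repetitions=10)

res = fit_predict_bnma(table, participants, "WM", cfg, n_repetitions=20)
p = permutation_test(res, table, participants, cfg, n_permutations=200)
print(f"signal condition (WM):  r = {res.r:.3f}, R^2 = {res.R2:.3f}, "
      f"p = {p:.4f}  (20 repetitions, 200 permutations)")

null = fit_predict_bnma(table, participants, "MOT", cfg, n_repetitions=20)
p_null = permutation_test(null, table, participants, cfg, n_permutations=200)
print(f"null condition (MOT):   r = {null.r:.3f}, R^2 = {null.R2:.3f}, "
      f"p = {p_null:.4f}")

# the planted condition predicts at roughly the oracle level sqrt(0.10) ~ 0.32
# minus mask/coefficient estimation loss; the unplanted condition hovers
# around zero and its permutation p is uniform.
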