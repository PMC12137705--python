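"""Derive the four predictor matrices from a structural connectome.

Builds a small synthetic weighted structural network, transforms it into the
cosine-similarity, path-length, communicability and search-information
matrices, and prints summary statistics.  Higher values always mean "easier
communication": path length and search information are negated after
computation, so a value of -2.0 means a shortest-path cost of 2.0.
"""

import numpy as np

from couplemap import AnalysisConfig, all_predictors
from couplemap.synthetic import GeneratorConfig, generate_sc

sc = generate_sc(GeneratorConfig(n_participants=1, n_regions=60, seed=42))[0]
print(f"structural connectome: {sc.n_regions} regions, "
      f"{int(np.count_nonzero(sc.weights) / 2)} edges, "
      f"weight range {sc.weights[sc.weights > 0].min():.3f}.."
      f"{sc.weights.max():.3f}")

for pred in all_predictors(sc, AnalysisConfig()):
    off = pred.values[~np.eye(sc.n_regions, dtype=bool)]
    print(f"{pred.measure:>3}: mean {off.mean():+.3f}  sd {off.std():.3f}  "
          f"range {off.min():+.3f}..{off.max():+.3f}  "
          f"adjusted={pred.adjusted}")

# The four matrices disagree most where communication is indirect: regions
# linked only via long multi-step routes are penalized hard by path length
# and search information, less so by communicability's walk ensemble.
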