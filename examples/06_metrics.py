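"""The evaluation metrics on small hand-checkable inputs."""

import numpy as np

from fsdta import (RankedScreen, bedroc, concordance_index, enrichment_factor,
                   mse, pearson, precision_at_n, r_squared, spearman)

y = np.array([5.2, 6.8, 7.1, 8.4, 9.0, 6.1])
yhat = np.array([5.5, 6.5, 7.4, 8.1, 8.7, 6.3])
print(f"MSE      = {mse(y, yhat):.4f}   (mean squared residual)")
print(f"CI       = {concordance_index(y, yhat):.4f}   (1.0 = every pair ranked right)")
print(f"R^2      = {r_squared(y, yhat):.4f}")
print(f"Spearman = {spearman(y, yhat):.4f}")
print(f"Pearson  = {pearson(y, yhat):.4f}")

# a screening deck of 50 compounds, 5 actives, scored so actives rank 1-3, 9, 20
scores = -np.arange(50, dtype=float)
labels = np.zeros(50, dtype=bool)
labels[[0, 1, 2, 8, 19]] = True
screen = RankedScreen(scores=scores, labels=labels)
print(f"EF@10%       = {enrichment_factor(screen, 10.0):.2f}  "
      f"(3 of 5 actives in the top 5 ranks)")
print(f"precision@10 = {precision_at_n(screen, 10):.2f}")
print(f"BEDROC(80.5) = {bedroc(screen, 80.5):.3f}")
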