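"""Recover planted informative dimensions with the cross-entropy method.

240 windows carry 40 feature dimensions of which only the first 8 differ
between classes.  CEM samples binary masks from an independent-Bernoulli
model, scores them with a penalised Fisher criterion, and refits the model
to the elite fraction until the informative subset emerges.
"""

import numpy as np

from momofuse import CEMConfig, cem_optimize

rng = np.random.default_rng(0)
X, y = [], []
for c in range(3):
    block = rng.normal(size=(80, 40))
    block[:, :8] += c - 1  # classes differ only on the first 8 dims
    X.append(block)
    y.extend([c] * 80)
X, y = np.vstack(X), np.array(y)

mask, history = cem_optimize(X, y, CEMConfig(population=50, iterations=30, seed=0))
selected = np.nonzero(mask.include)[0]
hits = int(mask.include[:8].sum())
print(f"selected {mask.n_selected}/40 dims: {selected.tolist()}")
print(f"precision {hits / mask.n_selected:.2f}, recall {hits / 8:.2f} "
      f"against the 8 planted dims")
print(f"best score per iteration: "
      + " ".join(f"{s:.2f}" for s in history["best_scores"][::6]))
print("A perfect run selects exactly dims 0..7; the score trace is")
print("non-decreasing because the best-ever mask is kept.")
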