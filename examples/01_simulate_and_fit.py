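"""Simulate DNase-seq cut profiles around motif instances and fit the mixture.

Draws 2000 candidate sites from the generative model (a monomer-only TF
with a footprint-shaped cut profile), fits the mixture by EM, and reports
how well the fitted posterior separates truly bound from unbound sites.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from footmix import (
    FitConfig, clip_counts, expand_lambda, fit, make_toy_model, simulate_dataset,
)

model = make_toy_model(K=0, L=10, margin=200, seed=1)
dataset = simulate_dataset(model, n=2000, seed=1)
clipped = clip_counts(dataset.matrices)            # cap read spikes (99.9% quantile)

result = fit(dataset.sites, clipped, config=FitConfig(seed=1))

p_bound = 1.0 - result.posterior[:, 0]
auc = roc_auc_score(dataset.true_states > 0, p_bound)
true_lam = expand_lambda(model.states[1]["+"], model.binning[1], "+")
est_lam = expand_lambda(result.params.states[1]["+"], result.params.binning[1], "+")
cosine = true_lam @ est_lam / (np.linalg.norm(true_lam) * np.linalg.norm(est_lam))

print(f"converged: {result.converged} in {result.n_iter} iterations")
print(f"AUC-ROC of posterior vs true binding state: {auc:.3f}")
print(f"cosine similarity of fitted vs true cut profile (+ strand): {cosine:.3f}")
print(f"fitted NB mean, bound state  (+): {result.params.states[1]['+'].mean:.1f}"
      f"  (true {model.states[1]['+'].mean:.1f})")
print(f"fitted NB mean, unbound state(+): {result.params.states[0]['+'].mean:.1f}"
      f"  (true {model.states[0]['+'].mean:.1f})")
# An AUC near 1 and cosine near 1 mean the EM recovered both who is bound
# and what the footprint looks like, from the cut counts alone.
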