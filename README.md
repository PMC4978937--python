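# footmix

Multi-state mixture modelling of DNase-seq cut profiles for transcription
factor (TF) binding site identification, with support for cooperative dimer
binding modes and a quantitative pioneer-factor statistic.

## Who this is for

Regulatory genomicists who have (i) candidate motif instances for a TF
(e.g. PWM matches, BED6), (ii) strand-specific per-base DNase I cut counts
(bedGraph pair or a read alignment file), and optionally (iii) ChIP-seq
peaks (narrowPeak) for benchmarking — and who want per-site probabilities
that the TF is bound, learned without any ChIP-seq supervision.

## The model

Each candidate motif instance *i* carries a latent state
*Z<sub>i</sub>* ∈ {0 (unbound), 1 (monomer), 2…K+1 (dimer modes)}.

**Prior (sequence) component** — multinomial logistic regression against the
unbound pivot, from prior characteristics *x<sub>i</sub><sup>(j)</sup>*
(PWM score, partner motif scores, …):

  P(Z<sub>i</sub>=k) / P(Z<sub>i</sub>=0) =
  exp(β₀<sup>(k)</sup> + Σ<sub>j</sub> β<sub>j</sub><sup>(k)</sup> γ<sub>j</sub><sup>(k)</sup> x<sub>i</sub><sup>(j)</sup>),

with binary indicators γ<sub>j</sub><sup>(k)</sup> selecting which
characteristics are active in mode *k* (the monomer mode masks all
partner-motif features).

**Chromatin component** — strand-asymmetric windows: forward-strand cuts
over a 200 bp upstream margin plus the motif, reverse-strand cuts over the
motif plus a 200 bp downstream margin. Per strand and state, the total cut
count follows a negative binomial NB(r, p) (mean p·r/(1−p)) and the spatial
arrangement a multinomial whose per-position coefficients ƛ<sub>j</sub> are
expanded from per-bin masses λ<sub>b</sub> (20 bp bins over the margin,
single-base bins in the motif; a single bin — the uniform null — for the
unbound state). With the default binning the multinomial component carries
only 2·(motif width + 9) free parameters per bound mode.

**Fitting** — EM: posterior E-steps via Bayes' theorem; closed-form
weighted M-steps for λ with a shrinkage estimator
δ·λ̂<sub>b</sub> + (1−δ)·|J<sub>b</sub>|/Σ|J<sub>b</sub>| (δ = 0.5),
and BFGS with analytic gradients for β and the NB dispersion r.
Initialization gives prior odds 100 to the top 10% of instances by total
cut count (and, for dimer modes, also by partner motif score), 0.01
elsewhere; iteration stops when no posterior entry changes by more than
0.001. Per-base counts are first clipped at their pooled 99.9% quantile to
remove artifactual read spikes.

**BCC** — Binding in Closed Chromatin, a pioneer-factor score: the area
under the empirical CDF of the chromatin-component probabilities (flat
prior odds, sequence prior excluded) at ChIP-bound sites. 0 means the TF
only binds open chromatin; across a panel of TFs, values more than one MAD
above the median flag pioneer candidates.

## Worked example

```bash
python examples/01_simulate_and_fit.py
```

prints (seeded, reproducible):

```
converged: True in 13 iterations
AUC-ROC of posterior vs true binding state: 1.000
cosine similarity of fitted vs true cut profile (+ strand): 0.995
fitted NB mean, bound state  (+): 29.9  (true 30.0)
fitted NB mean, unbound state(+): 4.8  (true 5.0)
```

i.e. on 2000 sites drawn from the generative model the EM converges
quickly, recovers the footprint-shaped cut profile and the per-state cut
depths, and the posterior probability of binding separates truly bound
from unbound sites essentially perfectly. `examples/02_*` scores
predictions against (synthetic) ChIP-seq peaks; `examples/03_*` contrasts
the BCC of an open-chromatin binder with a pioneer-like binder.

The same pipeline is available from the shell:

```bash
footmix simulate --n 500 --out-dir fixture/
footmix fit --bed fixture/sites.bed --features fixture/features.tsv \
    --fwd-bedgraph fixture/cuts_fwd.bedGraph --rev-bedgraph fixture/cuts_rev.bedGraph \
    --out-dir run/
footmix eval --posteriors run/posteriors.tsv --peaks peaks.narrowPeak --out run/eval.json
footmix bcc  --model run/model.json --bed fixture/sites.bed ... --out run/bcc.json
```

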