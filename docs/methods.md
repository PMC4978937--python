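# Methods

## Model

A candidate binding site *i* (a motif instance of length *L*) has a latent
state *Z_i* ∈ {0, …, K+1}: unbound, bound as monomer, or bound in one of K
cooperative dimer modes. Two conditionally independent data sources inform
the state.

**Prior component.** Log odds against the unbound pivot are linear in the
prior characteristics: η_i^(k) = β₀^(k) + Σ_j β_j^(k) γ_j^(k) x_i^(j),
with η^(0) ≡ 0. The binary indicators γ enforce that the monomer mode uses
only primary-motif features and each dimer mode additionally its own
partner-motif score. Coefficients for masked features are exactly zero by
construction.

**Chromatin component.** Cuts are collected in motif-sense orientation:
forward-strand cuts over [start − margin, end), reverse-strand cuts over
[start, end + margin); for minus-strand motifs both windows are mirrored
and reversed, so a single profile model serves both orientations. Given
*Z_i = k*, each strand factorises as NB(total; r, p) × Multinomial(spatial;
ƛ). The NB pmf convention is P(S=s) = C(s+r−1, s)(1−p)^r p^s, mean
p·r/(1−p). Per-position coefficients are expanded from per-bin masses:
ƛ_j ∝ λ_{b(j)}/|J_{b(j)}|, renormalised. λ_b is bin *mass* (sums to 1 over
bins) and the expansion divides by bin size: this makes the shrinkage
target (1−δ)|J_b|/Σ|J_b| exactly the per-position-uniform model, the only
reading consistent with the uniform unbound null. The alternative reading
(no size division) would make the shrinkage target non-uniform per
position and is deliberately not implemented.

**Posterior.** P(Z_i=k|X_i) ∝ exp(η_i^(k) + ℓ_i^(k)) over all states,
computed by log-sum-exp; logits are floored at −745 only inside the
normalisation so no probability underflows to a NaN. The score of interest
is p_i = 1 − P(Z_i=0|X_i).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| margin | 200 bp | window extent beyond the motif on each relevant strand |
| bin width | 20 bp | margin bin size; motif positions get single-base bins |
| clip quantile | 0.999 | spike cap on pooled matrix entries (0.99/0.9999 also reasonable) |
| δ | 0.5 | shrinkage mixing between the spatial MLE and per-position uniform |
| tol | 0.001 | max absolute posterior change at convergence |
| init odds | 100 / 0.01 | initial prior odds, high for top-10% instances |
| top fraction | 0.10 | share of instances (by cut total / partner score) given high odds |
| max_iter | 100 | iteration cap; typical convergence is well under 30 |
| ridge | 1e-6 | L2 on non-intercept β for separable soft labels |

With the default binning, each bound mode's multinomial carries
2·(L + margin/bin_width − 1) free parameters (one normalisation constraint
per strand): 38 for L = 10. Elsewhere a published figure of 48 free
parameters circulates for this configuration; it is inconsistent with the
binning arithmetic above and with the formula 2·(motif width + 9), so this
package implements the formula.

## EM details

- Initialization: odds as in the table, ties at the top-fraction cutoff
  broken by a seeded permutation; exactly ⌊fraction·n⌋ (at least one)
  instances selected.
- Step order: fit β to the initial odds-derived probabilities; run the
  first chromatin M-step with those probabilities as posterior weights;
  then alternate E-step and M-steps (λ, then (p, r) per state/strand, then
  β). Convergence is tested on the E-step posterior against the previous
  one (the initial probabilities for the first iteration), as the maximum
  absolute change over **all** instance × state entries.
- λ M-step is the weighted closed form λ̂_b = Σ_i w_i c_{i,b} / Σ_i w_i S_i,
  shrunk toward the size-proportional target; an all-zero weighted total
  returns the target itself.
- (p, r) M-step: BFGS over log r on the profile likelihood with the closed
  form p̂(r) = S̄_w/(S̄_w + r); the analytic gradient uses digamma terms. At
  the optimum the fitted mean equals the weighted sample mean exactly. The
  degenerate all-zero case returns a tiny p with r unchanged, with a
  warning.
- β M-step: BFGS with the analytic softmax gradient over the intercepts and
  the γ-unmasked coefficients, warm-started from the previous iterate;
  budget 200 evaluations. The tiny ridge keeps the problem bounded when
  soft labels are separable; with δ = 1 (no λ shrinkage) the penalised
  observed-data log-likelihood is non-decreasing per iteration up to
  optimizer inexactness (verified to 1e-6 in the tests).
- The unbound state's spatial model is pinned to the single-bin uniform;
  its NB parameters **are** fitted so the null absorbs the background
  sequencing depth.

## Synthetic data generator

`make_toy_model` + `simulate_dataset` draw data from the exact generative
story: standard-normal prior features (one motif score, plus an
independent partner score per dimer mode), states from the softmax prior,
per-strand NB totals, and multinomial placement of cuts. The default toy
model uses unbound mean 5 and bound mean 30 cuts per strand (r = 2 and 5),
a footprint with 60% depletion over the motif core and an elevated flank
ramp over the 40 bp nearest the motif, and β₀ = −1.5, β = 1 (≈ 20% of
sites bound). These are depths and effect sizes typical of a deeply
sequenced footprinting experiment at a well-bound TF; they were fixed once
when the generator was written.

The generator places sites on a single toy contig with non-overlapping
windows and alternating strands, and can emit the equivalent BED6 +
feature TSV + bedGraph pair, so the format readers and window extraction
are exercised end to end. It deliberately does **not** simulate DNase
sequence cutting bias, overlapping hypersensitive sites, copy-number or
mappability artefacts, or correlated fragment ends; passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to those real-data violations.

## Numerical choices

- Clipping threshold: linear-interpolation empirical quantile of the
  pooled entries of both strand matrices; values above are set to the
  threshold (which may be fractional). Re-clipping an already-clipped pair
  is a no-op.
- Sites whose window would cross a contig boundary are dropped (logged),
  not zero-padded — padding would bias the NB totals.
- Read-level cut extraction uses the 5′ base of the aligned tag (leftmost
  aligned base for forward reads, rightmost for reverse reads); an
  optional ±1 shift for the reverse strand is available but defaults to 0.
  Unmapped, secondary, supplementary and duplicate records are skipped.
- AUC-PR is step-based average precision (not trapezoidal, which is
  biased for PR curves); AUC-ROC equals the normalised Mann–Whitney U.
- The BCC probability uses flat prior odds across all K+2 states — the
  unique choice that injects no sequence information; the CLI records this
  choice (`bcc_mode`) in its output. The MAD in the pioneer threshold is
  unscaled (no 1.4826 factor); a scaled variant is available as an option.

## Problem sizes used in the test-suite and acceptance computations

Oracle-equivalence and normalisation checks run on enumerable 3–4 bp
windows. EM monotonicity uses five seeded toys at n = 300, L = 4,
margin = 40. Parameter recovery and the convergence claim use the default
study conditions, n = 2000 instances at L = 10, margin = 200, which fit
comfortably in memory and converge in seconds.

## Known limitations

- One DNase-like data type is modelled per run in practice; additional
  chromatin data types (e.g. histone ChIP-seq) are carried through the
  likelihood structurally but receive no data-type-specific modelling.
- No supervised training against ChIP-seq labels; labels are used for
  evaluation and BCC only.
- No fragment-size filtering or nucleosome-occupancy signal.
- Motif discovery and genome-wide PWM scanning are out of scope: motif
  instances and their scores arrive precomputed, and overlapping instances
  are kept as given.
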