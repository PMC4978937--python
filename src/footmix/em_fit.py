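"""Expectation-Maximization fitting of the binding mixture.

Initialization assigns high prior odds (100) to the instances most likely
bound a priori — the top 10% by total cut count for the monomer mode, and
additionally the top 10% by dimerization-partner motif score for dimer
modes — and low odds (0.01) to everything else. The prior coefficients are
fitted to these initial probabilities, the first M-step treats them as
posteriors, and E/M steps alternate until no posterior entry changes by
more than 0.001.

M-steps: per-bin spatial masses have a weighted closed form, regularised
by a shrinkage estimator mixing the MLE with the per-position-uniform
model (mixing delta, 0.5 by default); the negative binomial dispersion r
and the prior coefficients beta have no closed form and are maximised by
BFGS with analytic gradients (profile likelihood over log r with the
closed-form p(r) for the NB; softmax-against-pivot likelihood with a tiny
L2 ridge for beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from footmix.cut_profile import BinningScheme, CutMatrixPair, make_binning
from footmix.formats_io import MotifInstanceSet
from footmix.mixture_model import (
    BindingModeSpec,
    ModelParams,
    PriorCoefficients,
    StrandChromatinParams,
    chromatin_log_likelihood,
    posterior_probabilities,
    prior_log_odds,
)

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tunable knobs of the EM fit (defaults follow the model's defaults)."""

    delta: float = 0.5              # shrinkage mixing for spatial masses
    tol: float = 0.001              # max absolute posterior change at convergence
    max_iter: int = 100
    init_odds_high: float = 100.0
    init_odds_low: float = 0.01
    init_top_fraction: float = 0.10
    seed: int = 0
    bin_width: int = 20
    ridge: float = 1e-6             # L2 on non-intercept prior coefficients
    optimizer_budget: int = 200     # max evaluations per numeric M-step

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")


@dataclass
class FitResult:
    params: ModelParams
    posterior: np.ndarray
    n_iter: int
    converged: bool
    trajectory: list = field(default_factory=list)  # (iter, max dP, penalized loglik)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _top_fraction_mask(values: np.ndarray, fraction: float,
                       perm: np.ndarray) -> np.ndarray:
    """Boolean mask of the top `fraction` of instances by `values`.

    Exactly floor(fraction * n) instances (at least one) are selected; ties
    at the cutoff are broken by the seeded permutation `perm`.
    """
    n = len(values)
    n_top = max(1, int(np.floor(fraction * n)))
    order = np.lexsort((perm, -np.asarray(values, dtype=float)))
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_top]] = True
    return mask


def initialize_prior_odds(
    sites: MotifInstanceSet,
    matrices: CutMatrixPair,
    modes: BindingModeSpec,
    config: FitConfig,
) -> np.ndarray:
    """Initial per-instance prior odds P(Z=k)/P(Z=0), one column per bound mode.

    Monomer: odds `init_odds_high` for the top `init_top_fraction` of
    instances by total cut count, `init_odds_low` otherwise. Dimer mode k:
    high odds only for instances in the top fraction by total cuts AND in
    the top fraction by the mode's designated partner motif score.
    """
    features = _aligned_features(sites, matrices)
    n = matrices.n_instances
    totals = matrices.total_cuts()
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    top_cuts = _top_fraction_mask(totals, config.init_top_fraction, perm)

    odds = np.full((n, modes.n_bound_modes), config.init_odds_low)
    odds[top_cuts, 0] = config.init_odds_high
    for m in range(1, modes.n_bound_modes):
        partner = modes.partner_features[m]
        if partner is None:
            raise ValueError(
                f"dimer mode {modes.mode_names[m]!r} has no designated "
                "partner-motif-score feature"
            )
        partner_scores = features[partner].to_numpy()
        top_partner = _top_fraction_mask(
            partner_scores, config.init_top_fraction, perm)
        odds[top_cuts & top_partner, m] = config.init_odds_high
    return odds


def _aligned_features(sites: MotifInstanceSet, matrices: CutMatrixPair):
    """Feature table restricted to the sites retained in the matrices."""
    if matrices.kept is not None and len(matrices.kept) != len(sites):
        return sites.features.iloc[matrices.kept].reset_index(drop=True)
    return sites.features


def odds_to_probabilities(odds: np.ndarray) -> np.ndarray:
    """Convert per-bound-mode odds against unbound into state probabilities."""
    odds = np.atleast_2d(odds)
    denom = 1.0 + odds.sum(axis=1, keepdims=True)
    return np.hstack([1.0 / denom, odds / denom])


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------

def _bin_counts(counts: np.ndarray, bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Aggregate an (n, window) count matrix into (n, B) per-bin totals."""
    out = np.zeros((counts.shape[0], n_bins))
    np.add.at(out.T, bins, counts.T)
    return out


def m_step_multinomial(
    matrices: CutMatrixPair,
    binning: BinningScheme,
    weights: np.ndarray,
    delta: float,
) -> dict:
    """Shrinkage-regularised weighted MLE of per-bin spatial masses.

    Returns {"+": lam, "-": lam}. The weighted MLE lam_b = sum_i w_i c_ib /
    sum_i w_i S_i is mixed with the size-proportional (per-position uniform)
    target: delta * MLE + (1 - delta) * |J_b| / sum_b |J_b|. If the weighted
    cut total is zero the uniform target is returned.
    """
    weights = np.asarray(weights, dtype=float)
    out = {}
    for strand, counts in (("+", matrices.fwd), ("-", matrices.rev)):
        bins = binning.bins(strand)
        sizes = binning.sizes(strand)
        uniform = sizes / sizes.sum()
        binned = _bin_counts(np.asarray(counts, dtype=float), bins, len(sizes))
        num = weights @ binned
        denom = num.sum()
        mle = uniform if denom <= 0 else num / denom
        out[strand] = delta * mle + (1.0 - delta) * uniform
    return out


def _nb_profile_negloglik(log_r: float, s: np.ndarray, w: np.ndarray,
                          s_bar: float, w_sum: float):
    """Negative weighted NB log-likelihood profiled over p, and its gradient."""
    r = float(np.exp(np.asarray(log_r).ravel()[0]))
    p = s_bar / (s_bar + r)
    ll = (w @ (gammaln(s + r) - gammaln(s + 1.0)) - w_sum * gammaln(r)
          + w_sum * r * np.log1p(-p) + (w @ s) * np.log(p))
    dldr = w @ digamma(s + r) - w_sum * digamma(r) + w_sum * np.log1p(-p)
    return -ll, np.array([-dldr * r])


def m_step_negbin(
    totals: np.ndarray,
    weights: np.ndarray,
    previous: tuple,
    budget: int = 200,
) -> tuple:
    """Weighted NB MLE of (p, r) for the per-strand total cut counts.

    BFGS over log r on the profile likelihood with closed-form
    p(r) = mean/(mean + r); warm-started from the previous values. At the
    optimum the fitted mean p*r/(1-p) equals the weighted sample mean.
    """
    s = np.asarray(totals, dtype=float)
    w = np.asarray(weights, dtype=float)
    w_sum = w.sum()
    if w_sum <= 0:
        raise ValueError("weights sum to zero")
    s_bar = (w @ s) / w_sum
    p_prev, r_prev = previous
    if s_bar <= 0:
        logger.warning("all-zero weighted totals in NB M-step; p set to tiny")
        return (1e-8, r_prev)
    res = minimize(
        _nb_profile_negloglik,
        x0=np.array([np.log(max(r_prev, 1e-6))]),
        args=(s, w, s_bar, w_sum),
        method="BFGS",
        jac=True,
        options={"maxiter": budget, "gtol": 1e-8},
    )
    r = float(np.exp(np.clip(res.x[0], -30.0, 30.0)))
    p = s_bar / (s_bar + r)
    return (float(np.clip(p, 1e-12, 1.0 - 1e-12)), r)


def m_step_beta(
    features: np.ndarray,
    modes: BindingModeSpec,
    weights: np.ndarray,
    previous: PriorCoefficients | None = None,
    ridge: float = 1e-6,
    budget: int = 200,
) -> PriorCoefficients:
    """Weighted multinomial-logistic M-step for the prior coefficients.

    Maximises sum_i sum_k w_ik log softmax_k(eta_i) with the unbound pivot
    eta^(0) = 0 and gamma-masked coefficients, plus an L2 ridge on the
    non-intercept coefficients for separability. Deterministic; returns the
    best iterate with a warning if the optimizer budget is exhausted.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    n, J = x.shape
    M = modes.n_bound_modes
    gamma = modes.gamma
    free = [(m, j) for m in range(M) for j in range(J) if gamma[m, j]]

    def unpack(theta):
        beta0 = theta[:M]
        beta = np.zeros((M, J))
        for idx, (m, j) in enumerate(free):
            beta[m, j] = theta[M + idx]
        return beta0, beta

    def negloglik(theta):
        beta0, beta = unpack(theta)
        eta = beta0[None, :] + x @ beta.T                    # (n, M)
        logits = np.hstack([np.zeros((n, 1)), eta])          # (n, M+1)
        log_post = logits - logsumexp(logits, axis=1, keepdims=True)
        ll = np.sum(w * log_post)
        pen = 0.5 * ridge * np.sum(beta ** 2)
        # gradient
        p = np.exp(log_post)                                 # (n, M+1)
        resid = p[:, 1:] - w[:, 1:]                          # (n, M)
        g0 = resid.sum(axis=0)
        gbeta = resid.T @ x + ridge * beta
        grad = np.concatenate([g0, [gbeta[m, j] for (m, j) in free]])
        return -(ll - pen), grad

    theta0 = np.zeros(M + len(free))
    if previous is not None:
        theta0[:M] = previous.beta0
        for idx, (m, j) in enumerate(free):
            theta0[M + idx] = previous.beta[m, j]

    res = minimize(negloglik, theta0, method="BFGS", jac=True,
                   options={"maxiter": budget, "gtol": 1e-7})
    if not res.success and res.status != 2:  # status 2: precision loss, accept
        logger.warning("prior M-step optimizer stopped early: %s", res.message)
    beta0, beta = unpack(res.x)
    return PriorCoefficients(beta0=beta0, beta=beta)


# ---------------------------------------------------------------------------
# The EM loop
# ---------------------------------------------------------------------------

def _chromatin_m_step(matrices, binning_bound, posterior, states_prev, delta):
    """One full chromatin M-step: spatial masses and NB per state/strand."""
    n_states = posterior.shape[1]
    totals = {"+": matrices.fwd.sum(axis=1), "-": matrices.rev.sum(axis=1)}
    states = []
    for k in range(n_states):
        w = posterior[:, k]
        st = {}
        if k == 0:
            lam = {"+": np.array([1.0]), "-": np.array([1.0])}
        else:
            lam = m_step_multinomial(matrices, binning_bound, w, delta)
        for strand in ("+", "-"):
            prev = states_prev[k][strand]
            p, r = m_step_negbin(totals[strand], w, (prev.p, prev.r))
            st[strand] = StrandChromatinParams(p=p, r=r, lam=lam[strand])
        states.append(st)
    return states


def _observed_loglik(eta, chrom_ll, beta, ridge):
    """Penalized observed-data log-likelihood under the current parameters."""
    n = chrom_ll.shape[0]
    logits = np.hstack([np.zeros((n, 1)), eta])
    log_prior = logits - logsumexp(logits, axis=1, keepdims=True)
    ll = logsumexp(log_prior + chrom_ll, axis=1).sum()
    return ll - 0.5 * ridge * np.sum(beta ** 2)


def fit(
    sites: MotifInstanceSet,
    matrices: CutMatrixPair,
    modes: BindingModeSpec | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the full mixture by EM.

    Sequence: initialize prior odds; fit the prior coefficients to the
    initial probabilities; run a first M-step with those probabilities as
    posterior weights; then alternate E-steps and M-steps until no
    posterior entry changes by more than ``config.tol`` or ``max_iter`` is
    reached. The unbound spatial model stays fixed at uniform; unbound NB
    parameters are fitted so the null absorbs background depth.
    """
    config = config or FitConfig()
    features_df = _aligned_features(sites, matrices)
    if modes is None:
        modes = BindingModeSpec.monomer(n_features=features_df.shape[1])
    x = features_df.to_numpy(dtype=float)

    binning_bound = make_binning(
        sites.motif_length, matrices.margin, config.bin_width, mode="bound")
    binning_unbound = make_binning(
        sites.motif_length, matrices.margin, config.bin_width, mode="unbound")
    binning = [binning_unbound] + [binning_bound] * modes.n_bound_modes

    # (1) initial odds, (2) prior coefficients fitted to them
    odds = initialize_prior_odds(sites, matrices, modes, config)
    init_probs = odds_to_probabilities(odds)
    prior = m_step_beta(x, modes, init_probs, ridge=config.ridge,
                        budget=config.optimizer_budget)

    # (3) first M-step with the initial probabilities as posterior weights
    mean0 = max(matrices.total_cuts().mean() / 2.0, 0.1)
    seed_state = {"+": StrandChromatinParams(p=mean0 / (mean0 + 1.0), r=1.0,
                                             lam=np.array([1.0])),
                  "-": StrandChromatinParams(p=mean0 / (mean0 + 1.0), r=1.0,
                                             lam=np.array([1.0]))}
    states = _chromatin_m_step(
        matrices, binning_bound, init_probs,
        [seed_state] * (modes.n_bound_modes + 1), config.delta)

    params = ModelParams(prior=prior, modes=modes, states=states,
                         binning=binning, delta=config.delta)

    # (4) EM iterations
    posterior_prev = init_probs
    trajectory = []
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        eta = prior_log_odds(x, params.prior, modes)
        chrom_ll = chromatin_log_likelihood(matrices, params)
        posterior = posterior_probabilities(eta, chrom_ll)
        max_change = float(np.max(np.abs(posterior - posterior_prev)))
        pen_ll = _observed_loglik(eta, chrom_ll, params.prior.beta, config.ridge)
        trajectory.append((it, max_change, pen_ll))
        logger.info("iter %d: max dP=%.3g penalized loglik=%.6f",
                    it, max_change, pen_ll)
        posterior_prev = posterior
        if max_change <= config.tol:
            converged = True
            break
        states = _chromatin_m_step(matrices, binning_bound, posterior,
                                   params.states, config.delta)
        prior = m_step_beta(x, modes, posterior, previous=params.prior,
                            ridge=config.ridge, budget=config.optimizer_budget)
        params = ModelParams(prior=prior, modes=modes, states=states,
                             binning=binning, delta=config.delta)

    return FitResult(params=params, posterior=posterior_prev,
                     n_iter=n_iter, converged=converged, trajectory=trajectory)
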