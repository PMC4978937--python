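"""The multi-state binding mixture: prior odds, chromatin likelihood, posterior.

A candidate site's latent state Z is 0 (unbound), 1 (monomer), or
2..K+1 (cooperative dimer modes). The prior is a multinomial logistic
model against the unbound pivot: log[P(Z=k)/P(Z=0)] is linear in the
site's prior characteristics, with binary indicators gamma masking which
characteristics are active in which mode. Given the state, each strand's
cut-count vector factorises into a negative binomial for the total and a
multinomial for the spatial distribution, with per-bin spatial parameters
expanded to per-position coefficients. Bayes' theorem combines the two
components into a per-state posterior.

Negative binomial convention: P(S = s) = C(s + r - 1, s) (1-p)^r p^s with
success probability p in (0, 1) and real-valued number of failures r > 0,
so the mean is p*r/(1-p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from footmix.cut_profile import BinningScheme, CutMatrixPair

# log-likelihood floor applied inside log-sum-exp only, to avoid underflow
LOGLIK_FLOOR = -745.0


@dataclass
class BindingModeSpec:
    """Names and feature masks of the bound modes.

    ``gamma`` is a (K+1) x J boolean matrix over (bound mode, feature):
    gamma[k-1, j] says whether feature j enters the prior of bound mode k.
    The monomer mode (k=1) must mask every partner-motif feature.
    ``partner_features[k-1]`` names the dimerization-partner score feature
    used to initialize dimer mode k (None for the monomer).
    """

    gamma: np.ndarray
    mode_names: list[str] = field(default_factory=list)
    partner_features: list = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=bool)
        if self.gamma.ndim != 2:
            raise ValueError("gamma must be 2-D (bound modes x features)")
        if not self.mode_names:
            self.mode_names = ["monomer"] + [
                f"dimer_{k}" for k in range(2, self.gamma.shape[0] + 1)
            ]
        if not self.partner_features:
            self.partner_features = [None] * self.gamma.shape[0]
        if not self.feature_names:
            self.feature_names = ["motif_score"] + [
                f"feature_{j}" for j in range(1, self.gamma.shape[1])
            ]

    @property
    def n_bound_modes(self) -> int:
        return self.gamma.shape[0]

    @property
    def K(self) -> int:
        """Number of cooperative (dimer) modes."""
        return self.gamma.shape[0] - 1

    @classmethod
    def monomer(cls, n_features: int = 1) -> "BindingModeSpec":
        """The single-bound-mode (K=0) specification using all features."""
        return cls(gamma=np.ones((1, n_features), dtype=bool))


@dataclass
class PriorCoefficients:
    """Logistic-prior parameters: intercept and feature coefficients per bound mode."""

    beta0: np.ndarray  # (K+1,)
    beta: np.ndarray   # (K+1, J)

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if not (np.isfinite(self.beta0).all() and np.isfinite(self.beta).all()):
            raise ValueError("prior coefficients must be finite")


@dataclass
class StrandChromatinParams:
    """One strand's chromatin parameters for one state.

    ``p``: NB success probability; ``r``: NB number of failures;
    ``lam``: per-bin spatial mass (sums to 1 over bins). For the unbound
    state lam has length 1.
    """

    p: float
    r: float
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if (self.lam < 0).any() or not np.isclose(self.lam.sum(), 1.0, atol=1e-9):
            raise ValueError("lam must be a probability vector over bins")

    @property
    def mean(self) -> float:
        """NB mean total cut count, p*r/(1-p)."""
        return self.p * self.r / (1.0 - self.p)


@dataclass
class ModelParams:
    """All fitted parameters of the mixture model.

    ``states[k]`` is a dict {"+": StrandChromatinParams, "-": ...} for
    state k = 0..K+1 (0 = unbound). ``binning[k]`` is the BinningScheme of
    state k (single-bin for state 0).
    """

    prior: PriorCoefficients
    modes: BindingModeSpec
    states: list
    binning: list
    delta: float = 0.5

    def __post_init__(self) -> None:
        if len(self.states) != self.modes.n_bound_modes + 1:
            raise ValueError("need one state entry per mode plus unbound")
        if len(self.binning) != len(self.states):
            raise ValueError("need one binning per state")
        if len(self.states[0]["+"].lam) != 1 or len(self.states[0]["-"].lam) != 1:
            raise ValueError("unbound state must use the single-bin spatial model")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "modes": [
                {
                    "name": self.modes.mode_names[k],
                    "gamma": self.modes.gamma[k].astype(int).tolist(),
                    "partner_feature": self.modes.partner_features[k],
                    "beta0": float(self.prior.beta0[k]),
                    "beta": self.prior.beta[k].tolist(),
                }
                for k in range(self.modes.n_bound_modes)
            ],
            "states": [
                {
                    strand: {
                        "p": float(sp.p),
                        "r": float(sp.r),
                        "lambda": sp.lam.tolist(),
                    }
                    for strand, sp in st.items()
                }
                for st in self.states
            ],
            "binning": [b.to_dict() for b in self.binning],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        modes = BindingModeSpec(
            gamma=np.asarray([m["gamma"] for m in d["modes"]], dtype=bool),
            mode_names=[m["name"] for m in d["modes"]],
            partner_features=[m.get("partner_feature") for m in d["modes"]],
        )
        prior = PriorCoefficients(
            beta0=np.asarray([m["beta0"] for m in d["modes"]]),
            beta=np.asarray([m["beta"] for m in d["modes"]]),
        )
        states = [
            {
                strand: StrandChromatinParams(
                    p=sd["p"], r=sd["r"], lam=np.asarray(sd["lambda"]))
                for strand, sd in st.items()
            }
            for st in d["states"]
        ]
        binning = [BinningScheme.from_dict(b) for b in d["binning"]]
        return cls(prior=prior, modes=modes, states=states,
                   binning=binning, delta=d.get("delta", 0.5))


# ---------------------------------------------------------------------------
# Prior component
# ---------------------------------------------------------------------------

def prior_log_odds(
    features: np.ndarray,
    prior: PriorCoefficients,
    modes: BindingModeSpec,
) -> np.ndarray:
    """Log prior odds eta[i, k-1] = log[P(Z_i=k) / P(Z_i=0)] per bound mode.

    eta^(k) = beta0^(k) + sum_j beta_j^(k) gamma_j^(k) x_i^(j); the unbound
    pivot has implicit eta^(0) = 0 and is not returned.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    if x.shape[1] != modes.gamma.shape[1]:
        raise ValueError("feature dimension does not match gamma")
    masked = prior.beta * modes.gamma  # (K+1, J)
    return prior.beta0[None, :] + x @ masked.T


# ---------------------------------------------------------------------------
# Chromatin component
# ---------------------------------------------------------------------------

def expand_lambda(params: StrandChromatinParams, binning: BinningScheme,
                  strand: str = "+") -> np.ndarray:
    """Expand per-bin masses to per-position multinomial coefficients.

    Each bin's mass is spread uniformly over its positions and the result
    renormalised: lam_pos_j = (lam_b(j)/|J_b(j)|) / sum_j' (...). For the
    unbound single-bin state this is the uniform distribution.
    """
    bins = binning.bins(strand)
    sizes = binning.sizes(strand)
    if len(params.lam) != len(sizes):
        raise ValueError("lambda length does not match bin count")
    if params.lam.sum() <= 0:
        raise ValueError("all-zero lambda")
    per_pos = params.lam[bins] / sizes[bins]
    return per_pos / per_pos.sum()


def _log_nb_pmf(s, r: float, p: float):
    """log P(S=s) for NB with success prob p, failures r; mean p*r/(1-p)."""
    s = np.asarray(s, dtype=float)
    return (gammaln(s + r) - gammaln(r) - gammaln(s + 1.0)
            + r * np.log1p(-p) + s * np.log(p))


def strand_log_likelihood(
    counts: np.ndarray,
    params: StrandChromatinParams,
    binning: BinningScheme,
    strand: str = "+",
) -> np.ndarray:
    """log P(counts | state) for one strand: NB total x multinomial spatial.

    Accepts a single window vector or an (n, window) matrix; returns a
    scalar or per-row vector. Computed entirely in log space.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=float))
    lam_pos = expand_lambda(params, binning, strand)
    s = c.sum(axis=1)
    nb = _log_nb_pmf(s, params.r, params.p)
    pos_mass = lam_pos > 0
    log_lam = np.where(pos_mass, np.log(np.maximum(lam_pos, 1e-300)), 0.0)
    spatial = gammaln(s + 1.0) - gammaln(c + 1.0).sum(axis=1) + c @ log_lam
    if not pos_mass.all():
        # positive counts at zero-mass positions have zero likelihood
        impossible = (c[:, ~pos_mass] > 0).any(axis=1)
        spatial = np.where(impossible, -np.inf, spatial)
    out = nb + spatial
    return out[0] if np.asarray(counts).ndim == 1 else out


def chromatin_log_likelihood(
    matrices,
    params: ModelParams,
) -> np.ndarray:
    """Per-instance, per-state log P(X_i | Z_i = k).

    ``matrices`` is one CutMatrixPair or a list of them (one per chromatin
    data type); data types and strands are conditionally independent given
    the state, so their log-likelihoods add.
    """
    if isinstance(matrices, CutMatrixPair):
        matrices = [matrices]
    n = matrices[0].n_instances
    ll = np.zeros((n, params.n_states))
    for mat in matrices:
        for k in range(params.n_states):
            ll[:, k] += strand_log_likelihood(
                mat.fwd, params.states[k]["+"], params.binning[k], "+")
            ll[:, k] += strand_log_likelihood(
                mat.rev, params.states[k]["-"], params.binning[k], "-")
    return ll


def posterior_probabilities(
    prior_odds: np.ndarray,
    chromatin_loglik: np.ndarray,
) -> np.ndarray:
    """Bayes posterior over states from log prior odds and log-likelihoods.

    Returns an (n, K+2) matrix with rows summing to 1; column 0 is the
    unbound state. Computed via log-sum-exp; the bound probability of
    instance i is 1 - posterior[i, 0].
    """
    eta = np.atleast_2d(np.asarray(prior_odds, dtype=float))
    ll = np.atleast_2d(np.asarray(chromatin_loglik, dtype=float))
    if ll.shape[1] != eta.shape[1] + 1:
        raise ValueError("chromatin loglik must cover the unbound state")
    logits = ll.copy()
    logits[:, 1:] += eta
    logits = np.maximum(logits - logits.max(axis=1, keepdims=True), LOGLIK_FLOOR)
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
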