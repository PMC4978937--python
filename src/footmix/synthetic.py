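"""Generative simulator: data drawn from the exact model, for testing.

The simulator is the inverse of the fitted model: per instance it draws
prior characteristics, a latent binding state from the softmax prior,
per-strand total cut counts from the state's negative binomial, and
scatters the cuts over window positions from the state's multinomial.
The same draws are laid out on a toy contig and can be written as
BED6 + feature TSV + two bedGraph tracks so that the format readers and
window extraction are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from footmix.cut_profile import (
    CutMatrixPair,
    make_binning,
)
from footmix.formats_io import CutTrack, MotifInstanceSet, write_bedgraph
from footmix.mixture_model import (
    BindingModeSpec,
    ModelParams,
    PriorCoefficients,
    StrandChromatinParams,
    expand_lambda,
    prior_log_odds,
)

SIM_CONTIG = "chrSim"


@dataclass
class SimulatedDataset:
    """A dataset drawn from a known model, with its ground truth attached."""

    sites: MotifInstanceSet
    matrices: CutMatrixPair       # raw (unclipped) counts
    true_states: np.ndarray       # Z_i in 0..K+1
    true_params: ModelParams
    seed: int
    track: CutTrack

    def write(self, out_dir) -> dict:
        """Write BED6 + feature TSV + bedGraph pair + truth JSON; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "bed": out / "sites.bed",
            "features": out / "features.tsv",
            "fwd": out / "cuts_fwd.bedGraph",
            "rev": out / "cuts_rev.bedGraph",
            "truth": out / "truth.json",
        }
        with open(paths["bed"], "w") as fh:
            for i in range(len(self.sites)):
                fh.write("\t".join(map(str, (
                    self.sites.chrom[i], self.sites.start[i], self.sites.end[i],
                    self.sites.instance_id[i],
                    f"{self.sites.features.iloc[i, 0]:.6f}",
                    self.sites.strand[i]))) + "\n")
        feats = self.sites.features.copy()
        feats.insert(0, "instance_id", self.sites.instance_id)
        feats.to_csv(paths["features"], sep="\t", index=False, float_format="%.6f")
        write_bedgraph(self.track, paths["fwd"], paths["rev"])
        with open(paths["truth"], "w") as fh:
            json.dump({
                "seed": self.seed,
                "true_states": self.true_states.tolist(),
                "model": self.true_params.to_dict(),
            }, fh, indent=1)
        return {k: str(v) for k, v in paths.items()}


def _footprint_profile(L: int, margin: int, depth: float, mode_index: int) -> np.ndarray:
    """Per-position cut intensity over one strand window (margin + motif).

    Flat background over the margin with a rise toward the motif edge
    (hypersensitivity flanking the bound protein) and a depleted motif core
    (the footprint). depth=0 gives a uniform, spatially uninformative profile.
    Mode index shifts the flank boost so different modes are distinguishable.
    """
    w = margin + L
    profile = np.ones(w)
    if depth > 0:
        flank = min(40, margin)
        ramp = 1.0 + (0.8 + 0.3 * mode_index) * np.linspace(0, 1, flank)
        profile[margin - flank:margin] *= ramp
        core = np.ones(L) * (1.0 - depth)
        # leave the outermost motif base less protected for asymmetry
        if L >= 3:
            core[0] = 1.0 - 0.5 * depth
            core[-1] = 1.0 - 0.5 * depth
        profile[margin:] = core
    return profile


def _profile_to_bin_mass(profile: np.ndarray, bins: np.ndarray) -> np.ndarray:
    mass = np.bincount(bins, weights=profile)
    return mass / mass.sum()


def make_toy_model(
    K: int = 0,
    L: int = 10,
    margin: int = 200,
    footprint_depth: float = 0.6,
    seed: int = 0,
    bin_width: int = 20,
    unbound_mean: float = 5.0,
    bound_mean: float = 30.0,
) -> ModelParams:
    """A fully specified toy model with footprint-shaped bound profiles.

    Bound modes get a depleted motif core with elevated flanks (distinct per
    mode), NB totals with bound mean > unbound mean, and a prior with one
    informative feature per mode (motif score for the monomer, an
    additional partner score per dimer mode). Deterministic given the seed.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    binning_bound = make_binning(L, margin, bin_width, mode="bound")
    binning_unbound = make_binning(L, margin, bin_width, mode="unbound")

    n_features = 1 + K
    feature_names = ["motif_score"] + [f"partner_score_{k}" for k in range(2, K + 2)]
    gamma = np.zeros((K + 1, n_features), dtype=bool)
    gamma[:, 0] = True
    for k in range(1, K + 1):
        gamma[k, k] = True
    modes = BindingModeSpec(
        gamma=gamma,
        mode_names=["monomer"] + [f"dimer_{k}" for k in range(2, K + 2)],
        partner_features=[None] + feature_names[1:],
        feature_names=feature_names,
    )

    beta0 = np.array([-1.5] + [-2.5] * K)
    beta = np.zeros((K + 1, n_features))
    beta[:, 0] = 1.0
    for k in range(1, K + 1):
        beta[k, k] = 1.0
    prior = PriorCoefficients(beta0=beta0, beta=beta)

    states = []
    r_unbound, r_bound = 2.0, 5.0
    p_unbound = unbound_mean / (unbound_mean + r_unbound)
    states.append({
        "+": StrandChromatinParams(p=p_unbound, r=r_unbound, lam=np.array([1.0])),
        "-": StrandChromatinParams(p=p_unbound, r=r_unbound, lam=np.array([1.0])),
    })
    for k in range(1, K + 2):
        mean_k = bound_mean * (1.0 + 0.25 * (k - 1))
        p_k = mean_k / (mean_k + r_bound)
        st = {}
        for strand in ("+", "-"):
            profile = _footprint_profile(L, margin, footprint_depth, k - 1)
            if strand == "-":
                # mirror: motif first, margin after (rev window layout)
                profile = profile[::-1]
            st[strand] = StrandChromatinParams(
                p=p_k, r=r_bound,
                lam=_profile_to_bin_mass(profile, binning_bound.bins(strand)))
        states.append(st)

    binning = [binning_unbound] + [binning_bound] * (K + 1)
    return ModelParams(prior=prior, modes=modes, states=states,
                       binning=binning, delta=0.5)


def simulate_dataset(
    model: ModelParams,
    n: int,
    seed: int = 0,
    feature_generator=None,
) -> SimulatedDataset:
    """Draw n instances from the generative model.

    Per instance: features (standard normal by default), latent state from
    the softmax prior, per-strand NB totals and multinomial cut placement.
    Sites are laid on a single toy contig (alternating strands, windows well
    separated) and the equivalent per-base cut track is built alongside so
    that the file round-trip can be tested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    modes = model.modes
    n_features = modes.gamma.shape[1]
    L = _infer_motif_length(model)
    margin = len(model.binning[0].fwd_bins) - L

    if feature_generator is None:
        x = rng.standard_normal((n, n_features))
    else:
        x = np.asarray(feature_generator(rng, n), dtype=float)

    eta = prior_log_odds(x, model.prior, modes)
    logits = np.hstack([np.zeros((n, 1)), eta])
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    z = np.array([rng.choice(len(p_row), p=p_row) for p_row in probs])

    w = margin + L
    fwd = np.zeros((n, w), dtype=np.int64)
    rev = np.zeros((n, w), dtype=np.int64)
    for k in range(model.n_states):
        idx = np.flatnonzero(z == k)
        if len(idx) == 0:
            continue
        for strand, mat in (("+", fwd), ("-", rev)):
            sp = model.states[k][strand]
            totals = rng.negative_binomial(sp.r, 1.0 - sp.p, size=len(idx))
            lam_pos = expand_lambda(sp, model.binning[k], strand)
            mat[idx] = rng.multinomial(totals, lam_pos)

    # genomic layout: alternating strands, non-overlapping windows
    spacing = 2 * margin + L + 10
    starts = margin + spacing * np.arange(n)
    strands = np.where(np.arange(n) % 2 == 0, "+", "-").astype(object)
    ids = np.array([f"site_{i:05d}" for i in range(n)], dtype=object)
    features = pd.DataFrame(x, columns=modes.feature_names)
    sites = MotifInstanceSet(
        chrom=np.full(n, SIM_CONTIG, dtype=object),
        start=starts.astype(np.int64),
        end=(starts + L).astype(np.int64),
        strand=strands,
        instance_id=ids,
        features=features,
        motif_length=L,
    )

    track = CutTrack()
    for i in range(n):
        s, e = int(starts[i]), int(starts[i]) + L
        if strands[i] == "+":
            _deposit(track, SIM_CONTIG, "+", s - margin, fwd[i])
            _deposit(track, SIM_CONTIG, "-", s, rev[i])
        else:
            _deposit(track, SIM_CONTIG, "-", s, fwd[i][::-1])
            _deposit(track, SIM_CONTIG, "+", s - margin, rev[i][::-1])

    matrices = CutMatrixPair(fwd=fwd, rev=rev, margin=margin, motif_length=L,
                             kept=np.arange(n))
    return SimulatedDataset(sites=sites, matrices=matrices, true_states=z,
                            true_params=model, seed=seed, track=track)


def _deposit(track: CutTrack, contig: str, strand: str,
             start: int, counts: np.ndarray) -> None:
    for offset, c in enumerate(counts):
        if c > 0:
            track.add(contig, strand, start + offset, int(c))


def _infer_motif_length(model: ModelParams) -> int:
    """Motif length from the bound binning (number of single-base bins)."""
    bound = model.binning[1]
    return int(np.sum(bound.fwd_sizes == 1))
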