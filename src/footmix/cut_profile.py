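"""Strand-asymmetric cut-count matrices, spike clipping, and binning.

Around each candidate site we collect DNase I cuts in motif-sense
orientation: forward-strand cuts over the upstream margin plus the motif,
reverse-strand cuts over the motif plus the downstream margin. Artifactual
read spikes are removed by capping entries at a high empirical quantile
(99.9% by default) of the pooled entries of both matrices. Spatial
parameters of the likelihood are shared within bins: wide bins over the
margin, single-base bins within the motif, and one bin covering everything
for the unbound state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from footmix.formats_io import CutTrack, MotifInstanceSet

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 200
DEFAULT_BIN_WIDTH = 20
DEFAULT_CLIP_QUANTILE = 0.999


@dataclass
class CutMatrixPair:
    """Per-instance strand-specific cut-count matrices.

    ``fwd``: n x (margin + L), motif-sense forward-strand cuts from
    ``margin`` bp upstream through the last motif base.
    ``rev``: n x (L + margin), motif-sense reverse-strand cuts from the
    first motif base through ``margin`` bp downstream.
    Columns always run 5'->3' in motif orientation.
    """

    fwd: np.ndarray
    rev: np.ndarray
    margin: int
    motif_length: int
    clip_threshold: float | None = None
    kept: np.ndarray | None = None  # indices of sites retained (contig-edge drops)

    def __post_init__(self) -> None:
        w = self.margin + self.motif_length
        if self.fwd.shape[1] != w or self.rev.shape[1] != w:
            raise ValueError("matrix width must equal margin + motif length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("negative cut counts")

    @property
    def n_instances(self) -> int:
        return self.fwd.shape[0]

    @property
    def window_length(self) -> int:
        return self.margin + self.motif_length

    def total_cuts(self) -> np.ndarray:
        """Per-instance total cuts over both strand windows."""
        return self.fwd.sum(axis=1) + self.rev.sum(axis=1)


@dataclass
class BinningScheme:
    """Assignment of window positions to parameter bins, per strand.

    ``fwd_bins[j]`` / ``rev_bins[j]`` give the 0-based bin index of window
    position j. Bound modes use contiguous ``bin_width`` bp bins over the
    margin and single-base bins over the motif; the unbound mode puts all
    positions in a single bin (forcing the uniform spatial null).
    """

    fwd_bins: np.ndarray
    rev_bins: np.ndarray
    mode: str = "bound"
    fwd_sizes: np.ndarray = field(init=False)
    rev_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for bins in (self.fwd_bins, self.rev_bins):
            b = np.unique(bins)
            if not np.array_equal(b, np.arange(len(b))):
                raise ValueError("bin indices must be 0..B-1 with no gaps")
        self.fwd_sizes = np.bincount(self.fwd_bins)
        self.rev_sizes = np.bincount(self.rev_bins)

    def n_bins(self, strand: str) -> int:
        return len(self.fwd_sizes) if strand == "+" else len(self.rev_sizes)

    def bins(self, strand: str) -> np.ndarray:
        return self.fwd_bins if strand == "+" else self.rev_bins

    def sizes(self, strand: str) -> np.ndarray:
        return self.fwd_sizes if strand == "+" else self.rev_sizes

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "fwd_bins": self.fwd_bins.tolist(),
            "rev_bins": self.rev_bins.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(
            fwd_bins=np.asarray(d["fwd_bins"], dtype=np.int64),
            rev_bins=np.asarray(d["rev_bins"], dtype=np.int64),
            mode=d.get("mode", "bound"),
        )


def build_cut_matrices(
    track: CutTrack,
    sites: MotifInstanceSet,
    margin: int = DEFAULT_MARGIN,
) -> CutMatrixPair:
    """Collect per-instance strand-specific cut counts around each site.

    For a +-strand motif at [s, e): the fwd row holds +-strand counts over
    [s - margin, e) and the rev row holds −-strand counts over [s, e + margin).
    For a −-strand motif the windows are mirrored and reversed so that
    "forward" always means the motif-sense strand and columns run 5'->3' in
    motif orientation. Sites whose window would extend below position 0 are
    dropped with a warning.
    """
    L = sites.motif_length
    w = margin + L
    fwd_rows, rev_rows, kept = [], [], []
    for i in range(len(sites)):
        c = sites.chrom[i]
        s = int(sites.start[i])
        e = int(sites.end[i])
        if s - margin < 0:
            logger.warning("dropping site %s: window exceeds contig bounds",
                           sites.instance_id[i])
            continue
        if sites.strand[i] == "+":
            fwd = track.window(c, "+", s - margin, e)
            rev = track.window(c, "-", s, e + margin)
        else:
            fwd = track.window(c, "-", s, e + margin)[::-1]
            rev = track.window(c, "+", s - margin, e)[::-1]
        fwd_rows.append(fwd)
        rev_rows.append(rev)
        kept.append(i)
    if fwd_rows:
        fwd_mat = np.vstack(fwd_rows)
        rev_mat = np.vstack(rev_rows)
    else:
        fwd_mat = np.zeros((0, w), dtype=np.int64)
        rev_mat = np.zeros((0, w), dtype=np.int64)
    return CutMatrixPair(
        fwd=fwd_mat, rev=rev_mat, margin=margin, motif_length=L,
        kept=np.asarray(kept, dtype=np.int64),
    )


def clip_counts(matrices: CutMatrixPair, q: float = DEFAULT_CLIP_QUANTILE) -> CutMatrixPair:
    """Cap read spikes at the empirical q-quantile of the pooled entries.

    The threshold is the linear-interpolation empirical quantile over all
    entries of both matrices jointly; entries above it are set to the
    threshold. Re-applying to an already-clipped pair is a no-op (the
    stored threshold marks the pair as clipped).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("clip quantile must be in (0, 1)")
    if matrices.n_instances == 0:
        raise ValueError("cannot clip empty matrices")
    if matrices.clip_threshold is not None:
        return matrices
    pooled = np.concatenate([matrices.fwd.ravel(), matrices.rev.ravel()])
    threshold = float(np.quantile(pooled, q))
    fwd = np.minimum(matrices.fwd, threshold)
    rev = np.minimum(matrices.rev, threshold)
    return CutMatrixPair(
        fwd=fwd, rev=rev, margin=matrices.margin,
        motif_length=matrices.motif_length,
        clip_threshold=threshold, kept=matrices.kept,
    )


def make_binning(
    L: int,
    margin: int = DEFAULT_MARGIN,
    bin_width: int = DEFAULT_BIN_WIDTH,
    mode: str = "bound",
) -> BinningScheme:
    """Construct the positional binning for one state class.

    Bound: the fwd strand window gets margin/bin_width margin bins followed
    by L single-base motif bins; the rev strand window gets L single-base
    motif bins followed by the margin bins. Unbound: a single bin covering
    all margin + L positions on each strand.
    """
    if L <= 0:
        raise ValueError("motif length must be positive")
    if mode not in ("bound", "unbound"):
        raise ValueError("mode must be 'bound' or 'unbound'")
    w = margin + L
    if mode == "unbound":
        z = np.zeros(w, dtype=np.int64)
        return BinningScheme(fwd_bins=z, rev_bins=z.copy(), mode="unbound")
    if margin % bin_width != 0:
        logger.warning("margin %d not divisible by bin width %d; last margin bin truncated",
                       margin, bin_width)
    margin_bins = np.arange(margin) // bin_width
    n_margin_bins = int(margin_bins[-1]) + 1 if margin else 0
    fwd = np.concatenate([margin_bins, n_margin_bins + np.arange(L)])
    rev = np.concatenate([np.arange(L), L + margin_bins])
    return BinningScheme(fwd_bins=fwd.astype(np.int64),
                         rev_bins=rev.astype(np.int64), mode="bound")


def count_free_parameters(
    L: int,
    margin: int = DEFAULT_MARGIN,
    bin_width: int = DEFAULT_BIN_WIDTH,
    K: int = 0,
    n_active_features: list[int] | None = None,
) -> dict:
    """Free-parameter accounting for the default binning.

    Per bound mode the multinomial component has margin/bin_width + L bins
    per strand, minus one normalisation constraint per strand:
    2*(L + margin/bin_width - 1) free parameters (38 for a 10 bp motif with
    a 200 bp margin and 20 bp bins). The single-bin unbound multinomial is
    forced uniform and contributes none. The negative binomial contributes
    (p, r) per strand for every state including unbound. The prior
    contributes one intercept plus one coefficient per active feature for
    each bound mode.

    ``n_active_features``: active feature count per bound mode; default one
    for the monomer and two for each dimer mode.
    """
    n_bound = K + 1
    n_states = K + 2
    bins_per_strand = margin // bin_width + L
    multinomial = n_bound * 2 * (bins_per_strand - 1)
    negative_binomial = n_states * 2 * 2
    if n_active_features is None:
        n_active_features = [1] + [2] * K
    if len(n_active_features) != n_bound:
        raise ValueError("n_active_features must have one entry per bound mode")
    prior = sum(1 + a for a in n_active_features)
    return {
        "multinomial": multinomial,
        "negative_binomial": negative_binomial,
        "prior": prior,
        "total": multinomial + negative_binomial + prior,
    }
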