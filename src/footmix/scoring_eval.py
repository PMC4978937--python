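"""Evaluation against ChIP-seq labels and the BCC pioneer-factor statistic.

Binding predictions are scored against ChIP-seq-derived bound/unbound
labels with precision-recall and ROC curves (ties grouped at every distinct
score; AUC-PR is step-based average precision, AUC-ROC the normalised
Mann-Whitney U), plus the Spearman rank correlation of scores with peak
height at bound sites.

Binding in Closed Chromatin (BCC) quantifies pioneer-factor-like activity:
take the chromatin-component probability (prior excluded, flat odds over
all states) at ChIP-bound sites; BCC is the area under the empirical CDF
of those probabilities. A TF that only binds open chromatin has
probabilities near 1 and BCC near 0; tolerance of closed chromatin lifts
the CDF and the BCC. Across a collection of TFs, candidates are flagged
above the threshold median + 1 MAD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import spearmanr
from sklearn import metrics as _skm


@dataclass
class EvalResult:
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc_pr: float
    auc_roc: float
    spearman_rho: float | None = None

    def summary(self) -> dict:
        out = {"auc_pr": self.auc_pr, "auc_roc": self.auc_roc}
        if self.spearman_rho is not None and np.isfinite(self.spearman_rho):
            out["spearman_rho"] = self.spearman_rho
        return out


@dataclass
class BccResult:
    probabilities: np.ndarray   # chromatin-component probabilities at bound sites
    bcc: float
    threshold: float | None = None


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain at least one positive and one negative")
    return labels


def pr_curve(scores: np.ndarray, labels: np.ndarray):
    """Precision-recall curve and step-based average precision.

    Thresholds at every distinct score with ties grouped; AUC-PR is average
    precision (sum of precision * recall increments), not a trapezoid.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    auc_pr = float(_skm.average_precision_score(labels, scores))
    # sklearn returns the curve from high threshold to low; flip so recall ascends
    return precision[::-1], recall[::-1], auc_pr


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """ROC curve and AUC (equal to the normalised Mann-Whitney U statistic)."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, float(_skm.roc_auc_score(labels, scores))


def evaluate(scores, labels, peak_heights=None) -> EvalResult:
    """Full evaluation bundle: PR, ROC, and optional Spearman vs peak height."""
    precision, recall, auc_pr = pr_curve(scores, labels)
    fpr, tpr, auc_roc = roc_curve(scores, labels)
    rho = None
    if peak_heights is not None:
        labels_b = np.asarray(labels).astype(bool)
        rho = spearman_vs_peak_height(
            np.asarray(scores, dtype=float)[labels_b],
            np.asarray(peak_heights, dtype=float)[labels_b])
    return EvalResult(precision=precision, recall=recall, fpr=fpr, tpr=tpr,
                      auc_pr=auc_pr, auc_roc=auc_roc, spearman_rho=rho)


def spearman_vs_peak_height(scores: np.ndarray, peak_heights: np.ndarray) -> float:
    """Spearman rank correlation of predictions with ChIP-seq peak height
    at bound sites (average ranks for ties). Requires >= 3 bound sites."""
    scores = np.asarray(scores, dtype=float)
    peak_heights = np.asarray(peak_heights, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 bound sites for a rank correlation")
    rho, _ = spearmanr(scores, peak_heights)
    return float(rho)


def chromatin_component_probability(chromatin_loglik: np.ndarray) -> np.ndarray:
    """Probability of being bound in any mode from the chromatin component
    alone, under flat prior odds over all K+2 states (sequence prior excluded).
    """
    ll = np.atleast_2d(np.asarray(chromatin_loglik, dtype=float))
    total = logsumexp(ll, axis=1)
    bound = logsumexp(ll[:, 1:], axis=1)
    return np.exp(bound - total)


def bcc_score(probs: np.ndarray) -> float:
    """Binding in Closed Chromatin: area under the empirical CDF of the
    chromatin-component probabilities at ChIP-bound sites.

    Computed as the exact integral of the ECDF step function over [0, 1]
    (algebraically 1 - mean for probabilities in [0, 1]).
    """
    probs = np.sort(np.asarray(probs, dtype=float))
    if len(probs) == 0:
        raise ValueError("need at least one bound site")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    n = len(probs)
    # ECDF jumps to i/n at probs[i-1]; integrate the step function to 1
    breaks = np.concatenate([probs, [1.0]])
    heights = np.arange(n + 1) / n
    area = float(np.sum(heights[1:] * np.diff(np.concatenate([[0.0], breaks]))[1:]))
    # area above the first breakpoint; the segment [0, probs[0]) has height 0
    return area


def bcc_threshold(bcc_values: np.ndarray, scaled_mad: bool = False) -> tuple:
    """Pioneer-candidate cutoff over a collection of BCC values.

    threshold = median + 1 * MAD; the MAD is unscaled by default (no 1.4826
    consistency factor). Returns (threshold, boolean mask of values above).
    """
    v = np.asarray(bcc_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 BCC values")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if scaled_mad:
        mad *= 1.4826
    threshold = med + mad
    return threshold, v > threshold
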