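"""Confidence calibration of pipeline scores.

Scores are min-max scaled over an evaluation set and binned into equal-width
bins; the per-bin empirical accuracy yields a score-to-confidence curve. A
positive association between bin mean score and bin accuracy indicates a
well-calibrated scoring function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

__all__ = [
    "CalibrationCurve",
    "minmax_scale",
    "calibration_curve",
    "curve_spearman",
    "ConfidenceCalibrator",
    "plot_calibration",
]


@dataclass
class CalibrationCurve:
    """Equal-width bins over scaled score in [0, 1] with empirical accuracy."""

    edges: np.ndarray  # n_bins + 1 edges
    counts: np.ndarray  # per-bin evaluation counts
    accuracy: np.ndarray  # per-bin fraction correct (NaN where empty)
    mean_score: np.ndarray  # per-bin mean scaled score (NaN where empty)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def expected_accuracy(self, scaled_score: float) -> float:
        """Threshold -> expected-accuracy lookup (nearest non-empty bin)."""
        idx = int(np.clip(np.floor(scaled_score * self.n_bins), 0, self.n_bins - 1))
        if self.counts[idx] > 0:
            return float(self.accuracy[idx])
        valid = np.flatnonzero(self.counts > 0)
        if len(valid) == 0:
            return float("nan")
        nearest = valid[np.argmin(np.abs(valid - idx))]
        return float(self.accuracy[nearest])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "count": self.counts,
                "accuracy": self.accuracy,
                "mean_score": self.mean_score,
            }
        )


def minmax_scale(scores) -> np.ndarray:
    """(s - min) / (max - min); requires at least two distinct scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("all scores are equal; min-max scaling is undefined")
    return (scores - lo) / (hi - lo)


def calibration_curve(scaled_scores, correct, n_bins: int = 10) -> CalibrationCurve:
    """Bin scaled scores into equal-width bins and compute per-bin accuracy."""
    scaled = np.asarray(scaled_scores, dtype=float)
    flags = np.asarray(correct, dtype=bool)
    if scaled.shape != flags.shape:
        raise ValueError("scores and correctness flags must be aligned")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.floor(scaled * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    acc = np.full(n_bins, np.nan)
    mean_score = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            acc[b] = flags[sel].mean()
            mean_score[b] = scaled[sel].mean()
    return CalibrationCurve(edges, counts, acc, mean_score)


def curve_spearman(curve: CalibrationCurve) -> float:
    """Spearman correlation between bin mean score and bin accuracy."""
    sel = curve.counts > 0
    if sel.sum() < 2 or len(set(curve.accuracy[sel])) < 2:
        return float("nan")
    rho, _ = spearmanr(curve.mean_score[sel], curve.accuracy[sel])
    return float(rho)


class ConfidenceCalibrator(BaseEstimator):
    """Min-max scaling + binned-accuracy confidence estimates (sklearn-style).

    fit(scores, correct) learns the scaling constants and the curve on the
    evaluation set itself; `freeze_scale=True` keeps fitted constants for
    deployment on new scores.
    """

    def __init__(self, n_bins: int = 10, freeze_scale: bool = True):
        self.n_bins = n_bins
        self.freeze_scale = freeze_scale

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).ravel()
        scaled = minmax_scale(scores)
        self.score_min_ = float(scores.min())
        self.score_max_ = float(scores.max())
        self.curve_ = calibration_curve(scaled, np.asarray(y, dtype=bool), self.n_bins)
        self.spearman_ = curve_spearman(self.curve_)
        return self

    def scale(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.freeze_scale:
            span = self.score_max_ - self.score_min_
            return np.clip((scores - self.score_min_) / span, 0.0, 1.0)
        return minmax_scale(scores)

    def predict(self, X) -> np.ndarray:
        """Expected accuracy for raw scores."""
        scaled = self.scale(X)
        return np.array([self.curve_.expected_accuracy(s) for s in scaled])


def plot_calibration(curve: CalibrationCurve, path) -> None:
    """Write the score-vs-accuracy curve as a figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = curve.counts > 0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.mean_score[sel], curve.accuracy[sel], "o-")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("min-max scaled score")
    ax.set_ylabel("empirical accuracy")
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
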