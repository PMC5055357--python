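"""Histogram-based adjustment of raw prediction scores.

Raw scores from the factorization are regression outputs, not
probabilities.  Given labelled pairs (active / inactive / ambiguous), the
calibration (i) histograms the raw scores of each class in 0.05-wide bins,
discarding scores above 1.10 as outliers, (ii) models the ambiguous-class
histogram as a two-component mixture of the active and inactive histograms
and solves for the mixture weight w1 in closed form, and (iii) converts
each bin to an adjusted score B_i = pos / (pos + floor(ratio·neg)), where
ratio = w2/w1 inflates the under-represented inactive counts.  With the
fitted w1 ≈ 0.16 of a large bioactivity corpus the inflation ratio is 5.25.

Calibration is strictly post-hoc: benchmark cross-validation always ranks
raw scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateError
from .io import ACTIVE, AMBIGUOUS, INACTIVE


@dataclass(frozen=True)
class ScoreHistogram:
    """Per-class binned raw-score counts with half-open bins [lo, lo + width).

    The final retained bin absorbs its upper edge so that a score exactly
    at ``upper_limit`` is kept; scores strictly above are outliers.
    """

    bin_width: float
    upper_limit: float
    counts: dict[str, np.ndarray]
    outliers: dict[str, int]

    @property
    def n_bins(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def fractions(self, label: str) -> np.ndarray:
        total = self.counts[label].sum()
        if total == 0:
            raise DegenerateError(f"no retained scores for class {label!r}")
        return self.counts[label] / total

    def has_class(self, label: str) -> bool:
        return self.counts[label].sum() > 0


@dataclass(frozen=True)
class ScoreCalibration:
    """Fitted mixture weight and the per-bin adjusted-score lookup table."""

    w1: float
    bin_width: float
    upper_limit: float
    bin_scores: tuple[float | None, ...]

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def inflation_ratio(self) -> float:
        if self.w1 == 0:
            raise DegenerateError("w1 = 0 gives an infinite inflation ratio")
        return self.w2 / self.w1


def bin_scores(
    scored_labels: list[tuple[float, str]],
    bin_width: float = 0.05,
    upper_limit: float = 1.10,
) -> ScoreHistogram:
    """Histogram (raw score, label) pairs per class, excluding outliers."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(math.ceil(upper_limit / bin_width - 1e-9))
    counts = {label: np.zeros(n_bins, dtype=np.int64) for label in (ACTIVE, INACTIVE, AMBIGUOUS)}
    outliers = {label: 0 for label in counts}
    for score, label in scored_labels:
        if label not in counts:
            raise ValueError(f"unknown label {label!r}")
        if score > upper_limit:
            outliers[label] += 1
            continue
        idx = min(int(score / bin_width), n_bins - 1)
        counts[label][idx] += 1
    return ScoreHistogram(
        bin_width=bin_width, upper_limit=upper_limit, counts=counts, outliers=outliers
    )


def mixture_error(hist: ScoreHistogram, w1: float) -> float:
    """E_sum(w1) = Σ_i [A_i − (w1 p_i + (1 − w1) N_i)]²."""
    p = hist.fractions(ACTIVE)
    N = hist.fractions(INACTIVE)
    A = hist.fractions(AMBIGUOUS)
    return float(np.sum((A - (w1 * p + (1.0 - w1) * N)) ** 2))


def fit_mixture_weight(hist: ScoreHistogram) -> float:
    """Closed-form least-squares mixture weight, clipped to [0, 1].

    Minimizing E_sum over w1 gives w1 = Σ (p−N)(A−N) / Σ (p−N)².
    """
    for label in (ACTIVE, INACTIVE, AMBIGUOUS):
        if not hist.has_class(label):
            raise DegenerateError(f"class {label!r} has no retained scores")
    p = hist.fractions(ACTIVE)
    N = hist.fractions(INACTIVE)
    A = hist.fractions(AMBIGUOUS)
    denom = float(np.sum((p - N) ** 2))
    if denom == 0:
        raise DegenerateError("active and inactive histograms are identical")
    w1 = float(np.sum((p - N) * (A - N))) / denom
    return min(1.0, max(0.0, w1))


def adjusted_bin_score(pos_count: int, neg_count: int, inflation_ratio: float) -> float | None:
    """B_i = pos / (pos + floor(ratio·neg)); None marks an empty bin."""
    if pos_count < 0 or neg_count < 0:
        raise ValueError("counts must be nonnegative")
    if inflation_ratio <= 0:
        raise ValueError("inflation_ratio must be positive")
    if pos_count == 0 and neg_count == 0:
        return None
    inflated = math.floor(inflation_ratio * neg_count)
    if pos_count + inflated == 0:
        # all-negative bin whose inflated count floors to zero
        return 0.0
    return pos_count / (pos_count + inflated)


def fit_calibration(
    scored_labels: list[tuple[float, str]],
    bin_width: float = 0.05,
    upper_limit: float = 1.10,
) -> ScoreCalibration:
    """End-to-end calibration: histogram, mixture weight, per-bin scores."""
    hist = bin_scores(scored_labels, bin_width=bin_width, upper_limit=upper_limit)
    w1 = fit_mixture_weight(hist)
    if w1 == 0:
        raise DegenerateError("fitted w1 = 0; inflation ratio undefined")
    ratio = (1.0 - w1) / w1
    per_bin = tuple(
        adjusted_bin_score(int(p), int(n), ratio)
        for p, n in zip(hist.counts[ACTIVE], hist.counts[INACTIVE])
    )
    if all(b is None for b in per_bin):
        raise DegenerateError("every bin is empty; nothing to calibrate against")
    return ScoreCalibration(
        w1=w1, bin_width=bin_width, upper_limit=upper_limit, bin_scores=per_bin
    )


def calibrate_score(raw_score: float, calibration: ScoreCalibration) -> float:
    """Map a raw score to its bin's adjusted value.

    Scores above the outlier limit clamp to the highest non-empty bin;
    empty interior bins interpolate linearly between the nearest non-empty
    neighbours, and empty edge bins take the nearest non-empty value.
    """
    scores = calibration.bin_scores
    n_bins = len(scores)
    defined = [k for k, b in enumerate(scores) if b is not None]
    if not defined:
        raise DegenerateError("calibration has no non-empty bins")
    if raw_score > calibration.upper_limit:
        return scores[defined[-1]]
    idx = min(int(raw_score / calibration.bin_width), n_bins - 1)
    if scores[idx] is not None:
        return scores[idx]
    lower = [k for k in defined if k < idx]
    upper = [k for k in defined if k > idx]
    if not lower:
        return scores[upper[0]]
    if not upper:
        return scores[lower[-1]]
    lo, hi = lower[-1], upper[0]
    frac = (idx - lo) / (hi - lo)
    return scores[lo] + frac * (scores[hi] - scores[lo])
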