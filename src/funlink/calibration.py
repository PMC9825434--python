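"""Gold-standard benchmarking and monotone score calibration.

Raw scores become confidences by ranking pairs, measuring precision against
pathway co-membership in sliding windows, and fitting a weighted isotonic
(pool-adjacent-violators) regression through the windowed precisions.  The
same machinery also produces cutoff/frequency summaries of score multisets.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .model import CalibrationCurve, GoldStandard, Pair

__all__ = [
    "BenchmarkLabel",
    "label_pairs",
    "sliding_precision",
    "fit_calibration",
    "apply_calibration",
    "ThresholdSummary",
    "threshold_summary",
    "UnbenchmarkableError",
    "DEFAULT_WINDOW",
]

#: Default sliding-window width (pairs per precision estimate).
DEFAULT_WINDOW = 50


class UnbenchmarkableError(ValueError):
    """Raised when a dataset contains no pair the gold standard can label."""


class BenchmarkLabel(enum.Enum):
    """Truth label of a pair w.r.t. gold-standard pathway co-membership.

    positive: both proteins share at least one non-excluded pathway set.
    negative: both proteins are annotated but share no set.
    unbenchmarkable: at least one protein is unannotated.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNBENCHMARKABLE = "unbenchmarkable"


def label_pairs(pairs: Sequence[Pair], gold: GoldStandard) -> list[BenchmarkLabel]:
    """Label each pair positive / negative / unbenchmarkable against ``gold``."""
    if not gold:
        raise UnbenchmarkableError("gold standard is empty after exclusions")
    labels = []
    for pair in pairs:
        m1 = gold.memberships(pair.a.protein_id)
        m2 = gold.memberships(pair.b.protein_id)
        if not m1 or not m2:
            labels.append(BenchmarkLabel.UNBENCHMARKABLE)
        elif m1 & m2:
            labels.append(BenchmarkLabel.POSITIVE)
        else:
            labels.append(BenchmarkLabel.NEGATIVE)
    return labels


def sliding_precision(
    raw_scores: Sequence[float],
    labels: Sequence[BenchmarkLabel],
    window: int = DEFAULT_WINDOW,
) -> list[tuple[float, float, int]]:
    """Windowed precision along a ranking (highest raw score first).

    ``raw_scores`` and ``labels`` are aligned and sorted by raw score
    descending.  Unbenchmarkable pairs are dropped before windowing.  Windows
    of ``window`` benchmarkable pairs slide by ``max(1, window // 2)``; a
    dataset smaller than one window yields a single window covering it all.

    Returns (mean raw score, precision, weight) per window, where precision =
    positives / (positives + negatives) and weight is the window occupancy.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(raw_scores) != len(labels):
        raise ValueError("raw_scores and labels must be aligned")
    keep = [
        (s, lab is BenchmarkLabel.POSITIVE)
        for s, lab in zip(raw_scores, labels)
        if lab is not BenchmarkLabel.UNBENCHMARKABLE
    ]
    if not keep:
        raise UnbenchmarkableError("unbenchmarkable dataset: no labeled pairs")
    scores = np.array([s for s, _ in keep], dtype=float)
    pos = np.array([p for _, p in keep], dtype=bool)
    n = len(keep)
    step = max(1, window // 2)
    if n <= window:
        starts = [0]
        width = n
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] != n - window:  # always cover the tail
            starts.append(n - window)
        width = window
    out = []
    for s0 in starts:
        sl = slice(s0, s0 + width)
        occ = sl.stop - sl.start if sl.stop <= n else n - sl.start
        prec = float(pos[sl].mean())
        out.append((float(scores[sl].mean()), prec, occ))
    return out


def fit_calibration(points: Iterable[tuple[float, float, float]]) -> CalibrationCurve:
    """Fit a monotone calibration curve through (raw, precision, weight) points.

    Weighted isotonic regression (pool-adjacent-violators): the fitted
    confidences are non-decreasing in raw score and minimize the weighted
    squared deviation from the observed precisions.  Evaluation between
    breakpoints is linear; outside the fitted range the first/last confidence
    applies.
    """
    pts = sorted(points, key=lambda t: t[0])
    if not pts:
        raise ValueError("fit_calibration requires at least one point")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    w = np.array([p[2] for p in pts], dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("precisions must lie in [0, 1]")
    if len(pts) == 1:
        return CalibrationCurve([x[0]], [y[0]])
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(x, y, sample_weight=w)
    # deduplicate tied raw scores (isotonic assigns them one pooled value)
    ux, idx = np.unique(x, return_index=True)
    return CalibrationCurve(ux, fitted[idx])


def apply_calibration(curve: CalibrationCurve, raw) -> float:
    """Map a raw score through a fitted curve; clamps outside the range."""
    val = curve(raw)
    return float(val) if np.ndim(raw) == 0 else np.asarray(val)


def _round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (numpy/python round are half-to-even)."""
    factor = 10**decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class ThresholdSummary:
    """Counts and relative frequencies of scores above each cutoff.

    Frequencies are percentages of the count at the lowest cutoff, rounded
    half-away-from-zero to one decimal; the lowest cutoff is 100.0 by
    construction (when any score reaches it).
    """

    cutoffs: tuple[float, ...]
    counts: tuple[int, ...]
    frequencies: tuple[float, ...]


def threshold_summary(scores: Sequence[float], cutoffs: Sequence[float]) -> ThresholdSummary:
    """Summarize a score multiset at the given ascending cutoffs."""
    cut = np.asarray(cutoffs, dtype=float)
    if cut.size == 0:
        raise ValueError("cutoffs must be non-empty")
    if np.any(np.diff(cut) <= 0):
        raise ValueError("cutoffs must be strictly ascending")
    arr = np.asarray(scores, dtype=float)
    counts = tuple(int((arr >= c).sum()) for c in cut)
    base = counts[0]
    if base == 0:
        warnings.warn("no scores at or above the lowest cutoff; frequencies reported as 0.0")
        freqs = tuple(0.0 for _ in counts)
    else:
        freqs = tuple(float(_round_half_away(100.0 * c / base, 1)) for c in counts)
    return ThresholdSummary(tuple(float(c) for c in cut), counts, freqs)
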