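"""Probabilistic integration of channel scores and combined-score recalibration.

Channel scores are treated as independent probabilities of a true functional
association.  Each score is first corrected for the benchmark prior p (the
chance a random benchmarkable pair is positive), the corrected scores are
merged by a noisy-OR, and the prior is re-added:

    s' = max(0, (s - p) / (1 - p))
    combined = p + (1 - p) * (1 - prod(1 - s'))

Channels at or below the prior carry no signal and leave the result
unchanged.  Because the evidence sources are not truly independent, the
combined scores can optionally be recalibrated against the gold standard.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence, Union

from .calibration import (
    DEFAULT_WINDOW,
    UnbenchmarkableError,
    apply_calibration,
    fit_calibration,
    label_pairs,
    sliding_precision,
)
from .model import GoldStandard, Pair, ScoredEdge

__all__ = ["combine_scores", "estimate_prior", "recalibrate_combined"]

_PRIOR_CAP = 1.0 - 1e-9


def combine_scores(
    channel_scores: Union[Mapping[str, float], Iterable[float]],
    prior: float = 0.0,
) -> float:
    """Combine channel scores into one confidence via prior-corrected noisy-OR.

    Accepts a mapping channel -> score or a plain iterable of scores.
    Returns ``prior`` when every score is at or below it.
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior must be in [0, 1): {prior}")
    scores = list(channel_scores.values()) if isinstance(channel_scores, Mapping) else list(channel_scores)
    residual = 1.0
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score out of [0, 1]: {s}")
        corrected = max(0.0, (s - prior) / (1.0 - prior))
        residual *= 1.0 - corrected
    return prior + (1.0 - prior) * (1.0 - residual)


def estimate_prior(gold: GoldStandard, universe: Sequence[Pair]) -> float:
    """Fraction of benchmarkable universe pairs that are gold positives.

    The universe should reflect the pair population the scores are drawn
    from (e.g. all scored pairs, or all pairs of annotated proteins).
    """
    from .calibration import BenchmarkLabel  # local: avoid polluting module surface

    labels = label_pairs(universe, gold)
    n_pos = sum(lab is BenchmarkLabel.POSITIVE for lab in labels)
    n_bench = sum(lab is not BenchmarkLabel.UNBENCHMARKABLE for lab in labels)
    if n_bench == 0:
        raise UnbenchmarkableError("no benchmarkable pair in the universe")
    prior = n_pos / n_bench
    if prior >= 1.0:
        warnings.warn("all benchmarkable pairs are positive; capping prior below 1")
        prior = _PRIOR_CAP
    return prior


def recalibrate_combined(
    edges: Sequence[ScoredEdge],
    gold: GoldStandard,
    window: int = DEFAULT_WINDOW,
) -> list[ScoredEdge]:
    """Recalibrate combined scores against the gold standard.

    Corrects for the non-independence of the evidence sources: edges are
    ranked by combined score, windowed precision is measured against pathway
    co-membership, and a monotone curve maps each combined score to its
    recalibrated value.  Rank order is preserved up to ties.  With zero
    benchmarkable edges the input is returned unchanged (with a warning).
    """
    if not edges:
        return []
    ranked = sorted(edges, key=lambda e: (-e.combined, e.pair))
    labels = label_pairs([e.pair for e in ranked], gold)
    try:
        points = sliding_precision([e.combined for e in ranked], labels, window=window)
    except UnbenchmarkableError:
        warnings.warn("no benchmarkable edges; recalibration is the identity")
        return list(edges)
    curve = fit_calibration(points)
    return [
        ScoredEdge(
            pair=e.pair,
            channel_scores=dict(e.channel_scores),
            combined=float(apply_calibration(curve, e.combined)),
            grade=e.grade,
        )
        for e in edges
    ]
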