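"""Scoring of the experiments evidence channel.

Pipeline (one publication at a time):

1. Records are filtered by detection method against the PSI-MI controlled
   vocabulary: only 'experimental interaction detection' (MI:0045) and its
   descendants are admissible; author/curator inferences (MI:0363, MI:0364)
   and predictions (MI:0063) are excluded; 'genetic interference' (MI:0254)
   evidence is kept but flagged as strictly functional.
2. Duplicate records from different source databases are removed.
3. Records are grouped into experiments — all unique pairs sharing a
   publication id and detection method — and classified high-throughput
   (HT, >= 25 unique pairs) or low-throughput (LT).
4. HT experiments are scored individually: each pair gets a raw score from
   its shared/non-shared interactors within the experiment, the ranking is
   benchmarked against the gold standard and a calibration curve maps raw
   scores to confidences.
5. LT pairs are pooled per detection method across experiments, and the
   method's overall true-positive rate becomes the confidence of every pair
   it detected; no curve fitting.
6. Per-pair dataset scores are aggregated by prior-corrected noisy-OR, and
   each contributing dataset gets a three-tier grade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from .calibration import (
    DEFAULT_WINDOW,
    BenchmarkLabel,
    UnbenchmarkableError,
    apply_calibration,
    fit_calibration,
    label_pairs,
    sliding_precision,
)
from .combination import combine_scores
from .model import EvidenceRecord, GoldStandard, Pair, ProteinRef

__all__ = [
    "MethodOntology",
    "Experiment",
    "MethodScore",
    "PairChannelScore",
    "filter_methods",
    "deduplicate",
    "group_experiments",
    "ht_raw_score",
    "score_ht_experiment",
    "score_lt_methods",
    "aggregate_pair_score",
    "grade_dataset",
    "score_experiments_channel",
    "HT_MIN_PAIRS",
    "EXPERIMENTAL_DETECTION",
    "EXCLUDED_ROOTS",
    "GENETIC_INTERFERENCE",
    "GRADE_HIGH",
    "GRADE_MEDIUM",
]

logger = logging.getLogger(__name__)

#: Minimum unique pairs for an experiment to count as high-throughput.
HT_MIN_PAIRS = 25

#: PSI-MI CV anchors for method filtering.
EXPERIMENTAL_DETECTION = "MI:0045"
EXCLUDED_ROOTS = ("MI:0363", "MI:0364", "MI:0063")
GENETIC_INTERFERENCE = "MI:0254"

#: Default three-tier grade boundaries.
GRADE_HIGH = 0.7
GRADE_MEDIUM = 0.4


class MethodOntology:
    """PSI-MI-style controlled vocabulary as a DAG (term -> parents)."""

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self.parents: dict[str, frozenset[str]] = {}
        terms: set[str] = set()
        for child, pars in parents.items():
            ps = frozenset(pars)
            self.parents[child] = ps
            terms.add(child)
            terms.update(ps)
        self.terms: frozenset[str] = frozenset(terms)
        self._check_acyclic()
        self._children: dict[str, set[str]] = {}
        for child, pars in self.parents.items():
            for p in pars:
                self._children.setdefault(p, set()).add(child)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p in self.parents.get(t, ()):
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"ontology cycle through {t!r}")
                if s == 0:
                    visit(p)
            state[t] = 2

        for term in self.terms:
            if state.get(term, 0) == 0:
                visit(term)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    @lru_cache(maxsize=None)
    def descendants(self, term: str) -> frozenset[str]:
        """Term itself plus everything reachable downwards."""
        out = {term}
        stack = [term]
        while stack:
            for child in self._children.get(stack.pop(), ()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return frozenset(out)

    def is_under(self, term: str, ancestor: str) -> bool:
        return term in self.descendants(ancestor)


@dataclass(frozen=True)
class Experiment:
    """All unique pairs sharing one publication id and detection method."""

    publication_id: str
    method_term: str
    pairs: frozenset[Pair]

    @property
    def throughput(self) -> str:
        return "HT" if len(self.pairs) >= HT_MIN_PAIRS else "LT"


@dataclass(frozen=True)
class MethodScore:
    """Benchmark-derived confidence of one LT detection method."""

    method_term: str
    tp_rate: float
    n_benchmarked: int
    evidence_class: str = "physical"  # or "functional_only"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tp_rate <= 1.0:
            raise ValueError(f"tp_rate out of [0,1]: {self.tp_rate}")


@dataclass
class PairChannelScore:
    """Aggregated experiments-channel score of one pair."""

    pair: Pair
    score: float
    n_datasets: int
    best_grade: str
    dataset_scores: list[float] = field(default_factory=list)


def filter_methods(
    records: Iterable[EvidenceRecord],
    ontology: MethodOntology,
    root: str = EXPERIMENTAL_DETECTION,
    excluded_roots: Sequence[str] = EXCLUDED_ROOTS,
    functional_root: str = GENETIC_INTERFERENCE,
) -> list[EvidenceRecord]:
    """Keep records whose method is admissible experimental detection.

    A record survives iff its method term is ``root`` or a descendant, and
    is not under any excluded root.  Surviving records under
    ``functional_root`` are re-flagged as functional-only evidence
    (``physical=False``).  Records with a method unknown to the ontology
    are dropped with a logged warning.
    """
    if root not in ontology:
        raise ValueError(f"ontology lacks the filter root {root!r}")
    admissible = ontology.descendants(root)
    excluded: set[str] = set()
    for ex in excluded_roots:
        if ex in ontology:
            excluded |= ontology.descendants(ex)
    functional = ontology.descendants(functional_root) if functional_root in ontology else frozenset()
    out = []
    for rec in records:
        term = rec.method_term
        if term not in ontology:
            logger.warning("dropping record with unknown method term %r", term)
            continue
        if term not in admissible or term in excluded:
            continue
        physical = term not in functional
        if physical != rec.physical:
            rec = EvidenceRecord(
                pair=rec.pair,
                publication_id=rec.publication_id,
                method_term=rec.method_term,
                source_db=rec.source_db,
                channel=rec.channel,
                physical=physical,
            )
        out.append(rec)
    return out


def deduplicate(
    records: Iterable[EvidenceRecord],
    source_priority: Sequence[str] = (),
) -> list[EvidenceRecord]:
    """Keep one record per (pair, publication, method).

    The survivor's source database follows ``source_priority`` (first match
    wins); sources not listed rank after listed ones, ties broken
    lexicographically.  Idempotent.
    """
    rank = {db: i for i, db in enumerate(source_priority)}
    best: dict[tuple, EvidenceRecord] = {}
    for rec in records:
        key = (rec.pair, rec.publication_id, rec.method_term)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        new_key = (rank.get(rec.source_db, len(rank)), rec.source_db)
        cur_key = (rank.get(cur.source_db, len(rank)), cur.source_db)
        if new_key < cur_key:
            best[key] = rec
    return list(best.values())


def group_experiments(
    records: Iterable[EvidenceRecord],
    ht_min_pairs: int = HT_MIN_PAIRS,
) -> list[Experiment]:
    """Group deduplicated records into (publication, method) experiments."""
    grouped: dict[tuple[str, str], set[Pair]] = {}
    for rec in records:
        grouped.setdefault((rec.publication_id, rec.method_term), set()).add(rec.pair)
    exps = [
        Experiment(publication_id=pub, method_term=meth, pairs=frozenset(pairs))
        for (pub, meth), pairs in grouped.items()
    ]
    exps.sort(key=lambda e: (e.publication_id, e.method_term))
    if ht_min_pairs != HT_MIN_PAIRS:
        # custom threshold: wrap in a subclass carrying the override
        class _Exp(Experiment):
            @property
            def throughput(self) -> str:  # type: ignore[override]
                return "HT" if len(self.pairs) >= ht_min_pairs else "LT"

        exps = [_Exp(e.publication_id, e.method_term, e.pairs) for e in exps]
    return exps


def _neighbor_sets(experiment: Experiment) -> dict[tuple[str, str], set[ProteinRef]]:
    nbrs: dict[tuple[str, str], set[ProteinRef]] = {}
    for p in experiment.pairs:
        nbrs.setdefault(p.a.key, set()).add(p.b)
        nbrs.setdefault(p.b.key, set()).add(p.a)
    return nbrs


def ht_raw_score(experiment: Experiment, pair: Pair) -> float:
    """Raw within-experiment quality score of a pair.

    Jaccard index of the two endpoints' interactor sets within this
    experiment, excluding the endpoints themselves: more shared and fewer
    non-shared interactors give a higher score.  0 for an isolated pair.
    """
    if pair not in experiment.pairs:
        raise KeyError(f"{pair} not in experiment {experiment.publication_id}")
    nbrs = _neighbor_sets(experiment)
    na = nbrs[pair.a.key] - {pair.a, pair.b}
    nb = nbrs[pair.b.key] - {pair.a, pair.b}
    union = na | nb
    if not union:
        return 0.0
    return len(na & nb) / len(union)


def score_ht_experiment(
    experiment: Experiment,
    gold: GoldStandard,
    window: int = DEFAULT_WINDOW,
    fallback: Optional[float] = None,
) -> dict[Pair, float]:
    """Calibrated confidence per pair of one HT experiment.

    Pairs are ranked by raw score (stable order, ties broken by pair
    identity), windowed precision against the gold standard is fitted with
    an isotonic curve, and each pair's raw score is mapped through it.
    With zero benchmarkable pairs the experiment is unscorable: all pairs
    receive ``fallback`` (e.g. the global prior) if given, else the
    experiment is reported as an empty mapping with a warning.
    """
    if experiment.throughput != "HT":
        raise ValueError("score_ht_experiment requires an HT experiment")
    raw = {p: ht_raw_score(experiment, p) for p in experiment.pairs}
    ranked = sorted(experiment.pairs, key=lambda p: (-raw[p], p))
    labels = label_pairs(ranked, gold)
    try:
        points = sliding_precision([raw[p] for p in ranked], labels, window=window)
    except UnbenchmarkableError:
        warnings.warn(
            f"experiment {experiment.publication_id}/{experiment.method_term} "
            "has no benchmarkable pair; using fallback confidence"
        )
        if fallback is None:
            return {}
        return {p: fallback for p in experiment.pairs}
    curve = fit_calibration(points)
    return {p: float(apply_calibration(curve, raw[p])) for p in experiment.pairs}


def score_lt_methods(
    records: Iterable[EvidenceRecord],
    gold: GoldStandard,
) -> list[MethodScore]:
    """True-positive rate per detection method over pooled LT pairs.

    Pairs from all LT experiments of one method are pooled (methods are
    grouped to get benchmarkable sample sizes); tp_rate = positives /
    (positives + negatives) over the benchmarkable pool.  Methods with no
    benchmarkable pair are flagged unscorable (omitted, with a warning).
    """
    by_method: dict[str, set[Pair]] = {}
    physical: dict[str, bool] = {}
    for rec in records:
        by_method.setdefault(rec.method_term, set()).add(rec.pair)
        physical[rec.method_term] = rec.physical
    out = []
    for method in sorted(by_method):
        pairs = sorted(by_method[method])
        labels = label_pairs(pairs, gold)
        n_pos = sum(lab is BenchmarkLabel.POSITIVE for lab in labels)
        n_bench = sum(lab is not BenchmarkLabel.UNBENCHMARKABLE for lab in labels)
        if n_bench == 0:
            warnings.warn(f"method {method} has no benchmarkable pair; unscorable")
            continue
        out.append(
            MethodScore(
                method_term=method,
                tp_rate=n_pos / n_bench,
                n_benchmarked=n_bench,
                evidence_class="physical" if physical[method] else "functional_only",
            )
        )
    return out


def aggregate_pair_score(per_dataset_scores: Sequence[float], prior: float = 0.0) -> float:
    """One experiments-channel score from all dataset scores of a pair.

    Prior-corrected noisy-OR across HT-experiment and LT-method scores.
    An empty list means the pair has no channel score (caller omits it).
    """
    if len(per_dataset_scores) == 0:
        raise ValueError("no dataset scores; the pair has no channel score")
    return combine_scores(per_dataset_scores, prior)


def grade_dataset(
    confidence: float,
    high: float = GRADE_HIGH,
    medium: float = GRADE_MEDIUM,
) -> str:
    """Three-tier grade of one dataset's confidence."""
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence out of [0,1]: {confidence}")
    if confidence >= high:
        return "high"
    if confidence >= medium:
        return "medium"
    return "exploratory"


_GRADE_ORDER = {"high": 0, "medium": 1, "exploratory": 2}


def score_experiments_channel(
    records: Iterable[EvidenceRecord],
    ontology: MethodOntology,
    gold: GoldStandard,
    prior: float = 0.0,
    window: int = DEFAULT_WINDOW,
    source_priority: Sequence[str] = (),
    unscorable_ht_fallback: Optional[float] = None,
) -> dict[Pair, PairChannelScore]:
    """Full experiments-channel pipeline: filter, dedup, group, score, aggregate.

    Returns one aggregated channel score per pair, with the number of
    supporting datasets and the best per-dataset grade.  Stage counts are
    logged for auditability.
    """
    records = list(records)
    logger.info("experiments channel: %d raw records", len(records))
    kept = filter_methods(records, ontology)
    logger.info("after method filtering: %d records", len(kept))
    deduped = deduplicate(kept, source_priority=source_priority)
    logger.info("after deduplication: %d records", len(deduped))
    experiments = group_experiments(deduped)
    ht = [e for e in experiments if e.throughput == "HT"]
    lt = [e for e in experiments if e.throughput == "LT"]
    logger.info("experiments: %d HT, %d LT", len(ht), len(lt))

    per_pair: dict[Pair, list[float]] = {}
    fallback = unscorable_ht_fallback if unscorable_ht_fallback is not None else (prior or None)
    for exp in ht:
        for pair, conf in score_ht_experiment(exp, gold, window=window, fallback=fallback).items():
            per_pair.setdefault(pair, []).append(conf)

    lt_keys = {(e.publication_id, e.method_term) for e in lt}
    lt_records = [r for r in deduped if (r.publication_id, r.method_term) in lt_keys]
    method_scores = {m.method_term: m for m in score_lt_methods(lt_records, gold)}
    for rec in lt_records:
        m = method_scores.get(rec.method_term)
        if m is not None:
            per_pair.setdefault(rec.pair, []).append(m.tp_rate)

    out: dict[Pair, PairChannelScore] = {}
    for pair, scores in per_pair.items():
        grades = [grade_dataset(s) for s in scores]
        out[pair] = PairChannelScore(
            pair=pair,
            score=aggregate_pair_score(scores, prior),
            n_datasets=len(scores),
            best_grade=min(grades, key=_GRADE_ORDER.__getitem__),
            dataset_scores=scores,
        )
    return out
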