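"""Performance accounting for prioritised screening.

All quantities are expressed the way screening studies report them:

* **precision** — included records as a percentage of records screened
  (or retained above a threshold);
* **recall** — included records found as a percentage of all known
  relevant records (undefined when screening stopped early and the
  total is unknown);
* **screening reduction** — percentage of retrieved records that the
  policy removed from manual screening.

The module also provides the decade-binned score histogram used to
judge whether a classifier is fit for purpose, per-score-band
precision, stratified k-fold recall validation, and the per-band
screening-time summary from which time saved is extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import (FeatureConfig, ScoredRecord, TrainingRule,
                         train_classifier)
from .records import Corpus

__all__ = [
    "MetricsReport",
    "ScoreDistribution",
    "CrossValReport",
    "TimeBandSummary",
    "screening_metrics",
    "score_distribution",
    "suitability_check",
    "per_band_precision",
    "cumulative_includes_curve",
    "stratified_kfold_recall",
    "band_time_summary",
    "estimate_time_saved",
]


@dataclass(frozen=True)
class MetricsReport:
    """Box-score of a screening run.  Percentages are unrounded;
    presentation rounding is left to the caller/printer."""

    n_total: int
    n_screened: int
    n_relevant_found: int
    n_relevant_total: Optional[int]
    precision_pct: float
    recall_pct: Optional[float]
    screening_reduction_pct: float

    @property
    def n_unscreened(self) -> int:
        return self.n_total - self.n_screened

    def summary(self) -> str:
        rec = "n/a (total relevant unknown)" if self.recall_pct is None \
            else f"{self.recall_pct:.0f}%"
        return (
            f"screened {self.n_screened}/{self.n_total} "
            f"({self.n_unscreened} not screened)\n"
            f"precision {self.precision_pct:.2f}%  recall {rec}  "
            f"screening reduction {self.screening_reduction_pct:.0f}%"
        )


def screening_metrics(n_total: int, n_screened: int, n_relevant_found: int,
                      n_relevant_total: Optional[int] = None) -> MetricsReport:
    """Precision, recall and screening reduction from raw counts.

    ``n_relevant_total`` is the full gold-standard count of relevant
    records; leave it ``None`` when screening stopped early and recall
    cannot be known.
    """
    if not (0 <= n_relevant_found <= n_screened <= n_total):
        raise ValueError("need 0 <= n_relevant_found <= n_screened <= n_total")
    if n_relevant_total is not None and n_relevant_found > n_relevant_total:
        raise ValueError("found more relevant records than exist")
    precision = 100.0 * n_relevant_found / n_screened if n_screened else 0.0
    recall = (100.0 * n_relevant_found / n_relevant_total
              if n_relevant_total else None)
    reduction = 100.0 * (n_total - n_screened) / n_total if n_total else 0.0
    return MetricsReport(
        n_total=n_total, n_screened=n_screened,
        n_relevant_found=n_relevant_found, n_relevant_total=n_relevant_total,
        precision_pct=precision, recall_pct=recall,
        screening_reduction_pct=reduction,
    )


@dataclass
class ScoreDistribution:
    """Decade-binned histogram of relevance scores (0-9, 10-19, ..., 90-99)."""

    bin_edges: List[int]            # left edges; right edge of last bin is 99
    counts: List[int]

    @property
    def labels(self) -> List[str]:
        edges = self.bin_edges + [100]
        return [f"{lo}-{edges[i + 1] - 1}" for i, lo in enumerate(self.bin_edges)]

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"band": self.labels, "count": self.counts})


def score_distribution(scored: Sequence[ScoredRecord], bin_width: int = 10) -> ScoreDistribution:
    """Histogram of integer scores; counts always sum to the input size."""
    edges = list(range(0, 100, bin_width))
    counts = [0] * len(edges)
    for s in scored:
        if not (0 <= s.score <= 99):
            raise ValueError(f"score {s.score} outside [0, 99]")
        counts[min(s.score // bin_width, len(edges) - 1)] += 1
    return ScoreDistribution(bin_edges=edges, counts=counts)


def suitability_check(dist: ScoreDistribution, tolerance: float = 0.10) -> Tuple[bool, str]:
    """Judge whether a classifier's score distribution fits prioritised screening.

    A usable classifier concentrates the corpus at very low relevance
    and decays markedly through the higher scores.  The distribution is
    *suitable* iff the 0-9 bin exceeds both the 10-19 and the 20-29
    bins, and from the 20s bin upward no bin rises above its left
    neighbour by more than ``tolerance`` x the 0-9 count (a small bump
    of genuine includes at the top of the scale is tolerated).
    Returns (verdict, rationale naming the violated comparison).
    """
    c = dist.counts
    if len(c) < 3:
        raise ValueError("suitability check needs decade bins")
    if c[0] <= c[1]:
        return False, (f"unsuitable: fewer records at very low relevance "
                       f"(0-9: {c[0]}) than at 10-19 ({c[1]})")
    if c[0] <= c[2]:
        return False, (f"unsuitable: fewer records at very low relevance "
                       f"(0-9: {c[0]}) than at 20-29 ({c[2]})")
    slack = tolerance * c[0]
    labels = dist.labels
    for i in range(2, len(c) - 1):
        if c[i + 1] > c[i] + slack:
            return False, (f"unsuitable: counts rise from {labels[i]} ({c[i]}) "
                           f"to {labels[i + 1]} ({c[i + 1]}); no marked decay "
                           f"across high scores")
    return True, ("suitable: most records are of very low relevance and "
                  "counts decay markedly across higher scores")


def per_band_precision(scored: Sequence[ScoredRecord], labels: Dict[str, str],
                       bands: Optional[Sequence[Tuple[int, int]]] = None) -> pd.DataFrame:
    """Includes as a percentage of records per score band.

    ``bands`` is a list of inclusive (low, high) score ranges; decade
    bands by default.  Empty bands report precision as missing rather
    than zero.
    """
    if bands is None:
        bands = [(lo, lo + 9) for lo in range(0, 100, 10)]
    rows = []
    for lo, hi in bands:
        members = [s for s in scored if lo <= s.score <= hi]
        n = len(members)
        inc = sum(1 for s in members if labels[s.record_id] == "include")
        rows.append({
            "band": f"{lo}-{hi}",
            "n_records": n,
            "n_includes": inc,
            "precision_pct": 100.0 * inc / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def cumulative_includes_curve(scored: Sequence[ScoredRecord],
                              labels: Dict[str, str]) -> pd.DataFrame:
    """Includes found versus records screened, walking the ranking top-down.

    The curve is monotone non-decreasing and its final point is
    (number of records, total includes); a steep early rise is what
    makes prioritised screening pay off.
    """
    ordered = sorted(scored, key=lambda s: (-s.probability, s.record_id))
    found = np.cumsum([1 if labels[s.record_id] == "include" else 0 for s in ordered])
    return pd.DataFrame({
        "n_screened": np.arange(1, len(ordered) + 1),
        "n_includes_found": found,
        "score": [s.score for s in ordered],
    })


@dataclass
class CrossValReport:
    """Stratified k-fold recall validation of a training corpus."""

    k: int
    threshold: int
    seed: int
    fold_recall_pct: List[float]
    fold_n_relevant: List[int]
    fold_scores: List[List[int]] = field(repr=False, default_factory=list)

    @property
    def mean_recall_pct(self) -> float:
        return float(np.mean(self.fold_recall_pct))

    def summary(self) -> str:
        lo, hi = min(self.fold_recall_pct), max(self.fold_recall_pct)
        return (f"{self.k}-fold recall at threshold {self.threshold}: "
                f"mean {self.mean_recall_pct:.0f}% (range {hi:.0f}%-{lo:.0f}%, "
                f"{min(self.fold_n_relevant)}-{max(self.fold_n_relevant)} "
                f"relevant records per fold)")


def stratified_kfold_recall(corpus: Corpus, rule: TrainingRule = TrainingRule(),
                            config: FeatureConfig = FeatureConfig(), k: int = 5,
                            threshold: int = 10, seed: int = 0) -> CrossValReport:
    """Estimate recall by stratified k-fold cross-validation.

    Folds are stratified on the include/exclude class; each fold's
    model is trained on the other k-1 folds and the held-out positives
    are checked against ``threshold`` (a positive is recalled iff its
    score >= threshold).  Fold assignment is seeded and reproducible.
    """
    labelled = corpus.labelled()
    y = np.array([1 if rule.is_positive(r) else 0 for r in labelled])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(n_pos, n_neg) < k:
        raise ValueError(f"smallest class has {min(n_pos, n_neg)} records; "
                         f"cannot stratify into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    recalls, n_rel, fold_scores = [], [], []
    ids = [r.record_id for r in labelled]
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = labelled.subset([ids[i] for i in train_idx])
        model = train_classifier(train, rule, config, seed=seed)
        held_pos = [labelled[i] for i in test_idx if y[i] == 1]
        probs = model.predict_probability(held_pos)
        scores = [min(int(np.floor(p * 100)), 99) for p in probs]
        hit = sum(1 for s in scores if s >= threshold)
        recalls.append(100.0 * hit / len(held_pos))
        n_rel.append(len(held_pos))
        fold_scores.append(scores)
    return CrossValReport(k=k, threshold=threshold, seed=seed,
                          fold_recall_pct=recalls, fold_n_relevant=n_rel,
                          fold_scores=fold_scores)


@dataclass(frozen=True)
class TimeBandSummary:
    """Per-score-band screening-time summary (seconds per record)."""

    band: str
    n: int
    min_s: float
    max_s: float
    mean_s: float        # reported to 1 decimal place
    total_s: float


def band_time_summary(samples: Dict[str, Sequence[float]]) -> List[TimeBandSummary]:
    """Summarise measured per-record screening times by score band.

    ``samples`` maps a band label (e.g. "90-99") to the measured
    seconds for each record screened in that band.  Empty bands are
    skipped with a warning.
    """
    out = []
    for band, values in samples.items():
        values = list(values)
        if not values:
            warnings.warn(f"band {band!r} has no samples; skipped")
            continue
        out.append(TimeBandSummary(
            band=band, n=len(values),
            min_s=float(min(values)), max_s=float(max(values)),
            mean_s=round(float(np.mean(values)), 1),
            total_s=float(np.sum(values)),
        ))
    return out


def estimate_time_saved(n_unscreened: int, seconds_per_record: float) -> Tuple[int, float]:
    """Screening time saved by not screening ``n_unscreened`` records.

    Returns (hours rounded to the nearest integer, exact seconds).
    The per-record time should come from measurements at the relevance
    scores actually forgone (low scores screen fastest, so using their
    mean keeps the estimate conservative).
    """
    if n_unscreened < 0 or seconds_per_record < 0:
        raise ValueError("counts and times must be non-negative")
    seconds = n_unscreened * seconds_per_record
    return int(round(seconds / 3600.0)), seconds
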