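"""Threshold, batch and stopping rules for prioritised screening.

Once an update search has been ranked, screening effort is bounded by
a :class:`ThresholdPolicy`:

1. records scoring at or below ``low_cut`` are never screened;
2. records scoring at or above ``high_cut`` are always screened;
3. the middle zone is screened most-relevant-first in batches of
   ``batch_size``;
4. middle-zone screening stops once ``stop_interval`` consecutive
   records have been screened without an include (checked at batch
   boundaries), or — if ``floor_score`` is set — once the next batch
   starts below that score, whichever comes first.

:func:`simulate_prioritised_screening` replays this policy against
known labels, which is how a retrospective evaluation establishes what
a policy would have cost and found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .classifier import ScoredRecord

__all__ = [
    "ThresholdPolicy",
    "ScreeningPlan",
    "SimulationResult",
    "build_screening_plan",
    "simulate_prioritised_screening",
    "screening_workload",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Stopping-rule parameters on the 0-99 relevance-score scale.

    ``count_priority_zone`` controls whether non-includes screened in
    the always-screen zone count toward the stop interval (they do by
    default: the interval is "records since the last include",
    wherever that include occurred, but it can only terminate
    screening within the middle zone).
    """

    low_cut: int = 10
    high_cut: int = 20
    batch_size: int = 500
    stop_interval: int = 1000
    floor_score: Optional[int] = None
    count_priority_zone: bool = True

    def __post_init__(self):
        if not (0 <= self.low_cut < self.high_cut <= 99):
            raise ValueError("need 0 <= low_cut < high_cut <= 99")
        if self.batch_size < 1 or self.stop_interval < 1:
            raise ValueError("batch_size and stop_interval must be >= 1")
        if self.floor_score is not None and not (self.low_cut < self.floor_score < self.high_cut):
            raise ValueError("floor_score must lie strictly between low_cut and high_cut")


def _sorted_desc(scored: Sequence[ScoredRecord]) -> List[ScoredRecord]:
    return sorted(scored, key=lambda s: (-s.score, s.record_id))


@dataclass
class ScreeningPlan:
    """Partition of scored records into screening zones.

    priority_zone (score >= high_cut, always screened), middle_zone
    (low_cut < score < high_cut, batched), auto_excluded
    (score <= low_cut, never screened).  Each zone is descending by
    score with ascending-record_id tie-break.
    """

    priority_zone: List[ScoredRecord]
    middle_zone: List[ScoredRecord]
    auto_excluded: List[ScoredRecord]
    policy: ThresholdPolicy

    @property
    def middle_batches(self) -> List[List[ScoredRecord]]:
        b = self.policy.batch_size
        return [self.middle_zone[i:i + b] for i in range(0, len(self.middle_zone), b)]

    def __len__(self) -> int:
        return len(self.priority_zone) + len(self.middle_zone) + len(self.auto_excluded)


def build_screening_plan(scored: Sequence[ScoredRecord], policy: ThresholdPolicy = ThresholdPolicy()) -> ScreeningPlan:
    """Partition scored records into the three screening zones."""
    for s in scored:
        if not (0 <= s.score <= 99):
            raise ValueError(f"record {s.record_id!r}: score {s.score} outside [0, 99]")
    ordered = _sorted_desc(scored)
    return ScreeningPlan(
        priority_zone=[s for s in ordered if s.score >= policy.high_cut],
        middle_zone=[s for s in ordered if policy.low_cut < s.score < policy.high_cut],
        auto_excluded=[s for s in ordered if s.score <= policy.low_cut],
        policy=policy,
    )


@dataclass
class SimulationResult:
    """Outcome of replaying a screening plan against known decisions."""

    screened: List[Tuple[str, str]]            # (record_id, decision) in screening order
    unscreened: List[str]
    stop_reason: str                            # interval_reached | floor_reached | exhausted
    counts: Dict[str, int] = field(default_factory=dict)
    includes_found: int = 0

    @property
    def screened_ids(self) -> List[str]:
        return [rid for rid, _ in self.screened]


def simulate_prioritised_screening(plan: ScreeningPlan, labels: Dict[str, str],
                                   policy: Optional[ThresholdPolicy] = None) -> SimulationResult:
    """Replay prioritised screening with the stop-interval rule.

    The priority zone is screened in full.  Middle-zone batches are
    then taken in descending-score order; before each batch the
    simulator stops if the count of consecutively screened non-includes
    since the most recent include has reached ``stop_interval``, or if
    the batch's top score is below ``floor_score``.  Auto-excluded
    records and unreached batches are never screened.

    ``labels`` maps every planned record_id to "include"/"exclude"
    (retrospective evaluation needs full ground truth).
    """
    policy = policy or plan.policy
    for s in plan.priority_zone + plan.middle_zone + plan.auto_excluded:
        if s.record_id not in labels:
            raise ValueError(f"no label for planned record {s.record_id!r}")

    screened: List[Tuple[str, str]] = []
    includes_found = 0
    since_last_include = 0

    def screen_one(s: ScoredRecord):
        nonlocal includes_found, since_last_include
        decision = labels[s.record_id]
        screened.append((s.record_id, decision))
        if decision == "include":
            includes_found += 1
            since_last_include = 0
        else:
            since_last_include += 1

    for s in plan.priority_zone:
        screen_one(s)
    if not policy.count_priority_zone:
        since_last_include = 0

    stop_reason = "exhausted"
    middle_screened = 0
    for batch in plan.middle_batches:
        if since_last_include >= policy.stop_interval:
            stop_reason = "interval_reached"
            break
        if policy.floor_score is not None and batch[0].score < policy.floor_score:
            stop_reason = "floor_reached"
            break
        for s in batch:
            screen_one(s)
        middle_screened += len(batch)

    screened_set = {rid for rid, _ in screened}
    unscreened = [
        s.record_id
        for s in plan.middle_zone + plan.auto_excluded
        if s.record_id not in screened_set
    ]
    return SimulationResult(
        screened=screened,
        unscreened=unscreened,
        stop_reason=stop_reason,
        counts={
            "priority_screened": len(plan.priority_zone),
            "middle_screened": middle_screened,
            "middle_unscreened": len(plan.middle_zone) - middle_screened,
            "auto_excluded": len(plan.auto_excluded),
        },
        includes_found=includes_found,
    )


def screening_workload(result: SimulationResult) -> Tuple[int, int]:
    """(records screened, records not screened); the two sum to the plan size."""
    return len(result.screened), len(result.unscreened)
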