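"""Core bibliographic record types.

A screening project works on a :class:`Corpus` of :class:`CitationRecord`
objects.  Records carry the fields that matter for title/abstract screening
(title, abstract, notes, year, source) plus an optional
:class:`ScreeningLabel` holding the human screening decision that the
relevance classifier trains on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

__all__ = ["ScreeningLabel", "CitationRecord", "Corpus"]

VALID_DECISIONS = ("include", "exclude")
VALID_STAGES = ("title_abstract", "full_text")


@dataclass(frozen=True)
class ScreeningLabel:
    """A human screening decision.

    Parameters
    ----------
    decision:
        ``"include"`` or ``"exclude"``.
    code:
        Optional reason code from the project's code set (e.g. ``Ex1``
        for "off topic" or ``Include2`` for "randomised controlled
        trial").  Hierarchical code sets let one corpus train several
        classifiers under different inclusion rules.
    stage:
        Screening stage the decision was made at; defaults to
        ``title_abstract``.
    """

    decision: str
    code: Optional[str] = None
    stage: str = "title_abstract"

    def __post_init__(self) -> None:
        if self.decision not in VALID_DECISIONS:
            raise ValueError(f"decision must be one of {VALID_DECISIONS}, got {self.decision!r}")
        if self.stage not in VALID_STAGES:
            raise ValueError(f"stage must be one of {VALID_STAGES}, got {self.stage!r}")

    @property
    def effective_code(self) -> str:
        """The label's code, falling back to the bare decision."""
        return self.code if self.code else self.decision


@dataclass
class CitationRecord:
    """One bibliographic record (title, abstract, notes, provenance, label).

    ``extra`` holds unrecognised RIS tags so that files round-trip
    verbatim; ``score`` is populated once a relevance classifier has
    ranked the record (integer 0-99, 99 most relevant).
    """

    record_id: str
    title: str
    abstract: str = ""
    notes: str = ""
    year: Optional[int] = None
    source: str = ""
    label: Optional[ScreeningLabel] = None
    score: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.title or not self.title.strip():
            raise ValueError(f"record {self.record_id!r}: title must be non-empty")

    @property
    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())

    def copy(self, **changes) -> "CitationRecord":
        rec = replace(self, **{k: v for k, v in changes.items() if k != "extra"})
        rec.extra = dict(changes.get("extra", self.extra))
        return rec


class Corpus:
    """An ordered, id-unique collection of citation records.

    Iteration order is stable (insertion order) so that every
    downstream operation — deduplication, ranking tie-breaks, fold
    assignment — is reproducible.
    """

    def __init__(self, records: Sequence[CitationRecord] = (), code_set: Optional[set] = None):
        self._records: list[CitationRecord] = []
        self._index: dict[str, int] = {}
        self.code_set: set = set(code_set) if code_set else set()
        for rec in records:
            self.add(rec)

    def add(self, record: CitationRecord) -> None:
        if record.record_id in self._index:
            raise ValueError(f"duplicate record_id {record.record_id!r}")
        if record.label is not None and record.label.code is not None and self.code_set:
            if record.label.code not in self.code_set:
                raise ValueError(
                    f"record {record.record_id!r}: label code {record.label.code!r} "
                    f"not in declared code set"
                )
        self._index[record.record_id] = len(self._records)
        self._records.append(record)

    def get(self, record_id: str) -> CitationRecord:
        return self._records[self._index[record_id]]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CitationRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> CitationRecord:
        return self._records[i]

    def subset(self, record_ids: Sequence[str]) -> "Corpus":
        """A new corpus containing the named records, in the given order."""
        return Corpus([self.get(rid) for rid in record_ids], code_set=self.code_set)

    def attach_scores(self, scored) -> None:
        """Write integer scores from an iterable of ScoredRecord back onto records."""
        for s in scored:
            self.get(s.record_id).score = s.score

    def labelled(self) -> "Corpus":
        return Corpus([r for r in self._records if r.label is not None], code_set=self.code_set)

    def __repr__(self) -> str:
        n_lab = sum(1 for r in self._records if r.label is not None)
        return f"<Corpus: {len(self._records)} records, {n_lab} labelled>"
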