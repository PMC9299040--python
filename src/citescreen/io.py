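"""Reading, repairing, deduplicating and partitioning citation files.

Supported formats
-----------------
``ris``
    Tag-per-line interchange format (``TY  - JOUR`` ... ``ER  -``).
    Title from TI/T1, abstract from AB, notes from N1, year from PY/Y1,
    id from ID, source from DB.  The screening label travels in C1 as
    ``decision|code|stage`` and the relevance score in C2; unknown tags
    are preserved verbatim and written back on round-trip.
``tabular``
    Comma- or tab-delimited with a header row; recognised columns are
    record_id, title, abstract, notes, year, source, decision, code,
    stage, score.  Only ``title`` is required.
``jsonl``
    One JSON object per line with the same field names.

Records arriving from database exports are frequently defective: some
databases put the abstract in the notes field, and update searches
re-retrieve records already seen.  :func:`repair_abstract_field` and
:func:`deduplicate` implement the corresponding clean-up steps.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

from .records import CitationRecord, Corpus, ScreeningLabel

__all__ = [
    "read_records",
    "write_records",
    "repair_abstract_field",
    "deduplicate",
    "split_by_abstract",
    "DuplicateReport",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when a file yields no parseable records."""


TABULAR_COLUMNS = [
    "record_id", "title", "abstract", "notes", "year",
    "source", "decision", "code", "stage", "score",
]

# RIS tags with a dedicated CitationRecord field
_RIS_IN = {
    "ID": "record_id", "TI": "title", "T1": "title", "AB": "abstract",
    "N1": "notes", "PY": "year", "Y1": "year", "DB": "source",
}
_RIS_LINE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".ris":
        return "ris"
    if ext in (".csv", ".tsv", ".txt", ".tab"):
        return "tabular"
    if ext in (".jsonl", ".ndjson"):
        return "jsonl"
    raise FormatError(f"cannot infer format from extension {ext!r}; pass format explicitly")


def _fallback_id(position: int, title: str) -> str:
    digest = hashlib.sha1(title.encode("utf-8")).hexdigest()[:8]
    return f"rec-{position:05d}-{digest}"


def _parse_year(value) -> Optional[int]:
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    m = re.match(r"(\d{4})", s)
    return int(m.group(1)) if m else None


def _label_from_parts(decision, code, stage) -> Optional[ScreeningLabel]:
    decision = (decision or "").strip()
    if not decision:
        return None
    return ScreeningLabel(
        decision=decision,
        code=(code or "").strip() or None,
        stage=(stage or "").strip() or "title_abstract",
    )


def _record_from_fields(position: int, fields: dict, extra: Optional[dict] = None) -> CitationRecord:
    title = (fields.get("title") or "").strip()
    if not title:
        raise ValueError("missing title")
    rid = (fields.get("record_id") or "").strip() or _fallback_id(position, title)
    score = fields.get("score")
    if score is not None and str(score).strip() != "":
        score = int(float(score))
    else:
        score = None
    return CitationRecord(
        record_id=rid,
        title=title,
        abstract=(fields.get("abstract") or "").strip(),
        notes=(fields.get("notes") or "").strip(),
        year=_parse_year(fields.get("year")),
        source=(fields.get("source") or "").strip(),
        label=_label_from_parts(fields.get("decision"), fields.get("code"), fields.get("stage")),
        score=score,
        extra=dict(extra or {}),
    )


# ---------------------------------------------------------------------------
# RIS

def _iter_ris_entries(text: str):
    entry: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        m = _RIS_LINE.match(line)
        if m is None:
            # continuation line: append to previous tag's value
            if entry:
                tag, val = entry[-1]
                entry[-1] = (tag, val + " " + line.strip())
            continue
        tag, value = m.group(1), m.group(2)
        if tag == "ER":
            if entry:
                yield entry
            entry = []
        else:
            entry.append((tag, value))
    if entry:
        yield entry


def _read_ris(text: str) -> list[CitationRecord]:
    records = []
    skipped = 0
    for pos, entry in enumerate(_iter_ris_entries(text)):
        fields: dict = {}
        extra: dict = {}
        for tag, value in entry:
            if tag in _RIS_IN:
                name = _RIS_IN[tag]
                if name in fields and fields[name]:
                    fields[name] += " " + value
                else:
                    fields[name] = value
            elif tag == "C1":
                parts = (value.split("|") + ["", "", ""])[:3]
                fields["decision"], fields["code"], fields["stage"] = parts
            elif tag == "C2":
                fields["score"] = value
            else:
                extra.setdefault(tag, []).append(value)
        try:
            records.append(_record_from_fields(pos, fields, extra))
        except ValueError as exc:
            skipped += 1
            warnings.warn(f"skipping RIS entry {pos}: {exc}")
    if skipped:
        warnings.warn(f"{skipped} malformed RIS entr{'y' if skipped == 1 else 'ies'} skipped")
    return records


def _write_ris(corpus: Corpus, path: Path) -> int:
    lines = []
    for rec in corpus:
        lines.append(f"TY  - {rec.extra.get('TY', ['JOUR'])[0]}")
        lines.append(f"ID  - {rec.record_id}")
        lines.append(f"TI  - {rec.title}")
        if rec.abstract:
            lines.append(f"AB  - {rec.abstract}")
        if rec.notes:
            lines.append(f"N1  - {rec.notes}")
        if rec.year is not None:
            lines.append(f"PY  - {rec.year}")
        if rec.source:
            lines.append(f"DB  - {rec.source}")
        if rec.label is not None:
            lab = rec.label
            lines.append(f"C1  - {lab.decision}|{lab.code or ''}|{lab.stage}")
        if rec.score is not None:
            lines.append(f"C2  - {rec.score}")
        for tag, values in rec.extra.items():
            if tag == "TY":
                continue
            for v in values:
                lines.append(f"{tag}  - {v}")
        lines.append("ER  - ")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return len(corpus)


# ---------------------------------------------------------------------------
# tabular / jsonl

def _read_tabular(path: Path) -> list[CitationRecord]:
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        return []
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    records = []
    skipped = 0
    for pos, row in enumerate(reader):
        try:
            records.append(_record_from_fields(pos, {k: v for k, v in row.items() if k}))
        except ValueError as exc:
            skipped += 1
            warnings.warn(f"skipping row {pos}: {exc}")
    if skipped:
        warnings.warn(f"{skipped} malformed row{'' if skipped == 1 else 's'} skipped")
    return records


def _write_tabular(corpus: Corpus, path: Path) -> int:
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(TABULAR_COLUMNS)
        for rec in corpus:
            lab = rec.label
            writer.writerow([
                rec.record_id, rec.title, rec.abstract, rec.notes,
                rec.year if rec.year is not None else "",
                rec.source,
                lab.decision if lab else "",
                (lab.code or "") if lab else "",
                lab.stage if lab else "",
                rec.score if rec.score is not None else "",
            ])
    return len(corpus)


def _read_jsonl(path: Path) -> list[CitationRecord]:
    records = []
    skipped = 0
    for pos, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            records.append(_record_from_fields(pos, obj, obj.get("extra")))
        except (ValueError, AttributeError) as exc:
            skipped += 1
            warnings.warn(f"skipping line {pos}: {exc}")
    if skipped:
        warnings.warn(f"{skipped} malformed line{'' if skipped == 1 else 's'} skipped")
    return records


def _write_jsonl(corpus: Corpus, path: Path) -> int:
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            obj = {
                "record_id": rec.record_id, "title": rec.title,
                "abstract": rec.abstract, "notes": rec.notes,
                "year": rec.year, "source": rec.source,
            }
            if rec.label is not None:
                obj["decision"] = rec.label.decision
                obj["code"] = rec.label.code
                obj["stage"] = rec.label.stage
            if rec.score is not None:
                obj["score"] = rec.score
            if rec.extra:
                obj["extra"] = rec.extra
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    return len(corpus)


# ---------------------------------------------------------------------------
# public API

def read_records(path, format: Optional[str] = None, code_set: Optional[set] = None) -> Corpus:
    """Read a citation file into a :class:`Corpus`.

    Malformed entries are skipped with a warning; a file from which no
    record parses raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _detect_format(path)
    if fmt == "ris":
        records = _read_ris(path.read_text(encoding="utf-8"))
    elif fmt == "tabular":
        records = _read_tabular(path)
    elif fmt == "jsonl":
        records = _read_jsonl(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if not records:
        raise FormatError(f"no records parsed from {path}")
    return Corpus(records, code_set=code_set)


def write_records(corpus: Corpus, path, format: Optional[str] = None) -> int:
    """Write a corpus to ``path``; returns the number of records written.

    Round-trips losslessly with :func:`read_records` for every declared
    field, including labels and attached scores.
    """
    if len(corpus) == 0:
        raise ValueError("nothing to write: corpus is empty")
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "ris":
        return _write_ris(corpus, path)
    if fmt == "tabular":
        return _write_tabular(corpus, path)
    if fmt == "jsonl":
        return _write_jsonl(corpus, path)
    raise FormatError(f"unknown format {fmt!r}")


def repair_abstract_field(corpus: Corpus, min_length: int = 200) -> Tuple[Corpus, int]:
    """Move misplaced abstracts out of the notes field.

    Some database exports put the abstract in the notes field.  For
    every record with an empty abstract whose notes run to at least
    ``min_length`` characters, the notes text is moved (not copied)
    into the abstract.  The length floor keeps short annotations like
    "see attached file" where they are.
    """
    repaired = []
    count = 0
    for rec in corpus:
        if not rec.has_abstract and len(rec.notes.strip()) >= min_length:
            repaired.append(rec.copy(abstract=rec.notes.strip(), notes=""))
            count += 1
        else:
            repaired.append(rec)
    return Corpus(repaired, code_set=corpus.code_set), count


_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def dedup_key(title: str) -> str:
    """Title normalisation used for duplicate detection: case-fold,
    strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", title.casefold())).strip()


@dataclass
class DuplicateReport:
    """Groups of records merged by :func:`deduplicate`."""
    groups: list = field(default_factory=list)  # (kept_id, [merged_ids])

    @property
    def n_removed(self) -> int:
        return sum(len(m) for _, m in self.groups)


def deduplicate(corpus: Corpus) -> Tuple[Corpus, DuplicateReport]:
    """Merge records that share a normalised title (and a compatible year).

    Two records merge when their normalised titles match and their
    years do not conflict (a missing year matches any year).  Within a
    merged group the kept representative is chosen by preference —
    labelled over unlabelled, abstract-bearing over abstract-less,
    then first-seen — so deduplication never discards screening signal.
    Idempotent; never increases the record count.
    """
    # buckets: title key -> list of [year, member positions]
    buckets: dict[str, list[list]] = {}
    order: list[list] = []  # groups in first-seen order
    for pos, rec in enumerate(corpus):
        key = dedup_key(rec.title)
        placed = False
        for bucket in buckets.setdefault(key, []):
            byear = bucket[0]
            if rec.year is None or byear is None or rec.year == byear:
                if byear is None:
                    bucket[0] = rec.year
                bucket[1].append(pos)
                placed = True
                break
        if not placed:
            group = [rec.year, [pos]]
            buckets[key].append(group)
            order.append(group)

    kept_records = []
    report = DuplicateReport()
    for _, positions in order:
        members = [corpus[p] for p in positions]
        best = min(
            range(len(members)),
            key=lambda i: (members[i].label is None, not members[i].has_abstract, i),
        )
        kept = members[best]
        kept_records.append(kept)
        if len(members) > 1:
            merged = [m.record_id for i, m in enumerate(members) if i != best]
            report.groups.append((kept.record_id, merged))
    return Corpus(kept_records, code_set=corpus.code_set), report


def split_by_abstract(corpus: Corpus) -> Tuple[Corpus, Corpus]:
    """Partition into (records with abstracts, title-only records).

    Title-only records cannot be ranked meaningfully on abstract text
    and are screened manually in full; the two parts are disjoint and
    their sizes sum to the input size.
    """
    with_abs = [r for r in corpus if r.has_abstract]
    title_only = [r for r in corpus if not r.has_abstract]
    return (
        Corpus(with_abs, code_set=corpus.code_set),
        Corpus(title_only, code_set=corpus.code_set),
    )
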