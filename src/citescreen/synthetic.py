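"""Seeded synthetic citation corpora with screening-study structure.

Real screening corpora for broad public-health topics have a very low
include prevalence (well under 5%), diffuse vocabulary that both
classes share, variable abstract lengths, a slice of title-only
records, near-duplicate re-retrievals, and export defects such as
abstracts landing in the notes field.  :func:`generate_corpus`
emulates exactly these properties from a compact spec, so every other
module can be exercised end-to-end without any external data.

Class structure is a two-pool mixture controlled by one knob,
``separability``: each token comes from the record's own class-tilted
pool with probability ``separability`` and otherwise from the shared
vocabulary (background plus both tilted pools).  At separability 1 the
classes share only the background; at 0 they are statistically
identical.  Tokens are synthetic word-like strings with Zipf-weighted
frequencies, so no linguistic resource is needed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .records import CitationRecord, Corpus, ScreeningLabel

__all__ = ["CorpusSpec", "GeneratedCorpus", "generate_corpus", "inject_artifacts"]

CODE_SET = {"Include1", "Ex1"}

_CONSONANTS = list("bcdfghjklmnprstvwz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class CorpusSpec:
    """Generation parameters; the defaults mirror a low-prevalence
    update-search corpus (prevalence 2%, a quarter of records with the
    abstract misplaced into notes, ~8% title-only, a sprinkle of
    near-duplicates)."""

    n_records: int = 5000
    include_prevalence: float = 0.02
    vocab_background: int = 2000
    vocab_include: int = 150
    vocab_exclude: int = 300
    separability: float = 0.9
    abstract_length: Tuple[int, int] = (120, 40)   # mean, sd in tokens
    title_only_fraction: float = 0.077
    duplicate_fraction: float = 0.0025
    notes_misplacement_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("include_prevalence", "separability", "title_only_fraction",
                     "duplicate_fraction", "notes_misplacement_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")

    @property
    def n_includes(self) -> int:
        return int(round(self.n_records * self.include_prevalence))


@dataclass
class GeneratedCorpus:
    """A generated corpus plus its manifest (spec + seed + injected
    defects); regenerating from the manifest is bit-identical."""

    corpus: Corpus
    manifest: dict

    @property
    def ground_truth(self) -> Dict[str, str]:
        return {r.record_id: r.label.decision for r in self.corpus if r.label is not None}


def _make_words(rng: np.random.Generator, n: int, taken: set) -> List[str]:
    words = []
    while len(words) < n:
        k = int(rng.integers(2, 5))
        w = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))] +
            _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(k)
        )
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def _zipf_cdf(n: int, s: float = 1.1) -> np.ndarray:
    p = 1.0 / np.arange(1, n + 1) ** s
    return np.cumsum(p / p.sum())


class _Sampler:
    """Zipf-weighted word sampler over a fixed pool."""

    def __init__(self, words: List[str], probs: Optional[np.ndarray] = None):
        self.words = np.array(words, dtype=object)
        if probs is None:
            self.cdf = _zipf_cdf(len(words))
        else:
            self.cdf = np.cumsum(probs / probs.sum())

    def draw(self, rng: np.random.Generator, k: int) -> np.ndarray:
        idx = np.searchsorted(self.cdf, rng.random(k), side="right")
        return self.words[idx]


def _union_sampler(pools: List[List[str]]) -> _Sampler:
    """Shared-vocabulary sampler: a draw picks a pool with probability
    proportional to its size, then a word Zipf-weighted within that
    pool — so class-tilted terms keep a realistic share of the common
    token stream."""
    total = sum(len(p) for p in pools)
    words: List[str] = []
    probs: List[np.ndarray] = []
    for pool in pools:
        zipf = np.diff(_zipf_cdf(len(pool)), prepend=0.0)
        words.extend(pool)
        probs.append(zipf * (len(pool) / total))
    return _Sampler(words, np.concatenate(probs))


def _draw_clean(spec: CorpusSpec) -> GeneratedCorpus:
    rng = np.random.default_rng(spec.seed)
    n_inc = spec.n_includes
    if n_inc == 0:
        raise ValueError(
            f"include_prevalence {spec.include_prevalence} yields zero includes "
            f"at n_records {spec.n_records}; use a larger corpus")
    taken: set = set()
    background = _make_words(rng, spec.vocab_background, taken)
    inc_pool = _make_words(rng, spec.vocab_include, taken)
    exc_pool = _make_words(rng, spec.vocab_exclude, taken)
    shared = _union_sampler([background, inc_pool, exc_pool])
    samplers = {"include": _Sampler(inc_pool), "exclude": _Sampler(exc_pool)}

    include_idx = set(rng.choice(spec.n_records, size=n_inc, replace=False).tolist())
    mean_len, sd_len = spec.abstract_length
    records = []
    for i in range(spec.n_records):
        decision = "include" if i in include_idx else "exclude"
        own = samplers[decision]

        def mix(k: int) -> str:
            from_own = rng.random(k) < spec.separability
            words = shared.draw(rng, k)
            n_own = int(from_own.sum())
            if n_own:
                words[from_own] = own.draw(rng, n_own)
            return " ".join(words)

        title_len = int(rng.integers(5, 16))
        # floor of 40 tokens: real abstracts are rarely shorter, and it
        # keeps misplaced abstracts long enough to be detectably repaired
        abs_len = max(40, int(round(rng.normal(mean_len, sd_len))))
        records.append(CitationRecord(
            record_id=f"SYN-{i:05d}",
            title=mix(title_len).capitalize(),
            abstract=mix(abs_len).capitalize() + ".",
            year=int(rng.integers(2000, 2021)),
            source="synthetic",
            label=ScreeningLabel(decision, "Include1" if decision == "include" else "Ex1"),
        ))
    corpus = Corpus(records, code_set=CODE_SET)
    manifest = {
        "spec": asdict(spec),
        "artifacts": {"title_only_ids": [], "notes_moved_ids": [], "duplicate_pairs": []},
    }
    return GeneratedCorpus(corpus=corpus, manifest=manifest)


def inject_artifacts(generated: GeneratedCorpus, spec: Optional[CorpusSpec] = None) -> GeneratedCorpus:
    """Impose the spec's data defects on a clean corpus.

    Disjoint record subsets are (a) stripped of their abstract
    (title-only records), (b) given their abstract in the notes field
    instead, and (c) re-emitted as unlabelled near-duplicates whose
    titles differ only in case, punctuation or whitespace.  The
    manifest records every altered id, so repair/dedup closure is
    exactly checkable.  With all fractions zero the corpus is returned
    unchanged.
    """
    if spec is None:
        spec = CorpusSpec(**generated.manifest["spec"])
    corpus = generated.corpus
    n = len(corpus)
    rng = np.random.default_rng([spec.seed, 7])
    n_strip = int(round(n * spec.title_only_fraction))
    n_notes = int(round(n * spec.notes_misplacement_fraction))
    n_dup = int(round(n * spec.duplicate_fraction))
    if n_strip + n_notes > n:
        raise ValueError("title_only_fraction + notes_misplacement_fraction exceed the corpus")
    perm = rng.permutation(n)
    strip_idx = set(perm[:n_strip].tolist())
    notes_idx = set(perm[n_strip:n_strip + n_notes].tolist())
    # duplicates come from defect-free records, so repair/dedup closures
    # over the manifest's id lists stay exact
    pristine = np.array([i for i in range(n)
                         if i not in strip_idx and i not in notes_idx], dtype=int)
    if n_dup > len(pristine):
        raise ValueError("duplicate_fraction too high for the remaining pristine records")
    dup_idx = rng.choice(pristine, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)

    records: List[CitationRecord] = []
    title_only_ids, notes_moved_ids = [], []
    for i, rec in enumerate(corpus):
        if i in strip_idx:
            rec = rec.copy(abstract="")
            title_only_ids.append(rec.record_id)
        elif i in notes_idx:
            rec = rec.copy(notes=rec.abstract, abstract="")
            notes_moved_ids.append(rec.record_id)
        records.append(rec)

    duplicate_pairs = []
    for i in sorted(dup_idx.tolist()):
        orig = records[i]
        style = int(rng.integers(4))
        t = orig.title
        title = [t.upper(), t.lower(), t + ".", t.replace(" ", "  ", 1)][style]
        duplicate_pairs.append((orig.record_id, orig.record_id + "-dup"))
        records.append(CitationRecord(
            record_id=orig.record_id + "-dup",
            title=title, abstract=orig.abstract, notes=orig.notes,
            year=orig.year, source="synthetic-dup", label=None,
        ))

    manifest = dict(generated.manifest)
    manifest["artifacts"] = {
        "title_only_ids": title_only_ids,
        "notes_moved_ids": notes_moved_ids,
        "duplicate_pairs": duplicate_pairs,
    }
    return GeneratedCorpus(corpus=Corpus(records, code_set=corpus.code_set), manifest=manifest)


def generate_corpus(spec: CorpusSpec, artifacts: bool = True) -> GeneratedCorpus:
    """Generate a labelled corpus under ``spec``.

    The clean statistical draw and the defect injection are separable:
    pass ``artifacts=False`` for a pristine corpus, or call
    :func:`inject_artifacts` yourself.  Everything is deterministic in
    ``spec.seed``.
    """
    clean = _draw_clean(spec)
    if not artifacts:
        return clean
    return inject_artifacts(clean, spec)
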