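"""The custom-built relevance classifier.

The model is deliberately simple and transparent: a bag-of-words over
word n-grams (unigrams through trigrams by default), stop-word filtered
with the PubMed stop-word list, **without** stemming, fed to a linear
logistic-regression model fitted by stochastic gradient descent.
Trigrams let the model treat "randomized controlled trial" as a single
signal, and the absence of stemming keeps "trial" and "trials"
distinct — which separates reports of a single trial from reviews that
discuss many.

The fitted model scores any record with an integer **relevance score**
in [0, 99]: the predicted probability of inclusion multiplied by 100
and floored (99 = most relevant).  Scores, not probabilities, are what
screeners see, and every downstream threshold and stopping rule is
expressed on this scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit
from sklearn.linear_model import SGDClassifier

from .records import CitationRecord, Corpus

__all__ = [
    "load_pubmed_stopwords",
    "FeatureConfig",
    "TrainingRule",
    "ScoredRecord",
    "RelevanceModel",
    "tokenize",
    "ngrams",
    "fit_vocabulary",
    "featurize",
    "featurize_corpus",
    "train_classifier",
    "relevance_score",
    "rank_records",
    "probability_to_score",
]

import re

_TOKEN = re.compile(r"[0-9A-Za-z]+")


def load_pubmed_stopwords() -> frozenset:
    """The bundled PubMed stop-word list (lower-case)."""
    text = resources.files("citescreen.data").joinpath("pubmed_stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class FeatureConfig:
    """Text-featurisation settings.

    Stop words are removed *before* n-grams are formed, so "risk of
    bias" contributes the bigram "risk bias".  ``fields_used`` selects
    which record fields feed the featuriser (title and abstract,
    concatenated, by default).
    """

    ngram_min: int = 1
    ngram_max: int = 3
    stemming: bool = False
    stoplist: frozenset = field(default_factory=load_pubmed_stopwords)
    lowercase: bool = True
    fields_used: tuple = ("title", "abstract")
    min_df: int = 1

    def __post_init__(self):
        if not (1 <= self.ngram_min <= self.ngram_max <= 5):
            raise ValueError("need 1 <= ngram_min <= ngram_max <= 5")
        if self.stemming:
            raise NotImplementedError("stemming is deliberately unsupported")
        if not self.fields_used or not set(self.fields_used) <= {"title", "abstract"}:
            raise ValueError("fields_used must be a non-empty subset of {'title','abstract'}")

    def record_text(self, record: CitationRecord) -> str:
        return " ".join(getattr(record, f) for f in self.fields_used)


@dataclass(frozen=True)
class TrainingRule:
    """Which label codes count as the positive (include) class.

    A label matches if its reason code — or, when it has no code, its
    bare decision ("include"/"exclude") — is in ``include_codes``.
    Everything else labelled is negative.  Selecting different code
    subsets from a hierarchical exclusion code set yields differently
    strict classifiers from the same screening data.
    """

    include_codes: frozenset

    def __init__(self, include_codes: Iterable[str] = ("include",)):
        codes = frozenset(include_codes)
        if not codes:
            raise ValueError("include_codes must be non-empty")
        object.__setattr__(self, "include_codes", codes)

    def is_positive(self, record: CitationRecord) -> bool:
        if record.label is None:
            raise ValueError(f"record {record.record_id!r} is unlabelled")
        return record.label.effective_code in self.include_codes


@dataclass(frozen=True)
class ScoredRecord:
    """A record's relevance output: integer score 0-99 plus the raw probability."""

    record_id: str
    score: int
    probability: float
    empty_text: bool = False


def probability_to_score(probability: float) -> int:
    """floor(p x 100), capped at 99 so that p = 1.0 stays on the 0-99 scale."""
    return min(int(math.floor(probability * 100.0)), 99)


def tokenize(text: str, config: FeatureConfig) -> list:
    """Split on non-alphanumeric boundaries, case-fold, drop stop words.

    No stemming: inflectional variants stay distinct tokens.
    """
    if not text:
        return []
    tokens = _TOKEN.findall(text)
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    stoplist = config.stoplist
    return [t for t in tokens if t.lower() not in stoplist]


def ngrams(tokens: Sequence[str], nmin: int, nmax: int) -> list:
    """Contiguous space-joined n-grams for n in [nmin, nmax], in order."""
    out = []
    L = len(tokens)
    for n in range(nmin, nmax + 1):
        for i in range(L - n + 1):
            out.append(" ".join(tokens[i:i + n]))
    return out


def _record_ngrams(record: CitationRecord, config: FeatureConfig) -> list:
    return ngrams(tokenize(config.record_text(record), config), config.ngram_min, config.ngram_max)


def fit_vocabulary(corpus: Corpus, config: FeatureConfig) -> dict:
    """Map every n-gram with document frequency >= min_df to a column index.

    Ordering is lexicographic, so refitting on the same corpus gives an
    identical vocabulary.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    df: dict[str, int] = {}
    for rec in corpus:
        for g in set(_record_ngrams(rec, config)):
            df[g] = df.get(g, 0) + 1
    kept = sorted(g for g, d in df.items() if d >= config.min_df)
    if not kept:
        raise ValueError("no features: corpus has no usable text")
    return {g: i for i, g in enumerate(kept)}


def featurize(record: CitationRecord, vocabulary: dict, config: FeatureConfig) -> sparse.csr_matrix:
    """Sparse 1 x V raw-count vector; out-of-vocabulary n-grams are ignored."""
    return featurize_corpus([record], vocabulary, config)


def featurize_corpus(records: Iterable[CitationRecord], vocabulary: dict,
                     config: FeatureConfig) -> sparse.csr_matrix:
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    get = vocabulary.get
    for rec in records:
        counts: dict[int, int] = {}
        for g in _record_ngrams(rec, config):
            j = get(g)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64),
         np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int32)),
        shape=(len(indptr) - 1, len(vocabulary)),
    )


# SGD settings recorded in every serialised model
_SGD_PARAMS = dict(loss="log_loss", alpha=1e-4, max_iter=1000, tol=1e-3)


@dataclass
class RelevanceModel:
    """A fitted vocabulary + linear weights producing scores 0-99."""

    vocabulary: dict
    weights: np.ndarray
    intercept: float
    feature_config: FeatureConfig
    training_rule: TrainingRule
    seed: int
    training_summary: dict = field(default_factory=dict)

    def decision_value(self, X: sparse.csr_matrix) -> np.ndarray:
        return np.asarray(X @ self.weights).ravel() + self.intercept

    def predict_probability(self, records: Iterable[CitationRecord]) -> np.ndarray:
        X = featurize_corpus(records, self.vocabulary, self.feature_config)
        return expit(self.decision_value(X))

    # -- serialisation: a single self-describing JSON archive ---------------
    def save(self, path) -> None:
        payload = {
            "format": "citescreen-relevance-model/1",
            "vocabulary": list(self.vocabulary.keys()),
            "weights": [float(w).hex() for w in self.weights],
            "intercept": float(self.intercept).hex(),
            "feature_config": {
                "ngram_min": self.feature_config.ngram_min,
                "ngram_max": self.feature_config.ngram_max,
                "stemming": self.feature_config.stemming,
                "stoplist": sorted(self.feature_config.stoplist),
                "lowercase": self.feature_config.lowercase,
                "fields_used": list(self.feature_config.fields_used),
                "min_df": self.feature_config.min_df,
            },
            "training_rule": sorted(self.training_rule.include_codes),
            "seed": self.seed,
            "training_summary": self.training_summary,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RelevanceModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "citescreen-relevance-model/1":
            raise ValueError(f"{path}: not a citescreen model file")
        fc = payload["feature_config"]
        config = FeatureConfig(
            ngram_min=fc["ngram_min"], ngram_max=fc["ngram_max"],
            stemming=fc["stemming"], stoplist=frozenset(fc["stoplist"]),
            lowercase=fc["lowercase"], fields_used=tuple(fc["fields_used"]),
            min_df=fc["min_df"],
        )
        return cls(
            vocabulary={g: i for i, g in enumerate(payload["vocabulary"])},
            weights=np.array([float.fromhex(w) for w in payload["weights"]]),
            intercept=float.fromhex(payload["intercept"]),
            feature_config=config,
            training_rule=TrainingRule(payload["training_rule"]),
            seed=payload["seed"],
            training_summary=payload["training_summary"],
        )


def train_classifier(corpus: Corpus, rule: TrainingRule = TrainingRule(),
                     config: FeatureConfig = FeatureConfig(), seed: int = 0,
                     class_weight: Optional[str] = None) -> RelevanceModel:
    """Fit the SGD logistic-regression relevance model.

    Records whose configured fields carry no text are dropped from
    training with a warning (they contribute no features).  Training is
    deterministic for a fixed seed: the same corpus and seed reproduce
    bit-identical weights.
    """
    usable = []
    dropped = 0
    for rec in corpus:
        if rec.label is None:
            continue
        if tokenize(config.record_text(rec), config):
            usable.append(rec)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} labelled record(s) with no text in "
                      f"{config.fields_used} excluded from training")
    y = np.array([1 if rule.is_positive(r) else 0 for r in usable], dtype=np.int64)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        missing = "positive (include)" if n_pos == 0 else "negative (exclude)"
        raise ValueError(f"training set has no {missing} records under rule "
                         f"{sorted(rule.include_codes)}")
    vocab_corpus = Corpus(usable, code_set=corpus.code_set)
    vocabulary = fit_vocabulary(vocab_corpus, config)
    X = featurize_corpus(usable, vocabulary, config)
    clf = SGDClassifier(random_state=seed, class_weight=class_weight, **_SGD_PARAMS)
    clf.fit(X, y)
    return RelevanceModel(
        vocabulary=vocabulary,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_config=config,
        training_rule=rule,
        seed=seed,
        training_summary={
            "n_positive": n_pos, "n_negative": n_neg,
            "n_dropped_no_text": dropped,
            "n_features": len(vocabulary),
            "sgd_params": dict(_SGD_PARAMS, class_weight=class_weight),
        },
    )


def relevance_score(model: RelevanceModel, record: CitationRecord) -> ScoredRecord:
    """Score one record: integer floor(p x 100) in [0, 99].

    A record with no text in the configured fields is scored from the
    intercept alone and flagged ``empty_text``.
    """
    p = float(model.predict_probability([record])[0])
    return ScoredRecord(
        record_id=record.record_id,
        score=probability_to_score(p),
        probability=p,
        empty_text=not tokenize(model.feature_config.record_text(record),
                                model.feature_config),
    )


def rank_records(model: RelevanceModel, corpus: Corpus) -> list:
    """Score every record and sort most-relevant first.

    Ties in probability break by ascending record_id so rankings are
    reproducible regardless of input order.
    """
    probs = model.predict_probability(corpus)
    scored = [
        ScoredRecord(
            record_id=rec.record_id,
            score=probability_to_score(float(p)),
            probability=float(p),
            empty_text=not tokenize(model.feature_config.record_text(rec),
                                    model.feature_config),
        )
        for rec, p in zip(corpus, probs)
    ]
    return sorted(scored, key=lambda s: (-s.probability, s.record_id))
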