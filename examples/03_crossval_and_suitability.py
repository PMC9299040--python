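"""Classifier selection: cross-validated recall and the score histogram.

Before trusting a classifier on an update search, check (1) its
stratified k-fold recall at the intended threshold, and (2) whether
its score distribution has the right shape — most records at very low
relevance, decaying markedly across higher scores.
"""

import citescreen as cs

gen = cs.generate_corpus(cs.CorpusSpec(n_records=2000, include_prevalence=0.03,
                                       separability=0.9, seed=11), artifacts=False)

report = cs.stratified_kfold_recall(gen.corpus, cs.TrainingRule({"Include1"}),
                                    k=5, threshold=10, seed=11)
print(report.summary())

ids = [r.record_id for r in gen.corpus]
model = cs.train_classifier(gen.corpus.subset(ids[:1000]),
                            cs.TrainingRule({"Include1"}), seed=11)
scored = cs.rank_records(model, gen.corpus.subset(ids[1000:]))
dist = cs.score_distribution(scored)
print("\nscore distribution of the held-out half:")
for band, count in zip(dist.labels, dist.counts):
    print(f"  {band:>6} {'#' * max(1, count // 25) if count else '':<45} {count}")
verdict, rationale = cs.suitability_check(dist)
print(rationale)

table = cs.per_band_precision(scored, {r.record_id: r.label.decision
                                       for r in gen.corpus.subset(ids[1000:])})
print("\nprecision by score band (empty bands omitted):")
print(table.dropna().to_string(index=False))
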