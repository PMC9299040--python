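import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from citescreen import CitationRecord, Corpus, ScreeningLabel


def make_corpus(rows, code_set=None):
    """rows: (record_id, title, abstract, decision-or-None) tuples."""
    records = []
    for rid, title, abstract, decision in rows:
        label = ScreeningLabel(decision) if decision else None
        records.append(CitationRecord(record_id=rid, title=title,
                                      abstract=abstract, label=label))
    return Corpus(records, code_set=code_set)


@pytest.fixture
def zebra_corpus():
    """Linearly separable toy: every positive mentions 'zebra', no negative does."""
    rows = []
    for i in range(12):
        rows.append((f"pos-{i:02d}", f"Zebra stripes study {i}",
                     f"An intervention on zebra populations cohort {i} with zebra outcomes.",
                     "include"))
    for i in range(28):
        rows.append((f"neg-{i:02d}", f"Giraffe neck report {i}",
                     f"Observations of giraffe herds in region {i} with browse height.",
                     "exclude"))
    return make_corpus(rows)
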