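import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_genome():
    """A small labeled synthetic genome: sequences, truth table and records."""
    from gc3kog import records_from_cds
    from gc3kog.synthetic import generate_genome, human_kog_reference_spec

    spec = human_kog_reference_spec(seed=1234, scale=0.01, n_codons=60)
    seqs, truth = generate_genome(spec)
    records = records_from_cds(seqs)
    return seqs, truth, records


def annotate_with_truth(records, truth):
    """Attach the truth table's class labels directly (no filtering)."""
    from gc3kog.composition import GeneRecord
    from gc3kog.kog_catalog import category_of

    by_id = dict(zip(truth["id"], truth["kog_class"]))
    out = []
    for r in records:
        letter = by_id[r.id]
        cat = category_of(letter)
        out.append(
            GeneRecord(r.id, r.species, r.gc, r.gc3, r.n_codons,
                       kog_class=letter,
                       category=cat if cat != "POORLY_CHARACTERIZED" else None)
        )
    return out
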