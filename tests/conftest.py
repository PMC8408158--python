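import numpy as np
import pandas as pd
import pytest

from pblgenomics.synthetic import CohortConfig, generate_cohort, generate_screen_counts


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (study-condition defaults), fixed seed."""
    return generate_cohort(CohortConfig(seed=20240917))


@pytest.fixture(scope="session")
def screen_matrix():
    matrix, depleted = generate_screen_counts(CohortConfig(seed=20240917))
    return matrix, depleted


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_calls(records, **defaults):
    """Build a variant-call DataFrame from terse per-call dicts."""
    base = dict(
        sample_id="S1", chrom="1p", pos=100, ref="A", alt="T", gene="",
        vaf=0.4, depth=80, alt_f1r2=16, alt_f2r1=16,
        population_af=0.0, matched_normal_support=0,
    )
    base.update(defaults)
    rows = []
    for i, rec in enumerate(records):
        row = dict(base)
        row["pos"] = 100 + i  # unique keys unless overridden
        row.update(rec)
        rows.append(row)
    return pd.DataFrame(rows)
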