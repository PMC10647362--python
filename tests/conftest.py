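"""Shared fixtures: a worked mini-cohort and a small trained ensemble."""

import pytest

from ffrisk.cohort import load_schema
from ffrisk.ensemble import BaseModelSpec, FilterPolicy, build_ensemble
from ffrisk.preprocessing import preprocess
from ffrisk.synthetic import GeneratorConfig, generate_cohort, generate_worked_fixture


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def worked_cohort():
    """Deterministic 10-record cohort exercising every translation rule."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def small_clean_cohort():
    """A fully preprocessed 60-patient cohort with a strong class signal."""
    raw = generate_cohort(
        GeneratorConfig(
            n_patients=60,
            labeled_fraction=1.0,
            missing_rate=0.05,
            text_rate=0.5,
            signal_strength=2.0,
            seed=11,
        )
    )
    clean, _ = preprocess(raw)
    return clean


@pytest.fixture(scope="session")
def small_ensemble(small_clean_cohort):
    """A quick 6-group ensemble over held-out sizes 1 and 2."""
    return build_ensemble(
        small_clean_cohort,
        n_groups=6,
        heldout_sizes=(1, 2),
        spec=BaseModelSpec(n_trees=10),
        policy=FilterPolicy(),
        seed=5,
    )
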