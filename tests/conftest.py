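import numpy as np
import pytest

from tp53sig import CohortRecord, default_panel, table1_fixture


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table1():
    """(labeled scores, published calls) of the 34-sample development cohort."""
    return table1_fixture()


def make_record(sample_id="S1", **overrides) -> CohortRecord:
    """A valid cohort record with sensible defaults, overridable per test."""
    base = dict(
        sample_id=sample_id, age=58.0, p_stage="I", p_ln="negative",
        tumor_size_cm=1.5, grade=2, er="positive", pgr="positive",
        her2="negative", ki67_pct=8.0, adj_chemo="no", adj_endocrine="yes",
        tp53_status="wild", rfs_time=5.0, rfs_event=0, os_time=5.0,
        os_event=0, bcss_time=5.0, bcss_event=0,
    )
    base.update(overrides)
    return CohortRecord(**base)


def random_survival_cohort(rng, n, two_group=True):
    """Small random right-censored cohort for oracle cross-checks."""
    records = []
    for i in range(n):
        t = float(rng.exponential(3.0))
        c = float(rng.uniform(0, 6.0))
        status = "mutant" if (two_group and rng.random() < 0.5) else "wild"
        records.append(make_record(
            sample_id=f"R{i}", tp53_status=status,
            grade=int(rng.integers(1, 4)),
            rfs_time=min(t, c), rfs_event=int(t <= c),
            os_time=min(t, c) + 0.5, os_event=0,
        ))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
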