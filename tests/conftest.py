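import numpy as np
import pandas as pd
import pytest

from csfpanels import CohortTable


def make_cohort(values: np.ndarray, cdr=None, age=None, female=None,
                ldl: float = 0.1, below=None) -> CohortTable:
    """Small cohort builder for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = [f"S{i:03d}" for i in range(n)]
    analytes = [f"A{j}" for j in range(p)]
    if cdr is None:
        cdr = np.r_[np.zeros(n // 2), np.full(n - n // 2, 0.5)]
    if age is None:
        age = np.linspace(65, 85, n)
    if female is None:
        female = np.arange(n) % 2
    demo = pd.DataFrame(
        {
            "age_at_lp": np.asarray(age, float),
            "gender": np.where(np.asarray(female) == 1, "female", "male"),
            "apoe": ["e3e4" if i % 3 == 0 else "e3e3" for i in range(n)],
            "cdr": np.asarray(cdr, float),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    meta = pd.DataFrame(
        {"unit": ["pg/mL"] * p, "ldl": np.full(p, float(ldl))},
        index=pd.Index(analytes, name="analyte"),
    )
    if below is None:
        below = np.zeros((n, p), dtype=bool)
    return CohortTable(
        demographics=demo,
        values=pd.DataFrame(values, index=demo.index, columns=analytes),
        below_ldl=pd.DataFrame(np.asarray(below, bool), index=demo.index,
                               columns=analytes),
        analyte_meta=meta,
    )


@pytest.fixture
def toy_cohort():
    rng = np.random.default_rng(42)
    return make_cohort(100 + 10 * rng.standard_normal((30, 4)))
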