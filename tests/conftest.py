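import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rscore import QuantDataset, SurvivalCohort

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def make_dataset(
    symbols,
    lengths,
    matrix,
    conditions,
    dataset_id="toy",
    accessions=None,
) -> QuantDataset:
    """Assemble a QuantDataset from plain lists."""
    symbols = list(symbols)
    accessions = accessions or [f"ACC_{s}" for s in symbols]
    sample_ids = [f"S{i}" for i in range(len(conditions))]
    proteins = pd.DataFrame(
        {"accession": accessions, "length_aa": np.asarray(lengths, dtype=np.int64)},
        index=pd.Index(symbols, name="symbol"),
    )
    abundance = pd.DataFrame(np.asarray(matrix, dtype=float),
                             index=proteins.index, columns=sample_ids)
    return QuantDataset(
        dataset_id=dataset_id,
        proteins=proteins,
        abundance=abundance,
        conditions=pd.Series(list(conditions), index=sample_ids),
    )


def make_cohort(times, events, expression: dict, cohort_id="toy_cohort") -> SurvivalCohort:
    """Assemble a SurvivalCohort from plain lists."""
    n = len(times)
    data = pd.DataFrame(
        {"time": np.asarray(times, dtype=float),
         "event": np.asarray(events, dtype=np.int64),
         **{k: np.asarray(v, dtype=float) for k, v in expression.items()}},
        index=pd.Index([f"PT{i}" for i in range(n)], name="patient_id"),
    )
    return SurvivalCohort(cohort_id=cohort_id, endpoint="OS", data=data)


@pytest.fixture
def toy_dataset() -> QuantDataset:
    """3 proteins x 4 samples (2 tumor + 2 normal), one NA cell."""
    return make_dataset(
        symbols=["CD44", "PLXNB2", "ALB"],
        lengths=[742, 1838, 609],
        matrix=[[10, 12, 3, 4],
                [50, 40, 5, 6],
                [np.nan, 7, 8, 9]],
        conditions=["tumor", "tumor", "normal", "normal"],
    )


@pytest.fixture
def random_cohort():
    """Factory for seeded random survival cohorts with one marker."""

    def build(seed: int, n: int = 40) -> SurvivalCohort:
        rng = np.random.default_rng(seed)
        times = rng.exponential(20.0, n)
        events = (rng.random(n) < 0.7).astype(int)
        expr = rng.normal(0.0, 1.0, n)
        return make_cohort(times, events, {"MARKER": expr},
                           cohort_id=f"rand{seed}")

    return build
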