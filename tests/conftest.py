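import numpy as np
import pandas as pd
import pytest

from fittriage.cohort import CohortTable, ConversionCriteria


def build_cohort(fit_values, urgent, haemoglobin=None, age=None, sex=None,
                 crc=None, polyp_count=None, max_polyp_size=None, **extra_cols):
    """Construct a validated CohortTable directly from arrays.

    Findings default to the simplest configuration consistent with the urgent
    label under the default criteria: urgent patients carry CRC, non-urgent
    patients carry nothing.
    """
    fit_values = np.asarray(fit_values, dtype=float)
    urgent = np.asarray(urgent, dtype=bool)
    n = len(fit_values)
    if crc is None:
        crc = urgent.copy()
    if polyp_count is None:
        polyp_count = np.zeros(n, dtype=int)
    if max_polyp_size is None:
        max_polyp_size = np.zeros(n, dtype=float)
    frame = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": np.full(n, 60.0) if age is None else np.asarray(age, dtype=float),
            "sex": ["female" if i % 2 else "male" for i in range(n)] if sex is None else sex,
            "haemoglobin": (
                np.full(n, 110.0) if haemoglobin is None
                else np.asarray(haemoglobin, dtype=float)
            ),
            "fit_raw": [f"{v:.1f}" for v in fit_values],
            "fit_value": fit_values,
            "fit_censoring": ["exact"] * n,
            "crc": np.asarray(crc, dtype=bool),
            "polyp_count": np.asarray(polyp_count, dtype=int),
            "max_polyp_size": np.asarray(max_polyp_size, dtype=float),
            "bowel_prep": ["missing"] * n,
            "urgent": urgent,
            **extra_cols,
        }
    )
    return CohortTable(frame, provenance="test", criteria=ConversionCriteria())


def random_cohort(rng, n=200, prevalence=0.3, fit_scale=30.0):
    """Random cohort with ties (values on the 0.1 µg/g lattice) for oracle tests."""
    fit = np.round(rng.exponential(fit_scale, n) + 0.5, 1)
    urgent = rng.random(n) < prevalence
    return build_cohort(fit, urgent)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
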