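import numpy as np
import pandas as pd
import pytest

from stagemap import (
    CohortSpec,
    DoseResponseSpec,
    ExpressionMatrix,
    SampleAnnotation,
    simulate_expression_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Planted cohort at the documented default settings (seed 1)."""
    spec = CohortSpec(seed=1)
    X, ann, truth = simulate_expression_cohort(spec)
    return spec, X, ann, truth


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free planted cohort: recovery must be exact."""
    spec = CohortSpec(noise_sd=0.0, seed=2)
    X, ann, truth = simulate_expression_cohort(spec)
    return spec, X, ann, truth


@pytest.fixture()
def tiny_matrix():
    """Three samples per group, three groups; hand-computable ANOVA."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 5.0], "a2": [2.0, 5.0], "a3": [3.0, 5.0],
            "b1": [4.0, 5.0], "b2": [5.0, 5.0], "b3": [6.0, 5.0],
            "c1": [7.0, 5.0], "c2": [8.0, 5.0], "c3": [9.0, 5.0],
        },
        index=["g_signal", "g_flat"],
    )
    X = ExpressionMatrix(values=values)
    ann = SampleAnnotation(
        groups=pd.Series(
            ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
            index=list(values.columns),
        ),
        group_order=("A", "B", "C"),
    )
    return X, ann


def bh_stepup_oracle(p):
    """Independent Benjamini-Hochberg step-up reference implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
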