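from __future__ import annotations

import numpy as np
import pytest

import quantgraph as qg

# Reference worked example: a length-20 series discretised into 5 quantiles,
# with known quantile boundaries and the full weighted arc lists of its
# lag-1, lag-2 and lag-5 quantile graphs.
REFERENCE_BOUNDARIES = (-7.783, -3.050, 0.829, 4.657, 7.070, 9.090)

REFERENCE_ARCS = {
    1: [(1, 1, 1), (1, 3, 1), (1, 5, 2), (2, 1, 1), (2, 2, 1), (2, 4, 2),
        (3, 3, 2), (3, 4, 1), (4, 1, 1), (4, 2, 1), (4, 3, 1), (4, 4, 1),
        (5, 1, 1), (5, 2, 1), (5, 5, 2)],
    2: [(1, 3, 1), (1, 5, 2), (2, 1, 1), (2, 4, 2), (2, 5, 1), (3, 2, 1),
        (3, 3, 1), (3, 4, 1), (4, 1, 1), (4, 3, 2), (4, 4, 1), (5, 1, 1),
        (5, 2, 2), (5, 5, 1)],
    5: [(1, 4, 1), (1, 5, 1), (2, 3, 2), (2, 5, 1), (3, 1, 2), (3, 4, 1),
        (4, 2, 1), (4, 3, 1), (4, 4, 1), (5, 2, 2), (5, 3, 1), (5, 4, 1)],
}

REFERENCE_T = 20
REFERENCE_Q = 5


@pytest.fixture(scope="session")
def reference_counts():
    return {k: qg.arcs_to_counts(a, REFERENCE_Q) for k, a in REFERENCE_ARCS.items()}


@pytest.fixture(scope="session")
def two_group_cohort():
    """Control-vs-patient cohort, one channel, 24 subjects per group."""
    spec = qg.two_group_spec(channels=("F7",), groups=("A", "C"), seed=1)
    return qg.generate_cohort(spec)


@pytest.fixture(scope="session")
def four_group_cohort():
    """All four study groups on two channels, 24 subjects per group."""
    spec = qg.CohortSpec(
        seed=1, groups=("A", "B", "C", "D"), channels=("F7", "P3"),
        subjects_per_group=24,
    )
    return qg.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for structural tests (2 groups x 3 subjects x 2 channels)."""
    spec = qg.CohortSpec(
        seed=7, groups=("A", "C"), channels=("F7", "Cz"), subjects_per_group=3,
        T=256,
    )
    return qg.generate_cohort(spec)
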