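"""Shared fixtures: small synthetic studies sized for fast unit tests."""

from dataclasses import replace

import numpy as np
import pytest

from hepatox import SimulationConfig, generate_study
from hepatox.syndata import ExpressionStudy, SampleAnnotation


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast-but-nontrivial study: ~128 treated samples, 80 genes."""
    base = SimulationConfig(
        n_genes=80, n_modules=3, module_size=10, n_chemicals=16,
        doses_per_chemical=2, times_per_chemical=2, animals_per_cohort=2,
        seed=seed)
    return replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def small_study_truth():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def small_study(small_study_truth):
    return small_study_truth[0]


@pytest.fixture()
def hand_study():
    """Two genes, one control cohort {1,3} x2 genes, two treated samples —
    fold changes computable by hand."""
    samples = [
        SampleAnnotation("c1", "chemA", 1, 1, "control", "ctl", None,
                         np.zeros(3, dtype=int)),
        SampleAnnotation("c2", "chemA", 1, 1, "control", "ctl", None,
                         np.zeros(3, dtype=int)),
        SampleAnnotation("t1", "chemA", 1, 1, "treated", "trt", "ctl",
                         np.array([1, 0, 0])),
        SampleAnnotation("t2", "chemA", 1, 1, "treated", "trt", "ctl",
                         np.array([0, 0, 1])),
    ]
    matrix = np.array([
        [1.0, 1.0],
        [3.0, 3.0],
        [5.0, 4.0],
        [2.0, 6.0],
    ])
    return ExpressionStudy(["gA", "gB"], samples, matrix)
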