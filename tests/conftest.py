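import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scnet.datasets import ThicknessDataset
from scnet.preprocess import ResidualDataset
from scnet.simulate import CohortSpec, TopologySpec, generate_cohort


@pytest.fixture
def small_cohort() -> ThicknessDataset:
    """12+12 subjects, 16 regions, default small-world covariance."""
    return generate_cohort(CohortSpec(n_per_group=12, n_regions=16, seed=7))


@pytest.fixture
def null_spec() -> CohortSpec:
    """No planted structure at all: independent regions, no group effect."""
    return CohortSpec(
        n_per_group=20,
        n_regions=20,
        base_topology=TopologySpec(neighbors=0, rewiring=0.0),
        covariate_effects={"age": 0.0, "iq": 0.0},
        seed=11,
    )


def make_residuals(x: np.ndarray, groups, region_names=None) -> ResidualDataset:
    """Wrap a plain matrix as a ResidualDataset for graph/inference tests."""
    x = np.asarray(x, float)
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups))
    if region_names is None:
        region_names = [f"region_{i:02d}" for i in range(x.shape[1])]
    return ResidualDataset(
        residuals=x,
        coefficients=np.zeros((4, x.shape[1])),
        group=groups,
        region_names=list(region_names),
        case_label=levels[0],
        control_label=levels[-1] if len(levels) > 1 else levels[0],
    )
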