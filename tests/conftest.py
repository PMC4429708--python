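"""Shared fixtures: small synthetic cohorts and label-alignment helpers."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from adherevar import CohortConfig, generate_cohort
from adherevar.synthetic import cohort_to_frames

# well-separated mean curves (>= 15 adherence points apart everywhere),
# away from the [0, 100] boundaries so clipping stays inactive
SEPARATED_CURVES = (
    ((0, 92.0), (108, 92.0)),
    ((0, 72.0), (48, 72.0), (84, 52.0), (108, 68.0)),
    ((0, 50.0), (36, 22.0), (84, 52.0), (96, 37.0), (108, 37.0)),
)


def make_frames(config: CohortConfig) -> dict:
    return cohort_to_frames(generate_cohort(config))


def align_labels(pred: pd.Series, truth: pd.Series, n_classes: int = 3) -> float:
    """Best agreement rate over all label permutations of ``pred``."""
    pred, truth = pred.to_numpy(), truth.to_numpy()
    best = 0.0
    for perm in permutations(range(1, n_classes + 1)):
        relab = np.asarray(perm)[pred - 1]
        best = max(best, float((relab == truth).mean()))
    return best


@pytest.fixture(scope="session")
def small_cohort_frames() -> dict:
    """Default-condition cohort, small n for unit tests."""
    return make_frames(CohortConfig(n_patients=60, seed=123))


@pytest.fixture(scope="session")
def separated_cohort_frames() -> dict:
    """Well-separated classes, low noise: easy ground for recovery checks."""
    cfg = CohortConfig(
        n_patients=90,
        seed=7,
        mean_curves=SEPARATED_CURVES,
        noise_sd_by_var_class=(3.0, 3.0, 3.0),
        hazard_base=0.0,
    )
    return make_frames(cfg)
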