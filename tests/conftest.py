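import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stagemark as sm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced planted cohort shared by discovery-stage tests."""
    cfg = sm.CohortConfig(
        n_control=20, n_per_stage=(40, 60, 40, 20), n_genes=400,
        n_linear_signal=5, n_ordinal_signal=4, n_flat=20, seed=3,
    )
    matrix, design, truth = sm.generate_cohort(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def small_voom(small_cohort):
    _, matrix, design, _ = small_cohort
    filtered, _ = sm.filter_low_variance(matrix)
    return sm.voom_transform(filtered), design


@pytest.fixture(scope="session")
def pipeline_result(small_cohort):
    cfg, matrix, design, _ = small_cohort
    return sm.run_pipeline(sm.PipelineConfig(seed=cfg.seed), matrix, design)


def make_voom(log_cpm: np.ndarray, weights: np.ndarray, genes=None, samples=None):
    """Wrap raw arrays as a VoomResult for model-fitting tests."""
    g = genes or [f"g{i}" for i in range(log_cpm.shape[0])]
    s = samples or [f"s{i}" for i in range(log_cpm.shape[1])]
    return sm.VoomResult(
        pd.DataFrame(log_cpm, index=g, columns=s),
        pd.DataFrame(weights, index=g, columns=s),
        np.array([0.0, 1.0]), np.array([1.0, 1.0]),
    )


def make_design(stages):
    stages = np.asarray(stages)
    return sm.StageDesign(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(stages))],
        "class": np.where(stages == 0, "normal", "cancer"),
        "stage": stages,
    }))
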