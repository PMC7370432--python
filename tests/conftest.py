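import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome():
    return {"chr1": 100_000, "chr2": 50_000}


@pytest.fixture(scope="session")
def small_training():
    """Small simulated training set shared by classifier/scan tests."""
    from enhancerscan.simulate import SimulationConfig, simulate_training_set

    cfg = SimulationConfig(K=5, n_enh=80, n_prom=80, n_rand=160)
    cov, y, class_labels = simulate_training_set(cfg, seed=7)
    return cfg, cov, y, class_labels


@pytest.fixture(scope="session")
def small_predictor(small_training):
    """Final predictor trained on the small set, with calibrated thresholds."""
    from enhancerscan.classify import (
        HyperGrid,
        calibrate_thresholds,
        nested_cv_evaluate,
        train_final,
    )

    cfg, cov, y, class_labels = small_training
    grid = HyperGrid(C_exponents=(0.0, 5.0), gamma_exponents=(-8.0, -4.0))
    res = nested_cv_evaluate(cov, y, class_labels, grid=grid, seed=3)
    predictor = train_final(
        cov, y, class_labels, C=res["folds"][0]["C"],
        gamma=res["folds"][0]["gamma"], seed=3,
    )
    predictor.thresholds = calibrate_thresholds(res["oof_prob"], y)
    return cfg, predictor, res
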