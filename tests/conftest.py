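"""Shared fixtures.

The expensive end-to-end experiment runs are session-scoped so the
acceptance-level checks (accuracy bounds, saliency localization) share one
training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from berryspec.synthetic import PhantomConfig, simulate_phantom
from berryspec.workbench import (
    ExperimentConfig,
    run_classification_experiment,
    run_regression_experiment,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One mid-ripeness phantom at smoke scale with default noise."""
    cfg = PhantomConfig(red_fraction=0.6, n_bands=64, seed=11)
    return cfg, simulate_phantom(cfg)


@pytest.fixture(scope="session")
def classification_report():
    """Smoke-scale maturity classification: 1D and 3D models, one repeat.

    n_per_class=50, 24x24 cubes on a 64-band grid (49 bands after the
    441-947 nm crop), 1D 300 epochs / 3D 100 epochs, master seed 1.
    """
    config = ExperimentConfig(
        n_per_class=50,
        n_repeats=1,
        models=("1d", "3d"),
        epochs_1d=300,
        epochs_3d=100,
        master_seed=1,
    )
    return config, run_classification_experiment(config)


@pytest.fixture(scope="session")
def regression_report():
    """SSC regression on 144 class-coupled phantoms (36 per class)."""
    config = ExperimentConfig(n_per_class=36, master_seed=1)
    return config, run_regression_experiment(config)


@pytest.fixture(scope="session")
def saliency_recovery_reports():
    """Controlled saliency experiments.

    Classification: no SSC signature, so the class signal lives only in
    441-700 nm; input standardization off so the network sees the raw
    signal scale.  Regression: SSC decoupled from maturity class, so the
    SSC signal lives only in the 700-940 nm reshaping.
    """
    cls_config = ExperimentConfig(
        n_per_class=50,
        n_repeats=1,
        models=("1d",),
        epochs_1d=300,
        ssc_bump_amplitude=0.0,
        standardize_inputs=False,
        master_seed=1,
    )
    cls_report = run_classification_experiment(cls_config)
    reg_config = ExperimentConfig(n_per_class=36, couple_ssc_to_class=False, master_seed=1)
    reg_report = run_regression_experiment(reg_config)
    return cls_report, reg_report
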