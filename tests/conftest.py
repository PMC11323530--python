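import pathlib

import numpy as np
import pytest

from wedgepower import DesignSpec

EXAMPLES = pathlib.Path(__file__).resolve().parent.parent / "examples"


@pytest.fixture
def base_spec() -> DesignSpec:
    """Reference simulation design: 8 clusters, 5 periods, 15% control
    prevalence, increasing secular trend, balanced covariate."""
    return DesignSpec(
        n_clusters=8,
        n_periods=5,
        cluster_size=20,
        theta0=float(np.log(0.15 / 0.85)),
        gammas=(0.0, 0.1, 0.2, 0.3, 0.4),
        theta1=float(np.log(1.68)),
        theta2=float(np.log(1.5)),
        theta3=float(np.log(1.5)),
        prevalence=0.5,
        icc=0.1,
        cac=1.0,
    )


@pytest.fixture
def worked_example_spec() -> DesignSpec:
    """Goals-of-care disparity trial: no secular trend, 1/3 minority
    prevalence, nested exchangeable correlation, t-based Wald test."""
    return DesignSpec(
        n_clusters=8,
        n_periods=5,
        cluster_size=15,
        theta0=float(np.log(0.35 / 0.65)),
        gammas=(0.0, 0.0, 0.0, 0.0, 0.0),
        theta1=float(np.log(1.24)),
        theta2=float(np.log(0.33)),
        theta3=float(np.log(1.96)),
        prevalence=1.0 / 3.0,
        icc=0.1,
        cac=0.8,
        test="wald_t",
    )


@pytest.fixture
def tiny_spec(base_spec) -> DesignSpec:
    """Small design where dense-matrix oracles are cheap."""
    return base_spec.with_(n_clusters=4, n_periods=3, cluster_size=4,
                           gammas=(0.0, 0.1, 0.2))
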