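import numpy as np
import pytest

from binmr.simulate import SimulationConfig, draw_dataset

# Small datasets with varied regimes (effect sign, confounding, instrument
# strength, prevalence) used for oracle-equivalence checks. Generated
# programmatically so the repo ships no data files.
FIXTURE_CONFIGS = [
    SimulationConfig(alpha1=0.8, beta1=0.5, cx=0.3, cy=0.3, pZ=0.3, n=120, seed=101, n_reps=1),
    SimulationConfig(alpha1=0.3, beta1=0.0, cx=1.0, cy=1.0, pZ=0.2, n=200, seed=102, n_reps=1),
    SimulationConfig(alpha1=1.2, beta1=1.0, cx=0.01, cy=0.01, pZ=0.5, n=80, seed=103, n_reps=1),
    SimulationConfig(alpha1=0.5, beta1=-0.7, cx=0.5, cy=0.5, pZ=0.2, n=150, seed=104, n_reps=1),
    SimulationConfig(alpha1=0.2, beta1=1.0, cx=1.5, cy=1.5, pZ=0.4, n=300, seed=105, n_reps=1),
]


@pytest.fixture(params=range(len(FIXTURE_CONFIGS)), ids=lambda i: f"fixture{i}")
def small_dataset(request):
    return draw_dataset(FIXTURE_CONFIGS[request.param], 0)


@pytest.fixture(scope="session")
def all_small_datasets():
    return [draw_dataset(cfg, 0) for cfg in FIXTURE_CONFIGS]


@pytest.fixture
def eight_row():
    """Tiny non-separated logistic fixture."""
    Z = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=float)
    y = np.array([0, 1, 0, 1, 1, 1, 0, 0], dtype=float)
    return Z, y
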