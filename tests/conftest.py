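import numpy as np
import pytest

from predstack.alphabet import CANONICAL_AA, AA_TO_INDEX, N_AA
from predstack.formats_io import PredictionSet, SiteRecord
from predstack.synthetic import default_panel_config, simulate_panel


def one_hot(aa: str, conf: float = 1.0) -> np.ndarray:
    v = np.full(N_AA, (1.0 - conf) / (N_AA - 1))
    v[AA_TO_INDEX[aa]] = conf
    return v


@pytest.fixture
def uniform_vector() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


@pytest.fixture
def tiny_pset() -> tuple[PredictionSet, list[SiteRecord]]:
    """Two proteins x two sites x two models with known vectors."""
    rng = np.random.default_rng(7)
    pset = PredictionSet(model_ids=["m1", "m2"])
    labels = []
    for pid in ("pA", "pB"):
        for pos in (1, 2):
            labels.append(SiteRecord(pid, pos, CANONICAL_AA[rng.integers(N_AA)]))
            for mid in ("m1", "m2"):
                v = rng.dirichlet(np.ones(N_AA))
                pset.entries[(pid, pos, mid)] = v
    return pset, labels


@pytest.fixture(scope="session")
def small_panel():
    """Default synthetic panel, 30 proteins (shared, read-only)."""
    config = default_panel_config()
    pset, labels = simulate_panel(config, 30, seed=42)
    return config, pset, labels
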