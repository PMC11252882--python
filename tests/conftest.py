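import numpy as np
import pandas as pd
import pytest

from tilevote.basemodels import SimModelSpec, simulate_scores
from tilevote.wsi_labels import make_grid


@pytest.fixture
def unit_grid():
    """4x4 grid of unit tiles (side 1 px) on one WSI."""
    return make_grid("w1", 4, 4, side_px=1)


def random_labeled(n_tiles: int, seed: int, p_ic: float = 0.5) -> pd.DataFrame:
    """Labeled tile table with Bernoulli(p_ic) binary labels, one WSI."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "tile_id": [f"t{i:06d}" for i in range(n_tiles)],
            "wsi_id": "w1",
            "l": (rng.random(n_tiles) < p_ic).astype(int),
        }
    )


def scores_for(labeled: pd.DataFrame, n_models: int, p_correct: float,
               tau: float = 0.5, rho: float = 0.0, seed: int = 0) -> pd.DataFrame:
    specs = [
        SimModelSpec(f"m{i:02d}", p_correct=p_correct, true_threshold=tau,
                     correlation=rho)
        for i in range(n_models)
    ]
    return simulate_scores(labeled, specs, seed=seed)
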