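import numpy as np
import pytest

from protolra.titration import PhGrid, TitrationModel, TitrationSite


@pytest.fixture
def default_grid():
    return PhGrid()  # -10..20 at 0.25


@pytest.fixture
def small_grid():
    return PhGrid(0.0, 14.0, 0.25)


def make_random_model(n, rng, w_scale=0.6, pk_range=(0.0, 12.0)):
    """Random coupled model with mixed polarities."""
    w = rng.uniform(-w_scale, w_scale, (n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    sites = [
        TitrationSite(
            f"s{i}",
            rng.uniform(*pk_range),
            "anionic" if rng.random() < 0.5 else "cationic",
        )
        for i in range(n)
    ]
    return TitrationModel(sites=sites, w=w)


def single_site_model(pkint, polarity="anionic", site_id="a"):
    return TitrationModel([TitrationSite(site_id, pkint, polarity)], np.zeros((1, 1)))
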