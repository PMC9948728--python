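import numpy as np
import pandas as pd
import pytest

from assemblage.tables import CommunityTable, GeochemTable, SiteGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_community():
    """Six samples at three sites, five taxa, hand-chosen counts."""
    counts = pd.DataFrame(
        [
            [10, 5, 0, 3, 0],
            [8, 0, 2, 4, 1],
            [0, 12, 6, 0, 0],
            [1, 1, 1, 1, 1],
            [20, 0, 0, 0, 5],
            [3, 3, 3, 3, 0],
        ],
        index=[f"s{i}" for i in range(1, 7)],
        columns=[f"t{k}" for k in range(1, 6)],
    )
    sites = ["A", "A", "B", "B", "C", "C"]
    return CommunityTable(counts=counts, site_ids=sites)


@pytest.fixture
def random_community(rng):
    """40 samples x 12 taxa with lognormal depth heterogeneity."""
    n, t = 40, 12
    base = rng.dirichlet(np.full(t, 0.8), size=n)
    depths = np.exp(rng.normal(7.0, 1.2, size=n)).astype(int) + 50
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, base)])
    frame = pd.DataFrame(
        counts,
        index=[f"s{i:02d}" for i in range(n)],
        columns=[f"t{k:02d}" for k in range(t)],
    )
    sites = [f"site{i % 8}" for i in range(n)]
    return CommunityTable(counts=frame, site_ids=sites)


@pytest.fixture
def projected_geometry():
    coords = pd.DataFrame(
        {"x_km": [0.0, 0.0, 10.0, 10.0, 40.0, 40.0], "y_km": [0.0, 0.0, 2.0, 2.0, -1.0, -1.0]},
        index=[f"s{i}" for i in range(1, 7)],
    )
    return SiteGeometry(coords=coords, crs="projected")


@pytest.fixture
def small_geochem(rng, small_community):
    values = pd.DataFrame(
        np.exp(rng.normal(1.0, 0.8, size=(6, 4))),
        index=small_community.sample_ids,
        columns=["Cl", "Na", "NO3", "moisture"],
    )
    return GeochemTable(values=values)
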