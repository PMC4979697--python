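import numpy as np
import pytest

import surveygap as sg


@pytest.fixture(scope="session")
def landscape():
    """200-cell landscape shared by read-only tests."""
    return sg.make_landscape(20, 10, seed=7)


@pytest.fixture(scope="session")
def uniform_pool():
    """Easy completeness regime: equal abundances, broad niches."""
    niche = sg.NicheSpec(axis="mat", optimum_range=(5.0, 25.0), breadth_range=(8.0, 12.0))
    return sg.make_species_pool(50, sad="uniform", niche=niche, seed=3)


@pytest.fixture(scope="session")
def logseries_pool():
    """Hard completeness regime: long-tailed abundances."""
    return sg.make_species_pool(50, sad="logseries", seed=3)


def ks_brute_force(a, b):
    """Independent K-S oracle: sup of |ECDF difference| over pooled points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.unique(np.concatenate([a, b])):
        d = abs((a <= x).mean() - (b <= x).mean())
        best = max(best, d)
    return best


def survey_stats_frame(records, grid, scheme=None, dataset="synth"):
    """records -> classified per-survey metrics, the standard chain."""
    scheme = scheme or sg.TimePeriodScheme.complete()
    with_cells = sg.assign_cells(records, grid)
    inv = sg.build_inventories(with_cells, scheme, dataset=dataset)
    return sg.classify_cells(sg.compute_metrics(sg.inventory_stats(inv)))
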