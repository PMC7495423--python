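import logging

import dendropy
import numpy as np
import pytest

from phylolegacy.grid import SiteGrid
from phylolegacy.io import ClimateStack, CommunityMatrix

logging.getLogger("phylolegacy").setLevel(logging.ERROR)


@pytest.fixture
def toy_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")


@pytest.fixture
def balanced_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="((t1:1,t2:1):1,(t3:1,t4:1):1);",
                             schema="newick")


@pytest.fixture
def full_grid() -> SiteGrid:
    return SiteGrid(5, 5, 50.0, np.ones((5, 5), bool))


def make_community(grid: SiteGrid, presence: np.ndarray,
                   species: list[str]) -> CommunityMatrix:
    ids = grid.masked_ids[: presence.shape[0]]
    return CommunityMatrix(site_ids=ids, coords=grid.coords[ids],
                           species_ids=species, presence=presence)


def make_stack(grid: SiteGrid, arrays_by_var: dict[str, np.ndarray],
               step_years: float = 1000.0) -> ClimateStack:
    n_t = next(iter(arrays_by_var.values())).shape[0]
    ages = np.arange(n_t)[::-1] * step_years
    data = {}
    for var, arr in arrays_by_var.items():
        a = np.asarray(arr, float).copy()
        a[:, ~grid.mask] = np.nan
        data[var] = a
    return ClimateStack(grid=grid, variables=list(arrays_by_var),
                        data=data, ages=ages)


def random_tree_and_sites(rng: np.random.Generator, n_tips: int,
                          n_sites: int = 2):
    """Random ultrametric-ish binary tree (positive lengths) + site sets."""
    labels = [f"t{i}" for i in range(n_tips)]
    items = [f"{lab}:{rng.uniform(0.2, 2.0):.6f}" for lab in labels]
    while len(items) > 1:
        i = int(rng.integers(len(items)))
        a = items.pop(i)
        j = int(rng.integers(len(items)))
        b = items.pop(j)
        items.append(f"({a},{b}):{rng.uniform(0.2, 2.0):.6f}")
    newick = f"{items[0][:items[0].rfind(':')]};"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    sites = []
    for _ in range(n_sites):
        while True:
            pres = rng.random(n_tips) < 0.6
            if pres.any():
                break
        sites.append(pres)
    return tree, labels, np.array(sites)
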