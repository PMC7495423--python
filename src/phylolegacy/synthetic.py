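"""Synthetic landscapes with known refugial ground truth.

The generator emulates the statistical structure the analysis assumes:

* a quasi-regular metric lattice of ~50 km cells (a stylized European
  50 x 50 km community grid);
* two climate variables (annual mean temperature, annual precipitation
  sum) over 22 slices spanning 21 kyr in 1000-year steps, each variable
  a sum of a south-north spatial gradient, a regionally varying temporal
  trend, a persistent per-cell microclimate offset and per-slice noise;
* an ultrametric Yule phylogeny whose tips carry climatic niche optima
  evolved by Brownian motion (phylogenetically conserved niches);
* species ranges produced by deterministic dispersal-limited spread from
  known refugial cells through the time-sliced suitability, so the
  refugia-inference stage has a recoverable ground truth.

The default scenario makes the glacial mechanism explicit: at the LGM
the northern half of the landscape is too cold for nearly every species,
so refugia concentrate in the south; post-glacial warming opens the
north, which is recolonized - through patchy, noise-broken suitability -
by the subset of species with sufficiently broad niches.  The north is
also where the regionally varying precipitation trend and the larger
climate noise place high climate-change velocity and low stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .grid import SiteGrid
from .io import ClimateStack, CommunityMatrix
from .refugia import P_DET, derive_seed, deterministic_spread_many

logger = logging.getLogger(__name__)

__all__ = [
    "VariableConfig",
    "ScenarioConfig",
    "Scenario",
    "generate_landscape",
    "region_labels",
    "hotspot_centers",
    "generate_paleoclimate",
    "simulate_phylogeny",
    "evolve_niche_optima",
    "gaussian_suitability",
    "simulate_species_ranges",
    "generate_scenario",
    "standard_scenario",
]

#: retry cap when a species ends up with an empty range; silent dropping
#: would bias turnover, so exhausting retries is a hard error.
MAX_RETRIES = 20


@dataclass
class VariableConfig:
    """Generating model of one climate variable.

    Slice value at a cell: ``base + spatial_gradient * y_km +
    trend_by_region[region] * t_ky + microclimate(cell) +
    noise(cell, slice)``, with ``t_ky`` the slice index in kyr since the
    LGM.  ``trend_by_region`` and ``noise_sd`` accept a single float
    (spatially uniform) or a ``{"south": ..., "north": ...}`` mapping.
    Niche fields drive species generation: tip optima evolve by Brownian
    motion (sd ``niche_bm_sd`` over one tree depth) around
    ``niche_root_optimum``; per-species Gaussian niche widths are
    lognormal around ``niche_width``.
    """

    base: float
    spatial_gradient: float
    trend_by_region: dict | float
    noise_sd: dict | float = 0.0
    microclimate_sd: dict | float = 0.0
    micro_hotspot_amp: float = 0.0
    micro_hotspot_scale_km: float = 150.0
    niche_root_optimum: float = 0.0
    niche_bm_sd: float = 1.0
    niche_width: float = 1.0
    niche_width_log_sd: float = 0.0

    def regional(self, value: dict | float, region: np.ndarray) -> np.ndarray:
        if isinstance(value, dict):
            return np.where(region == "north", value["north"], value["south"])
        return np.full(region.shape, float(value))


@dataclass
class ScenarioConfig:
    """Full recipe of a synthetic study; seed determines every output."""

    n_x: int = 20
    n_y: int = 20
    cell_size: float = 50.0
    mask_fraction: float = 1.0
    n_species: int = 28
    n_slices: int = 22
    step_years: float = 1000.0
    variables: dict[str, VariableConfig] = field(default_factory=dict)
    refugia_per_species: int = 3
    refugia_hotspots: int = 3
    hotspot_radius_km: float = 120.0
    iterations_per_step_true: int = 2
    true_refugia: dict[str, list[int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("need at least 2 climate slices")
        if not 1 <= self.iterations_per_step_true <= 10:
            raise ValueError("iterations_per_step_true must be in [1, 10]")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["variables"] = {k: VariableConfig(**v) for k, v in d["variables"].items()}
        return cls(**d)


@dataclass
class Scenario:
    """A generated study: landscape, climate, tree, communities, truth."""

    config: ScenarioConfig
    grid: SiteGrid
    climate: ClimateStack
    tree: dendropy.Tree
    community: CommunityMatrix
    true_refugia: dict[str, np.ndarray]
    niche_optima: dict[str, dict[str, float]]
    niche_widths: dict[str, dict[str, float]]


# ----------------------------------------------------------------------
# landscape
# ----------------------------------------------------------------------
def generate_landscape(n_x: int, n_y: int, cell_size: float,
                       mask_fraction: float, seed: int) -> SiteGrid:
    """Random landscape whose land mask is a single 8-connected region.

    The mask grows from a random seed cell by repeatedly annexing a
    random frontier cell, which guarantees contiguity for any target
    cell count >= 1.
    """
    if n_x < 3 or n_y < 3:
        raise ValueError("grid must be at least 3x3")
    if not 0 < mask_fraction <= 1:
        raise ValueError("mask_fraction must be in (0, 1]")
    target = int(round(mask_fraction * n_x * n_y))
    if target < 1:
        raise ValueError("mask_fraction leaves no land cells")
    if target == n_x * n_y:
        return SiteGrid(n_x, n_y, cell_size, np.ones((n_y, n_x), bool))
    rng = np.random.default_rng(seed)
    mask = np.zeros((n_y, n_x), bool)
    start = (rng.integers(n_y), rng.integers(n_x))
    mask[start] = True
    frontier = set()

    def add_frontier(iy, ix):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                jy, jx = iy + dy, ix + dx
                if 0 <= jy < n_y and 0 <= jx < n_x and not mask[jy, jx]:
                    frontier.add((jy, jx))

    add_frontier(*start)
    while mask.sum() < target:
        cells = sorted(frontier)
        iy, ix = cells[rng.integers(len(cells))]
        frontier.discard((iy, ix))
        mask[iy, ix] = True
        add_frontier(iy, ix)
    return SiteGrid(n_x, n_y, cell_size, mask)


def region_labels(grid: SiteGrid) -> np.ndarray:
    """Per-cell 'south'/'north' labels: southern half of rows vs the rest."""
    _, iy = grid.cell_xy(np.arange(grid.n_cells))
    labels = np.where(iy < grid.n_y / 2, "south", "north")
    return labels.reshape(grid.n_y, grid.n_x)


def hotspot_centers(grid: SiteGrid, config: ScenarioConfig) -> np.ndarray:
    """Flat cell ids of the shared southern refugial hotspots.

    The hotspots play a double role, as in the glacial history they
    emulate: refugium cells concentrate around them, and (optionally)
    the microclimate amplitude decays away from them - refugial regions
    are the topographically complex ones.
    """
    if config.refugia_hotspots <= 0:
        return np.empty(0, dtype=int)
    rng = np.random.default_rng(derive_seed(config.seed, "hotspots"))
    south_ids = grid.masked_ids[
        region_labels(grid).ravel()[grid.masked_ids] == "south"]
    return rng.choice(south_ids,
                      size=min(config.refugia_hotspots, len(south_ids)),
                      replace=False)


# ----------------------------------------------------------------------
# paleoclimate
# ----------------------------------------------------------------------
def generate_paleoclimate(grid: SiteGrid, config: ScenarioConfig) -> ClimateStack:
    """Time-sliced climate from the additive generating model.

    Slices are ordered oldest (LGM) to present; ages run
    ``(n_slices-1)*step_years .. 0``.  Off-mask cells are NaN.
    """
    region = region_labels(grid)
    y_km = grid.coords[:, 1].reshape(grid.n_y, grid.n_x)
    n_t = config.n_slices
    ky_per_step = config.step_years / 1000.0
    centers = hotspot_centers(grid, config)
    d_hot = None
    if len(centers):
        d = np.linalg.norm(grid.coords[:, None, :]
                           - grid.coords[centers][None, :, :], axis=2)
        d_hot = d.min(axis=1).reshape(grid.n_y, grid.n_x)
    data: dict[str, np.ndarray] = {}
    for var, vc in config.variables.items():
        rng = np.random.default_rng(derive_seed(config.seed, "climate", var))
        trend = vc.regional(vc.trend_by_region, region)
        noise_sd = vc.regional(vc.noise_sd, region)
        micro_sd = vc.regional(vc.microclimate_sd, region)
        if vc.micro_hotspot_amp > 0 and d_hot is not None:
            micro_sd = micro_sd + vc.micro_hotspot_amp * np.exp(
                -d_hot / vc.micro_hotspot_scale_km)
        micro = rng.normal(0.0, 1.0, size=region.shape) * micro_sd
        base_field = vc.base + vc.spatial_gradient * y_km + micro
        slices = np.empty((n_t, grid.n_y, grid.n_x))
        for t in range(n_t):
            eps = rng.normal(0.0, 1.0, size=region.shape) * noise_sd
            slices[t] = base_field + trend * (t * ky_per_step) + eps
        slices[:, ~grid.mask] = np.nan
        data[var] = slices
    ages = (np.arange(n_t)[::-1]) * config.step_years
    return ClimateStack(grid=grid, variables=list(config.variables),
                        data=data, ages=ages)


# ----------------------------------------------------------------------
# phylogeny and niches
# ----------------------------------------------------------------------
def simulate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with ``n_species`` tips.

    Unit birth rate; only relative branch lengths matter downstream.
    Tip labels are ``s001, s002, ...`` in order of lineage creation.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("children", "t", "label")

        def __init__(self, t):
            self.children, self.t, self.label = [], t, None

    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active[i]
        node.t = t
        kids = [_N(t), _N(t)]
        node.children = kids
        active[i] = kids[0]
        active.append(kids[1])
    depth = t + rng.exponential(1.0 / n_species)
    for i, leaf in enumerate(active):
        leaf.t = depth
        leaf.label = f"s{i + 1:03d}"

    def newick(node, parent_t):
        if not node.children:
            return f"{node.label}:{node.t - parent_t:.12g}"
        inner = ",".join(newick(c, node.t) for c in node.children)
        if parent_t is None:
            return f"({inner});"
        return f"({inner}):{node.t - parent_t:.12g}"

    return dendropy.Tree.get(data=newick(root, None), schema="newick")


def evolve_niche_optima(tree: dendropy.Tree, root_value: float, bm_sd: float,
                        seed: int) -> dict[str, float]:
    """Brownian-motion tip values: variance ``bm_sd^2`` over one tree depth.

    Edge lengths are rescaled by the root-to-tip depth so the expected
    tip dispersion is controlled regardless of the simulated tree's
    absolute height.
    """
    rng = np.random.default_rng(seed)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    values: dict[int, float] = {id(tree.seed_node): root_value}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = values[id(node.parent_node)]
        frac = (node.edge.length or 0.0) / depth
        values[id(node)] = parent_val + rng.normal(0.0, bm_sd * np.sqrt(frac))
    return {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}


def gaussian_suitability(stack: ClimateStack, optima: dict[str, float],
                         widths: dict[str, float]) -> np.ndarray:
    """Per-slice suitability: product over variables of Gaussian kernels."""
    h = np.ones((stack.n_slices, stack.grid.n_y, stack.grid.n_x))
    for var in stack.variables:
        d = stack.data[var] - optima[var]
        h *= np.exp(-(d**2) / (2.0 * widths[var] ** 2))
    h[:, ~stack.grid.mask] = np.nan
    return h


# ----------------------------------------------------------------------
# species ranges
# ----------------------------------------------------------------------
def simulate_species_ranges(grid: SiteGrid, climate: ClimateStack,
                            tree: dendropy.Tree, config: ScenarioConfig
                            ) -> tuple[CommunityMatrix, dict[str, np.ndarray],
                                       dict, dict]:
    """Dispersal-limited present-day ranges from known refugia.

    Each species' range is the set of cells reached by the deterministic
    spread automaton from its true refugial cells through the climate
    slices at ``iterations_per_step_true``, intersected with present-day
    suitability of its generating Gaussian niche.  Species whose niche
    leaves them without an LGM-suitable cell or with an empty final range
    get a fresh optimum (up to 20 retries), then a hard error.

    Returns (community over all masked cells, true refugia per species,
    niche optima, niche widths).
    """
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(species) != config.n_species:
        raise ValueError("tree tip count != n_species")
    optima = {
        var: evolve_niche_optima(tree, vc.niche_root_optimum, vc.niche_bm_sd,
                                 derive_seed(config.seed, "bm", var))
        for var, vc in config.variables.items()
    }
    widths: dict[str, dict[str, float]] = {}
    for var, vc in config.variables.items():
        rng = np.random.default_rng(derive_seed(config.seed, "width", var))
        widths[var] = {
            s: vc.niche_width * np.exp(rng.normal(0.0, vc.niche_width_log_sd))
            for s in species
        }

    masked = grid.masked_ids
    presence = np.zeros((len(masked), len(species)), dtype=bool)
    refugia: dict[str, np.ndarray] = {}

    # shared southern refugial hotspots: refugium cells are drawn with a
    # Gaussian preference around a few common centers, emulating the
    # small number of major refugial regions most lineages retreated to;
    # each species draws one refugium per hotspot (round-robin when
    # refugia_per_species differs from the hotspot count)
    hotspot_w = None
    centers = hotspot_centers(grid, config)
    if len(centers):
        d2 = ((grid.coords[:, None, :] - grid.coords[centers][None, :, :]) ** 2
              ).sum(axis=2)
        r2 = config.hotspot_radius_km ** 2
        hotspot_w = np.exp(-d2 / (2.0 * r2)).T + 1e-12  # (n_hotspots, n_cells)
    for j, sp in enumerate(species):
        rng = np.random.default_rng(derive_seed(config.seed, "range", sp))
        fixed = None
        if config.true_refugia and sp in config.true_refugia:
            fixed = np.asarray(config.true_refugia[sp], dtype=int)
            if not np.isin(fixed, masked).all():
                raise ValueError(f"true refugia of {sp} off mask")
        for attempt in range(MAX_RETRIES + 1):
            opt = {v: optima[v][sp] for v in climate.variables}
            wid = {v: widths[v][sp] for v in climate.variables}
            suit = gaussian_suitability(climate, opt, wid)
            lgm_ok = masked[suit[0].ravel()[masked] ** 2 > P_DET]
            if len(lgm_ok) == 0:
                origins = None
            elif fixed is not None:
                origins = fixed
            else:
                n_draw = min(config.refugia_per_species, len(lgm_ok))
                if hotspot_w is None:
                    origins = rng.choice(lgm_ok, size=n_draw, replace=False)
                else:
                    picks: list[int] = []
                    for k in range(n_draw):
                        wk = hotspot_w[k % hotspot_w.shape[0]][lgm_ok].copy()
                        wk[np.isin(lgm_ok, picks)] = 0.0
                        if wk.sum() == 0:
                            break
                        picks.append(int(rng.choice(lgm_ok, p=wk / wk.sum())))
                    origins = np.asarray(picks, dtype=int)
            if origins is not None and (fixed is None or
                                        np.isin(origins, lgm_ok).all()):
                reached = (np.zeros((grid.n_y, grid.n_x), bool)
                           if len(origins) == 0 else
                           deterministic_spread_many(
                               suit, grid, origins,
                               config.iterations_per_step_true).any(axis=0))
                rng_mask = reached & (np.nan_to_num(suit[-1]) ** 2 > P_DET)
                if rng_mask.any():
                    presence[:, j] = rng_mask.ravel()[masked]
                    refugia[sp] = np.sort(np.asarray(origins, dtype=int))
                    break
            # regenerate this tip's niche (optimum and width) from the
            # marginal distributions; a fixed too-narrow width could
            # otherwise fail every retry on a fragmented landscape
            logger.debug("simulate_species_ranges: retry %d for %s", attempt + 1, sp)
            for var, vc in config.variables.items():
                optima[var][sp] = rng.normal(vc.niche_root_optimum, vc.niche_bm_sd)
                widths[var][sp] = vc.niche_width * np.exp(
                    rng.normal(0.0, vc.niche_width_log_sd))
        else:
            raise RuntimeError(
                f"species {sp}: empty range after {MAX_RETRIES} niche retries"
            )

    community = CommunityMatrix(
        site_ids=masked,
        coords=grid.coords[masked],
        species_ids=species,
        presence=presence,
    )
    return community, refugia, optima, widths


# ----------------------------------------------------------------------
# scenario assembly
# ----------------------------------------------------------------------
def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Landscape -> paleoclimate -> phylogeny -> ranges, all from one seed."""
    grid = generate_landscape(config.n_x, config.n_y, config.cell_size,
                              config.mask_fraction,
                              derive_seed(config.seed, "landscape"))
    climate = generate_paleoclimate(grid, config)
    tree = simulate_phylogeny(config.n_species, derive_seed(config.seed, "tree"))
    community, refugia, optima, widths = simulate_species_ranges(
        grid, climate, tree, config
    )
    optima_by_sp = {
        s: {v: optima[v][s] for v in climate.variables}
        for s in community.species_ids
    }
    widths_by_sp = {
        s: {v: widths[v][s] for v in climate.variables}
        for s in community.species_ids
    }
    return Scenario(config=config, grid=grid, climate=climate, tree=tree,
                    community=community, true_refugia=refugia,
                    niche_optima=optima_by_sp, niche_widths=widths_by_sp)


def standard_scenario(seed: int = 0, n_x: int = 20, n_y: int = 20,
                      n_species: int = 60,
                      mask_fraction: float = 1.0) -> ScenarioConfig:
    """The default glacial-legacy scenario (see module docstring).

    Temperature falls from ~13 C at the southern edge to ~-2 C in the
    far north at the LGM (gradient -0.016 C/km) and warms by 2.1 C in
    the stable south versus 4.2 C in the north over 21 kyr, so the
    north opens to colonization only gradually.  Niche optima evolve by
    Brownian motion around a warm-biased root (13 C), which - because a
    species must have had habitat at the LGM - piles the diversity ridge
    against the warm southern edge, as in a Mediterranean refugial belt.
    Persistent microclimate heterogeneity is strong in the rugged south
    (sd 1.6 C) and nearly absent on the flat northern plains (0.1 C):
    narrow-niche southern species live in fragmented, refugium-anchored
    patches while broad-niche generalists blanket the north.
    Precipitation carries the strong regional trend and slice-to-slice
    noise contrast (north high), placing high climate-change velocity
    and low climate stability in the north.  Each species descends from
    a single true refugial cell with 2 automaton iterations per
    1000-year step.
    """
    variables = {
        "temp": VariableConfig(
            base=13.5, spatial_gradient=-0.016,
            trend_by_region={"south": 0.02, "north": 0.15},
            noise_sd={"south": 0.1, "north": 0.1},
            microclimate_sd={"south": 0.4, "north": 0.1},
            micro_hotspot_amp=1.6, micro_hotspot_scale_km=150.0,
            niche_root_optimum=13.0, niche_bm_sd=2.5,
            niche_width=1.8, niche_width_log_sd=0.6,
        ),
        "prec": VariableConfig(
            base=550.0, spatial_gradient=0.4,
            trend_by_region={"south": 2.0, "north": 12.0},
            noise_sd={"south": 4.0, "north": 14.0},
            microclimate_sd={"south": 15.0, "north": 10.0},
            micro_hotspot_amp=40.0, micro_hotspot_scale_km=150.0,
            niche_root_optimum=800.0, niche_bm_sd=100.0,
            niche_width=700.0, niche_width_log_sd=0.4,
        ),
    }
    return ScenarioConfig(n_x=n_x, n_y=n_y, cell_size=50.0,
                          mask_fraction=mask_fraction, n_species=n_species,
                          n_slices=22, variables=variables,
                          refugia_per_species=3, iterations_per_step_true=2,
                          seed=seed)
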