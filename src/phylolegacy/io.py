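"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* community table: CSV with columns ``id,x,y`` followed by one 0/1 column
  per species; one row per masked cell.
* phylogeny: Newick with branch lengths (read via dendropy).
* rasters: ESRI-style ASCII grids with a 6-line header (``ncols, nrows,
  xllcorner, yllcorner, cellsize, nodata_value``).  On disk the first data
  row is the *northern*most row (the ASCII-grid convention); in memory
  rasters are ``(n_y, n_x)`` arrays with row 0 in the *south* (see
  :mod:`phylolegacy.grid`), so readers/writers flip rows.
* config: flat YAML key/value files.

All readers validate and reject malformed input rather than coercing it;
every writer produces files its reader accepts bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .grid import SiteGrid

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "ClimateStack",
    "read_community",
    "write_community",
    "read_tree",
    "write_tree",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_climate_stack",
    "write_climate_stack",
    "read_config",
    "write_config",
]


# ----------------------------------------------------------------------
# domain containers
# ----------------------------------------------------------------------
@dataclass
class CommunityMatrix:
    """Sites x species presence/absence.

    ``site_ids`` are flat grid cell ids; ``coords`` the matching (x, y)
    centroids in km; ``presence`` a boolean ``(n_sites, n_species)``
    array.  Invariant: no species column is all-zero (such columns are
    dropped with a warning on read).
    """

    site_ids: np.ndarray
    coords: np.ndarray
    species_ids: list[str]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        n, s = self.presence.shape
        if len(self.site_ids) != n or self.coords.shape != (n, 2):
            raise ValueError("site_ids/coords/presence shapes disagree")
        if len(self.species_ids) != s:
            raise ValueError("species_ids length != presence columns")
        if len(np.unique(self.site_ids)) != n:
            raise ValueError("duplicate site ids")

    @property
    def n_sites(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    @property
    def richness(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    @property
    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per species (column sums)."""
        return self.presence.sum(axis=0)


@dataclass
class ClimateStack:
    """Time-sliced gridded climate for one or more variables.

    ``data[var]`` is a ``(n_slices, n_y, n_x)`` float array (NaN off
    mask); ``ages`` are years BP, strictly decreasing to the present-day
    slice (last).
    """

    grid: SiteGrid
    variables: list[str]
    data: dict[str, np.ndarray] = field(repr=False)
    ages: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("climate stack needs at least one variable")
        self.ages = np.asarray(self.ages, dtype=float)
        if np.any(np.diff(self.ages) >= 0):
            raise ValueError("slice ages must be strictly decreasing (oldest first)")
        shape = (len(self.ages), self.grid.n_y, self.grid.n_x)
        for var in self.variables:
            arr = np.asarray(self.data[var], dtype=float)
            if arr.shape != shape:
                raise ValueError(f"variable {var!r}: shape {arr.shape} != {shape}")
            self.data[var] = arr

    @property
    def n_slices(self) -> int:
        return len(self.ages)

    def present(self, var: str) -> np.ndarray:
        """Present-day (most recent) slice of a variable."""
        return self.data[var][-1]

    def present_site_values(self, site_ids: np.ndarray) -> np.ndarray:
        """``(n_sites, n_vars)`` present-day values at flat cell ids."""
        cols = [self.present(v).ravel()[site_ids] for v in self.variables]
        return np.column_stack(cols)

    def intersect_mask(self) -> SiteGrid:
        """Grid whose mask drops any cell that is NaN in any slice/variable.

        The pipeline uses a single shared mask: a cell missing anywhere is
        missing everywhere (logged).
        """
        mask = self.grid.mask.copy()
        for var in self.variables:
            finite = np.isfinite(self.data[var]).all(axis=0)
            mask &= finite
        dropped = int(self.grid.mask.sum() - mask.sum())
        if dropped:
            logger.warning("intersect_mask: dropped %d cells with missing climate", dropped)
        return self.grid.with_mask(mask)


# ----------------------------------------------------------------------
# community CSV
# ----------------------------------------------------------------------
def write_community(path: str | Path, community: CommunityMatrix) -> None:
    df = pd.DataFrame(
        community.presence.astype(int), columns=community.species_ids
    )
    df.insert(0, "y", community.coords[:, 1])
    df.insert(0, "x", community.coords[:, 0])
    df.insert(0, "id", community.site_ids)
    df.to_csv(path, index=False)


def read_community(path: str | Path) -> CommunityMatrix:
    """Read a community CSV, validating ids and 0/1 values.

    All-zero species columns are dropped with a warning; duplicate site
    ids or non-binary values raise ``ValueError``.
    """
    df = pd.read_csv(path)
    required = ["id", "x", "y"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"community CSV must start with columns {required}")
    site_ids = df["id"].to_numpy()
    if len(np.unique(site_ids)) != len(site_ids):
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"duplicate site ids: {dupes}")
    species = list(df.columns[3:])
    values = df[species].to_numpy()
    bad = (values != 0) & (values != 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary value {values[r, c]!r} at site id {site_ids[r]}, "
            f"column {species[c]!r}"
        )
    keep = values.sum(axis=0) > 0
    if not keep.all():
        dropped = [s for s, k in zip(species, keep) if not k]
        logger.warning("read_community: dropping %d all-zero species: %s",
                       len(dropped), dropped)
        species = [s for s, k in zip(species, keep) if k]
        values = values[:, keep]
    return CommunityMatrix(
        site_ids=site_ids,
        coords=df[["x", "y"]].to_numpy(),
        species_ids=species,
        presence=values.astype(bool),
    )


# ----------------------------------------------------------------------
# Newick trees
# ----------------------------------------------------------------------
def read_tree(path: str | Path, community_species: Sequence[str] | None = None
              ) -> dendropy.Tree:
    """Read a Newick tree, check branch lengths, reconcile with a community.

    Tips absent from the community are pruned (warning); community species
    absent from the tree raise ``ValueError`` listing the missing names.
    Edges without a length (other than the root edge) or with length <= 0
    are rejected.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    _check_branch_lengths(tree)
    if community_species is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = sorted(set(community_species) - tips)
        if missing:
            raise ValueError(
                f"community species absent from tree: {missing}"
            )
        extra = sorted(tips - set(community_species))
        if extra:
            logger.warning("read_tree: pruning %d tips not in community: %s",
                           len(extra), extra)
            tree.retain_taxa_with_labels(list(community_species))
    return tree


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge: length optional, ignored
            continue
        if edge.length is None:
            raise ValueError("tree has an edge with no branch length")
        if edge.length <= 0:
            raise ValueError(f"non-positive branch length {edge.length}")


def write_tree(path: str | Path, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ----------------------------------------------------------------------
# ASCII-grid rasters
# ----------------------------------------------------------------------
_NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: SiteGrid,
                     fmt: str = "%.10g") -> None:
    """Write a ``(n_y, n_x)`` raster (row 0 = south) as an ASCII grid.

    NaN and off-mask cells become the nodata value; rows are flipped so
    the file's first data row is the northernmost, per the format.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_y, grid.n_x):
        raise ValueError(f"raster shape {values.shape} != grid ({grid.n_y}, {grid.n_x})")
    out = values.copy()
    out[~grid.mask] = np.nan
    out = np.where(np.isfinite(out), out, _NODATA)
    header = (
        f"ncols {grid.n_x}\n"
        f"nrows {grid.n_y}\n"
        f"xllcorner 0\n"
        f"yllcorner 0\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"nodata_value {_NODATA:.10g}\n"
    )
    body = "\n".join(" ".join(fmt % v for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ASCII grid; returns ``(values, cell_size)``.

    Values come back as a ``(n_y, n_x)`` array with row 0 = south and
    nodata as NaN.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", _NODATA)
    data = np.loadtxt(lines[6:])
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise ValueError(f"raster body shape {data.shape} != header ({nrows}, {ncols})")
    data = data[::-1].copy()  # file is north-first; memory is south-first
    data[data == nodata] = np.nan
    return data, header["cellsize"]


# ----------------------------------------------------------------------
# climate stacks
# ----------------------------------------------------------------------
def write_climate_stack(directory: str | Path, stack: ClimateStack) -> list[Path]:
    """One ASCII grid per variable per slice: ``<var>_<ageBP>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for var in stack.variables:
        for t, age in enumerate(stack.ages):
            p = directory / f"{var}_{int(age):06d}.asc"
            write_ascii_grid(p, stack.data[var][t], stack.grid)
            written.append(p)
    return written


def read_climate_stack(paths_by_var: dict[str, Sequence[str | Path]],
                       ages: Sequence[float],
                       mask: np.ndarray | None = None) -> ClimateStack:
    """Assemble a stack from per-variable ordered slice files (oldest first).

    All slices must share one shape and cell size; ages must strictly
    decrease.  NaN cells in any slice are removed from the shared mask.
    """
    ages = np.asarray(ages, dtype=float)
    data: dict[str, np.ndarray] = {}
    grid: SiteGrid | None = None
    for var, paths in paths_by_var.items():
        if len(paths) != len(ages):
            raise ValueError(f"variable {var!r}: {len(paths)} files != {len(ages)} ages")
        slices = []
        for i, p in enumerate(paths):
            arr, cell = read_ascii_grid(p)
            if grid is None:
                m = np.ones(arr.shape, bool) if mask is None else np.asarray(mask, bool)
                grid = SiteGrid(arr.shape[1], arr.shape[0], cell, m)
            elif arr.shape != (grid.n_y, grid.n_x):
                raise ValueError(
                    f"variable {var!r}, slice {i}: shape {arr.shape} != "
                    f"({grid.n_y}, {grid.n_x})"
                )
            slices.append(arr)
        data[var] = np.stack(slices)
    stack = ClimateStack(grid=grid, variables=list(paths_by_var), data=data, ages=ages)
    stack.grid = stack.intersect_mask()
    for var in stack.variables:
        stack.data[var][:, ~stack.grid.mask] = np.nan
    return stack


# ----------------------------------------------------------------------
# config
# ----------------------------------------------------------------------
def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
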