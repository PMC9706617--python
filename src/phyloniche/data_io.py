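"""Readers and writers for occurrences, raster layers and dated trees.

Grids follow common raster conventions: cell values refer to cell centers,
row 0 is the northernmost row, and a point maps to the cell whose
half-open interval ``[edge, next_edge)`` contains it on both axes.
Rasters are exchanged as single-band ESRI ASCII grids in geographic
(lon/lat) coordinates; values round-trip at full double precision.

Trees are Newick with branch lengths in millions of years (MY).  Node
ages are measured back from the present: a node's age is its distance to
its deepest descendant tip, so tips of an ultrametric tree sit at age 0.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "OccurrenceReport",
    "EnvLayer",
    "LayerStack",
    "Phylo",
    "read_occurrences",
    "read_layer",
    "write_layer",
    "read_newick",
    "resolve_duplicate_tips",
]


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced species record (WGS84 decimal degrees)."""

    species: str
    longitude: float
    latitude: float
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be non-empty")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


@dataclass
class OccurrenceReport:
    """Bookkeeping from :func:`read_occurrences`."""

    n_read: int = 0
    n_dropped: int = 0
    n_deduplicated: int = 0


def read_occurrences(
    path: str | Path,
    dedupe: bool = False,
    columns: tuple[str, str, str] = ("species", "longitude", "latitude"),
    source_column: str | None = None,
) -> tuple[list[OccurrenceRecord], OccurrenceReport]:
    """Read an occurrence CSV into validated records.

    Rows with missing or unparseable coordinates, out-of-range
    coordinates, or an empty species label are dropped and counted in the
    returned report.  With ``dedupe=True`` exact duplicates of
    (species, longitude, latitude) collapse to a single record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    sp_col, lon_col, lat_col = columns
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"occurrence file {path} lacks mandatory column {col!r}")

    report = OccurrenceReport(n_read=len(df))
    records: list[OccurrenceRecord] = []
    seen: set[tuple[str, float, float]] = set()
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    for i in range(len(df)):
        sp = df[sp_col].iloc[i]
        x, y = lon.iloc[i], lat.iloc[i]
        if (
            pd.isna(sp)
            or not str(sp).strip()
            or pd.isna(x)
            or pd.isna(y)
            or not (-180.0 <= x <= 180.0)
            or not (-90.0 <= y <= 90.0)
        ):
            report.n_dropped += 1
            continue
        key = (str(sp), float(x), float(y))
        if dedupe and key in seen:
            report.n_deduplicated += 1
            continue
        seen.add(key)
        src = None
        if source_column is not None and source_column in df.columns:
            raw = df[source_column].iloc[i]
            src = None if pd.isna(raw) else str(raw)
        records.append(OccurrenceRecord(str(sp), float(x), float(y), src))
    return records, report


# ---------------------------------------------------------------------------
# Raster layers
# ---------------------------------------------------------------------------

_NODATA_DEFAULT = -9999.0


@dataclass
class EnvLayer:
    """A single environmental variable on a regular lon/lat grid.

    ``values`` has shape (nrows, ncols) with row 0 the northernmost row;
    ``nodata_mask`` is True where the cell carries no data.  ``extent``
    is (lon_min, lon_max, lat_min, lat_max) in degrees and ``resolution``
    the cell size in arc-minutes.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    extent: tuple[float, float, float, float]
    resolution: float
    variable_id: str = "env"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask must be matching 2-D grids")
        lon_min, lon_max, lat_min, lat_max = self.extent
        step = self.cell_size_deg
        nrows = round((lat_max - lat_min) / step)
        ncols = round((lon_max - lon_min) / step)
        if (nrows, ncols) != self.values.shape:
            raise ValueError(
                f"grid shape {self.values.shape} inconsistent with extent "
                f"{self.extent} at {self.resolution} arc-min "
                f"(expected {(nrows, ncols)})"
            )
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values outside the nodata mask")

    @property
    def cell_size_deg(self) -> float:
        return self.resolution / 60.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lon_centers(self) -> np.ndarray:
        lon_min = self.extent[0]
        step = self.cell_size_deg
        return lon_min + step * (np.arange(self.shape[1]) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 first (northernmost)."""
        lat_max = self.extent[3]
        step = self.cell_size_deg
        return lat_max - step * (np.arange(self.shape[0]) + 0.5)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def cell_of(self, longitude: float, latitude: float) -> tuple[int, int] | None:
        """Map a point to its (row, col), or None if outside the extent.

        Half-open convention: a point exactly on an interior edge belongs
        to the cell east/south of it; the extent's max edges are closed so
        boundary points are not lost.
        """
        lon_min, lon_max, lat_min, lat_max = self.extent
        step = self.cell_size_deg
        if not (lon_min <= longitude <= lon_max and lat_min <= latitude <= lat_max):
            return None
        col = int((longitude - lon_min) // step)
        row = int((lat_max - latitude) // step)
        col = min(col, self.shape[1] - 1)
        row = min(row, self.shape[0] - 1)
        return row, col


@dataclass
class LayerStack:
    """An ordered set of cell-aligned :class:`EnvLayer` grids."""

    layers: list[EnvLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("LayerStack needs at least one layer")
        ref = self.layers[0]
        for lyr in self.layers[1:]:
            if (
                lyr.shape != ref.shape
                or lyr.extent != ref.extent
                or lyr.resolution != ref.resolution
            ):
                raise ValueError(
                    f"layer {lyr.variable_id!r} not aligned with {ref.variable_id!r}"
                )

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, key: int | str) -> EnvLayer:
        if isinstance(key, str):
            for lyr in self.layers:
                if lyr.variable_id == key:
                    return lyr
            raise KeyError(key)
        return self.layers[key]

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer of the stack."""
        mask = self.layers[0].valid_mask.copy()
        for lyr in self.layers[1:]:
            mask &= lyr.valid_mask
        return mask


def write_layer(layer: EnvLayer, path: str | Path, nodata: float = _NODATA_DEFAULT) -> None:
    """Write a layer as a single-band ESRI ASCII grid at full precision."""
    path = Path(path)
    lon_min, _, lat_min, _ = layer.extent
    nrows, ncols = layer.shape
    out = layer.values.copy()
    out[layer.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {lon_min!r}\n")
        fh.write(f"yllcorner {lat_min!r}\n")
        fh.write(f"cellsize {layer.cell_size_deg!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_layer(path: str | Path, variable_id: str | None = None) -> EnvLayer:
    """Read a single-band ESRI ASCII grid in geographic coordinates.

    The header must use geographic cell sizes (degrees); grids written in
    a projected CRS must be reprojected to lon/lat before use.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and re.fullmatch(r"[A-Za-z_]+", parts[0]):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA_DEFAULT)
    lat_top = header["yllcorner"] + nrows * cellsize
    if cellsize > 30.0 or abs(header["yllcorner"]) > 90.0 + 1e-9 or lat_top > 90.0 + 1e-9:
        raise ValueError(
            f"{path}: grid coordinates exceed geographic bounds "
            "(projected CRS?); reproject to lon/lat degrees first"
        )
    values = np.loadtxt(io.StringIO("\n".join(lines[n_header:])), dtype=float)
    values = values.reshape(nrows, ncols)
    mask = values == nodata
    lon_min = header["xllcorner"]
    lat_min = header["yllcorner"]
    extent = (
        lon_min,
        lon_min + ncols * cellsize,
        lat_min,
        lat_min + nrows * cellsize,
    )
    return EnvLayer(
        values=values,
        nodata_mask=mask,
        extent=extent,
        resolution=cellsize * 60.0,
        variable_id=variable_id or path.stem,
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Phylo:
    """A rooted tree with branch lengths in MY and derived node ages.

    Thin wrapper around a :class:`dendropy.Tree`.  Every node carries a
    deterministic postorder id (``node_id`` annotation, tips first in
    traversal order) and an ``age``: the maximum distance from the node
    to any descendant tip, so ultrametric tips sit at age 0.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        require_ultrametric: bool = False,
        ultrametric_rel_tol: float = 1e-6,
    ) -> None:
        if tree.seed_node is None or not tree.leaf_nodes():
            raise ValueError("tree has no taxa")
        if tree.is_rooted is False:
            raise ValueError("tree must be rooted")
        self.tree = tree
        self.ultrametric_rel_tol = ultrametric_rel_tol
        self._annotate()
        if require_ultrametric and not self.is_ultrametric():
            raise ValueError(
                "tree is not ultrametric within relative tolerance "
                f"{ultrametric_rel_tol}"
            )

    def _annotate(self) -> None:
        for i, node in enumerate(self.tree.postorder_node_iter()):
            node.node_id = i
        # depth (distance from root) by preorder accumulation
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                node.depth = 0.0
            else:
                el = node.edge.length or 0.0
                if el < 0:
                    raise ValueError("negative branch length")
                node.depth = node.parent_node.depth + el
        # age = max distance to a descendant tip, by postorder
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.age = 0.0
            else:
                node.age = max(
                    c.age + (c.edge.length or 0.0) for c in node.child_nodes()
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def node_ages(self) -> dict[int, float]:
        return {n.node_id: n.age for n in self.tree.postorder_node_iter()}

    def postorder(self) -> list[dendropy.Node]:
        return list(self.tree.postorder_node_iter())

    def preorder(self) -> list[dendropy.Node]:
        return list(self.tree.preorder_node_iter())

    def is_ultrametric(self) -> bool:
        depths = [leaf.depth for leaf in self.tree.leaf_node_iter()]
        span = max(depths) - min(depths)
        scale = max(max(depths), 1e-300)
        return span <= self.ultrametric_rel_tol * scale

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def clone(self) -> "Phylo":
        return Phylo(
            self.tree.clone(depth=1),
            ultrametric_rel_tol=self.ultrametric_rel_tol,
        )

    def tip_descendant_sets(self) -> dict[int, frozenset[str]]:
        """Map node_id -> set of descendant tip labels (tips map to themselves)."""
        out: dict[int, frozenset[str]] = {}
        sets: dict[int, frozenset[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                s = frozenset([node.taxon.label])
            else:
                s = frozenset().union(*(sets[c.node_id] for c in node.child_nodes()))
            sets[node.node_id] = s
            out[node.node_id] = s
        return out


def read_newick(
    path: str | Path,
    require_ultrametric: bool = False,
    ultrametric_rel_tol: float = 1e-6,
) -> Phylo:
    """Read a rooted Newick tree with branch lengths.

    Trees without an explicit rooting flag are treated as rooted at the
    basal node of the string; trees flagged ``[&U]`` are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if "[&U]" in text.upper().replace(" ", ""):
        raise ValueError(f"{path}: tree is flagged unrooted; root it first")
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return Phylo(
        tree,
        require_ultrametric=require_ultrametric,
        ultrametric_rel_tol=ultrametric_rel_tol,
    )


def resolve_duplicate_tips(
    phylo: Phylo,
    rng_seed: int,
    species_map: dict[str, str] | Callable[[str], str] | None = None,
) -> Phylo:
    """Reduce conspecific tips to a single random representative.

    Trees often carry several accessions or subspecific taxa per species.
    ``species_map`` assigns a species to each tip label (default: the
    label itself, so only exact duplicate labels collapse).  For each
    species one tip is kept, chosen uniformly with the given seed; the
    others are pruned and unifurcations are suppressed with branch
    lengths summed so every retained tip keeps its root-to-tip distance.
    """
    if species_map is None:
        mapper: Callable[[str], str] = lambda s: s
    elif callable(species_map):
        mapper = species_map
    else:
        mapper = lambda s: species_map.get(s, s)  # noqa: E731

    tree = phylo.tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    groups: dict[str, list[dendropy.Node]] = {}
    for leaf in leaves:
        groups.setdefault(mapper(leaf.taxon.label), []).append(leaf)

    rng = np.random.default_rng(rng_seed)
    drop: list[dendropy.Node] = []
    for species in sorted(groups):
        members = groups[species]
        if len(members) == 1:
            members[0].taxon.label = species
            continue
        keep = members[int(rng.integers(len(members)))]
        keep.taxon.label = species
        drop.extend(m for m in members if m is not keep)

    for leaf in drop:
        parent = leaf.parent_node
        parent.remove_child(leaf)
        # walk up removing now-childless internals
        while parent is not None and not parent.child_nodes():
            gp = parent.parent_node
            if gp is None:
                break
            gp.remove_child(parent)
            parent = gp

    # suppress unifurcations, merging branch lengths additively
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_node_iter()):
            kids = node.child_nodes()
            if len(kids) == 1 and node.parent_node is not None:
                child = kids[0]
                child.edge.length = (child.edge.length or 0.0) + (
                    node.edge.length or 0.0
                )
                gp = node.parent_node
                gp.remove_child(node)
                gp.add_child(child)
                changed = True
    # a unifurcate root collapses onto its child
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        tree.seed_node = child

    return Phylo(tree, ultrametric_rel_tol=phylo.ultrametric_rel_tol)
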