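"""Accessible areas and per-species continuous niche profiles.

The accessible area M of a species is the region hypothesized to have
been reachable by it over relevant time; here it is built as the union
of geodesic buffers (default 500 km) around known occurrences, on the
analysis grid.  Environmental conditions outside M are *unavailable* to
the species, which is what later motivates the "unknown" character
state: absence under conditions a species could never reach is not
evidence about its niche.

A niche profile summarizes one species on one environmental variable as
two nested continuous intervals: the *used* range (values at occurrence
cells, trimmed to a central confidence level, default 95%) inside the
*available* range (values across M).  Both are treated as continuous,
filling gaps between the observed minimum and maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from phyloniche.data_io import EnvLayer, LayerStack, OccurrenceRecord

__all__ = [
    "AccessibleArea",
    "NicheProfile",
    "haversine_km",
    "build_accessible_area",
    "clip_area",
    "extract_use",
    "extract_availability",
    "trim_range",
    "pca_layers",
    "make_profile",
]

EARTH_RADIUS_KM = 6371.0

DEFAULT_BUFFER_KM = 500.0
DEFAULT_TRIM_LEVEL = 0.95


@dataclass
class AccessibleArea:
    """Boolean accessible-area (M) mask for one species on the grid.

    ``mask`` is True where the cell is inside M; ``occ_mask`` marks the
    cells that contain occurrences (always a subset of ``mask`` unless
    occurrences fall on nodata cells).
    """

    species: str
    mask: np.ndarray
    buffer_km: float
    occ_mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.occ_mask = np.asarray(self.occ_mask, dtype=bool)
        if self.mask.shape != self.occ_mask.shape:
            raise ValueError("mask and occ_mask shapes differ")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


@dataclass
class NicheProfile:
    """Continuous use/availability intervals for one species x variable."""

    species: str
    variable_id: str
    used_range: tuple[float, float]
    available_range: tuple[float, float]
    n_occurrences: int
    trim_level: float

    def __post_init__(self) -> None:
        ulo, uhi = self.used_range
        alo, ahi = self.available_range
        if ulo > uhi or alo > ahi:
            raise ValueError("interval lower bound exceeds upper bound")
        if ulo < alo - 1e-12 or uhi > ahi + 1e-12:
            raise ValueError("used_range must lie within available_range")


def haversine_km(
    lon1: np.ndarray | float,
    lat1: np.ndarray | float,
    lon2: np.ndarray | float,
    lat2: np.ndarray | float,
) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def build_accessible_area(
    records: list[OccurrenceRecord],
    grid: EnvLayer,
    buffer_km: float = DEFAULT_BUFFER_KM,
) -> AccessibleArea:
    """Union of geodesic buffers around occurrences, on the grid.

    A cell is in M if its center lies within ``buffer_km`` great-circle
    distance of any occurrence, or if it contains an occurrence (so a
    zero buffer yields exactly the occupied cells).  The result is
    intersected with the grid's valid (non-nodata) cells.
    """
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    inside = [r for r in records if grid.cell_of(r.longitude, r.latitude) is not None]
    if not inside:
        raise ValueError("no occurrence falls inside the grid extent")
    species = inside[0].species

    occ_mask = np.zeros(grid.shape, dtype=bool)
    for r in inside:
        row, col = grid.cell_of(r.longitude, r.latitude)
        occ_mask[row, col] = True

    mask = occ_mask.copy()
    if buffer_km > 0:
        lons = grid.lon_centers[np.newaxis, :]
        lats = grid.lat_centers[:, np.newaxis]
        for r in inside:
            d = haversine_km(r.longitude, r.latitude, lons, lats)
            mask |= d <= buffer_km
    mask &= grid.valid_mask
    occ_mask &= grid.valid_mask
    return AccessibleArea(species=species, mask=mask, buffer_km=buffer_km, occ_mask=occ_mask)


def clip_area(
    area: AccessibleArea,
    keep_mask: np.ndarray,
    allow_occ_loss: bool = False,
) -> AccessibleArea:
    """Restrict M to ``keep_mask`` (e.g. drop an unreachable island).

    Refuses to discard occurrence cells unless ``allow_occ_loss`` is set,
    and refuses to produce an empty area.
    """
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if keep_mask.shape != area.mask.shape:
        raise ValueError("keep_mask not aligned with the area grid")
    lost = area.occ_mask & ~keep_mask
    if lost.any() and not allow_occ_loss:
        raise ValueError(
            f"clip would remove {int(lost.sum())} occupied cell(s) for "
            f"{area.species}; pass allow_occ_loss=True to force"
        )
    new_mask = area.mask & keep_mask
    if not new_mask.any():
        raise ValueError(f"clip leaves an empty accessible area for {area.species}")
    return AccessibleArea(
        species=area.species,
        mask=new_mask,
        buffer_km=area.buffer_km,
        occ_mask=area.occ_mask & keep_mask,
    )


def extract_use(
    records: list[OccurrenceRecord],
    layer: EnvLayer,
) -> tuple[np.ndarray, int]:
    """Layer values at occurrence cells; returns (values, n_skipped).

    Occurrences outside the extent or on nodata cells are skipped and
    counted; all of them skipped is an error.
    """
    values: list[float] = []
    skipped = 0
    for r in records:
        cell = layer.cell_of(r.longitude, r.latitude)
        if cell is None or layer.nodata_mask[cell]:
            skipped += 1
            continue
        values.append(float(layer.values[cell]))
    if not values:
        raise ValueError("all occurrences fall outside the grid or on nodata cells")
    return np.asarray(values), skipped


def extract_availability(area: AccessibleArea, layer: EnvLayer) -> np.ndarray:
    """Layer values across the accessible area (nodata cells excluded)."""
    sel = area.mask & layer.valid_mask
    if not sel.any():
        raise ValueError(f"accessible area of {area.species} has no valid cells on {layer.variable_id}")
    return layer.values[sel]


def trim_range(values: np.ndarray | list[float], level: float) -> tuple[float, float]:
    """Central interval holding ``level`` of the values.

    Bounds are the (1-level)/2 and 1-(1-level)/2 percentiles with linear
    interpolation; ``level=1`` returns [min, max].
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trim_range needs at least one value")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(values, [tail, 100.0 - tail])
    return float(lo), float(hi)


def pca_layers(
    stack: LayerStack,
    k: int,
    fit_mask: np.ndarray | None = None,
) -> tuple[LayerStack, np.ndarray]:
    """Principal-component layers from a stack of variables.

    Each variable is z-scored over the fit cells, then projected onto the
    top-k eigenvectors of the correlation matrix.  Component sign is
    fixed so the loading of largest magnitude is positive.  Returns the
    component stack (nodata wherever any input is nodata) and the
    explained-variance fractions.
    """
    if k < 1 or k > len(stack):
        raise ValueError(f"k={k} must be in 1..{len(stack)}")
    valid = stack.valid_mask
    fit = valid if fit_mask is None else (np.asarray(fit_mask, dtype=bool) & valid)
    if fit.sum() < 2:
        raise ValueError("fewer than two cells to fit the PCA on")

    X_fit = np.column_stack([lyr.values[fit] for lyr in stack])
    mu = X_fit.mean(axis=0)
    sd = X_fit.std(axis=0)
    for lyr, s in zip(stack, sd):
        if s == 0.0:
            raise ValueError(f"layer {lyr.variable_id!r} is constant over the fit cells")
    Z_fit = (X_fit - mu) / sd

    pca = PCA(n_components=k)
    pca.fit(Z_fit)
    components = pca.components_.copy()  # (k, n_layers)
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]

    X_all = np.column_stack([lyr.values[valid] for lyr in stack])
    scores = ((X_all - mu) / sd) @ components.T

    ref = stack[0]
    out_layers = []
    for i in range(k):
        grid = np.zeros(ref.shape)
        grid[valid] = scores[:, i]
        out_layers.append(
            EnvLayer(
                values=grid,
                nodata_mask=~valid,
                extent=ref.extent,
                resolution=ref.resolution,
                variable_id=f"PC{i + 1}",
            )
        )
    return LayerStack(out_layers), pca.explained_variance_ratio_.copy()


def make_profile(
    species: str,
    variable_id: str,
    use_values: np.ndarray | list[float],
    avail_values: np.ndarray | list[float],
    trim_level: float = DEFAULT_TRIM_LEVEL,
) -> NicheProfile:
    """Assemble the continuous use-within-availability profile.

    The used range is the trimmed interval of occurrence values, clipped
    into the availability envelope [min, max] over M (with a warning when
    clipping occurs — in a well-formed pipeline occurrences lie inside M,
    so clipping signals e.g. a heavily trimmed singleton).
    """
    use_values = np.asarray(use_values, dtype=float)
    avail_values = np.asarray(avail_values, dtype=float)
    if use_values.size == 0 or avail_values.size == 0:
        raise ValueError("use and availability value lists must be non-empty")
    alo, ahi = float(avail_values.min()), float(avail_values.max())
    ulo, uhi = trim_range(use_values, trim_level)
    if uhi < alo or ulo > ahi:
        raise ValueError(
            f"used range [{ulo}, {uhi}] of {species}/{variable_id} is disjoint "
            f"from availability [{alo}, {ahi}]; occurrences are not inside M"
        )
    if ulo < alo or uhi > ahi:
        warnings.warn(
            f"used range of {species}/{variable_id} clipped into availability",
            stacklevel=2,
        )
    ulo, uhi = max(ulo, alo), min(uhi, ahi)
    return NicheProfile(
        species=species,
        variable_id=variable_id,
        used_range=(ulo, uhi),
        available_range=(alo, ahi),
        n_occurrences=int(use_values.size),
        trim_level=trim_level,
    )
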