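"""Gridded spatial data model on a global equirectangular (WGS84-style) lattice.

Everything downstream works on coarse global grids: named covariate surfaces
("layers") indexed by an optional decade, a land mask, and per-cell spherical
areas.  The default study lattice is 1° (360 × 180); synthetic worlds use
coarser grids with the same conventions.

Conventions
-----------
* Arrays are shaped ``(n_lat, n_lon)``, row-major from the south-west corner:
  row 0 is the southernmost latitude band, column 0 the westernmost band.
* Missing values are NaN.  Interchange files always carry explicit lon/lat
  cell-centre coordinates, never bare indices.
* Temporal tags are strings: ``"static"``, a decade year (``"1970"`` ...
  ``"2000"``), or a change interval (``"1990-2000"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Decade layers available for time-varying covariates.
DECADES = (1970, 1980, 1990, 2000)

STATIC = "static"


def change_tag(earlier: int, later: int) -> str:
    """Temporal tag for a change layer spanning ``earlier -> later``."""
    return f"{earlier}-{later}"


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

def band_area_km2(lat_bottom: float, lat_top: float, dlon_deg: float,
                  radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area of one spherical cell in a latitude band.

    Exact spherical formula ``R^2 * dλ * (sin φ_top − sin φ_bottom)`` with the
    longitudinal width ``dλ`` in radians.  Depends only on the latitude band,
    so cells in the same row share an area.
    """
    if not -90.0 <= lat_bottom < lat_top <= 90.0:
        raise ValueError(f"invalid latitude band [{lat_bottom}, {lat_top}]")
    dlam = math.radians(dlon_deg)
    return radius_km ** 2 * dlam * (
        math.sin(math.radians(lat_top)) - math.sin(math.radians(lat_bottom))
    )


@dataclass(frozen=True)
class GridSpec:
    """A global lon/lat lattice with a land mask and per-cell spherical areas.

    Parameters
    ----------
    n_lon, n_lat
        Number of cells along longitude/latitude.  Cell size is
        ``360/n_lon`` × ``180/n_lat`` degrees; the default 360 × 180 gives the
        1° study grid.
    land_mask
        Boolean ``(n_lat, n_lon)`` array; must contain at least one land cell.
    """

    n_lon: int = 360
    n_lat: int = 180
    land_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.land_mask is None:
            object.__setattr__(self, "land_mask",
                               np.ones((self.n_lat, self.n_lon), dtype=bool))
        mask = np.asarray(self.land_mask, dtype=bool)
        if mask.shape != (self.n_lat, self.n_lon):
            raise ValueError(
                f"land_mask shape {mask.shape} != {(self.n_lat, self.n_lon)}")
        if not mask.any():
            raise ValueError("land_mask has no land cells")
        object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def dlon(self) -> float:
        return 360.0 / self.n_lon

    @property
    def dlat(self) -> float:
        return 180.0 / self.n_lat

    @property
    def lon_centers(self) -> np.ndarray:
        return -180.0 + self.dlon * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return -90.0 + self.dlat * (np.arange(self.n_lat) + 0.5)

    @property
    def cell_area(self) -> np.ndarray:
        """Per-cell spherical area in km², broadcast across longitude."""
        bottoms = -90.0 + self.dlat * np.arange(self.n_lat)
        row_areas = np.array([band_area_km2(b, b + self.dlat, self.dlon)
                              for b in bottoms])
        return np.repeat(row_areas[:, None], self.n_lon, axis=1)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a lon/lat point."""
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise ValueError(f"point ({lon}, {lat}) off the globe")
        col = min(int((lon + 180.0) / self.dlon), self.n_lon - 1)
        row = min(int((lat + 90.0) / self.dlat), self.n_lat - 1)
        return row, col

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of a cell rectangle."""
        lon0 = -180.0 + col * self.dlon
        lat0 = -90.0 + row * self.dlat
        return lon0, lat0, lon0 + self.dlon, lat0 + self.dlat


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

@dataclass
class Layer:
    """One named covariate surface on a grid, with an optional temporal tag."""

    name: str
    values: np.ndarray
    temporal: str = STATIC

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be 2-D (n_lat, n_lon)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, **kw) -> "Layer":
        return replace(self, **kw)


def rescale_to_grid(fine_values: np.ndarray, grid: GridSpec, method: str,
                    name: str = "rescaled", temporal: str = STATIC) -> Layer:
    """Aggregate a finer global field onto the study grid by integer blocks.

    The fine grid must nest evenly inside the study grid (its shape an integer
    multiple of the coarse shape).  ``method="sum"`` counts missing fine cells
    as 0; ``method="mean"`` excludes them.
    """
    fine = np.asarray(fine_values, dtype=float)
    if fine.ndim != 2:
        raise ValueError("fine field must be 2-D")
    fy, fx = fine.shape
    if fy % grid.n_lat or fx % grid.n_lon:
        raise ValueError(
            f"fine shape {fine.shape} is not an integer multiple of the "
            f"target grid {grid.shape}: non-integer aggregation factor")
    by, bx = fy // grid.n_lat, fx // grid.n_lon
    if by != bx:
        raise ValueError(
            f"anisotropic aggregation factors ({by}, {bx}) not supported")
    blocks = fine.reshape(grid.n_lat, by, grid.n_lon, bx).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(grid.n_lat, grid.n_lon, by * bx)
    if method == "sum":
        out = np.nansum(blocks, axis=-1)
    elif method == "mean":
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks, axis=-1)
    else:
        raise ValueError(f"method must be 'sum' or 'mean', got {method!r}")
    return Layer(name=name, values=out, temporal=temporal)


def diff_decades(later: Layer, earlier: Layer) -> Layer:
    """Inter-decadal change layer: elementwise ``later − earlier``.

    Both layers must carry the same name and tag consecutive decades.
    """
    if later.name != earlier.name:
        raise ValueError(
            f"cannot difference layers with different names: "
            f"{later.name!r} vs {earlier.name!r}")
    try:
        d1, d0 = int(later.temporal), int(earlier.temporal)
    except ValueError as exc:
        raise ValueError("both layers must carry decade-year tags") from exc
    if d1 - d0 != 10:
        raise ValueError(f"decades {d0} and {d1} are not consecutive")
    return Layer(name=later.name, values=later.values - earlier.values,
                 temporal=change_tag(d0, d1))


def match_decade(year: int) -> int:
    """Map an event year to the nearest decadal covariate layer.

    Years ending in 5 round up; years after the last available decade (2000)
    clamp to it.  Years before the study window (1970) are rejected — events
    are filtered before covariate matching.
    """
    if year < 1970:
        raise ValueError(f"year {year} precedes the 1970 study cutoff")
    if year > 2008:
        raise ValueError(f"year {year} beyond the study window (2008)")
    return min(int(math.floor((year + 5) / 10)) * 10, 2000)


def change_interval_for_year(year: int) -> str:
    """Change-layer tag used for a sample in ``year``.

    The right endpoint is ``match_decade(year)``, floored at 1980 so that
    years matching the first decade still resolve to the first available
    interval (1970–1980).
    """
    right = max(match_decade(year), 1980)
    return change_tag(right - 10, right)


def sum_headcounts(layers: Sequence[Layer], name: str = "headcount_sum") -> Layer:
    """Elementwise sum of headcount layers (e.g. livestock species), NaN→0."""
    layers = list(layers)
    if not layers:
        raise ValueError("cannot sum an empty list of layers")
    shape = layers[0].shape
    tag = layers[0].temporal
    for lay in layers[1:]:
        if lay.shape != shape:
            raise ValueError("headcount layers are on different grids")
        if lay.temporal != tag:
            raise ValueError("headcount layers carry different temporal tags")
    total = np.zeros(shape)
    for lay in layers:
        total += np.nan_to_num(lay.values, nan=0.0)
    return Layer(name=name, values=total, temporal=tag)


def sd_scale(values: np.ndarray, k: float = 2.5) -> np.ndarray:
    """Standard-deviation scaling for map rendering: z-score clipped to ±k.

    A zero-variance surface degenerates to all zeros.  NaN cells propagate.
    """
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing cells to scale")
    mu = vals[finite].mean()
    sd = vals[finite].std()
    out = np.full_like(vals, np.nan)
    if sd == 0.0:
        out[finite] = 0.0
        return out
    out[finite] = np.clip((vals[finite] - mu) / sd, -k, k)
    return out


# ---------------------------------------------------------------------------
# Predictor sets
# ---------------------------------------------------------------------------

class PredictorSet:
    """A named collection of covariate layers with temporal resolution rules.

    For each name the set holds either one static layer, one layer per decade,
    or one layer per change interval.  ``resolve(name, year)`` always returns
    exactly one layer: static names ignore the year; decadal names use
    :func:`match_decade`; change names use :func:`change_interval_for_year`.
    """

    def __init__(self):
        self._layers: dict[str, dict[str, Layer]] = {}

    def add(self, layer: Layer) -> None:
        slot = self._layers.setdefault(layer.name, {})
        slot[str(layer.temporal)] = layer

    def names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def layers_for(self, name: str) -> dict[str, Layer]:
        return dict(self._layers[name])

    def decades_available(self, name: str) -> list[int]:
        tags = self._layers[name]
        return sorted(int(t) for t in tags if t.isdigit())

    def is_static(self, name: str) -> bool:
        return set(self._layers[name]) == {STATIC}

    def is_change(self, name: str) -> bool:
        return all("-" in t for t in self._layers[name])

    def validate(self) -> None:
        """Check the shared-decade invariant across decadal names."""
        decade_sets = {name: tuple(self.decades_available(name))
                       for name in self.names()
                       if not self.is_static(name) and not self.is_change(name)}
        if len(set(decade_sets.values())) > 1:
            raise ValueError(
                f"decadal names carry different decade sets: {decade_sets}")

    def resolve(self, name: str, year: int) -> Layer:
        if name not in self._layers:
            raise KeyError(f"unknown predictor {name!r}")
        slot = self._layers[name]
        if self.is_static(name):
            return slot[STATIC]
        if self.is_change(name):
            return slot[change_interval_for_year(year)]
        return slot[str(match_decade(year))]

    def complete_mask(self, grid: GridSpec) -> np.ndarray:
        """Land cells with non-missing values in every layer of every name."""
        mask = grid.land_mask.copy()
        for slot in self._layers.values():
            for lay in slot.values():
                mask &= np.isfinite(lay.values)
        return mask

    def design_row(self, row: int, col: int, year: int,
                   names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.names()
        return np.array([self.resolve(n, year).values[row, col] for n in names])


# ---------------------------------------------------------------------------
# I/O: long-format CSV and single-band TIFF
# ---------------------------------------------------------------------------

def layers_to_csv(layers: Iterable[Layer], grid: GridSpec, path: str | Path) -> None:
    """Write layers as long-format CSV (lon, lat, name, decade, value).

    Cell-centre coordinates are explicit; missing cells are omitted.  The
    round-trip through :func:`layers_from_csv` is lossless.
    """
    lon = np.tile(grid.lon_centers, grid.n_lat)
    lat = np.repeat(grid.lat_centers, grid.n_lon)
    frames = []
    for lay in layers:
        vals = lay.values.ravel()
        ok = np.isfinite(vals)
        frames.append(pd.DataFrame({
            "lon": lon[ok], "lat": lat[ok], "name": lay.name,
            "decade": str(lay.temporal), "value": vals[ok],
        }))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["lon", "lat", "name", "decade", "value"]))
    out.to_csv(path, index=False, float_format="%.17g")


def layers_from_csv(path: str | Path, grid: GridSpec) -> list[Layer]:
    df = pd.read_csv(path, dtype={"decade": str},
                     float_precision="round_trip")
    layers = []
    for (name, decade), sub in df.groupby(["name", "decade"], sort=True):
        vals = np.full(grid.shape, np.nan)
        rows = ((sub["lat"].to_numpy() + 90.0) / grid.dlat - 0.5).round().astype(int)
        cols = ((sub["lon"].to_numpy() + 180.0) / grid.dlon - 0.5).round().astype(int)
        vals[rows, cols] = sub["value"].to_numpy()
        layers.append(Layer(name=name, values=vals, temporal=decade))
    return layers


def layer_to_tiff(layer: Layer, path: str | Path) -> None:
    """Write a layer as a single-band float TIFF, north-up row order.

    The global equirectangular georeferencing is implied by the grid
    convention (cell 0,0 at 180°W, 90°S); no embedded geokeys are written.
    """
    import tifffile

    tifffile.imwrite(str(path), layer.values[::-1].astype(np.float64))


def layer_from_tiff(path: str | Path, name: str, temporal: str = STATIC) -> Layer:
    import tifffile

    vals = np.asarray(tifffile.imread(str(path)), dtype=float)
    return Layer(name=name, values=vals[::-1], temporal=temporal)
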