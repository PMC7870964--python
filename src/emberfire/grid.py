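"""Grid geometry, monthly fields, region partitions, and gridded file I/O.

Conventions: cell-center registered coordinates, latitude ascending,
longitude in [-180, 180). Field arrays are shaped ``(time, lat, lon)`` with
``NaN`` marking missing values. The time axis is a contiguous, strictly
increasing sequence of calendar months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

EARTH_RADIUS_KM = 6371.0
KM2_PER_MHA = 1.0e4  # 1 Mha = 10^4 km^2

#: Base subcontinental region codes and the merges applied on top of them.
BASE_REGION_CODES = [
    "BONA", "TENA", "CEAM", "NHSA", "SHSA", "EURO", "MIDE",
    "NHAF", "SHAF", "BOAS", "CEAS", "SEAS", "EQAS", "AUS",
]
DEFAULT_MERGES = {
    "TENA": "TCAM", "CEAM": "TCAM",
    "NHSA": "SA", "SHSA": "SA",
    "EURO": "EUME", "MIDE": "EUME",
}
MERGED_REGION_CODES = [
    "NHAF", "SHAF", "SA", "SEAS", "TCAM", "BONA",
    "AUS", "CEAS", "BOAS", "EQAS", "EUME",
]

#: The twelve land-cover classes carried as per-cell fractions.
VEG_TYPES = [
    "non_vegetated",
    "needleleaved_evergreen",
    "broadleaved_evergreen",
    "needleleaved_deciduous",
    "broadleaved_deciduous",
    "mixed_forests",
    "open_shrublands",
    "closed_shrublands",
    "woody_savannas",
    "savannas",
    "grasslands",
    "croplands",
]


class GridError(ValueError):
    """Raised for malformed grid geometry or dimension mismatches."""


class FormatError(ValueError):
    """Raised when a gridded file does not match the expected layout."""


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid of cell centers."""

    n_lat: int
    n_lon: int
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    resolution: float

    def __post_init__(self):
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if lat.shape != (self.n_lat,) or lon.shape != (self.n_lon,):
            raise GridError("coordinate lengths do not match grid shape")
        if np.any(np.abs(lat) > 90.0):
            raise GridError("latitudes must lie in [-90, 90]")
        for axis in (lat, lon):
            if len(axis) > 1:
                steps = np.diff(axis)
                if not np.allclose(steps, steps[0], atol=1e-9):
                    raise GridError("grid spacing must be uniform")
        if self.n_lat > 1 and lat[1] < lat[0]:
            raise GridError("latitude must be ascending")

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, resolution: float = 1.0,
                lat0: float | None = None, lon0: float = -180.0) -> "GridSpec":
        """Build a grid of ``n_lat x n_lon`` cells of edge ``resolution`` degrees.

        By default the latitude band is centered on the equator.
        """
        if lat0 is None:
            lat0 = -0.5 * n_lat * resolution
        lat = lat0 + resolution * (np.arange(n_lat) + 0.5)
        lon = lon0 + resolution * (np.arange(n_lon) + 0.5)
        return cls(n_lat, n_lon, lat, lon, resolution)

    def cell_areas(self, flat: bool = False) -> np.ndarray:
        """Cell areas, shape (n_lat, n_lon).

        Spherical areas in km^2 by default; ``flat=True`` returns unit areas
        (useful for synthetic tests where absolute Mha are irrelevant).
        """
        if flat:
            return np.ones((self.n_lat, self.n_lon))
        dlam = np.deg2rad(self.resolution)
        lat_n = np.deg2rad(np.minimum(self.lat_centers + 0.5 * self.resolution, 90.0))
        lat_s = np.deg2rad(np.maximum(self.lat_centers - 0.5 * self.resolution, -90.0))
        band = EARTH_RADIUS_KM ** 2 * dlam * (np.sin(lat_n) - np.sin(lat_s))
        return np.repeat(band[:, None], self.n_lon, axis=1)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon


def month_range(start_year: int, start_month: int, n_months: int):
    """Contiguous (year, month) axis of length ``n_months``."""
    years = np.empty(n_months, dtype=int)
    months = np.empty(n_months, dtype=int)
    y, m = start_year, start_month
    for i in range(n_months):
        years[i], months[i] = y, m
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return years, months


@dataclass
class MonthlyField:
    """One gridded variable on a monthly time axis; NaN marks missing."""

    grid: GridSpec
    values: np.ndarray  # (time, lat, lon)
    years: np.ndarray
    months: np.ndarray
    name: str = "field"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        nt = self.values.shape[0]
        if self.values.shape != (nt, self.grid.n_lat, self.grid.n_lon):
            raise GridError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_lat}, {self.grid.n_lon})")
        if self.years.shape != (nt,) or self.months.shape != (nt,):
            raise GridError("time axis length does not match values")
        idx = self.years * 12 + (self.months - 1)
        if nt > 1 and not np.all(np.diff(idx) == 1):
            raise GridError("time axis must be strictly increasing, contiguous months")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def time_axis(self):
        return list(zip(self.years.tolist(), self.months.tolist()))

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "MonthlyField":
        return MonthlyField(
            self.grid,
            self.values.copy() if values is None else np.asarray(values, dtype=float),
            self.years.copy(), self.months.copy(),
            self.name if name is None else name, self.units)

    def like(self, values: np.ndarray, name: str = "field") -> "MonthlyField":
        return MonthlyField(self.grid, values, self.years, self.months, name, self.units)


@dataclass
class VegetationFractions:
    """Static per-cell fractional cover for each vegetation type."""

    grid: GridSpec
    fractions: np.ndarray  # (n_type, lat, lon)
    types: list = field(default_factory=lambda: list(VEG_TYPES))

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.types), self.grid.n_lat, self.grid.n_lon):
            raise GridError("fractions shape does not match (n_type, lat, lon)")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise GridError("vegetation fractions must lie in [0, 1]")
        total = self.fractions.sum(axis=0)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise GridError("vegetation fractions must sum to 1 per cell (tol 1e-6)")

    def fraction_of(self, veg_type: str) -> np.ndarray:
        return self.fractions[self.types.index(veg_type)]


@dataclass
class RegionPartition:
    """Per-cell region codes ('' = unassigned) with merge table applied."""

    grid: GridSpec
    codes: np.ndarray  # (lat, lon) array of str
    merge_table: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=object)
        if self.codes.shape != (self.grid.n_lat, self.grid.n_lon):
            raise GridError("region codes shape does not match grid")
        if self.merge_table:
            merged = np.empty_like(self.codes)
            for i, row in enumerate(self.codes):
                merged[i] = [self.merge_table.get(c, c) for c in row]
            self.codes = merged

    @classmethod
    def from_blocks(cls, grid: GridSpec, blocks, merge_table: dict | None = None) -> "RegionPartition":
        """Build a partition from rectangular blocks.

        ``blocks`` is a list of ``(code, (ilat_lo, ilat_hi), (ilon_lo, ilon_hi))``
        with half-open index ranges. Overlapping blocks are rejected.
        """
        codes = np.full((grid.n_lat, grid.n_lon), "", dtype=object)
        for code, (la, lb), (lo, lb2) in blocks:
            patch = codes[la:lb, lo:lb2]
            if np.any(patch != ""):
                raise GridError(f"region block {code!r} overlaps an existing region")
            codes[la:lb, lo:lb2] = code
        return cls(grid, codes, merge_table or {})

    def region_codes(self):
        present = sorted({c for c in self.codes.ravel() if c})
        return present

    def mask(self, code: str) -> np.ndarray:
        return self.codes == code


# ---------------------------------------------------------------------------
# Operations


def coarse_grain(fine: MonthlyField, factor: int) -> MonthlyField:
    """Block-average a field onto a grid coarser by ``factor`` per axis.

    Each coarse value is the mean of the non-missing fine values in its
    block; an all-missing block stays missing.
    """
    if factor == 1:
        return fine.copy()
    g = fine.grid
    if g.n_lat % factor or g.n_lon % factor:
        raise GridError(
            f"grid ({g.n_lat}x{g.n_lon}) not divisible by factor {factor}")
    nt = fine.n_time
    nlat, nlon = g.n_lat // factor, g.n_lon // factor
    blocks = fine.values.reshape(nt, nlat, factor, nlon, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        coarse = np.nanmean(blocks, axis=(2, 4))
    lat = fine.grid.lat_centers.reshape(nlat, factor).mean(axis=1)
    lon = fine.grid.lon_centers.reshape(nlon, factor).mean(axis=1)
    cg = GridSpec(nlat, nlon, lat, lon, g.resolution * factor)
    return MonthlyField(cg, coarse, fine.years, fine.months, fine.name, fine.units)


def burnable_mask(veg: VegetationFractions, threshold: float = 0.30) -> np.ndarray:
    """Cells with at least ``threshold`` non-agricultural vegetation cover.

    A cell is retained iff ``1 - cropland - non_vegetated >= threshold``
    (inclusive boundary).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    natural = 1.0 - veg.fraction_of("croplands") - veg.fraction_of("non_vegetated")
    return natural >= threshold - 1e-12


def interpolate_quinquennial(snapshots, grid: GridSpec, years: np.ndarray,
                             months: np.ndarray, name: str = "field") -> MonthlyField:
    """Linearly interpolate sparse (e.g. 5-yearly) snapshots to a monthly axis.

    ``snapshots`` is a list of ``(year, 2-D array)``; between bracketing
    snapshot years values are linear in continuous time, outside them the
    nearest snapshot is held constant.
    """
    if len(snapshots) == 0:
        raise ValueError("at least one snapshot required")
    snap_years = np.array([y for y, _ in snapshots], dtype=float)
    if np.any(np.diff(snap_years) <= 0):
        raise ValueError("snapshot years must be increasing")
    if len(snapshots) == 1:
        warnings.warn("single snapshot: field held constant in time")
    stack = np.stack([np.asarray(a, dtype=float) for _, a in snapshots])  # (s, lat, lon)
    t_query = np.asarray(years, dtype=float) + (np.asarray(months, dtype=float) - 0.5) / 12.0
    flat = stack.reshape(len(snapshots), -1)
    out = np.empty((len(t_query), flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_query, snap_years, flat[:, j])
    values = out.reshape(len(t_query), grid.n_lat, grid.n_lon)
    return MonthlyField(grid, values, years, months, name)


# ---------------------------------------------------------------------------
# File I/O (NetCDF conventions via xarray; scipy backend, NETCDF3_64BIT)


def _to_dataset(fields) -> xr.Dataset:
    first = next(iter(fields.values()))
    coords = {
        "lat": ("lat", first.grid.lat_centers),
        "lon": ("lon", first.grid.lon_centers),
        "time": ("time", np.arange(first.n_time)),
        "year": ("time", first.years),
        "month": ("time", first.months),
    }
    data_vars = {}
    for name, f in fields.items():
        if f.values.shape != (first.n_time, first.grid.n_lat, first.grid.n_lon):
            raise GridError("all fields in one file must share grid and time axis")
        data_vars[name] = (("time", "lat", "lon"), f.values, {"units": f.units})
    ds = xr.Dataset(data_vars, coords=coords)
    ds.attrs["resolution"] = first.grid.resolution
    ds.attrs["Conventions"] = "cell-center registered, lat ascending, lon in [-180, 180)"
    return ds


def write_gridded(field_or_fields, path) -> None:
    """Write one field or a dict of fields sharing a grid/time axis."""
    if isinstance(field_or_fields, MonthlyField):
        fields = {field_or_fields.name: field_or_fields}
    else:
        fields = dict(field_or_fields)
    _to_dataset(fields).to_netcdf(path, engine="scipy")


def read_gridded(path, name: str | None = None) -> MonthlyField:
    """Read one variable from a gridded file written by :func:`write_gridded`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for dim in ("time", "lat", "lon"):
        if dim not in ds.dims:
            raise FormatError(f"file {path} lacks required dimension {dim!r}")
    names = [v for v in ds.data_vars if v not in ("year", "month")]
    if name is None:
        if len(names) != 1:
            raise FormatError(
                f"file {path} holds variables {names}; specify one by name")
        name = names[0]
    if name not in ds.data_vars:
        raise FormatError(f"variable {name!r} not found in {path} (has {names})")
    grid = GridSpec(
        ds.sizes["lat"], ds.sizes["lon"],
        ds["lat"].values, ds["lon"].values,
        float(ds.attrs.get("resolution",
                           abs(float(ds["lat"][1] - ds["lat"][0])) if ds.sizes["lat"] > 1 else 1.0)))
    var = ds[name]
    return MonthlyField(grid, var.values, ds["year"].values, ds["month"].values,
                        name, str(var.attrs.get("units", "")))


def read_all_gridded(path) -> dict:
    """Read every variable in a multi-variable gridded file."""
    with xr.open_dataset(path, engine="scipy") as ds:
        names = [v for v in ds.data_vars if v not in ("year", "month")]
    return {n: read_gridded(path, n) for n in names}
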