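"""Gridded ocean fields and space-time interpolation.

Daily-mean current velocity (u, v) and temperature fields on a regular
lon/lat grid with fixed z-levels, plus a land/sea mask, are the physical
driver of the larval-dispersal simulator.  Horizontal interpolation is
bilinear, vertical and temporal interpolation linear; daily means are
stamped at 12:00 so a query at noon of a stored day returns the stored
value exactly.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

# 1 degree of latitude in meters; longitude is scaled by cos(lat).
# Local equirectangular approximation: adequate for a basin spanning ~6 deg.
METERS_PER_DEGREE = 111_320.0

#: Fill value marking land cells in NetCDF files.
FILL_VALUE = 1e20


class FieldFormatError(ValueError):
    """A NetCDF file does not conform to the expected layout."""


class OutOfDomainError(LookupError):
    """A query fell outside the grid's spatial or temporal extent."""


class DryCellError(LookupError):
    """A query landed on a land (dry) cell."""


def meters_to_degrees(dx_m: float, dy_m: float, lat: float) -> tuple[float, float]:
    """Convert local eastward/northward displacements in meters to degrees."""
    dlat = dy_m / METERS_PER_DEGREE
    dlon = dx_m / (METERS_PER_DEGREE * np.cos(np.deg2rad(lat)))
    return dlon, dlat


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with fixed depth levels and daily time steps.

    Grid nodes sit at ``lon_min + i*d_lon``; the cell around each node is
    the region closer to it than to any other node.  ``depth_levels`` are
    positive depths in meters, surface first, strictly increasing.
    ``time_origin`` is the calendar date of day 0; day ``d`` covers
    [d, d+1) in continuous time with its mean stamped at d + 0.5.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    d_lon: float = 1.0 / 45.0
    d_lat: float = 1.0 / 45.0
    depth_levels: tuple[float, ...] = (1.0,)
    time_origin: datetime.date = datetime.date(2004, 1, 1)
    n_days: int = 1

    def __post_init__(self) -> None:
        if self.d_lon <= 0 or self.d_lat <= 0:
            raise ValueError("grid spacing must be positive")
        depths = tuple(float(z) for z in self.depth_levels)
        if len(depths) == 0 or any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depth_levels must be nonempty and strictly increasing")
        object.__setattr__(self, "depth_levels", depths)
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.lon_max < self.lon_min or self.lat_max < self.lat_min:
            raise ValueError("empty domain")

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.d_lon)) + 1
        return self.lon_min + self.d_lon * np.arange(n)

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.d_lat)) + 1
        return self.lat_min + self.d_lat * np.arange(n)

    @property
    def times(self) -> np.ndarray:
        """Continuous-day stamps of the daily means (noon of each day)."""
        return np.arange(self.n_days) + 0.5

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.n_days, len(self.depth_levels), len(self.lats), len(self.lons))


@dataclass
class OceanField:
    """Daily u/v/T fields on a :class:`GridSpec` with a wet/dry mask.

    Arrays have shape (time, depth, lat, lon); ``wet_mask`` has shape
    (lat, lon) and is True on sea cells.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    temperature: np.ndarray
    wet_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = self.grid.shape
        if self.wet_mask is None:
            self.wet_mask = np.ones(shape[2:], dtype=bool)
        self.wet_mask = np.asarray(self.wet_mask, dtype=bool)
        for name in ("u", "v", "temperature"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape} from grid"
                )
            if not np.all(np.isfinite(arr[:, :, self.wet_mask])):
                raise ValueError(f"{name} contains non-finite values on wet cells")
            setattr(self, name, arr)
        if self.wet_mask.shape != shape[2:]:
            raise ValueError("wet_mask shape mismatch")
        if not self.wet_mask.any():
            raise ValueError("wet_mask must contain at least one wet cell")

    # ------------------------------------------------------------------
    # index helpers
    # ------------------------------------------------------------------

    def _axis_bracket(self, coords: np.ndarray, value: float, what: str):
        """Indices (i0, i1) and weight w of value between coords[i0], coords[i1]."""
        if value < coords[0] or value > coords[-1]:
            raise OutOfDomainError(f"{what}={value} outside [{coords[0]}, {coords[-1]}]")
        if len(coords) == 1:
            return 0, 0, 0.0
        i0 = int(np.clip(np.searchsorted(coords, value, side="right") - 1, 0, len(coords) - 2))
        w = (value - coords[i0]) / (coords[i0 + 1] - coords[i0])
        return i0, i0 + 1, float(w)

    def _depth_bracket(self, depth: float):
        """Vertical bracket; depths outside the level range are clamped
        (constant extrapolation above the first and below the last level)."""
        levels = np.asarray(self.grid.depth_levels)
        return self._axis_bracket(levels, float(np.clip(depth, levels[0], levels[-1])),
                                  "depth")

    def _time_bracket(self, time: float):
        """Temporal bracket; daily means stamped at noon, clamped at the ends."""
        stamps = self.grid.times
        if time < 0 or time > self.grid.n_days:
            raise OutOfDomainError(f"time={time} outside field span")
        if time <= stamps[0]:
            return 0, 0, 0.0
        if time >= stamps[-1]:
            return len(stamps) - 1, len(stamps) - 1, 0.0
        return self._axis_bracket(stamps, time, "time")

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Indices (j_lat, i_lon) of the grid node whose cell contains (lon, lat)."""
        g = self.grid
        i = int(round((lon - g.lon_min) / g.d_lon))
        j = int(round((lat - g.lat_min) / g.d_lat))
        if not (0 <= i < len(g.lons) and 0 <= j < len(g.lats)):
            raise OutOfDomainError(f"({lon}, {lat}) outside grid")
        return j, i

    def is_wet_arrays(self, lon, lat) -> np.ndarray:
        """Vectorized :meth:`is_wet`; out-of-domain points are dry."""
        g = self.grid
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.round((lon - g.lon_min) / g.d_lon).astype(int)
        j = np.round((lat - g.lat_min) / g.d_lat).astype(int)
        inside = (i >= 0) & (i < len(g.lons)) & (j >= 0) & (j < len(g.lats))
        out = np.zeros(lon.shape, dtype=bool)
        out[inside] = self.wet_mask[j[inside], i[inside]]
        return out

    def is_wet(self, lon: float, lat: float) -> bool:
        """True iff (lon, lat) falls in a wet cell; out-of-domain is dry."""
        try:
            j, i = self.nearest_cell(lon, lat)
        except OutOfDomainError:
            return False
        return bool(self.wet_mask[j, i])

    # ------------------------------------------------------------------
    # interpolation
    # ------------------------------------------------------------------

    def _interp(self, var: np.ndarray, lon: float, lat: float, depth: float,
                time: float, dry_zero: bool) -> float:
        """Tri(+time)-linear interpolation of ``var``.

        ``dry_zero``: dry nodes contribute 0 (free-slip; used for velocity);
        otherwise weights are renormalized over wet nodes (temperature).
        """
        g = self.grid
        i0, i1, wx = self._axis_bracket(g.lons, lon, "lon")
        j0, j1, wy = self._axis_bracket(g.lats, lat, "lat")
        k0, k1, wz = self._depth_bracket(depth)
        t0, t1, wt = self._time_bracket(time)
        if not self.is_wet(lon, lat):
            raise DryCellError(f"({lon}, {lat}) is a dry cell")

        js = np.array([j0, j0, j1, j1])
        is_ = np.array([i0, i1, i0, i1])
        w_horiz = np.array([(1 - wx) * (1 - wy), wx * (1 - wy),
                            (1 - wx) * wy, wx * wy])
        wet = self.wet_mask[js, is_]

        def plane(t_idx: int, k_idx: int) -> float:
            vals = var[t_idx, k_idx, js, is_]
            if dry_zero:
                vals = np.where(wet, vals, 0.0)
                return float(np.dot(w_horiz, vals))
            w = w_horiz * wet
            tot = w.sum()
            if tot == 0.0:
                raise DryCellError(f"no wet nodes around ({lon}, {lat})")
            return float(np.dot(w / tot, vals[:]))

        def level(t_idx: int) -> float:
            a = plane(t_idx, k0)
            if k1 == k0:
                return a
            return (1 - wz) * a + wz * plane(t_idx, k1)

        a = level(t0)
        if t1 == t0:
            return a
        return (1 - wt) * a + wt * level(t1)

    def sample_uv(self, lon: float, lat: float, depth: float, time: float) -> tuple[float, float]:
        """Interpolated (u, v) in m/s at a point; dry neighbors contribute 0."""
        return (self._interp(self.u, lon, lat, depth, time, dry_zero=True),
                self._interp(self.v, lon, lat, depth, time, dry_zero=True))

    def sample_temp(self, lon: float, lat: float, depth: float, time: float) -> float:
        """Interpolated temperature in deg C at a point."""
        return self._interp(self.temperature, lon, lat, depth, time, dry_zero=False)

    # ------------------------------------------------------------------
    # vectorized sampling (particle cohorts)
    # ------------------------------------------------------------------

    def _interp_arrays(self, var: np.ndarray, lon: np.ndarray, lat: np.ndarray,
                       depth: np.ndarray, time: float, dry_zero: bool):
        """Vectorized counterpart of :meth:`_interp` for particle cohorts.

        Returns (values, in_domain).  Out-of-domain points yield NaN with
        ``in_domain`` False; dry-surrounded points yield 0 (velocity) or
        NaN (temperature) but remain in-domain.
        """
        g = self.grid
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        in_dom = ((lon >= g.lons[0]) & (lon <= g.lons[-1])
                  & (lat >= g.lats[0]) & (lat <= g.lats[-1]))
        lon_s = np.where(in_dom, lon, g.lons[0])
        lat_s = np.where(in_dom, lat, g.lats[0])

        fx = (lon_s - g.lons[0]) / g.d_lon
        fy = (lat_s - g.lats[0]) / g.d_lat
        i0 = np.clip(np.floor(fx).astype(int), 0, len(g.lons) - 2)
        j0 = np.clip(np.floor(fy).astype(int), 0, len(g.lats) - 2)
        wx = fx - i0
        wy = fy - j0

        levels = np.asarray(g.depth_levels)
        dclip = np.clip(np.asarray(depth, dtype=float), levels[0], levels[-1])
        if len(levels) == 1:
            kk0 = np.zeros_like(i0)
            kk1 = kk0
            wzz = np.zeros(lon_s.shape)
        else:
            kk0 = np.clip(np.searchsorted(levels, dclip, side="right") - 1,
                          0, len(levels) - 2)
            kk1 = kk0 + 1
            wzz = (dclip - levels[kk0]) / (levels[kk1] - levels[kk0])
        t0, t1, wt = self._time_bracket(float(time))

        def plane(t_idx, k_idx):
            tot = np.zeros(lon_s.shape)
            wsum = np.zeros(lon_s.shape)
            for dj, di, w in (
                (0, 0, (1 - wx) * (1 - wy)), (0, 1, wx * (1 - wy)),
                (1, 0, (1 - wx) * wy), (1, 1, wx * wy),
            ):
                jj, ii = j0 + dj, i0 + di
                wet = self.wet_mask[jj, ii]
                vals = var[t_idx][k_idx, jj, ii]
                if dry_zero:
                    tot += w * np.where(wet, vals, 0.0)
                    wsum += w
                else:
                    tot += np.where(wet, w * vals, 0.0)
                    wsum += np.where(wet, w, 0.0)
            if dry_zero:
                return tot
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(wsum > 0, tot / wsum, np.nan)

        def level(t_idx):
            a = plane(t_idx, kk0)
            if len(levels) == 1:
                return a
            return (1 - wzz) * a + wzz * plane(t_idx, kk1)

        vals = level(t0)
        if t1 != t0:
            vals = (1 - wt) * vals + wt * level(t1)
        return np.where(in_dom, vals, np.nan), in_dom

    def sample_uv_arrays(self, lon, lat, depth, time: float):
        """(u, v, in_domain) for arrays of positions at one instant."""
        u, in_dom = self._interp_arrays(self.u, lon, lat, depth, time, dry_zero=True)
        v, _ = self._interp_arrays(self.v, lon, lat, depth, time, dry_zero=True)
        return u, v, in_dom

    def sample_temp_arrays(self, lon, lat, depth, time: float):
        """(temperature, in_domain) for arrays of positions at one instant."""
        return self._interp_arrays(self.temperature, lon, lat, depth, time,
                                   dry_zero=False)


# Module-level functional aliases mirroring the operation names.

def sample_uv(field: OceanField, lon: float, lat: float, depth: float, time: float):
    return field.sample_uv(lon, lat, depth, time)


def sample_temp(field: OceanField, lon: float, lat: float, depth: float, time: float):
    return field.sample_temp(lon, lat, depth, time)


def is_wet(field: OceanField, lon: float, lat: float) -> bool:
    return field.is_wet(lon, lat)


# ----------------------------------------------------------------------
# NetCDF I/O
# ----------------------------------------------------------------------

_REQUIRED_VARS = ("u", "v", "temp", "wet_mask")


def write_field(ocean: OceanField, path) -> None:
    """Write an :class:`OceanField` to NetCDF (land filled with 1e20)."""
    g = ocean.grid
    land = ~ocean.wet_mask

    def masked(arr: np.ndarray) -> np.ndarray:
        out = arr.copy()
        out[:, :, land] = FILL_VALUE
        return out

    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), masked(ocean.u)),
            "v": (("time", "depth", "lat", "lon"), masked(ocean.v)),
            "temp": (("time", "depth", "lat", "lon"), masked(ocean.temperature)),
            "wet_mask": (("lat", "lon"), ocean.wet_mask.astype(np.int8)),
        },
        coords={
            "time": g.times,
            "depth": np.asarray(g.depth_levels, dtype=float),
            "lat": g.lats,
            "lon": g.lons,
        },
        attrs={"time_origin": g.time_origin.isoformat(),
               "d_lon": g.d_lon, "d_lat": g.d_lat,
               "lon_min": g.lon_min, "lon_max": g.lon_max,
               "lat_min": g.lat_min, "lat_max": g.lat_max},
    )
    ds.to_netcdf(path, engine="scipy")


def load_field(path) -> OceanField:
    """Read a NetCDF file written per the package's field layout."""
    with xr.open_dataset(path, engine="scipy", mask_and_scale=False) as ds:
        for name in _REQUIRED_VARS:
            if name not in ds:
                raise FieldFormatError(f"missing variable '{name}'")
        for name in ("u", "v", "temp"):
            if ds[name].dims != ("time", "depth", "lat", "lon"):
                raise FieldFormatError(
                    f"variable '{name}' has dims {ds[name].dims}, "
                    "expected (time, depth, lat, lon)")
        lons = ds["lon"].values
        lats = ds["lat"].values
        if len(lons) < 2 or len(lats) < 2:
            raise FieldFormatError("grid must have at least 2 nodes per horizontal axis")
        grid = GridSpec(
            lon_min=float(ds.attrs.get("lon_min", lons[0])),
            lon_max=float(ds.attrs.get("lon_max", lons[-1])),
            lat_min=float(ds.attrs.get("lat_min", lats[0])),
            lat_max=float(ds.attrs.get("lat_max", lats[-1])),
            d_lon=float(ds.attrs.get("d_lon", lons[1] - lons[0])),
            d_lat=float(ds.attrs.get("d_lat", lats[1] - lats[0])),
            depth_levels=tuple(float(z) for z in ds["depth"].values),
            time_origin=datetime.date.fromisoformat(ds.attrs["time_origin"]),
            n_days=ds.sizes["time"],
        )
        wet = ds["wet_mask"].values.astype(bool)
        arrs = {}
        for name in ("u", "v", "temp"):
            arr = ds[name].values.astype(float)
            arr[np.abs(arr) >= FILL_VALUE / 2] = 0.0  # land fill -> harmless zero
            arr[:, :, ~wet] = 0.0
            arrs[name] = arr
    return OceanField(grid=grid, u=arrs["u"], v=arrs["v"],
                      temperature=arrs["temp"], wet_mask=wet)
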