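"""Climate covariates for specimen localities.

Turns a monthly climate grid plus a specimen's locality and collection
date into the five model covariates:

* ``mean_temp`` / ``temp_sd`` — mean and sample SD (°C) of the 25
  buffer-averaged monthly mean temperatures for the summer months
  (April–August) of the 5 calendar years before collection;
* ``recent_precip`` — mean monthly precipitation (mm) over the summer of
  the calendar year immediately prior to collection;
* ``rel_min_temp`` / ``rel_max_temp`` — relative temperature extremity
  (RTE): the prior-year summer mean of the monthly minimum (maximum)
  temperature, minus the 5-year mean of those yearly summer means,
  divided by their standard deviation.  Dimensionless, comparable across
  climates; positive values mean the variable was unusually high.

Buffer values are means over grid cells whose centers fall within a
great-circle radius (default 15 km) of the locality; cells are equally
weighted and missing (NaN) cells are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ClimateGrid",
    "SummerSeries",
    "CovariateConfig",
    "buffer_mean",
    "extract_summer_series",
    "mean_temperature",
    "temperature_sd",
    "recent_precipitation",
    "relative_extremity",
    "covariates_for_specimens",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088
CLIMATE_VARIABLES = ("tmin", "tmax", "tmean", "precip")
SUMMER_MONTHS = (4, 5, 6, 7, 8)


class ClimateCovariateError(ValueError):
    """Base class for extraction failures."""


class OutsideExtentError(ClimateCovariateError):
    pass


class EmptyBufferError(ClimateCovariateError):
    pass


class IncompleteCoverageError(ClimateCovariateError):
    pass


class DegenerateClimateError(ClimateCovariateError):
    """Raised when the RTE denominator SD is zero (constant climate)."""


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a WGS84 sphere (R = 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class ClimateGrid:
    """Monthly gridded climate on a regular WGS84 lat/lon grid.

    Wraps an :class:`xarray.Dataset` with dims ``(year, month, lat, lon)``
    and variables ``tmin, tmax, tmean`` (°C) and ``precip`` (mm/month).
    The month axis is the complete 1..12; the year axis is contiguous.
    """

    def __init__(self, ds: xr.Dataset, validate: bool = True):
        for v in CLIMATE_VARIABLES:
            if v not in ds:
                raise ValueError(f"missing climate variable {v!r}")
            if tuple(ds[v].dims) != ("year", "month", "lat", "lon"):
                raise ValueError(f"{v} must have dims (year, month, lat, lon)")
        self.ds = ds
        self.years = np.asarray(ds["year"].values, dtype=int)
        self.months = np.asarray(ds["month"].values, dtype=int)
        self.lats = np.asarray(ds["lat"].values, dtype=float)
        self.lons = np.asarray(ds["lon"].values, dtype=float)
        if not np.array_equal(self.months, np.arange(1, 13)):
            raise ValueError("month axis must be the complete 1..12")
        if not np.array_equal(self.years, np.arange(self.years[0], self.years[-1] + 1)):
            raise ValueError("year axis must be contiguous")
        for ax, name in ((self.lats, "lat"), (self.lons, "lon")):
            if len(ax) < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            if not np.allclose(np.diff(ax), ax[1] - ax[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"{name} axis must be regular")
        self._arrays: dict[str, np.ndarray] = {}
        if validate:
            tmin, tmean, tmax = (self._array(v) for v in ("tmin", "tmean", "tmax"))
            if np.nanmax(tmin - tmean) > 1e-6 or np.nanmax(tmean - tmax) > 1e-6:
                raise ValueError("ordering tmin <= tmean <= tmax violated")
            if np.nanmin(self._array("precip")) < 0:
                raise ValueError("negative precipitation")

    # -- raw access -----------------------------------------------------

    def _array(self, variable: str) -> np.ndarray:
        if variable not in self._arrays:
            self._arrays[variable] = np.asarray(self.ds[variable].values, dtype=float)
        return self._arrays[variable]

    @property
    def cell_size(self) -> float:
        return float(self.lats[1] - self.lats[0])

    def contains(self, lat: float, lon: float) -> bool:
        half = self.cell_size / 2.0
        return (
            self.lats[0] - half <= lat <= self.lats[-1] + half
            and self.lons[0] - half <= lon <= self.lons[-1] + half
        )

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Index of the grid cell containing (or nearest to) the point."""
        if not self.contains(lat, lon):
            raise OutsideExtentError(f"point ({lat:.4f}, {lon:.4f}) outside grid extent")
        return int(np.argmin(np.abs(self.lats - lat))), int(np.argmin(np.abs(self.lons - lon)))

    def cells_within(self, lat: float, lon: float, radius_km: float) -> tuple[np.ndarray, np.ndarray]:
        """Indices (lat_idx, lon_idx) of cells whose centers lie within radius_km."""
        if radius_km < 0:
            raise ValueError("radius_km must be >= 0")
        if not self.contains(lat, lon):
            raise OutsideExtentError(f"point ({lat:.4f}, {lon:.4f}) outside grid extent")
        if radius_km == 0:
            i, j = self.cell_index(lat, lon)
            return np.array([i]), np.array([j])
        # candidate window in degrees, padded by one cell
        dlat = radius_km / 110.574 + self.cell_size
        coslat = max(np.cos(np.radians(lat)), 1e-6)
        dlon = radius_km / (111.320 * coslat) + self.cell_size
        li = np.nonzero(np.abs(self.lats - lat) <= dlat)[0]
        lj = np.nonzero(np.abs(self.lons - lon) <= dlon)[0]
        if len(li) == 0 or len(lj) == 0:
            raise EmptyBufferError(
                f"no grid cells within {radius_km} km of ({lat:.4f}, {lon:.4f})"
            )
        glat, glon = np.meshgrid(self.lats[li], self.lons[lj], indexing="ij")
        dist = haversine_km(lat, lon, glat, glon)
        ii, jj = np.nonzero(dist <= radius_km)
        if len(ii) == 0:
            raise EmptyBufferError(
                f"no cell centers within {radius_km} km of ({lat:.4f}, {lon:.4f})"
            )
        return li[ii], lj[jj]

    # -- IO ---------------------------------------------------------------

    UNITS = {"tmin": "degC", "tmax": "degC", "tmean": "degC", "precip": "mm/month"}

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        for v in CLIMATE_VARIABLES:
            ds[v] = ds[v].astype("float32")
            ds[v].attrs["units"] = self.UNITS[v]
        ds.attrs["crs"] = "WGS84 decimal degrees"
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())


@dataclass
class SummerSeries:
    """Buffer-averaged monthly climate for one specimen.

    ``data[var]`` is a (years_back, n_months) matrix; row 0 is year
    offset 1 = calendar year (collection year − 1), row i-1 is offset i.
    """

    collection_year: int
    years: np.ndarray  # calendar years, offset order (cy-1, cy-2, ...)
    months: tuple[int, ...]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def require_complete(self) -> None:
        for v, m in self.data.items():
            if m.shape != (len(self.years), len(self.months)):
                raise ValueError(f"{v}: malformed series shape {m.shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{v}: missing values in summer series")


def buffer_mean(
    grid: ClimateGrid,
    lat: float,
    lon: float,
    radius_km: float,
    variable: str,
    year: int,
    month: int,
) -> float:
    """Mean of `variable` over cells within `radius_km` of the point.

    Cell centers within the great-circle radius are equally weighted;
    NaN cells are excluded.  ``radius_km = 0`` returns the containing
    cell's value.
    """
    if variable not in CLIMATE_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if year not in grid.years:
        raise IncompleteCoverageError(f"year {year} not covered by grid")
    li, lj = grid.cells_within(lat, lon, radius_km)
    yi = int(year - grid.years[0])
    vals = grid._array(variable)[yi, month - 1, li, lj]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise EmptyBufferError(
            f"all cells missing for {variable} at ({lat:.4f}, {lon:.4f}), {year}-{month:02d}"
        )
    return float(vals.mean())


def extract_summer_series(
    grid: ClimateGrid,
    lat: float,
    lon: float,
    collection_year: int,
    radius_km: float = 15.0,
    years_back: int = 5,
    months: tuple[int, ...] = SUMMER_MONTHS,
) -> SummerSeries:
    """Buffer-averaged monthly values for the `years_back` calendar years
    before collection, for the given months, for all four variables."""
    years = np.array([collection_year - i for i in range(1, years_back + 1)])
    missing = [
        (int(y), int(m)) for y in years for m in months if y not in grid.years
    ]
    if missing:
        raise IncompleteCoverageError(
            f"grid does not cover (year, month) pairs: {sorted(set(missing))}"
        )
    li, lj = grid.cells_within(lat, lon, radius_km)
    yidx = (years - grid.years[0]).astype(int)
    midx = np.asarray(months, dtype=int) - 1
    nlon = len(grid.lons)
    flat = li * nlon + lj
    out = SummerSeries(collection_year=int(collection_year), years=years, months=tuple(months))
    for v in CLIMATE_VARIABLES:
        a = grid._array(v).reshape(len(grid.years), 12, -1)
        block = a[np.ix_(yidx, midx, flat)]
        with np.errstate(invalid="ignore"):
            vals = np.nanmean(block, axis=2)
        if not np.all(np.isfinite(vals)):
            raise EmptyBufferError(f"all cells missing for {v} in buffer")
        out.data[v] = vals
    return out


def mean_temperature(series: SummerSeries) -> float:
    """Mean of the 25 monthly mean temperatures (°C)."""
    series.require_complete()
    return float(series.data["tmean"].mean())


def temperature_sd(series: SummerSeries) -> float:
    """Sample SD (n−1) of the 25 monthly mean temperatures (°C)."""
    series.require_complete()
    return float(series.data["tmean"].std(ddof=1))


def recent_precipitation(series: SummerSeries) -> float:
    """Mean monthly precipitation over the summer of the prior calendar year."""
    series.require_complete()
    return float(series.data["precip"][0].mean())


def relative_extremity(series: SummerSeries, which: str = "min", sd_mode: str = "yearly") -> float:
    """Relative temperature extremity (RTE), dimensionless.

    RTE = (prior-year summer mean − mean of the 5 yearly summer means)
    divided by a standard deviation.  ``sd_mode='yearly'`` (default)
    uses the sample SD of the 5 yearly summer means, matching the
    summation over yearly terms in the defining formula;
    ``sd_mode='monthly'`` uses the sample SD of all 25 monthly values.
    Invariant under affine transforms (shift + positive scale) of
    temperature.
    """
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    if sd_mode not in ("yearly", "monthly"):
        raise ValueError("sd_mode must be 'yearly' or 'monthly'")
    series.require_complete()
    m = series.data["tmin" if which == "min" else "tmax"]
    yearly = m.mean(axis=1)
    sd = yearly.std(ddof=1) if sd_mode == "yearly" else m.std(ddof=1)
    if sd <= 0:
        raise DegenerateClimateError(
            f"zero SD of t{which} at this locality: constant climate, RTE undefined"
        )
    return float((yearly[0] - yearly.mean()) / sd)


@dataclass(frozen=True)
class CovariateConfig:
    radius_km: float = 15.0
    years_back: int = 5
    months: tuple[int, ...] = SUMMER_MONTHS
    sd_mode: str = "yearly"
    on_reject: str = "fail"  # "fail" | "skip"

    def __post_init__(self):
        if self.on_reject not in ("fail", "skip"):
            raise ValueError("on_reject must be 'fail' or 'skip'")
        if self.sd_mode not in ("yearly", "monthly"):
            raise ValueError("sd_mode must be 'yearly' or 'monthly'")


def covariates_for_specimens(
    grid: ClimateGrid,
    specimens: pd.DataFrame,
    config: CovariateConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One covariate row per specimen; failures go to a rejects report.

    Returns ``(covariates, rejects)``.  Covariate columns:
    ``key, mean_temp, temp_sd, recent_precip, rel_min_temp, rel_max_temp``.
    With ``on_reject='fail'`` (default) any extraction failure raises
    after collecting all failures; with ``'skip'`` the pipeline proceeds
    with the extractable specimens.
    """
    config = config or CovariateConfig()
    rows: list[dict] = []
    rejects: list[dict] = []
    for idx, sp in specimens.iterrows():
        key = sp.get("catalog_id", idx)
        try:
            lat = float(sp["decimal_latitude"])
            lon = float(sp["decimal_longitude"])
            if not grid.contains(lat, lon):
                raise OutsideExtentError("outside extent")
            series = extract_summer_series(
                grid, lat, lon, int(sp["year"]),
                radius_km=config.radius_km,
                years_back=config.years_back,
                months=config.months,
            )
            rows.append(
                {
                    "key": key,
                    "mean_temp": mean_temperature(series),
                    "temp_sd": temperature_sd(series),
                    "recent_precip": recent_precipitation(series),
                    "rel_min_temp": relative_extremity(series, "min", config.sd_mode),
                    "rel_max_temp": relative_extremity(series, "max", config.sd_mode),
                }
            )
        except ClimateCovariateError as exc:
            reason = "outside extent" if isinstance(exc, OutsideExtentError) else str(exc)
            rejects.append({"key": key, "reason": reason})
    cov_cols = ["key", "mean_temp", "temp_sd", "recent_precip", "rel_min_temp", "rel_max_temp"]
    cov = pd.DataFrame(rows, columns=cov_cols)
    rej = pd.DataFrame(rejects, columns=["key", "reason"])
    if len(rej) and config.on_reject == "fail":
        raise ClimateCovariateError(
            f"{len(rej)} specimens failed covariate extraction: "
            + "; ".join(f"{r['key']}: {r['reason']}" for r in rejects[:10])
        )
    return cov, rej
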