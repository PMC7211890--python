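"""Synthetic climate grids and specimen tables with known generative
parameters.

The generator emulates the two inputs of the analysis so that every
downstream stage (covariate extraction, GAMM fit, diagnostics) can be
exercised with a known ground truth:

* a PRISM-like monthly climate grid (~0.04° cells) over a
  California-like latitudinal extent, with a deterministic
  latitude-driven temperature trend, a seasonal sinusoid, year-level
  interannual anomalies shared by all months of a year, and cell-month
  noise.  Minimum and maximum temperature are the mean temperature
  minus/plus a positive diurnal half-range (with its own year-level
  anomalies, so relative minimum and maximum extremity are not
  perfectly collinear), which guarantees tmin ≤ tmean ≤ tmax exactly;

* a specimen table whose bill surface area follows the fitted model
  structure: SA = x'β (the full fixed-effect design, interactions
  included) + a smooth spatial surface + a year random intercept +
  Gaussian residual.  Bill length/width/depth are back-solved from SA
  using fixed subspecies aspect ratios, so recomputing SA from the
  stored linear measurements reproduces the generated response.

Default coefficients and variance components are the headline estimates
of the analysis this package reimplements; climate-field defaults are
chosen so the derived covariates land in realistic ranges (5-year mean
summer temperature roughly 10–19 °C across the extent, prior-summer
precipitation with 10th/90th percentiles near 4 and 61 mm/month).
All generation is a pure function of (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import xarray as xr

from . import morphometry
from .climate_covariates import ClimateGrid, CovariateConfig, covariates_for_specimens

__all__ = [
    "GenerativeParams",
    "DEFAULT_COEFFICIENTS",
    "generate_climate_grid",
    "generate_specimens",
    "simulate_dataset",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

SCHEMA_VERSION = 1

#: Default fixed-effect coefficients (response: bill surface area, mm²).
#: Keys match the design-column names of the fitted model.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": 90.0,
    "rel_min_temp": -5.22,
    "rel_max_temp": 3.80,
    "mean_temp": 0.02,
    "rel_min_temp:mean_temp": 1.57,
    "rel_max_temp:mean_temp": -1.25,
    "temp_sd": 0.27,
    "recent_precip": -0.02,
    "rel_min_temp:recent_precip": 0.20,
    "rel_max_temp:recent_precip": -0.17,
    "month": -0.04,
    "subspecies_thurberi": -3.06,
    "tarsus_mm": 1.58,
    "sex_male": 1.59,
}


@dataclass
class GenerativeParams:
    """Ground-truth parameters for grid and specimen generation."""

    # sampling design
    n: int = 516
    seed: int = 0
    first_year: int = 1900
    last_year: int = 1950

    # spatial extent (WGS84 decimal degrees) and resolution
    lat_min: float = 34.0
    lat_max: float = 40.0
    lon_min: float = -123.0
    lon_max: float = -118.0
    cell_size: float = 0.04
    locality_margin: float = 0.2  # keep buffers inside the grid
    sampling: str = "uniform"  # "uniform" | "clustered"
    n_clusters: int = 8
    cluster_sd: float = 0.3  # degrees

    # climate field (°C, mm/month)
    base_temp: float = 14.3  # annual-mean level at lat_min
    lat_gradient: float = -1.6  # °C per degree northward
    seasonal_amplitude: float = 8.0
    seasonal_peak_month: int = 7
    anomaly_sd: float = 0.75  # year-level tmean anomaly, shared across months
    noise_sd: float = 0.5  # independent cell-month noise
    diurnal_half_range: float = 6.0
    half_range_anomaly_sd: float = 0.4  # year-level, separate for tmin and tmax
    precip_base: float = 18.0
    precip_year_log_sd: float = 1.0  # year-level log-normal anomaly
    precip_month_log_sd: float = 0.3
    precip_cell_log_sd: float = 0.15

    # response model (SA in mm²)
    coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    year_variance: float = 0.713
    residual_variance: float = 28.972
    spatial_amplitude: float = 3.0

    # specimen attributes
    p_male: float = 0.5
    p_thurberi: float = 0.6
    tarsus_mean: float = 20.5
    tarsus_sd: float = 0.8
    wing_mean: float = 76.0
    wing_sd: float = 3.0
    # subspecies -> (width/length, depth/length)
    aspect_ratios: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"pinosus": (0.5, 0.55), "thurberi": (0.5, 0.55)}
    )

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("year_variance", "residual_variance", "anomaly_sd", "noise_sd",
                     "half_range_anomaly_sd", "precip_year_log_sd", "precip_month_log_sd",
                     "precip_cell_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("non-positive grid extent")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.last_year < self.first_year:
            raise ValueError("last_year before first_year")
        if self.sampling not in ("uniform", "clustered"):
            raise ValueError("sampling must be 'uniform' or 'clustered'")

    @property
    def grid_first_year(self) -> int:
        """Grid span starts 6 years before the first collection year."""
        return self.first_year - 6


def _seasonal(months: np.ndarray, params: GenerativeParams) -> np.ndarray:
    return params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (months - params.seasonal_peak_month) / 12.0
    )


def generate_climate_grid(
    params: GenerativeParams, rng: np.random.Generator | None = None
) -> ClimateGrid:
    """Generate the monthly climate grid for the full required span.

    Each variable is a deterministic latitude/seasonal trend plus a
    year-level anomaly (shared by all months within the year) plus
    cell-month noise.  tmin/tmax are tmean ∓ a positive half-range, so
    the ordering invariant holds everywhere by construction.
    """
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    years = np.arange(params.grid_first_year, params.last_year + 1)
    months = np.arange(1, 13)
    nlat = int(round((params.lat_max - params.lat_min) / params.cell_size))
    nlon = int(round((params.lon_max - params.lon_min) / params.cell_size))
    if nlat < 1 or nlon < 1:
        raise ValueError("non-positive grid dimensions")
    lats = params.lat_min + params.cell_size * (0.5 + np.arange(nlat))
    lons = params.lon_min + params.cell_size * (0.5 + np.arange(nlon))
    ny = len(years)
    shape = (ny, 12, nlat, nlon)

    trend = (
        params.base_temp
        + params.lat_gradient * (lats - params.lat_min)[None, None, :, None]
        + _seasonal(months, params)[None, :, None, None]
    ).astype(np.float32)
    a_year = (params.anomaly_sd * rng.standard_normal(ny)).astype(np.float32)
    noise = rng.standard_normal(shape, dtype=np.float32) * np.float32(params.noise_sd)
    tmean = trend + a_year[:, None, None, None] + noise

    def half_range() -> np.ndarray:
        h_year = params.half_range_anomaly_sd * rng.standard_normal(ny)
        h = (
            params.diurnal_half_range
            + h_year[:, None, None, None]
            + 0.5 * params.noise_sd * rng.standard_normal(shape)
        )
        return np.maximum(h, 0.05).astype(np.float32)

    tmin = tmean - half_range()
    tmax = tmean + half_range()

    # year/month log-anomalies truncated at 2.5 sigma: preserves the target
    # 10th-90th percentile spread while avoiding implausible precip extremes
    p_year = params.precip_year_log_sd * np.clip(rng.standard_normal(ny), -2.5, 2.5)
    p_month = params.precip_month_log_sd * np.clip(rng.standard_normal((ny, 12)), -2.5, 2.5)
    p_cell = params.precip_cell_log_sd * rng.standard_normal(shape).astype(np.float32)
    precip = (
        params.precip_base
        * np.exp(p_year[:, None, None, None] + p_month[:, :, None, None] + p_cell)
    ).astype(np.float32)

    ds = xr.Dataset(
        {
            v: (("year", "month", "lat", "lon"), arr)
            for v, arr in (("tmin", tmin), ("tmax", tmax), ("tmean", tmean), ("precip", precip))
        },
        coords={"year": years, "month": months, "lat": lats, "lon": lons},
    )
    return ClimateGrid(ds, validate=False)


def _linear_predictor(frame: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Fixed-effect linear predictor from the merged specimen/covariate frame."""
    cols = {
        "intercept": 1.0,
        "rel_min_temp": frame["rel_min_temp"],
        "rel_max_temp": frame["rel_max_temp"],
        "mean_temp": frame["mean_temp"],
        "rel_min_temp:mean_temp": frame["rel_min_temp"] * frame["mean_temp"],
        "rel_max_temp:mean_temp": frame["rel_max_temp"] * frame["mean_temp"],
        "temp_sd": frame["temp_sd"],
        "recent_precip": frame["recent_precip"],
        "rel_min_temp:recent_precip": frame["rel_min_temp"] * frame["recent_precip"],
        "rel_max_temp:recent_precip": frame["rel_max_temp"] * frame["recent_precip"],
        "month": frame["month"],
        "subspecies_thurberi": (frame["subspecies"] == "thurberi").astype(float),
        "tarsus_mm": frame["tarsus_mm"],
        "wing_chord_mm": frame["wing_chord_mm"],
        "sex_male": (frame["sex"] == "male").astype(float),
    }
    lp = np.zeros(len(frame))
    for name, beta in coefs.items():
        if name not in cols:
            raise KeyError(f"unknown coefficient {name!r}")
        lp = lp + beta * np.asarray(cols[name], dtype=float)
    return lp


def spatial_surface(lat, lon, params: GenerativeParams) -> np.ndarray:
    """Smooth deterministic spatial effect on SA (mm²), amplitude-scaled.

    One full sine/cosine period across the extent: genuinely nonlinear
    (not absorbable by the smooth's {1, lat, lon} null space), gentle
    enough for a moderate thin-plate basis to capture.
    """
    u = (np.asarray(lat, float) - params.lat_min) / (params.lat_max - params.lat_min)
    v = (np.asarray(lon, float) - params.lon_min) / (params.lon_max - params.lon_min)
    return params.spatial_amplitude * np.sin(2.0 * np.pi * u) * np.cos(2.0 * np.pi * v)


def _back_solve_bill(sa: np.ndarray, ratios: np.ndarray) -> tuple[np.ndarray, ...]:
    """Solve bill (l, w, d) from SA given per-specimen (w/l, d/l) ratios.

    With c = (w/l + d/l)/4, SA = π·c·sqrt(c²+1)·l², so the single scale
    factor l is recovered in closed form.
    """
    c = (ratios[:, 0] + ratios[:, 1]) / 4.0
    l = np.sqrt(sa / (np.pi * c * np.sqrt(c * c + 1.0)))
    return l, ratios[:, 0] * l, ratios[:, 1] * l


def _draw_attributes(grid: ClimateGrid, params: GenerativeParams, rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Draw localities, dates and individual attributes for n specimens."""
    lo_lat = params.lat_min + params.locality_margin
    hi_lat = params.lat_max - params.locality_margin
    lo_lon = params.lon_min + params.locality_margin
    hi_lon = params.lon_max - params.locality_margin
    if params.sampling == "uniform":
        lat = rng.uniform(lo_lat, hi_lat, n)
        lon = rng.uniform(lo_lon, hi_lon, n)
    else:
        centers = np.column_stack(
            [rng.uniform(lo_lat, hi_lat, params.n_clusters), rng.uniform(lo_lon, hi_lon, params.n_clusters)]
        )
        pick = rng.integers(0, params.n_clusters, n)
        lat = np.clip(centers[pick, 0] + params.cluster_sd * rng.standard_normal(n), lo_lat, hi_lat)
        lon = np.clip(centers[pick, 1] + params.cluster_sd * rng.standard_normal(n), lo_lon, hi_lon)
    for la, lo in zip(lat, lon):
        if not grid.contains(la, lo):
            raise ValueError(f"requested locality ({la}, {lo}) outside grid")
    years = rng.integers(params.first_year, params.last_year + 1, n)
    dates = []
    for y in years:
        start = date(int(y), 3, 15)
        span = (date(int(y), 9, 30) - start).days
        dates.append(start + timedelta(days=int(rng.integers(0, span + 1))))
    return pd.DataFrame(
        {
            "decimal_latitude": lat,
            "decimal_longitude": lon,
            "event_date": [d.isoformat() for d in dates],
            "year": years,
            "month": [d.month for d in dates],
            "sex": np.where(rng.random(n) < params.p_male, "male", "female"),
            "subspecies": np.where(rng.random(n) < params.p_thurberi, "thurberi", "pinosus"),
            "tarsus_mm": np.maximum(params.tarsus_mean + params.tarsus_sd * rng.standard_normal(n), 1.0),
            "wing_chord_mm": np.maximum(params.wing_mean + params.wing_sd * rng.standard_normal(n), 1.0),
        }
    )


def _lp_for(df: pd.DataFrame, grid: ClimateGrid, params: GenerativeParams,
            year_effects: pd.Series) -> tuple[np.ndarray, pd.DataFrame]:
    """Linear predictor (fixed + surface + year effect) and covariates,
    aligned positionally with df."""
    work = df.reset_index(drop=True).copy()
    work["catalog_id"] = np.arange(len(work))
    cov, _ = covariates_for_specimens(grid, work, CovariateConfig(on_reject="fail"))
    frame = work.merge(cov, left_on="catalog_id", right_on="key")
    lp = _linear_predictor(frame, params.coefficients)
    lp = lp + spatial_surface(frame["decimal_latitude"], frame["decimal_longitude"], params)
    lp = lp + year_effects.loc[frame["year"]].to_numpy()
    return lp, cov.drop(columns="key")


def generate_specimens(
    grid: ClimateGrid,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the specimen table from the response model.

    Returns ``(specimens, info)``; ``info`` carries the realized
    per-year random effects, the covariate table used to build the
    response, and the counts of redraws needed to keep SA > 0
    (residual redraws first; a specimen whose linear predictor leaves
    no room for a positive response is redrawn entirely, so the output
    is the generative distribution conditioned on SA > 0).
    """
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    if grid.years[0] > params.first_year - 5:
        raise ValueError(
            "grid span too short: must start at least 5 years before the first collection year"
        )
    n = params.n
    all_years = np.arange(params.first_year, params.last_year + 1)
    u = np.sqrt(params.year_variance) * rng.standard_normal(len(all_years))
    year_effects = pd.Series(u, index=all_years, name="year_effect")

    df = _draw_attributes(grid, params, rng, n)
    lp, cov = _lp_for(df, grid, params, year_effects)
    resid_sd = np.sqrt(params.residual_variance)
    sa = lp + resid_sd * rng.standard_normal(n)

    n_resampled = 0
    n_redrawn = 0
    tries = 0
    while (sa <= 0).any():
        tries += 1
        if tries > 60:
            raise ValueError("could not keep SA positive; check coefficient/variance scales")
        bad = np.nonzero(sa <= 0)[0]
        if tries % 4 != 0:
            n_resampled += len(bad)
            sa[bad] = lp[bad] + resid_sd * rng.standard_normal(len(bad))
        else:
            # residual redraws cannot rescue a non-positive linear
            # predictor: redraw those specimens entirely
            n_redrawn += len(bad)
            repl = _draw_attributes(grid, params, rng, len(bad))
            for c in df.columns:
                df.loc[df.index[bad], c] = repl[c].to_numpy()
            lp_new, cov_new = _lp_for(repl, grid, params, year_effects)
            lp[bad] = lp_new
            cov.iloc[bad] = cov_new.to_numpy()
            sa[bad] = lp[bad] + resid_sd * rng.standard_normal(len(bad))
    if n_resampled or n_redrawn:
        warnings.warn(
            f"kept SA > 0 via {n_resampled} residual redraws and {n_redrawn} specimen redraws",
            RuntimeWarning,
        )
    df.insert(0, "catalog_id", [f"SYN-{i:05d}" for i in range(n)])
    cov.insert(0, "key", df["catalog_id"].to_numpy())

    ratios = np.array([params.aspect_ratios[s] for s in df["subspecies"]])
    l, w, d = _back_solve_bill(sa, ratios)
    df["bill_length_mm"] = l
    df["bill_width_mm"] = w
    df["bill_depth_mm"] = d

    info = {
        "year_effects": year_effects,
        "covariates": cov,
        "surface": spatial_surface(
            df["decimal_latitude"].to_numpy(), df["decimal_longitude"].to_numpy(), params
        ),
        "sa": sa,
        "n_resampled": n_resampled,
        "n_redrawn": n_redrawn,
    }
    return df, info


def simulate_dataset(
    params: GenerativeParams | None = None, seed: int | None = None
) -> tuple[ClimateGrid, pd.DataFrame, dict]:
    """Grid + specimens in one call; `seed` overrides `params.seed`."""
    params = params or GenerativeParams()
    if seed is not None:
        params = dataclasses.replace(params, seed=int(seed))
    rng = np.random.default_rng(params.seed)
    grid = generate_climate_grid(params, rng)
    specimens, info = generate_specimens(grid, params, rng)
    return grid, specimens, info


# ---------------------------------------------------------------------------
# fixture bundle IO
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    grid: ClimateGrid,
    specimens: pd.DataFrame,
    params: GenerativeParams,
    path,
) -> dict[str, str]:
    """Write climate NetCDF + specimen CSV + ground-truth JSON sidecar."""
    from pathlib import Path

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "climate": str(out / "climate.nc"),
        "specimens": str(out / "specimens.csv"),
        "params": str(out / "params.json"),
    }
    grid.to_netcdf(paths["climate"])
    specimens.to_csv(paths["specimens"], index=False)
    payload = {"schema_version": SCHEMA_VERSION, "params": dataclasses.asdict(params)}
    with open(paths["params"], "w") as fh:
        json.dump(payload, fh, indent=2, default=list)
    return paths


def read_fixture_bundle(path) -> tuple[ClimateGrid, pd.DataFrame, GenerativeParams]:
    from pathlib import Path

    p = Path(path)
    grid = ClimateGrid.from_netcdf(p / "climate.nc")
    specimens = pd.read_csv(p / "specimens.csv")
    with open(p / "params.json") as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported sidecar schema: {payload.get('schema_version')}")
    raw = payload["params"]
    raw["aspect_ratios"] = {k: tuple(v) for k, v in raw["aspect_ratios"].items()}
    params = GenerativeParams(**raw)
    return grid, specimens, params
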