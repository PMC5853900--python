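"""Environmental variables at occurrence points.

Looks up direct raster layers at cleaned occurrence coordinates and derives
the bioclim-style summaries used by the analysis from monthly temperature and
precipitation stacks:

* MAT — mean annual temperature (mean of 12 monthly means, degC);
* MAP — mean annual precipitation (sum of monthly totals, mm);
* growing-season temperature — mean temperature of the wettest quarter, a
  quarter being any 3 consecutive months with December-January wrap-around;
* minimum temperature — coldest monthly value (degC; supply monthly minima to
  get the conventional "minimum temperature of the coldest month");
* minimum precipitation — driest monthly total (mm);
* rainfall seasonality — a 0-100 index of how concentrated rain is in the
  year: 0 for equal rain in all months, 100 when all annual rain falls in a
  single month.  Computed as the annual-total-normalised sum of absolute
  monthly deviations, rescaled so those two endpoints hold exactly:

      SI = 100 * [sum_m |x_m - R/12| / R] / (11/6),   R = sum_m x_m.

Frost days, wet days, sunshine, fire return interval, soil variables and
altitude have no in-package derivation and are accepted as direct layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .occurrence_qc import OccurrenceRecord, retained
from .rasters import EnvGrid, MonthlyStack, check_same_spec

#: Canonical variable order for environment matrices.
VARIABLE_REGISTRY = (
    "MAT",                          # degC
    "MAP",                          # mm
    "growing_season_temperature",   # degC, wettest quarter mean
    "minimum_temperature",          # degC, coldest month
    "frost_days",                   # days / yr (direct layer only)
    "minimum_precipitation",        # mm, driest month
    "wet_days",                     # days / yr (direct layer only)
    "sunshine",                     # % of maximum (direct layer only)
    "rainfall_seasonality",         # index 0-100
    "fire_return_interval",         # index (direct layer only)
    "organic_carbon",               # % weight, topsoil
    "TEB",                          # cmol/kg, total exchangeable bases
    "CEC",                          # cmol/kg, cation exchange capacity
    "pH",                           # -log[H+]
    "altitude",                     # m
)

CLIMATE_VARIABLES = (
    "MAT", "MAP", "growing_season_temperature", "minimum_temperature",
    "frost_days", "minimum_precipitation", "wet_days", "sunshine",
    "rainfall_seasonality", "fire_return_interval",
)
SOIL_VARIABLES = ("organic_carbon", "TEB", "CEC", "pH")

META_COLUMNS = ("taxon", "latitude", "longitude")


def extract_at_points(grid: EnvGrid, points) -> np.ndarray:
    """Values of the containing cell for each (lat, lon); NaN if off-extent/nodata."""
    return np.array([grid.value_at(lat, lon) for lat, lon in points], dtype=float)


def _quarter_sums(layers: np.ndarray) -> np.ndarray:
    """(12, ...) array of 3-month sums for quarters starting at each month."""
    return np.stack([layers[[m, (m + 1) % 12, (m + 2) % 12]].sum(axis=0) for m in range(12)])


def derive_bioclim(temps: MonthlyStack, precs: MonthlyStack) -> dict[str, EnvGrid]:
    """Derive MAT, MAP, wettest-quarter temperature, coldest-month and
    driest-month extremes from aligned monthly stacks.

    Wettest-quarter ties break to the earliest calendar start month.
    """
    spec = check_same_spec(temps.spec, precs.spec)
    t, p = temps.layers, precs.layers
    mat = t.mean(axis=0)
    mapp = p.sum(axis=0)
    qp = _quarter_sums(p)
    qt = _quarter_sums(t) / 3.0
    start = qp.argmax(axis=0)  # argmax takes the first maximum: earliest start
    gst = np.take_along_axis(qt, start[None], axis=0)[0]
    tmin = t.min(axis=0)
    pmin = p.min(axis=0)
    out = {
        "MAT": mat,
        "MAP": mapp,
        "growing_season_temperature": gst,
        "minimum_temperature": tmin,
        "minimum_precipitation": pmin,
    }
    return {name: EnvGrid(spec, name, vals) for name, vals in out.items()}


def rainfall_seasonality(precs: MonthlyStack) -> EnvGrid:
    """Seasonality index grid in [0, 100]; zero-rain cells map to 0."""
    p = precs.layers
    if np.any(p[np.isfinite(p)] < 0):
        raise ValueError("negative monthly precipitation")
    total = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(p - total / 12.0).sum(axis=0)
        si = 100.0 * (dev / total) / (11.0 / 6.0)
    si = np.where(total > 0, si, 0.0)
    return EnvGrid(precs.spec, "rainfall_seasonality", si)


def assemble_env_matrix(
    records, layers: dict[str, EnvGrid]
) -> pd.DataFrame:
    """One row per retained record, one column per supplied registry variable.

    Columns follow the registry order; off-grid/nodata lookups are NaN and are
    serialised as empty CSV fields downstream.
    """
    unknown = set(layers) - set(VARIABLE_REGISTRY)
    if unknown:
        raise ValueError(f"unknown environmental variables: {sorted(unknown)}")
    recs = retained(records)
    points = [(r.latitude, r.longitude) for r in recs]
    data = {
        "taxon": [r.taxon for r in recs],
        "latitude": [r.latitude for r in recs],
        "longitude": [r.longitude for r in recs],
    }
    for name in VARIABLE_REGISTRY:
        if name in layers:
            data[name] = (
                extract_at_points(layers[name], points) if recs else np.array([])
            )
    return pd.DataFrame(data)


def env_variables(matrix: pd.DataFrame) -> list[str]:
    """Registry variables present in an environment matrix, in registry order."""
    return [c for c in matrix.columns if c in VARIABLE_REGISTRY]


def write_env_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=False, float_format="%.12g")


def read_env_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
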