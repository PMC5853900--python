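"""Quality control of georeferenced occurrence records.

Raw aggregator downloads (GBIF-style) carry characteristic errors: impossible
or placeholder coordinates, points in the sea, points geocoded to the
aggregator's headquarters, and repeated records of the same collection. The
cleaning pipeline applies four filters in a fixed order --

    1. coordinate validation (non-finite, out-of-range, or exactly (0, 0));
    2. land-mask test (containing grid cell must be land);
    3. institution proximity (great-circle distance to a configurable centre,
       default GBIF headquarters in Copenhagen, 50 km radius);
    4. per-taxon deduplication at two-decimal-degree resolution (first record
       of each rounded key wins, and keeps the rounded coordinates).

-- and every dropped record keeps exactly one machine-readable reason, so the
report is auditable and the pipeline is idempotent.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default institution-proximity centre: GBIF headquarters, Copenhagen.
GBIF_HEADQUARTERS = (55.6761, 12.5683)
DEFAULT_RADIUS_KM = 50.0
EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

DROP_REASONS = (
    "invalid_coordinate",
    "off_land",
    "institution_proximity",
    "duplicate",
)


@dataclass
class OccurrenceRecord:
    """One georeferenced observation of a taxon, with QC provenance."""

    taxon: str
    latitude: float
    longitude: float
    status: str = "retained"
    drop_reason: str = "none"
    extra: dict = field(default_factory=dict)

    @property
    def retained(self) -> bool:
        return self.status == "retained"


def _drop(rec: OccurrenceRecord, reason: str) -> OccurrenceRecord:
    return replace(rec, status="dropped", drop_reason=reason)


def _is_valid_coord(lat, lon) -> bool:
    try:
        lat = float(lat)
        lon = float(lon)
    except (TypeError, ValueError):
        return False
    if not (math.isfinite(lat) and math.isfinite(lon)):
        return False
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        return False
    if lat == 0.0 and lon == 0.0:  # "null island" placeholder
        return False
    return True


def validate_coordinates(
    records: Sequence[OccurrenceRecord],
) -> list[OccurrenceRecord]:
    """Drop records with missing, non-finite, out-of-range or (0, 0) coordinates."""
    out = []
    for rec in records:
        if rec.retained and not _is_valid_coord(rec.latitude, rec.longitude):
            rec = _drop(rec, "invalid_coordinate")
        out.append(rec)
    return out


def filter_landmass(records: Sequence[OccurrenceRecord], mask) -> list[OccurrenceRecord]:
    """Drop retained records whose containing cell is sea or off the mask extent.

    ``mask`` is a :class:`~c3c4niche.rasters.LandMask`; cell ownership follows
    the raster half-open convention.
    """
    if not mask.values.any():
        warnings.warn("land mask has zero land cells; all records will be dropped")
    out = []
    for rec in records:
        if rec.retained and not mask.is_land(rec.latitude, rec.longitude):
            rec = _drop(rec, "off_land")
        out.append(rec)
    return out


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a spherical Earth."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def filter_institution_proximity(
    records: Sequence[OccurrenceRecord],
    center: tuple[float, float] = GBIF_HEADQUARTERS,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> list[OccurrenceRecord]:
    """Drop retained records within ``radius_km`` great-circle km of ``center``."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    clat, clon = center
    out = []
    for rec in records:
        if rec.retained and haversine_km(rec.latitude, rec.longitude, clat, clon) <= radius_km:
            rec = _drop(rec, "institution_proximity")
        out.append(rec)
    return out


def round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero (deterministic, unlike float banker's rounding)."""
    scale = 10**digits
    # str() round-trips the shortest repr, avoiding 1.005*100 = 100.4999... artifacts
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def deduplicate(
    records: Sequence[OccurrenceRecord], digits: int = 2
) -> list[OccurrenceRecord]:
    """Per taxon, keep the first record of each coordinate key rounded to ``digits``.

    The retained record's coordinates are replaced by the rounded values, so a
    second pass is a no-op (idempotence of the whole pipeline).
    """
    seen: set[tuple[str, float, float]] = set()
    out = []
    for rec in records:
        if not rec.retained:
            out.append(rec)
            continue
        key = (
            rec.taxon,
            round_half_away(rec.latitude, digits),
            round_half_away(rec.longitude, digits),
        )
        if key in seen:
            rec = _drop(rec, "duplicate")
        else:
            seen.add(key)
            rec = replace(rec, latitude=key[1], longitude=key[2])
        out.append(rec)
    return out


@dataclass
class QcConfig:
    center: tuple[float, float] = GBIF_HEADQUARTERS
    radius_km: float = DEFAULT_RADIUS_KM
    digits: int = 2


@dataclass
class QcReport:
    """Counts of retained/dropped records, in total and per taxon."""

    totals: dict
    per_taxon: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(self.totals, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        self.per_taxon.to_csv(path, index=False)


def _report(records: Sequence[OccurrenceRecord]) -> QcReport:
    rows = [
        {"taxon": r.taxon, "status": r.status, "drop_reason": r.drop_reason}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["taxon", "status", "drop_reason"])
    totals = {"input": len(records), "retained": int((df["status"] == "retained").sum())}
    for reason in DROP_REASONS:
        totals[reason] = int((df["drop_reason"] == reason).sum())
    if len(df):
        per_taxon = (
            df.assign(outcome=df["drop_reason"].where(df["status"] == "dropped", "retained"))
            .groupby(["taxon", "outcome"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["retained", *DROP_REASONS], fill_value=0)
            .reset_index()
            .sort_values("taxon")
            .reset_index(drop=True)
        )
    else:
        per_taxon = pd.DataFrame(columns=["taxon", "retained", *DROP_REASONS])
    return QcReport(totals=totals, per_taxon=per_taxon)


def clean(
    records: Sequence[OccurrenceRecord],
    mask=None,
    config: QcConfig | None = None,
) -> tuple[list[OccurrenceRecord], QcReport]:
    """Apply the four filters in order and return (all records, report).

    Proximity and land tests see the original coordinates; rounding happens
    only at deduplication, so the filter order is load-bearing.
    """
    config = config or QcConfig()
    records = validate_coordinates(records)
    logger.info("validate_coordinates: %d records", len(records))
    if mask is not None:
        records = filter_landmass(records, mask)
        logger.info("filter_landmass done")
    records = filter_institution_proximity(records, config.center, config.radius_km)
    records = deduplicate(records, config.digits)
    report = _report(records)
    logger.info("QC totals: %s", report.totals)
    return records, report


def retained(records: Iterable[OccurrenceRecord]) -> list[OccurrenceRecord]:
    return [r for r in records if r.retained]


# ---------------------------------------------------------------------------
# CSV interface (Darwin-Core-like column names)

LAT_COL = "decimalLatitude"
LON_COL = "decimalLongitude"


def read_occurrences(path) -> list[OccurrenceRecord]:
    """Read an occurrence CSV with columns taxon, decimalLatitude, decimalLongitude.

    Extra columns are carried through untouched in ``extra``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"taxon", LAT_COL, LON_COL} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    extras = [c for c in df.columns if c not in ("taxon", LAT_COL, LON_COL)]
    recs = []
    for d in df.to_dict(orient="records"):
        recs.append(
            OccurrenceRecord(
                taxon=str(d["taxon"]),
                latitude=d[LAT_COL],
                longitude=d[LON_COL],
                extra={c: d[c] for c in extras},
            )
        )
    return recs


def write_occurrences(records: Sequence[OccurrenceRecord], path, include_qc=True) -> None:
    rows = []
    for r in records:
        row = {"taxon": r.taxon, LAT_COL: r.latitude, LON_COL: r.longitude}
        row.update(r.extra)
        if include_qc:
            row["status"] = r.status
            row["drop_reason"] = r.drop_reason
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
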