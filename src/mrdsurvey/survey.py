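"""Survey data model: strata, effort, sightings, and duplicate resolution.

Double-observer aerial line-transect surveys record schools twice — once per
observer platform (mid-seat and rear-seat). This module holds the tabular data
model for those records, converts inclinometer declination angles to
perpendicular distances, resolves duplicate detections between the two
platforms into unique sightings, and applies left/right distance truncation.

Sighting tables are plain :class:`pandas.DataFrame` objects with documented
column schemas (see :data:`RAW_SIGHTING_COLUMNS` and
:data:`UNIQUE_SIGHTING_COLUMNS`); strata and effort use small dataclasses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape, mapping

#: metres flown above the sea surface (500 ft)
DEFAULT_ALTITUDE_M = 152.4

#: condition covariates carried on every sighting record
CONDITION_COLUMNS = ["beaufort", "cloud_cover", "turbidity", "glare"]

RAW_SIGHTING_COLUMNS = [
    "platform", "side", "timestamp", "transect_id", "declination_deg",
    "perp_distance_m", "species", "school_size", *CONDITION_COLUMNS,
]

UNIQUE_SIGHTING_COLUMNS = [
    "perp_distance_m", "school_size", "detected_mid", "detected_rear",
    "transect_id", "season", *CONDITION_COLUMNS,
]


@dataclass(frozen=True)
class Stratum:
    """One analysis region with its own area, effort and estimates."""

    id: str
    name: str
    area_km2: float
    polygon: Polygon | None = None

    def __post_init__(self):
        if self.area_km2 <= 0:
            raise ValueError(f"stratum {self.id}: area must be positive")
        if self.polygon is not None and not self.polygon.is_valid:
            raise ValueError(f"stratum {self.id}: polygon is not valid")


@dataclass(frozen=True)
class TransectEffort:
    """A flown line: id, stratum membership, on-effort length, season."""

    transect_id: str
    stratum_id: str
    length_km: float
    season: str = "summer_autumn"

    def __post_init__(self):
        if self.length_km <= 0:
            raise ValueError(f"transect {self.transect_id}: length must be positive")


def declination_to_distance(altitude_m: float, declination_deg) -> float:
    """Horizontal perpendicular distance (m) for a sighting abeam.

    The observer reads the angle below the horizontal with an inclinometer;
    at altitude ``h`` the school lies ``h / tan(angle)`` metres out from the
    trackline. 90 deg is directly beneath the aircraft (distance 0).
    """
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    decl = np.asarray(declination_deg, dtype=float)
    if np.any(decl <= 0) or np.any(decl > 90):
        raise ValueError("declination must lie in (0, 90] degrees")
    out = altitude_m / np.tan(np.radians(decl))
    # tan(90 deg) overflows to a huge finite float; clamp exactly to zero
    out = np.where(decl == 90.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def distance_to_declination(altitude_m: float, perp_distance_m) -> float:
    """Inverse of :func:`declination_to_distance` (degrees below horizontal)."""
    x = np.asarray(perp_distance_m, dtype=float)
    if np.any(x < 0):
        raise ValueError("perpendicular distance must be non-negative")
    out = np.degrees(np.arctan2(altitude_m, x))
    return float(out) if out.ndim == 0 else out


def truncate(sightings: pd.DataFrame, left: float, right: float) -> pd.DataFrame:
    """Keep sightings with left <= x <= right (closed interval, order kept).

    Left truncation removes the obstructed strip under the aircraft; right
    truncation discards outlier detections at long distances.
    """
    if not 0 <= left < right:
        raise ValueError(f"require 0 <= left < right, got ({left}, {right})")
    x = sightings["perp_distance_m"]
    return sightings[(x >= left) & (x <= right)].copy()


def _require_sorted(df: pd.DataFrame, name: str) -> None:
    ts = df["timestamp"].to_numpy()
    if len(ts) > 1 and np.any(np.diff(ts) < 0):
        raise ValueError(f"{name} sightings must be sorted by timestamp")


def match_duplicates(
    mid: pd.DataFrame,
    rear: pd.DataFrame,
    time_tol: float = 10.0,
    angle_tol: float = 10.0,
    altitude_m: float = DEFAULT_ALTITUDE_M,
    season: str = "summer_autumn",
    strict_species: bool = False,
) -> pd.DataFrame:
    """Resolve tandem-platform detections into unique sightings.

    A mid-platform and a rear-platform record are duplicate candidates when
    they share transect and aircraft side and agree in timing (``|dt| <=
    time_tol`` seconds) and declination (``|dangle| <= angle_tol`` degrees).
    Candidates are matched greedily one-to-one, closest in time first (ties
    broken by angle). Matched pairs yield one unique sighting detected by
    both platforms, with perpendicular distance and school size averaged over
    the pair; unmatched records keep their own values with a single platform
    flag set.

    The count identity ``n_unique = n_mid + n_rear - n_matched`` always holds.
    """
    mid = _normalise_raw(mid, altitude_m)
    rear = _normalise_raw(rear, altitude_m)
    _require_sorted(mid, "mid")
    _require_sorted(rear, "rear")

    # candidate pairs within tolerance, ranked by |dt| then |dangle|
    pairs = []
    rear_by_key: dict[tuple, list[int]] = {}
    for j, r in rear.iterrows():
        rear_by_key.setdefault((r["transect_id"], r["side"]), []).append(j)
    for i, m in mid.iterrows():
        for j in rear_by_key.get((m["transect_id"], m["side"]), []):
            r = rear.loc[j]
            dt = abs(m["timestamp"] - r["timestamp"])
            da = abs(m["declination_deg"] - r["declination_deg"])
            if dt <= time_tol and da <= angle_tol:
                if strict_species and m["species"] != r["species"]:
                    continue
                pairs.append((dt, da, i, j))
    pairs.sort(key=lambda t: (t[0], t[1]))

    used_mid: set = set()
    used_rear: set = set()
    matches: list[tuple] = []
    for dt, da, i, j in pairs:
        if i in used_mid or j in used_rear:
            continue
        used_mid.add(i)
        used_rear.add(j)
        matches.append((i, j))

    # columns outside the raw schema (e.g. stratum_id, along-track position)
    # ride along; a duplicate pair takes the mid platform's value
    extras = [c for c in mid.columns
              if c in rear.columns and c not in RAW_SIGHTING_COLUMNS]
    rows = []
    for i, j in matches:
        m, r = mid.loc[i], rear.loc[j]
        row = {
            "perp_distance_m": 0.5 * (m["perp_distance_m"] + r["perp_distance_m"]),
            "school_size": 0.5 * (m["school_size"] + r["school_size"]),
            "detected_mid": True,
            "detected_rear": True,
            "transect_id": m["transect_id"],
            "season": season,
        }
        for c in CONDITION_COLUMNS:
            row[c] = m[c] if pd.notna(m[c]) else r[c]
        for c in extras:
            row[c] = m[c]
        rows.append(row)
    for i in mid.index.difference(used_mid):
        rows.append(_single_row(mid.loc[i], True, False, season, extras))
    for j in rear.index.difference(used_rear):
        rows.append(_single_row(rear.loc[j], False, True, season, extras))

    out = pd.DataFrame(rows, columns=UNIQUE_SIGHTING_COLUMNS + extras)
    assert len(out) == len(mid) + len(rear) - len(matches)
    return out.sort_values("perp_distance_m", kind="stable").reset_index(drop=True)


def _single_row(s: pd.Series, is_mid: bool, is_rear: bool, season: str,
                extras=()) -> dict:
    row = {
        "perp_distance_m": s["perp_distance_m"],
        "school_size": float(s["school_size"]),
        "detected_mid": is_mid,
        "detected_rear": is_rear,
        "transect_id": s["transect_id"],
        "season": season,
    }
    for c in CONDITION_COLUMNS:
        row[c] = s[c]
    for c in extras:
        row[c] = s[c]
    return row


def _normalise_raw(df: pd.DataFrame, altitude_m: float) -> pd.DataFrame:
    """Fill whichever of declination / perpendicular distance is absent."""
    df = df.copy()
    if "declination_deg" not in df.columns:
        df["declination_deg"] = np.nan
    if "perp_distance_m" not in df.columns:
        df["perp_distance_m"] = np.nan
    have_decl = df["declination_deg"].notna()
    have_dist = df["perp_distance_m"].notna()
    if not (have_decl | have_dist).all():
        raise ValueError("each sighting needs a declination or a perpendicular distance")
    need_dist = have_decl & ~have_dist
    if need_dist.any():
        df.loc[need_dist, "perp_distance_m"] = declination_to_distance(
            altitude_m, df.loc[need_dist, "declination_deg"].to_numpy()
        )
    need_decl = have_dist & ~have_decl
    if need_decl.any():
        df.loc[need_decl, "declination_deg"] = distance_to_declination(
            altitude_m, df.loc[need_decl, "perp_distance_m"].to_numpy()
        )
    for c in CONDITION_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    if "species" not in df.columns:
        df["species"] = "unknown"
    if (df["school_size"] < 1).any():
        raise ValueError("school_size must be >= 1")
    return df


# ---------------------------------------------------------------------------
# file I/O


def read_sightings(path, altitude_m: float = DEFAULT_ALTITUDE_M) -> pd.DataFrame:
    """Read a per-platform sighting CSV and derive the missing distance field."""
    return _normalise_raw(pd.read_csv(path, float_precision="round_trip"),
                          altitude_m)


def read_unique(path) -> pd.DataFrame:
    """Read a unique-sighting CSV written by :func:`write_sightings`.

    Round-trip float parsing, so a write/read cycle reproduces every field
    bit-exactly.
    """
    return pd.read_csv(path, float_precision="round_trip")


def write_sightings(df: pd.DataFrame, path) -> None:
    # shortest round-trip repr, so re-reading the CSV reproduces every
    # float bit-exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_effort(path) -> list[TransectEffort]:
    df = pd.read_csv(path)
    return [
        TransectEffort(str(r.transect_id), str(r.stratum_id), float(r.length_km),
                       str(r.season))
        for r in df.itertuples()
    ]


def write_effort(effort: list[TransectEffort], path) -> None:
    pd.DataFrame(
        [
            {"transect_id": e.transect_id, "stratum_id": e.stratum_id,
             "length_km": e.length_km, "season": e.season}
            for e in effort
        ]
    ).to_csv(path, index=False)


def read_strata(path) -> list[Stratum]:
    """Read strata from GeoJSON (one Feature per stratum, planar km coords)."""
    with open(path) as fh:
        gj = json.load(fh)
    strata = []
    seen = set()
    for feat in gj["features"]:
        props = feat["properties"]
        sid = str(props["id"])
        if sid in seen:
            raise ValueError(f"duplicate stratum id {sid}")
        seen.add(sid)
        strata.append(
            Stratum(sid, props.get("name", sid), float(props["area_km2"]),
                    shape(feat["geometry"]))
        )
    return strata


def write_strata(strata: list[Stratum], path) -> None:
    feats = []
    for s in strata:
        geom = mapping(s.polygon) if s.polygon is not None else None
        feats.append({
            "type": "Feature",
            "properties": {"id": s.id, "name": s.name, "area_km2": s.area_km2},
            "geometry": geom,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
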