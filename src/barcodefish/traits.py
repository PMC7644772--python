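"""Morphometric diagnostics and range-area computation.

Recomputes the printed integrative-taxonomy numbers from a measurement
table (14 standard frog morphometric variables, all in mm) and the
minimum convex polygon (MCP) area of occurrence localities on a sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "MEASUREMENT_VARIABLES",
    "MeasurementRecord",
    "LocalityRecord",
    "load_measurements",
    "load_localities",
    "ratio_percent",
    "group_range",
    "mcp_area",
]

#: The 14 morphometric variables (mm): snout-vent length, head width,
#: head length, tympanum diameter, eye diameter, eye-nostril distance,
#: nostril-snout distance, internarial distance, hand length, forelimb
#: length, hindlimb length, foot+tarsus length, foot length, tibia length.
MEASUREMENT_VARIABLES = (
    "SVL", "HW", "HL", "TD", "ED", "END", "NSD",
    "NND", "HAL", "FORL", "HIL", "FOTL", "FOL", "TIBL",
)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass
class MeasurementRecord:
    """One specimen's measurements plus identity and status."""

    catalogue: str
    field_number: str
    species: str
    lineage: str
    sex: str              # "M" or "F"
    status: str           # adult | subadult | holotype | paratype
    measurements: dict[str, float | None]

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", ""):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        for var, val in self.measurements.items():
            if val is not None and val <= 0:
                raise ValueError(
                    f"{self.catalogue}: non-positive {var} = {val}"
                )

    @property
    def is_adult(self) -> bool:
        # holotype/paratype imply adult unless flagged subadult
        return self.status != "subadult"


@dataclass
class LocalityRecord:
    """An occurrence site in decimal degrees (south/west negative)."""

    name: str
    lat: float
    lon: float
    species: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"{self.name}: latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"{self.name}: longitude {self.lon} out of range")


def load_measurements(path: str | PathLike) -> list[MeasurementRecord]:
    """Load a TSV/CSV measurement table.

    The header must contain all 14 variable abbreviations plus
    identifying columns; a sex cell like ``"F (SA)"`` marks a subadult
    female.  Status codes HT/PT mark the holotype/paratypes.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [v for v in MEASUREMENT_VARIABLES if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing measurement columns {missing}")

    records = []
    for idx, row in df.iterrows():
        sex_raw = row.get("sex", "").strip()
        sex = sex_raw.split()[0] if sex_raw else ""
        subadult = "(SA)" in sex_raw or "SA" == row.get("status", "").strip()
        status_raw = row.get("status", "").strip().upper()
        if subadult:
            status = "subadult"
        elif status_raw == "HT":
            status = "holotype"
        elif status_raw == "PT":
            status = "paratype"
        else:
            status = "adult"
        meas: dict[str, float | None] = {}
        for var in MEASUREMENT_VARIABLES:
            cell = str(row[var]).strip()
            if cell in ("", "NA", "nan"):
                meas[var] = None
                continue
            try:
                meas[var] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric {var} in row {idx + 2}: {cell!r}"
                ) from None
        records.append(
            MeasurementRecord(
                catalogue=row.get("catalogue", "").strip(),
                field_number=row.get("field_number", "").strip(),
                species=row.get("species", "").strip(),
                lineage=row.get("lineage", "").strip(),
                sex=sex,
                status=status,
                measurements=meas,
            )
        )
    return records


def load_localities(path: str | PathLike) -> list[LocalityRecord]:
    """Load a TSV locality table (columns: name, lat, lon, species)."""
    df = pd.read_csv(path, sep="\t")
    return [
        LocalityRecord(
            name=str(row["name"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            species=str(row.get("species", "")),
        )
        for _, row in df.iterrows()
    ]


def ratio_percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half away from zero.

    E.g. foot/tibia 20.3/20.7 -> 98; tympanum/eye 3.0/4.5 -> 67.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def group_range(
    records: list[MeasurementRecord],
    variable: str,
    species: str | None = None,
    sex: str | None = None,
    include_subadults: bool = False,
) -> tuple[float, float, int]:
    """(min, max, n) of one variable over a filtered set of specimens.

    Subadults are excluded unless requested, so ranges match the adult
    size ranges quoted in diagnoses.
    """
    if variable not in MEASUREMENT_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    values = [
        r.measurements[variable]
        for r in records
        if (species is None or r.species == species)
        and (sex is None or r.sex == sex)
        and (include_subadults or r.is_adult)
        and r.measurements[variable] is not None
    ]
    if not values:
        raise ValueError("no records match the selection")
    return min(values), max(values), len(values)


def _angular_dist(p1: np.ndarray, p2: np.ndarray) -> float:
    """Great-circle angle between two unit vectors."""
    return float(np.arctan2(np.linalg.norm(np.cross(p1, p2)), np.dot(p1, p2)))


def _unit(lat_deg: float, lon_deg: float) -> np.ndarray:
    lat, lon = math.radians(lat_deg), math.radians(lon_deg)
    return np.array(
        [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon),
         math.sin(lat)]
    )


def _spherical_triangle_excess(a: float, b: float, c: float) -> float:
    """Spherical excess by l'Huilier's theorem from side angles."""
    s = 0.5 * (a + b + c)
    arg = (
        math.tan(0.5 * s)
        * math.tan(0.5 * (s - a))
        * math.tan(0.5 * (s - b))
        * math.tan(0.5 * (s - c))
    )
    if arg <= 0.0:  # degenerate (collinear) triangle
        return 0.0
    return 4.0 * math.atan(math.sqrt(arg))


def mcp_area(localities: list[LocalityRecord]) -> float:
    """Minimum-convex-polygon area of localities, in km^2.

    The convex hull is taken over (lon, lat); the polygon area is
    computed on a sphere of radius 6371.0088 km by summing spherical
    triangle excesses (l'Huilier).  Full precision is returned; round to
    3 significant figures for reporting (:func:`round_sigfig`).  Fewer
    than 3 distinct, non-collinear points give 0.
    """
    pts = sorted({(loc.lon, loc.lat) for loc in localities})
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(np.array(pts))
    except QhullError:  # collinear points
        return 0.0
    verts = [pts[i] for i in hull.vertices]
    units = [_unit(lat, lon) for lon, lat in verts]
    excess = 0.0
    for i in range(1, len(units) - 1):
        a = _angular_dist(units[0], units[i])
        b = _angular_dist(units[i], units[i + 1])
        c = _angular_dist(units[i + 1], units[0])
        excess += _spherical_triangle_excess(a, b, c)
    return excess * EARTH_RADIUS_KM**2


def round_sigfig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (for reported areas)."""
    if x == 0.0:
        return 0.0
    digits = sig - int(math.floor(math.log10(abs(x)))) - 1
    return round(x, digits)
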