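"""Geolocation consistency checks between predicted and metadata coordinates.

Sample metadata often carries latitude/longitude fields whose values are
unreliable: swapped coordinates, wrong hemisphere signs, or coordinates of
the submitting institution rather than the sampling site.  The model, in
turn, predicts a textual location.  This module extracts coordinates from
metadata, compares predicted location text with a coordinate-derived
location (via an offline gazetteer standing in for remote geocoders),
measures great-circle distances, buckets mismatches into distance
categories, and triages the likely cause of a mismatch by testing candidate
corrections of the metadata point (swap, sign flips).
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from .metadata_io import MetadataRecord

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A validated point on the globe (degrees)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} out of bounds")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} out of bounds")


class DistanceCategory(str, Enum):
    LT100 = "LT100"
    KM100_500 = "KM100_500"
    KM500_1000 = "KM500_1000"
    KM1000_4000 = "KM1000_4000"
    GT4000 = "GT4000"


class TriageCode(str, Enum):
    METADATA_COMPLETELY_WRONG = "metadata_completely_wrong"
    LATLON_SWAPPED = "latlon_swapped"
    LON_SIGN_NEG = "lon_sign_neg"
    LON_SIGN_POS = "lon_sign_pos"
    LAT_SIGN_NEG = "lat_sign_neg"
    LAT_WRONG = "lat_wrong"
    INSTITUTION_COORDS = "institution_coords"
    SEMANTIC_NAME_MISMATCH = "semantic_name_mismatch"
    LLM_INSTITUTION_AS_SITE = "llm_institution_as_site"
    LLM_WATERBODY_COUNTRY = "llm_waterbody_country"
    LOCATION_NOT_IN_TEXT = "location_not_in_text"
    UNRESOLVABLE = "unresolvable"


@dataclass
class GeoMatch:
    """Predicted-vs-coordinate-derived location comparison for one sample."""

    sample_id: str
    predicted_text: str | None
    geocoded_text: str | None
    text_match: bool
    distance_km: float | None = None
    category: DistanceCategory | None = None
    triage: TriageCode | None = None


# --- coordinate extraction ------------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?"
_HEMI_PAIR_RE = re.compile(
    rf"({_NUM})\s*°?\s*([NS])[,;\s]+({_NUM})\s*°?\s*([EW])", re.IGNORECASE
)
_SIGNED_PAIR_RE = re.compile(rf"({_NUM})[,;\s]+({_NUM})")

_COMBINED_FIELD_RE = re.compile(r"lat[\s_]*lon|lat[\s_/]*long|geographic location", re.IGNORECASE)
_LAT_FIELD_RE = re.compile(r"\blat(itude)?\b", re.IGNORECASE)
_LON_FIELD_RE = re.compile(r"\blon(gitude)?\b|\blong\b", re.IGNORECASE)


def _parse_pair_text(value: str) -> tuple[float, float] | None:
    """Parse '37.77 N 122.42 W' or signed-decimal pair forms; None if unparseable."""
    m = _HEMI_PAIR_RE.search(value)
    if m:
        lat = float(m.group(1)) * (-1 if m.group(2).upper() == "S" else 1)
        lon = float(m.group(3)) * (-1 if m.group(4).upper() == "W" else 1)
        return lat, lon
    m = _SIGNED_PAIR_RE.search(value)
    if m:
        return float(m.group(1)), float(m.group(2))
    return None


def _parse_single(value: str) -> float | None:
    m = re.search(rf"({_NUM})\s*°?\s*([NSEW])?", value)
    if not m:
        return None
    num = float(m.group(1))
    hemi = (m.group(2) or "").upper()
    if hemi in ("S", "W"):
        num = -num
    return num


def extract_raw_pair(record: MetadataRecord) -> tuple[float, float] | None:
    """Extract the stored (lat, lon) pair without bounds validation.

    Triage needs the raw pair as submitted: a swapped pair may be out of
    bounds and would be rejected by :func:`parse_lat_lon`.
    """
    for name, value in record.fields:
        if _COMBINED_FIELD_RE.search(name):
            pair = _parse_pair_text(value)
            if pair is not None:
                return pair
    lat = lon = None
    for name, value in record.fields:
        if _COMBINED_FIELD_RE.search(name):
            continue
        if lat is None and _LAT_FIELD_RE.search(name):
            lat = _parse_single(value)
        elif lon is None and _LON_FIELD_RE.search(name):
            lon = _parse_single(value)
    if lat is not None and lon is not None:
        return lat, lon
    return None


def parse_lat_lon(record: MetadataRecord) -> GeoPoint | None:
    """Extract a validated coordinate from a record, or None.

    Searches combined ``lat_lon``-style fields (hemisphere-letter or signed
    decimal pair forms) and separate latitude/longitude fields.  Values
    outside [-90, 90] x [-180, 180] are rejected with a warning.
    """
    pair = extract_raw_pair(record)
    if pair is None:
        return None
    try:
        return GeoPoint(*pair)
    except ValueError:
        logger.warning(
            "record %s: coordinates %r out of bounds; ignored", record.sample_id, pair
        )
        return None


# --- distances ------------------------------------------------------------

def haversine_km(p: GeoPoint, q: GeoPoint) -> float:
    """Great-circle distance in km (mean Earth radius 6371.0 km)."""
    phi1, phi2 = math.radians(p.lat), math.radians(q.lat)
    dphi = phi2 - phi1
    dlam = math.radians(q.lon - p.lon)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def categorize_distance(km: float) -> DistanceCategory:
    """Bucket a mismatch distance: [0,100), [100,500), [500,1000), [1000,4000), [4000,inf)."""
    if km < 0:
        raise ValueError("distance must be non-negative")
    if km < 100:
        return DistanceCategory.LT100
    if km < 500:
        return DistanceCategory.KM100_500
    if km < 1000:
        return DistanceCategory.KM500_1000
    if km < 4000:
        return DistanceCategory.KM1000_4000
    return DistanceCategory.GT4000


# --- location text matching ----------------------------------------------

_PUNCT_RE = re.compile(r"[^\w\s-]")


def _location_tokens(text: str) -> set[str]:
    return set(_PUNCT_RE.sub(" ", text.lower()).split())


def match_location_text(predicted: str | None, geocoded: str | None) -> bool:
    """Word-level containment in either direction after normalization.

    'Los Angeles, USA' matches a geocoded 'Los Angeles, California, United
    States, USA'; 'McMurdo Station' does not match 'Antarctica' (a semantic,
    not textual, relation).  An NA/absent prediction never matches.
    """
    if predicted is None or geocoded is None:
        return False
    a, b = _location_tokens(predicted), _location_tokens(geocoded)
    if not a or not b:
        return False
    return a <= b or b <= a


# --- gazetteer ------------------------------------------------------------

@dataclass(frozen=True)
class GazetteerEntry:
    name: str
    country: str
    point: GeoPoint
    kind: str  # place | institution


class Gazetteer:
    """Offline place-name <-> coordinate lookup used instead of remote geocoders."""

    def __init__(self, entries: list[GazetteerEntry]):
        self.entries = entries
        self._by_name = {e.name.lower(): e for e in entries}

    @classmethod
    def from_csv(cls, path: str | Path | None = None) -> "Gazetteer":
        """Load from CSV (name,country,lat,lon,kind); defaults to the bundled file."""
        if path is None:
            ref = resources.files("metabiome").joinpath("data/gazetteer.csv")
            text = ref.read_text(encoding="utf-8")
        else:
            text = Path(path).read_text(encoding="utf-8")
        entries = []
        for row in csv.DictReader(text.splitlines()):
            entries.append(
                GazetteerEntry(
                    name=row["name"],
                    country=row["country"],
                    point=GeoPoint(float(row["lat"]), float(row["lon"])),
                    kind=row.get("kind", "place") or "place",
                )
            )
        return cls(entries)

    def places(self) -> list[GazetteerEntry]:
        return [e for e in self.entries if e.kind == "place"]

    def institutions(self) -> list[GazetteerEntry]:
        return [e for e in self.entries if e.kind == "institution"]

    def forward(self, name: str) -> GeoPoint | None:
        """Place name -> coordinates (case-insensitive; 'Name, Country' accepted)."""
        key = name.strip().lower()
        if key in self._by_name:
            return self._by_name[key].point
        head = key.split(",")[0].strip()
        entry = self._by_name.get(head)
        return entry.point if entry else None

    def reverse(self, point: GeoPoint, max_km: float = 300.0) -> str | None:
        """Coordinates -> 'Name, Country' of the nearest entry within *max_km*."""
        best: tuple[float, GazetteerEntry] | None = None
        for entry in self.entries:
            d = haversine_km(point, entry.point)
            if d <= max_km and (best is None or d < best[0]):
                best = (d, entry)
        if best is None:
            return None
        return f"{best[1].name}, {best[1].country}"


# --- mismatch triage ------------------------------------------------------

def triage_mismatch(
    meta_raw: tuple[float, float],
    predicted_point: GeoPoint | None,
    threshold_km: float = 100.0,
    institutions: list[GeoPoint] | None = None,
) -> TriageCode:
    """Diagnose why metadata coordinates disagree with the predicted location.

    Tests candidate corrections of the raw metadata pair — swap(lat, lon),
    negate longitude, negate latitude — and returns the corresponding code
    when the corrected point lands within *threshold_km* of the predicted
    point.  Institution coordinates are recognized against an optional list.
    Called only for established text mismatches; a raw pair already within
    the threshold is a precondition violation.
    """
    if predicted_point is None:
        return TriageCode.LOCATION_NOT_IN_TEXT
    lat, lon = meta_raw

    def _dist(cand_lat: float, cand_lon: float) -> float | None:
        try:
            cand = GeoPoint(cand_lat, cand_lon)
        except ValueError:
            return None
        return haversine_km(cand, predicted_point)

    d0 = _dist(lat, lon)
    if d0 is not None and d0 <= threshold_km:
        raise ValueError(
            "metadata point already within threshold of prediction; "
            "should have matched upstream"
        )
    d = _dist(lon, lat)
    if d is not None and d <= threshold_km:
        return TriageCode.LATLON_SWAPPED
    d = _dist(lat, -lon)
    if d is not None and d <= threshold_km:
        return TriageCode.LON_SIGN_POS if lon > 0 else TriageCode.LON_SIGN_NEG
    d = _dist(-lat, lon)
    if d is not None and d <= threshold_km:
        return TriageCode.LAT_SIGN_NEG if lat < 0 else TriageCode.LAT_WRONG
    if institutions:
        try:
            meta_point = GeoPoint(lat, lon)
        except ValueError:
            meta_point = None
        if meta_point is not None and any(
            haversine_km(meta_point, inst) <= threshold_km for inst in institutions
        ):
            return TriageCode.INSTITUTION_COORDS
    return TriageCode.METADATA_COMPLETELY_WRONG


def geo_report(
    records: list[MetadataRecord],
    predicted_locations: dict[str, str | None],
    gazetteer: Gazetteer,
    threshold_km: float = 100.0,
) -> list[GeoMatch]:
    """Compare predicted location text against metadata coordinates per sample.

    For each record with a parseable coordinate: reverse-geocode it, test a
    textual match against the prediction, and on mismatch compute the
    distance to the forward-geocoded prediction, its category, and a triage
    code.
    """
    institutions = [e.point for e in gazetteer.institutions()]
    matches: list[GeoMatch] = []
    for record in records:
        raw = extract_raw_pair(record)
        if raw is None:
            continue
        meta_point = parse_lat_lon(record)
        geocoded = gazetteer.reverse(meta_point) if meta_point is not None else None
        predicted = predicted_locations.get(record.sample_id)
        text_match = match_location_text(predicted, geocoded)
        gm = GeoMatch(
            sample_id=record.sample_id,
            predicted_text=predicted,
            geocoded_text=geocoded,
            text_match=text_match,
        )
        if not text_match:
            predicted_point = gazetteer.forward(predicted) if predicted else None
            if predicted_point is not None:
                d = haversine_km(GeoPoint(*raw), predicted_point) if meta_point else None
                if d is None:
                    # raw pair out of bounds; distance from corrected swap is
                    # what triage measures, leave distance undefined
                    pass
                else:
                    gm.distance_km = d
                    gm.category = categorize_distance(d)
            try:
                gm.triage = triage_mismatch(raw, predicted_point, threshold_km, institutions)
            except ValueError:
                # within threshold despite text mismatch: name-level disagreement
                gm.triage = TriageCode.SEMANTIC_NAME_MISMATCH
        matches.append(gm)
    return matches


def write_geo_csv(matches: list[GeoMatch], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "predicted_text", "geocoded_text", "text_match",
             "distance_km", "category", "triage"]
        )
        for m in matches:
            writer.writerow(
                [m.sample_id, m.predicted_text or "", m.geocoded_text or "",
                 m.text_match,
                 f"{m.distance_km:.3f}" if m.distance_km is not None else "",
                 m.category.value if m.category else "",
                 m.triage.value if m.triage else ""]
            )
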