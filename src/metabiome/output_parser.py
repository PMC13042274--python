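"""Parsing of model responses into per-sample annotations.

Two response dialects are supported: the inline triple-underscore format
(``SRS123456___animal___Los Angeles, USA___{kw1, ...}___human elbow``) and a
JSON format (array of objects).  Parsing is defensive: the parser never
raises on arbitrary text; every failure becomes data in a
:class:`ParseReport` so that missing or malformed sample IDs can be
re-requested.  Soft prompt contracts (5-8 keywords, sub-biome of at most 3
words) are validated but violations only flag the annotation — discarding
them would bias downstream accuracy measurement.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .metadata_io import ACCESSION_RE

NA = "NA"

KEYWORD_MIN, KEYWORD_MAX = 5, 8
SUB_BIOME_MAX_WORDS = 3

_JSON_FENCE_RE = re.compile(r"^```(?:json)?\s*|\s*```$", re.MULTILINE)

_ID_KEYS = ("sample_id", "id", "sample", "accession", "sampleid")
_BIOME_KEYS = ("biome", "category", "source_category", "source")
_LOCATION_KEYS = ("location", "geographic_location", "geo_location", "geographical_location")
_KEYWORD_KEYS = ("keywords", "key_terms", "key_words")
_SUB_KEYS = ("sub_biome", "sub-biome", "subbiome", "specific_origin", "sub biome")


def normalize_label(text: str) -> str:
    """Lowercase, trim and collapse internal whitespace.

    Parentheticals are preserved; disambiguating clarifying text (e.g.
    ``"animal (incl. human)"``) is the lenient matcher's job.
    """
    return " ".join(text.strip().lower().split())


@dataclass
class Annotation:
    """Parsed model answer for one sample."""

    sample_id: str
    biome_raw: str
    location: str | None = None
    keywords: list[str] | None = None
    sub_biome: str | None = None
    flags: list[str] = field(default_factory=list)
    status: str = "ok"  # ok | flagged | unresolved

    def core(self) -> tuple:
        """Content fields, ignoring derived flags/status."""
        return (
            self.sample_id,
            self.biome_raw,
            self.location,
            tuple(self.keywords) if self.keywords is not None else None,
            self.sub_biome,
        )


def make_annotation(
    sample_id: str,
    biome_raw: str,
    location: str | None,
    keywords: list[str] | None,
    sub_biome: str | None,
) -> Annotation:
    """Build an annotation and apply the soft-contract flags."""
    ann = Annotation(sample_id, biome_raw, location, keywords, sub_biome)
    _apply_flags(ann)
    return ann


def _apply_flags(ann: Annotation) -> None:
    flags = []
    if ann.keywords is not None and not (KEYWORD_MIN <= len(ann.keywords) <= KEYWORD_MAX):
        flags.append("keyword_count")
    if ann.sub_biome is not None and len(ann.sub_biome.split()) > SUB_BIOME_MAX_WORDS:
        flags.append("sub_biome_length")
    ann.flags = flags
    ann.status = "flagged" if flags else "ok"


@dataclass
class ParseReport:
    """Reconciliation of expected vs returned sample IDs for one response."""

    expected_ids: set[str]
    parsed_ids: set[str] = field(default_factory=set)
    missing_ids: set[str] = field(default_factory=set)
    malformed_lines: list[tuple[str, str]] = field(default_factory=list)
    duplicate_ids: set[str] = field(default_factory=set)
    unexpected_ids: set[str] = field(default_factory=set)

    def finalize(self) -> "ParseReport":
        self.missing_ids = set(self.expected_ids) - self.parsed_ids
        return self


def _na(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return None if (not value or value.upper() == NA) else value


def _split_keywords(raw: str) -> list[str] | None:
    raw = raw.strip()
    if raw.upper() == NA or not raw:
        return None
    raw = raw.strip("{}[]")
    items = [kw.strip() for kw in raw.split(",")]
    items = [kw for kw in items if kw]
    return items or None


def parse_inline(raw: str, expected_ids: Iterable[str]) -> tuple[list[Annotation], ParseReport]:
    """Parse the triple-underscore inline dialect.

    Each response line must split on the literal ``___`` into exactly 5
    fields, the first being a valid accession.  Duplicate IDs keep the first
    occurrence; IDs outside the expected set are recorded separately.
    """
    report = ParseReport(expected_ids=set(expected_ids))
    annotations: list[Annotation] = []
    for line in raw.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("___")
        if len(parts) != 5:
            report.malformed_lines.append(
                (line, f"expected 5 ___-separated fields, got {len(parts)}")
            )
            continue
        sid = parts[0].strip()
        if not ACCESSION_RE.fullmatch(sid):
            report.malformed_lines.append((line, "first field is not a valid accession"))
            continue
        if sid in report.parsed_ids or sid in report.unexpected_ids:
            report.duplicate_ids.add(sid)
            continue
        if sid not in report.expected_ids:
            report.unexpected_ids.add(sid)
            continue
        annotations.append(
            make_annotation(
                sid,
                parts[1].strip(),
                _na(parts[2]),
                _split_keywords(parts[3]),
                _na(parts[4]),
            )
        )
        report.parsed_ids.add(sid)
    return annotations, report.finalize()


def _first_key(obj: dict, keys: Sequence[str]):
    lowered = {str(k).strip().lower(): v for k, v in obj.items()}
    for key in keys:
        if key in lowered:
            return lowered[key]
    return None


def parse_json(raw: str, expected_ids: Iterable[str]) -> tuple[list[Annotation], ParseReport]:
    """Parse the JSON dialect (single object or array of objects).

    A syntactically invalid response marks the whole response malformed and
    all its expected IDs missing.  Key aliases (``id``/``sample_id``,
    ``sub-biome``/``sub_biome``, ...) are normalized; keywords given as a
    comma-joined string are split into a list.
    """
    report = ParseReport(expected_ids=set(expected_ids))
    annotations: list[Annotation] = []
    cleaned = _JSON_FENCE_RE.sub("", raw.strip())
    try:
        payload = json.loads(cleaned)
    except (json.JSONDecodeError, ValueError):
        report.malformed_lines.append((raw[:200], "invalid JSON"))
        return annotations, report.finalize()
    objects = payload if isinstance(payload, list) else [payload]
    for obj in objects:
        if not isinstance(obj, dict):
            report.malformed_lines.append((json.dumps(obj)[:200], "entry is not an object"))
            continue
        sid = _first_key(obj, _ID_KEYS)
        sid = str(sid).strip() if sid is not None else ""
        if not ACCESSION_RE.fullmatch(sid):
            report.malformed_lines.append(
                (json.dumps(obj)[:200], "missing or invalid sample id")
            )
            continue
        if sid in report.parsed_ids or sid in report.unexpected_ids:
            report.duplicate_ids.add(sid)
            continue
        if sid not in report.expected_ids:
            report.unexpected_ids.add(sid)
            continue
        keywords = _first_key(obj, _KEYWORD_KEYS)
        if isinstance(keywords, str):
            keywords = _split_keywords(keywords)
        elif isinstance(keywords, list):
            keywords = [str(k).strip() for k in keywords if str(k).strip()] or None
        else:
            keywords = None
        biome = _first_key(obj, _BIOME_KEYS)
        location = _first_key(obj, _LOCATION_KEYS)
        sub = _first_key(obj, _SUB_KEYS)
        annotations.append(
            make_annotation(
                sid,
                str(biome).strip() if biome is not None else "",
                _na(str(location)) if location is not None else None,
                keywords,
                _na(str(sub)) if sub is not None else None,
            )
        )
        report.parsed_ids.add(sid)
    return annotations, report.finalize()


def parse_response(
    raw: str, expected_ids: Iterable[str], dialect: str = "inline"
) -> tuple[list[Annotation], ParseReport]:
    if dialect == "inline":
        return parse_inline(raw, expected_ids)
    if dialect == "json":
        return parse_json(raw, expected_ids)
    raise ValueError(f"unknown response dialect: {dialect}")


def render_inline(annotations: Iterable[Annotation]) -> str:
    """Emit annotations in the inline dialect (inverse of :func:`parse_inline`)."""

    def _field(value: str | None) -> str:
        return value if value is not None else NA

    lines = []
    for ann in annotations:
        kw = "{" + ", ".join(ann.keywords) + "}" if ann.keywords is not None else NA
        lines.append(
            "___".join(
                [ann.sample_id, ann.biome_raw, _field(ann.location), kw, _field(ann.sub_biome)]
            )
        )
    return "\n".join(lines)


def render_json(annotations: Iterable[Annotation]) -> str:
    """Emit annotations in the JSON dialect (inverse of :func:`parse_json`)."""
    objs = [
        {
            "sample_id": ann.sample_id,
            "biome": ann.biome_raw,
            "location": ann.location if ann.location is not None else NA,
            "keywords": ann.keywords if ann.keywords is not None else NA,
            "sub_biome": ann.sub_biome if ann.sub_biome is not None else NA,
        }
        for ann in annotations
    ]
    return json.dumps(objs, indent=1)


def write_annotations_csv(
    annotations: Iterable[Annotation],
    unresolved_ids: Iterable[str],
    path: str | Path,
) -> None:
    """Consolidated output CSV: one row per sample, unresolved rows included."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "biome", "location", "keywords", "sub_biome", "status"])
        for ann in annotations:
            writer.writerow(
                [
                    ann.sample_id,
                    ann.biome_raw,
                    ann.location or NA,
                    "|".join(ann.keywords) if ann.keywords else NA,
                    ann.sub_biome or NA,
                    ann.status,
                ]
            )
        for sid in sorted(unresolved_ids):
            writer.writerow([sid, NA, NA, NA, NA, "unresolved"])
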