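"""Reading, cleaning and normalising per-sample sequencing metadata.

SRA-style metadata arrives as plain-text ``field: value`` lines grouped per
sample.  This module parses two dialects (one record per file, or a
consolidated multi-record file delimited by accession lines), strips
uninformative content (empty fields, placeholder values such as "missing" or
"NaN", wet-lab ``experiment*`` fields), translates compact ontology
identifiers (CURIEs such as ``ENVO:00002297``) into their textual labels, and
serialises records into the deterministic text blocks submitted to a language
model.  Every destructive step is logged so that the provenance of each
removed line and translated code can be audited.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Accession pattern: SRA/ENA/DDBJ sample prefixes plus the SYN prefix used by
#: the bundled synthetic benchmark generator.
ACCESSION_RE = re.compile(r"(?:SRS|ERS|DRS|SYN)\d+")

#: Placeholder values removed during cleaning (compared case-insensitively on
#: the whole trimmed value).
DEFAULT_PLACEHOLDERS = frozenset(
    {"missing", "nan", "not applicable", "unknown", "na", "none", "null"}
)

CURIE_RE = re.compile(r"\b([A-Za-z]+):(\d+)\b")


@dataclass
class MetadataRecord:
    """One sample's ordered field_name -> free-text mapping."""

    sample_id: str
    fields: list[tuple[str, str]] = field(default_factory=list)
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def field_names(self) -> list[str]:
        return [name for name, _ in self.fields]

    def get(self, name: str) -> str | None:
        """First value stored under *name*, or None."""
        for fname, value in self.fields:
            if fname == name:
                return value
        return None


@dataclass
class OntologyDictionary:
    """CURIE -> textual label mapping consolidated from several ontologies."""

    entries: dict[str, str]
    source_ontologies: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for curie, label in self.entries.items():
            if not CURIE_RE.fullmatch(curie):
                raise ValueError(f"malformed CURIE key: {curie!r}")
            if not label:
                raise ValueError(f"empty label for {curie}")
        if not self.source_ontologies:
            self.source_ontologies = {c.split(":")[0] for c in self.entries}

    @property
    def prefixes(self) -> set[str]:
        return {c.split(":")[0] for c in self.entries}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OntologyDictionary":
        """Load a 2-column TSV (CURIE, label); blank and '#' lines skipped."""
        entries: dict[str, str] = {}
        with _open_text(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                curie, _, label = line.partition("\t")
                entries[curie.strip()] = label.strip()
        return cls(entries)


@dataclass
class CleaningLog:
    """Audit trail of one record's cleaning / translation pass."""

    sample_id: str
    removed: list[tuple[str, str]] = field(default_factory=list)  # (line, reason)
    translated: list[tuple[str, str]] = field(default_factory=list)  # (CURIE, label)
    untranslated: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.removed or self.translated or self.untranslated)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "removed": self.removed,
                "translated": self.translated,
                "untranslated": self.untranslated,
            }
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8", errors="replace")
    return open(path, "r", encoding="utf-8", errors="replace")


def _parse_field_line(line: str) -> tuple[str, str] | None:
    """Split a ``name: value`` line at the first colon."""
    name, sep, value = line.partition(":")
    if not sep:
        return None
    return name.strip(), value.strip()


def load_records(
    path: str | Path, dialect: str = "consolidated-multirecord"
) -> list[MetadataRecord]:
    """Parse metadata records from *path*.

    Dialects:

    ``consolidated-multirecord``
        Records are delimited by a bare accession line at column 0; the lines
        that follow are ``name: value`` pairs belonging to that sample.
    ``per-sample-file``
        The whole file is a single record; the first line holds the accession.

    Malformed lines are logged as warnings, never silently dropped.
    """
    path = Path(path)
    if dialect not in ("consolidated-multirecord", "per-sample-file"):
        raise ValueError(f"unknown dialect: {dialect}")
    records: list[MetadataRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    if dialect == "per-sample-file":
        if not lines:
            return []
        header = lines[0].strip()
        m = ACCESSION_RE.search(header)
        if m is None:
            logger.warning("record header %r lacks an accession; skipped", header)
            return []
        rec = MetadataRecord(sample_id=m.group(0), source_path=str(path))
        _fill_fields(rec, lines[1:])
        return [rec] if rec.fields else _warn_empty(rec)

    current: MetadataRecord | None = None
    pending: list[str] = []
    orphan: list[str] = []
    for line in lines:
        stripped = line.strip()
        if ACCESSION_RE.fullmatch(stripped):
            if current is not None:
                _fill_fields(current, pending)
                records.extend([current] if current.fields else _warn_empty(current))
            current = MetadataRecord(sample_id=stripped, source_path=str(path))
            pending = []
        elif current is None:
            if stripped:
                orphan.append(line)
        else:
            pending.append(line)
    if current is not None:
        _fill_fields(current, pending)
        records.extend([current] if current.fields else _warn_empty(current))
    if orphan:
        logger.warning(
            "%d line(s) before any parsable accession header were skipped", len(orphan)
        )
    return records


def _warn_empty(rec: MetadataRecord) -> list[MetadataRecord]:
    logger.warning("record %s has no parsable fields; skipped", rec.sample_id)
    return []


def _fill_fields(rec: MetadataRecord, lines: Iterable[str]) -> None:
    for line in lines:
        if not line.strip():
            continue
        parsed = _parse_field_line(line)
        if parsed is None:
            logger.warning("record %s: malformed line %r", rec.sample_id, line)
            continue
        rec.fields.append(parsed)


def clean_record(
    record: MetadataRecord, placeholders: Iterable[str] | None = None
) -> tuple[MetadataRecord, CleaningLog]:
    """Drop empty fields, placeholder values and wet-lab ``experiment*`` fields.

    Placeholder comparison is case-insensitive on the whole trimmed value, so
    informative text merely containing a placeholder word survives.  Cleaning
    is idempotent: running it twice yields an identical record and empty log.
    """
    placeholder_set = (
        {p.strip().lower() for p in placeholders}
        if placeholders is not None
        else set(DEFAULT_PLACEHOLDERS)
    )
    log = CleaningLog(sample_id=record.sample_id)
    kept: list[tuple[str, str]] = []
    for name, value in record.fields:
        line = f"{name}: {value}"
        if name.lower().startswith("experiment"):
            log.removed.append((line, "experiment_prefix"))
        elif not value.strip():
            log.removed.append((line, "empty"))
        elif value.strip().lower() in placeholder_set:
            log.removed.append((line, "placeholder"))
        else:
            kept.append((name, value))
    cleaned = MetadataRecord(
        sample_id=record.sample_id, fields=kept, source_path=record.source_path
    )
    return cleaned, log


def translate_ontology(
    record: MetadataRecord, ontology: OntologyDictionary
) -> tuple[MetadataRecord, CleaningLog]:
    """Replace every known CURIE token in field values by its textual label.

    CURIEs whose prefix is known but which are absent from the dictionary are
    left intact and logged as untranslated.  The field count never changes.
    """
    log = CleaningLog(sample_id=record.sample_id)
    prefixes = ontology.prefixes
    if not prefixes:
        return record, log
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(p) for p in sorted(prefixes)) + r"):(\d+)\b"
    )

    def _sub(m: re.Match) -> str:
        curie = m.group(0)
        label = ontology.entries.get(curie)
        if label is None:
            log.untranslated.append(curie)
            return curie
        log.translated.append((curie, label))
        return label

    new_fields = [(name, pattern.sub(_sub, value)) for name, value in record.fields]
    translated = MetadataRecord(
        sample_id=record.sample_id, fields=new_fields, source_path=record.source_path
    )
    return translated, log


def shard_key(sample_id: str) -> str:
    """Directory key: the last 3 digits of the accession, zero-padded.

    Sharding on trailing digits spreads millions of samples over at most
    1,000 directories deterministically.
    """
    digits = re.search(r"(\d+)$", sample_id)
    if digits is None:
        raise ValueError(f"accession {sample_id!r} has no trailing digits")
    tail = digits.group(1)[-3:]
    return tail.zfill(3)


def serialize_for_prompt(record: MetadataRecord) -> str:
    """Render one record as the text block sent to the model.

    First line is the accession, then one ``name: value`` line per field in
    stored order.  Newlines inside values are flattened to single spaces so
    the block stays line-parseable.
    """
    lines = [record.sample_id]
    for name, value in record.fields:
        flat = " ".join(value.split())
        lines.append(f"{name}: {flat}")
    return "\n".join(lines)


def deserialize_prompt_block(text: str) -> MetadataRecord:
    """Inverse of :func:`serialize_for_prompt` for flattened records."""
    lines = text.splitlines()
    if not lines or ACCESSION_RE.fullmatch(lines[0].strip()) is None:
        raise ValueError("block does not start with an accession line")
    rec = MetadataRecord(sample_id=lines[0].strip())
    _fill_fields(rec, lines[1:])
    return rec


def write_records(records: Iterable[MetadataRecord], path: str | Path) -> None:
    """Write records in the consolidated multi-record dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(serialize_for_prompt(rec))
            fh.write("\n")


def write_cleaning_logs(logs: Iterable[CleaningLog], path: str | Path) -> None:
    """One JSON object per record (JSON-lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        for log in logs:
            fh.write(log.to_json())
            fh.write("\n")


def iter_shards(records: Iterable[MetadataRecord]) -> Iterator[tuple[str, list[MetadataRecord]]]:
    """Group records by :func:`shard_key` (sorted by key)."""
    buckets: dict[str, list[MetadataRecord]] = {}
    for rec in records:
        buckets.setdefault(shard_key(rec.sample_id), []).append(rec)
    for key in sorted(buckets):
        yield key, buckets[key]
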