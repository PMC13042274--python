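"""Which metadata fields carry sample-origin information?

For each sample, the curator-assigned sub-biome is searched in every field:
a *full* match means the entire sub-biome phrase occurs with word
boundaries in the field value ("cow rumen" in "isolated from cow rumen
fluid"), a *lenient* match means any constituent content word (length >= 3,
stop-words excluded) occurs as a whole word ("rumen" in "bovine rumen").
Aggregation over a benchmark then ranks fields by how often they report the
origin, overall and per biome.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metadata_io import MetadataRecord
from .output_parser import normalize_label
from .validation import BIOMES, GoldLabel

MIN_WORD_LENGTH = 3

STOPWORDS = frozenset(
    {"the", "and", "for", "from", "with", "this", "that", "not",
     "are", "was", "were", "has", "have", "its", "other"}
)


@dataclass
class FieldMatchProfile:
    sample_id: str
    full_match_fields: set[str] = field(default_factory=set)
    lenient_match_fields: set[str] = field(default_factory=set)


def _word_re(phrase: str) -> re.Pattern:
    return re.compile(r"(?<!\w)" + re.escape(phrase) + r"(?!\w)")


def _content_words(sub_biome: str) -> list[str]:
    words = re.findall(r"[a-z0-9]+", normalize_label(sub_biome))
    return [w for w in words if len(w) >= MIN_WORD_LENGTH and w not in STOPWORDS]


def match_subbiome_fields(record: MetadataRecord, gold_sub_biome: str) -> FieldMatchProfile:
    """Find the fields whose value mentions the sub-biome, fully or in part."""
    if not gold_sub_biome:
        raise ValueError("sub_biome must be non-empty")
    phrase = normalize_label(gold_sub_biome)
    phrase_re = _word_re(phrase)
    word_res = [_word_re(w) for w in _content_words(gold_sub_biome)]
    profile = FieldMatchProfile(sample_id=record.sample_id)
    for name, value in record.fields:
        norm_value = normalize_label(value)
        if phrase_re.search(norm_value):
            profile.full_match_fields.add(name)
        if any(wr.search(norm_value) for wr in word_res):
            profile.lenient_match_fields.add(name)
    # a full phrase hit counts as a lenient hit even when all constituent
    # words fall below the length cutoff
    profile.lenient_match_fields |= profile.full_match_fields
    return profile


@dataclass
class FieldFrequencyReport:
    """Aggregate field-usage statistics over a benchmark."""

    table: pd.DataFrame            # all fields: full_count, lenient_count, mean_words
    per_biome: pd.DataFrame        # lenient counts per biome, thresholded fields only
    mean_full_per_sample: float
    sd_full_per_sample: float
    mean_lenient_per_sample: float
    sd_lenient_per_sample: float
    min_count: int


def field_frequency_report(
    profiles: Sequence[FieldMatchProfile],
    gold: Mapping[str, GoldLabel],
    records: Sequence[MetadataRecord] | None = None,
    min_count: int = 20,
) -> FieldFrequencyReport:
    """Aggregate match profiles into per-field counts and per-sample stats.

    Fields with fewer than *min_count* lenient matches are excluded from the
    per-biome breakdown but kept in the totals table.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    full_counts: dict[str, int] = {}
    lenient_counts: dict[str, int] = {}
    biome_counts: dict[str, dict[str, int]] = {}
    for profile in profiles:
        biome = gold[profile.sample_id].biome
        for name in profile.full_match_fields:
            full_counts[name] = full_counts.get(name, 0) + 1
        for name in profile.lenient_match_fields:
            lenient_counts[name] = lenient_counts.get(name, 0) + 1
            biome_counts.setdefault(name, {b: 0 for b in BIOMES})[biome] += 1

    word_means: dict[str, float] = {}
    if records is not None:
        lengths: dict[str, list[int]] = {}
        for record in records:
            for name, value in record.fields:
                lengths.setdefault(name, []).append(len(value.split()))
        word_means = {name: float(np.mean(v)) for name, v in lengths.items()}

    all_fields = sorted(set(full_counts) | set(lenient_counts))
    table = pd.DataFrame(
        {
            "field_name": all_fields,
            "full_count": [full_counts.get(f, 0) for f in all_fields],
            "lenient_count": [lenient_counts.get(f, 0) for f in all_fields],
            "mean_words": [word_means.get(f, float("nan")) for f in all_fields],
        }
    ).set_index("field_name")

    kept = [f for f in all_fields if lenient_counts.get(f, 0) >= min_count]
    per_biome = pd.DataFrame(
        {b: [biome_counts.get(f, {}).get(b, 0) for f in kept] for b in BIOMES},
        index=kept,
    )

    n_full = np.array([len(p.full_match_fields) for p in profiles], dtype=float)
    n_lenient = np.array([len(p.lenient_match_fields) for p in profiles], dtype=float)
    return FieldFrequencyReport(
        table=table,
        per_biome=per_biome,
        mean_full_per_sample=float(n_full.mean()),
        sd_full_per_sample=float(n_full.std()),
        mean_lenient_per_sample=float(n_lenient.mean()),
        sd_lenient_per_sample=float(n_lenient.std()),
        min_count=min_count,
    )


def write_field_report_csv(report: FieldFrequencyReport, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["field_name", "full_count", "lenient_count", "mean_words"]
                        + [f"lenient_{b}" for b in BIOMES])
        for name, row in report.table.iterrows():
            biome_cols = (
                list(report.per_biome.loc[name]) if name in report.per_biome.index
                else [""] * len(BIOMES)
            )
            writer.writerow([name, row["full_count"], row["lenient_count"],
                             row["mean_words"]] + biome_cols)
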