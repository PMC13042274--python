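"""Keyword-whitelist biome classifier used as the comparison baseline.

This reimplements the non-semantic approach the LLM pipeline is measured
against: tokens extracted from a sample's metadata are matched against
environment-specific term sets, and the sample is assigned the unique biome
whose set intersects its tokens.  Intersections with two or more biome term
sets (e.g. "leaf, banana, tree, insect") — or with none — yield "unknown";
for confusion-matrix comparison against the LLM, "unknown" is aligned with
the "other" category.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .metadata_io import MetadataRecord
from .validation import BIOMES

UNKNOWN = "unknown"

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@dataclass
class TermSets:
    """biome -> set of lowercase whitelist keywords (overlap is allowed)."""

    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        unknown_biomes = set(self.sets) - set(BIOMES)
        if unknown_biomes:
            raise ValueError(f"term sets for unknown biomes: {sorted(unknown_biomes)}")
        for biome, terms in self.sets.items():
            if not terms:
                raise ValueError(f"term set for {biome!r} is empty")
            self.sets[biome] = {t.lower() for t in terms}

    @classmethod
    def default(cls) -> "TermSets":
        """The small demonstration whitelists bundled with the package."""
        ref = resources.files("metabiome").joinpath("data/term_sets.tsv")
        return cls._from_tsv_text(ref.read_text(encoding="utf-8"))

    @classmethod
    def from_file(cls, path: str | Path) -> "TermSets":
        """Load from 2-column TSV (biome, keyword) or JSON (biome -> list)."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix == ".json":
            return cls({b: set(kws) for b, kws in json.loads(text).items()})
        return cls._from_tsv_text(text)

    @classmethod
    def _from_tsv_text(cls, text: str) -> "TermSets":
        sets: dict[str, set[str]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            biome, _, keyword = line.partition("\t")
            sets.setdefault(biome.strip(), set()).add(keyword.strip().lower())
        return cls(sets)


def extract_keywords(record: MetadataRecord) -> list[str]:
    """Lowercased alphanumeric(+hyphen) tokens from all field values,
    deduplicated preserving first occurrence."""
    seen: set[str] = set()
    tokens: list[str] = []
    for _, value in record.fields:
        for token in _TOKEN_RE.findall(value.lower()):
            if token not in seen:
                seen.add(token)
                tokens.append(token)
    return tokens


def classify_keywords(tokens: list[str], term_sets: TermSets) -> str:
    """The unique biome whose term set intersects the tokens, else "unknown".

    Zero intersections and multiple intersections are both indecisive and
    map to "unknown".
    """
    token_set = set(tokens)
    hits = [biome for biome, terms in term_sets.sets.items() if terms & token_set]
    return hits[0] if len(hits) == 1 else UNKNOWN


def classify_record(record: MetadataRecord, term_sets: TermSets) -> str:
    return classify_keywords(extract_keywords(record), term_sets)


def align_unknown(label: str) -> str:
    """Map "unknown" onto "other" for direct comparison with LLM output."""
    return "other" if label == UNKNOWN else label
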