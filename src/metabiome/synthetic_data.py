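"""Synthetic SRA-like benchmark generation and mock model behaviour.

The curated benchmark the pipeline was designed around (1,000 samples, 200
per biome) cannot be redistributed, so this module generates gold-labeled
metadata records that emulate its structure: verbose study abstracts,
concise host/isolation-source fields, embedded ontology codes, placeholder
noise, and coordinate fields with injectable error modes (swapped values,
sign flips, institution coordinates).  Biome curation conventions are baked
into the template banks: rhizosphere templates are gold-labeled *plant* and
sediment templates *water*.

A mock annotator emits well-formed inline or JSON responses whose biome
labels follow a configurable row-stochastic confusion matrix, enabling
parameter-recovery tests (a designed diagonal accuracy must be recovered by
the validation module within binomial error).  All outputs are deterministic
given a seed.  Template text is hand-written and synthetic; accessions use
the ``SYN`` prefix so they can never collide with real SRA records.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .geoloc import Gazetteer, GazetteerEntry
from .metadata_io import MetadataRecord, write_records
from .output_parser import Annotation, make_annotation, render_inline, render_json
from .validation import BIOMES, GoldLabel, write_gold_csv

# --- template banks (synthetic, hand-written) ------------------------------

#: Per-biome sub-biome templates: (sub_biome, scientific_name, host,
#: isolation_source, env_term).  Host None means the field is omitted.
TEMPLATES: dict[str, list[tuple[str, str, str | None, str, str]]] = {
    "animal": [
        ("human gut", "human gut metagenome", "Homo sapiens",
         "isolated from human gut contents", "animal-associated habitat"),
        ("cow rumen", "bovine rumen metagenome", "Bos taurus",
         "isolated from cow rumen fluid", "animal-associated habitat"),
        ("mouse skin", "mouse skin metagenome", "Mus musculus",
         "swab of mouse skin surface", "animal-associated habitat"),
        ("chicken cecum", "chicken gut metagenome", "Gallus gallus",
         "chicken cecum digesta", "animal-associated habitat"),
        ("human saliva", "human oral metagenome", "Homo sapiens",
         "human saliva collected by passive drool", "animal-associated habitat"),
    ],
    "plant": [
        ("olive tree leaf", "phyllosphere metagenome", "Olea europaea",
         "surface of olive tree leaf", "plant-associated habitat"),
        ("maize root", "root metagenome", "Zea mays",
         "washed maize root tissue", "plant-associated habitat"),
        ("rhizosphere", "rhizosphere metagenome", "Triticum aestivum",
         "wheat rhizosphere soil fraction", "rhizosphere"),
        ("grape leaf", "phyllosphere metagenome", "Vitis vinifera",
         "grape leaf surface wash", "plant-associated habitat"),
        ("banana leaf", "phyllosphere metagenome", "Musa acuminata",
         "banana leaf tissue from crop plantation", "plant-associated habitat"),
    ],
    "water": [
        ("river water", "freshwater metagenome", None,
         "surface river water grab sample", "river water"),
        ("sea water", "marine metagenome", None,
         "coastal sea water at 5 m depth", "sea water"),
        ("wastewater", "wastewater metagenome", None,
         "influent of municipal wastewater treatment", "wastewater"),
        ("lake water", "freshwater metagenome", None,
         "epilimnion lake water sample", "freshwater lake"),
        ("sediment", "sediment metagenome", None,
         "estuarine sediment core top layer", "sediment"),
    ],
    "soil": [
        ("agricultural", "soil metagenome", None,
         "agricultural field topsoil 0-10 cm", "agricultural soil"),
        ("forest", "soil metagenome", None,
         "forest soil organic horizon", "forest soil"),
        ("desert", "soil metagenome", None,
         "arid desert soil crust", "agricultural soil"),
        ("tundra", "soil metagenome", None,
         "permafrost tundra active layer soil", "forest soil"),
        ("peatland", "soil metagenome", None,
         "ombrotrophic peatland bog soil", "agricultural soil"),
    ],
    "other": [
        ("bioreactor", "bioreactor metagenome", None,
         "anaerobic digester bioreactor sludge", "bioreactor"),
        ("laboratory", "synthetic metagenome", None,
         "laboratory mock community standard", "bioreactor"),
        ("urban", "indoor metagenome", None,
         "urban subway handrail swab", "air"),
        ("feed/food", "food metagenome", None,
         "fermented food product sample", "air"),
        ("air", "air metagenome", None,
         "outdoor air filter collection", "air"),
    ],
}

#: CURIE stand-ins used when ontology-code noise is injected (codes resolve
#: through the bundled synthetic demo ontology dictionary).
ENV_TERM_TO_CURIE = {
    "agricultural soil": "ENVO:0000001",
    "river water": "ENVO:0000002",
    "rhizosphere": "ENVO:0000003",
    "forest soil": "ENVO:0000004",
    "sea water": "ENVO:0000005",
    "wastewater": "ENVO:0000006",
    "sediment": "ENVO:0000007",
    "air": "ENVO:0000008",
    "bioreactor": "ENVO:0000009",
    "freshwater lake": "ENVO:0000010",
}

KEYWORD_BANK: dict[str, list[str]] = {
    "animal": ["host", "gut", "microbiota", "feces", "16S rRNA", "digestive tract",
               "mucosa", "colonization", "diet", "probiotic"],
    "plant": ["leaf", "root", "rhizosphere", "phyllosphere", "crop", "plant growth",
              "endophyte", "nitrogen fixation", "field trial", "cultivar"],
    "water": ["river", "marine", "plankton", "nutrient cycling", "freshwater",
              "salinity", "depth profile", "eutrophication", "water column", "estuary"],
    "soil": ["soil", "carbon cycling", "nitrogen", "land use", "topsoil",
             "microbial diversity", "pH", "organic matter", "drought", "tillage"],
    "other": ["bioreactor", "laboratory", "urban", "built environment", "aerosol",
              "fermentation", "mock community", "process control", "sludge", "indoor"],
}

PLACEHOLDER_VALUES = ["missing", "NaN", "not applicable", "unknown", "NA"]

#: Sub-biome paraphrases applied by the mock annotator (near-gold variants).
PARAPHRASES = {
    "human gut": "human intestine",
    "cow rumen": "bovine rumen",
    "river water": "freshwater river",
    "sea water": "ocean water",
    "agricultural": "farmland soil",
    "forest": "forest soil",
    "bioreactor": "anaerobic digester",
    "rhizosphere": "root zone",
    "sediment": "estuary sediment",
    "urban": "city environment",
}

_ABSTRACT_TEMPLATE = (
    "We characterized the microbial community structure of {sub} samples using "
    "high-throughput 16S rRNA amplicon sequencing. Samples were collected near "
    "{place}, {country}, and processed under a standardized protocol. "
    "Community composition was compared across replicate {sub} sites to assess "
    "spatial and temporal variability, and taxonomic profiles were linked to "
    "environmental covariates."
)


@dataclass
class NoiseProfile:
    """Rates of the irregularities the generator and mock can inject."""

    placeholder_rate: float = 0.0
    ontology_code_rate: float = 0.0
    verbose_abstract: bool = True
    coord_error_rates: dict[str, float] = dc_field(default_factory=dict)
    omission_rate: float = 0.0
    malformation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("placeholder_rate", "ontology_code_rate", "omission_rate",
                     "malformation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(self.coord_error_rates.values())
        if any(r < 0 for r in self.coord_error_rates.values()) or total > 1.0 + 1e-9:
            raise ValueError("coordinate error rates must be non-negative and sum to <= 1")


@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic biome confusion matrix for the mock annotator."""

    rows: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for biome in BIOMES:
            row = self.rows[biome]
            total = sum(row.get(b, 0.0) for b in BIOMES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"confusion row for {biome!r} sums to {total}, not 1")

    @classmethod
    def identity(cls) -> "ConfusionSpec":
        return cls({b: {b2: 1.0 if b2 == b else 0.0 for b2 in BIOMES} for b in BIOMES})

    @classmethod
    def uniform_diagonal(cls, accuracy: float) -> "ConfusionSpec":
        """Diagonal *accuracy*, remaining mass spread evenly off-diagonal."""
        off = (1.0 - accuracy) / (len(BIOMES) - 1)
        return cls(
            {b: {b2: accuracy if b2 == b else off for b2 in BIOMES} for b in BIOMES}
        )

    def draw(self, gold_biome: str, rng: random.Random) -> str:
        u = rng.random()
        acc = 0.0
        for b in BIOMES:
            acc += self.rows[gold_biome].get(b, 0.0)
            if u < acc:
                return b
        return BIOMES[-1]


def _format_lat_lon(lat: float, lon: float) -> str:
    return (
        f"{abs(lat):.4f} {'N' if lat >= 0 else 'S'} "
        f"{abs(lon):.4f} {'E' if lon >= 0 else 'W'}"
    )


def generate_benchmark(
    n_per_biome: int,
    seed: int,
    noise: NoiseProfile | None = None,
    gazetteer: Gazetteer | None = None,
) -> tuple[list[MetadataRecord], dict[str, GoldLabel]]:
    """Generate 5 x n_per_biome gold-labeled SRA-like records.

    Each record draws a sub-biome template of its biome (host, isolation
    source, scientific name, environmental term), a sampling location from
    the gazetteer (reflected in abstract, location and lat/lon fields), and
    optional placeholder / ontology-code noise at the profile's rates.
    Deterministic for a fixed seed.
    """
    if n_per_biome < 1:
        raise ValueError("n_per_biome must be >= 1")
    noise = noise or NoiseProfile()
    gazetteer = gazetteer or Gazetteer.from_csv()
    places = gazetteer.places()
    rng = random.Random(seed)
    records: list[MetadataRecord] = []
    gold: dict[str, GoldLabel] = {}
    counter = 1
    for biome in BIOMES:
        for _ in range(n_per_biome):
            sid = f"SYN{counter:06d}"
            counter += 1
            sub, sci_name, host, iso_source, env_term = rng.choice(TEMPLATES[biome])
            place = rng.choice(places)
            fields: list[tuple[str, str]] = [
                ("study_STUDY_TITLE", f"Microbial community survey of {sub} samples"),
            ]
            if noise.verbose_abstract:
                fields.append(
                    ("study_STUDY_ABSTRACT",
                     _ABSTRACT_TEMPLATE.format(sub=sub, place=place.name,
                                               country=place.country))
                )
            fields.append(("sample_SCIENTIFIC_NAME", sci_name))
            if host is not None:
                fields.append(("sample_host", host))
            fields.append(("sample_isolation_source", iso_source))
            env_value = env_term
            if rng.random() < noise.ontology_code_rate and env_term in ENV_TERM_TO_CURIE:
                env_value = ENV_TERM_TO_CURIE[env_term]
            fields.append(("sample_env_biome", env_value))
            fields.append(
                ("sample_geographic location (country and/or sea)",
                 f"{place.country}: {place.name}")
            )
            fields.append(("lat_lon", _format_lat_lon(place.point.lat, place.point.lon)))
            if rng.random() < noise.placeholder_rate:
                fields.append(("sample_age", rng.choice(PLACEHOLDER_VALUES)))
                fields.append(("experiment_library_strategy", "AMPLICON"))
            records.append(MetadataRecord(sample_id=sid, fields=fields))
            gold[sid] = GoldLabel(sample_id=sid, biome=biome, sub_biome=sub)
    return records, gold


def record_location_text(record: MetadataRecord) -> str | None:
    """'Place, Country' text from the record's geographic-location field."""
    value = record.get("sample_geographic location (country and/or sea)")
    if value is None:
        return None
    country, _, place = value.partition(":")
    place, country = place.strip(), country.strip()
    return f"{place}, {country}" if place else country


# --- mock annotation -------------------------------------------------------

def draw_annotation(
    sample_id: str,
    gold_label: GoldLabel,
    seed: int,
    confusion: ConfusionSpec,
    paraphrase_rate: float = 0.2,
    location: str | None = None,
) -> Annotation:
    """Deterministically sample one mock annotation for a sample.

    The randomness is keyed on (seed, sample_id) only, so the same sample
    receives the same answer no matter how requests are chunked or retried.
    """
    rng = random.Random(f"{seed}:ann:{sample_id}")
    biome = confusion.draw(gold_label.biome, rng)
    sub = gold_label.sub_biome
    if rng.random() < paraphrase_rate:
        sub = PARAPHRASES.get(sub, f"{sub} sample")
    bank = KEYWORD_BANK[biome]
    n_kw = rng.randint(5, 8)
    keywords = rng.sample(bank, min(n_kw, len(bank)))
    return make_annotation(sample_id, biome, location, keywords, sub)


def mock_annotate(
    sample_ids: Sequence[str],
    gold: Mapping[str, GoldLabel],
    confusion: ConfusionSpec | None = None,
    seed: int = 0,
    noise: NoiseProfile | None = None,
    response_format: str = "inline",
    locations: Mapping[str, str | None] | None = None,
    paraphrase_rate: float = 0.2,
) -> str:
    """Emit a raw LLM-style response for *sample_ids*.

    Biome labels follow the confusion distribution; omission and
    malformation are applied per sample at the noise profile's rates
    (omitted samples are absent from the response, malformed inline lines
    lose a field, malformed JSON entries lose their id).
    """
    confusion = confusion or ConfusionSpec.identity()
    noise = noise or NoiseProfile()
    annotations: list[Annotation] = []
    malformed: list[str] = []
    for sid in sample_ids:
        rng_noise = random.Random(f"{seed}:noise:{sid}")
        if rng_noise.random() < noise.omission_rate:
            continue
        loc = locations.get(sid) if locations else None
        ann = draw_annotation(sid, gold[sid], seed, confusion, paraphrase_rate, loc)
        if rng_noise.random() < noise.malformation_rate:
            malformed.append(sid)
        annotations.append(ann)
    if response_format == "inline":
        text = render_inline(annotations)
        if malformed:
            lines = text.splitlines()
            bad = set(malformed)
            lines = [
                ln.rsplit("___", 1)[0] if ln.split("___", 1)[0] in bad else ln
                for ln in lines
            ]
            text = "\n".join(lines)
        return text
    if response_format == "json":
        import json as _json

        kept = [a for a in annotations if a.sample_id not in set(malformed)]
        text = render_json(kept)
        if malformed:
            objs = _json.loads(text)
            # malformed entries lose their sample id, so their expected IDs
            # are reported missing and queued for retry
            objs.extend({"biome": "unparseable"} for _ in malformed)
            text = _json.dumps(objs, indent=1)
        return text
    raise ValueError(f"unknown response format: {response_format}")


# --- coordinate error injection -------------------------------------------

COORD_ERROR_MODES = (
    "latlon_swapped",
    "lon_sign_neg",
    "lon_sign_pos",
    "lat_sign_neg",
    "institution_coords",
    "metadata_completely_wrong",
)


def _replace_location(
    record: MetadataRecord, old: GazetteerEntry, new: GazetteerEntry
) -> MetadataRecord:
    fields = [
        (name,
         value.replace(old.name, new.name).replace(old.country, new.country))
        for name, value in record.fields
    ]
    return MetadataRecord(record.sample_id, fields, record.source_path)


def inject_coordinate_errors(
    records: Sequence[MetadataRecord],
    rates: Mapping[str, float],
    seed: int,
    gazetteer: Gazetteer | None = None,
) -> tuple[list[MetadataRecord], pd.DataFrame]:
    """Corrupt coordinates of a random subset of records, one mode each.

    Sign-flip modes require a suitable hemisphere, so affected records are
    first relocated to a compatible gazetteer place (all location fields
    rewritten consistently) before the corruption is applied.  Returns the
    mutated records and a truth table (sample_id, mode, true/stored coords)
    enabling triage-recovery tests.
    """
    from .geoloc import parse_lat_lon  # local import to keep module load light

    unknown = set(rates) - set(COORD_ERROR_MODES)
    if unknown:
        raise ValueError(f"unknown coordinate error modes: {sorted(unknown)}")
    gazetteer = gazetteer or Gazetteer.from_csv()
    places = gazetteer.places()
    by_name = {p.name: p for p in places}
    # hemisphere-compatible pools; margins keep corrections well beyond the
    # 100 km triage threshold
    pool = {
        "latlon_swapped": [p for p in places if abs(p.point.lat - p.point.lon) > 5],
        "lon_sign_neg": [p for p in places if p.point.lon > 5 and abs(p.point.lat) < 66],
        "lon_sign_pos": [p for p in places if p.point.lon < -5 and abs(p.point.lat) < 66],
        "lat_sign_neg": [p for p in places if p.point.lat > 5],
    }
    institutions = gazetteer.institutions()
    mode_names = list(rates)
    cum: list[tuple[str, float]] = []
    acc = 0.0
    for mode in mode_names:
        acc += rates[mode]
        cum.append((mode, acc))

    out: list[MetadataRecord] = []
    rows = []
    for record in records:
        rng = random.Random(f"{seed}:coord:{record.sample_id}")
        u = rng.random()
        mode = next((m for m, edge in cum if u < edge), None)
        point = parse_lat_lon(record)
        if mode is None or point is None:
            out.append(record)
            continue
        rec = record
        if mode in pool:
            loc_text = record_location_text(record)
            current = by_name.get(loc_text.split(",")[0].strip()) if loc_text else None
            if current is None or current not in pool[mode]:
                new = rng.choice(pool[mode])
                if current is not None:
                    rec = _replace_location(record, current, new)
                point = new.point
                # rewrite the coordinate field for the new location
                rec = _set_lat_lon(rec, point.lat, point.lon)
        lat, lon = point.lat, point.lon
        if mode == "latlon_swapped":
            stored = (lon, lat)
        elif mode in ("lon_sign_neg", "lon_sign_pos"):
            stored = (lat, -lon)
        elif mode == "lat_sign_neg":
            stored = (-lat, lon)
        elif mode == "institution_coords":
            inst = rng.choice(institutions)
            stored = (inst.point.lat, inst.point.lon)
        else:  # metadata_completely_wrong: random distant relocation
            from .geoloc import GeoPoint, haversine_km

            while True:
                cand = (rng.uniform(-60, 70), rng.uniform(-179, 179))
                if haversine_km(GeoPoint(*cand), GeoPoint(lat, lon)) > 1000:
                    stored = cand
                    break
        rec = _set_lat_lon(rec, stored[0], stored[1], raw=True)
        out.append(rec)
        rows.append(
            {"sample_id": record.sample_id, "mode": mode,
             "true_lat": lat, "true_lon": lon,
             "stored_lat": stored[0], "stored_lon": stored[1]}
        )
    truth = pd.DataFrame(rows, columns=["sample_id", "mode", "true_lat", "true_lon",
                                        "stored_lat", "stored_lon"])
    return out, truth


def _set_lat_lon(record: MetadataRecord, lat: float, lon: float, raw: bool = False) -> MetadataRecord:
    """Rewrite the lat_lon field; raw pairs use the signed-decimal form,
    which can represent out-of-bounds swap artifacts."""
    value = f"{lat:.4f}, {lon:.4f}" if raw else _format_lat_lon(lat, lon)
    fields = [
        (name, value if name == "lat_lon" else v) for name, v in record.fields
    ]
    return MetadataRecord(record.sample_id, fields, record.source_path)


def write_fixture_bundle(
    directory: str | Path,
    records: Sequence[MetadataRecord],
    gold: Mapping[str, GoldLabel],
    truth: pd.DataFrame | None = None,
    noise: NoiseProfile | None = None,
) -> None:
    """Write records (metadata dialect), gold CSV, truth table, noise JSON."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_records(records, directory / "records.txt")
    write_gold_csv(gold, directory / "gold.csv")
    if truth is not None:
        truth.to_csv(directory / "coord_truth.csv", index=False)
    if noise is not None:
        (directory / "noise_profile.json").write_text(
            json.dumps(
                {
                    "placeholder_rate": noise.placeholder_rate,
                    "ontology_code_rate": noise.ontology_code_rate,
                    "verbose_abstract": noise.verbose_abstract,
                    "coord_error_rates": noise.coord_error_rates,
                    "omission_rate": noise.omission_rate,
                    "malformation_rate": noise.malformation_rate,
                },
                indent=2,
            )
        )
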