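import pytest

from metabiome.geoloc import Gazetteer
from metabiome.metadata_io import MetadataRecord, OntologyDictionary
from metabiome.synthetic_data import NoiseProfile, generate_benchmark


@pytest.fixture(scope="session")
def gazetteer() -> Gazetteer:
    return Gazetteer.from_csv()


@pytest.fixture()
def demo_ontology() -> OntologyDictionary:
    return OntologyDictionary(
        {
            "ENVO:0000001": "test biome",
            "ENVO:0000002": "river water",
            "UBERON:0000001": "gut",
        }
    )


@pytest.fixture()
def sample_record() -> MetadataRecord:
    return MetadataRecord(
        sample_id="SRS994677",
        fields=[
            ("sample_isolation_source", "cow rumen"),
            ("sample_host", "NaN"),
            ("experiment_library_strategy", "AMPLICON"),
            ("sample_env_biome", "ENVO:0000001"),
            ("study_STUDY_ABSTRACT", "Digester wastewater sampled in Zurich, Switzerland."),
            ("empty_field", "   "),
        ],
    )


@pytest.fixture(scope="session")
def clean_benchmark():
    """Small zero-noise synthetic benchmark shared across tests."""
    records, gold = generate_benchmark(10, seed=11, noise=NoiseProfile())
    return records, gold
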