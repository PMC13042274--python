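# metabiome

**LLM-assisted re-annotation of microbiome sequencing metadata — with a fully
offline validation harness.**

Public sequence repositories hold millions of microbiome samples whose
submitter-provided metadata is verbose, inconsistent, and littered with
placeholders ("missing", "NaN", "TODO"). That makes the single most useful
piece of context — *where did this sample come from?* — hard to recover
programmatically. `metabiome` implements a pipeline that re-annotates such
records against a simple operational scheme: five **biomes** (`animal`,
`plant`, `water`, `soil`, `other`), a concise free-text **sub-biome**
("human gut", "river water"), a geographic location, and 5–8 descriptive
keywords — by cleaning each record, packing records into token-budgeted
requests, prompting a chat-completion model, parsing and reconciling its
answers, and scoring the result against curator labels.

It is aimed at researchers curating SRA/BioSample-scale metadata and at
anyone who needs a reproducible, testable harness around an LLM annotation
loop. No network access or model account is needed to use the validation
machinery: a deterministic mock backend, a hashing text embedder, and an
offline gazetteer stand in for the remote services.

## What is inside

| Module | Role |
| --- | --- |
| `metadata_io` | parse/clean records, translate ontology CURIEs (ENVO, FOODON, …) to labels, shard by accession, serialize for prompting |
| `chunker` | token counting (pluggable; default ≈ chars/4) and first-fit-decreasing packing under a token budget |
| `llm_interface` | system-prompt variants, sync/async submission, transport retries, missing-ID retry loop, run-parameter filenames |
| `output_parser` | inline (`___`-separated) and JSON response dialects, strict ID reconciliation |
| `keyword_baseline` | the keyword-whitelist classifier used as the non-LLM comparison baseline |
| `validation` | exact/lenient matching, accuracy/precision/F1/Cohen's κ, McNemar + t tests + Bonferroni, embedding cosine similarity |
| `geoloc` | coordinate extraction, haversine distances, distance categories, mismatch triage (swaps, sign flips, institution coordinates) |
| `field_analysis` | which metadata fields actually report the sample origin |
| `synthetic_data` | gold-labeled SRA-like benchmark generator and mock model behaviour |
| `pipeline_cli` | end-to-end orchestration, cost estimator, `metabiome` command line |

Scoring has two criteria. An **exact** match requires the predicted label to
equal the curator's after normalization. A **lenient** match accepts exactly
one allowed biome word plus clarifying text (`"animal (incl. human)"`), which
models produce under some decoding settings; ambiguous answers containing two
biome words fail both. Cohen's κ is computed from the full confusion matrix
(unresolved predictions count as wrong in a sixth column):

κ = (p_o − p_e) / (1 − p_e)

Run comparisons pick their test from the sample-ID sets: McNemar's test
(paired binary outcomes) plus a paired t test on cosine similarities when
the IDs coincide, Welch t tests when they are disjoint, with Bonferroni
correction across each comparison family.

## Worked example

```python
from metabiome import (RequestConfig, PipelinePaths, run_pipeline,
                       generate_benchmark)
from metabiome.metadata_io import write_records
from metabiome.validation import write_gold_csv
from pathlib import Path

records, gold = generate_benchmark(n_per_biome=10, seed=11)
write_records(records, "records.txt")
write_gold_csv(gold, "gold.csv")

manifest = run_pipeline(
    RequestConfig(rs=3, chunksize=3000),
    PipelinePaths(metadata=Path("records.txt"), outdir=Path("out"),
                  gold=Path("gold.csv")),
)
print(manifest.metrics)
```

prints (mock backend, zero-noise benchmark):

```
{'exact_accuracy': 100.0, 'exact_kappa': 1.0,
 'lenient_accuracy': 100.0, 'lenient_kappa': 1.0,
 'geo_text_match_rate': 100.0}
```

meaning every one of the 50 generated samples was annotated with its gold
biome (both criteria), agreement is perfect (κ = 1), and every predicted
location textually matches the location reverse-geocoded from the record's
coordinates. `out/` contains the consolidated annotation CSV (named after
the run parameters), per-sample results, the geolocation report, cleaning
logs, and a JSON manifest. The same flow works from the shell:

```bash
metabiome generate-benchmark --outdir bench --n-per-biome 10 --seed 11
metabiome run --metadata bench/records.txt --gold bench/gold.csv --outdir out
metabiome estimate-cost --n-tokens 1044000000 --price-per-million 0.5 --reduction 0.35
```

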