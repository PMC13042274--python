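# Methods

This note documents the models, procedures, numerical choices, and known
limitations behind `metabiome`, in the spirit of a package's own methods
section. It states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## The annotation task and its assumptions

Each sample is a bag of `field: value` metadata lines. The pipeline assigns
four attributes: an operational **biome** from a closed five-label scheme
(`animal`, `plant`, `water`, `soil`, `other`), a free-text **sub-biome** of
at most three words, a textual **location** including the country, and 5–8
**keywords**. The biome scheme is a controlled label for source context, not
an ecological or ENVO biome; by convention rhizosphere samples are `plant`
and sediment samples are `water`, and those conventions are baked into both
the "better" prompt variant and the synthetic template banks. The scheme
assumes every sample has a single dominant origin; genuinely ambiguous
samples (a coastal sediment, a mock community from a gut study) are an
irreducible error source for any classifier under this scheme.

## Metadata cleaning

Cleaning removes three kinds of lines: empty values; values that are, in
their entirety (case-insensitive, trimmed), one of the placeholder strings
`missing, NaN, not applicable, unknown, NA, none, null`; and fields whose
name begins with `experiment` (case-insensitive), which describe wet-lab
procedure rather than sample origin. Placeholder matching is deliberately
whole-value, never substring, so informative text like "NaN-free soil"
survives. Cleaning is idempotent and fully logged (JSON-lines, one object
per record). CURIE translation replaces ontology codes (`ENVO:0000001`)
with their textual labels using a word-boundary regex restricted to the
prefixes present in the loaded dictionary — this avoids false hits inside
longer identifiers — and logs lookup misses without failing. Whether the
original SRA exports also used placeholders like "n/a" or "-" is unknowable
from the outside; the placeholder set is a parameter.

The consolidated-file dialect (records delimited by a bare accession line,
fields split at the first colon) is an assumption: the upstream archive
format's exact grammar is not published. The parser is deliberately
forgiving — malformed lines are warned about, never silently dropped.

## Token counting and chunking

The default tokenizer approximation is `ceil(characters / 4)`, a standard
rule of thumb for BPE tokenizers on English text; the tokenizer is a plain
`text -> int` callable so a vendor-exact counter can be plugged in. Packing
uses first-fit decreasing: sort samples by token count descending (ties
broken by accession, ascending, for bit-reproducible runs), place each into
the first chunk with room under `capacity − prompt_tokens`, else open a new
chunk. FFD carries the classical guarantee of at most `(11/9)·OPT + 6/9`
bins; the test suite verifies `≤ (11/9)·OPT + 1` against an exhaustive
oracle on all instances of ≤ 8 items. Samples exceeding the effective
budget become flagged singleton chunks rather than errors, leaving the
disposition (send anyway, truncate, skip) to the caller.

## Prompts

The standard inline prompt asks for the five-way source category, the
location, 5–8 curly-braced keywords, and an up-to-3-word sub-biome, with
`NA` for missing information and values separated by `___`; it embeds a
worked example response. The "better" variant is exactly the standard
prompt plus one clause directing rhizosphere to `plant` and sediment to
`water`. The JSON variant requests an array of objects instead of inline
lines. The standard prompt is stored verbatim as package data; the better
and JSON variants are *reconstructions* (their original full texts are not
public) built from the standard prompt plus the documented deltas, and the
code treats their precise wording as configuration, not ground truth.

## Request orchestration and the retry contract

Synchronous submission performs one backend call per chunk; asynchronous
submission is one request per sample, never chunked. Transport failures
(network-level) are retried up to 3 times with exponential backoff and are
kept strictly separate from content failures: after parsing, sample IDs
missing from the output or failing the format are re-requested —
**always unchunked**, to isolate per-sample failures — up to `max_retries`
(default 2) rounds. Whatever remains is reported with status `unresolved`
and scored as wrong downstream; nothing is silently dropped. Output
filenames encode every run parameter (`nspb`, `rs`, chunking, chunk size,
model, max tokens, the four decoding parameters, free-text tag, request
count or batch id, timestamp) and parse back into a config, so a results
file is self-describing.

The decoding-parameter defaults (`temp=1.0`, `topp=1.0`, `freqp=0.0`,
`presp=0.0`) are the baseline settings from which perturbation experiments
depart; bounds (`temp ∈ [0,2]`, `topp ∈ [0,1]`, penalties `∈ [−2,2]`) are
enforced at construction.

## Response parsing

The inline dialect splits each line on the literal `___` into exactly five
fields; the first must be a syntactically valid accession (this rejects
chatter/header lines even when they happen to contain four separators).
Keywords come from the curly-brace block, comma-split. The JSON dialect
accepts a single object or an array, normalizes key aliases
(`id`/`sample_id`, `sub-biome`/`sub_biome`, …), splits comma-joined keyword
strings, and treats syntactically invalid JSON as a whole-response failure
(all expected IDs become missing). Soft prompt contracts — keyword count
outside 5–8, sub-biome longer than 3 words — *flag* the annotation instead
of rejecting it: models violate these bounds under some settings, and
discarding such answers would bias accuracy measurement. Duplicate IDs keep
the first occurrence; unexpected IDs are recorded separately. The parser
never raises on arbitrary input; every failure is data in the parse report,
and `|parsed| + |missing| = |expected|` holds for any input.

## Scoring

Exact match: normalized prediction equals the gold label. Lenient match:
exactly one of the five labels occurs as a complete word and equals the
gold label — so `"animal (incl. human)"` counts, `"animals"` does not, and
a prediction containing two biome words is ambiguous and fails. Lenient is
by construction implied by exact, so lenient accuracy ≥ exact accuracy.

Aggregate metrics live on a 5-gold-row × 6-column confusion layout whose
sixth column collects unresolved and out-of-vocabulary predictions
(counting them as errors mirrors a production consumer's experience).
Precision/recall/F1 are **macro-averaged** over the five biomes — the
benchmark design is balanced per biome, and macro matches the per-biome
framing; this averaging choice is a documented reconstruction, as is the
whole-matrix κ. McNemar's test uses the χ²(1) statistic `(b−c)²/(b+c)`
without continuity correction when the discordant count `b+c ≥ 25` and the
exact two-sided binomial probability below that (standard practice; the
variant used originally is unstated). Paired t tests compare cosine
similarity vectors on shared IDs; Welch's t is used for disjoint sample
sets; Bonferroni (`p·m`, capped at 1) adjusts within each comparison
family. Degenerate inputs are pinned down: zero discordance gives `p = 1`;
an all-zero paired difference vector gives `p = 1`; a constant non-zero
difference vector is an error (no variance to test against).

Sub-biome agreement uses embedding cosine similarity behind a provider
contract. The bundled offline provider is a hashed bag of word tokens plus
character 3-grams (dimension 256, word weight 3): deterministic, and built
so texts sharing more whole words score higher — sufficient for contract
and monotonicity tests, but *not* a semantic embedding; absolute similarity
values from it are not comparable to any remote embedding model, and
vectors from different providers are refused comparison.

## Geolocation consistency

Coordinates are extracted from `lat_lon`-style fields (hemisphere-letter
"37.77 N 122.42 W" and signed-decimal forms) or separate latitude/longitude
fields; out-of-bounds values are rejected with a warning, but a separate
raw-pair extractor preserves them because triage needs the pair exactly as
stored (a swapped pair is out of bounds by construction). Distances use the
haversine formula with mean Earth radius 6371.0 km. Mismatch distances are
bucketed into half-open, lower-inclusive intervals [0,100), [100,500),
[500,1000), [1000,4000), [4000,∞) km — the boundary convention is ours, as
only the category labels are conventional. Text matching between the
predicted location and the reverse-geocoded one is word-level containment
in either direction after lowercasing and punctuation stripping; this is a
documented reconstruction of an unspecified criterion, chosen so "Los
Angeles, USA" matches a fuller geocoder string while genuinely different
names ("McMurdo Station" vs "Antarctica") do not.

Triage tests candidate corrections of the stored pair against the
forward-geocoded prediction: swap(lat, lon), longitude sign flip, latitude
sign flip, each accepted when the corrected point lands within 100 km
(configurable) of the prediction; a stored point within 100 km of a known
institution is classified as institution coordinates; anything else is
"metadata completely wrong". A stored point already within the threshold
is a precondition violation (it should have matched upstream) and is
reported as a semantic name mismatch by the report builder. Geocoding is a
pluggable contract; the bundled gazetteer (~50 places + 5 institutions
with real coordinates) replaces remote geocoders so the whole suite runs
offline. Its coarse reverse-geocode radius (300 km nearest-entry) is a
stand-in, not a production geocoder.

## Field informativeness

A field *fully* reports the origin when the normalized sub-biome phrase
occurs with word boundaries in its value, and *leniently* when any
constituent word of length ≥ 3 (stop-words excluded — the cutoff stops
"of"/"in" from inflating counts) occurs as a whole word. Aggregation
reports per-field counts, per-sample means and SDs (population SD), and a
per-biome breakdown from which fields with fewer than 20 lenient matches
(configurable) are excluded while totals keep them.

## Synthetic benchmark and mock model

The generator emulates the structure of the curated 1,000-sample benchmark
(200 per biome) without shipping any real metadata: per-biome template
banks (hand-written, synthetic) provide hosts, isolation sources,
scientific names, environmental terms and sub-biome vocabulary, including
the rhizosphere-as-plant and sediment-as-water conventions; sampling
locations come from the gazetteer and appear consistently in the abstract,
the location field, and the coordinate field. Noise is injected at
configurable rates: placeholder fields plus an `experiment_*` line,
ontology codes in place of textual terms, response omission and
malformation, and one coordinate error mode per affected sample (swap,
either longitude sign flip, latitude sign flip, institution coordinates,
random distant relocation ≥ 1000 km) with a truth table for recovery
tests. Sign-flip modes first relocate the sample to a hemisphere where the
flip is well-defined and moves the point far beyond the 100 km triage
threshold (|lon| > 5°, |lat| < 66° for longitude flips, and so on).
Accessions use a `SYN` prefix to be unmistakably synthetic.

The mock annotator draws each sample's biome from a row-stochastic
confusion matrix keyed on `(seed, sample_id)` only, so an answer is
identical regardless of chunking or retry order; sub-biomes are gold or a
near-gold paraphrase (default rate 0.2), keywords come from per-biome
banks, and the omission/malformation machinery produces exactly the failure
shapes the parser and retry loop must handle. What passing tests therefore
demonstrate is that the *machinery* — cleaning, packing, parsing,
reconciliation, scoring, triage — is correct and bit-reproducible; they say
nothing about how well any actual language model classifies real SRA
records, which requires live model access and the original curated
benchmark.

## Cost model

`cost = n_tokens · (1 − reduction) · price_per_million / 10⁶`, with a
reporting helper rounding to the nearest ten currency units. The cleaning
stage's token reduction is the input to this model, not an output of it.

## Problem sizes in tests

The default suite and the acceptance script use a 1,000-sample benchmark
for parameter recovery (binomial 3·SE band around a designed 0.806
diagonal accuracy), 2,000 samples for coordinate-triage recovery, 200
samples for the retry contract, exhaustive enumeration up to `b+c = 24`
discordant pairs for McNemar, ≤ 8-item instances against the exact
bin-packing oracle, and 2,000 Monte-Carlo replicates for t-test
calibration. These sizes make the statistical bands tight enough to be
meaningful while keeping the whole suite to a few seconds.

## Known limitations

- No live LLM, embedding, or geocoding service is bundled or called; the
  remote-backend client is provided but unexercised by the suite.
- The inline dialect assumes answers never contain a literal `___` inside a
  field value.
- The gazetteer is tiny; reverse geocoding at production quality needs a
  real geocoder behind the same contract.
- The keyword baseline ships demonstration whitelists only; reproducing any
  particular production keyword system requires its term sets.
- Ontology translation consumes a pre-built CURIE→label TSV; parsing OBO/OWL
  sources is out of scope.
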