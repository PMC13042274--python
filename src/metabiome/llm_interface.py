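"""Prompt construction, request submission, and ID reconciliation with retry.

Three system-prompt variants are supported: the standard inline prompt, a
"better" variant adding explicit guidance for the two hardest curation
conventions (rhizosphere -> plant, sediment -> water), and a JSON variant
requesting structured output.  The standard prompt is stored verbatim; the
better and JSON variants are reconstructions built from it (see
docs/methods.md).

Requests go through a pluggable backend contract.  The bundled mock backend
answers deterministically from gold labels through a configurable confusion
matrix, with controllable omission and malformation, which makes the whole
submit -> parse -> retry loop testable offline and bit-reproducible under a
fixed seed.  Sample IDs missing from a response or failing to parse are
re-requested (always unchunked) up to a retry budget; whatever remains is
reported as unresolved, never silently dropped.
"""

from __future__ import annotations

import abc
import json
import logging
import random
import re
import time
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

from .chunker import Chunk
from .metadata_io import ACCESSION_RE
from .output_parser import Annotation, ParseReport, parse_response

logger = logging.getLogger(__name__)

PROMPT_VARIANTS = ("standard_inline", "better_inline", "json")

#: Clause appended to the standard prompt in the "better" variant.
BETTER_CLAUSE = (
    "Please note that rhizosphere samples should be categorized as 'plant' "
    "and sediment samples as 'water'."
)


def build_system_prompt(variant: str) -> str:
    """Return the full system prompt for a variant.

    ``better_inline`` is exactly the standard prompt plus the
    rhizosphere/sediment clause, so the delta between the two is the clause
    itself.
    """
    if variant not in PROMPT_VARIANTS:
        raise ValueError(f"unknown prompt variant: {variant!r}; use one of {PROMPT_VARIANTS}")
    prompts = resources.files("metabiome").joinpath("prompts")
    if variant == "json":
        return prompts.joinpath("json.txt").read_text(encoding="utf-8")
    standard = prompts.joinpath("standard_inline.txt").read_text(encoding="utf-8")
    if variant == "standard_inline":
        return standard
    return standard + "\n" + BETTER_CLAUSE + "\n"


class RequestConfig(BaseModel):
    """Run parameters, mirroring the pipeline's command-line flag set."""

    model: str = "gpt-3.5-turbo-0125"
    maxtokens: int = Field(default=4096, ge=1)
    temp: float = Field(default=1.0, ge=0.0, le=2.0)
    topp: float = Field(default=1.0, ge=0.0, le=1.0)
    freqp: float = Field(default=0.0, ge=-2.0, le=2.0)
    presp: float = Field(default=0.0, ge=-2.0, le=2.0)
    chunking: bool = True
    chunksize: int = Field(default=3000, ge=1)
    nspb: int = Field(default=200, ge=1)  # samples per biome
    rs: int = 42  # random seed
    opt_text: str = ""
    mode: Literal["sync", "async"] = "sync"

    @model_validator(mode="after")
    def _async_never_chunked(self) -> "RequestConfig":
        if self.mode == "async" and self.chunking:
            object.__setattr__(self, "chunking", False)
        return self


class TransportError(RuntimeError):
    """A network-level failure, distinct from a content/parse failure."""


class LLMBackend(abc.ABC):
    """Contract every backend (remote API or offline mock) fulfils."""

    @abc.abstractmethod
    def complete(self, system_prompt: str, payload: str, config: RequestConfig) -> str:
        """One synchronous chat completion; returns the raw response text."""

    @abc.abstractmethod
    def submit_batch(self, requests: Sequence[tuple[str, str]], config: RequestConfig) -> str:
        """Submit (system_prompt, payload) pairs; returns an opaque batch id."""

    @abc.abstractmethod
    def fetch_batch(self, batch_id: str) -> list[str] | None:
        """Raw responses for a batch, or None while still pending."""


class MockLLMBackend(LLMBackend):
    """Deterministic offline backend generating answers from gold labels.

    Biome labels follow the configured confusion matrix; omission (once per
    sample by default, so a retry succeeds) and permanent omission are
    controllable for retry-contract tests.  Identical (payload, seed) always
    produce identical output.
    """

    def __init__(
        self,
        gold,
        confusion=None,
        seed: int = 0,
        response_format: str = "inline",
        omission_rate: float = 0.0,
        malformation_rate: float = 0.0,
        omit_once: bool = True,
        permanent_omit: Iterable[str] = (),
        locations: Mapping[str, str | None] | None = None,
        paraphrase_rate: float = 0.2,
    ):
        from .synthetic_data import ConfusionSpec

        self.gold = gold
        self.confusion = confusion or ConfusionSpec.identity()
        self.seed = seed
        self.response_format = response_format
        self.omission_rate = omission_rate
        self.malformation_rate = malformation_rate
        self.omit_once = omit_once
        self.permanent_omit = set(permanent_omit)
        self.locations = locations or {}
        self.paraphrase_rate = paraphrase_rate
        self.calls = 0
        self._seen: set[str] = set()
        self._batches: dict[str, list[str]] = {}

    def _ids_in_payload(self, payload: str) -> list[str]:
        ids = []
        for line in payload.splitlines():
            line = line.strip()
            if ACCESSION_RE.fullmatch(line):
                ids.append(line)
        return ids

    def _respond(self, payload: str) -> str:
        from .synthetic_data import NoiseProfile, mock_annotate

        self.calls += 1
        ids = self._ids_in_payload(payload)
        kept = []
        for sid in ids:
            if sid in self.permanent_omit:
                continue
            rng = random.Random(f"{self.seed}:omit:{sid}")
            first_time = sid not in self._seen
            self._seen.add(sid)
            if first_time and self.omit_once and rng.random() < self.omission_rate:
                continue
            kept.append(sid)
        return mock_annotate(
            kept,
            self.gold,
            confusion=self.confusion,
            seed=self.seed,
            noise=NoiseProfile(malformation_rate=self.malformation_rate),
            response_format=self.response_format,
            locations=self.locations,
            paraphrase_rate=self.paraphrase_rate,
        )

    def complete(self, system_prompt: str, payload: str, config: RequestConfig) -> str:
        return self._respond(payload)

    def submit_batch(self, requests: Sequence[tuple[str, str]], config: RequestConfig) -> str:
        batch_id = f"mock{len(self._batches):06d}"
        self._batches[batch_id] = [self._respond(payload) for _, payload in requests]
        return batch_id

    def fetch_batch(self, batch_id: str) -> list[str] | None:
        return self._batches.get(batch_id)


class OpenAICompatBackend(LLMBackend):
    """Minimal client for an OpenAI-compatible chat-completions endpoint.

    Endpoint and key come from the caller (typically a config file plus an
    environment variable for the secret).  Not exercised in the offline test
    suite; the contract is validated against the mock backend.
    """

    def __init__(self, endpoint: str, api_key: str, timeout_s: float = 120.0):
        self.endpoint = endpoint.rstrip("/")
        self.api_key = api_key
        self.timeout_s = timeout_s

    def complete(self, system_prompt: str, payload: str, config: RequestConfig) -> str:
        body = json.dumps(
            {
                "model": config.model,
                "max_tokens": config.maxtokens,
                "temperature": config.temp,
                "top_p": config.topp,
                "frequency_penalty": config.freqp,
                "presence_penalty": config.presp,
                "messages": [
                    {"role": "system", "content": system_prompt},
                    {"role": "user", "content": payload},
                ],
            }
        ).encode("utf-8")
        req = urllib.request.Request(
            f"{self.endpoint}/chat/completions",
            data=body,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {self.api_key}",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout_s) as resp:
                data = json.loads(resp.read().decode("utf-8"))
        except OSError as exc:
            raise TransportError(str(exc)) from exc
        return data["choices"][0]["message"]["content"]

    def submit_batch(self, requests: Sequence[tuple[str, str]], config: RequestConfig) -> str:
        raise NotImplementedError("batch submission requires the vendor batch API")

    def fetch_batch(self, batch_id: str) -> list[str] | None:
        raise NotImplementedError("batch retrieval requires the vendor batch API")


# --- submission ------------------------------------------------------------

#: Transport-level retry policy (distinct from content/parse retries).
MAX_TRANSPORT_ATTEMPTS = 3


def _complete_with_transport_retry(
    backend: LLMBackend,
    system_prompt: str,
    payload: str,
    config: RequestConfig,
    backoff_base_s: float = 0.5,
) -> str | None:
    for attempt in range(MAX_TRANSPORT_ATTEMPTS):
        try:
            return backend.complete(system_prompt, payload, config)
        except TransportError as exc:
            logger.warning("transport failure (attempt %d): %s", attempt + 1, exc)
            if attempt < MAX_TRANSPORT_ATTEMPTS - 1 and backoff_base_s > 0:
                time.sleep(backoff_base_s * 2**attempt)
    return None


def submit_sync(
    chunks: Sequence[Chunk],
    sample_texts: Mapping[str, str],
    config: RequestConfig,
    backend: LLMBackend,
    system_prompt: str,
    backoff_base_s: float = 0.5,
) -> tuple[list[str], int]:
    """One backend call per chunk; returns (raw responses, request count).

    A chunk's payload is the concatenation of its members' serialized
    records.  Chunks whose transport retries are exhausted yield no response
    and their IDs surface later as missing.
    """
    if config.mode != "sync":
        raise ValueError("submit_sync requires config.mode == 'sync'")
    responses: list[str] = []
    for chunk in chunks:
        payload = "\n".join(sample_texts[sid] for sid in chunk.members)
        raw = _complete_with_transport_retry(
            backend, system_prompt, payload, config, backoff_base_s
        )
        if raw is not None:
            responses.append(raw)
    return responses, len(chunks)


def submit_async(
    sample_texts: Mapping[str, str],
    config: RequestConfig,
    backend: LLMBackend,
    system_prompt: str,
    poll_interval_s: float = 0.0,
    max_polls: int = 100,
) -> tuple[list[str], str]:
    """Batch submission: exactly one request per sample, never chunked."""
    requests = [(system_prompt, text) for _, text in sorted(sample_texts.items())]
    batch_id = backend.submit_batch(requests, config)
    for _ in range(max_polls):
        raw = backend.fetch_batch(batch_id)
        if raw is not None:
            return raw, batch_id
        if poll_interval_s:
            time.sleep(poll_interval_s)
    raise TransportError(f"batch {batch_id} still pending after {max_polls} polls")


@dataclass
class PipelineResult:
    """Outcome of submit -> parse -> retry for one run."""

    annotations: dict[str, Annotation] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)
    reports: list[ParseReport] = field(default_factory=list)
    retry_rounds: int = 0
    backend_calls: int = 0


def reconcile_and_retry(
    expected_ids: Iterable[str],
    sample_texts: Mapping[str, str],
    raw_responses: Sequence[str],
    config: RequestConfig,
    backend: LLMBackend,
    system_prompt: str,
    dialect: str = "inline",
    max_retries: int = 2,
    backoff_base_s: float = 0.5,
) -> PipelineResult:
    """Parse responses, re-request missing/malformed IDs, report leftovers.

    Retries are always unchunked (one sample per request) regardless of the
    original run's chunking, isolating per-sample failures.  IDs still
    unresolved after the retry budget keep status ``unresolved``.
    """
    expected = set(expected_ids)
    result = PipelineResult()
    outstanding = expected
    for raw in raw_responses:
        annotations, report = parse_response(raw, outstanding, dialect)
        result.reports.append(report)
        for ann in annotations:
            result.annotations.setdefault(ann.sample_id, ann)
    missing = expected - set(result.annotations)

    rounds = 0
    calls = 0
    while missing and rounds < max_retries:
        rounds += 1
        still_missing: set[str] = set()
        for sid in sorted(missing):
            raw = _complete_with_transport_retry(
                backend, system_prompt, sample_texts[sid], config, backoff_base_s
            )
            calls += 1
            if raw is None:
                still_missing.add(sid)
                continue
            annotations, report = parse_response(raw, {sid}, dialect)
            result.reports.append(report)
            if annotations:
                result.annotations.setdefault(sid, annotations[0])
            else:
                still_missing.add(sid)
        missing = still_missing
    for sid in sorted(missing):
        ann = Annotation(sample_id=sid, biome_raw="", status="unresolved")
        result.annotations[sid] = ann
        result.unresolved.add(sid)
    result.retry_rounds = rounds
    result.backend_calls = calls
    return result


# --- output filename convention -------------------------------------------

_FILENAME_KEYS = (
    "nspb", "rs", "chunking", "chunksize", "model", "maxtokens",
    "temp", "topp", "freqp", "presp", "opt",
)

_SAFE_RE = re.compile(r"[^A-Za-z0-9.+-]")


def _sanitize(value: str) -> str:
    return _SAFE_RE.sub("-", value)


def output_filename(
    config: RequestConfig,
    timestamp: datetime,
    request_count: int | None = None,
    batch_id: str | None = None,
    extension: str = "csv",
) -> str:
    """Encode the run parameters into the consolidated output's filename.

    Synchronous runs embed the total request count; asynchronous runs embed
    the word ``batch`` plus the vendor batch id.  The filename parses back
    into a :class:`RequestConfig` via :func:`parse_output_filename`.
    """
    parts = [
        f"nspb-{config.nspb}",
        f"rs-{config.rs}",
        f"chunking-{config.chunking}",
        f"chunksize-{config.chunksize}",
        f"model-{_sanitize(config.model)}",
        f"maxtokens-{config.maxtokens}",
        f"temp-{config.temp}",
        f"topp-{config.topp}",
        f"freqp-{config.freqp}",
        f"presp-{config.presp}",
        f"opt-{_sanitize(config.opt_text)}",
    ]
    if config.mode == "async":
        if batch_id is None:
            raise ValueError("async filenames require a batch_id")
        parts.append(f"batch-{_sanitize(batch_id)}")
    else:
        parts.append(f"req-{request_count if request_count is not None else 0}")
    parts.append(f"ts-{timestamp.strftime('%Y%m%dT%H%M%S')}")
    return "__".join(parts) + f".{extension}"


def parse_output_filename(name: str) -> tuple[RequestConfig, dict]:
    """Inverse of :func:`output_filename`.

    Returns the reconstructed config plus extras (request_count or batch_id,
    and the timestamp).
    """
    stem = name.rsplit(".", 1)[0]
    kv: dict[str, str] = {}
    for part in stem.split("__"):
        key, _, value = part.partition("-")
        kv[key] = value
    extras: dict = {}
    mode = "async" if "batch" in kv else "sync"
    if mode == "async":
        extras["batch_id"] = kv["batch"]
    else:
        extras["request_count"] = int(kv["req"])
    extras["timestamp"] = datetime.strptime(kv["ts"], "%Y%m%dT%H%M%S")
    config = RequestConfig(
        nspb=int(kv["nspb"]),
        rs=int(kv["rs"]),
        chunking=kv["chunking"] == "True",
        chunksize=int(kv["chunksize"]),
        model=kv["model"],
        maxtokens=int(kv["maxtokens"]),
        temp=float(kv["temp"]),
        topp=float(kv["topp"]),
        freqp=float(kv["freqp"]),
        presp=float(kv["presp"]),
        opt_text=kv["opt"],
        mode=mode,
    )
    return config, extras
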