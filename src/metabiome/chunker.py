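"""Token counting and first-fit-decreasing packing of samples into requests.

Submitting one sample per request wastes tokens on repeating the system
prompt.  Chunking packs several samples' serialized metadata into one request
under a token budget (``chunksize``) that includes the system prompt.  The
packing heuristic is first-fit decreasing (FFD): sort samples by token count
descending, then place each into the first open chunk with room, opening a
new chunk when none fits.  FFD is the classical bin-packing heuristic with a
worst-case guarantee of (11/9)*OPT + 6/9 bins.

Token counting is a pluggable contract; the default approximation is
ceil(characters / 4), a conventional rule of thumb for BPE tokenizers on
English text.  Vendor-exact counting can be plugged in where available.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

#: A tokenizer is any text -> token-count callable.
Tokenizer = Callable[[str], int]


def approx_tokenizer(text: str) -> int:
    """Default token-count approximation: ceil(len(text) / 4)."""
    return math.ceil(len(text) / 4)


def count_tokens(text: str, tokenizer: Tokenizer = approx_tokenizer) -> int:
    """Count tokens of *text* under the given tokenizer contract."""
    if not text:
        return 0
    n = tokenizer(text)
    if n < 0:
        raise ValueError("tokenizer returned a negative count")
    return n


@dataclass(frozen=True)
class TokenizedSample:
    sample_id: str
    token_count: int

    def __post_init__(self) -> None:
        if self.token_count < 0:
            raise ValueError("token_count must be non-negative")


@dataclass
class Chunk:
    """An ordered set of samples packed under a token budget for one request."""

    members: list[str] = field(default_factory=list)
    payload_tokens: int = 0
    capacity: int = 0
    oversize_flag: bool = False


class ChunkingConfigError(ValueError):
    pass


def pack_ffd(
    samples: Sequence[TokenizedSample], capacity: int, prompt_tokens: int = 0
) -> list[Chunk]:
    """Pack samples into the fewest chunks by first-fit decreasing.

    ``capacity`` is the whole-request token budget including the system
    prompt, so the payload budget per chunk is ``capacity - prompt_tokens``.
    Samples are considered in descending token order (ties broken by
    ascending sample_id for full determinism); each goes into the first
    existing chunk it fits, else opens a new chunk.  Samples too large for an
    empty chunk become singleton chunks with ``oversize_flag`` set rather
    than errors.
    """
    if capacity <= prompt_tokens:
        raise ChunkingConfigError(
            f"capacity ({capacity}) must exceed prompt_tokens ({prompt_tokens})"
        )
    effective = capacity - prompt_tokens
    ordered = sorted(samples, key=lambda s: (-s.token_count, s.sample_id))
    chunks: list[Chunk] = []
    oversize: list[Chunk] = []
    for sample in ordered:
        if sample.token_count > effective:
            oversize.append(
                Chunk(
                    members=[sample.sample_id],
                    payload_tokens=sample.token_count,
                    capacity=capacity,
                    oversize_flag=True,
                )
            )
            continue
        for chunk in chunks:
            if chunk.payload_tokens + sample.token_count <= effective:
                chunk.members.append(sample.sample_id)
                chunk.payload_tokens += sample.token_count
                break
        else:
            chunks.append(
                Chunk(
                    members=[sample.sample_id],
                    payload_tokens=sample.token_count,
                    capacity=capacity,
                )
            )
    return chunks + oversize


def tokenize_samples(
    texts: dict[str, str], tokenizer: Tokenizer = approx_tokenizer
) -> list[TokenizedSample]:
    """Measure each serialized sample text once with a single tokenizer."""
    return [
        TokenizedSample(sample_id=sid, token_count=count_tokens(text, tokenizer))
        for sid, text in texts.items()
    ]


def write_chunk_manifest(chunks: Iterable[Chunk], path: str | Path) -> None:
    """CSV manifest: chunk_index, sample_id, token_count (chunk payload), oversize_flag."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chunk_index", "sample_id", "payload_tokens", "oversize_flag"])
        for i, chunk in enumerate(chunks):
            for sid in chunk.members:
                writer.writerow([i, sid, chunk.payload_tokens, chunk.oversize_flag])
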