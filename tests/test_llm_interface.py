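"""Prompt variants, filename convention, mock backend, submission and retry."""

from datetime import datetime

import pytest

from metabiome.chunker import Chunk
from metabiome.llm_interface import (
    BETTER_CLAUSE,
    MockLLMBackend,
    RequestConfig,
    TransportError,
    build_system_prompt,
    output_filename,
    parse_output_filename,
    reconcile_and_retry,
    submit_async,
    submit_sync,
)
from metabiome.metadata_io import serialize_for_prompt
from metabiome.validation import GoldLabel


@pytest.fixture()
def gold5():
    subs = ["human gut", "rhizosphere", "river water", "forest", "bioreactor"]
    biomes = ["animal", "plant", "water", "soil", "other"]
    return {
        f"SYN{i:06d}": GoldLabel(f"SYN{i:06d}", biomes[i - 1], subs[i - 1])
        for i in range(1, 6)
    }


def texts_for(gold):
    return {sid: f"{sid}\nsample_isolation_source: {g.sub_biome}" for sid, g in gold.items()}


class TestPrompts:
    def test_standard_contains_keyword_instruction(self):
        assert "Extract strictly 5–8 keywords" in build_system_prompt("standard_inline")

    def test_standard_contains_separator_instruction(self):
        text = build_system_prompt("standard_inline")
        assert '3 underscores ("___")' in text
        assert "SRS123456___animal___Los Angeles, USA" in text

    def test_better_is_standard_plus_clause(self):
        standard = build_system_prompt("standard_inline")
        better = build_system_prompt("better_inline")
        assert better.startswith(standard)
        delta = better[len(standard):].strip()
        assert delta == BETTER_CLAUSE
        assert ("rhizosphere samples should be categorized as 'plant' "
                "and sediment samples as 'water'") in better

    def test_json_variant_requests_json(self):
        assert "JSON format" in build_system_prompt("json")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            build_system_prompt("clever_prompt")


class TestRequestConfig:
    def test_async_forces_unchunked(self):
        config = RequestConfig(mode="async", chunking=True)
        assert config.chunking is False

    def test_decoding_parameter_bounds(self):
        with pytest.raises(ValueError):
            RequestConfig(temp=2.5)
        with pytest.raises(ValueError):
            RequestConfig(freqp=-3.0)


class TestOutputFilename:
    def test_round_trip_identity(self):
        config = RequestConfig(nspb=100, rs=7, chunking=True, chunksize=2000,
                               model="gpt-3.5-turbo-0125", maxtokens=512,
                               temp=0.5, topp=0.9, freqp=-0.5, presp=1.5,
                               opt_text="pilot")
        name = output_filename(config, datetime(2026, 9, 22, 10, 0, 0), request_count=37)
        parsed, extras = parse_output_filename(name)
        assert parsed == config
        assert extras["request_count"] == 37
        assert output_filename(parsed, extras["timestamp"], request_count=37) == name

    def test_async_contains_batch(self):
        config = RequestConfig(mode="async")
        name = output_filename(config, datetime(2026, 1, 1), batch_id="abc123")
        assert "batch-abc123" in name
        parsed, extras = parse_output_filename(name)
        assert parsed.mode == "async" and extras["batch_id"] == "abc123"

    def test_distinct_seeds_distinct_names(self):
        ts = datetime(2026, 1, 1)
        a = output_filename(RequestConfig(rs=1), ts, request_count=1)
        b = output_filename(RequestConfig(rs=2), ts, request_count=1)
        assert a != b


class TestSubmitSync:
    def test_one_call_per_chunk(self, gold5):
        texts = texts_for(gold5)
        ids = sorted(texts)
        chunks = [Chunk(members=ids[:3]), Chunk(members=ids[3:])]
        backend = MockLLMBackend(gold5, seed=1)
        responses, count = submit_sync(chunks, texts, RequestConfig(), backend, "sys")
        assert count == 2 and backend.calls == 2 and len(responses) == 2

    def test_empty_chunk_list(self, gold5):
        backend = MockLLMBackend(gold5, seed=1)
        responses, count = submit_sync([], texts_for(gold5), RequestConfig(), backend, "sys")
        assert responses == [] and count == 0 and backend.calls == 0

    def test_unchunked_is_one_request_per_sample(self, gold5):
        texts = texts_for(gold5)
        chunks = [Chunk(members=[sid]) for sid in sorted(texts)]
        backend = MockLLMBackend(gold5, seed=1)
        _, count = submit_sync(chunks, texts, RequestConfig(chunking=False), backend, "sys")
        assert count == len(texts)

    def test_transport_failures_retried_then_dropped(self, gold5):
        texts = texts_for(gold5)

        class FlakyBackend(MockLLMBackend):
            def __init__(self, *a, fail_times=0, **kw):
                super().__init__(*a, **kw)
                self.fail_times = fail_times

            def complete(self, system_prompt, payload, config):
                if self.fail_times > 0:
                    self.fail_times -= 1
                    raise TransportError("boom")
                return super().complete(system_prompt, payload, config)

        flaky = FlakyBackend(gold5, seed=1, fail_times=2)
        responses, _ = submit_sync(
            [Chunk(members=sorted(texts))], texts, RequestConfig(), flaky, "sys",
            backoff_base_s=0,
        )
        assert len(responses) == 1  # succeeded on 3rd transport attempt

        always = FlakyBackend(gold5, seed=1, fail_times=99)
        responses, _ = submit_sync(
            [Chunk(members=sorted(texts))], texts, RequestConfig(), always, "sys",
            backoff_base_s=0,
        )
        assert responses == []


class TestAsync:
    def test_one_request_per_sample_never_chunked(self, gold5):
        texts = texts_for(gold5)
        backend = MockLLMBackend(gold5, seed=1)
        responses, batch_id = submit_async(
            texts, RequestConfig(mode="async"), backend, "sys"
        )
        assert len(responses) == len(texts)
        assert batch_id.startswith("mock")


class TestReconcileAndRetry:
    def test_all_parsed_first_pass_no_retry(self, gold5):
        texts = texts_for(gold5)
        backend = MockLLMBackend(gold5, seed=1)
        raw = backend.complete("sys", "\n".join(texts.values()), RequestConfig())
        result = reconcile_and_retry(
            texts.keys(), texts, [raw], RequestConfig(), backend, "sys",
            backoff_base_s=0,
        )
        assert result.unresolved == set()
        assert result.retry_rounds == 0 and result.backend_calls == 0

    def test_omit_once_resolved_after_one_retry(self, gold5):
        texts = texts_for(gold5)
        backend = MockLLMBackend(gold5, seed=5, omission_rate=0.5, omit_once=True)
        raw = backend.complete("sys", "\n".join(texts.values()), RequestConfig())
        result = reconcile_and_retry(
            texts.keys(), texts, [raw], RequestConfig(), backend, "sys",
            max_retries=2, backoff_base_s=0,
        )
        assert result.unresolved == set()
        assert result.retry_rounds <= 1
        assert len(result.annotations) == len(texts)

    def test_permanent_omission_reported_unresolved(self, gold5):
        texts = texts_for(gold5)
        victim = sorted(texts)[0]
        backend = MockLLMBackend(gold5, seed=1, permanent_omit={victim})
        raw = backend.complete("sys", "\n".join(texts.values()), RequestConfig())
        result = reconcile_and_retry(
            texts.keys(), texts, [raw], RequestConfig(), backend, "sys",
            max_retries=2, backoff_base_s=0,
        )
        assert result.unresolved == {victim}
        assert result.annotations[victim].status == "unresolved"
        # exactly 2 retry calls for the single missing ID
        assert result.backend_calls == 2 and result.retry_rounds == 2

    def test_bit_reproducible_with_fixed_seed(self, gold5):
        texts = texts_for(gold5)

        def run():
            backend = MockLLMBackend(gold5, seed=9, omission_rate=0.3)
            raw = backend.complete("sys", "\n".join(texts.values()), RequestConfig())
            result = reconcile_and_retry(
                texts.keys(), texts, [raw], RequestConfig(), backend, "sys",
                backoff_base_s=0,
            )
            return [(sid, ann.core()) for sid, ann in sorted(result.annotations.items())]

        assert run() == run()
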