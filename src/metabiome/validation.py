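"""Scoring of model annotations against curator gold labels.

Biome predictions are scored with two criteria: an *exact* match (the
prediction equals the gold label after normalization) and a *lenient* match
(exactly one of the five allowed biome labels occurs as a complete word in
the prediction — capturing outputs like ``"animal (incl. human)"`` — and it
equals the gold label).  Lenient is strictly weaker than exact, so lenient
accuracy is always >= exact accuracy.

Aggregate metrics (accuracy, macro precision/recall/F1, Cohen's kappa,
confusion matrices) are computed from definitions over a 5-biome + "none"
column layout, where unresolved or unparseable predictions count as wrong
rather than being excluded.  Run-to-run comparisons use McNemar's test for
paired binary outcomes on shared sample IDs (chi-square form for >= 25
discordant pairs, exact binomial otherwise), paired or Welch t-tests for
similarity scores, and a Bonferroni family correction.

Sub-biome agreement is quantified by cosine similarity between text
embeddings; the embedding provider is a contract, with a deterministic
hashing bag-of-tokens embedder bundled for offline use.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .output_parser import Annotation, normalize_label

BIOMES = ("animal", "plant", "water", "soil", "other")
NONE_LABEL = "none"

_BIOME_WORD_RE = re.compile(r"\b(" + "|".join(BIOMES) + r")\b")


@dataclass(frozen=True)
class GoldLabel:
    """Curator-assigned biome and sub-biome for one sample."""

    sample_id: str
    biome: str
    sub_biome: str

    def __post_init__(self) -> None:
        if self.biome not in BIOMES:
            raise ValueError(f"gold biome {self.biome!r} not in {BIOMES}")
        if not self.sub_biome:
            raise ValueError("sub_biome must be non-empty")


def load_gold_csv(path: str | Path) -> dict[str, GoldLabel]:
    """Gold table CSV with columns sample_id, biome, sub_biome."""
    gold: dict[str, GoldLabel] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            gold[row["sample_id"]] = GoldLabel(
                row["sample_id"], row["biome"], row["sub_biome"]
            )
    return gold


def write_gold_csv(gold: Mapping[str, GoldLabel], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "biome", "sub_biome"])
        for sid in sorted(gold):
            g = gold[sid]
            writer.writerow([g.sample_id, g.biome, g.sub_biome])


@dataclass(frozen=True)
class MatchResult:
    exact: bool
    lenient: bool


def extract_biome_label(prediction: str) -> str | None:
    """The unique allowed biome occurring as a whole word, else None."""
    found = set(_BIOME_WORD_RE.findall(normalize_label(prediction)))
    if len(found) == 1:
        return found.pop()
    return None


def match_biome(prediction: str, gold: str) -> MatchResult:
    """Score one biome prediction against the gold label.

    Exact: the normalized prediction equals the gold label verbatim.
    Lenient: exactly one allowed label occurs as a complete word (extra
    clarifying text permitted) and it equals the gold label.  A prediction
    containing two distinct biome words is ambiguous and fails both.
    """
    if gold not in BIOMES:
        raise ValueError(f"gold biome {gold!r} not in {BIOMES}")
    norm = normalize_label(prediction)
    exact = norm == gold
    lenient = extract_biome_label(norm) == gold
    return MatchResult(exact=exact, lenient=lenient)


@dataclass
class MetricsReport:
    """Aggregate biome classification metrics (percent scales)."""

    accuracy: float
    per_biome_accuracy: dict[str, float]
    precision: float
    recall: float
    f1: float
    kappa: float
    confusion: pd.DataFrame  # rows: gold biomes; cols: biomes + "none"
    confusion_normalized: pd.DataFrame
    n: int


def _assigned_label(prediction: str | Annotation | None, match_mode: str) -> str:
    """Map a prediction to a confusion-matrix column."""
    if prediction is None:
        return NONE_LABEL
    if isinstance(prediction, Annotation):
        if prediction.status == "unresolved":
            return NONE_LABEL
        prediction = prediction.biome_raw
    norm = normalize_label(prediction)
    if match_mode == "exact":
        return norm if norm in BIOMES else NONE_LABEL
    label = extract_biome_label(norm)
    return label if label is not None else NONE_LABEL


def compute_metrics(
    predictions: Mapping[str, str | Annotation | None],
    gold: Mapping[str, GoldLabel],
    match_mode: str = "lenient",
) -> MetricsReport:
    """Score predictions against gold labels under *match_mode*.

    Unresolved or out-of-vocabulary predictions land in a sixth "none"
    column and count as errors.  Precision/recall/F1 are macro-averaged over
    the five biomes; kappa is computed from the full confusion matrix.
    """
    if match_mode not in ("exact", "lenient"):
        raise ValueError(f"unknown match_mode: {match_mode}")
    ids = sorted(set(gold) & set(predictions))
    if not ids:
        raise ValueError("no overlapping sample IDs between predictions and gold")
    cols = list(BIOMES) + [NONE_LABEL]
    counts = pd.DataFrame(0, index=list(BIOMES), columns=cols, dtype=int)
    for sid in ids:
        counts.loc[gold[sid].biome, _assigned_label(predictions[sid], match_mode)] += 1

    n = len(ids)
    mat = counts.to_numpy(dtype=float)
    diag = np.array([counts.loc[b, b] for b in BIOMES], dtype=float)
    row_sums = mat.sum(axis=1)
    col_sums = mat.sum(axis=0)[: len(BIOMES)]
    accuracy = diag.sum() / n

    per_biome = {
        b: (100.0 * diag[i] / row_sums[i]) if row_sums[i] else float("nan")
        for i, b in enumerate(BIOMES)
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col_sums > 0, diag / col_sums, 0.0)
        rec = np.where(row_sums > 0, diag / row_sums, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)

    # kappa over the square 6x6 layout (the "none" gold row is empty)
    square = np.zeros((len(cols), len(cols)))
    square[: len(BIOMES), :] = mat
    p_o = np.trace(square) / n
    p_e = float(square.sum(axis=1) @ square.sum(axis=0)) / (n * n)
    if abs(1 - p_e) < 1e-12:
        kappa = 1.0 if abs(1 - p_o) < 1e-12 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)

    normalized = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    return MetricsReport(
        accuracy=100.0 * accuracy,
        per_biome_accuracy=per_biome,
        precision=100.0 * float(prec.mean()),
        recall=100.0 * float(rec.mean()),
        f1=100.0 * float(f1.mean()),
        kappa=float(kappa),
        confusion=counts,
        confusion_normalized=normalized,
        n=n,
    )


# --- statistical tests ----------------------------------------------------

@dataclass
class StatTestResult:
    test_name: str  # mcnemar | paired_t | independent_t
    statistic: float
    p: float
    p_adjusted: float | None = None
    n: int | None = None
    b: int | None = None  # A-only successes (McNemar)
    c: int | None = None  # B-only successes (McNemar)


#: Discordant-pair threshold below which the exact binomial form is used.
MCNEMAR_EXACT_THRESHOLD = 25


def mcnemar_test(paired: Sequence[tuple[bool, bool]]) -> StatTestResult:
    """McNemar's test for paired binary outcomes.

    With b and c the discordant counts (A-only and B-only successes): for
    b + c >= 25 the chi-square form (b-c)^2/(b+c) on 1 df; below that, the
    exact two-sided binomial probability of min(b, c) under Binomial(b+c, 1/2).
    b + c = 0 yields statistic 0 and p = 1 by convention.
    """
    b = sum(1 for a_ok, b_ok in paired if a_ok and not b_ok)
    c = sum(1 for a_ok, b_ok in paired if b_ok and not a_ok)
    nd = b + c
    if nd == 0:
        return StatTestResult("mcnemar", 0.0, 1.0, n=len(paired), b=b, c=c)
    statistic = (b - c) ** 2 / nd
    if nd >= MCNEMAR_EXACT_THRESHOLD:
        p = float(stats.chi2.sf(statistic, df=1))
    else:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), nd, 0.5)))
    return StatTestResult("mcnemar", float(statistic), p, n=len(paired), b=b, c=c)


def t_tests(
    sims_a: Sequence[float], sims_b: Sequence[float], paired: bool
) -> StatTestResult:
    """Two-sided t test on similarity (or correctness) scores.

    Paired form for shared sample IDs; Welch's independent form otherwise.
    Degenerate paired input (all differences identical): p = 1 when the
    common difference is zero, error otherwise (no variance to test against).
    """
    a = np.asarray(sims_a, dtype=float)
    b = np.asarray(sims_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired t-test requires equal-length vectors")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        diffs = a - b
        if np.ptp(diffs) == 0:
            if diffs[0] == 0:
                return StatTestResult("paired_t", 0.0, 1.0, n=len(a))
            raise ValueError("zero-variance non-zero paired differences")
        res = stats.ttest_rel(a, b)
        return StatTestResult("paired_t", float(res.statistic), float(res.pvalue), n=len(a))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
        return StatTestResult("independent_t", 0.0 if a[0] == b[0] else np.inf, p, n=len(a) + len(b))
    res = stats.ttest_ind(a, b, equal_var=False)
    return StatTestResult("independent_t", float(res.statistic), float(res.pvalue), n=len(a) + len(b))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Family-wise adjustment: p_adj = min(1, p * m)."""
    m = len(p_values)
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in p_values]


# --- embeddings -----------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingVector:
    values: np.ndarray
    provider: str

    @property
    def dimension(self) -> int:
        return int(self.values.shape[0])


class EmbeddingProvider(Protocol):
    """Contract for embedding backends (remote service or offline mock)."""

    name: str

    def embed_one(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Deterministic offline embedder: hashed bag of word tokens + char 3-grams.

    Word tokens are weighted more heavily than character trigrams so that
    texts sharing more whole words score a higher cosine similarity, while
    trigrams give partial credit to morphological variants.  Identical texts
    always map to identical vectors.
    """

    def __init__(self, dimension: int = 256, word_weight: float = 3.0):
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self.word_weight = word_weight
        self.name = f"hashing-{dimension}"

    def _bucket(self, token: str) -> int:
        digest = hashlib.md5(token.encode("utf-8")).digest()
        return int.from_bytes(digest[:4], "big") % self.dimension

    def embed_one(self, text: str) -> np.ndarray:
        if not text or not text.strip():
            raise ValueError("cannot embed empty text")
        vec = np.zeros(self.dimension)
        words = re.findall(r"[\w-]+", text.lower())
        for word in words:
            vec[self._bucket("w:" + word)] += self.word_weight
            padded = f"#{word}#"
            for i in range(len(padded) - 2):
                vec[self._bucket("g:" + padded[i : i + 3])] += 1.0
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError("text produced no tokens")
        return vec / norm


def embed_texts(
    texts: Sequence[str], provider: EmbeddingProvider
) -> tuple[list[EmbeddingVector | None], list[tuple[int, str]]]:
    """Embed each text; failures become per-text error records, never silent."""
    vectors: list[EmbeddingVector | None] = []
    errors: list[tuple[int, str]] = []
    for i, text in enumerate(texts):
        try:
            vectors.append(EmbeddingVector(provider.embed_one(text), provider.name))
        except Exception as exc:  # noqa: BLE001 - contract: error records, not raises
            vectors.append(None)
            errors.append((i, str(exc)))
    return vectors, errors


def cosine_similarity(a: EmbeddingVector, b: EmbeddingVector) -> float:
    """dot(a, b) / (|a| |b|); vectors must share provider and dimension."""
    if a.provider != b.provider:
        raise ValueError("refusing to compare embeddings from different providers")
    if a.dimension != b.dimension:
        raise ValueError("dimension mismatch")
    na, nb = np.linalg.norm(a.values), np.linalg.norm(b.values)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    return float(np.dot(a.values, b.values) / (na * nb))


# --- run scoring and comparison -------------------------------------------

@dataclass
class SampleScore:
    sample_id: str
    gold_biome: str
    pred_biome: str
    exact: bool
    lenient: bool
    cosine_sim: float | None = None


def score_run(
    annotations: Mapping[str, Annotation],
    gold: Mapping[str, GoldLabel],
    embedder: EmbeddingProvider | None = None,
) -> dict[str, SampleScore]:
    """Per-sample exact/lenient correctness plus sub-biome cosine similarity.

    Samples present in gold but unresolved (absent from *annotations*) are
    scored as non-matches with no similarity.
    """
    scores: dict[str, SampleScore] = {}
    for sid, g in gold.items():
        ann = annotations.get(sid)
        if ann is None or ann.status == "unresolved":
            scores[sid] = SampleScore(sid, g.biome, "", exact=False, lenient=False)
            continue
        m = match_biome(ann.biome_raw, g.biome)
        sim = None
        if embedder is not None and ann.sub_biome:
            vecs, errs = embed_texts([ann.sub_biome, g.sub_biome], embedder)
            if not errs:
                sim = cosine_similarity(vecs[0], vecs[1])
        scores[sid] = SampleScore(sid, g.biome, ann.biome_raw, m.exact, m.lenient, sim)
    return scores


@dataclass
class ComparisonReport:
    """Paired/unpaired comparison of two scored runs with Bonferroni family."""

    design: str  # paired | independent
    tests: list[StatTestResult] = field(default_factory=list)


def compare_runs(
    run_a: Mapping[str, SampleScore],
    run_b: Mapping[str, SampleScore],
    criterion: str = "lenient",
) -> ComparisonReport:
    """Compare two scored runs, choosing the test design from the ID sets.

    Identical ID sets: McNemar on biome correctness + paired t on cosine
    similarity.  Disjoint sets: Welch t on correctness indicators and on
    similarities.  Partial overlap is ambiguous and raises.
    """
    ids_a, ids_b = set(run_a), set(run_b)
    overlap = ids_a & ids_b
    if ids_a == ids_b:
        ids = sorted(ids_a)
        correct = [
            (getattr(run_a[sid], criterion), getattr(run_b[sid], criterion)) for sid in ids
        ]
        tests = [mcnemar_test(correct)]
        sims = [
            (run_a[sid].cosine_sim, run_b[sid].cosine_sim)
            for sid in ids
            if run_a[sid].cosine_sim is not None and run_b[sid].cosine_sim is not None
        ]
        if len(sims) >= 2:
            tests.append(t_tests([s[0] for s in sims], [s[1] for s in sims], paired=True))
        design = "paired"
    elif not overlap:
        a_correct = [float(getattr(s, criterion)) for s in run_a.values()]
        b_correct = [float(getattr(s, criterion)) for s in run_b.values()]
        tests = [t_tests(a_correct, b_correct, paired=False)]
        a_sims = [s.cosine_sim for s in run_a.values() if s.cosine_sim is not None]
        b_sims = [s.cosine_sim for s in run_b.values() if s.cosine_sim is not None]
        if len(a_sims) >= 2 and len(b_sims) >= 2:
            tests.append(t_tests(a_sims, b_sims, paired=False))
        design = "independent"
    else:
        raise ValueError(
            "runs share only part of their sample IDs; restrict to the "
            "intersection for a paired design or disjoint sets for unpaired"
        )
    adjusted = bonferroni([t.p for t in tests])
    for t, p_adj in zip(tests, adjusted):
        t.p_adjusted = p_adj
    return ComparisonReport(design=design, tests=tests)


def write_results_csv(scores: Mapping[str, SampleScore], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "gold_biome", "pred_biome", "exact", "lenient", "cosine_sim"])
        for sid in sorted(scores):
            s = scores[sid]
            writer.writerow(
                [s.sample_id, s.gold_biome, s.pred_biome, s.exact, s.lenient,
                 f"{s.cosine_sim:.4f}" if s.cosine_sim is not None else ""]
            )


def write_stats_csv(reports: Mapping[str, ComparisonReport], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["comparison", "test_name", "statistic", "p", "p_adjusted"])
        for name, report in reports.items():
            for t in report.tests:
                writer.writerow([name, t.test_name, t.statistic, t.p, t.p_adjusted])
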