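"""Match rules, metrics vs from-definitions oracles, paired statistics, embeddings."""

import math
import random

import numpy as np
import pytest
from scipy import stats as sps

from metabiome.output_parser import make_annotation
from metabiome.validation import (
    BIOMES,
    EmbeddingVector,
    GoldLabel,
    HashingEmbedder,
    bonferroni,
    compare_runs,
    compute_metrics,
    cosine_similarity,
    embed_texts,
    match_biome,
    mcnemar_test,
    score_run,
    t_tests,
)


class TestMatchBiome:
    @pytest.mark.parametrize(
        "pred,gold,exact,lenient",
        [
            ("animal", "animal", True, True),
            ("Animal ", "animal", True, True),
            ("animal (human)", "animal", False, True),
            ("animal (incl. human)", "animal", False, True),
            ("animals", "animal", False, False),
            ("animal or soil", "animal", False, False),  # ambiguous: two labels
            ("wetland", "water", False, False),
            ("soil", "water", False, False),
        ],
    )
    def test_examples(self, pred, gold, exact, lenient):
        m = match_biome(pred, gold)
        assert (m.exact, m.lenient) == (exact, lenient)

    def test_exact_implies_lenient_over_many_predictions(self):
        rng = random.Random(0)
        snippets = ["animal", "plant (leaf)", "soil", "soils", "water body",
                    "other", "animal water", "", "Water"]
        for _ in range(200):
            pred = rng.choice(snippets)
            gold = rng.choice(BIOMES)
            m = match_biome(pred, gold)
            assert m.lenient or not m.exact


def oracle_metrics(pairs):
    """From-definitions metrics oracle over (gold, predicted) label pairs.

    Pure-python loops, independent of the implementation under test.
    """
    n = len(pairs)
    correct = sum(1 for g, p in pairs if g == p)
    accuracy = 100.0 * correct / n
    precs, recs, f1s = [], [], []
    for b in BIOMES:
        tp = sum(1 for g, p in pairs if g == b and p == b)
        pred_b = sum(1 for _, p in pairs if p == b)
        gold_b = sum(1 for g, _ in pairs if g == b)
        prec = tp / pred_b if pred_b else 0.0
        rec = tp / gold_b if gold_b else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    labels = list(BIOMES) + ["none"]
    p_o = correct / n
    p_e = sum(
        (sum(1 for g, _ in pairs if g == lab) / n)
        * (sum(1 for _, p in pairs if p == lab) / n)
        for lab in labels
    )
    kappa = (p_o - p_e) / (1 - p_e) if abs(1 - p_e) > 1e-12 else 1.0
    return accuracy, 100 * sum(precs) / 5, 100 * sum(recs) / 5, 100 * sum(f1s) / 5, kappa


class TestComputeMetrics:
    def _to_inputs(self, pairs):
        gold = {}
        preds = {}
        for i, (g, p) in enumerate(pairs):
            sid = f"SYN{i:06d}"
            gold[sid] = GoldLabel(sid, g, "x")
            preds[sid] = None if p == "none" else p
        return preds, gold

    def test_perfect_predictions(self):
        pairs = [(b, b) for b in BIOMES for _ in range(4)]
        preds, gold = self._to_inputs(pairs)
        report = compute_metrics(preds, gold, "exact")
        assert report.accuracy == 100.0
        assert report.f1 == 100.0
        assert report.kappa == pytest.approx(1.0)

    def test_two_class_hand_computed_kappa(self):
        # confusion [[45, 5], [15, 35]] between animal and plant:
        # p_o = 0.8, p_e = 0.5 -> kappa 0.6
        pairs = (
            [("animal", "animal")] * 45 + [("animal", "plant")] * 5
            + [("plant", "animal")] * 15 + [("plant", "plant")] * 35
        )
        preds, gold = self._to_inputs(pairs)
        report = compute_metrics(preds, gold, "exact")
        assert report.accuracy == pytest.approx(80.0)
        assert report.kappa == pytest.approx(0.60)

    def test_agrees_with_from_definitions_oracle(self):
        rng = random.Random(42)
        labels = list(BIOMES) + ["none"]
        for _ in range(300):
            n = rng.randint(5, 40)
            pairs = [(rng.choice(BIOMES), rng.choice(labels)) for _ in range(n)]
            preds, gold = self._to_inputs(pairs)
            report = compute_metrics(preds, gold, "exact")
            acc, prec, rec, f1, kappa = oracle_metrics(pairs)
            assert report.accuracy == pytest.approx(acc)
            assert report.precision == pytest.approx(prec)
            assert report.recall == pytest.approx(rec)
            assert report.f1 == pytest.approx(f1)
            assert report.kappa == pytest.approx(kappa)

    def test_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = random.Random(7)
        for _ in range(50):
            pairs = [(rng.choice(BIOMES), rng.choice(BIOMES)) for _ in range(60)]
            preds, gold = self._to_inputs(pairs)
            report = compute_metrics(preds, gold, "exact")
            y_true = [g for g, _ in pairs]
            y_pred = [p for _, p in pairs]
            assert report.kappa == pytest.approx(
                sklearn.cohen_kappa_score(y_true, y_pred)
            )
            prec, rec, f1, _ = sklearn.precision_recall_fscore_support(
                y_true, y_pred, labels=list(BIOMES), average="macro", zero_division=0
            )
            assert report.precision == pytest.approx(100 * prec)
            assert report.recall == pytest.approx(100 * rec)
            assert report.f1 == pytest.approx(100 * f1)

    def test_confusion_rows_sum_to_class_counts(self):
        rng = random.Random(3)
        pairs = [(rng.choice(BIOMES), rng.choice(BIOMES)) for _ in range(100)]
        preds, gold = self._to_inputs(pairs)
        report = compute_metrics(preds, gold, "exact")
        assert report.confusion.to_numpy().sum() == 100
        for b in BIOMES:
            assert report.confusion.loc[b].sum() == sum(1 for g, _ in pairs if g == b)
        norm = report.confusion_normalized.sum(axis=1)
        assert np.allclose(norm.dropna(), 1.0)

    def test_lenient_geq_exact_accuracy(self):
        gold = {f"SYN{i}": GoldLabel(f"SYN{i}", "animal", "x") for i in range(4)}
        preds = {
            "SYN0": "animal",
            "SYN1": "animal (incl. human)",
            "SYN2": "plant",
            "SYN3": "animals",
        }
        exact = compute_metrics(preds, gold, "exact").accuracy
        lenient = compute_metrics(preds, gold, "lenient").accuracy
        assert lenient >= exact
        assert exact == pytest.approx(25.0)
        assert lenient == pytest.approx(50.0)

    def test_disjoint_ids_error(self):
        gold = {"SYN1": GoldLabel("SYN1", "soil", "x")}
        with pytest.raises(ValueError):
            compute_metrics({"SYN2": "soil"}, gold, "exact")


class TestMcNemar:
    def test_symmetric_discordance(self):
        paired = [(True, False)] * 10 + [(False, True)] * 10 + [(True, True)] * 5
        res = mcnemar_test(paired)
        assert res.statistic == 0.0 and res.p == 1.0
        assert (res.b, res.c) == (10, 10)

    def test_exact_branch_hand_computed(self):
        paired = [(True, False)] * 1 + [(False, True)] * 9
        res = mcnemar_test(paired)
        assert res.p == pytest.approx(22 / 1024)

    def test_chi_square_branch_against_cdf_oracle(self):
        paired = [(True, False)] * 40 + [(False, True)] * 20
        res = mcnemar_test(paired)
        assert res.statistic == pytest.approx(400 / 60)
        assert res.p == pytest.approx(1 - sps.chi2.cdf(400 / 60, 1))

    def test_no_discordance_convention(self):
        res = mcnemar_test([(True, True)] * 5 + [(False, False)] * 5)
        assert res.p == 1.0 and res.statistic == 0.0

    def test_exact_branch_matches_full_binomial_enumeration(self):
        # oracle: enumerate P(X = k) = C(n, k) / 2^n directly
        for n in range(1, 25):
            for b in range(n + 1):
                c = n - b
                paired = [(True, False)] * b + [(False, True)] * c
                res = mcnemar_test(paired)
                k = min(b, c)
                p_oracle = min(
                    1.0, 2 * sum(math.comb(n, j) for j in range(k + 1)) / 2**n
                )
                assert res.p == pytest.approx(p_oracle), (b, c)

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = random.Random(1)
        for _ in range(30):
            b, c = rng.randint(0, 40), rng.randint(0, 40)
            if b + c == 0:
                continue
            paired = [(True, False)] * b + [(False, True)] * c
            res = mcnemar_test(paired)
            table = [[0, b], [c, 0]]
            exact = (b + c) < 25
            ref = sm.mcnemar(table, exact=exact, correction=False)
            assert res.p == pytest.approx(ref.pvalue)


class TestTTests:
    def test_identical_paired_vectors_p_one(self):
        res = t_tests([0.5, 0.6, 0.7], [0.5, 0.6, 0.7], paired=True)
        assert res.p == 1.0 and res.statistic == 0.0

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError):
            t_tests([1.0, 2.0, 3.0], [0.5, 1.5, 2.5], paired=True)

    def test_shifted_paired_vector_tiny_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.5, 0.01, size=50)
        res = t_tests(base + 0.1, base + rng.normal(0, 0.01, size=50), paired=True)
        assert res.p < 1e-6

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            t_tests([1.0], [2.0], paired=True)
        with pytest.raises(ValueError):
            t_tests([1.0], [2.0, 3.0], paired=False)

    def test_independent_false_positive_rate_calibrated(self):
        # equal means: rejection rate at alpha = 0.05 should be ~5%
        rng = np.random.default_rng(2026)
        reps, n = 2000, 30
        a = rng.normal(0.0, 1.0, size=(reps, n))
        b = rng.normal(0.0, 1.0, size=(reps, n))
        rejections = 0
        for i in range(reps):
            if t_tests(a[i], b[i], paired=False).p < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.015


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01] * 5)[0] == pytest.approx(0.05)
        assert bonferroni([0.4] * 5)[0] == 1.0
        assert bonferroni([0.3]) == [0.3]

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestEmbeddings:
    def test_cosine_identity_orthogonal_hand(self):
        a = EmbeddingVector(np.array([1.0, 2.0, 2.0]), "x")
        b = EmbeddingVector(np.array([2.0, 1.0, 2.0]), "x")
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, b) == pytest.approx(8 / 9)
        e1 = EmbeddingVector(np.array([1.0, 0.0]), "x")
        e2 = EmbeddingVector(np.array([0.0, 1.0]), "x")
        assert cosine_similarity(e1, e2) == pytest.approx(0.0)

    def test_provider_and_zero_vector_guards(self):
        a = EmbeddingVector(np.array([1.0, 0.0]), "x")
        b = EmbeddingVector(np.array([1.0, 0.0]), "y")
        with pytest.raises(ValueError):
            cosine_similarity(a, b)
        z = EmbeddingVector(np.zeros(2), "x")
        with pytest.raises(ValueError):
            cosine_similarity(a, z)

    def test_mock_embedder_deterministic(self):
        emb = HashingEmbedder()
        vecs, errs = embed_texts(["human gut", "human gut"], emb)
        assert not errs
        assert cosine_similarity(vecs[0], vecs[1]) == pytest.approx(1.0)

    def test_mock_embedder_word_overlap_monotonicity(self):
        emb = HashingEmbedder()
        vecs, _ = embed_texts(
            ["human gut", "human intestine-free-text-overlap gut", "desert soil"], emb
        )
        close = cosine_similarity(vecs[0], vecs[1])
        far = cosine_similarity(vecs[0], vecs[2])
        assert close > far

    def test_empty_text_error_record_no_silent_loss(self):
        emb = HashingEmbedder()
        vecs, errs = embed_texts(["human gut", "", "soil"], emb)
        assert vecs[0] is not None and vecs[2] is not None
        assert vecs[1] is None
        assert errs and errs[0][0] == 1


class TestCompareRuns:
    def _scored(self, gold, preds, seed=0):
        anns = {
            sid: make_annotation(sid, p, None, None, gold[sid].sub_biome)
            for sid, p in preds.items()
        }
        return score_run(anns, gold, HashingEmbedder())

    def _gold(self, ids):
        return {sid: GoldLabel(sid, "soil", "forest soil") for sid in ids}

    def test_same_ids_selects_mcnemar_and_paired_t(self):
        ids = [f"SYN{i}" for i in range(20)]
        gold = self._gold(ids)
        run_a = self._scored(gold, {sid: "soil" for sid in ids})
        run_b = self._scored(gold, {sid: ("soil" if i % 2 else "water")
                                    for i, sid in enumerate(ids)})
        report = compare_runs(run_a, run_b)
        assert report.design == "paired"
        assert report.tests[0].test_name == "mcnemar"

    def test_disjoint_ids_selects_independent_t(self):
        ids_a = [f"SYN{i}" for i in range(10)]
        ids_b = [f"SYN{i}" for i in range(10, 20)]
        run_a = self._scored(self._gold(ids_a), {sid: "soil" for sid in ids_a})
        run_b = self._scored(self._gold(ids_b), {sid: "water" for sid in ids_b})
        report = compare_runs(run_a, run_b)
        assert report.design == "independent"
        assert report.tests[0].test_name == "independent_t"

    def test_identical_runs_all_p_one(self):
        ids = [f"SYN{i}" for i in range(10)]
        gold = self._gold(ids)
        run = self._scored(gold, {sid: "soil" for sid in ids})
        report = compare_runs(run, dict(run))
        assert all(t.p == 1.0 for t in report.tests)
        assert all(t.p_adjusted == 1.0 for t in report.tests)

    def test_partial_overlap_rejected(self):
        gold = self._gold([f"SYN{i}" for i in range(10)])
        run_a = self._scored(gold, {sid: "soil" for sid in list(gold)[:6]})
        run_b = self._scored(gold, {sid: "soil" for sid in list(gold)[4:]})
        run_a = {k: v for k, v in run_a.items() if k in list(gold)[:6]}
        run_b = {k: v for k, v in run_b.items() if k in list(gold)[4:]}
        with pytest.raises(ValueError):
            compare_runs(run_a, run_b)
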