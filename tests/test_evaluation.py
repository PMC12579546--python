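import math

import numpy as np
import pytest

from phoszsl.evaluation import (
    MetricError,
    ScoreMatrix,
    aggregated_ap,
    average_precision,
    evaluate,
    hit_at_k,
    macro_ap,
    masked_group_ap,
    phosphosite_ap,
    random_baseline_ap,
)

from . import oracles


class TestAveragePrecision:
    def test_all_positives_ranked_first(self):
        assert average_precision([3.0, 2.0, 1.0], [1, 1, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        assert average_precision([3.0, 2.0, 1.0], [0, 0, 1]) == pytest.approx(1 / 3)

    def test_all_positive_is_one_regardless_of_scores(self):
        assert average_precision([0.1, 5.0, -2.0], [1, 1, 1]) == 1.0

    def test_no_positives_is_undefined(self):
        with pytest.raises(MetricError):
            average_precision([1.0, 2.0], [0, 0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=8)
            labels = rng.integers(0, 2, size=8)
            if not labels.any():
                labels[0] = 1
            a = average_precision(scores, labels)
            b = average_precision(np.exp(2 * scores) + 5, labels)
            assert a == pytest.approx(b, abs=1e-12)

    def test_agrees_with_sklearn_on_tie_free_scores(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        for _ in range(10):
            scores = rng.normal(size=12)
            labels = rng.integers(0, 2, size=12)
            if not labels.any():
                labels[3] = 1
            assert average_precision(scores, labels) == pytest.approx(
                sklearn_metrics.average_precision_score(labels, scores)
            )


def _random_instance(rng, n_sites, n_kinases):
    site_ids = [f"s{i}" for i in range(n_sites)]
    kinase_ids = [f"k{j}" for j in range(n_kinases)]
    values = rng.normal(size=(n_sites, n_kinases))
    labels = {}
    for s in site_ids:
        chosen = [k for k in kinase_ids if rng.random() < 0.5]
        if not chosen:
            chosen = [kinase_ids[int(rng.integers(n_kinases))]]
        labels[s] = set(chosen)
    return ScoreMatrix(values, site_ids, kinase_ids), labels


class TestMetricSuiteAgainstOracles:
    def test_macro_ap_toy_example(self):
        matrix = ScoreMatrix(
            np.array([[0.9, 0.1], [0.8, 0.7], [0.2, 0.6]]),
            ["s0", "s1", "s2"],
            ["k0", "k1"],
        )
        labels = {"s0": {"k0"}, "s1": {"k0", "k1"}, "s2": {"k1"}}
        got, per = macro_ap(matrix, labels)
        expected, _ = oracles.bf_macro_ap(matrix.values, matrix.site_ids,
                                          matrix.kinase_ids, labels)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(np.mean(list(per.values())))

    def test_perfect_scores_give_macro_one(self):
        rng = np.random.default_rng(2)
        matrix, labels = _random_instance(rng, 5, 4)
        perfect = np.array(
            [[1.0 if k in labels[s] else 0.0 for k in matrix.kinase_ids]
             for s in matrix.site_ids]
        )
        got, _ = macro_ap(ScoreMatrix(perfect, matrix.site_ids,
                                      matrix.kinase_ids), labels)
        assert got == 1.0

    def test_phosphosite_ap_single_site_rank_two(self):
        matrix = ScoreMatrix(np.array([[0.9, 0.5, 0.3, 0.1]]), ["s0"],
                             ["k0", "k1", "k2", "k3"])
        assert phosphosite_ap(matrix, {"s0": {"k1"}}) == pytest.approx(0.5)

    def test_singleton_classes_make_aggregation_identity(self):
        rng = np.random.default_rng(3)
        matrix, labels = _random_instance(rng, 4, 3)
        mapping = {k: k for k in matrix.kinase_ids}
        macro, _ = macro_ap(matrix, labels)
        assert aggregated_ap(matrix, labels, mapping) == pytest.approx(macro)

    def test_single_class_aggregation_is_one(self):
        rng = np.random.default_rng(4)
        matrix, labels = _random_instance(rng, 4, 3)
        mapping = {k: "ALL" for k in matrix.kinase_ids}
        assert aggregated_ap(matrix, labels, mapping) == 1.0

    def test_masked_ap_with_singleton_groups_is_one(self):
        rng = np.random.default_rng(5)
        matrix, labels = _random_instance(rng, 5, 4)
        mapping = {k: k for k in matrix.kinase_ids}
        assert masked_group_ap(matrix, labels, mapping) == 1.0

    def test_masked_ap_with_one_group_equals_macro(self):
        rng = np.random.default_rng(6)
        matrix, labels = _random_instance(rng, 5, 4)
        mapping = {k: "G" for k in matrix.kinase_ids}
        macro, _ = macro_ap(matrix, labels)
        assert masked_group_ap(matrix, labels, mapping) == pytest.approx(macro)

    def test_full_suite_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_sites = int(rng.integers(1, 6))
            n_kin = int(rng.integers(1, 5))
            matrix, labels = _random_instance(rng, n_sites, n_kin)
            groups = {k: f"g{int(rng.integers(2))}" for k in matrix.kinase_ids}
            macro, _ = macro_ap(matrix, labels)
            bf, _ = oracles.bf_macro_ap(matrix.values, matrix.site_ids,
                                        matrix.kinase_ids, labels)
            assert macro == pytest.approx(bf, abs=1e-12)
            assert phosphosite_ap(matrix, labels) == pytest.approx(
                oracles.bf_phosphosite_ap(matrix.values, matrix.site_ids,
                                          matrix.kinase_ids, labels), abs=1e-12)
            assert aggregated_ap(matrix, labels, groups) == pytest.approx(
                oracles.bf_aggregated_ap(matrix.values, matrix.site_ids,
                                         matrix.kinase_ids, labels, groups),
                abs=1e-12)
            assert masked_group_ap(matrix, labels, groups) == pytest.approx(
                oracles.bf_masked_group_ap(matrix.values, matrix.site_ids,
                                           matrix.kinase_ids, labels, groups),
                abs=1e-12)
            for k in (1, 2, n_kin + 3):
                assert hit_at_k(matrix, labels, [k])[k] == pytest.approx(
                    oracles.bf_hit_at_k(matrix.values, matrix.site_ids,
                                        matrix.kinase_ids, labels, k),
                    abs=1e-12)


class TestHitAtK:
    def test_k_at_least_kinase_count_is_one(self):
        rng = np.random.default_rng(8)
        matrix, labels = _random_instance(rng, 4, 3)
        assert hit_at_k(matrix, labels, [3])[3] == 1.0

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(9)
        matrix, labels = _random_instance(rng, 5, 4)
        values = hit_at_k(matrix, labels, [1, 2, 3, 4])
        seq = [values[k] for k in (1, 2, 3, 4)]
        assert seq == sorted(seq)


class TestRandomBaseline:
    def test_every_pair_positive_gives_exactly_one(self):
        labels = {f"s{i}": {"k0", "k1"} for i in range(3)}
        mean, std = random_baseline_ap(labels, ["k0", "k1"], n_runs=5, seed=0)
        assert mean == 1.0
        assert std == 0.0

    def test_converges_to_exhaustive_permutation_expectation(self):
        # single kinase, 2 of 4 sites positive
        labels = {"s0": {"k"}, "s1": set(), "s2": {"k"}, "s3": set()}
        expected = oracles.exhaustive_random_ap(labels, list(labels), 1, "k")
        mean, _ = random_baseline_ap(labels, ["k"], n_runs=4000, seed=1)
        assert mean == pytest.approx(expected, abs=0.02)


class TestEvalReport:
    def test_report_fields_and_serialisation(self, tmp_path):
        rng = np.random.default_rng(10)
        matrix, labels = _random_instance(rng, 5, 4)
        groups = {k: f"g{int(rng.integers(2))}" for k in matrix.kinase_ids}
        report = evaluate(matrix, labels, family_mapping=groups,
                          group_mapping=groups, ks=[1, 2])
        assert 0 <= report.macro_ap <= 1
        assert report.macro_ap == pytest.approx(
            np.mean(list(report.per_kinase_ap.values())))
        assert report.masked_group_ap >= report.macro_ap - 1e-12
        text = report.to_json(tmp_path / "report.json")
        assert "macro_ap" in text
        report.per_kinase_tsv(tmp_path / "per_kinase.tsv")
        assert (tmp_path / "per_kinase.tsv").exists()
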