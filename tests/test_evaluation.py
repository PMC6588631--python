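"""Study designs, balanced sampling, top-5 scoring and the statistics."""

import itertools
from collections import namedtuple

import numpy as np
import pytest
from scipy import stats as sps

from histosearch.evaluation import (
    GLEASON_CATEGORIES,
    HISTOLOGIC_FEATURES,
    StudyDesign,
    balanced_subsample,
    clopper_pearson_ci,
    confusion_matrix,
    feature_labels,
    gleason_design,
    grade_of,
    hit_vector,
    mann_whitney_u,
    mcnemar_test,
    multi_organ_design,
    normal_ci,
    organ_of,
    organ_specific_design,
    random_top5_expected,
    run_study,
    top5_score,
)
from histosearch.index import PatchMeta
from histosearch.search import SearchResult

LabelRecord = namedtuple("LabelRecord", ["labels", "slide_id"])


def _result(labels, rank=1, record_id=0):
    meta = PatchMeta(record_id, "s", 0.0, 0.0, 1.0, 1.0, "10x", frozenset(labels))
    return SearchResult(meta=meta, orientation=0, distance=0.5, rank=rank)


class TestLabelChannels:
    def test_prefix_helpers(self):
        labels = frozenset({"artery", "organ=prostate", "grade=GP3"})
        assert feature_labels(labels) == frozenset({"artery"})
        assert organ_of(labels) == "prostate"
        assert grade_of(labels) == "GP3"
        assert organ_of(frozenset({"fat"})) is None


class TestDesigns:
    def test_design_count_arithmetic(self):
        organ = organ_specific_design()
        assert organ.n_classes == 9
        assert (organ.database_total, organ.query_total) == (45_000, 9_000)
        multi = multi_organ_design()
        assert multi.n_classes == 29  # 3 organs x 10 features - prostate lymphocyte
        assert (multi.database_total, multi.query_total) == (87_000, 14_500)
        gleason = gleason_design()
        assert gleason.n_classes == 4
        assert (gleason.database_total, gleason.query_total) == (40_000, 8_000)

    def test_chance_floor_for_nine_classes(self):
        assert round(100 / organ_specific_design().n_classes) == 11

    def test_class_of_requires_all_labels(self):
        design = multi_organ_design()
        assert design.class_of(frozenset({"fat", "organ=breast"})) == frozenset(
            {"fat", "organ=breast"}
        )
        assert design.class_of(frozenset({"fat"})) is None
        assert design.class_of(frozenset({"lymphocyte", "organ=prostate"})) is None


class TestBalancedSubsample:
    @staticmethod
    def _records(design, per_class, n_slides=40):
        records = []
        i = 0
        for cls in design.classes:
            for _ in range(per_class):
                records.append(LabelRecord(cls, f"slide{i % n_slides}"))
                i += 1
        return records

    def test_exact_counts_and_slide_disjointness(self):
        design = StudyDesign(
            "toy",
            tuple(frozenset({f}) for f in ("a", "b", "c")),
            db_per_class=30,
            query_per_class=10,
        )
        records = self._records(design, per_class=60)
        db_set, query_set = balanced_subsample(records, design, seed=0)
        assert len(db_set) == design.database_total
        assert len(query_set) == design.query_total
        assert not ({r.slide_id for r in db_set} & {r.slide_id for r in query_set})
        for cls in design.classes:
            assert sum(r.labels == cls for r in db_set) == 30
            assert sum(r.labels == cls for r in query_set) == 10

    def test_sampling_is_without_replacement_and_seeded(self):
        design = StudyDesign(
            "toy", (frozenset({"a"}),), db_per_class=5, query_per_class=5
        )
        records = [LabelRecord(frozenset({"a"}), f"s{i % 10}") for i in range(40)]
        db1, q1 = balanced_subsample(records, design, seed=3)
        db2, q2 = balanced_subsample(records, design, seed=3)
        assert db1 == db2 and q1 == q2
        assert len(set(map(id, db1 + q1))) == len(db1 + q1)

    def test_shortfall_error_names_class_and_count(self):
        design = StudyDesign(
            "toy", (frozenset({"rare"}),), db_per_class=50, query_per_class=5
        )
        records = [LabelRecord(frozenset({"rare"}), f"s{i % 6}") for i in range(30)]
        with pytest.raises(ValueError, match="rare"):
            balanced_subsample(records, design, seed=0)


class TestTop5Score:
    def test_all_hits_and_all_misses(self):
        labels = [frozenset({"a"})] * 4
        hits = [[_result({"a"})] for _ in range(4)]
        misses = [[_result({"b"})] for _ in range(4)]
        assert top5_score(hits, labels) == 100.0
        assert top5_score(misses, labels) == 0.0

    def test_seven_of_ten_matches_hand_count(self):
        labels = [frozenset({"a"})] * 10
        results = [
            [_result({"a"})] if i < 7 else [_result({"b"}), _result({"c"})]
            for i in range(10)
        ]
        assert top5_score(results, labels) == pytest.approx(70.0)
        # brute-force recount oracle
        recount = sum(
            any("a" in r.labels for r in rs) for rs in results
        ) / 10 * 100
        assert top5_score(results, labels) == pytest.approx(recount)

    def test_empty_result_list_is_a_miss(self):
        assert top5_score([[]], [frozenset({"a"})]) == 0.0

    def test_more_than_five_results_rejected(self):
        with pytest.raises(ValueError, match="at most 5"):
            top5_score([[_result({"a"})] * 6], [frozenset({"a"})])

    def test_combined_predicates(self):
        q = frozenset({"fat", "organ=breast", "grade=GP4"})
        same_feature_wrong_organ = [_result({"fat", "organ=colon"})]
        assert top5_score([same_feature_wrong_organ], [q], "feature") == 100.0
        assert top5_score([same_feature_wrong_organ], [q], "feature_organ") == 0.0
        grade_only = [_result({"stroma", "grade=GP4"})]
        assert top5_score([grade_only], [q], "gleason") == 100.0
        assert top5_score([grade_only], [q], "gleason_feature") == 0.0


class TestConfusionMatrix:
    @staticmethod
    def _design():
        return StudyDesign(
            "toy",
            tuple(frozenset({f}) for f in ("a", "b", "c")),
            db_per_class=1,
            query_per_class=1,
        )

    def test_own_class_results_give_identity(self):
        design = self._design()
        labels = [frozenset({c}) for c in ("a", "b", "c")]
        results = [[_result(l)] for l in labels]
        m = confusion_matrix(results, labels, design)
        np.testing.assert_array_equal(m.values, np.eye(3))

    def test_multi_class_row(self):
        design = self._design()
        results = [[_result({"a"}), _result({"b"})]]
        m = confusion_matrix(results, [frozenset({"a"})], design)
        assert m.loc["a", "a"] == 1.0
        assert m.loc["a", "b"] == 1.0
        assert m.loc["a", "c"] == 0.0

    def test_three_class_toy_matches_hand_enumeration(self):
        design = self._design()
        queries = [frozenset({"a"}), frozenset({"a"}), frozenset({"b"})]
        results = [
            [_result({"a"}), _result({"c"})],
            [_result({"b"})],
            [_result({"b"}), _result({"b"})],
        ]
        m = confusion_matrix(results, queries, design)
        # hand enumeration: class a queries: 1/2 hit a, 1/2 hit b, 1/2 hit c
        assert m.loc["a"].tolist() == [0.5, 0.5, 0.5]
        assert m.loc["b"].tolist() == [0.0, 1.0, 0.0]
        # diagonal equals per-class top-5 score under class matching
        hits_a = hit_vector(
            results[:2], queries[:2], lambda q, r: design.class_of(q) == design.class_of(r)
        )
        assert m.loc["a", "a"] == pytest.approx(hits_a.mean())


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        a = [True] * 10 + [False] * 10 + [True] * 5
        b = [False] * 10 + [True] * 10 + [True] * 5
        assert mcnemar_test(a, b) == pytest.approx(1.0)

    def test_exact_one_sided_discordance(self):
        # b=5, c=0 -> exact two-sided binomial p = 2 * 0.5^5
        a = [True] * 5 + [True] * 10
        b = [False] * 5 + [True] * 10
        assert mcnemar_test(a, b) == pytest.approx(2 * 0.5**5)

    def test_identical_vectors_give_p_one(self):
        v = [True, False, True, True]
        assert mcnemar_test(v, v) == 1.0

    def test_exact_matches_binomial_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            b = int(rng.integers(0, 12))
            c = int(rng.integers(0, 12))
            if b + c == 0:
                continue
            a_vec = [True] * b + [False] * c + [True] * 3
            b_vec = [False] * b + [True] * c + [True] * 3
            # textbook oracle: two-sided exact binomial on min(b, c)
            n, k = b + c, min(b, c)
            p_oracle = min(
                1.0,
                2 * sum(sps.binom.pmf(i, n, 0.5) for i in range(0, k + 1)),
            )
            assert mcnemar_test(a_vec, b_vec) == pytest.approx(p_oracle, rel=1e-9)

    def test_large_discordance_uses_chi_square(self):
        a = [True] * 30 + [False] * 5 + [True] * 10
        b = [False] * 30 + [True] * 5 + [True] * 10
        p = mcnemar_test(a, b)
        chi2 = (abs(30 - 5) - 1) ** 2 / (30 + 5)
        assert p == pytest.approx(float(sps.chi2.sf(chi2, df=1)), rel=1e-9)


class TestMannWhitney:
    def test_disjoint_small_samples_exact(self):
        # U = 0; all 20 rank splits enumerable: two-sided p = 2/20
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_u([2, 2, 2], [2, 2, 2]) == 1.0

    def test_symmetry(self):
        a, b = [1.0, 5.0, 3.0, 7.0], [2.0, 8.0, 6.0]
        assert mann_whitney_u(a, b) == pytest.approx(mann_whitney_u(b, a))

    def test_exact_matches_enumeration_oracle(self):
        # full permutation enumeration of the U statistic, n=4 vs 3
        a = [1.3, 2.9, 4.1, 6.2]
        b = [0.7, 3.5, 5.0]
        pooled = a + b
        u_obs = sum(x > y for x in a for y in b)
        n_a = len(a)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            grp_a = [pooled[i] for i in combo]
            grp_b = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = sum(x > y for x in grp_a for y in grp_b)
            total += 1
            if min(u, n_a * len(grp_b) - u) <= min(u_obs, n_a * len(b) - u_obs):
                count += 1
        assert mann_whitney_u(a, b) == pytest.approx(count / total, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        n, alpha = 12, 0.05
        lower, upper = clopper_pearson_ci(0, n, alpha)
        assert lower == 0.0
        assert upper == pytest.approx(1 - (alpha / 2) ** (1 / n), rel=1e-12)

    def test_all_successes_upper_is_one(self):
        lower, upper = clopper_pearson_ci(10, 10)
        assert upper == 1.0
        # Beta(n, 1) quantile: lower = (alpha/2)^(1/n)
        assert lower == pytest.approx(0.025 ** (1 / 10), rel=1e-12)

    def test_matches_beta_quantile_oracle(self):
        lower, upper = clopper_pearson_ci(50, 100, 0.05)
        assert lower == pytest.approx(float(sps.beta.ppf(0.025, 50, 51)), rel=1e-12)
        assert upper == pytest.approx(float(sps.beta.ppf(0.975, 51, 50)), rel=1e-12)
        assert lower < 0.5 < upper

    def test_interval_contains_point_estimate(self):
        for x, n in [(1, 7), (3, 9), (8, 11)]:
            lower, upper = clopper_pearson_ci(x, n)
            assert lower <= x / n <= upper


class TestNormalCI:
    def test_constant_list_zero_width(self):
        lower, upper = normal_ci([42.0, 42.0, 42.0])
        assert lower == upper == 42.0

    def test_two_point_hand_arithmetic(self):
        # {0, 100}: mean 50, sample SD 70.71, SE 50, half-width 1.96*50
        lower, upper = normal_ci([0.0, 100.0])
        assert (lower + upper) / 2 == pytest.approx(50.0)
        assert upper - lower == pytest.approx(2 * 1.96 * 50.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            normal_ci([1.0])


class TestRandomEngineCalibration:
    def test_closed_form(self):
        assert random_top5_expected(9) == pytest.approx(100 * (1 - (8 / 9) ** 5))
        assert random_top5_expected(4) == pytest.approx(100 * (1 - 0.75**5))

    def test_run_study_random_engine_matches_closed_form(self, fixture_db, fixture_patches):
        # 4 balanced classes; the random engine's top-5 score must approach
        # 100*(1-(3/4)^5) within 3 binomial SEs.
        patches, _ = fixture_patches
        design = StudyDesign(
            "toy",
            tuple(frozenset({f"tex{i}"}) for i in range(4)),
            db_per_class=1,
            query_per_class=1,
        )
        rng = np.random.default_rng(11)
        queries = [patches[int(i)] for i in rng.integers(0, len(patches), size=400)]
        report = run_study(
            {"real": (fixture_db, _emb()), "random": "random"},
            queries,
            design,
            seed=5,
        )
        expected = random_top5_expected(4)
        se = np.sqrt(expected * (100 - expected) / len(queries))
        assert abs(report.engines["random"].score - expected) <= 3 * se


def _emb():
    from histosearch.embedding import HistogramEmbedder

    return HistogramEmbedder()


class TestRunStudy:
    def test_report_structure_and_mcnemar_presence(self, fixture_db, fixture_patches, default_emb):
        patches, _ = fixture_patches
        design = StudyDesign(
            "toy",
            tuple(frozenset({f"tex{i}"}) for i in range(4)),
            db_per_class=1,
            query_per_class=1,
        )
        queries = patches[::6]
        report = run_study(
            {"default": (fixture_db, default_emb), "random": "random"},
            queries,
            design,
            seed=1,
        )
        assert set(report.engines) == {"default", "random"}
        assert "default_vs_random" in report.mcnemar
        for engine in report.engines.values():
            assert 0.0 <= engine.score <= 100.0
            assert engine.ci[0] <= engine.score <= engine.ci[1]
            assert engine.confusion.shape == (4, 4)
        payload = report.to_dict()
        assert payload["n_queries"] == len(queries)

    def test_random_engine_requires_a_database(self, fixture_patches):
        patches, _ = fixture_patches
        design = StudyDesign(
            "toy", (frozenset({"tex0"}),), db_per_class=1, query_per_class=1
        )
        with pytest.raises(ValueError, match="database"):
            run_study({"random": "random"}, patches[:2], design)
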