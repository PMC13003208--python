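"""Merging, embedding space, centroid topic vectors, and assignment."""

from __future__ import annotations

import numpy as np
import pytest

from qadiscourse.embedding import build_embedding, cosine
from qadiscourse.errors import ConfigError, DataError
from qadiscourse.lda import LDAResults, fit_lda
from qadiscourse.topics import (
    MergeMap,
    assign_documents,
    categorize_questions,
    characterize_topic,
    merge_topics,
    topic_vector,
)

from .test_lda import two_topic_corpus


def results_from_theta(theta, keywords=None):
    theta = np.asarray(theta, dtype=float)
    K = theta.shape[1]
    return LDAResults(
        K=K, vocab=["w"], phi=np.full((K, 1), 1.0), theta=theta,
        alpha=1.0, beta=0.01, seed=0, doc_index=list(range(theta.shape[0])),
        excluded=[], keywords=keywords or [[] for _ in range(K)],
    )


class TestMergeMap:
    def test_non_total_map_names_missing_indices(self):
        mm = MergeMap({0: "A"})
        with pytest.raises(ConfigError, match=r"missing raw topics \[1\]"):
            mm.validate(2)

    def test_yaml_round_trip(self, tmp_path):
        mm = MergeMap({0: "A", 1: "B", 2: "A"}, label_order=["A", "B"])
        mm.to_yaml(tmp_path / "mm.yaml")
        back = MergeMap.from_yaml(tmp_path / "mm.yaml")
        assert back.mapping == mm.mapping
        assert back.label_order == mm.label_order


class TestMergeTopics:
    def test_all_topics_to_one_label(self):
        res = results_from_theta([[0.5, 0.5], [0.9, 0.1]])
        labels, _ = merge_topics(res, MergeMap({0: "A", 1: "A"}))
        assert labels == ["A", "A"]

    def test_argmax_of_theta(self):
        res = results_from_theta([[0.6, 0.4]])
        labels, _ = merge_topics(res, MergeMap({0: "A", 1: "B"}))
        assert labels == ["A"]

    def test_summed_mass_beats_single_topic(self):
        res = results_from_theta([[0.3, 0.3, 0.4]])
        labels, _ = merge_topics(res, MergeMap({0: "A", 1: "A", 2: "B"}))
        assert labels == ["A"]

    def test_keyword_pools_are_unions(self):
        res = results_from_theta([[1.0, 0.0, 0.0]],
                                 keywords=[["x", "y"], ["y", "z"], ["q"]])
        _, pools = merge_topics(res, MergeMap({0: "A", 1: "A", 2: "B"}))
        assert pools == {"A": ["x", "y", "z"], "B": ["q"]}

    def test_label_permutation_equivalence(self):
        # a consistent permutation of raw topics + merge map leaves labels fixed
        rng = np.random.default_rng(3)
        theta = rng.dirichlet(np.ones(4), size=20)
        mapping = {0: "A", 1: "B", 2: "A", 3: "C"}
        perm = [2, 0, 3, 1]  # new position of each raw topic
        res = results_from_theta(theta)
        labels, _ = merge_topics(res, MergeMap(mapping, ["A", "B", "C"]))
        theta_p = theta[:, np.argsort(perm)]
        mapping_p = {perm[k]: lab for k, lab in mapping.items()}
        res_p = results_from_theta(theta_p)
        labels_p, _ = merge_topics(res_p, MergeMap(mapping_p, ["A", "B", "C"]))
        assert labels == labels_p


class TestEmbedding:
    def test_repeated_token_doc_colinear_with_word_vector(self):
        docs = [["x", "x", "x"], ["x", "y"], ["x", "y"]]
        wv, dv, _ = build_embedding(docs, 2)
        assert cosine(dv[0], wv["x"]) == pytest.approx(1.0)

    def test_identical_token_multisets_identical_vectors(self):
        docs = [["x", "y", "x"], ["y", "x", "x"], ["z", "q"]]
        _, dv, _ = build_embedding(docs, 2)
        assert np.allclose(dv[0], dv[1])

    def test_within_topic_cosine_exceeds_between(self):
        docs, _, _ = two_topic_corpus()
        _, dv, _ = build_embedding(docs, 10)
        within, between = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                (within if (i < 10) == (j < 10) else between).append(float(dv[i] @ dv[j]))
        assert np.mean(within) > np.mean(between)

    def test_deterministic(self):
        docs, _, _ = two_topic_corpus()
        wv1, dv1, _ = build_embedding(docs, 5)
        wv2, dv2, _ = build_embedding(docs, 5)
        assert np.array_equal(dv1, dv2)
        assert all(np.array_equal(wv1[t], wv2[t]) for t in wv1)

    def test_too_small_vocabulary_rejected(self):
        with pytest.raises(DataError):
            build_embedding([["a", "b"]], 5)


class TestTopicVector:
    def test_identical_members_give_that_vector(self):
        v = np.array([1.0, 2.0])
        assert np.allclose(topic_vector([v, v, v]), v)

    def test_opposite_members_give_degenerate_zero(self):
        v = np.array([1.0, 0.0])
        centroid = topic_vector([v, -v])
        assert np.allclose(centroid, 0.0)
        with pytest.raises(DataError):
            characterize_topic(centroid, ["x"], {"x": v})

    def test_arithmetic_mean(self):
        vs = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0])]
        assert np.allclose(topic_vector(vs), [2 / 3, 2 / 3])

    def test_no_members_is_error(self):
        with pytest.raises(DataError):
            topic_vector([])

    def test_centroid_minimizes_sum_of_squared_distances(self):
        rng = np.random.default_rng(8)
        members = rng.normal(size=(12, 3))
        centroid = topic_vector(members)
        sse = ((members - centroid) ** 2).sum()
        for _ in range(50):  # random probes never beat the centroid
            probe = centroid + rng.normal(scale=0.1, size=3)
            assert ((members - probe) ** 2).sum() >= sse


class TestCharacterize:
    def test_vector_equal_to_topic_vector_ranks_first(self):
        tv = np.array([1.0, 1.0])
        wv = {"hit": tv.copy(), "miss": np.array([1.0, -1.0])}
        assert characterize_topic(tv, ["miss", "hit"], wv, J=2)[0] == "hit"

    def test_j_larger_than_pool_returns_whole_ranked_pool(self):
        tv = np.array([1.0, 0.0])
        wv = {"a": np.array([1.0, 0.1]), "b": np.array([0.0, 1.0])}
        assert characterize_topic(tv, ["a", "b"], wv, J=10) == ["a", "b"]

    def test_candidate_without_vector_skipped(self):
        tv = np.array([1.0, 0.0])
        wv = {"a": np.array([1.0, 0.0])}
        assert characterize_topic(tv, ["ghost", "a"], wv, J=5) == ["a"]


class TestAssign:
    def test_doc_equal_to_topic_vector_gets_that_label(self):
        tvs = {"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0])}
        out = assign_documents({"d": np.array([0.0, 1.0])}, tvs, ["A", "B"])
        assert out == {"d": "B"}

    def test_equal_cosine_tie_takes_first_label(self):
        tvs = {"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0])}
        out = assign_documents({"d": np.array([1.0, 1.0])}, tvs, ["B", "A"])
        assert out == {"d": "B"}

    def test_degenerate_doc_vector_gets_fallback(self):
        tvs = {"A": np.array([1.0, 0.0])}
        out = assign_documents({"d": np.zeros(2)}, tvs, ["A"], fallback_label="A")
        assert out == {"d": "A"}


class TestCategorizeQuestions:
    def test_end_to_end_on_planted_corpus(self, small_world):
        _, records, truth = small_world
        assignment = categorize_questions(records, K=2, n_sweeps=150, seed=0,
                                          embedding_dimension=10)
        labels = assignment.labels["merged_label"]
        # topic proportions sum to corpus size
        assert labels.value_counts().sum() == len(records)
        # recovery up to label permutation
        truth_topics = truth.loc[labels.index, "true_topic"]
        acc = max(
            (labels == labels.unique()[0]).eq(truth_topics == t).mean() for t in (0, 1)
        )
        assert acc >= 0.9
        # every topic keyword characterization draws from that topic's pool
        for lab, kws in assignment.space.topic_keywords.items():
            assert set(kws) <= set(assignment.merged_keyword_pools[lab])

    def test_refinement_pass_changes_only_assignment_route(self, small_world):
        _, records, _ = small_world
        a1 = categorize_questions(records, K=2, n_sweeps=100, seed=0,
                                  embedding_dimension=10)
        a2 = categorize_questions(records, K=2, n_sweeps=100, seed=0,
                                  embedding_dimension=10, refine_with_centroids=True)
        # same LDA state either way; labels highly concordant on separable data
        assert np.array_equal(a1.lda.theta, a2.lda.theta)
        agree = (a1.labels["merged_label"] == a2.labels["merged_label"]).mean()
        assert agree >= 0.9

    def test_requires_k_or_candidates(self, small_world):
        _, records, _ = small_world
        with pytest.raises(ConfigError):
            categorize_questions(records)
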