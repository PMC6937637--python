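"""kd-tree lookup and the classification protocols built on it."""

import numpy as np
import pytest

from fcgrseq.benchmarks import prepare_features, same_genome_neighbor_rate
from fcgrseq.classify import (
    Prediction,
    ReferenceIndex,
    calibrate_neighbor_count,
    candidate_pool,
    classify_nn,
    consensus_hosts,
    evaluate,
    majority_classify,
    nearest_neighbors,
    predict,
)
from fcgrseq.config import PipelineConfig
from fcgrseq.embedding import EmbeddedCorpus
from fcgrseq.synth import make_benchmark


def make_index(vectors, labels=None, ids=None):
    m = len(vectors)
    return ReferenceIndex(
        EmbeddedCorpus(
            vectors=np.asarray(vectors, dtype=float),
            ids=ids or [f"v{i}" for i in range(m)],
            labels=labels or [{} for _ in range(m)],
        )
    )


class TestNearestNeighbors:
    def test_stored_vector_retrieves_itself(self, rng):
        vecs = rng.normal(size=(30, 5))
        index = make_index(vecs)
        for i in (0, 7, 29):
            nb = nearest_neighbors(index, vecs[i], 1)[0]
            assert nb.index == i and nb.distance < 1e-8

    def test_matches_brute_force_scan(self, rng):
        stored = rng.normal(size=(200, 8))
        index = make_index(stored)
        for q in rng.normal(size=(50, 8)):
            got = [nb.index for nb in nearest_neighbors(index, q, 20)]
            dists = np.linalg.norm(stored - q, axis=1)
            expected = list(np.lexsort((np.arange(200), dists))[:20])
            assert got == expected

    def test_single_point_index(self):
        index = make_index([[1.0, 2.0]])
        assert nearest_neighbors(index, np.array([0.0, 0.0]), 1)[0].index == 0

    def test_k_clamped_with_warning(self, rng):
        index = make_index(rng.normal(size=(3, 2)))
        with pytest.warns(UserWarning, match="clamping"):
            nbs = nearest_neighbors(index, np.zeros(2), 10)
        assert len(nbs) == 3

    def test_distances_non_decreasing(self, rng):
        index = make_index(rng.normal(size=(40, 4)))
        d = [nb.distance for nb in nearest_neighbors(index, rng.normal(size=4), 10)]
        assert d == sorted(d)


class TestClassifyNN:
    def test_two_point_index(self):
        index = make_index([[0.0], [10.0]], labels=[{"species": "a"}, {"species": "b"}])
        assert classify_nn(index, np.array([1.0]), "species") == "a"
        assert classify_nn(index, np.array([9.0]), "species") == "b"

    def test_missing_rank_names_neighbor(self):
        index = make_index([[0.0]], labels=[{"genus": "g"}], ids=["ref1"])
        with pytest.raises(KeyError, match="ref1"):
            classify_nn(index, np.array([0.0]), "species")

    def test_synthetic_queries_recover_species(self, feats20, config):
        from fcgrseq.embedding import fit_svd, project

        model, embedded = fit_svd(feats20.M, config.r)
        index = make_index(
            embedded, labels=[u.labels for u in feats20.units],
            ids=[u.id for u in feats20.units],
        )
        correct = sum(
            classify_nn(index, project(model, feats20.M[i]), "species")
            == feats20.units[i].labels["species"]
            for i in range(len(feats20.units))
        )
        assert correct == len(feats20.units)


class TestCandidatePool:
    def test_single_label_index(self):
        index = make_index([[0.0], [1.0]], labels=[{"g": "x"}, {"g": "x"}])
        assert candidate_pool(index, np.array([0.5]), "g", K=2) == ["x"]

    def test_top1_label_is_first(self, rng):
        labels = [{"g": f"lab{i % 4}"} for i in range(20)]
        index = make_index(rng.normal(size=(20, 3)), labels=labels)
        for q in rng.normal(size=(10, 3)):
            pool = candidate_pool(index, q, "g", K=8)
            assert pool[0] == classify_nn(index, q, "g")

    def test_pool_recovers_truth_missed_by_top1(self):
        # truth 'a' is second-nearest: top-1 is wrong, the pool catches it
        index = make_index(
            [[0.0], [2.0]], labels=[{"g": "b"}, {"g": "a"}], ids=["rb", "ra"]
        )
        q = np.array([0.9])
        assert classify_nn(index, q, "g") == "b"
        assert "a" in candidate_pool(index, q, "g", K=2)


class TestMajority:
    def test_plain_majority(self):
        index = make_index(
            [[0.0], [1.0]], labels=[{"s": "a"}, {"s": "b"}]
        )
        queries = np.array([[0.1], [0.2], [0.9]])  # votes a, a, b
        assert majority_classify(index, queries, "s") == "a"

    def test_tie_broken_by_best_distance(self):
        index = make_index([[0.0], [1.0]], labels=[{"s": "a"}, {"s": "b"}])
        # one vote each; a's winning distance 0.05 beats b's 0.2
        queries = np.array([[0.05], [0.8]])
        assert majority_classify(index, queries, "s") == "a"

    def test_empty_queries_rejected(self):
        index = make_index([[0.0]], labels=[{"s": "a"}])
        with pytest.raises(ValueError):
            majority_classify(index, np.empty((0, 1)), "s")


class TestConsensusHosts:
    @staticmethod
    def _index():
        labels = [{"genus": g} for g in ["g1", "g1", "g2", "g3"]]
        return make_index([[0.0], [0.1], [0.2], [0.3]], labels=labels)

    def test_min_count_two(self):
        assert consensus_hosts(self._index(), np.array([0.0]), 4, 2) == ["g1"]

    def test_min_count_one_gives_all_distinct(self):
        got = consensus_hosts(self._index(), np.array([0.0]), 4, 1)
        assert set(got) == {"g1", "g2", "g3"}
        assert got[0] == "g1"  # highest count first

    def test_empty_consensus_possible(self):
        labels = [{"genus": g} for g in ["a", "b", "c"]]
        index = make_index([[0.0], [1.0], [2.0]], labels=labels)
        assert consensus_hosts(index, np.array([0.0]), 3, 2) == []

    def test_superset_of_candidate_pool(self, rng):
        labels = [{"genus": f"g{i % 5}"} for i in range(30)]
        index = make_index(rng.normal(size=(30, 3)), labels=labels)
        for q in rng.normal(size=(5, 3)):
            pool = candidate_pool(index, q, "genus", K=10)
            cons = consensus_hosts(index, q, n_neighbors=10, min_count=1)
            assert set(pool) <= set(cons)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            consensus_hosts(self._index(), np.array([0.0]), 1, 2)


class TestCalibrate:
    def test_constant_set_size_corpus(self):
        # every neighbor has a distinct genus: consensus size with
        # min_count=1 equals n, so the calibrated n equals the target
        labels = [{"genus": f"g{i}"} for i in range(10)]
        index = make_index([[float(i)] for i in range(10)], labels=labels)
        queries = np.array([[0.0], [9.0]])
        n = calibrate_neighbor_count(index, queries, 1, 3.0, n_range=range(1, 8))
        assert n == 3

    def test_mean_size_monotone_in_n(self, rng):
        labels = [{"genus": f"g{i % 6}"} for i in range(40)]
        index = make_index(rng.normal(size=(40, 3)), labels=labels)
        queries = rng.normal(size=(8, 3))
        means = []
        for n in range(2, 30, 4):
            sizes = [len(consensus_hosts(index, q, n, 2)) for q in queries]
            means.append(np.mean(sizes))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestEvaluate:
    @staticmethod
    def _preds(outcomes):
        return [
            Prediction(query_id=f"q{i}", neighbors=[], predicted={"s": p}, candidates=[p])
            for i, p in enumerate(outcomes)
        ]

    def test_all_correct(self):
        truth = {f"q{i}": {"s": "a"} for i in range(4)}
        report = evaluate(self._preds(["a"] * 4), truth, "s")
        assert report.top1_pct[0] == 100.0

    def test_none_correct(self):
        truth = {f"q{i}": {"s": "a"} for i in range(4)}
        report = evaluate(self._preds(["b"] * 4), truth, "s")
        assert report.top1_pct[0] == 0.0

    def test_two_of_three(self):
        truth = {f"q{i}": {"s": "a"} for i in range(3)}
        report = evaluate(self._preds(["a", "a", "b"]), truth, "s")
        assert abs(report.top1_pct[0] - 66.7) < 0.05

    def test_no_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate(self._preds(["a"]), {}, "s")


def test_predict_training_vector_exact_match(rng):
    vecs = rng.normal(size=(10, 4))
    index = make_index(vecs, labels=[{"s": f"l{i}"} for i in range(10)])
    preds = predict(index, ["q"], vecs[3][None, :], "s", K_pool=5)
    assert preds[0].neighbors[0].distance < 1e-8
    assert preds[0].predicted["s"] == "l3"


def test_same_genome_self_similarity_probe():
    """Chunks of one genome share a compositional signature: the nearest
    non-self chunk comes from the same genome in the large majority of
    cases on a corpus with pronounced per-genome signatures."""
    bench = make_benchmark(
        n_species=5, genomes_per_species=2, genome_length=200000,
        seed=201, genome_concentration=10.0,
    )
    feats = prepare_features(bench.corpus, PipelineConfig(), chunk=True)
    assert same_genome_neighbor_rate(feats) >= 0.70
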